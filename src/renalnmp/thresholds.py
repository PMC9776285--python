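"""Critical-threshold analysis by piecewise regression.

The oxygen-extraction-vs-delivery relationship of a perfused kidney is
biphasic: extraction is roughly flow-independent while delivery is adequate
and rises steeply once delivery falls below a critical value.  The critical
point is estimated as the intersection of a two-segment least-squares fit,
and the companion thresholds (critical flow, consumption, pressure) are
propagated through the fitted marker relationships:

* RBF_crit by substituting DO2_crit into the linear RBF~DO2 fit,
* VO2_crit as (ERO2_crit/100) * DO2_crit,
* AP_crit as the smaller real root of the quadratic RBF~AP fit solved at
  RBF_crit (the smaller root lies inside the observed pressure range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LineFit", "Poly2Fit", "TwoSegmentFit", "CriticalPoints",
    "fit_line", "fit_two_segment", "fit_poly2", "intersect_lines",
    "propagate_critical", "class_time_means",
]


@dataclass
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    x_range: tuple[float, float]

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class Poly2Fit:
    a: float            # quadratic coefficient
    b: float
    c: float
    r_squared: float
    x_range: tuple[float, float]

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x * x + self.b * x + self.c


@dataclass
class TwoSegmentFit:
    left: LineFit
    right: LineFit
    breakpoint: float
    no_breakpoint: bool = False


@dataclass
class CriticalPoints:
    """Critical marker values; ``raw`` carries the unrounded chain."""

    do2_crit: float     # mL/min/100 g
    ero2_crit: float    # percent
    rbf_crit: float     # mL/min/100 g
    vo2_crit: float     # mL/min/100 g
    ap_crit: float      # mmHg
    raw: Optional["CriticalPoints"] = None


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def _as_xy(xs, ys) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    return xs[ok], ys[ok]


def fit_line(xs: Sequence[float], ys: Sequence[float]) -> LineFit:
    """Ordinary least squares line; R² is the squared Pearson correlation.

    A constant response is returned as slope 0 with R² = 0.
    """
    xs, ys = _as_xy(xs, ys)
    if np.unique(xs).size < 2:
        raise ValueError("need at least 2 distinct x values")
    if np.ptp(ys) == 0.0:
        return LineFit(0.0, float(ys[0]), 0.0, (float(xs.min()), float(xs.max())))
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return LineFit(float(slope), float(intercept), float(r * r),
                   (float(xs.min()), float(xs.max())))


def fit_poly2(xs: Sequence[float], ys: Sequence[float]) -> Poly2Fit:
    """Least-squares degree-2 polynomial with coefficient-of-determination R²."""
    xs, ys = _as_xy(xs, ys)
    if np.unique(xs).size < 3:
        raise ValueError("need at least 3 distinct x values")
    a, b, c = np.polyfit(xs, ys, 2)
    resid = ys - (a * xs * xs + b * xs + c)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return Poly2Fit(float(a), float(b), float(c), r2,
                    (float(xs.min()), float(xs.max())))


def _sse(fit: LineFit, xs: np.ndarray, ys: np.ndarray) -> float:
    return float(np.sum((ys - fit(xs)) ** 2))


def fit_two_segment(xs: Sequence[float], ys: Sequence[float],
                    rel_tol: float = 1e-9) -> TwoSegmentFit:
    """Two-segment OLS with exhaustive breakpoint search.

    Candidate breakpoints are the midpoints between consecutive distinct
    sorted x values such that each side keeps at least two distinct x; the
    candidate minimizing total SSE wins (ties go to the smaller breakpoint).
    Data that a single line explains equally well are flagged
    ``no_breakpoint`` with both segments equal to the global fit.
    """
    xs, ys = _as_xy(xs, ys)
    ux = np.unique(xs)
    if ux.size < 4:
        raise ValueError("need at least 4 distinct x values spanning a breakpoint")
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]

    best: tuple[float, float, LineFit, LineFit] | None = None
    for i in range(1, ux.size - 2):
        b = 0.5 * (ux[i] + ux[i + 1])
        lmask = xs < b
        left = fit_line(xs[lmask], ys[lmask])
        right = fit_line(xs[~lmask], ys[~lmask])
        sse = _sse(left, xs[lmask], ys[lmask]) + _sse(right, xs[~lmask], ys[~lmask])
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, left, right)
    assert best is not None
    sse2, bkp, left, right = best

    single = fit_line(xs, ys)
    sse1 = _sse(single, xs, ys)
    scale = float(np.sum((ys - ys.mean()) ** 2)) or 1.0
    if sse2 >= sse1 - rel_tol * scale:
        return TwoSegmentFit(single, single, float(bkp), no_breakpoint=True)
    return TwoSegmentFit(left, right, float(bkp))


def intersect_lines(a: LineFit, b: LineFit) -> tuple[float, float]:
    """Intersection point of two fitted lines; parallel lines are an error."""
    denom = a.slope - b.slope
    scale = max(abs(a.slope), abs(b.slope), 1.0)
    if abs(denom) < 1e-12 * scale:
        raise ValueError("lines are parallel (or identical); no intersection")
    x = (b.intercept - a.intercept) / denom
    return float(x), float(a.slope * x + a.intercept)


def _smaller_quadratic_root(fit: Poly2Fit, target: float) -> float:
    """Smaller real root x of a*x^2 + b*x + c = target."""
    a, b, c = fit.a, fit.b, fit.c - target
    if a == 0:
        if b == 0:
            raise ValueError("degenerate quadratic")
        return -c / b
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("quadratic has no real root at the critical flow")
    r = math.sqrt(disc)
    return min((-b - r) / (2.0 * a), (-b + r) / (2.0 * a))


def propagate_critical(
    ero2_do2: TwoSegmentFit,
    rbf_do2: LineFit,
    rbf_ap: Poly2Fit,
) -> CriticalPoints:
    """Derive all critical thresholds from the fitted marker relations.

    The reported values follow the study's printed precision (one decimal
    for DO2/VO2, integers for percent extraction, flow and pressure) and the
    rounded values are substituted stepwise, mirroring how the printed
    thresholds chain into one another; the fully unrounded chain is attached
    as ``.raw``.
    """
    if ero2_do2.no_breakpoint:
        raise ValueError("ERO2~DO2 relation has no breakpoint; "
                         "no critical point exists")
    do2_raw, ero2_raw = intersect_lines(ero2_do2.left, ero2_do2.right)
    if do2_raw <= 0 or ero2_raw <= 0:
        raise ValueError("critical point is non-positive")

    rbf_raw = float(rbf_do2(do2_raw))
    vo2_raw = ero2_raw / 100.0 * do2_raw
    ap_raw = _smaller_quadratic_root(rbf_ap, rbf_raw)
    raw = CriticalPoints(do2_raw, ero2_raw, rbf_raw, vo2_raw, ap_raw)

    do2 = _round_half_up(do2_raw, 1)
    ero2 = _round_half_up(ero2_raw, 0)
    rbf = _round_half_up(float(rbf_do2(do2)), 0)
    vo2 = _round_half_up(ero2 / 100.0 * do2, 1)
    ap = _round_half_up(_smaller_quadratic_root(rbf_ap, rbf), 0)
    return CriticalPoints(do2, ero2, rbf, vo2, ap, raw=raw)


def class_time_means(pooled, x_marker: str, y_marker: str,
                     scale_y: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Class-by-time mean scatter for a marker pair.

    ``pooled`` is the long frame from :func:`renalnmp.markers.pool_tables`;
    each point is the mean over kidneys of one function class at one
    analysis time, the same aggregation used to draw the study's scatter
    relationships (3 classes x 12 times).
    """
    g = pooled.groupby(["function_class", "t_min"])[[x_marker, y_marker]].mean()
    g = g.dropna()
    return g[x_marker].to_numpy(), g[y_marker].to_numpy() * scale_y
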