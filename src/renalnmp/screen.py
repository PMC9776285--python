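"""Per-marker, per-time-point three-class significance screening.

Each (marker, time) cell is tested for class differences with a routed
procedure: if every class group passes Shapiro-Wilk normality (p > 0.05),
homoscedasticity decides between classical ANOVA with Bonferroni-corrected
pairwise t tests (Levene p > 0.05) and Welch ANOVA with Games-Howell post
hocs (Levene p <= 0.05); any non-normal group routes the cell to
Kruskal-Wallis with Dunn's rank test and Sidak correction.  Routing is
exhaustive and mutually exclusive.  No multiplicity correction is applied
across markers or time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerTable
from .records import GRID_20MIN, GRID_60MIN, MARKERS_20MIN, MARKER_ORDER

__all__ = ["RouteResult", "SignificanceMap", "route_and_test",
           "build_significance_map", "dunn_sidak"]

PAIRS: tuple[tuple[int, int], ...] = ((1, 3), (2, 3), (1, 2))


def _pair_label(a: int, b: int) -> str:
    return f"{a}v{b}"


@dataclass
class RouteResult:
    route: str                       # anova | welch | kruskal
    omnibus_p: float
    pairwise: dict[tuple[int, int], float]


@dataclass
class SignificanceMap:
    """(marker, time, class pair) -> p-value and significance flag."""

    alpha: float
    table: pd.DataFrame  # columns: marker, t_min, pair, route, p, significant

    def significant_cells(self, pair_rule: str = "class3") -> pd.DataFrame:
        """Distinct (marker, t_min) cells deemed significant.

        ``pair_rule='class3'`` requires a significant contrast involving
        class 3 (1v3 or 2v3), the contrasts the study annotates;
        ``'any'`` accepts any pair.
        """
        t = self.table[self.table["significant"].astype(bool)]
        if pair_rule == "class3":
            t = t[t["pair"].isin(["1v3", "2v3"])]
        elif pair_rule != "any":
            raise ValueError(f"unknown pair rule {pair_rule!r}")
        return t[["marker", "t_min"]].drop_duplicates().reset_index(drop=True)


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    """True if the sample is consistent with normality (p > alpha)."""
    if np.ptp(x) == 0.0:
        return False  # degenerate sample: treat as non-normal
    return stats.shapiro(x).pvalue > alpha


def dunn_sidak(groups: Sequence[np.ndarray],
               labels: Sequence[int]) -> dict[tuple[int, int], float]:
    """Dunn's rank-based pairwise z tests with Sidak correction.

    Ranks are taken over the pooled sample with tie correction; each pairwise
    p is adjusted as 1 - (1 - p)^m with m the number of comparisons.
    """
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    idx = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[a:b].mean() for a, b in zip(idx, idx[1:])]

    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(tie_counts ** 3 - tie_counts))
    var_term = n_tot * (n_tot + 1) / 12.0 - ties / (12.0 * (n_tot - 1))

    m = len(list(combinations(range(len(groups)), 2)))
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_term * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        out[(labels[i], labels[j])] = float(1.0 - (1.0 - p) ** m)
    return out


def route_and_test(groups: Sequence[Sequence[float]],
                   labels: Sequence[int] = (1, 2, 3),
                   alpha: float = 0.05) -> RouteResult:
    """Routed omnibus + post-hoc testing of three class samples."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if any(a.size < 3 for a in arrs):
        raise ValueError("each group needs at least 3 observations")
    labels = list(labels)

    if all(_shapiro_normal(a, alpha) for a in arrs):
        if stats.levene(*arrs, center="median").pvalue <= alpha:
            return _welch_games_howell(arrs, labels)
        return _anova_bonferroni(arrs, labels)
    return _kruskal_dunn(arrs, labels)


def _welch_games_howell(arrs, labels) -> RouteResult:
    import pingouin as pg

    df = pd.DataFrame({
        "y": np.concatenate(arrs),
        "g": np.repeat(labels, [a.size for a in arrs]),
    })
    omnibus = float(pg.welch_anova(dv="y", between="g", data=df)["p_unc"][0])
    gh = pg.pairwise_gameshowell(dv="y", between="g", data=df)
    pw = {}
    for _, row in gh.iterrows():
        key = tuple(sorted((int(row["A"]), int(row["B"]))))
        pw[key] = float(row["pval"])
    return RouteResult("welch", omnibus, pw)


def _anova_bonferroni(arrs, labels) -> RouteResult:
    omnibus = float(stats.f_oneway(*arrs).pvalue)
    m = len(list(combinations(range(len(arrs)), 2)))
    pw = {}
    for i, j in combinations(range(len(arrs)), 2):
        p = stats.ttest_ind(arrs[i], arrs[j], equal_var=True).pvalue
        pw[(labels[i], labels[j])] = float(min(1.0, p * m))
    return RouteResult("anova", omnibus, pw)


def _kruskal_dunn(arrs, labels) -> RouteResult:
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        # all observations identical: nothing to distinguish
        pw = {tuple(sorted((labels[i], labels[j]))): 1.0
              for i, j in combinations(range(len(arrs)), 2)}
        return RouteResult("kruskal", 1.0, pw)
    omnibus = float(stats.kruskal(*arrs).pvalue)
    return RouteResult("kruskal", omnibus, dunn_sidak(arrs, labels))


def build_significance_map(
    tables: Sequence[MarkerTable],
    alpha: float = 0.05,
    min_n: int = 3,
    markers: Optional[Sequence[str]] = None,
) -> SignificanceMap:
    """Screen every (marker, time) cell of a cohort.

    Missing values are dropped listwise within each class group; cells where
    any class falls below ``min_n`` observations are flagged untestable
    (route 'untestable', NaN p-values) rather than failing the run.
    """
    classes = sorted({t.function_class for t in tables})
    if len(classes) < 2:
        raise ValueError("need at least two classes to screen")
    markers = list(markers) if markers is not None else list(MARKER_ORDER)

    rows = []
    for marker in markers:
        grid = GRID_20MIN if marker in MARKERS_20MIN else GRID_60MIN
        for t in grid:
            groups, labels = [], []
            for cls in classes:
                vals = np.array([
                    tab.frame.loc[t, marker] for tab in tables
                    if tab.function_class == cls
                ], dtype=float)
                vals = vals[np.isfinite(vals)]
                groups.append(vals)
                labels.append(cls)
            if any(g.size < min_n for g in groups):
                for a, b in PAIRS:
                    rows.append((marker, t, _pair_label(a, b),
                                 "untestable", np.nan, False))
                continue
            res = route_and_test(groups, labels, alpha)
            for a, b in PAIRS:
                p = res.pairwise.get((a, b), np.nan)
                rows.append((marker, t, _pair_label(a, b), res.route,
                             p, bool(np.isfinite(p) and p <= alpha)))

    table = pd.DataFrame(
        rows, columns=["marker", "t_min", "pair", "route", "p", "significant"])
    return SignificanceMap(alpha=alpha, table=table)
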