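"""Core data containers for normothermic machine perfusion (NMP) experiments.

One perfusion experiment is a :class:`KidneyRecord`: a continuously sampled
hemodynamic stream (renal blood flow, arterial pressure, kidney temperature),
arterial and venous blood-gas panels on a 20-min grid, urea/GST assays and
cumulative urine volume on a 60-min grid, plus identity metadata (weight,
ischemia times, reference function class, train/test split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Analysis grid for hemodynamic and blood-gas markers (minutes).
GRID_20MIN: tuple[int, ...] = tuple(range(20, 241, 20))
#: Analysis grid for urea, urine production and GST (minutes).
GRID_60MIN: tuple[int, ...] = (60, 120, 180, 240)
#: Blood sampling times: baseline plus the 20-min grid (13 sample times).
PANEL_TIMES: tuple[int, ...] = (0,) + GRID_20MIN

#: Markers derived on the 20-min grid.
MARKERS_20MIN: tuple[str, ...] = (
    "do2", "vo2", "ero2", "co2p", "rbf", "ap", "irr", "t_kidney",
)
#: Markers derived on the 60-min grid.
MARKERS_60MIN: tuple[str, ...] = ("rel_urea", "urine_rate", "rel_gst")
#: Canonical marker order (also the tie-break order for the VIF filter).
MARKER_ORDER: tuple[str, ...] = MARKERS_20MIN + MARKERS_60MIN

FUNCTION_CLASSES: tuple[int, ...] = (1, 2, 3)

WIT_RANGE_MIN = (4.0, 185.0)    # warm ischemia, minutes
CIT_RANGE_MIN = (94.0, 790.0)   # cold ischemia, minutes


@dataclass
class BloodGasPanel:
    """One arterial or venous blood-gas measurement at a sampling time.

    Parameters mirror a point-of-care blood gas analyzer read-out:
    partial pressures in mmHg, saturation in percent, hemoglobin in g/dL.
    """

    site: str               # "arterial" | "venous"
    t: float                # minutes since perfusion start
    po2: float              # mmHg
    so2: float              # % (0-100)
    hb: float               # g/dL
    ph: float
    pco2: float             # mmHg

    def __post_init__(self) -> None:
        if self.site not in ("arterial", "venous"):
            raise ValueError(f"unknown sampling site {self.site!r}")
        if not (0.0 <= self.so2 <= 100.0):
            raise ValueError(f"sO2 must be within 0-100%, got {self.so2}")
        if self.po2 <= 0 or self.pco2 <= 0 or self.hb <= 0:
            raise ValueError("pO2, pCO2 and hemoglobin must be positive")
        if not (6.5 < self.ph < 8.0):
            raise ValueError(f"pH {self.ph} outside plausible range (6.5, 8.0)")


@dataclass
class HemoStream:
    """Continuously sampled hemodynamics sharing one time base (minutes)."""

    t_min: np.ndarray       # strictly increasing, 0 .. 240 min
    rbf: np.ndarray         # renal blood flow, mL/min (raw, not per 100 g)
    ap: np.ndarray          # arterial pressure, mmHg
    t_kidney: np.ndarray    # kidney temperature, deg C
    dt_s: float = 0.2

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.rbf = np.asarray(self.rbf, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.t_kidney = np.asarray(self.t_kidney, dtype=float)
        n = self.t_min.size
        if n == 0:
            raise ValueError("empty hemodynamic stream")
        if not (self.rbf.size == self.ap.size == self.t_kidney.size == n):
            raise ValueError("hemodynamic series lengths differ")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("time base must be strictly increasing")
        if np.any(self.rbf < 0):
            raise ValueError("renal blood flow must be non-negative")
        if np.any(self.ap <= 0):
            raise ValueError("arterial pressure must be positive")

    def channel(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown hemodynamic channel {name!r}") from None


@dataclass
class AssaySample:
    """One plasma assay value (urea concentration or GST activity)."""

    analyte: str            # "urea" | "gst"
    t: float                # minutes
    value: float            # concentration / activity, consistent units, > 0

    def __post_init__(self) -> None:
        if self.analyte not in ("urea", "gst"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.value <= 0:
            raise ValueError("assay value must be positive")


@dataclass
class UrineSample:
    """Cumulative urine volume collected up to time t."""

    t: float                # minutes
    cumulative_volume: float  # mL, non-decreasing over samples

    def __post_init__(self) -> None:
        if self.cumulative_volume < 0:
            raise ValueError("cumulative urine volume must be non-negative")


@dataclass
class KidneyRecord:
    """One NMP experiment: raw measurements plus identity metadata."""

    kidney_id: str
    function_class: int     # 1 nonfunctional / 2 limited / 3 functional
    weight_g: float
    wit_min: float          # warm ischemia time
    cit_min: float          # cold ischemia time
    split: str              # "train" | "test"
    hemo: HemoStream
    panels: list[BloodGasPanel] = field(default_factory=list)
    assays: list[AssaySample] = field(default_factory=list)
    urine: list[UrineSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise ValueError(f"unknown function class {self.function_class}")
        if self.weight_g <= 0:
            raise ValueError("kidney weight must be positive")
        if self.split not in ("train", "test"):
            raise ValueError(f"unknown split {self.split!r}")
        urine_t = [u.t for u in self.urine]
        if urine_t != sorted(urine_t):
            raise ValueError("urine samples must be time-ordered")
        vols = [u.cumulative_volume for u in self.urine]
        if any(b < a - 1e-9 for a, b in zip(vols, vols[1:])):
            raise ValueError("cumulative urine volume must be non-decreasing")

    def panel_at(self, site: str, t: float) -> Optional[BloodGasPanel]:
        """Panel for a site at time t (minutes), or None if it is missing."""
        for p in self.panels:
            if p.site == site and abs(p.t - t) < 1e-9:
                return p
        return None

    def assay_series(self, analyte: str) -> list[AssaySample]:
        return sorted(
            (a for a in self.assays if a.analyte == analyte), key=lambda a: a.t
        )


def stratified_split_counts(
    n_per_class: Sequence[int], test_fraction: float
) -> list[int]:
    """Per-class test-set sizes by largest-remainder apportionment.

    The overall test-set size is ``round(test_fraction * n_total)``; per-class
    quotas ``test_fraction * n_c`` are floored and the leftover seats go to
    the largest fractional remainders (ties broken by class order).
    """
    n_per_class = list(n_per_class)
    total_test = int(round(test_fraction * sum(n_per_class)))
    quotas = [test_fraction * n for n in n_per_class]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = total_test - sum(counts)
    for idx in sorted(range(len(counts)), key=lambda i: -remainders[i])[:leftover]:
        counts[idx] += 1
    # never hold out a whole class
    for i, (c, n) in enumerate(zip(counts, n_per_class)):
        if c >= n:
            counts[i] = n - 1
    return counts
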