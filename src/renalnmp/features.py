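"""Multicollinearity filtering and feature-matrix construction.

The variance inflation factor of marker j is the j-th diagonal element of
the inverse correlation matrix of the per-kidney marker summary (equivalent
to 1/(1 - R²_j) from regressing marker j on the others).  Markers whose VIF
exceeds the threshold are removed one at a time - always the current
maximum, ties broken by canonical marker order - until all remaining VIFs
are acceptable.

Feature matrices (kidneys x (marker, time) columns) come in five variants:
variant A uses every grid time of each eligible marker up to 240 min;
variants B-E restrict to the (marker, time) cells flagged significant, with
time cutoffs 240/180/120/60 min respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .markers import MarkerTable
from .records import GRID_20MIN, GRID_60MIN, MARKERS_20MIN, MARKER_ORDER
from .screen import SignificanceMap

__all__ = [
    "FeatureMatrix", "marker_summary", "vif", "vif_filter",
    "interpolate_missing", "build_variant", "standardize",
]

VARIANT_CUTOFF_MIN = {"A": 240, "B": 240, "C": 180, "D": 120, "E": 60}


@dataclass
class FeatureMatrix:
    """Kidneys x features, each feature tagged (marker, time)."""

    variant: str
    X: pd.DataFrame                 # index kidney_id, columns "marker@t"
    y: pd.Series                    # function class per kidney
    split: pd.Series                # "train"/"test" per kidney
    tags: list[tuple[str, int]]     # (marker, t_min) per column

    def subset(self, split: str) -> tuple[pd.DataFrame, pd.Series]:
        mask = self.split == split
        return self.X.loc[mask], self.y.loc[mask]


def marker_summary(tables: Sequence[MarkerTable]) -> pd.DataFrame:
    """Per-kidney marker summary: time-mean over available grid points."""
    rows = {
        tab.kidney_id: tab.frame.mean(axis=0, skipna=True)
        for tab in tables
    }
    return pd.DataFrame(rows).T.loc[:, list(MARKER_ORDER)]


def vif(matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: diagonal of the inverse correlation matrix.

    Perfectly collinear columns are reported as infinite rather than raising.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 variables for VIF")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("VIF input must be complete (no missing values)")
    if np.any(np.std(x, axis=0) == 0.0):
        raise ValueError("VIF input has a zero-variance column")
    corr = np.corrcoef(x, rowvar=False)
    try:
        diag = np.diag(np.linalg.inv(corr))
        if np.all(diag >= 1.0 - 1e-8):
            return pd.Series(diag, index=matrix.columns)
    except np.linalg.LinAlgError:
        pass
    # singular correlation matrix: fall back to per-column R^2
    out = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(len(x)), others])
        beta, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
        resid = x[:, j] - design @ beta
        ss_tot = float(np.sum((x[:, j] - x[:, j].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.Series(out, index=matrix.columns)


def vif_filter(
    matrix: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative VIF elimination.

    Removes exactly the maximum-VIF variable per pass (ties broken by the
    canonical marker order, then column order) and recomputes until every
    remaining VIF is <= threshold or fewer than two variables remain.
    Returns the retained variable names and a removal log.
    """
    cols = list(matrix.columns)
    log_rows = []
    step = 0
    while len(cols) >= 2:
        v = vif(matrix[cols])
        if v.max() <= threshold:
            break
        step += 1
        worst = v.max()
        candidates = [c for c in cols if v[c] >= worst - 1e-12]
        order = {m: i for i, m in enumerate(MARKER_ORDER)}
        candidates.sort(key=lambda c: (order.get(str(c).split("@")[0], 99),
                                       cols.index(c)))
        removed = candidates[0]
        log_rows.append({"step": step, "removed": removed,
                         "vif": float(v[removed])})
        cols.remove(removed)
    log = pd.DataFrame(log_rows, columns=["step", "removed", "vif"])
    return cols, log


def interpolate_missing(tables: Sequence[MarkerTable]) -> list[MarkerTable]:
    """Fill missing marker values per kidney by linear interpolation in time.

    Interior gaps are interpolated linearly; edge gaps take the nearest
    observed value.  Only each marker's own grid is touched.  Markers with
    no observation at all for a kidney remain missing.
    """
    out = []
    for tab in tables:
        frame = tab.frame.copy()
        for marker in frame.columns:
            grid = list(GRID_20MIN if marker in MARKERS_20MIN else GRID_60MIN)
            s = frame.loc[grid, marker]
            if s.notna().any():
                s = s.interpolate(method="index", limit_direction="both")
                frame.loc[grid, marker] = s
        out.append(MarkerTable(tab.kidney_id, tab.function_class,
                               tab.weight_g, tab.split, frame))
    return out


def build_variant(
    tables: Sequence[MarkerTable],
    sig_map: SignificanceMap,
    variant: str,
    retained_markers: Sequence[str],
    pair_rule: str = "class3",
) -> FeatureMatrix:
    """Assemble one feature-matrix variant.

    A marker is eligible iff it survived the VIF filter and is significant
    (per ``pair_rule``) at at least one time point.  Variant A expands every
    eligible marker over its full grid; variants B-E keep only the
    significant (marker, time) cells within the variant's time cutoff.
    Columns are ordered by (canonical marker order, time).
    """
    variant = variant.upper()
    if variant not in VARIANT_CUTOFF_MIN:
        raise ValueError(f"unknown variant {variant!r}")
    cutoff = VARIANT_CUTOFF_MIN[variant]
    sig_cells = sig_map.significant_cells(pair_rule)
    sig_set = {(m, int(t)) for m, t in sig_cells.itertuples(index=False)}

    eligible = [m for m in retained_markers if any(c[0] == m for c in sig_set)]
    cells: list[tuple[str, int]] = []
    for m in eligible:
        grid = GRID_20MIN if m in MARKERS_20MIN else GRID_60MIN
        for t in grid:
            if t > cutoff:
                continue
            if variant == "A" or (m, t) in sig_set:
                cells.append((m, t))
    order = {m: i for i, m in enumerate(MARKER_ORDER)}
    cells.sort(key=lambda c: (order.get(c[0], 99), c[1]))
    if not cells:
        raise ValueError(f"variant {variant} has no features")

    filled = interpolate_missing(tables)
    data, ids, ys, splits = {}, [], [], []
    for tab in filled:
        ids.append(tab.kidney_id)
        ys.append(tab.function_class)
        splits.append(tab.split)
    for m, t in cells:
        data[f"{m}@{t}"] = [tab.frame.loc[t, m] for tab in filled]
    X = pd.DataFrame(data, index=pd.Index(ids, name="kidney_id"))
    # listwise completion: a marker entirely missing for one kidney falls
    # back to the column mean so no kidney is dropped from the small cohort
    if X.isna().any().any():
        X = X.fillna(X.mean(axis=0))
    return FeatureMatrix(
        variant=variant, X=X,
        y=pd.Series(ys, index=X.index, name="function_class"),
        split=pd.Series(splits, index=X.index, name="split"),
        tags=cells,
    )


def standardize(
    train: pd.DataFrame, other: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, Optional[pd.DataFrame], StandardScaler]:
    """Z-score columns with mean/SD fitted on the training rows only.

    Zero-variance training columns are dropped (with a warning) from both
    matrices, since they carry no information and break scaling.
    """
    variances = train.var(axis=0, ddof=0)
    keep = variances[variances > 0].index
    if len(keep) < train.shape[1]:
        warnings.warn(
            f"dropping {train.shape[1] - len(keep)} zero-variance columns",
            stacklevel=2)
    train = train[keep]
    scaler = StandardScaler().fit(train.to_numpy())
    train_z = pd.DataFrame(scaler.transform(train.to_numpy()),
                           index=train.index, columns=train.columns)
    other_z = None
    if other is not None:
        other = other[keep]
        other_z = pd.DataFrame(scaler.transform(other.to_numpy()),
                               index=other.index, columns=other.columns)
    return train_z, other_z, scaler
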