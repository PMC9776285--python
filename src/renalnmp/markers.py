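"""Derivation of the eleven perfusion function/injury markers.

Oxygen metabolism follows the Fick principle: arterial oxygen content
C_aO2 = 1.34 * c(Hb) * sO2/100 + 0.0031 * pO2 (Hüfner constant 1.34 mL O2
per g Hb, plasma solubility 0.0031 mL/(mmHg*dL)); oxygen delivery
DO2 = RBF * C_aO2, consumption VO2 = RBF * (C_aO2 - C_vO2), extraction
ERO2 = VO2/DO2.  CO2 production uses whole-blood CO2 content from the
Douglas model.  Hemodynamic markers (RBF, AP, IRR = AP/RBF, T_kidney) are
window means of the continuous stream (analysis time +/- 2 min).  Filtration
markers are baseline-relative urea, per-interval urine production, and
baseline-relative GST.  All flow/volume/oxygen markers are normalized to a
kidney weight of 100 g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    GRID_20MIN,
    GRID_60MIN,
    MARKER_ORDER,
    AssaySample,
    BloodGasPanel,
    HemoStream,
    KidneyRecord,
)

__all__ = [
    "HUEFNER", "O2_SOLUBILITY", "MarkerTable",
    "oxygen_content", "oxygen_delivery", "oxygen_consumption",
    "oxygen_extraction", "co2_content", "co2_production",
    "intrarenal_resistance", "window_mean", "relative_series",
    "derive_marker_table", "pool_tables",
]

HUEFNER = 1.34          # mL O2 bound per g hemoglobin
O2_SOLUBILITY = 0.0031  # mL O2 / (mmHg * dL) dissolved in plasma
ML_PER_MMOL_CO2 = 22.26


def oxygen_content(panel: BloodGasPanel, hb_median: float) -> float:
    """Blood O2 content in mL/dL from saturation, pO2 and the kidney's
    median hemoglobin concentration."""
    if hb_median <= 0:
        raise ValueError("median hemoglobin must be positive")
    return HUEFNER * hb_median * panel.so2 / 100.0 + O2_SOLUBILITY * panel.po2


def oxygen_delivery(rbf: float, cao2: float, weight_g: float) -> float:
    """Oxygen delivery DO2 in mL O2/min per 100 g.

    ``rbf`` is raw flow in mL/min, ``cao2`` in mL/dL; the /100 converts the
    content denominator from dL to mL of blood.
    """
    if weight_g <= 0:
        raise ValueError("kidney weight must be positive")
    if rbf < 0:
        raise ValueError("renal blood flow must be non-negative")
    return rbf * cao2 / 100.0 / (weight_g / 100.0)


def oxygen_consumption(rbf: float, cao2: float, cvo2: float,
                       weight_g: float) -> float:
    """Fick-principle oxygen consumption VO2 in mL O2/min per 100 g.

    A venous content exceeding the arterial one is physically impossible in
    steady state and flags a measurement problem; the (negative) value is
    still returned with a warning.
    """
    if weight_g <= 0:
        raise ValueError("kidney weight must be positive")
    if rbf < 0:
        raise ValueError("renal blood flow must be non-negative")
    if cvo2 > cao2:
        warnings.warn(
            "venous O2 content exceeds arterial; negative VO2 returned",
            stacklevel=2)
    return rbf * (cao2 - cvo2) / 100.0 / (weight_g / 100.0)


def oxygen_extraction(vo2: float, do2: float) -> float:
    """Oxygen extraction ratio VO2/DO2 (fraction); NaN when DO2 is zero."""
    if do2 == 0:
        return float("nan")
    return vo2 / do2


def co2_content(panel: BloodGasPanel, temp_c: float = 37.0) -> float:
    """Whole-blood CO2 concentration in mL/L (Douglas model).

    Plasma CO2 (mmol/L) = s * pCO2 * (1 + 10**(pH - pK')) with the
    temperature-dependent solubility s and apparent pK', corrected to whole
    blood by the hemoglobin/saturation/pH ratio, then converted to mL/L.
    Monotonically increasing in pCO2 at fixed pH, Hb, sO2.
    """
    ph, pco2 = panel.ph, panel.pco2
    if not (6.8 <= ph <= 7.8):
        raise ValueError(f"pH {ph} outside the model's validity range")
    dt = 37.0 - temp_c
    s = 0.0307 + 0.00057 * dt + 0.00002 * dt * dt
    pk = 6.086 + 0.042 * (7.4 - ph) + (38.0 - temp_c) * (
        0.00472 + 0.00139 * (7.4 - ph))
    plasma_mmol = s * pco2 * (1.0 + 10.0 ** (ph - pk))
    ratio = 1.0 - (0.0289 * panel.hb) / (
        (3.352 - 0.456 * panel.so2 / 100.0) * (8.142 - ph))
    return plasma_mmol * ratio * ML_PER_MMOL_CO2


def co2_production(rbf: float, cvco2: float, caco2: float,
                   weight_g: float) -> float:
    """CO2 production in mL CO2/min per 100 g.

    ``rbf`` in mL/min is converted to L/min to match the mL/L contents;
    negative values are meaningful (net CO2 conversion by the tissue).
    """
    if weight_g <= 0:
        raise ValueError("kidney weight must be positive")
    if rbf < 0:
        raise ValueError("renal blood flow must be non-negative")
    return (rbf / 1000.0) * (cvco2 - caco2) / (weight_g / 100.0)


def intrarenal_resistance(ap: float, rbf: float) -> float:
    """IRR = AP/RBF in mmHg/(mL/min); NaN when flow is zero.

    With ``rbf`` already normalized per 100 g the result is the per-100 g
    resistance used throughout the analysis.
    """
    if rbf == 0:
        return float("nan")
    return ap / rbf


def window_mean(stream: HemoStream, channel: str, t_center: float,
                half_width: float = 2.0) -> float:
    """Mean of a hemodynamic channel over [t_center - hw, t_center + hw].

    Both window edges are inclusive; the sampling interval drops out, so the
    operator is dt-agnostic.
    """
    t = stream.t_min
    lo, hi = t_center - half_width, t_center + half_width
    i0 = int(np.searchsorted(t, lo - 1e-12, side="left"))
    i1 = int(np.searchsorted(t, hi + 1e-12, side="right"))
    if i1 <= i0:
        raise ValueError(
            f"window [{lo}, {hi}] min contains no samples")
    return float(stream.channel(channel)[i0:i1].mean())


def relative_series(samples: list[AssaySample]) -> pd.Series:
    """Assay values as percent of the t=0 baseline (baseline maps to 100)."""
    if not samples:
        raise ValueError("empty assay series")
    by_t = sorted(samples, key=lambda a: a.t)
    base = [a for a in by_t if abs(a.t) < 1e-9]
    if not base:
        raise ValueError("no baseline sample at t = 0")
    b = base[0].value
    if b <= 0:
        raise ValueError("baseline assay value must be positive")
    # divide before scaling so the baseline maps to exactly 100.0
    return pd.Series({a.t: (a.value / b) * 100.0 for a in by_t})


@dataclass
class MarkerTable:
    """Per-kidney derived markers on the analysis time grid.

    ``frame`` is indexed by analysis time (minutes) and has one column per
    marker; 60-min-grid markers are NaN off their grid, as are markers whose
    blood-gas panels are missing (no imputation here).
    """

    kidney_id: str
    function_class: int
    weight_g: float
    split: str
    frame: pd.DataFrame

    def values_at(self, marker: str, times=None) -> pd.Series:
        s = self.frame[marker]
        return s if times is None else s.loc[list(times)]


def derive_marker_table(record: KidneyRecord, half_width: float = 2.0) -> MarkerTable:
    """Compute all eleven markers for one kidney.

    The per-kidney hemoglobin median is taken once over every panel of the
    experiment and reused in every oxygen-content evaluation.  Missing
    blood-gas panels leave the oxygen/CO2 markers missing at that time point
    without aborting the table.
    """
    w = record.weight_g
    w100 = w / 100.0
    hbs = [p.hb for p in record.panels]
    hb_med = float(np.median(hbs)) if hbs else float("nan")

    frame = pd.DataFrame(index=pd.Index(list(GRID_20MIN), name="t_min"),
                         columns=list(MARKER_ORDER), dtype=float)

    for t in GRID_20MIN:
        rbf_raw = window_mean(record.hemo, "rbf", t, half_width)
        ap = window_mean(record.hemo, "ap", t, half_width)
        tk = window_mean(record.hemo, "t_kidney", t, half_width)
        rbf_n = rbf_raw / w100
        frame.loc[t, "rbf"] = rbf_n
        frame.loc[t, "ap"] = ap
        frame.loc[t, "t_kidney"] = tk
        frame.loc[t, "irr"] = intrarenal_resistance(ap, rbf_n)

        pa = record.panel_at("arterial", t)
        pv = record.panel_at("venous", t)
        if pa is None or pv is None:
            continue
        cao2 = oxygen_content(pa, hb_med)
        cvo2 = oxygen_content(pv, hb_med)
        do2 = oxygen_delivery(rbf_raw, cao2, w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vo2 = oxygen_consumption(rbf_raw, cao2, cvo2, w)
        frame.loc[t, "do2"] = do2
        frame.loc[t, "vo2"] = vo2
        frame.loc[t, "ero2"] = oxygen_extraction(vo2, do2)
        try:
            frame.loc[t, "co2p"] = co2_production(
                rbf_raw, co2_content(pv, tk), co2_content(pa, tk), w)
        except ValueError:
            pass  # CO2 model out of validity at this time point: left missing

    for analyte, col in (("urea", "rel_urea"), ("gst", "rel_gst")):
        series = record.assay_series(analyte)
        if series:
            rel = relative_series(series)
            for t in GRID_60MIN:
                if t in rel.index:
                    frame.loc[t, col] = rel[t]

    vols = {u.t: u.cumulative_volume for u in record.urine}
    prev = 0.0
    for t in GRID_60MIN:
        if t in vols:
            frame.loc[t, "urine_rate"] = (vols[t] - prev) / w100  # mL/h/100 g
            prev = vols[t]

    return MarkerTable(
        kidney_id=record.kidney_id,
        function_class=record.function_class,
        weight_g=record.weight_g,
        split=record.split,
        frame=frame,
    )


def pool_tables(tables: list[MarkerTable]) -> pd.DataFrame:
    """Long-format pool of all kidneys' marker tables.

    Columns: kidney_id, function_class, split, t_min, one column per marker.
    """
    parts = []
    for tab in tables:
        df = tab.frame.reset_index()
        df.insert(0, "kidney_id", tab.kidney_id)
        df.insert(1, "function_class", tab.function_class)
        df.insert(2, "split", tab.split)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
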