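"""Synthetic NMP cohort generator.

Emulates the measurement schedule of a pressure-controlled porcine kidney
perfusion: a hemodynamic stream sampled every 0.2 s for four hours, arterial
and venous blood-gas panels every 20 min, urea and GST assays plus cumulative
urine volume every 60 min.

The physiologically primitive latent quantity is the intrarenal resistance
(IRR) trajectory; flow and pressure follow from it through the perfusion
controller: the pump targets an arterial pressure of 100-110 mmHg by setting
flow to ``AP_set / IRR``, but never reduces raw flow below an operator floor,
so a kidney whose resistance keeps rising ends up pressure-elevated at the
flow floor instead of pressure-regulated.  Class-conditional IRR, oxygen
extraction, CO2 gap, urea clearance, urine output and GST release shapes
encode the three reference function classes:

* class 3 (functional): low, slowly falling resistance, flow held well above
  23 mL/min/100 g at the 100-110 mmHg setpoint, normothermic, rising oxygen
  consumption, urea cleared, transient GST release.
* class 2 (limited): intermediate early course, resistance climbing after
  ~100 min so flow declines below the critical 23 mL/min/100 g and the organ
  cools after ~120 min.
* class 1 (nonfunctional): resistance high from the start, flow pinned at the
  operator floor, pressure near/above 155 mmHg early, temperature below
  33.5 degC throughout, no urea clearance, elevated non-recovering GST.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .records import (
    CIT_RANGE_MIN,
    FUNCTION_CLASSES,
    GRID_20MIN,
    GRID_60MIN,
    PANEL_TIMES,
    WIT_RANGE_MIN,
    AssaySample,
    BloodGasPanel,
    HemoStream,
    KidneyRecord,
    UrineSample,
    stratified_split_counts,
)

__all__ = ["GeneratorConfig", "simulate_kidney", "simulate_cohort", "qc_exclude"]


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic cohort generator.

    Noise standard deviations are measurement-level; per-kidney biological
    spread is controlled by the ``*_sd`` random-effect fields.  Setting
    ``noise_scale`` to 0 collapses every random draw (measurement noise,
    random effects, ischemia times, panel dropout) to its central value, so
    two runs with different seeds produce identical records.
    """

    # schedule
    dt_s: float = 0.2
    duration_min: float = 240.0

    # perfusion controller
    ap_setpoint: float = 105.0        # mmHg, middle of the 100-110 band
    rbf_init: float = 50.0            # mL/min systemic flow while connecting
    init_hold_min: float = 2.0        # minutes at the initial systemic flow
    rbf_floor: float = 15.0           # mL/min, operator minimum raw flow
    controller_tau_s: float = 45.0    # first-order pump response

    # kidney-level random effects
    weight_mean_g: float = 105.0
    weight_sd_g: float = 12.0
    hb_mean: float = 6.2              # g/dL, autologous blood perfusate
    hb_sd: float = 1.8
    irr_scale_sd: float = 0.26        # lognormal sd of the IRR trajectory
    # oxygen demand: end-of-perfusion demand follows delivery sub-linearly
    # (bigger, better-perfused organs metabolize more, less than 1:1), and
    # the recovery trajectory toward it varies per kidney
    demand_exponent: float = 0.75     # dem_final ~ DO2_final ** exponent
    demand_sd: float = 0.09           # lognormal sd around the demand law
    extraction_target: float = 0.56   # extraction at reference delivery
    do2_reference: float = 4.6        # mL/min/100 g, reference delivery
    shape_s0: float = 0.62            # initial demand fraction at connection
    shape_s0_sd: float = 0.15
    shape_gamma_sd: float = 0.56      # lognormal sd of the recovery exponent
    extraction_max: float = 0.655      # supply-limited extraction ceiling
    extraction_max_sd: float = 0.14
    extraction_noise: float = 0.12   # per-panel extraction measurement error
    severity_wit_gain: float = 0.12   # WIT-linked within-class severity
    rbf_floor_sd: float = 3.2         # operator-to-operator flow floor spread
    t_blood_sd: float = 1.0           # heater setpoint spread, degC
    clearance_sd: float = 0.40        # lognormal spread of urea clearance
    gst_amp_sd: float = 0.40          # lognormal spread of GST release
    co2_gap_sd: float = 0.45          # lognormal spread of the venous CO2 gap

    # thermal model
    t_blood: float = 38.6             # degC, perfusate at full flow
    t_start: float = 25.0             # degC, organ leaving cold storage
    t_tau_min: float = 6.0
    t_rbf_ref: float = 36.0           # mL/min/100 g where cooling begins
    t_slope: float = 0.31             # degC lost per mL/min/100 g deficit

    # measurement noise SDs
    sd_rbf: float = 1.0               # mL/min
    sd_ap: float = 1.5                # mmHg
    sd_t: float = 0.1                 # degC
    sd_so2: float = 1.5               # %
    sd_po2: float = 4.0               # mmHg
    sd_hb: float = 0.12               # g/dL
    sd_ph: float = 0.015
    sd_pco2: float = 1.2              # mmHg
    sd_assay_frac: float = 0.05       # relative assay noise
    sd_urine: float = 1.5             # mL on cumulative volume

    # missing-data emulation: probability a 20-min blood-gas pair is dropped
    # (per class: borderline organs were hardest to sample reliably)
    panel_dropout: float = 0.25
    panel_dropout_by_class: tuple[float, float, float] = (0.25, 0.40, 0.15)

    # global switch: 0 -> fully deterministic records
    noise_scale: float = 1.0

    n_per_class: tuple[int, int, int] = (4, 10, 12)
    test_fraction: float = 0.23

    def __post_init__(self) -> None:
        if self.weight_mean_g <= 0:
            raise ValueError("kidney weight must be positive")
        if self.dt_s <= 0 or self.duration_min <= 0:
            raise ValueError("dt and duration must be positive")
        if not (0.0 <= self.panel_dropout < 1.0):
            raise ValueError("panel_dropout must be in [0, 1)")

    @classmethod
    def noiseless(cls, **overrides) -> "GeneratorConfig":
        """Config with all randomness (noise, random effects, dropout) off."""
        return cls(noise_scale=0.0, panel_dropout=0.0, **overrides)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


# --------------------------------------------------------------------------
# class-conditional latent trajectories (t in minutes, vectorized)

def _irr_base(cls: int, t: np.ndarray) -> np.ndarray:
    """Latent intrarenal resistance, mmHg per (mL/min/100 g)."""
    t = np.asarray(t, dtype=float)
    if cls == 3:
        return 2.34 - 0.47 * t / 240.0
    if cls == 2:
        return 2.9 + 7.1 / (1.0 + np.exp(-(t - 150.0) / 30.0))
    # class 1: already high at connection, rising to a plateau
    return 4.2 + 7.8 * (1.0 - np.exp(-t / 35.0))


#: borderline (limited-function) organs are the most heterogeneous group
_IRR_SPREAD_FACTOR = {1: 1.0, 2: 1.6, 3: 1.0}


def _demand_shape(t: np.ndarray, s0: float, gamma: float) -> np.ndarray:
    """Metabolic recovery profile: rises from s0 at connection to 1 at 240 min."""
    t = np.asarray(t, dtype=float)
    return s0 + (1.0 - s0) * (np.clip(t, 0.0, 240.0) / 240.0) ** gamma


def _pco2_gap_base(cls: int, t: np.ndarray) -> np.ndarray:
    """Venous minus arterial pCO2 (mmHg); class 3 turns negative ~140 min."""
    t = np.asarray(t, dtype=float)
    if cls == 3:
        return 6.0 - 10.0 * t / 240.0
    if cls == 2:
        return 5.0 - 3.0 * t / 240.0
    return np.full_like(t, 3.0)


def _urea_fraction(cls: int, t: np.ndarray) -> np.ndarray:
    """Blood urea as a fraction of baseline (clearance = decay)."""
    t = np.asarray(t, dtype=float)
    if cls == 3:
        return 0.33 + 0.67 * np.exp(-t / 110.0)
    if cls == 2:
        return 0.72 + 0.28 * np.exp(-t / 90.0)
    return 0.93 + 0.07 * np.exp(-t / 60.0)


def _gst_fraction(cls: int, t: np.ndarray) -> np.ndarray:
    """Plasma GST activity relative to baseline (tubular injury release)."""
    t = np.asarray(t, dtype=float)
    if cls == 1:
        return 1.0 + 1.9 * (1.0 - np.exp(-t / 50.0))       # rise and plateau
    if cls == 2:
        tp = 80.0
        return 1.0 + 0.9 * (t / tp) * np.exp(1.0 - t / tp)  # rise then recover
    tp = 60.0
    return 1.0 + 0.5 * (t / tp) * np.exp(1.0 - t / tp)


def _urine_rate_base(cls: int, t: np.ndarray) -> np.ndarray:
    """Urine production, mL/h per 100 g."""
    t = np.asarray(t, dtype=float)
    if cls == 3:
        return np.full_like(t, 28.0)
    if cls == 2:
        return 8.0 * (1.0 - 0.5 * t / 240.0)
    return np.full_like(t, 1.5)


# --------------------------------------------------------------------------

def _first_order(x: np.ndarray, x0: float, dt_s: float, tau_s: float) -> np.ndarray:
    """First-order lag of series x with initial state x0."""
    a = float(np.exp(-dt_s / tau_s))
    y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=[a * x0])
    return y


def _colored_noise(rng: np.random.Generator, n: int, dt_s: float,
                   tau_s: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    a = float(np.exp(-dt_s / tau_s))
    w = rng.standard_normal(n) * sd * np.sqrt(1.0 - a * a)
    y, _ = lfilter([1.0], [1.0, -a], w, zi=[rng.standard_normal() * sd * a])
    return y


def simulate_kidney(
    function_class: int,
    params: Optional[GeneratorConfig] = None,
    seed: int = 0,
    kidney_id: Optional[str] = None,
    split: str = "train",
) -> KidneyRecord:
    """Generate one complete synthetic NMP experiment.

    Parameters
    ----------
    function_class
        Reference function class: 1 nonfunctional, 2 limited, 3 functional.
    params
        Generator configuration; defaults emulate the study conditions.
    seed
        Seeds all randomness of this kidney.
    """
    if function_class not in FUNCTION_CLASSES:
        raise ValueError(f"unknown function class {function_class}")
    cfg = params or GeneratorConfig()
    rng = np.random.default_rng(seed)
    ns = cfg.noise_scale

    # ---- kidney-level random effects ------------------------------------
    weight = float(np.clip(
        cfg.weight_mean_g + ns * cfg.weight_sd_g * rng.standard_normal(),
        60.0, 180.0))
    w100 = weight / 100.0
    hb_k = float(np.clip(
        cfg.hb_mean + ns * cfg.hb_sd * rng.standard_normal(), 3.5, 9.0))
    wit = float(np.interp(0.5 + ns * (rng.uniform() - 0.5), [0, 1], WIT_RANGE_MIN))
    cit = float(np.interp(0.5 + ns * (rng.uniform() - 0.5), [0, 1], CIT_RANGE_MIN))
    # WIT-linked severity nudges resistance and extraction within a class
    wit_z = (wit - np.mean(WIT_RANGE_MIN)) / (np.ptp(WIT_RANGE_MIN) / 2.0)
    cit_z = (cit - np.mean(CIT_RANGE_MIN)) / (np.ptp(CIT_RANGE_MIN) / 2.0)
    irr_z = float(np.clip(rng.standard_normal(), -1.5, 2.2))  # winsorized:
    # renal autoregulation bounds how extreme a resistance trajectory can be
    log_irr = ns * (cfg.irr_scale_sd * _IRR_SPREAD_FACTOR[function_class]
                    * irr_z + cfg.severity_wit_gain * wit_z)
    irr_scale = float(np.exp(log_irr))
    demand_eps = float(np.exp(ns * cfg.demand_sd * rng.standard_normal()))
    s0_k = float(np.clip(
        cfg.shape_s0 + ns * cfg.shape_s0_sd * rng.standard_normal(), 0.30, 0.95))
    gamma_k = float(np.exp(ns * cfg.shape_gamma_sd * rng.standard_normal()))
    e_max_k = float(np.clip(
        cfg.extraction_max + ns * cfg.extraction_max_sd * rng.standard_normal(),
        0.45, 0.92))
    po2a_k = 120.0 + ns * 8.0 * rng.standard_normal()
    pco2a_k = 40.0 + ns * 1.5 * rng.standard_normal()
    # operator / rig idiosyncrasies
    ap_set_k = cfg.ap_setpoint + ns * 10.0 * (rng.uniform() - 0.5)
    floor_k = float(np.clip(
        cfg.rbf_floor + ns * cfg.rbf_floor_sd * rng.standard_normal(),
        8.0, 22.0))
    t_blood_k = cfg.t_blood + ns * cfg.t_blood_sd * rng.standard_normal()
    t_slope_k = cfg.t_slope * float(np.exp(ns * 0.40 * rng.standard_normal()))
    # cold ischemia hits tubular integrity: clearance, injury release and
    # urine output share the CIT severity axis on top of their own spread
    clearance_k = float(np.exp(ns * (cfg.clearance_sd * rng.standard_normal()
                                     - 0.30 * cit_z)))
    gst_amp_k = float(np.exp(ns * (cfg.gst_amp_sd * rng.standard_normal()
                                   + 0.40 * cit_z)))
    urine_k = float(np.exp(ns * (0.38 * rng.standard_normal()
                                 - 0.30 * cit_z)))
    co2_gap_k = float(np.exp(ns * cfg.co2_gap_sd * rng.standard_normal()))

    # ---- hemodynamic stream ---------------------------------------------
    n = int(round(cfg.duration_min * 60.0 / cfg.dt_s)) + 1
    t_min = np.arange(n) * (cfg.dt_s / 60.0)

    irr_n = _irr_base(function_class, t_min) * irr_scale
    irr_n = irr_n * (1.0 + ns * 0.06
                     * _colored_noise(rng, n, cfg.dt_s, 120.0, 1.0))
    irr_n = np.clip(irr_n, 0.3, 30.0)

    floor_n = floor_k / w100
    # the operator floor yields to the 185 mmHg pressure ceiling: flow is
    # reduced further rather than tolerating nonphysiological pressure
    rbf_cmd = np.maximum(ap_set_k / irr_n,
                         np.minimum(floor_n, 185.0 / irr_n))       # per 100 g
    rbf_cmd = np.minimum(rbf_cmd, 85.0)   # hyperemia ceiling, mL/min/100 g
    rbf_cmd[t_min <= cfg.init_hold_min] = cfg.rbf_init / w100
    rbf_n = _first_order(rbf_cmd, rbf_cmd[0], cfg.dt_s, cfg.controller_tau_s)
    ap = irr_n * rbf_n
    rbf_raw = rbf_n * w100

    t_inf = t_blood_k - t_slope_k * np.maximum(0.0, cfg.t_rbf_ref - rbf_n)
    t_inf = np.clip(t_inf, 28.0, t_blood_k)
    t_kid = _first_order(t_inf, cfg.t_start, cfg.dt_s, cfg.t_tau_min * 60.0)

    rbf_meas = np.clip(
        rbf_raw + ns * _colored_noise(rng, n, cfg.dt_s, 20.0, cfg.sd_rbf),
        0.0, None)
    ap_meas = np.clip(
        ap + ns * _colored_noise(rng, n, cfg.dt_s, 20.0, cfg.sd_ap),
        1.0, None)
    t_meas = t_kid + ns * _colored_noise(rng, n, cfg.dt_s, 60.0, cfg.sd_t)

    hemo = HemoStream(t_min=t_min, rbf=rbf_meas, ap=ap_meas,
                      t_kidney=t_meas, dt_s=cfg.dt_s)

    # end-of-perfusion demand from the sub-linear demand law
    cao2_lat = 1.34 * hb_k * 0.975 + 0.0031 * po2a_k
    do2_fin = float(rbf_n[t_min >= 180.0].mean()) * cao2_lat / 100.0
    dem_fin = (cfg.extraction_target * cfg.do2_reference
               * (max(do2_fin, 1e-6) / cfg.do2_reference) ** cfg.demand_exponent
               * demand_eps)

    # ---- blood-gas panels ------------------------------------------------
    p_drop = cfg.panel_dropout_by_class[function_class - 1] \
        if cfg.panel_dropout_by_class is not None else cfg.panel_dropout
    dropped = {
        t for t in GRID_20MIN
        if ns > 0 and rng.uniform() < p_drop
    }
    panels: list[BloodGasPanel] = []
    for t in PANEL_TIMES:
        if t in dropped:
            continue
        so2_a = float(np.clip(97.5 + ns * cfg.sd_so2 * rng.standard_normal(),
                              90.0, 100.0))
        po2_a = max(30.0, po2a_k + ns * cfg.sd_po2 * rng.standard_normal())
        hb_a = max(1.0, hb_k + ns * cfg.sd_hb * rng.standard_normal())
        ph_a = float(np.clip(7.38 + ns * cfg.sd_ph * rng.standard_normal(),
                             6.85, 7.7))
        pco2_a = max(5.0, pco2a_k + ns * cfg.sd_pco2 * rng.standard_normal())
        panels.append(BloodGasPanel("arterial", float(t), po2_a, so2_a,
                                    hb_a, ph_a, pco2_a))

        # demand-limited extraction with a supply-limited ceiling
        idx = min(n - 1, int(round(t * 60.0 / cfg.dt_s)))
        do2_lat = max(1e-6, rbf_n[idx] * cao2_lat / 100.0)
        dem = dem_fin * float(_demand_shape(np.array([t]), s0_k, gamma_k)[0])
        e = float(np.clip(
            min(e_max_k, dem / do2_lat)
            + ns * cfg.extraction_noise * rng.standard_normal(),
            0.05, 0.95))
        cao2 = 1.34 * hb_a * so2_a / 100.0 + 0.0031 * po2_a
        po2_v = max(15.0, 30.0 + 25.0 * (1.0 - e)
                    + ns * cfg.sd_po2 * 0.5 * rng.standard_normal())
        cvo2 = max(0.0, (1.0 - e) * cao2)
        so2_v = (cvo2 - 0.0031 * po2_v) / (1.34 * hb_a) * 100.0
        so2_v += ns * 1.6 * cfg.sd_so2 * rng.standard_normal()  # dark blood
        so2_v = float(np.clip(so2_v, 0.0, so2_a))   # extraction non-negative
        hb_v = max(1.0, hb_k + ns * cfg.sd_hb * rng.standard_normal())
        gap = float(co2_gap_k * _pco2_gap_base(function_class, np.array([t]))[0]
                    + ns * 0.6 * rng.standard_normal())
        pco2_v = max(5.0, pco2_a + gap)
        ph_v = float(np.clip(ph_a - 0.006 * gap, 6.85, 7.7))
        panels.append(BloodGasPanel("venous", float(t), po2_v, so2_v,
                                    hb_v, ph_v, pco2_v))

    # ---- assays and urine -------------------------------------------------
    assays: list[AssaySample] = []
    urea0 = 45.0 * (1.0 + ns * 0.15 * rng.standard_normal())
    gst0 = 6.0 * (1.0 + ns * 0.20 * rng.standard_normal())
    for t in (0,) + GRID_60MIN:
        frac = float(_urea_fraction(function_class, np.array([t]))[0])
        frac = frac ** clearance_k    # per-kidney clearance rate, baseline 1
        noise = 1.0 if t == 0 else (
            1.0 + ns * cfg.sd_assay_frac * rng.standard_normal())
        assays.append(AssaySample("urea", float(t),
                                  max(1e-6, urea0 * frac * noise)))
    for t in (0,) + GRID_60MIN:
        frac = float(_gst_fraction(function_class, np.array([t]))[0])
        frac = 1.0 + gst_amp_k * (frac - 1.0)  # release amplitude, baseline 1
        noise = 1.0 if t == 0 else (
            1.0 + ns * cfg.sd_assay_frac * rng.standard_normal())
        assays.append(AssaySample("gst", float(t),
                                  max(1e-6, gst0 * frac * noise)))

    rate = _urine_rate_base(function_class, np.asarray(GRID_60MIN, float))
    rate = rate * w100 * urine_k                                  # mL/h raw
    vols = np.cumsum(np.maximum(0.0, rate))
    vols = vols + ns * cfg.sd_urine * rng.standard_normal(len(vols))
    vols = np.maximum.accumulate(np.maximum(0.0, vols))  # non-decreasing
    urine = [UrineSample(0.0, 0.0)] + [
        UrineSample(float(t), float(v)) for t, v in zip(GRID_60MIN, vols)
    ]

    return KidneyRecord(
        kidney_id=kidney_id or f"K{seed:03d}",
        function_class=function_class,
        weight_g=weight,
        wit_min=wit,
        cit_min=cit,
        split=split,
        hemo=hemo,
        panels=panels,
        assays=assays,
        urine=urine,
    )


def simulate_cohort(
    n_per_class: Sequence[int] = (4, 10, 12),
    seed: int = 0,
    params: Optional[GeneratorConfig] = None,
) -> list[KidneyRecord]:
    """Generate a cohort with a stratified 77/23 train/test split.

    Kidneys are numbered K01.. in class order; the split is assigned by
    largest-remainder apportionment of the test fraction within each class
    and is reproducible from ``seed``.
    """
    n_per_class = list(n_per_class)
    if len(n_per_class) != 3 or any(n <= 0 for n in n_per_class):
        raise ValueError("n_per_class must be three positive counts")
    if any(n < 2 for n in n_per_class):
        raise ValueError("each class needs at least 2 kidneys to stratify")
    cfg = params or GeneratorConfig()
    rng = np.random.default_rng(seed)
    test_counts = stratified_split_counts(n_per_class, cfg.test_fraction)

    records: list[KidneyRecord] = []
    kid = 0
    for cls, n_c, n_test in zip(FUNCTION_CLASSES, n_per_class, test_counts):
        test_idx = set(rng.choice(n_c, size=n_test, replace=False).tolist())
        for i in range(n_c):
            kid += 1
            records.append(simulate_kidney(
                cls,
                params=cfg,
                seed=int(rng.integers(0, 2**31 - 1)),
                kidney_id=f"K{kid:02d}",
                split="test" if i in test_idx else "train",
            ))
    return records


def qc_exclude(record: KidneyRecord) -> tuple[bool, str]:
    """Exclusion rule: arterial pressure > 190 mmHg sustained > 30 min.

    Returns ``(True, reason)`` if the record must be excluded.
    """
    hemo = record.hemo
    if hemo.t_min.size == 0:
        raise ValueError("empty hemodynamic stream")
    over = hemo.ap > 190.0
    if not over.any():
        return False, ""
    # longest contiguous run of over-pressure samples, in minutes
    edges = np.flatnonzero(np.diff(np.concatenate(([0], over.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    longest = 0.0
    for a, b in zip(starts, stops):
        t0 = hemo.t_min[a]
        t1 = hemo.t_min[min(b, hemo.t_min.size - 1)]
        longest = max(longest, t1 - t0)
    if longest > 30.0:
        return True, (f"arterial pressure > 190 mmHg sustained "
                      f"{longest:.1f} min (> 30 min)")
    return False, ""
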