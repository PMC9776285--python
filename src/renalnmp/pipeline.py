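"""End-to-end orchestration: simulate -> derive -> thresholds/screen ->
features -> bench -> report."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bench as bench_mod
from . import features as feat_mod
from . import io as io_mod
from . import markers as markers_mod
from . import screen as screen_mod
from . import synth as synth_mod
from . import thresholds as thr_mod
from .records import MARKER_ORDER

__all__ = ["PipelineConfig", "run_pipeline", "critical_threshold_report"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run depends on, serializable to YAML."""

    n_per_class: tuple[int, int, int] = (4, 10, 12)
    dt_s: float = 1.0               # hemodynamic sampling for pipeline runs
    # None keeps the generator's class-dependent dropout; a number replaces it
    panel_dropout: Optional[float] = None
    noise_scale: float = 1.0
    alpha: float = 0.05
    vif_threshold: float = 10.0
    variants: tuple[str, ...] = ("A", "B", "C", "D", "E")
    pair_rule: str = "class3"
    classifiers: tuple[str, ...] = bench_mod.FAMILIES
    scale_features: bool = True
    seed_generator: int = 1
    seed_bench: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0 and self.alpha != 0.0:
            raise ValueError("alpha must be non-negative")
        if self.vif_threshold <= 0:
            raise ValueError("vif_threshold must be positive")
        if not self.variants:
            raise ValueError("variant set must be non-empty")

    def generator_config(self) -> synth_mod.GeneratorConfig:
        kw = dict(dt_s=self.dt_s, noise_scale=self.noise_scale,
                  n_per_class=tuple(self.n_per_class))
        if self.panel_dropout is not None:
            kw["panel_dropout"] = self.panel_dropout
            kw["panel_dropout_by_class"] = None
        return synth_mod.GeneratorConfig(**kw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["n_per_class"] = list(d["n_per_class"])
        d["variants"] = list(d["variants"])
        d["classifiers"] = list(d["classifiers"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        for key in ("n_per_class", "variants", "classifiers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def critical_threshold_report(tables: Sequence[markers_mod.MarkerTable]) -> dict:
    """Fit the marker relationships of a cohort and propagate thresholds.

    Points are class-by-time means (the aggregation drawn in the study's
    scatter plots); ERO2 is expressed in percent.  The VO2~DO2 relation is
    reported as quadratic below / linear above the breakpoint inherited
    from the ERO2 analysis.
    """
    pooled = markers_mod.pool_tables(tables)
    x_eo, y_eo = thr_mod.class_time_means(pooled, "do2", "ero2", scale_y=100.0)
    seg = thr_mod.fit_two_segment(x_eo, y_eo)
    x_rd, y_rd = thr_mod.class_time_means(pooled, "do2", "rbf")
    rbf_do2 = thr_mod.fit_line(x_rd, y_rd)
    x_ra, y_ra = thr_mod.class_time_means(pooled, "ap", "rbf")
    rbf_ap = thr_mod.fit_poly2(x_ra, y_ra)
    try:
        crit = thr_mod.propagate_critical(seg, rbf_do2, rbf_ap)
        crit_err = None
    except ValueError as exc:
        # small or degenerate cohorts need not support a critical elbow
        crit, crit_err = None, str(exc)

    vo2_below = vo2_above = None
    if crit is not None:
        x_vd, y_vd = thr_mod.class_time_means(pooled, "do2", "vo2")
        below = x_vd <= crit.raw.do2_crit
        vo2_below = (thr_mod.fit_poly2(x_vd[below], y_vd[below])
                     if np.sum(below) >= 3 else None)
        vo2_above = (thr_mod.fit_line(x_vd[~below], y_vd[~below])
                     if np.unique(x_vd[~below]).size >= 2 else None)

    def _line(f): return {"slope": f.slope, "intercept": f.intercept,
                          "r_squared": f.r_squared}

    report = {
        "fits": {
            "ero2_do2_left": _line(seg.left),
            "ero2_do2_right": _line(seg.right),
            "ero2_do2_breakpoint": seg.breakpoint,
            "rbf_do2": _line(rbf_do2),
            "rbf_ap": {"a": rbf_ap.a, "b": rbf_ap.b, "c": rbf_ap.c,
                       "r_squared": rbf_ap.r_squared},
        },
        "critical_points": {
            "do2_crit": crit.do2_crit, "ero2_crit": crit.ero2_crit,
            "rbf_crit": crit.rbf_crit, "vo2_crit": crit.vo2_crit,
            "ap_crit": crit.ap_crit,
            "ap_crit_note": "smaller quadratic root (inside observed AP range)",
            "raw": {
                "do2_crit": crit.raw.do2_crit, "ero2_crit": crit.raw.ero2_crit,
                "rbf_crit": crit.raw.rbf_crit, "vo2_crit": crit.raw.vo2_crit,
                "ap_crit": crit.raw.ap_crit,
            },
        } if crit is not None else {"error": crit_err},
    }
    if vo2_below is not None:
        report["fits"]["vo2_do2_below"] = {
            "a": vo2_below.a, "b": vo2_below.b, "c": vo2_below.c,
            "r_squared": vo2_below.r_squared}
    if vo2_above is not None:
        report["fits"]["vo2_do2_above"] = _line(vo2_above)
    return report


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Path] = None) -> dict:
    """Execute all stages; optionally write the report bundle to disk.

    Returns a bundle dict with the cohort, marker tables, threshold report,
    significance map, VIF log, feature matrices and bench results, every
    artifact stamped with the config hash and seeds.
    """
    stamp = {"config_hash": config.config_hash(),
             "seed_generator": config.seed_generator,
             "seed_bench": config.seed_bench}

    records = synth_mod.simulate_cohort(
        config.n_per_class, seed=config.seed_generator,
        params=config.generator_config())
    kept, excluded = [], []
    for r in records:
        flag, reason = synth_mod.qc_exclude(r)
        (excluded if flag else kept).append((r, reason) if flag else r)

    tables = [markers_mod.derive_marker_table(r) for r in kept]
    thresholds_report = critical_threshold_report(tables)
    sig_map = screen_mod.build_significance_map(tables, alpha=config.alpha)

    # per-kidney linear interpolation precedes the collinearity summary
    summary = feat_mod.marker_summary(feat_mod.interpolate_missing(tables))
    retained, vif_log = feat_mod.vif_filter(summary, config.vif_threshold)

    variants = {}
    for v in config.variants:
        try:
            variants[v] = feat_mod.build_variant(
                tables, sig_map, v, retained, pair_rule=config.pair_rule)
        except ValueError:
            pass  # a variant without features is skipped, not fatal
    if not variants:
        raise RuntimeError("no feature variant could be built")

    bench_result = bench_mod.run_bench(
        variants, seed=config.seed_bench,
        classifiers=config.classifiers, scale=config.scale_features)

    bundle = {
        "stamp": stamp,
        "records": kept,
        "excluded": excluded,
        "tables": tables,
        "thresholds": thresholds_report,
        "significance": sig_map,
        "marker_summary": summary,
        "retained_markers": retained,
        "vif_log": vif_log,
        "variants": variants,
        "bench": bench_result,
    }
    if out_dir is not None:
        _write_bundle(bundle, config, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(config.to_yaml())
    io_mod.write_cohort(bundle["records"], out_dir / "cohort",
                        seed=config.seed_generator)
    io_mod.write_marker_tables(bundle["tables"], out_dir / "marker_tables.csv")
    io_mod.write_json({**bundle["stamp"], **bundle["thresholds"]},
                      out_dir / "critical_points.json")
    bundle["significance"].table.to_csv(out_dir / "significance.csv",
                                        index=False)
    bundle["vif_log"].to_csv(out_dir / "vif_removals.csv", index=False)
    for v, fm in bundle["variants"].items():
        df = fm.X.copy()
        df.insert(0, "function_class", fm.y)
        df.insert(1, "split", fm.split)
        df.to_csv(out_dir / f"features_{v}.csv")
    res: bench_mod.BenchResult = bundle["bench"]
    res.summary.to_csv(out_dir / "bench_metrics.csv")
    res.per_kidney.to_csv(out_dir / "per_kidney.csv")
    io_mod.write_json(
        {**bundle["stamp"],
         "retained_markers": bundle["retained_markers"],
         "best_cells": [list(b) for b in res.best],
         "metrics": res.summary.reset_index().to_dict(orient="records")},
        out_dir / "report.json")
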