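"""CSV/JSON interchange for cohorts, marker tables and reports.

The measurement interchange schema is a long-format CSV with columns
``kidney_id, channel, site, t_min, value`` plus a kidney manifest CSV
(``kidney_id, function_class, weight_g, wit_min, cit_min, split``), so real
laboratory exports can replace the synthetic generator without code changes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import MarkerTable
from .records import (
    MARKER_ORDER,
    AssaySample,
    BloodGasPanel,
    HemoStream,
    KidneyRecord,
    UrineSample,
)

__all__ = [
    "cohort_to_frames", "write_cohort", "read_cohort",
    "write_marker_tables", "read_marker_tables", "write_json",
]

HEMO_CHANNELS = ("rbf", "ap", "t_kidney")
PANEL_FIELDS = ("po2", "so2", "hb", "ph", "pco2")


def cohort_to_frames(records: Sequence[KidneyRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(measurements, manifest) frames for a cohort."""
    chunks = []
    manifest_rows = []
    for r in records:
        manifest_rows.append({
            "kidney_id": r.kidney_id, "function_class": r.function_class,
            "weight_g": r.weight_g, "wit_min": r.wit_min,
            "cit_min": r.cit_min, "split": r.split,
        })
        n = r.hemo.t_min.size
        for ch in HEMO_CHANNELS:
            chunks.append(pd.DataFrame({
                "kidney_id": r.kidney_id, "channel": ch, "site": "na",
                "t_min": r.hemo.t_min, "value": r.hemo.channel(ch),
            }))
        panel_rows = [
            {"kidney_id": r.kidney_id, "channel": f, "site": p.site,
             "t_min": p.t, "value": getattr(p, f)}
            for p in r.panels for f in PANEL_FIELDS
        ]
        assay_rows = [
            {"kidney_id": r.kidney_id, "channel": a.analyte, "site": "na",
             "t_min": a.t, "value": a.value}
            for a in r.assays
        ]
        urine_rows = [
            {"kidney_id": r.kidney_id, "channel": "urine_volume", "site": "na",
             "t_min": u.t, "value": u.cumulative_volume}
            for u in r.urine
        ]
        chunks.append(pd.DataFrame(panel_rows + assay_rows + urine_rows))
    measurements = pd.concat(chunks, ignore_index=True)
    return measurements, pd.DataFrame(manifest_rows)


def write_cohort(records: Sequence[KidneyRecord], out_dir: Path,
                 seed: int | None = None) -> None:
    """Write measurements.csv and manifest.csv (seed recorded in manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    measurements, manifest = cohort_to_frames(records)
    if seed is not None:
        manifest["generator_seed"] = seed
    measurements.to_csv(out_dir / "measurements.csv", index=False)
    manifest.to_csv(out_dir / "manifest.csv", index=False)


def read_cohort(out_dir: Path) -> list[KidneyRecord]:
    """Rebuild KidneyRecords from measurements.csv + manifest.csv."""
    out_dir = Path(out_dir)
    meas = pd.read_csv(out_dir / "measurements.csv")
    manifest = pd.read_csv(out_dir / "manifest.csv")
    records = []
    for _, m in manifest.iterrows():
        kid = meas[meas["kidney_id"] == m["kidney_id"]]
        hemo_parts = {}
        for ch in HEMO_CHANNELS:
            part = kid[kid["channel"] == ch].sort_values("t_min")
            hemo_parts[ch] = part
        t_min = hemo_parts["rbf"]["t_min"].to_numpy()
        dt_s = float(np.median(np.diff(t_min)) * 60.0) if t_min.size > 1 else 0.2
        hemo = HemoStream(
            t_min=t_min,
            rbf=hemo_parts["rbf"]["value"].to_numpy(),
            ap=hemo_parts["ap"]["value"].to_numpy(),
            t_kidney=hemo_parts["t_kidney"]["value"].to_numpy(),
            dt_s=dt_s,
        )
        panels = []
        pf = kid[kid["channel"].isin(PANEL_FIELDS)]
        for (site, t), grp in pf.groupby(["site", "t_min"]):
            vals = dict(zip(grp["channel"], grp["value"]))
            panels.append(BloodGasPanel(site=site, t=float(t), **vals))
        panels.sort(key=lambda p: (p.t, p.site))
        assays = [
            AssaySample(row["channel"], float(row["t_min"]), float(row["value"]))
            for _, row in kid[kid["channel"].isin(("urea", "gst"))].iterrows()
        ]
        urine = [
            UrineSample(float(row["t_min"]), float(row["value"]))
            for _, row in kid[kid["channel"] == "urine_volume"]
            .sort_values("t_min").iterrows()
        ]
        records.append(KidneyRecord(
            kidney_id=str(m["kidney_id"]),
            function_class=int(m["function_class"]),
            weight_g=float(m["weight_g"]),
            wit_min=float(m["wit_min"]),
            cit_min=float(m["cit_min"]),
            split=str(m["split"]),
            hemo=hemo, panels=panels, assays=assays, urine=urine,
        ))
    return records


def write_marker_tables(tables: Sequence[MarkerTable], path: Path) -> None:
    """Wide CSV: kidney_id, class, split, weight_g, t_min, marker columns."""
    rows = []
    for tab in tables:
        df = tab.frame.reset_index()
        df.insert(0, "kidney_id", tab.kidney_id)
        df.insert(1, "function_class", tab.function_class)
        df.insert(2, "split", tab.split)
        df.insert(3, "weight_g", tab.weight_g)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_marker_tables(path: Path) -> list[MarkerTable]:
    df = pd.read_csv(path)
    tables = []
    for kid, grp in df.groupby("kidney_id", sort=False):
        frame = grp.set_index("t_min")[list(MARKER_ORDER)].astype(float)
        frame.index = frame.index.astype(int)
        tables.append(MarkerTable(
            kidney_id=str(kid),
            function_class=int(grp["function_class"].iloc[0]),
            weight_g=float(grp["weight_g"].iloc[0]),
            split=str(grp["split"].iloc[0]),
            frame=frame,
        ))
    return tables


def write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
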