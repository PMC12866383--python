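"""Deterministic text/CSV/JSON report artifacts and run manifests.

Formatting follows the dose-escalation report conventions: dosimetry
grids as "mean (SD)" with 2 significant figures rounded half away from
zero; count tables as "n (percentage)" with one decimal.  Identical
inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import RunConfig, config_hash
from .dosimetry import round_sig
from .trial import TrialRecord

__all__ = ["format_dose_table", "report", "write_manifest"]


def format_dose_table(summary: pd.DataFrame) -> str:
    """Render a summarize_dosimetry frame as a "mean (SD)" text grid."""
    if summary.empty:
        return "dl\torgan\tn\n"
    lines = ["dl\torgan\tn\tadc Gy/GBq\tprojected CAD Gy"]
    has_cad = "projected_cad_mean" in summary.columns

    def cell(mean: float, sd: float) -> str:
        if pd.isna(mean):
            return "-"
        if pd.isna(sd):
            return f"{round_sig(mean)}"
        return f"{round_sig(mean)} ({round_sig(sd)})"

    for _, row in summary.iterrows():
        cad = (
            cell(row["projected_cad_mean"], row["projected_cad_sd"]) if has_cad else "-"
        )
        lines.append(
            f"{row['dl']}\t{row['organ']}\t{row['n']}\t"
            f"{cell(row['adc_mean'], row['adc_sd'])}\t{cad}"
        )
    return "\n".join(lines) + "\n"


def _records_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        for st in rec.dl_states:
            rows.append(
                {
                    "trial": i,
                    "dl_index": st.dl_index,
                    "n": st.n_evaluable,
                    "y": st.n_dlt,
                    "eliminated": st.eliminated,
                    "mtd_index": rec.mtd_index,
                }
            )
    cols = ["trial", "dl_index", "n", "y", "eliminated", "mtd_index"]
    return pd.DataFrame(rows, columns=cols)


def report(results, fmt: str, path: str | Path) -> Path:
    """Write a results artifact; supported formats: text, csv, json.

    ``results`` may be a dosimetry summary DataFrame, a safety table, or
    a sequence of TrialRecord.  Output bytes depend only on the input.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        frame = results
    elif results and isinstance(results[0], TrialRecord):
        frame = _records_frame(results)
    else:
        frame = _records_frame(list(results)) if not results else pd.DataFrame(results)
    if fmt == "text":
        if {"adc_mean", "organ"}.issubset(frame.columns):
            path.write_text(format_dose_table(frame))
        else:
            path.write_text(frame.to_string() + "\n")
    elif fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(frame.to_json(orient="records", indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def write_manifest(cfg: RunConfig, out_dir: str | Path, extra: Optional[dict] = None) -> Path:
    """Record config hash and seed so a run can be reproduced exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
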