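"""Probe-table readers/writers and structured result reports.

The interchange format is plain delimited text (tab or comma, header
required) with columns ``probeset_id, k, L, pm, mm`` and optionally
``is_control, control_region``.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import QCResult
from .probe_model import ChipData

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("probeset_id", "k", "L", "pm", "mm")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_probe_table(path: str | Path) -> ChipData:
    """Read a delimited probe table into a validated :class:`ChipData`.

    A missing ``mm`` column engages PM-only mode: Σ reduces to log PM (MM is
    mirrored from PM internally), the PM/MM hook cannot be fitted, but the
    positional degradation metrics remain available.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    pm_only = "mm" not in df.columns
    if pm_only:
        warnings.warn("probe table has no 'mm' column: PM-only mode engaged", stacklevel=2)
        df["mm"] = df["pm"]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    bad_rows = []
    for col in ("k", "L", "pm", "mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_rows.extend((int(i) + 2, col) for i in df.index[bad])  # +2: header + 1-based
        df[col] = coerced
    if bad_rows:
        listing = "; ".join(f"line {ln}: column {col}" for ln, col in bad_rows[:10])
        raise ValueError(f"non-numeric values in probe table ({listing})")
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    chip = ChipData(df, metadata={"source": str(path), "pm_only": pm_only})
    return chip


def write_probe_table(chip: ChipData, path: str | Path, sep: str = "\t") -> None:
    chip.probes.to_csv(path, sep=sep, index=False, float_format="%.6g")


# ---------------------------------------------------------------------- #
# structured reports


def summary_record(result: QCResult) -> dict:
    """Deterministically ordered, JSON-ready summary of one QC run."""
    s, f = result.summary, result.hook_fit
    rec = {
        "hook": {
            "alpha": f.alpha,
            "beta": f.beta,
            "sigma_start": f.sigma_start,
            "delta_start": f.delta_start,
            "logM": f.logM,
            "pct_absent": f.pct_absent,
            "phi": f.phi,
        },
        "degradation": {
            "tongs_opening": s.tongs_opening,
            "tongs_opening_max": s.tongs_opening_max,
            "d_tongs": s.d_tongs,
            "log_dk": s.log_dk,
            "lambda_k": s.lambda_k,
            "lambda_L": s.lambda_L,
            "mean_log_d": s.mean_log_d,
            "affyslope": s.affyslope,
            "decay_fits": {
                scale: {
                    "lambda": fit.lambda_,
                    "d_inf": fit.d_inf,
                    "x0": fit.x0,
                    "fit_range": list(fit.fit_range),
                    "residual_norm": fit.residual_norm,
                }
                for scale, fit in sorted(s.decay_fits.items())
            },
            "flags": list(s.flags),
        },
    }
    if result.control_report is not None:
        r = result.control_report
        rec["controls"] = {
            "threshold": result.threshold_hook.constant_threshold,
            "delta_gamma_calibrated": result.threshold_hook.delta_gamma,
            "tp": r.tp,
            "fp": r.fp,
            "tn": r.tn,
            "fn": r.fn,
            "ppv": r.ppv,
            "sp": r.sp,
            "pairs": [
                {
                    "gene": p.gene_label,
                    "sigma_sum": p.sigma_sum,
                    "sigma_mean": p.sigma_mean,
                    "delta_35": p.delta_35,
                }
                for p in result.control_pairs
            ],
        }
    return rec


def write_summary(result: QCResult, out_dir: str | Path) -> Path:
    """Write the machine-readable summary plus delimited curve tables.

    Produces ``summary.json``, ``hook_curve.tsv``, ``tongs.tsv`` and
    ``per_set.tsv`` inside ``out_dir``; returns the summary path.  Output is
    byte-identical across runs on identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = summary_record(result)
    if not np.isfinite(rec["hook"]["alpha"]):
        raise ValueError("refusing to write empty/NaN analysis summary")
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(rec, indent=2, sort_keys=False) + "\n")

    pd.DataFrame(
        {"sigma": result.hook_curve.sigma, "delta": result.hook_curve.delta}
    ).to_csv(out / "hook_curve.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "sigma": result.tongs.sigma,
            "dsigma_3p": result.tongs.d3,
            "dsigma_m": result.tongs.dm,
            "dsigma_5p": result.tongs.d5,
        }
    ).to_csv(out / "tongs.tsv", sep="\t", index=False, float_format="%.6g")
    result.per_set.to_csv(out / "per_set.tsv", sep="\t", float_format="%.6g")
    return summary_path


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
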