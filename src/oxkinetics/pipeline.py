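"""Orchestration: per-dose analysis and dose-response summaries.

Runs the elongation, growth, qPCR and catalase stages over scenario bundles
and assembles the study-level summary: elongation rate at 5 min versus dose,
lag versus dose, recovery classification and the threshold dose (the
smallest dose whose culture never recovers).  The threshold is taken from
the growth-recovery classification, not from the elongation rate alone, so
a strain that elongates at 0.8 aa/s yet recovers is not miscalled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import catalase as cat
from . import growth as gr
from . import qpcr
from . import translation as tr
from .exceptions import ValidationError
from .presets import ScenarioBundle

__all__ = [
    "DoseResponseRow",
    "BundleAnalysis",
    "percent_change",
    "analyze_bundle",
    "build_dose_response",
    "report",
]

logger = logging.getLogger("oxkinetics")


def percent_change(before: float, after: float) -> float:
    """Percent drop from ``before`` to ``after``: ``100*(before-after)/before``."""
    if before == 0:
        raise ValidationError("percent_change undefined for before == 0")
    return 100.0 * (before - after) / before


@dataclass
class DoseResponseRow:
    """One dose's summary across all assays."""

    dose_mM: float
    er_5min: float
    lag_min: Optional[float]
    recovered: bool
    trna_fold_5min: Optional[float]
    condition: str = ""
    strain: str = "WT"
    notes: str = ""


@dataclass
class BundleAnalysis:
    """Full per-bundle analysis: every stage's fitted results."""

    condition: str
    dose_mM: float
    strain: str
    er_fits: Dict[float, tr.SchleifFit]
    phases: gr.GrowthPhases
    trna_folds: pd.DataFrame
    catalase_folds: pd.DataFrame
    row: DoseResponseRow = field(init=False)

    def __post_init__(self) -> None:
        er5 = self.er_fits.get(5.0)
        if er5 is None and self.er_fits:
            first = sorted(self.er_fits)[0]
            er5 = self.er_fits[first]
        fold5 = None
        if not self.trna_folds.empty:
            at5 = self.trna_folds[self.trna_folds["sample"] == "t5"]
            if not at5.empty:
                fold5 = float(at5["fold"].median())
        self.row = DoseResponseRow(
            dose_mM=self.dose_mM,
            er_5min=0.0 if er5 is None else er5.er_aa_per_s,
            lag_min=self.phases.lag_min,
            recovered=self.phases.recovered,
            trna_fold_5min=fold5,
            condition=self.condition,
            strain=self.strain,
        )


def analyze_bundle(bundle: ScenarioBundle) -> BundleAnalysis:
    """Run every analysis stage on one synthetic (or assembled) bundle."""
    er_fits = {
        minute: tr.schleif_fit(trace) for minute, trace in bundle.induction_traces.items()
    }
    phases = gr.detect_phases(bundle.growth)
    trna = qpcr.relative_levels(bundle.ct_table)
    activities = [
        cat.activity_from_trace(trace) for trace in bundle.catalase_traces.values()
    ]
    ref_minute = min(bundle.catalase_traces)
    ref_cond = bundle.catalase_traces[ref_minute].condition
    cat_folds = cat.relative_activity(activities, reference=ref_cond)
    return BundleAnalysis(
        condition=bundle.preset.name,
        dose_mM=bundle.preset.dose_mM,
        strain=bundle.preset.strain,
        er_fits=er_fits,
        phases=phases,
        trna_folds=trna,
        catalase_folds=cat_folds,
    )


def build_dose_response(rows: Sequence[DoseResponseRow]) -> pd.DataFrame:
    """Assemble the dose-response table and the threshold dose.

    Rows must carry distinct conditions; the returned frame is sorted by
    dose and carries the threshold (smallest non-recovering dose) in
    ``frame.attrs['threshold_dose_mM']`` (None when every dose recovers).
    Lag is never fabricated for a non-recovered dose.
    """
    if len(rows) < 2:
        raise ValidationError("dose-response needs at least 2 doses")
    conditions = [r.condition for r in rows]
    if len(set(conditions)) != len(conditions):
        dupes = sorted({c for c in conditions if conditions.count(c) > 1})
        raise ValidationError(f"duplicate condition labels in dose-response: {dupes}")
    frame = pd.DataFrame(
        [
            {
                "dose_mM": r.dose_mM,
                "condition": r.condition,
                "strain": r.strain,
                "er_5min": r.er_5min,
                "lag_min": r.lag_min if r.recovered else None,
                "recovered": r.recovered,
                "trna_fold_5min": r.trna_fold_5min,
                "notes": r.notes,
            }
            for r in rows
        ]
    ).sort_values("dose_mM").reset_index(drop=True)
    failed = frame.loc[~frame["recovered"], "dose_mM"]
    frame.attrs["threshold_dose_mM"] = None if failed.empty else float(failed.min())
    return frame


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report(
    table: pd.DataFrame,
    analyses: Sequence[BundleAnalysis],
    outdir: Path,
    plots: bool = False,
) -> List[Path]:
    """Write the dose-response table, per-fit CSVs and a JSON summary.

    With ``plots=True`` also renders Schleif plots, growth curves with the
    detected lag shaded, and the dose-response panel.  Returns the list of
    files written; identical inputs produce identical CSV/JSON content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    path = outdir / "dose_response.csv"
    table.to_csv(path, index=False)
    written.append(path)
    logger.info("wrote %s", path)

    fit_rows = []
    for an in analyses:
        for minute, fit in sorted(an.er_fits.items()):
            fit_rows.append(
                {
                    "condition": an.condition,
                    "minute": minute,
                    "t_first_s": None if fit.stalled else fit.t_first_s,
                    "er_aa_per_s": fit.er_aa_per_s,
                    "stalled": fit.stalled,
                    "r_squared": None if fit.stalled else fit.r_squared,
                }
            )
    fits_path = outdir / "elongation_fits.csv"
    pd.DataFrame(
        fit_rows,
        columns=["condition", "minute", "t_first_s", "er_aa_per_s", "stalled", "r_squared"],
    ).to_csv(fits_path, index=False)
    written.append(fits_path)
    logger.info("wrote %s", fits_path)

    summary = {
        "n_conditions": int(len(table)),
        "threshold_dose_mM": table.attrs.get("threshold_dose_mM"),
        "conditions": [
            {
                "condition": rec["condition"],
                "dose_mM": rec["dose_mM"],
                "er_5min": rec["er_5min"],
                "lag_min": None if pd.isna(rec["lag_min"]) else rec["lag_min"],
                "recovered": bool(rec["recovered"]),
            }
            for rec in table.to_dict("records")
        ]
        if len(table)
        else [],
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=_json_default) + "\n")
    written.append(summary_path)
    logger.info("wrote %s", summary_path)

    if plots:
        written.extend(_render_plots(table, analyses, outdir))
    return written


def _render_plots(
    table: pd.DataFrame, analyses: Sequence[BundleAnalysis], outdir: Path
) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: List[Path] = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    rec = table[table["recovered"]]
    axes[0].plot(table["dose_mM"], table["er_5min"], "o-")
    axes[0].set_xlabel("H2O2 dose (mM)")
    axes[0].set_ylabel("ER at 5 min (aa/s)")
    axes[1].plot(rec["dose_mM"], rec["lag_min"], "s-")
    axes[1].set_xlabel("H2O2 dose (mM)")
    axes[1].set_ylabel("lag (min)")
    fig.tight_layout()
    panel = outdir / "dose_response.png"
    fig.savefig(panel, dpi=120)
    plt.close(fig)
    written.append(panel)
    logger.info("wrote %s", panel)
    return written
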