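"""Tidy-CSV readers and writers for the assay tables.

All on-disk formats are plain CSV: induction traces (``time_s,signal``),
growth curves (``time_min,od600``), long Ct tables
(``sample,target,replicate,ct``) and absorbance traces (``time_s,a240``)
with a per-sample manifest (``sample,file,protein_conc``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from .catalase import AbsorbanceTrace
from .exceptions import ValidationError
from .growth import GrowthCurve
from .qpcr import validate_ct_table
from .translation import InductionTrace, ReporterSpec

PathLike = Union[str, Path]


def _require(df: pd.DataFrame, cols: tuple, path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_induction_csv(
    path: PathLike, reporter: ReporterSpec, condition: str = ""
) -> InductionTrace:
    df = pd.read_csv(path)
    _require(df, ("time_s", "signal"), path)
    df = df.sort_values("time_s")
    return InductionTrace(
        df["time_s"].to_numpy(float), df["signal"].to_numpy(float), reporter, condition
    )


def write_induction_csv(trace: InductionTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.times_s, "signal": trace.signal}).to_csv(path, index=False)


def read_growth_csv(
    path: PathLike, stress_time_min: Optional[float] = None, condition: str = ""
) -> GrowthCurve:
    df = pd.read_csv(path)
    _require(df, ("time_min", "od600"), path)
    df = df.sort_values("time_min")
    return GrowthCurve(
        df["time_min"].to_numpy(float),
        df["od600"].to_numpy(float),
        stress_time_min=stress_time_min,
        condition=condition,
    )


def write_growth_csv(curve: GrowthCurve, path: PathLike) -> None:
    pd.DataFrame({"time_min": curve.times_min, "od600": curve.od600}).to_csv(path, index=False)


def read_ct_csv(path: PathLike) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path))


def read_absorbance_traces(
    manifest_path: PathLike, traces_dir: Optional[PathLike] = None
) -> Dict[str, AbsorbanceTrace]:
    """Load A240 traces listed in a manifest CSV (sample,file,protein_conc)."""
    manifest = pd.read_csv(manifest_path)
    _require(manifest, ("sample", "file", "protein_conc"), manifest_path)
    base = Path(traces_dir) if traces_dir is not None else Path(manifest_path).parent
    traces: Dict[str, AbsorbanceTrace] = {}
    for rec in manifest.to_dict("records"):
        df = pd.read_csv(base / rec["file"])
        _require(df, ("time_s", "a240"), rec["file"])
        df = df.sort_values("time_s")
        traces[rec["sample"]] = AbsorbanceTrace(
            df["time_s"].to_numpy(float),
            df["a240"].to_numpy(float),
            float(rec["protein_conc"]),
            condition=str(rec["sample"]),
        )
    return traces


def write_absorbance_csv(trace: AbsorbanceTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.times_s, "a240": trace.a240}).to_csv(path, index=False)
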