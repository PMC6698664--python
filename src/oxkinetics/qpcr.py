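"""Relative quantification of tRNA/mRNA pools from qPCR cycle thresholds.

Fold changes are computed with the textbook 2^-ddCt transform: each target's
Ct is normalised against a stable reference target (5S rRNA, whose level does
not change under oxidative stress) and against a reference sample (time zero,
whose fold is 1 by construction).  Induction kinetics of strongly induced
mRNAs are expressed directly as 2^(Ct(0) - Ct(t)).  Replicates are averaged
on the Ct scale, which corresponds to geometric-mean aggregation on the fold
scale; amplification efficiency is assumed to be a perfect doubling per cycle
(configurable through the ``efficiency`` argument).

Ct tables are tidy :class:`pandas.DataFrame` objects with columns
``sample, target, replicate, ct``.
"""

from __future__ import annotations

import math
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "CT_COLUMNS",
    "CtAggregate",
    "ddct_fold",
    "direct_fold",
    "aggregate_replicates",
    "simulate_ct_table",
    "relative_levels",
    "validate_ct_table",
]

CT_COLUMNS = ("sample", "target", "replicate", "ct")


class CtAggregate(NamedTuple):
    """Replicate summary on the Ct scale."""

    mean: float
    sd: float
    n: int
    low_confidence: bool


def _log_eff(efficiency: float) -> float:
    if efficiency <= 1.0:
        raise ValidationError("amplification efficiency must exceed 1 (2.0 = doubling)")
    return math.log2(efficiency)


def ddct_fold(
    ct_target_t: float,
    ct_ref_t: float,
    ct_target_0: float,
    ct_ref_0: float,
    efficiency: float = 2.0,
) -> float:
    """Fold change of a target at time t relative to time 0 by 2^-ddCt.

    ``dCt_t = Ct_target(t) - Ct_ref(t)``, ``dCt_0 = Ct_target(0) - Ct_ref(0)``
    and ``fold = efficiency^-(dCt_t - dCt_0)``.
    """
    for v in (ct_target_t, ct_ref_t, ct_target_0, ct_ref_0):
        if not math.isfinite(v):
            raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_t - ct_ref_t) - (ct_target_0 - ct_ref_0)
    return float(efficiency ** (-ddct))


def direct_fold(ct_0: float, ct_t: float, efficiency: float = 2.0) -> float:
    """Un-normalised relative abundance ``efficiency^(Ct(0) - Ct(t))``.

    Used for induction kinetics of strongly induced transcripts where the
    time-zero template is the only reference.
    """
    if not (math.isfinite(ct_0) and math.isfinite(ct_t)):
        raise ValidationError("Ct values must be finite")
    return float(efficiency ** (ct_0 - ct_t))


def aggregate_replicates(cts: Sequence[float]) -> CtAggregate:
    """Mean and SD of replicate Ct values (sample SD, ddof=1).

    A single replicate yields sd 0 flagged ``low_confidence``; fold changes
    should be computed from the mean Ct, with ``2^(+/- sd)`` as the error
    band, i.e. geometric aggregation on the fold scale.
    """
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValidationError("at least one replicate is required")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("Ct values must be finite")
    if arr.size == 1:
        return CtAggregate(float(arr[0]), 0.0, 1, True)
    return CtAggregate(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size), False)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy Ct table for the required columns and finite Ct values."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table is missing columns {missing}")
    if table.empty:
        raise ValidationError("Ct table is empty")
    if not np.all(np.isfinite(table["ct"].to_numpy(dtype=float))):
        raise ValidationError("Ct values must be finite")
    return table


def simulate_ct_table(
    true_folds: Mapping[str, Mapping[str, float]],
    ct0_target: Union[float, Mapping[str, float]] = 20.0,
    ct_ref: float = 12.0,
    replicate_sd: float = 0.1,
    n_reps: int = 3,
    seed: Optional[int] = None,
    reference_target: str = "5S_rRNA",
    reference_sample: str = "t0",
) -> pd.DataFrame:
    """Generate a tidy Ct table realising given true fold changes.

    ``true_folds`` maps target -> {sample -> fold relative to the reference
    sample}.  Target Ct at sample s is ``ct0_target - log2(fold)`` plus
    Gaussian replicate noise; the reference target Ct is constant across
    samples (a stable rRNA pool) with the same noise model.  The reference
    sample is always emitted with fold 1.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if replicate_sd < 0:
        raise ValidationError("replicate_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    samples: list[str] = [reference_sample]
    for per_sample in true_folds.values():
        for s in per_sample:
            if s not in samples:
                samples.append(s)

    def noise() -> float:
        return float(rng.normal(0.0, replicate_sd)) if replicate_sd > 0 else 0.0

    for target, per_sample in true_folds.items():
        base = ct0_target[target] if isinstance(ct0_target, Mapping) else float(ct0_target)
        for sample in samples:
            fold = 1.0 if sample == reference_sample else per_sample.get(sample)
            if fold is None:
                continue
            if fold <= 0:
                raise ValidationError(f"fold for {target}/{sample} must be positive")
            ct_true = base - math.log2(fold)
            for rep in range(1, n_reps + 1):
                rows.append((sample, target, rep, ct_true + noise()))
    for sample in samples:
        for rep in range(1, n_reps + 1):
            rows.append((sample, reference_target, rep, ct_ref + noise()))
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def relative_levels(
    table: pd.DataFrame,
    reference_target: str = "5S_rRNA",
    reference_sample: str = "t0",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """2^-ddCt fold changes for every sample x target in a tidy Ct table.

    Returns a DataFrame with columns ``sample, target, fold, sd_ct,
    fold_lo, fold_hi``; ``sd_ct`` combines target and reference replicate
    SDs at the same sample in quadrature and the fold band is
    ``fold * efficiency^(+/- sd_ct)``.  The reference sample's folds are 1
    by construction (up to replicate noise in the Ct means).
    """
    validate_ct_table(table)
    log_e = _log_eff(efficiency)
    agg = (
        table.groupby(["sample", "target"])["ct"]
        .agg(["mean", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0])
        .rename(columns={"mean": "ct_mean", "<lambda_0>": "ct_sd"})
    )
    agg.columns = ["ct_mean", "ct_sd"]
    if reference_target not in table["target"].unique():
        raise ValidationError(f"reference target {reference_target!r} not in table")
    if reference_sample not in table["sample"].unique():
        raise ValidationError(f"reference sample {reference_sample!r} not in table")

    ref_by_sample = agg.xs(reference_target, level="target")
    rows = []
    for (sample, target), rec in agg.iterrows():
        if target == reference_target:
            continue
        if sample not in ref_by_sample.index:
            raise ValidationError(f"no reference-target Ct for sample {sample!r}")
        dct_t = rec["ct_mean"] - ref_by_sample.loc[sample, "ct_mean"]
        dct_0 = (
            agg.loc[(reference_sample, target), "ct_mean"]
            - ref_by_sample.loc[reference_sample, "ct_mean"]
        )
        fold = float(efficiency ** (-(dct_t - dct_0)))
        sd_ct = float(
            math.hypot(rec["ct_sd"], ref_by_sample.loc[sample, "ct_sd"])
        )
        rows.append(
            {
                "sample": sample,
                "target": target,
                "fold": fold,
                "sd_ct": sd_ct,
                "fold_lo": fold * efficiency ** (-sd_ct),
                "fold_hi": fold * efficiency ** (sd_ct),
            }
        )
    return pd.DataFrame(rows).sort_values(["sample", "target"]).reset_index(drop=True)
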