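"""Named dose presets emulating the measured H2O2 dose-response trajectories.

Each :class:`DosePreset` bundles, for one condition, the elongation-rate
time course (aa/s; 0 encodes complete stalling), the growth behaviour
(pre/post rates, lag, recovery mode), the median tRNA fold time course
(relative to time zero) and the catalase-activity fold time course.  The
values anchor on the study's printed numbers: ~16 aa/s unstressed; at 5 min
post-shock ~8 aa/s (0.5 mM), ~3 aa/s (1.5 mM), ~1 aa/s (5 mM) and 0 aa/s
(6 mM, the non-recovering threshold dose); lags of ~15/38/90 min for
0.5/1.5/5 mM; tRNA median folds of ~0.1 at 1.5 mM and ~0.05 at 5 mM at
5 min; catalase rising several-fold within 30 min at low doses but flat at
6 mM.  Elongation rates at intermediate recovery times that were only
plotted, not printed, are linear interpolations between anchors and are
flagged in ``interpolated_minutes``.

:func:`generate_bundle` drives all four module simulators from one preset
and one seed, producing a fully synthetic but internally consistent
scenario for end-to-end round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import catalase as cat
from . import growth as gr
from . import qpcr
from . import translation as tr
from .exceptions import ValidationError

__all__ = [
    "DosePreset",
    "NoiseLevels",
    "ScenarioBundle",
    "builtin_presets",
    "generate_bundle",
    "WILDTYPE_DOSE_PRESETS",
]


@dataclass(frozen=True)
class NoiseLevels:
    """Noise magnitudes for bundle generation (all configurable).

    ``induction_frac`` scales the induction-signal SD as a fraction of the
    trace's dynamic range; ``od_cv`` is the multiplicative OD noise CV;
    ``ct_sd`` the qPCR replicate SD in cycles; ``a240_sd`` additive
    absorbance noise.
    """

    induction_frac: float = 0.05
    od_cv: float = 0.01
    ct_sd: float = 0.1
    a240_sd: float = 0.002

    @classmethod
    def zero(cls) -> "NoiseLevels":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DosePreset:
    """One named stress scenario: the trajectories that drive the generators."""

    name: str
    dose_mM: float
    er_timecourse: Dict[float, float]  # minutes after stress -> aa/s (0 = stalled)
    growth_mode: str = "recovering"
    lag_min: Optional[float] = None
    lambda_pre: float = 0.96
    lambda_post: float = 0.94
    trna_fold_timecourse: Dict[float, float] = field(default_factory=dict)
    catalase_fold_timecourse: Dict[float, float] = field(default_factory=dict)
    strain: str = "WT"
    interpolated_minutes: Tuple[float, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.er_timecourse.values()):
            raise ValidationError("elongation rates must be nonnegative")
        if (self.growth_mode == "recovering") != (self.lag_min is not None):
            raise ValidationError("lag_min must be present iff growth_mode is recovering")
        if any(v <= 0 for v in self.trna_fold_timecourse.values()):
            raise ValidationError("tRNA folds must be positive")
        if any(v <= 0 for v in self.catalase_fold_timecourse.values()):
            raise ValidationError("catalase folds must be positive")


def builtin_presets() -> Dict[str, DosePreset]:
    """The built-in dose presets encoding the study conditions."""
    presets = [
        DosePreset(
            name="normal",
            dose_mM=0.0,
            # unstressed: ER constant at ~16 aa/s
            er_timecourse={0.0: 16.0, 30.0: 16.0, 60.0: 16.0},
            growth_mode="recovering",
            lag_min=0.0,
            lambda_pre=0.96,
            lambda_post=0.96,
            trna_fold_timecourse={0.0: 1.0, 30.0: 1.0},
            catalase_fold_timecourse={0.0: 1.0, 30.0: 1.0},
        ),
        DosePreset(
            name="0.5mM",
            dose_mM=0.5,
            # ER halved (~8 aa/s) at 5 min, back to normal by 30 min
            er_timecourse={5.0: 8.0, 15.0: 12.0, 30.0: 16.0},
            growth_mode="recovering",
            lag_min=15.0,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.3, 15.0: 0.6, 30.0: 1.0},
            catalase_fold_timecourse={0.0: 1.0, 10.0: 2.0, 30.0: 5.0, 60.0: 6.0},
            interpolated_minutes=(15.0,),
        ),
        DosePreset(
            name="1.5mM",
            dose_mM=1.5,
            # ~3 aa/s at 5 min, recovered at 60 min; lag 38 min; tRNA ~90% down
            er_timecourse={5.0: 3.0, 15.0: 8.0, 30.0: 12.0, 60.0: 16.0},
            growth_mode="recovering",
            lag_min=38.0,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.1, 15.0: 0.3, 30.0: 0.6},
            catalase_fold_timecourse={0.0: 1.0, 10.0: 2.0, 30.0: 5.0, 60.0: 6.0},
            interpolated_minutes=(15.0, 30.0),
        ),
        DosePreset(
            name="5mM",
            dose_mM=5.0,
            # ~1 aa/s at 5 min, ~3 at 40, ~10 at end of the ~90-min lag
            er_timecourse={5.0: 1.0, 40.0: 3.0, 80.0: 10.0, 120.0: 16.0},
            growth_mode="recovering",
            lag_min=90.0,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.05, 40.0: 0.2, 80.0: 0.6},
            catalase_fold_timecourse={0.0: 1.0, 30.0: 1.5, 60.0: 2.5, 100.0: 3.0},
        ),
        DosePreset(
            name="6mM",
            dose_mM=6.0,
            # threshold dose: translation fully stalled, no recovery
            er_timecourse={5.0: 0.0, 80.0: 0.0},
            growth_mode="plateau_then_decline",
            lag_min=None,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.05, 80.0: 0.05},
            catalase_fold_timecourse={0.0: 1.0, 30.0: 1.0, 60.0: 1.0, 100.0: 1.0},
        ),
        DosePreset(
            name="preadapted-8mM",
            dose_mM=8.0,
            # pre-adaptation to 1.5 mM keeps ER significant (3.6 aa/s) at 8 mM
            er_timecourse={5.0: 3.6, 30.0: 10.0, 60.0: 16.0},
            growth_mode="recovering",
            lag_min=30.0,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.15, 30.0: 0.5},
            catalase_fold_timecourse={0.0: 1.0, 30.0: 2.0, 60.0: 3.0},
            strain="preadapted",
            interpolated_minutes=(30.0,),
        ),
        DosePreset(
            name="pRIL-6mM",
            dose_mM=6.0,
            # tRNA overexpression keeps ER at 0.8 aa/s and allows recovery (~2 h lag)
            er_timecourse={5.0: 0.8, 60.0: 6.0, 120.0: 16.0},
            growth_mode="recovering",
            lag_min=120.0,
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.1, 60.0: 0.4},
            catalase_fold_timecourse={0.0: 1.0, 60.0: 2.0, 120.0: 3.0},
            strain="pRIL",
            interpolated_minutes=(60.0,),
        ),
        DosePreset(
            name="Cm",
            dose_mM=1.0,
            # sublethal chloramphenicol: doubling time 170 min vs 43 min drug-free,
            # i.e. the overall translational rate down by ~75%
            er_timecourse={5.0: 4.0, 60.0: 4.0},
            growth_mode="recovering",
            lag_min=100.0,
            lambda_pre=gr.rate_from_doubling(170.0),
            lambda_post=gr.rate_from_doubling(170.0),
            trna_fold_timecourse={0.0: 1.0, 5.0: 0.2},
            catalase_fold_timecourse={0.0: 1.0, 30.0: 1.5},
            strain="Cm",
            notes="lag is qualitative (much longer than drug-free at the same dose)",
        ),
    ]
    return {p.name: p for p in presets}


#: Wild-type dose series used for dose-response and threshold analyses.
WILDTYPE_DOSE_PRESETS = ("normal", "0.5mM", "1.5mM", "5mM", "6mM")


@dataclass
class ScenarioBundle:
    """All synthetic measurements generated from one preset and seed."""

    preset: DosePreset
    induction_traces: Dict[float, tr.InductionTrace]
    growth: gr.GrowthCurve
    ct_table: pd.DataFrame
    catalase_traces: Dict[float, cat.AbsorbanceTrace]
    seed: int
    noise: NoiseLevels


def _species_multipliers(n_targets: int, rng: np.random.Generator, sd_log2: float = 0.3) -> np.ndarray:
    """Per-species fold multipliers, lognormal with SD 0.3 log2 units.

    Re-centred so the multiplier median is exactly one: the median across
    species of ``multiplier * median_fold`` is then exactly the preset's
    median fold.
    """
    mult = np.exp2(rng.normal(0.0, sd_log2, size=n_targets))
    return mult / np.median(mult)


def generate_bundle(
    preset: DosePreset,
    seed: int = 0,
    noise: NoiseLevels = NoiseLevels(),
    reporter: tr.ReporterSpec = tr.LACZ,
    n_targets: int = 26,
    n_reps: int = 3,
    amplitude: float = 1e-3,
    base_catalase_rate: float = 0.05,
) -> ScenarioBundle:
    """Generate every synthetic measurement for one dose preset.

    Child seeds for the four generators are derived deterministically from
    ``seed``, so regeneration with the same seed is bit-identical.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(preset.er_timecourse))]
    growth_seed, ct_seed, species_seed, cat_seed, *induction_seeds = seeds

    calib = tr.InitiationCalibration()
    induction: Dict[float, tr.InductionTrace] = {}
    for (minute, er), ind_seed in zip(sorted(preset.er_timecourse.items()), induction_seeds):
        cond = f"{preset.name}@{minute:g}min"
        if er == 0.0:
            grid = np.arange(0.0, 2400.0 + 15.0, 30.0)
            noise_sd = noise.induction_frac * amplitude * 600.0**2
            induction[minute] = tr.simulate_stalled(
                reporter, baseline=0.0, times_s=grid, noise_sd=noise_sd,
                seed=ind_seed, condition=cond,
            )
        else:
            grid = tr.default_sampling_grid(er, reporter, calib)
            t_first = calib.t_init_s + reporter.length_aa / er
            span = amplitude * (grid[-1] - t_first) ** 2
            induction[minute] = tr.simulate_induction(
                reporter, er, calib, amplitude=amplitude, baseline=0.0,
                times_s=grid, noise_sd=noise.induction_frac * span,
                seed=ind_seed, condition=cond,
            )

    growth = gr.simulate_growth(
        lambda_pre=preset.lambda_pre,
        od0=0.05,
        od_stress=0.2,
        lag_min=preset.lag_min if preset.lag_min is not None else 0.0,
        lambda_post=preset.lambda_post,
        mode=preset.growth_mode,
        noise_cv=noise.od_cv,
        seed=growth_seed,
        condition=preset.name,
    )

    species_rng = np.random.default_rng(species_seed)
    mult = _species_multipliers(n_targets, species_rng)
    true_folds: Dict[str, Dict[str, float]] = {}
    for i in range(n_targets):
        target = f"tRNA_{i + 1:02d}"
        true_folds[target] = {
            f"t{minute:g}": float(fold * mult[i])
            for minute, fold in preset.trna_fold_timecourse.items()
            if minute > 0
        }
    ct_table = qpcr.simulate_ct_table(
        true_folds,
        ct0_target=20.0,
        ct_ref=12.0,
        replicate_sd=noise.ct_sd,
        n_reps=n_reps,
        seed=ct_seed,
    )

    cat_rng = np.random.default_rng(cat_seed)
    catalase_traces: Dict[float, cat.AbsorbanceTrace] = {}
    for minute, fold in sorted(preset.catalase_fold_timecourse.items()):
        catalase_traces[minute] = cat.simulate_absorbance_trace(
            rate_au_per_min=base_catalase_rate * fold,
            a0=1.2,
            protein_conc=2.0,
            noise_sd=noise.a240_sd,
            seed=int(cat_rng.integers(2**31)),
            condition=f"{preset.name}@{minute:g}min",
        )

    return ScenarioBundle(
        preset=preset,
        induction_traces=induction,
        growth=growth,
        ct_table=ct_table,
        catalase_traces=catalase_traces,
        seed=seed,
        noise=noise,
    )
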