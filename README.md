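# oxkinetics

Quantitative analysis of bacterial oxidative-stress physiology: how fast do
ribosomes elongate when *E. coli* is hit with hydrogen peroxide, how long does
growth stay arrested, what happens to the tRNA pools, and how quickly does
catalase accumulate?

The package implements the full measurement-analysis chain of this kind of
study as tested, reusable code, together with a synthetic-data layer that
emulates the dose-dependent measurements so every stage can be verified end
to end without laboratory data. It is aimed at quantitative microbial
physiologists who run reporter-induction, plate-reader growth, qRT-PCR and
enzyme-kinetics assays and want a reproducible way to turn the raw traces
into rates, lags and fold changes.

## What it computes

**Translational elongation rate (ER) from induction kinetics.** After a
gratuitous inducer is added, ribosomes load onto the reporter mRNA at a
constant rate, so the first full-length protein appears at

```
T_first = t_init + L / ER
```

with `L` the reporter length (aa), `ER` the elongation rate (aa/s) and
`t_init` = 10 s the fixed initiation-time calibration. Beyond `T_first` the
accumulated signal grows quadratically, so the square root of the
background-subtracted signal is linear in time — the classical square-root
(Schleif) plot. `SchleifPlotModel.fit()` finds the rise set, regresses
`sqrt(signal − baseline)` on time, takes the x-intercept as `T_first` and
reports `ER = L / (T_first − t_init)`. A trace that never rises above
baseline within the 40-min assay horizon is a *stalled* call (`ER = 0`,
censored), not a failure.

**Growth arrest and lag.** `GrowthPhaseModel.fit()` decomposes an OD600
curve around the stress time into the pre-stress exponential rate λ₁, the
lag (first sustained return of the sliding-window instantaneous rate to
≥ 90% of λ₁), the post-recovery rate λ₂, and a recovered/declining
classification. `doubling_time` and `rate_from_doubling` convert via
`t_d = 60·ln2/λ`.

**qPCR relative quantification.** `relative_levels` applies the 2^−ΔΔCt
transform to tidy Ct tables against a stable 5S rRNA reference target and a
time-zero reference sample; `direct_fold` gives `2^(Ct(0)−Ct(t))` induction
kinetics; replicates are aggregated on the Ct scale (geometric on folds).

**Catalase activity.** `CatalaseAssayModel.fit()` extracts the initial
linear decay rate of A240 (H2O2 decomposition), normalises by total protein
and reports fold changes against a reference condition.

**Dose presets and the pipeline.** `builtin_presets()` encodes the studied
H2O2 conditions (0 / 0.5 / 1.5 / 5 / 6 mM wild type, plus pre-adapted,
tRNA-overexpressing and chloramphenicol-treated scenarios) as ER, lag, tRNA
and catalase trajectories; `generate_bundle` drives all simulators from one
preset and seed, and `build_dose_response` assembles the summary table with
the threshold dose — the smallest dose whose culture never recovers.

## Worked example

Simulate the 1.5 mM scenario and fit the 5-minute induction trace:

```
$ oxkinetics simulate --preset 1.5mM --seed 7 --outdir bundle/
wrote bundle for preset 1.5mM to bundle

$ oxkinetics fit-elongation --input bundle/induction_5min.csv --reporter lacZ
{"t_first_s": 338.24889433980945, "er_aa_per_s": 3.1195840036552744,
 "stalled": false, "r_squared": 0.9854394202029809, "fit_window": [20, 28]}
```

The first LacZ chain appears ~340 s after induction instead of the
unstressed ~74 s, i.e. elongation has slowed about five-fold to ~3 aa/s.
Running the whole wild-type dose series:

```
$ oxkinetics run-all --seed 7 --outdir results/
threshold dose: 6.0 mM
```

with `results/dose_response.csv` containing (abridged):

| dose_mM | er_5min | lag_min | recovered | trna_fold_5min |
|---------|---------|---------|-----------|----------------|
| 0.0     | 19.1    | 0.0     | True      |                |
| 0.5     | 7.7     | 19.4    | True      | 0.32           |
| 1.5     | 3.1     | 37.4    | True      | 0.11           |
| 5.0     | 0.98    | 89.4    | True      | 0.054          |
| 6.0     | 0.0     |         | False     | 0.054          |

Elongation at 5 min after the shock falls monotonically with dose, the lag
grows with dose, and at 6 mM translation is fully stalled and the culture
never recovers — 6 mM is the threshold dose. The tRNA column shows the
median fold remaining at 5 min (≈ 90% depleted at 1.5 mM).

The same stages are available as library calls (`simulate_induction`,
`schleif_fit`, `detect_phases`, `relative_levels`, `activity_from_trace`,
`analyze_bundle`, ...) on in-memory arrays and DataFrames.

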