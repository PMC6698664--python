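# Methods

This note documents the models, estimators and numerical choices behind
oxkinetics, and what the synthetic-data layer does and does not emulate.

## Reporter-induction kinetics and the square-root plot

Model. After inducer addition, ribosomes initiate on the reporter mRNA at a
constant rate. Completion of the first full-length chain occurs at
`T_first = t_init + L/ER`; afterwards chains finish at a constant rate, so
the accumulated reporter signal is

```
S(t) = baseline + A · max(0, t − T_first)²
```

with `A` an arbitrary signal amplitude (units signal/s²). `t_init` (default
10 s) is an opaque calibration offset covering the initiation steps before
elongation; the package does not attempt to decompose it. The inversion is
`ER = L/(T_first − t_init)`, defined only for `T_first > t_init`. Reporter
lengths: the two GFP fusions are 639 and 952 aa; LacZ is a configured
constant of 1024 aa (consistent with the induction-assay literature and
with the printed (≈350 s, ≈3 aa/s) pair; override via `ReporterSpec`).

Estimator. The Schleif fit:

1. Baseline = mean of the first `baseline_window` (4) points.
2. Noise SD = `1.4826·median(|ΔS|)/√2` over the whole trace. Successive
   differences are noise-dominated because the quadratic is locally flat at
   the sampling scale, and the median tolerates the rise contributions.
   The SD of only four baseline points proved far too unstable: an
   underestimate lets pre-rise noise into the rise set and drags the
   x-intercept toward zero.
3. Detection threshold = baseline + `detection_k` (3) noise SDs, with a
   floor of 2% of the background-subtracted maximum when the noise estimate
   is exactly zero (noiseless fixtures).
4. Rise set = the contiguous tail of points above the threshold (everything
   after the last below-threshold point). On noisy traces the first
   `boundary_drop` (2) tail points are discarded: they are in the set
   *because* they beat the threshold, and that selection biases them upward.
5. Unweighted OLS of `sqrt(S − baseline)` on time over the rise set;
   `T_first` is the x-intercept. A negative slope, an R² below the
   configured minimum (0.5) or `T_first ≤ t_init` raise a fit failure —
   deliberately distinct from the stalled call.
6. Stalled: fewer than `min_fit_points` (5) rise points within the
   `max_horizon_s` (40-min) assay horizon. The call is monotone under
   truncation: shortening an already-flat trace can only shrink the rise
   set.

Weighted least squares on the sqrt scale was evaluated (the transform makes
the noise heteroscedastic, Var[√S] ≈ σ²/4S) but did not improve the
ensemble bias, which is dominated by detection-boundary selection; the
simpler unweighted fit is kept and cross-checked in the tests against an
independent raw-signal grid-search oracle that never applies the transform.

Sampling grids. Default grids use 10-s spacing for ER ≥ 5 aa/s and 30-s
spacing below (manual 10–30-s aliquot sampling), with the horizon chosen so
the expected `T_first` sits ~60% of the way through the assay. This mirrors
the practice of sampling until the rise is clearly established and keeps
the x-intercept extrapolation short; stretching the horizon far beyond the
rise was found to condition the intercept badly at fast rates. Stalled
assays span the full 40 min at 30-s spacing.

## Growth curves

Simulation: exponential at λ_pre (per hour) until OD reaches `od_stress`,
then per mode: flat for `lag_min` followed by exponential at λ_post
(recovering); flat plateau (default 180 min) then exponential decline
(plateau_then_decline); or immediate decline. Noise is multiplicative
lognormal with the given CV (instrument error scales with signal), mean-one
parameterisation.

Analysis: λ estimates are OLS slopes of ln(OD) versus hours.
The instantaneous rate is a centred 5-point sliding-window slope (truncated
at the edges). The lag endpoint is operationalised — the endpoint criterion
is not part of the assay itself — as the first time the instantaneous rate
reaches and sustains ≥ 90% of λ_pre for 3 consecutive windows; the reported
resume time subtracts half a window (the window centre lags the kink in
ln OD by construction), which places the detected lag within one sampling
interval of the truth on noiseless curves. Declining means the terminal
rate stays below −0.02/h for 3 windows, so noise cannot trigger a spurious
death call; a curve that ends too soon after the stress raises an
inconclusive error rather than a non-recovery call.

## qPCR quantification

Fold changes use the textbook 2^−ΔΔCt with amplification efficiency fixed
at 2.0 (configurable; no efficiency correction is applied by default).
Replicates are aggregated on the Ct scale — arithmetic mean and sample SD —
which is exactly geometric-mean aggregation on the fold scale; the fold
error band is `fold·2^(±sd)` with target and reference SDs at the same
sample combined in quadrature. A single replicate is flagged low
confidence. The reference target (default `5S_rRNA`) is modelled as
constant across samples, reflecting the stability of rRNA pools under
oxidative stress; the reference sample (default `t0`) has fold 1 by
construction.

The Ct simulator inverts the transform: `Ct = Ct0 − log2(fold)` plus
Gaussian replicate noise (SD 0.1 cycles by default, triplicates).

## Catalase assay

A240 decay is modelled as linear over the initial-rate window (zero-order
in excess substrate); activity is the negative OLS slope over the first
120 s (default), clipped at zero, divided by the protein concentration
(mg/mL). An exponential mode (slope of ln A240, reported as the initial
rate) exists but the linear number is the default. Activity is invariant
to constant absorbance offsets; fold changes divide by a reference
condition's normalised activity.

## Dose presets and the synthetic layer

Each preset records, for one condition, the ER time course, growth
behaviour and the median tRNA and catalase fold time courses. Anchor values
are the study conditions: unstressed ER ≈ 16 aa/s and λ ≈ 0.96/h; at 5 min
post-shock ER ≈ 8 / 3 / 1 / 0 aa/s for 0.5 / 1.5 / 5 / 6 mM with lags of
15 / 38 / 90 min and a non-recovering 6 mM threshold (≈3-h plateau, then
decline); median tRNA folds at 5 min of 0.3 / 0.1 / 0.05; catalase rising
several-fold within 30 min at low doses, slower at 5 mM, flat at 6 mM;
plus pre-adapted (3.6 aa/s at 8 mM), tRNA-overexpressing (0.8 aa/s at 6 mM
yet recovering, ~2-h lag) and chloramphenicol (λ from a 170-min doubling
time) scenarios. Time points between anchors are linear interpolations and
are flagged `interpolated_minutes`, never treated as measured values. Where
a value was needed but only qualitative information exists (e.g. the
0.5 mM tRNA drop "milder" than 1.5 mM, the chloramphenicol lag "much
longer"), a single realistic value was fixed once and is noted on the
preset.

Per-species tRNA scatter is lognormal around the preset median with SD 0.3
log2 units, with multipliers re-centred to median exactly 1 so that the
median recovered fold of a noiseless bundle equals the preset value
exactly. Default noise: induction SD 5% of the trace's dynamic range, OD
CV 1%, Ct SD 0.1 cycles, A240 SD 0.002 AU — all configurable, all drawn
from child seeds derived deterministically from the bundle seed, so
regeneration with the same seed is bit-identical.

What the generator does not emulate: pipetting/timing irregularities and
plate-position effects, baseline drift and autofluorescence, qPCR
efficiency differences between targets, substrate-depletion curvature in
the catalase assay, biological replicate-to-replicate variability, and any
mechanistic coupling between the four assays (each trajectory is imposed,
not derived from a shared H2O2-clearance model). Passing round-trip tests
therefore demonstrates that the estimators invert the stated measurement
models at realistic noise levels — not that those models capture every
failure mode of real instruments.

## Problem sizes and determinism

Round-trip and ensemble tests use 26 qPCR targets × 3 replicates, growth
curves of 150–300 points at 2-min sampling, induction traces of 20–70
points, and 100-trace Monte-Carlo ensembles for the noisy Schleif fit —
sizes matching the emulated assays while keeping the whole suite fast. All
stochastic paths take explicit seeds; hypothesis-based property tests are
bounded and deterministic under its default derandomised CI profile.

## Known limitations

- The Schleif estimator's per-trace spread grows quickly for fast rates
  (short `T_first` against a fixed 10-s sampling floor); ensemble means at
  ER = 16 aa/s carry a few-percent upward bias from the 1/(T_first−t_init)
  convexity. Slow rates (≤ 8 aa/s), where the biology of interest lives,
  recover to within a few percent.
- The lag detector assumes an abrupt arrest and an abrupt resume; gradually
  accelerating recoveries would read as a longer lag.
- ΔΔCt assumes equal amplification efficiency for target and reference;
  set `efficiency` explicitly if calibration data say otherwise.
- The threshold dose is identified from recovery classification over the
  supplied dose set; it is a property of that set, not an interpolated
  critical concentration.
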