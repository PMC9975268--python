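# Methods

## Scope and design

The package is organised as an analysis project: the library under
`src/pepstress/` holds every computation (cohort simulation, quality
control, stress statistics, load-state classification, BP-uncertainty
propagation), the numbered scripts under `analysis/` are thin narrative
drivers, and `scripts/acceptance.py` recomputes the headline statistics from
scratch. Because no raw recordings of the emulated study are publicly
deposited, all analyses run on synthetic cohorts whose generator encodes the
study's printed statistical structure; the analyses themselves are written
against plain CSV tables and work unchanged on real per-measurement records
with the same schema.

## The cohort model

**Subjects.** 71 subjects by default (34 male / 37 female). Age, height and
weight are truncated Gaussians per sex (men 183.3 ± 7.1 cm, 79.2 ± 10.1 kg;
women 167.6 ± 4.9 cm, 59.2 ± 6.2 kg; ages ~22 ± 3 y), with a within-sex
height–weight correlation of 0.4. Maximum heart rate is 220 − age; resting
heart rate is ~N(65, 8) bpm truncated to [48, 92].

**Resting PEP (ms).** For subject *i*:

```
pep_rest_i = 104.5 + 0.26·(w_i − w̄) + 0.02·(h_i − h̄) + sex_i
             − 0.30·(hr_rest_i − h̄r) + ε_i,   ε_i ~ N(0, 10.5²)
```

All covariate terms are centred so the cohort mean stays at 104.5 ms. The
female sex term is −0.3 ms; most of the raw female−male difference
(≈ −6 ms) flows through the weight/height channels, mirroring how sex,
stature and resting PEP are entangled in observational cohorts. The
between-subject SD (~12.5 ms total) is an order of magnitude above the
within-subject measurement SD (4.5 ms), giving the ~50% inter-individual
range seen at rest.

**Mental load.** The fractional PEP reduction at stress question *q* is
`reactivity_i · g(q)` with `g(q) = 0.88 + 0.12·0.70^(q−1)`: a dominant
sustained-arousal component plus a habituating transient.
`reactivity_i ~ N(0.145, 0.10)` truncated to [0.02, 0.30]. Heart rate rises
by 125 bpm per unit of drive (≈ +17 bpm at the mean first question). The
sustained fraction is deliberately large: a first-question reduction of
~14–15% *and* an all-question mean PEP of ~90 ms (−13.9%) are only jointly
possible if the effect decays mildly — a response that collapses to zero by
the last question would leave the pooled mean several ms higher. The
habituation profile is therefore "attenuation", not extinction; both
parameters are configurable for stronger-habituation scenarios.

**Physical load.** Load rises in steps of 0.4 W per kg body mass; heart
rate responds linearly (~0.62 ± 0.05 bpm/W) until it exceeds 80% of maximum
(measurement at the exceeding step included, then a break, a short second
ascent to the previous top step, and end-of-session rest). Expected PEP
while treading is

```
pep = pep_rest·(1 − 0.14) + slope_i·(HR − hr_rest),   floored at 0.5·pep_rest
```

— a treading onset offset (posture/motor activation shortens PEP before
heart rate has moved much), then a linear decline along a per-subject slope
(the geometric slope to the stop line, log-normally jittered by 8%), capped
at a 50% total reduction. The onset offset realises the observed state
ordering at matched heart rate (rest > mental > physical); the cap encodes
the physiological floor of isovolumetric contraction. During breaks PEP
recovers along the same line but attenuated by 0.30: PEP rebounds quickly
while post-exercise tachycardia decays slowly. This fast-PEP/slow-HR
recovery is what separates the pooled PEP~HR R² (~0.55) from the
treading-only R² (~0.60–0.65) — recovery points sit well above the pooled
regression line.

**Coupled surrogates.** Heather index, LVET and SBP are statistical
emulations coupled to the expected (noise-free) PEP, with noise SDs set so
the pooled cohort R² values match the study level (≈ 0.65 / 0.31 / 0.45):
Heather = 11 + 0.28·(104.5 − PEP) ± 3.9 (the index's absolute scale is
arbitrary); LVET = 295 + 1.9·(PEP − 104.5) ± 53 ms; SBP = rest SBP
(~121 ± 9 mmHg) − 0.8·ΔPEP ± 9.5 mmHg; DBP is a passthrough column. These
are *not* beat-physiology models — they exist so that correlation analyses
have the right cohort-level answer.

**Beats.** Beat-level PEP = phase expectation + a slow AR(1) fluctuation
(lag-1 0.93; vagal/respiratory modulation) + 1 ms white jitter. The AR(1)
scale is derived analytically (plus a small calibrated correction) so that
the *measured* SD of the 4-beat-averaged resting series over a 60-s window
is the configured 4.5 ms — the autocorrelation is why 4-beat averaging
barely reduces it, while genuinely white noise is reduced by ~1/4 (a
property the QC tests check separately). The Q–R interval is drawn per beat
(subject mean ~36 ± 3 ms, within-subject SD 2.5 ms) independently of heart
rate; Q-start PEP = R-start PEP + Q–R interval. Optional artifacts multiply
heart rate by 1.5 for short runs at a configured per-beat rate. Beat windows
for different phases are separated by 120 s of unrecorded protocol time, so
protocol transitions are not mistaken for artifacts.

**Cuff curves.** Linear inflation to SBP + 35 mmHg, 1-s hold, 3 mmHg/s
deflation, 10 Hz sampling, 0.15 mmHg sensor noise. Disturbances add a
Gaussian bump (14–20 mmHg, σ = 0.6 s) mid-deflation, sized to exceed the
8 mmHg rejection threshold net of the ramp.

**Seeding.** One master seed; `numpy.random.SeedSequence` spawns independent
substreams for subjects, measurements, beats and cuff curves. Identical
(config, seed) reproduces the dataset byte-for-byte.

## Quality control

* **Heart-rate artifacts:** a beat is invalid if its rate differs by more
  than 30% from *any* beat within the preceding 3 s (strictest reading;
  both thresholds configurable). Exclusion granularity is epoch-level by
  default, per-beat optionally.
* **Cuff curves:** the deflation segment (peak onward) must not climb more
  than 8 mmHg — measured as the maximum cumulative rise from any earlier
  deflation sample, which is robust to sampling rate; exactly 8 mmHg passes
  (the rule is a strict inequality).
* **Averaging:** right-aligned 4-beat sliding mean over valid beats only,
  preserving series length for regression against measurement epochs.

## Statistics

Relative PEP is each measurement divided by the subject's first valid
resting measurement (the calibration), making the rest reference exactly 1.
Phase CIs are seeded bootstrap percentiles (1000 resamples, 95%). All
regressions are ordinary least squares; R² for the linear fits equals the
squared Pearson correlation (asserted in tests). The SBP correlation is
computed on deltas from rest for both variables. The heart-rate relation is
additionally fitted with a configurable polynomial (degree 2 default) for
its non-linear pooled distribution. Group contrasts use
within-subject-centred least squares with cluster-robust intuition (each
subject contributes its own reference) rather than reproducing any specific
mixed-model software configuration; the three-condition contrast (rest /
first question / top load) is a one-way ANOVA with Bonferroni-corrected
pairwise tests (family of 3).

## Classifier

One (ΔPEP, ΔHR) point per subject per state: state means minus the single
rest-calibration measurement (the rest point uses the remaining rest-state
measurements, so it scatters around the origin with realistic calibration
noise). k-NN with k = 13 on z-scored features (standardisation fitted on
training folds only), Euclidean distance; vote ties resolved by smaller
summed neighbour distance, then fixed class order — fully deterministic.
Evaluation partitions *subjects* into five folds (80/20), repeated 20 times
with reshuffled fold assignments; PPV and sensitivity are averaged over the
three classes and all folds. The scikit-learn k-NN serves as an independent
cross-check on tie-free data in the tests.

## BP-uncertainty propagation

Published PWV↔SBP relations differ, so the mapping is pluggable with two
built-in monotone forms — exponential PWV growth
(`PWV = 5·exp(0.008·(SBP − 100))` m/s) and quadratic
(`SBP = 30 + 12·PWV + 0.4·PWV²`) — with an arterial path length of height ×
0.5 (1.80 m standard human → 0.90 m, heart-to-periphery convention). Every
asserted property (decomposition identity, nested bands, monotone error
growth, strategy ordering) holds for both forms; the absolute band curves
depend on the chosen relation and are not claimed to match any particular
published figure. PTT is inverted to SBP by bracketed root finding on the
supported range (40–220 mmHg); band edges leaving the range are clipped
with a warning. The ±1/±2 SD bands use the binned residual SD of the PEP
polynomial (10 mmHg bins); note the top SBP bin is populated by
maximal-load measurements whose PEP sits near the 50% floor, so its
residual SD — and hence the band width there — can dip even though the
mapping itself steepens (visible in the worked example).

Strategy comparison simulates (true SBP, PAT = PTT(SBP) + observed PEP)
pairs from the cohort: *neglect* inverts PAT as if it were PTT; *estimate*
solves the fixed point PTT(ŝ) = PAT − fitted-PEP(ŝ); *calibrate* subtracts
the subject's resting PEP. Reported as absolute-error summaries.

## Calibration of generator defaults

Parameters the emulated study prints (cohort composition, 104.5 ms, 4.5 ms,
the 0.4 W/kg step, the 80% stop rule, QC thresholds, k = 13, fivefold) are
taken as-is. Free parameters — noise SDs, coupling strengths, the
reactivity distribution, recovery dynamics — were calibrated once, by
simulation, so the generator reproduces the study-level statistics
(stratified and pooled R², sex difference, anthropometric R², classifier
performance, matched-heart-rate ordering) under the default conditions, and
then frozen. They are study-condition definitions, not fitting knobs; the
acceptance script measures them from fresh seeded cohorts at run time.

## Problem sizes

Default analyses use the study-scale cohort (71 subjects, ~1770 measurement
epochs). Aggregated recoveries average over seeded replicates: 50 cohorts
for the PEP means, 12 for beat-window SDs, 10 pooled for regressions, 20
for the sex difference. The full test suite runs in about a minute; the
acceptance script in ~15 s.

## What passing does and does not show

The generator reproduces the study's *statistical* structure: means,
dispersions, couplings, protocol geometry and artifact rules. It does not
synthesise waveforms, beat-morphology noise, device-specific bias, motion
artifacts beyond the modelled heart-rate jumps, drifting baselines, or
diseased/older physiology (the emulated cohort is young and healthy — PEP
behaviour under medication, arrhythmia or stiff arteries is out of scope).
Passing tests therefore demonstrates that the analysis code recovers known
structure correctly and propagates it faithfully — not that a specific
device or population will show these exact numbers. Likewise the absolute
SBP-error magnitudes depend on the configured PWV↔SBP form; the robust
findings are the orderings and scalings, which hold for any monotone
mapping.

## Known limitations

* The mental response model keeps a large sustained component (see above);
  scenarios with full habituation require lowering
  `mental_sustained_fraction`.
* The `estimate` strategy assumes the PEP–SBP regression from the same
  cohort is available — in deployment it would come from a reference
  population, adding transfer error not modelled here.
* Recovery dynamics use fixed recovery fractions rather than a continuous
  exponential; only the measurement epochs are modelled.
* The Heather index scale is arbitrary (device index units); only its
  correlation structure is meaningful.
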