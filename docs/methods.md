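# Methods

`neonatal_ema` estimates a functional brain age — the EEG maturational age
(EMA) — for preterm infants from multichannel cot-side EEG, and evaluates
how well that estimate tracks the post-menstrual age (PMA) across serial
recordings.  This note documents the model, the parameters that matter,
the synthetic cohort used for validation, and the numerical choices made
where the design was genuinely open.

## Signal model and preprocessing

Input is referential EEG (9 scalp electrodes, Cz reference) at its native
rate (typically 256 Hz).  Preprocessing normalises bandwidth and rate
before any feature sees the data:

1. zero-phase band-pass 0.5–32 Hz.  The filter is an order-8 Butterworth
   applied forward–backward (`sosfiltfilt`); the order was chosen so the
   passband droop stays below 5% out to 25 Hz while 0.1 Hz drift and
   45 Hz interference are attenuated by far more than 20 dB.  Zero-phase
   filtering matters because burst timestamps feed interval statistics:
   a causal filter would shift every onset by the group delay.
2. polyphase resampling to 64 Hz (anti-aliasing is already guaranteed by
   the 32 Hz band limit).
3. fixed bipolar montage Fp1-C3, C3-O1, Fp1-T3, T3-O1, Fp2-C4, C4-O2,
   Fp2-T4, T4-O2.  Filtering precedes montage construction; both are
   linear so the order is immaterial for the bipolar result, but the
   referential channels are retained at the same bandwidth because one
   artefact rule operates on them.
4. segmentation into 1-hour epochs with 75% overlap (offsets 0, 15, 30,
   45 min …).  Trailing partial epochs are dropped — every feature
   assumes a full epoch of context.  Shorter epochs (e.g. 10 minutes in
   simulation studies) are supported via `PipelineConfig.epoch_len_s`,
   with the SAT% window, step and minimum-run lengths scaled
   proportionally (window = epoch/12, step = epoch/60).

## Burst (SAT) detection

Preterm EEG alternates high-amplitude spontaneous activity transients
(SATs) with low-amplitude inter-SAT periods; the interval statistics of
this discontinuity are among the strongest maturational signals.  SATs
are detected per bipolar channel with a rectified cross-form nonlinear
energy operator, psi[n] = |x[n]·x[n−3] − x[n−1]·x[n−2]|, smoothed by a
1.5 s moving average.  Samples above a threshold θ form candidate
events; gaps shorter than 1 s are merged and events shorter than 1 s
dropped.

θ defaults to 160 µV².  It was calibrated on the synthetic generator
(below) against the contract that bursts with envelope scale ≥ 25 µV are
detected with ≥ 95% event-level sensitivity while pure inter-burst
activity produces ≤ 5% false events: the smoothed-NLEO level of term-age
inter-burst activity (99th percentile ≈ 154 µV²) stays below the level
inside the weakest 24-week bursts (10th percentile ≈ 217 µV²), so a
single absolute threshold in that gap separates the two classes at every
age.  Measured performance at θ = 160: sensitivity ≥ 98.9%, false-event
rate ≤ 1.9%, median onset error < 0.7 s.  All detector parameters are
exposed in `SATDetectorConfig`.

A per-epoch consensus annotation marks samples active on at least half
of the non-excluded channels (SATs are spatially widespread; the SAT%
trace and SAT-timing features use one annotation per epoch).  Per-channel
annotations are retained for the high-amplitude artefact rule and the
synchrony index.

**SAT% and the quiet-sleep proxy.**  SAT% is the percentage of a
5-minute window covered by consensus SAT activity, advanced in 1-minute
steps (56 windows per 1-h epoch).  The low-SAT% segment — a proxy for
quiet sleep, when the EEG is most discontinuous — is delimited in two
passes: threshold the trace at its lower quartile, discard
below-threshold runs shorter than 5 minutes, re-estimate the quartile
from the remaining windows and emit the surviving runs.  A run of k
consecutive windows counts as k minutes.  "Below threshold" is strict;
when the quartile ties with the trace minimum (two-level traces) the
comparison becomes inclusive so the low level is still selected.  A
constant trace yields the full epoch with a warning.

## Artefact screening

Two deterministic amplitude rules replace visual preselection:

* **High amplitude:** a SAT is artefactual if |v| exceeds 500 µV at any
  time during the SAT on any channel (evaluated on the filtered 64 Hz
  signal, where the annotations live).  The epoch-level contamination
  fraction is the union of artefactual SAT time over channels divided by
  the epoch length.
* **Low amplitude (electrode shorting):** a bipolar channel is excluded
  when its median envelope over time is below 50% of the median envelope
  over time and channels.  Because several simultaneously flat channels
  drag the pooled median down, the rule iterates to a fixed point,
  excluding the worst channel first.  A referential electrode is flagged
  when its median envelope is below 50% of the pooled referential median
  *and* its 95th-percentile envelope is under 25 µV; every bipolar
  channel derived from it is then excluded.

An epoch is accepted iff no channel is excluded and the contamination
fraction is at most 20%.  Ties (exactly 50%, exactly 25 µV, exactly 20%)
are non-exclusions: the rules are strict inequalities.

## Features

Twenty-three features per analysis segment, two segments (full epoch and
low-SAT% segment), 46 in total:

| family | features | estimation |
|---|---|---|
| envelope | p50, p95 of |analytic signal| | per channel → median |
| range-EEG | p5, p50, p95 of per-window peak-to-peak (2 s non-overlapping windows) | per channel → median |
| spectrum | absolute power in delta 0–3, theta 3–8, alpha 8–15, beta 15–30 Hz; total 0–30 Hz; 4 relative powers | Welch (2 s Hamming, 50% overlap), per channel → median |
| SAT timing | SATs/hour; SAT-duration p5, p50, p95; inter-SAT-interval p5, p50, p95 and RMS | consensus annotation |
| synchrony | activation synchrony index | homologous channel pairs |

Notes:

* The total power is the sum of the four band powers (the bands
  partition 0–30 Hz).  The cross-channel median is not linear, so the
  aggregated relative powers are renormalised to sum to one — they
  remain a composition by construction.
* In the low-SAT% segment, SAT intervals are clipped to the mask and
  inter-SAT intervals never bridge disjoint mask blocks; rEEG windows are
  kept when their centre lies in the mask; envelopes are computed on the
  full epoch and subsampled by the mask (avoids Hilbert edge effects at
  block boundaries).
* The activation synchrony index binarises burst activity at 1 s
  resolution per derivation (a second is active when at least half of it
  is inside a SAT) and computes, per homologous left/right pair, the
  coincidence ratio CR = P(both)/(P(left)·P(right)); the index is the
  median CR over valid pairs.  CR is 1 under independence and 1/P under
  perfect synchrony; pairs with a zero marginal are dropped.  This is a
  deliberately simple coincidence statistic, not a reimplementation of
  any published synchrony measure.
* Features that cannot be estimated (fewer than two SATs in a segment,
  zero total power) are left missing and imputed with training-fold
  medians at model time — never with test-fold statistics.

## Brain-age regression

The EMA is an RBF-kernel ε-SVR over the 46 z-scored features, target in
days.  Evaluation is leave-one-infant-out (LOIO): all recordings of an
infant form one outer test fold, so no infant straddles train and test.
Per training fold:

* hyperparameters are grid-searched in an internal 3-fold CV (grouped by
  infant) minimising MSE: C ∈ 2^−2…2^6, ε ∈ {0.5, 1, 2, 4, 8} days,
  γ ∈ 2^−6…2^2 divided by the number of active features;
* optional backward feature selection runs a complete elimination path
  46 → 1, scoring each candidate subset by 10-fold CV MSE and removing
  the feature whose removal scores best (ties: lowest roster index); the
  returned subset is the path minimum;
* the per-recording EMA is predicted from the mean feature vector over
  the recording's accepted epochs (predict-per-epoch-then-average is
  config-selectable); predictions are clamped to a plausible reporting
  range of 140–320 days with a warning.

Two numerical choices keep the complete path tractable on one CPU.
First, the RBF kernel depends on the feature subset only through the
pairwise squared distance, which is additive over features; per CV split
the per-feature squared-difference matrices are precomputed and the
current subset's distance matrix updated incrementally, so scoring one
candidate removal costs O(n²) plus an SVR fit on a precomputed kernel.
Second, by default the hyperparameters used along the path are the ones
optimised for the full feature set on that training fold (γ rescaled
with subset size); `selection_grid="full"` nests the entire grid search
inside every subset evaluation instead, at roughly 400× the cost.  The
selection CV and the final refit re-run the standard search.

Null behaviour worth knowing: on pure-noise features the cross-validated
MSE of the full-feature SVR sits at the target variance (no fake skill),
but the *outer* LOIO MSE after complete-path selection lands above the
target variance — leave-one-out predictions anti-correlate with the
held-out target (factor (n/(n−1))² ≈ 1.05 at n = 40) and minimising over
~1080 correlated subset evaluations adds a winner's-curse overfit
(measured ≈ 1.4× at n = 40).  This is a property of the nested procedure
itself, not of the implementation.

## Repeated-measures evaluation

Serial recordings within an infant are correlated, so agreement between
EMA and PMA is summarised by a linear mixed model
EMA_ij = β₀ + β₁·PMA_ij + u_i + ε_ij with a random intercept per infant
(REML).  The adjusted correlation is the Pearson r between PMA and the
random-intercept-corrected EMA (EMA − û_i); a marginal-R² variant was
considered and rejected as less interpretable for this design.  Singular
fits (zero intercept variance) fall back to OLS with a warning.  Error
metrics are per-recording: MSE (days²), bias, error SD, mean absolute
error as % of mean PMA, and the share of recordings within 1 and 2 weeks
(|e| ≤ 7 and ≤ 14 days, inclusive).  Growth analysis classifies each
infant's trajectory (first-to-last and consecutive-pair increases) and
attributes decreasing pairs to outlier recordings (|EMA − PMA| > 14
days).  Reduced-montage variants (4- and 2-channel symmetric subsets of
the 8 derivations) are compared with the 8-channel reference by a
two-sided Wilcoxon signed-rank test on per-recording squared errors,
zero differences dropped.

## Synthetic cohort

No clinical neonatal EEG can ship with the package, so a generator
produces cohorts with known ground truth.  It emulates the *statistical*
fingerprint the estimator exploits, not the visual morphology of preterm
EEG (no delta brushes, no temporal sawtooth, no true sleep-cycle
architecture):

* burst/inter-burst alternation with gamma-distributed inter-SAT
  intervals whose mean falls log-linearly from 30 s at 24 weeks PMA to
  6 s at 38 weeks; lognormal burst durations (median 4 s, deliberately
  age-flat — burst duration carries little age information);
* burst envelope scale rising 50 → 120 µV and inter-burst floor
  5 → 25 µV; signals are band-weighted Gaussian noise (delta-dominant at
  all ages, beta weight rising with age) modulated by the burst
  envelope; each electrode carries an independent noise realisation with
  its hemisphere's shared schedule, so bipolar derivations keep bursts;
* interhemispheric synchrony: each left-hemisphere event is copied to
  the right with an age-rising probability (0.4 → 0.9), otherwise
  displaced within its local gap;
* a two-state slow modulation (active/quiet) doubles the mean inter-SAT
  interval in quiet periods so every epoch has a genuine low-SAT%
  segment;
* biological variability: the generative age of a recording is the
  chart PMA plus a stable per-infant offset (SD 7 days — differing
  maturational tempo and conception-date uncertainty) plus a
  per-recording jitter (SD 3 days).  Without this the cohort is
  unrealistically clean and any regressor recovers age almost exactly;
  with it, the evaluation's random-intercept structure is actually
  exercised;
* injectable artefacts with labels: >500 µV excursions inside chosen
  SATs and near-flat (5%-scale) electrodes.

Recordings are written as EDF (16-bit, 1-s records, ±1000 µV physical
range) at 256 Hz to exercise the resampling path; the writer is built in
(no installed package exports EDF) and round-trips against the
independent `mne` reader in tests.

Passing tests on this cohort demonstrate that the pipeline recovers the
statistical structure it is designed to read; they say nothing about
robustness to real-world EEG morphology, electrode artefact variety
beyond the two amplitude classes, or inter-device differences.

## Validation problem sizes

Simulation studies use 10-minute recordings (one epoch each) with
proportionally scaled SAT% windows, 30-infant cohorts (2–4 recordings
per infant, 4–5 week spacing), and the complete selection path in its
default fixed-hyperparameter mode.  At these sizes the full
end-to-end recovery runs in a few minutes: the adjusted r on the default
cohort is ≈ 0.99 with MSE ≈ 35 days², every infant shows increasing EMA
first-to-last, detector sensitivity is ≥ 99% with ≤ 2% false events, and
the three informative features in the support-recovery study are
retained in 100% of folds (all values recomputed by
`scripts/acceptance.py` and the test suite, not asserted constants).

## Known limitations

* The SAT detector threshold is absolute (µV² on the smoothed NLEO) and
  calibrated to the generator's amplitude trends; real recordings with
  different gains would need recalibration or the config hook.
* The 23-feature roster fixes the envelope family to {p50, p95}; the
  roster is config-extensible but the 46-column contract is fixed.
* The activation synchrony index is a coincidence ratio, not a
  validated clinical synchrony measure.
* `compare_montages` covers subsets of the fixed 8-derivation montage;
  derivations outside it (e.g. central-temporal) would require new
  bipolar pairs from the referential data.
* The mixed model assumes a common slope; infant-specific slopes are out
  of scope.
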