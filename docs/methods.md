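# Methods

This note documents the models, procedures and numerical choices behind
`laterp`, in the order the pipeline runs them.

## Experimental design being emulated

Each trial of the search task has a *pattern phase* — streams of runic
symbols left and right of fixation, one side cycling fixed ordered triplets
(drawn from a 9-symbol inventory partitioned into three triplets), the other
showing a disjoint 9-symbol set pseudo-randomly with immediate repeats
forbidden — followed by a *search phase* in which an Exemplar Match target,
a category Foil, or nothing task-relevant appears on one side.  A block
holds 28 Exemplar Match, 28 Foil and 4 Target Absent trials; the sided types
split 14/14 left–right; the patterned side is constant per participant;
order is randomized within block; the pattern phase shows 1, 2 or 3 triplets
(3/6/9 symbols at 400 ms each, so 1200/2400/3600 ms); responses must arrive
within 1600 ms.  `design.generate_design` reproduces these counts exactly
and derives each trial's *symbol position*: `patterned` when the item's side
equals the patterned side, `random` otherwise.  With the 14/14 split this
yields 98 patterned and 98 random trials per lateralized trial type over 7
blocks.

Design gaps filled by the generator (the experiment source does not fix
them): triplet order within a pattern phase is sampled uniformly with
replacement; the random-stream alphabet is the 9 symbols disjoint from the
triplet inventory; foil identities are sampled with replacement.

## Synthetic EEG

Epochs span −100…500 ms at 500 Hz (301 samples).  Per non-Target-Absent
trial a raised-cosine pulse

    s(t) = (a/2) · (1 − cos(2π (t − t₀)/w)),   t ∈ [t₀, t₀ + w]

is injected into the posterior channel contralateral to the item
(PO8 for left items, PO7 for right), nothing into the ipsilateral channel.
The raised cosine was chosen for smoothness, compact support and analytic
integrability — its window mean, threshold-crossing time and fractional-area
time have closed/near-closed forms used as oracles in the tests.

Reference conditions (the defaults): amplitude −2 µV for Exemplar Match,
−0.5 µV for Foil (foil effects are attenuated relative to targets); onset
180 ms for items on the patterned side vs. 240 ms on the random side (a
60 ms attention-shift advantage); width 200 ms; per-sample noise SD 10 µV.

Noise is Gaussian per channel, independently across channels and trials,
with half its variance white and half 1/f-shaped (spectrum weights
f^(−1/2), normalized per trace).  What this emulates: the broadband +
low-frequency mixture of ongoing EEG.  What it does not emulate: spatial
correlation between electrodes (real contra/ipsi subtraction cancels
common-mode noise; the simulation is therefore *conservative* for
difference-wave SNR), non-Gaussian artifacts other than the injected ocular
excursions, and between-participant variation in component parameters
(participants differ only by noise realization, so passing recovery tests
demonstrates estimator correctness and calibration, not robustness to
population heterogeneity).

Ocular artifacts are injected with a configurable per-trial probability: a
100 ms boxcar of ±60 µV on HEOG or ±100 µV on VEOG inside 0–300 ms, flagged
in the trial table so rejection can be checked against ground truth.

Behavior: log-normal RTs (moment-matched mean/SD per trial type; defaults
616 ms Exemplar Match, 660 ms Foil), Bernoulli accuracy, responses beyond
the 1600 ms deadline recorded as missing.  The recognition test draws
two-alternative choices at a configurable probability (default 0.51,
i.e. no usable explicit knowledge) with a categorical confidence
distribution on 1–4.

## Preprocessing

Order: re-reference to averaged earlobes (A1/A2 dropped afterwards) →
zero-phase Butterworth filtering → baseline correction (−100…0 ms) →
artifact rejection → retention of correct, non-Target-Absent trials.

Filters: 40 Hz low-pass (order 8 ≈ 48 dB/octave), 0.1 Hz high-pass
(order 2 ≈ 12 dB/octave), 60 Hz IIR notch (±2.5 Hz half-width), each applied
forward–backward (`sosfiltfilt`) so extrema keep their sample positions.
The nominal roll-offs are mapped to orders at 6 dB/octave/order; the notch
width is a package default.  Filtering is applied to epochs; on a 301-sample
epoch the high-Q notch does not reach steady state near the edges, which
only matters for sustained narrowband content (none is simulated).

Rejection reads "exceeding ±X µV" literally: a trial is rejected iff the
instantaneous absolute amplitude exceeds the class threshold anywhere inside
the class's closed window (HEOG ±25 µV and VEOG ±60 µV in 0–300 ms, all
other channels ±80 µV in −100…500 ms), boundaries inclusive at sample
resolution.  Rejection is monotone in the thresholds, and on noise-free
simulator output the rejected set equals the injected-artifact set exactly.

## Difference waves

Laterality: left-hemifield item → contra = PO8; right → contra = PO7;
Target Absent trials have no reference object and no laterality.  Condition
averages are trialwise means of the contra and ipsi channels per
`(symbol_position, trial_type)` cell; the difference wave is contra − ipsi;
grand averages are unweighted across participants (standard ERP convention,
matching the per-participant structure of the permutation test); jackknife
grand averages leave one participant out at a time.

## Component measures

All measures operate on closed windows at sample resolution with linear
interpolation between samples (2 ms steps would otherwise quantize jackknife
statistics).

*Signed negative area* integrates `min(D, 0)` treating the wave as the
linear interpolant of its samples — a trapezoid rule refined at interpolated
zero crossings, hence exact for the interpolant.  Units are µV·ms; the value
is reported as a non-negative magnitude (larger = more negative area).

*Fractional-area latency* inverts the cumulative negative area at a stated
fraction (default 50%) with linear interpolation inside the bracketing
sample segment; it is undefined (flagged, never silently 0) when the window
holds no negative area, mirroring the exclusion of participants whose data
fail the measure.

*Onset latency* defaults to the first above-to-below crossing of −0.75 µV.
Two robustness options exist for noisy grand averages: `n_sustained = k`
requires k consecutive sub-threshold samples, and `anchor = "peak"` walks
backward from the window's most negative sample to the leading edge of the
component's own sub-threshold run, ignoring disconnected noise dips.  On a
clean wave all variants agree.  First-crossing onsets on noisy averages are
biased early (any noise dip can only advance the first crossing) — with the
default simulation conditions the grand-average noise SD is ≈0.33 µV against
a 0.75 µV threshold, and the bias is a few ms near shallow-sloped crossings.

*Jackknife latency analysis* measures latency on every leave-one-out grand
average, retrieves per-participant scores via `sᵢ = n·L_all − (n−1)·L₍₋ᵢ₎`,
and divides paired t statistics computed on the subsample latencies by
`n − 1` (the jackknife variance-compression correction).  Conditions in
which any subsample misses the threshold are flagged and excluded from
contrasts, and zero-variance contrasts are reported as undefined rather
than infinite.  Two analysis choices matter in practice and are the
package's defaults for its own validation analyses:

* the onset *search window* must cover the expected crossing — for the
  reference conditions the random-side crossing lies near 282 ms, so onset
  analyses use 150–400 ms rather than the 150–300 ms area window, which
  would truncate leave-one-out crossings at the edge;
* latency *contrasts* between conditions use the fractional-area latency
  (`measure="fractional_area"`), a smooth functional of the wave whose
  leave-one-out values cannot jump between rival threshold candidates; the
  absolute-threshold crossing remains the onset *estimate*.  Under the
  reference conditions the corrected jackknife contrast on fractional-area
  latencies detects the 60 ms onset difference essentially always, whereas
  the same contrast on first-crossing onsets fails in roughly 10–20% of
  simulated cohorts purely through crossing-candidate instability.

## Resampling inference

*Signed-area permutation test.*  Within each participant, trial labels
(patterned vs. random symbol position) are reshuffled — separately within
Exemplar Match and Foil trials by default; joint shuffling is an option.
Because the patterned side is fixed within a participant, the label is
one-to-one with the presumed item side, so reassigning it swaps the
contra/ipsi channels and flips the sign of the trial's lateralized trace:
misassigned trials cancel signal while preserving noise.  Each of the 500
reshuffles rebuilds all four grand-average difference waves and their signed
areas, giving one null distribution per condition.  Significance uses the
nearest-rank 95th percentile; p-values use the add-one estimator
`(b+1)/(N+1)`, which is unbiased-conservative and consistent with an
extreme observation reporting p = 1/501 ≈ 0.002 at N = 500.  The procedure's
empirical type-I rate is the theoretical 11/201 ≈ 5.5% per condition
(verified by Monte-Carlo in the acceptance suite).

*Cluster-level t mass.*  Per-time-point one-sample t against chance
(one-tailed, above chance); maximal runs of points with p < α form clusters
scored by their summed t.  Zero-variance points are reported as t = 0
(non-significant, warned) at chance and +∞ above chance.  The null
distribution of maximal cluster masses is built either from a binomial
Monte-Carlo surrogate — per participant and point,
`Binomial(n_attempts, chance)/n_attempts`, the model of a decoder scoring
independent attempts on exchangeable labels (fast, default; it ignores the
temporal autocorrelation of real decoding timecourses and is therefore used
for calibration studies, not as a drop-in for real data) — or from a
user-supplied sampler that re-runs the decoder with permuted labels (exact,
slow).  The critical mass is the null's 95th percentile; cluster p-values
are add-one proportions.

*Bootstrapped SME.*  For one participant and condition, each of
`n_bootstrap` iterations draws `n` trials with replacement, averages them
and applies the measure; the bSME is the SD of those values.  Resampling is
implemented by gathering and averaging trial rows (chunked), so identical
trials give bitwise-identical averages and an exact bSME of 0.  Iterations
in which a latency measure is undefined are dropped and counted.  For the
linear mean-amplitude measure the bSME matches the analytic standard error
σ/√(n·m) (m window samples) for white noise, and scales as 1/√n.  The group
aggregate is the root mean square of per-participant bSMEs.  Study-scale
counts are 10 000 bootstraps and 10 000 cluster permutations; the pipeline
defaults are 2 000 and 1 000, which resolve p to 10⁻³-level granularity at a
desk-scale runtime, with the study-scale values one config assignment away.

## Decoding

Features are the 30 scalp channels (HEOG, VEOG and the earlobe references
excluded), restricted to the analysis window when requested.  Classes are
equated by random subsampling to the smaller class.  Per iteration each
class's trials are partitioned into 3 equal blocks (remainders dropped at
random and logged) and block-averaged; every fold serves as test once — the
full rotation is required for the bookkeeping 2 classes × 3 folds × 10
iterations = 60 attempts per time point.  At each time point features are
standardized with training-block statistics only and a linear SVM (C = 1) is
trained on the 4 training block-averages and tested on the 2 held-out ones.
Class randomization is keyed to each class's trial-index *set* rather than
its label, making accuracy invariant under exchanging the two labels (up to
isolated tied attempts where the decision function is exactly zero).
Degenerate time points (identical training vectors) default to the first
class with a warning.  Window means are tested against 0.50 with a
two-sided one-sample t and Cohen's d; zero-variance samples are reported as
such.

## Pipeline and reproducibility

`AnalysisConfig` holds every constant (windows, thresholds, resampling
counts, decoding setup, cohort design, seed); every output embeds its
SHA-256 digest.  All randomness flows from the config seed through
`numpy.random.Generator`s, and a fixed config reproduces every table,
null distribution and summary byte-for-byte.  `N2pcStudy.fit()` runs
preprocessing → waveforms → measures → permutation test → jackknife →
decoding with cluster inference → bSME/RMS → behavioral and 2AFC summaries,
and returns an `N2pcResults` with tidy tables, a text `summary()` and a
`save()` bundle (CSV + JSON).  The 2×2 within-subject ANOVA is computed from
paired contrast scores (each effect 1 df, F = t², partial η² = F/(F+n−1)),
cross-checked against an independent implementation in the tests; listwise
exclusion handles participants with undefined cells, with the excluded count
reported, so degrees of freedom always reflect the actual qualifying sample.

Problem sizes used by the validation analyses: 19 synthetic participants ×
98 trials/condition for parameter recovery (20 seeds); 200 simulated
6-participant datasets × 200 permutations for permutation calibration;
20 seeds × 98 trials/class × 30 channels × 76 time points for decoding
calibration; 2 000 bootstraps for SME checks; 1 000 permutations for cluster
calibration.  These sizes make the full validation suite run in a few
minutes while keeping every Monte-Carlo band (±2–3 percentage points on
rates, ±10% on SME ratios) comfortably wider than the corresponding
standard errors.

## Known limitations

* The generator omits between-participant parameter heterogeneity and
  inter-channel noise correlation (see above); absolute effect sizes from
  simulations should not be read as predictions for real cohorts.
* First-crossing onset latency is intrinsically unstable when the threshold
  sits within ~2–3 SD of the grand-average noise; prefer the peak-anchored
  variant for estimates and fractional-area latency for contrasts in that
  regime.
* The binomial surrogate null for cluster inference ignores temporal
  autocorrelation of decoding accuracy; use the label-permutation sampler
  for real-data inference.
* Signed areas are reported in µV·ms; toolbox conventions that print areas
  in "µV" rescale by the window length and are not matched numerically.
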