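# laterp

Analysis of lateralized EEG attention components (the **N2pc**) in a
two-location visual-search task whose search displays are preceded by
task-irrelevant symbol streams — one screen side structured into fixed
triplets, the other unstructured.  The package is aimed at cognitive
neuroscientists who want a tested, reproducible implementation of the whole
analysis chain for this class of experiment: epoched-EEG preprocessing,
contralateral-minus-ipsilateral difference waves, scalar component measures,
resampling inference, time-resolved decoding — plus a synthetic-experiment
generator that reproduces the trial design with known ground-truth component
parameters, so every stage can be validated against a recoverable target.

## The measures and tests at the core

For a difference wave `D(t) = contra(t) − ipsi(t)` built from the posterior
pair PO7/PO8 (contralateral defined by the search item's hemifield):

* **Mean amplitude** — mean of `D(t)` over 200–300 ms (µV).
* **Signed negative area** — `A = −∫ min(D(t), 0) dt` over 150–300 ms
  (µV·ms, reported as a magnitude: larger = more negative area).
* **Fractional-area latency** — the time `t*` with
  `∫₁₅₀^t* min(D,0) dt = 0.5 · A`, linearly interpolated.
* **Onset latency** — first crossing of a −0.75 µV threshold, linearly
  interpolated between samples (options: sustained-crossing, peak-anchored).
* **Jackknife latency inference** — onsets measured on leave-one-participant-
  out grand averages; per-participant scores retrieved as
  `sᵢ = n·L_all − (n−1)·L₍₋ᵢ₎`; paired t statistics divided by `n − 1`.
* **Signed-area permutation test** — within each participant the
  symbol-position label is reshuffled across trials (separately for Exemplar
  Match and Foil trials); because the label is one-to-one with the presumed
  item side, misassignment flips the lateralized trace and cancels signal.
  500 reshuffles yield a null distribution of grand-average areas; the
  observed area is significant when it exceeds the null's 95th percentile,
  with add-one p-values `(b+1)/(N+1)`.
* **Decoding** — at each time point a linear SVM separates the scalp
  topography of patterned-side vs. random-side trials; per class the trials
  are split into 3 averaged blocks, and a full cross-validation rotation
  repeated over 10 iterations gives 60 decoding attempts per time point
  (chance 0.50).  Window means are tested against chance; per-point t
  series are summarized by cluster-level t mass against a permutation null.
* **Data quality** — bootstrapped standardized measurement error (bSME): the
  SD of a measure across with-replacement resamples of one participant's
  trials, aggregated across participants by root mean square (RMS).

## Worked example

```python
from laterp import AnalysisConfig, N2pcStudy

config = AnalysisConfig(
    seed=7,
    n_participants=10,
    n_blocks=3,
    noise_sd_uv=5.0,
    artifact_rate=0.05,
    n_permutations=500,
    n_cluster_permutations=500,
    n_bootstrap=1000,
)
results = N2pcStudy.from_config(config).fit()
print(results.summary())
```

prints (abridged):

```
Lateralized ERP (N2pc) analysis
==================================
config digest: c73ef71014f69727   seed: 7
participants: 10

Trial retention (per participant mean): 151.6 of 180.0

Mean amplitude, 200-300 ms (uV):
  exemplar_match / patterned M =  -1.258  SD = 0.783
            foil / patterned M =  -0.150  SD = 0.965
  exemplar_match / random    M =  -0.227  SD = 0.923
            foil / random    M =  -0.279  SD = 1.133

Signed negative area permutation test (150-300 ms, 500 permutations):
  exemplar_match / patterned area =   127.68 uV*ms  p = 0.0080  significant
  exemplar_match / random    area =    30.22 uV*ms  p = 0.0060  significant
            foil / patterned area =    18.04 uV*ms  p = 0.1477  n.s.
            foil / random    area =    42.66 uV*ms  p = 0.1637  n.s.

Jackknife onset latency (-0.75 uV threshold):
  exemplar_match / patterned onset =   226.6 ms
  exemplar_match / random    onset =   277.5 ms
  ('patterned', 'exemplar_match') vs ('random', 'exemplar_match'): t_c(9) = -5.85, p = 0.0002
...
2AFC recognition: proportion = 0.527, t(9) = 1.53, p = 0.160, mean confidence = 2.73
```

Reading the output: the simulated cohort injects a −2 µV raised-cosine
negativity on Exemplar Match trials (−0.5 µV on Foil trials) with onset
180 ms when the item appears on the patterned side and 240 ms on the random
side.  The fit recovers exactly that structure — a robust target N2pc in
both symbol positions (significant signed areas), little or no foil effect,
an earlier onset in the patterned location (corrected jackknife
t_c(9) = −5.85), and behavioral/2AFC tables showing faster Exemplar Match
responses with no explicit pattern knowledge.

The same pipeline runs from the shell:

```bash
laterp simulate --config cfg.yaml --out cohort/   # epochs (HDF5) + trial CSVs
laterp run --config cfg.yaml --out report/        # full fit -> report bundle
```

Per-participant epochs can also be supplied directly
(`N2pcStudy([EpochSet...], config)`); `EpochSet` reads/writes a portable
HDF5 layout and a plain CSV-directory format for tiny fixtures.

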