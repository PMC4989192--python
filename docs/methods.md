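# Methods

`posterp` re-implements, end to end, the analysis of post-error
behavioral and neural adjustments in an equiprobable visual Go/No-go
task: from continuous EEG plus an event log to post-error slowing (PES)
and post-error improvement of accuracy (PIA), condition-sorted ERP
averages, preparatory-component measures (prefrontal negativity pN,
Bereitschaftspotential BP), visual P1/N1 measures, and the inferential
layer (repeated-measures ANOVA, Bonferroni post-hocs, paired t-tests,
Pearson correlations).  Because no compatible public dataset carries the
required trial-sequence structure, the package ships a first-class
synthetic-data module that generates cohorts with known ground truth, so
every stage of the pipeline is verifiable by parameter recovery.

## Task and behavioral model

The simulated task presents 4 equiprobable stimuli (2 Go, 2 No-go) for
260 ms with a stimulus-onset asynchrony drawn uniformly from
1000–2000 ms, in 10 blocks of 80 trials (800 trials, exactly 400 Go and
400 No-go, balanced and shuffled within blocks).  EEG is sampled at
250 Hz.

Behavior follows a first-order sequential rule with these defaults
(group means of the study the package emulates):

| parameter | default | meaning |
|---|---|---|
| `p_fa_after_correct` | 0.111 | P(false alarm) on a No-go trial after a correct trial |
| `p_fa_after_error` | 0.0404 | same, after a false alarm (post-error improvement) |
| `p_miss` | 0.01 | P(no response) on Go trials (unreported in the source; a small value keeps the d' ceiling-correction path exercised) |
| `rt_hit_pre_error_ms` | 408 | median hit RT outside the post-error context |
| `rt_hit_post_error_ms` | 445 | median hit RT after an error (PES = 37 ms) |
| `rt_fa_ms` | 395 | median false-alarm RT |
| `rt_spread_ms` | 70 | RT dispersion (≈ SD in ms) |

RTs are log-normal, parameterized by the median m and a multiplicative
spread exp(sigma) with sigma = spread/m, clipped to the response window
(100–1000 ms after stimulus onset; presses outside that window are not
counted as responses — the SOA floor of 1000 ms makes the assignment of
presses to stimuli unambiguous).  The first trial of a block has no
predecessor and uses the after-correct false-alarm probability.

PES is the median RT of post-error hits minus the median RT of
pre-error hits (positive = slowing); PIA is the false-alarm rate after
correct trials minus the rate after errors (positive = improvement).
Note a small (~2 ms at the default rates) negative bias is built into
any pre-vs-post PES estimate: a hit flanked by two errors counts as
pre-error while being drawn from the slowed post-error distribution.
Sensitivity and bias use d' = z(H) − z(FA) and C = −(z(H) + z(FA))/2
with the extreme-rate correction 1 → 1 − 1/(2N), 0 → 1/(2N) applied to
each rate on its own trial count.

## Forward model of the EEG

A recording is a noise realization plus, for every trial, each
applicable component template placed at its lock time and scaled by the
trial's sequential context.  Templates are piecewise-linear
(rise-peak-fall) time courses with per-channel gains:

* **pN** — negative pre-stimulus ramp at Fp1/Fp2 (right > left), from
  −600 ms to a −2.8 µV peak at stimulus onset.  Over the (−600, 0) ms
  measurement window a triangular ramp averages to half its peak, so the
  post-correct window mean is −1.4 µV; the post-error gain of 2.14
  yields −3.0 µV.
* **BP** — negative pre-stimulus ramp at C1/Cz/C2 (C2 largest), from
  −500 ms to −3.6 µV at onset; window means −1.8 µV (post-correct) and
  −0.8 µV (post-error gain 0.44).
* **P1 / N1** — post-stimulus visual peaks at PO8 (+5 µV, 120 ms) and
  PO7 (−6 µV, 170 ms), with no condition scaling (the study found none).
* **Ne / Pe** — response-locked error complex on false-alarm trials
  only: Ne −5 µV at 50 ms, Pe +4.375 µV at 200 ms with a late negative
  rebound −1.875 µV at 400 ms after the press.

Two deliberate, stylized properties of the forward model keep the
previous trial's activity out of the next trial's measurement frame, the
temporal segregation that the task's SOA jitter is designed to provide:

1. the preparation ramps terminate at stimulus onset (no post-stimulus
   decay tail), and
2. the error complex has zero net area *and* zero first moment — no
   slow-frequency content — so its average smeared over the 1000 ms SOA
   jitter leaves neither a plateau nor a drift in the following epoch.

Both choices were made from an exact bleed computation (the smeared
cumulative integral of a response-locked transient is proportional to
its first moment), not fitted to data: without them, deterministic
leakage of adjacent-trial activity into the epoch-initial baseline and
the pre-stimulus windows adds a condition-dependent offset of order
0.1–0.2 µV, which is material relative to the small post-error BP mean
(−0.8 µV).  What passing recovery therefore shows is that the *pipeline*
measures what was injected; it does not show that real recordings are
free of such overlap — in real data the residual overlap is an
irreducible property of the paradigm, attenuated (not removed) by the
jitter.

Noise is a spectrally shaped Gaussian process (power ∝ 1/f, total SD
10 µV per channel), an alpha-band sinusoid (10 Hz, 4 µV, random phase
per channel), and sporadic artifacts: per trial, with probability 0.05,
a 200 ms triangular excursion of ±200 µV at a random channel and time
inside that trial's epoch, above the ±120 µV rejection threshold by
design.  The noise model has no volume conduction, no ocular artifact
physiology and no line noise; channels are spatially independent, so
channel covariance of real EEG is not emulated.

Between-subject variation perturbs each behavioral parameter and the
pN/BP post-error gains with independent truncated Gaussians
(`ProfileJitter`; gain SDs 0.40 and 0.12).  A subject's post-error RT
median is coupled to their BP gain deviation (−150 ms per unit gain), so
smaller BP goes with slower post-error responses — inducing the
positive amplitude–RT correlation the analysis probes, with r ≈ 0.4–0.5
at the defaults.

## ERP processing

Stimulus-locked epochs span −1100 to +900 ms (501 samples at 250 Hz,
both endpoints included; the lock sample is at index 275).  An epoch is
rejected iff any channel sample strictly exceeds 120 µV in absolute
value ("exceeding ±120 µV" read as strict; the boundary is retained);
rejection is per-epoch and order-independent, computed on unsmoothed
single epochs.  Retained epochs are averaged per condition: post-error
and post-correct (current Go and No-go trials pooled, classified by the
predecessor within the same block; post-miss trials carry neither
context), plus the error (false-alarm) trials themselves for display and
control.  Averages are low-pass filtered with a 4th-order Butterworth at
25 Hz (24 dB/octave) applied forward and backward (zero phase, so
latencies are preserved; two passes double the stopband attenuation).
The default baseline is the mean over the first 200 ms of the epoch
(−1100 to −900 ms); the control schemes −1500/−1300 ms (with the
response-locked and expanded segmentations) and the traditional 100 ms
pre-stimulus baseline are also implemented.

Components are quantified on the smoothed, baseline-corrected averages:
pN as the mean amplitude over (−600, 0) ms at Fp1 and Fp2, BP over
(−500, 0) ms at C1, Cz, C2; P1/N1 as the signed extremum and its latency
at PO8 (60–160 ms, positive) and PO7 (100–220 ms, negative; both search
ranges are package defaults, configurable).  The fixed windows are the
shipped defaults so that reproduction never depends on the discovery
heuristic; optionally windows can be discovered from a sample-by-sample
paired t-test between conditions, taking the longest run of consecutive
p < .05 samples lasting at least 40 ms (10 samples at 250 Hz — the
package's operational definition of "consistently significant",
configurable).

A subject enters the group analysis iff they produced at least one
false alarm and at least 20 artifact-free false-alarm epochs survive
rejection (boundary inclusive).

## Inference

The two-way repeated-measures ANOVA (Condition × Site) uses the
classical fully-within partition: each effect is tested against its own
effect-by-subject interaction mean square, with *no* sphericity
correction, giving the integer design dfs (Condition: 1, n−1; Site over
three levels: 2, 2(n−1)).  Greenhouse–Geisser is intentionally not
applied, matching the uncorrected dfs of the analysis being reproduced;
sums of squares that are pure rounding residue of a constant table are
treated as zero (F = 0).  Post-hocs are within-subject paired t-tests
with the multiplied-p Bonferroni adjustment capped at 1.  Behavioral
contrasts (PIA, PES) are two-tailed paired t-tests on per-subject rates
and median RTs.  Correlations are Pearson r between per-subject signed
window amplitudes and the post-error median hit RT (medians, matching
the RT summary used throughout; whether the original analysis used
medians or means for this step is not stated — medians are this
package's documented choice).  Percent amplitude change works on
magnitudes, 100·(|test| − |reference|)/|reference|, so "reduction" and
"enhancement" read correctly for negative-going components.

Degenerate inputs are handled explicitly: zero-variance differences give
a signed infinite t with p = 0 (or t = 0, p = 1 for identical inputs);
empty behavioral contexts yield missing fields, never fabricated zeros;
a condition with no retained epochs is reported absent; a one-subject
cohort reports its ANOVA section as absent with the reason.

## Null calibration

The calibration null sets both false-alarm probabilities equal, removes
the RT shift, sets all condition gains to 1 *and removes the error
complex* — Ne/Pe occur only on error trials, so they are themselves
condition-dependent signal and would make the null false by
construction.  Under this generator the post-error/post-correct
contrast is exchangeable and the Condition effect's rejection rate is
checked against the nominal 5%.

## Problem sizes and numerical choices

Parameter recovery runs 20 replicate cohorts of 36 subjects on the
8-channel analysis montage (Fp1, Fp2, C1, Cz, C2, PO7, PO8 + one
EOG-like noise channel; the full 64-channel 10-10 montage is a config
away but adds nothing to the analysis path).  Null calibration runs 200
replicate cohorts of 12 subjects on 2 channels.  These sizes give
sub-percent Monte-Carlo error on the recovered ratios and ±1.5
percentage points (3 SE) on the null rejection rate, and are the sizes
the test suite and `scripts/acceptance.py` use.  Per-subject seeds are
spawned from the master seed (`numpy` `SeedSequence`), so any prefix of
a cohort is reproducible and two runs with the same seed are
bit-identical, including serialized reports.  Sample timing follows
t = start + k/rate with all lock times rounded to the sample grid;
window masks include both endpoints with a 1e-9 ms guard against float
jitter.

## Known limitations

* The forward model is a template-plus-noise abstraction: no volume
  conduction, no topography beyond the analysis channels, no
  non-stationarity, no ocular physiology.  Recovery results validate
  the pipeline, not the neural interpretation.
* The stylized temporal-segregation properties above mean the generator
  under-represents the residual error-complex overlap present in real
  recordings.
* PES is the simple pre-vs-post median difference; local matched-pair
  estimators are out of scope.
* The sample-wise t-test used for window discovery is uncorrected by
  design (it only selects windows); no cluster-based correction is
  provided.
* Ne/Pe are simulated and displayed but not quantified, and N2/P3/pP2
  are excluded from measurement, mirroring the scope of the analysis
  being reproduced.
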