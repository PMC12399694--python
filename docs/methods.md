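# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a methods appendix. It states no empirical claim
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and synthetic generator

A 12-lead AF surface ECG is modelled as the superposition of five
components, each generated separately so that the atrial ground truth is
exact by construction:

- **Atrial (f-wave) component** — a harmonic-limited sawtooth, the classic
  surface-AF simulation form: five 1/h-weighted sine harmonics of a
  fundamental at 4–9 Hz (default 6 Hz), normalized so the requested
  peak-to-trough amplitude is analytic. Cycle-to-cycle lognormal frequency
  jitter (default 5 % SD) and slow sinusoidal amplitude modulation
  (default 10 % depth at 0.2 Hz) emulate the non-stationarity of real
  f-waves. Per-lead amplitudes default to a table with the largest value
  on lead III (0.064 mV), the smallest on the posterior lead V6b
  (0.018 mV) and a 12-lead mean near 0.042 mV, matching the reported
  spatial distribution of f-wave amplitude in persistent AF.
- **Ventricular component** — per beat, a Q/R/S triplet of Gaussians
  (R width 12 ms, default 1.0 mV) plus a raised-cosine T wave (240 ms wide,
  centred 260 ms after R, default 0.3 mV), scaled by a per-lead polarity
  table and by a slow (0.25 Hz, 5 %) beat-amplitude modulation standing in
  for respiration. RR intervals are i.i.d. lognormal (mean 0.8 s, CV 0.2)
  with a 0.25 s refractory floor — the simplest model producing AF-like
  irregularity; atrioventricular memory is deliberately not modelled.
- **Disturbances** — two-tone baseline wander below 0.5 Hz, 50 Hz mains,
  white noise. Presets: `clean` (atrial only), `typical`
  (wander 0.05 mV, mains 0.01 mV, noise 0.005 mV), `noisy` (0.2/0.05/0.02).

All randomness flows through one `numpy` generator per call, so identical
parameters give byte-identical records on any platform at double precision.

The cohort generator draws a patient-level lognormal amplitude factor
around a group median (defaults: SUCCESS 0.040 mV, FAILURE 0.038 mV at
baseline, log-SD 0.20), spreads it across leads with the amplitude table
plus independent lead noise (log-SD 0.15), and applies one normally
distributed relative reduction per patient (defaults 5 ± 12 % vs
16 ± 12 %), chosen so the end-of-procedure group medians land near
0.038 vs 0.032 mV while the baseline difference stays non-discriminating —
the qualitative pattern reported for wide-area pulmonary-vein isolation in
persistent AF. Recurrence times are exponential (median 12 months in
FAILURE, effectively none in SUCCESS), censored at a 36-month
administrative horizon with 10 % additional uniform censoring.

What the generator does **not** emulate: spatially correlated f-wave
content across leads, ectopy and detection-hostile QRS morphologies,
electrode motion artefacts, AV-nodal RR dependence, or any within-patient
correlation between amplitude and outcome beyond the group structure.
Passing recovery tests on this data therefore demonstrates correctness of
the measurement chain, not clinical performance on real recordings.

## Atrial signal extraction

**Beat detection.** 10–25 Hz bandpass, squaring, 150-ms moving-window
integration, candidate peaks at a 250 ms refractory spacing. The adaptive
threshold keeps peaks above 25 % of the 90th percentile of candidate
heights — an upper quantile, because the candidate set necessarily
includes inter-beat background maxima. A record is declared beat-free when
that reference height is less than 8× the median envelope: continuous
f-wave energy produces a flat envelope (ratio near 1), while genuine QRS
bursts stand two to four orders of magnitude above the background.
Default detection is a consensus (greedy 100-ms clustering, majority vote,
median location) over leads II, V1 and V4.

**QRST cancellation.** A single-beat method with QRS and T treated
separately: per lead and per beat, the template is the mean of the 10
nearest-in-time aligned complexes (self excluded), fitted to the beat by a
single least-squares amplitude scale and subtracted under a 10-ms cosine
edge taper. Window defaults follow standard adult intervals — QRS from
R−60 ms to R+80 ms, T from the QRS offset to 280 ms later, truncated at
the next QRS onset. With fewer than three beats the template falls back to
the global average beat. Outside the QRST windows the output equals the
input sample-exactly, and cancelling a beat-free signal is the identity.
A scalar amplitude fit (rather than morphological warping) is the robust
choice at 60-s epoch lengths; per-beat scaling absorbs slow amplitude
modulation exactly.

**Stage ordering.** `extract_atrial` deliberately orders the stages as
*detection → median-filter baseline removal → cancellation → 1–50 Hz
bandpass*, i.e. the linear bandpass runs **after** the QRST subtraction.
A linear 1 Hz highpass applied while the QRST pulses are still present
redistributes the pulse train's low-frequency energy into the inter-beat
segments — on the typical preset this pseudo-wander reaches 0.067 mV RMS
on lead II, larger than the f-waves themselves and partly inside the
4–9 Hz band, where no windowed subtraction can reach it. Baseline wander
is instead removed before cancellation by a cascaded running-median
estimate (0.2 s then 0.6 s windows on a 100 Hz grid), which is immune to
the transient pulses precisely because the median ignores them. The
1–50 Hz Butterworth bandpass (order 4, forward–backward for zero phase,
with an optional 50 Hz notch, on by default) then conditions the nearly
ventricle-free signal. The filter family and order are configuration
defaults, not claims about any reference system; zero-phase filtering is
chosen because amplitude fidelity, not causality, is what matters here.

## f-wave amplitude estimation

Local extrema are located on a 100-ms sliding window advanced in
full-window steps (a configuration flag enables 50 % overlap). One
numerical subtlety drives the implementation: at 4–9 Hz the f-wave period
(110–250 ms) is of the same order as the window, so a window need not
contain a genuine oscillation crest; its raw maximum then falls on a
window edge (or on a small harmonic ripple) and systematically biases the
envelope low — for a 6 Hz tone the bias on the mean envelope is tens of
percent. A window extremum is therefore kept only when it dominates a
two-window neighbourhood of the signal, which rejects edge running-maxima
and inter-crest ripples while keeping every true crest (and every sample
of a constant signal). With this rule the full chain recovers the
peak-to-trough amplitude of ventricle-free records to within a fraction
of a percent.

Each extremum series is linearly interpolated onto the uniform sampling
grid (edge values held) and zero-phase lowpassed at 2 Hz — below the
4–9 Hz f-wave band but above physiological amplitude-modulation rates; the
cutoff is configurable. Filtering the irregular extremum sequence as if it
were uniformly sampled was rejected because it distorts time constants.
fWA is the temporal mean of (upper − lower), floored at zero (flooring is
logged); `central_frac` restricts the average away from filter edge
transients (0.8 is used in the validation suites). meanfWA averages all
12 leads, including aVR, by default; lead subsets are configurable.

## Statistics layer

Implemented from first principles, with library implementations used only
as independent cross-checks in the tests:

- **Mann–Whitney U** — midranks for ties; exact two-sided p by full
  enumeration of the permutation distribution when n+m ≤ 16 without ties,
  otherwise the normal approximation with tie and continuity corrections.
- **Fisher's exact test** — two-sided p as the sum of hypergeometric
  probabilities no larger than the observed table's (relative tolerance
  1+1e-7); a zero margin gives p = 1 with a warning. Pearson chi-squared
  uses 1 df without continuity correction by default (Yates optional).
- **ROC** — empirical AUC via the rank/U identity (equal to the
  trapezoidal area over all empirical thresholds); DeLong 95 % CI; the
  optimal cutoff maximizes sensitivity + specificity over observed values,
  ties broken in favour of higher sensitivity, then the smaller threshold
  (the tie-break is a fixed, documented convention). The decision
  direction is auto-selected so AUC ≥ 0.5 and reported alongside.
- **Logistic regression** — Newton–Raphson ML on a standardized predictor,
  Wald CI and p. Odds ratios are reported per stated increment — 0.01 mV
  for amplitude predictors and one percentage point for relative-change
  predictors — because a per-1-mV step is meaningless for amplitudes of
  order 0.04 mV. Complete separation and constant predictors are detected
  and flagged rather than silently iterated.
- **Kaplan–Meier / log-rank** — product-limit estimator and the standard
  two-group 1-df log-rank statistic.
- No multiple-testing correction is applied by default (per-lead p-values
  are raw); an optional Benjamini–Hochberg column is available.

## Outcome decision rule

`classify` applies the two-threshold rule — predict SUCCESS when baseline
meanfWA ≥ 0.044 mV **or** the relative decrease ≤ 11 % — with inclusive
boundaries; an amplitude increase (negative decrease) always predicts
SUCCESS, and the prediction is monotone in both features. SUCCESS is the
positive class in all reported metrics. `fit_rule` learns both thresholds
by a two-stage procedure: the baseline cutoff is the ROC-optimal threshold
of baseline meanfWA, and the decrease cutoff is the ROC-optimal threshold
of the decrease among patients *below* that cutoff (the only patients the
second branch can affect). This staged construction is this package's
explicit interpretation of a two-split decision tree on these features; it
is labelled as such in outputs and is not a general CART implementation.

## Problem sizes and numerical conventions

The validation suites use 60-s records at 2 kHz (the pipeline's nominal
epoch), 20 generator seeds for pipeline-recovery checks, 5000 null
replicates (n = 20 per arm) for Mann–Whitney calibration, 1000 replicates
(n = 100) for logistic slope recovery, and exhaustive enumeration of all
2×2 tables with grand total ≤ 30 for the Fisher oracle. Voltages are mV
end-to-end; readers convert from native units on load. CSV is the
canonical interchange dialect (a `# fs=` header comment carries the
sampling rate); WFDB/EDF readers are available behind optional imports.
Seeds below 2³¹ are used everywhere; identical seeds give byte-identical
simulation output.

## Known limitations

- The QRST canceller assumes reasonably repetitive beat morphology;
  ectopic beats, bundle-branch block patterns or severe motion artefact
  would degrade the per-beat scaled-template fit.
- The envelope estimator's extremum-dominance rule assumes the f-wave
  fundamental stays below ~10 Hz for the default 100-ms window; faster
  oscillations need a shorter window.
- fWA values measured on noisy records are biased upward: window extrema
  of signal-plus-noise exceed those of the signal alone, and the envelope
  method has no noise-floor correction.
- The decision-rule thresholds (0.044 mV, 11 %) are fixed conventions of
  the implemented rule; refitting on synthetic cohorts recovers thresholds
  near, not at, these values, and nothing here validates them clinically.
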