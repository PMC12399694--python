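# fwave

Surface-ECG **f-wave amplitude (fWA)** analysis for persistent atrial
fibrillation (AF), aimed at signal-processing and electrophysiology
researchers studying whether the amplitude of the fibrillatory waves — and
its change during catheter ablation — predicts long-term rhythm outcome.

During AF the P wave is replaced by a continuous low-amplitude atrial
oscillation (f-waves, 4–9 Hz, a few hundredths of a millivolt) buried under
ventricular QRST complexes one to two orders of magnitude larger. The
package implements the complete measurement and analysis chain on 12-lead
recordings (with chest lead V6 relocated to the back, "V6b"):

1. **Atrial signal extraction** — energy-based QRS detection, then
   single-beat QRST cancellation: for every beat the ventricular waveform
   is estimated as an amplitude-scaled average of the nearest-in-time
   aligned complexes, with the QRS and T waves treated separately, and
   subtracted under a cosine edge taper.
2. **fWA estimation** — local maxima/minima of the atrial signal on a
   100-ms sliding window; upper and lower envelopes *u(t)*, *l(t)* by
   lowpass-filtering each extremum series; per lead

   &nbsp;&nbsp;&nbsp;&nbsp;fWA = ⟨u(t) − l(t)⟩ₜ  [mV],

   and **meanfWA** = the unweighted mean of fWA over the 12 leads.
3. **Change metrics** — ΔfWA% = 100·(fWA_end − fWA_base)/fWA_base between
   the baseline and end-of-procedure (endWPVI) epochs; the positive-valued
   "decrease" is −ΔfWA%.
4. **Cohort statistics** (implemented from first principles, with scipy /
   statsmodels / lifelines as independent cross-checks in the tests) —
   Mann–Whitney U (exact enumeration for small tie-free samples), Fisher's
   exact and Pearson chi-squared tests, ROC analysis with the
   highest-sensitivity-plus-specificity cutoff and DeLong AUC confidence
   intervals, univariate logistic odds ratios per stated increment
   (0.01 mV for amplitudes), Kaplan–Meier and the log-rank test.
5. **Outcome decision rule** — predict sinus-rhythm maintenance (SUCCESS)
   when *baseline meanfWA ≥ 0.044 mV* **or** *decrease ≤ 11 %*; predict
   recurrence (FAILURE) only when both fail. Thresholds can also be
   re-fitted from a cohort by a two-stage ROC procedure.

Because clinical recordings of this kind are generally not shareable, the
package ships a first-class synthetic generator: 12-lead AF ECGs (sawtooth
atrial component with analytic ground truth, Gaussian-QRS/raised-cosine-T
ventricular activity at irregular lognormal RR intervals, baseline wander,
mains interference, noise) and synthetic cohorts with group-structured
amplitudes, reductions and censored recurrence times.

## Worked example

```python
import fwave as fw

params = fw.preset_params("typical", seed=1, duration_s=60.0)   # QRS 1.0 mV, f-waves 0.05 mV
record, truth = fw.simulate_af_ecg(params)
atrial = fw.extract_atrial(record, ground_truth=truth)
meas = fw.measure_fwa(atrial, central_frac=0.8)
print(f"beats: {atrial.beats.n_beats}, meanfWA: {meas.meanfwa:.4f} mV")

rule = fw.DecisionRule(baseline_cutoff=0.044, decrease_cutoff=11.0)
cohort = fw.simulate_cohort(fw.CohortSimParams(seed=1))
perf = fw.evaluate(rule, cohort)
print(f"SE {perf.sensitivity:.2f}, SP {perf.specificity:.2f}")
```

prints

```
beats: 79, meanfWA: 0.0507 mV
SE 0.83, SP 0.35
```

The 79 detected beats match the simulated RR sequence; the measured
meanfWA of 0.0507 mV recovers the generator's 0.05 mV peak-to-trough
atrial amplitude through detection, cancellation and envelope estimation
(the residual ventricular power is below 2 % per lead). On the synthetic
80-patient cohort the fixed rule reaches sensitivity 0.83 for sinus-rhythm
maintenance; its specificity is limited by how much the two synthetic
groups overlap, not by the classifier.

The same stages are scriptable from the shell:

```bash
fwave simulate-ecg --out rec.csv --preset typical --seed 1
fwave extract --in rec.csv --out fwa.csv
fwave simulate-cohort --out cohort.csv --seed 1
fwave stats --cohort cohort.csv --out stats.json
fwave classify --cohort cohort.csv --out pred.json
```

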