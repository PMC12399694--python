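"""Synthetic 12-lead AF ECGs and synthetic cohorts with known ground truth.

During atrial fibrillation the surface ECG shows a continuous low-amplitude
atrial oscillation (f-waves, 4--9 Hz) superimposed on ventricular QRST
activity at irregular RR intervals.  The generator here follows the classic
surface-AF simulation form: the atrial component is a harmonic-limited
sawtooth with controllable per-lead peak-to-trough amplitude, cycle-to-cycle
frequency jitter and slow amplitude modulation; the ventricular component is
a synthetic QRS (sum of Gaussians) plus a raised-cosine T wave with a
per-lead amplitude scaling table; baseline wander, 50 Hz mains interference
and white noise are added on top.  Because each component is built
separately, the atrial ground truth is analytic: the record minus the
ground-truth atrial series equals the other components sample-exactly.

Cohort simulation draws per-patient per-lead f-wave amplitudes (fWA) at two
procedural epochs (baseline and end of pulmonary-vein isolation) with
group-wise medians, applies a group-specific relative amplitude reduction,
and attaches exponential recurrence times with censoring — mirroring the
statistical structure of a persistent-AF ablation cohort in which roughly
sixty percent of patients maintain sinus rhythm off drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    STANDARD_LEADS,
    CohortTable,
    ConfigurationError,
    EcgRecord,
    ValidationError,
)

__all__ = [
    "AfEcgParams",
    "AtrialGroundTruth",
    "CohortSimParams",
    "simulate_af_ecg",
    "simulate_cohort",
    "preset_params",
    "LEAD_FWA_MV",
    "LEAD_VENTRICULAR_SCALE",
]

#: Per-lead f-wave peak-to-trough amplitudes (mV) used as the default
#: generator table: largest on lead III, smallest on the posterior lead V6b,
#: 12-lead mean ~= 0.042 mV.
LEAD_FWA_MV: dict[str, float] = {
    "I": 0.035, "II": 0.050, "III": 0.064,
    "aVR": 0.045, "aVL": 0.028, "aVF": 0.055,
    "V1": 0.050, "V2": 0.045, "V3": 0.040,
    "V4": 0.040, "V5": 0.034, "V6b": 0.018,
}

#: Relative ventricular (QRS/T) amplitude per lead; signs give roughly
#: realistic 12-lead polarity.
LEAD_VENTRICULAR_SCALE: dict[str, float] = {
    "I": 0.6, "II": 1.0, "III": 0.5,
    "aVR": -0.7, "aVL": 0.3, "aVF": 0.8,
    "V1": -0.5, "V2": 0.7, "V3": 0.9,
    "V4": 1.1, "V5": 1.0, "V6b": 0.5,
}


@dataclass(frozen=True)
class AfEcgParams:
    """Parameters of the synthetic 12-lead AF ECG.

    Amplitudes are mV; ``f_wave_amplitude_per_lead`` is peak-to-trough
    before slow amplitude modulation.  ``rr_cv`` is the coefficient of
    variation of the lognormal RR-interval model (i.i.d., no AV-node
    memory — the simplest model producing AF-like irregularity) with a
    0.25 s refractory floor.
    """

    fs: float = 2000.0
    duration_s: float = 60.0
    f_wave_amplitude_per_lead: Mapping[str, float] | float = field(
        default_factory=lambda: dict(LEAD_FWA_MV)
    )
    f_wave_freq: float = 6.0
    n_harmonics: int = 5
    f_freq_jitter: float = 0.05
    amp_modulation_depth: float = 0.1
    amp_modulation_hz: float = 0.2
    mean_rr_s: float = 0.8
    rr_cv: float = 0.2
    qrs_amplitude: float = 1.0
    t_amplitude: float = 0.3
    beat_amp_modulation: float = 0.05
    baseline_wander_amp: float = 0.05
    mains_amp: float = 0.01
    noise_sd: float = 0.005
    lead_labels: tuple[str, ...] = STANDARD_LEADS
    seed: int = 0

    def amplitude_vector(self) -> np.ndarray:
        """Per-lead peak-to-trough amplitude array aligned with lead_labels."""
        a = self.f_wave_amplitude_per_lead
        if isinstance(a, Mapping):
            try:
                vec = np.array([a[l] for l in self.lead_labels], dtype=float)
            except KeyError as exc:
                raise ConfigurationError(f"missing f-wave amplitude for lead {exc}")
        elif np.isscalar(a):
            vec = np.full(len(self.lead_labels), float(a))
        else:
            vec = np.asarray(a, dtype=float)
            if vec.shape != (len(self.lead_labels),):
                raise ConfigurationError("amplitude vector length != number of leads")
        if (vec < 0).any():
            raise ConfigurationError("f-wave amplitudes must be >= 0")
        return vec

    def validate(self) -> None:
        if not 0 < self.f_wave_freq < self.fs / 2:
            raise ConfigurationError("f_wave_freq must lie in (0, fs/2)")
        if self.f_wave_freq * self.n_harmonics >= self.fs / 2:
            raise ConfigurationError(
                "highest sawtooth harmonic reaches the Nyquist frequency; "
                "reduce n_harmonics or f_wave_freq"
            )
        if not 0 <= self.rr_cv < 1:
            raise ConfigurationError("rr_cv must lie in [0, 1)")
        for name in ("qrs_amplitude", "t_amplitude", "baseline_wander_amp",
                     "mains_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        self.amplitude_vector()


@dataclass(frozen=True)
class AtrialGroundTruth:
    """Ground-truth decomposition of a simulated AF record (all mV).

    ``atrial`` is the atrial-only component; ``ventricular`` the QRST
    component; ``r_peaks`` the true R-peak sample indices.  The parent
    record equals atrial + ventricular + wander + mains + noise exactly.
    """

    atrial: np.ndarray
    ventricular: np.ndarray
    r_peaks: np.ndarray
    fs: float
    lead_labels: tuple[str, ...]

    def atrial_record(self, epoch_label: str = "other") -> EcgRecord:
        return EcgRecord(self.atrial, self.fs, self.lead_labels, epoch_label)


def _sawtooth_shape(n_harmonics: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak-to-trough harmonic sawtooth sampled on a dense phase grid."""
    phi = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    h = np.arange(1, n_harmonics + 1)
    wave = np.sum(np.sin(np.outer(phi, h)) / h, axis=1)
    wave /= wave.max() - wave.min()
    return phi, wave


def _atrial_phase(rng, n: int, fs: float, f0: float, jitter: float) -> np.ndarray:
    """Instantaneous phase with i.i.d. cycle-to-cycle frequency jitter."""
    t = np.arange(n) / fs
    total = n / fs
    # generous cycle budget; lognormal jitter keeps frequencies positive
    n_cycles = int(np.ceil(total * f0 * 2)) + 8
    freqs = f0 * np.exp(jitter * rng.standard_normal(n_cycles)) if jitter > 0 else (
        np.full(n_cycles, f0)
    )
    durations = 1.0 / freqs
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    idx = np.searchsorted(starts, t, side="right") - 1
    frac = (t - starts[idx]) / durations[idx]
    return 2 * np.pi * (idx + frac)


def _qrs_t_shape(fs: float, qrs_amp: float, t_amp: float) -> tuple[np.ndarray, int]:
    """One ventricular beat waveform centred on the R peak.

    QRS = Q/R/S Gaussians (width ~10 ms), T = raised cosine centred 260 ms
    after R with 240 ms width.  Returns (waveform, offset of R within it).
    """
    pre, post = 0.10, 0.45
    t = np.arange(-round(pre * fs), round(post * fs)) / fs
    qrs = (
        qrs_amp * np.exp(-0.5 * (t / 0.012) ** 2)
        - 0.12 * qrs_amp * np.exp(-0.5 * ((t + 0.035) / 0.008) ** 2)
        - 0.22 * qrs_amp * np.exp(-0.5 * ((t - 0.035) / 0.009) ** 2)
    )
    t_center, t_width = 0.26, 0.24
    in_t = np.abs(t - t_center) < t_width / 2
    t_wave = np.zeros_like(t)
    t_wave[in_t] = t_amp * 0.5 * (1 + np.cos(2 * np.pi * (t[in_t] - t_center) / t_width))
    return qrs + t_wave, round(pre * fs)


def simulate_af_ecg(params: AfEcgParams) -> tuple[EcgRecord, AtrialGroundTruth]:
    """Simulate a multi-lead AF surface ECG with analytic atrial ground truth.

    Returns the composite record (atrial + ventricular + baseline wander +
    mains + white noise) and the :class:`AtrialGroundTruth` decomposition.
    Identical parameters (including seed) give byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = round(fs * params.duration_s)
    n_leads = len(params.lead_labels)
    t = np.arange(n) / fs

    # --- atrial component: jittered harmonic sawtooth with slow AM --------
    phi_grid, shape = _sawtooth_shape(params.n_harmonics)
    phase = _atrial_phase(rng, n, fs, params.f_wave_freq, params.f_freq_jitter)
    base_wave = np.interp(np.mod(phase, 2 * np.pi), phi_grid, shape, period=2 * np.pi)
    am = 1.0 + params.amp_modulation_depth * np.sin(
        2 * np.pi * params.amp_modulation_hz * t + rng.uniform(0, 2 * np.pi)
    )
    amps = params.amplitude_vector()
    atrial = np.outer(base_wave * am, amps)

    # --- ventricular component: irregular RR, per-beat amplitude wobble ---
    ventricular = np.zeros((n, n_leads))
    r_peaks = np.empty(0, dtype=int)
    if params.qrs_amplitude > 0 or params.t_amplitude > 0:
        sigma2 = np.log1p(params.rr_cv**2)
        mu = np.log(params.mean_rr_s) - sigma2 / 2
        n_beats = int(np.ceil(params.duration_s / params.mean_rr_s * 2)) + 4
        rr = np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(n_beats))
        rr = np.maximum(rr, 0.25)  # atrioventricular refractory floor
        r_times = 0.35 + np.cumsum(rr) - rr[0]
        r_times = r_times[r_times < params.duration_s - 0.05]
        beat, r_off = _qrs_t_shape(fs, params.qrs_amplitude, params.t_amplitude)
        scale = np.array([LEAD_VENTRICULAR_SCALE.get(l, 1.0) for l in params.lead_labels])
        r_peaks = np.round(r_times * fs).astype(int)
        for rp, rt in zip(r_peaks, r_times):
            wobble = 1.0 + params.beat_amp_modulation * np.sin(2 * np.pi * 0.25 * rt)
            lo = rp - r_off
            hi = lo + len(beat)
            blo, bhi = max(0, -lo), len(beat) - max(0, hi - n)
            ventricular[max(0, lo):min(n, hi)] += np.outer(
                beat[blo:bhi] * wobble, scale
            )

    # --- disturbances ------------------------------------------------------
    other = np.zeros((n, n_leads))
    if params.baseline_wander_amp > 0:
        for j in range(n_leads):
            ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
            other[:, j] += params.baseline_wander_amp * (
                np.sin(2 * np.pi * 0.15 * t + ph1)
                + 0.6 * np.sin(2 * np.pi * 0.33 * t + ph2)
            )
    if params.mains_amp > 0:
        ph = rng.uniform(0, 2 * np.pi)
        other += params.mains_amp * np.sin(2 * np.pi * 50.0 * t + ph)[:, None]
    if params.noise_sd > 0:
        other += params.noise_sd * rng.standard_normal((n, n_leads))

    record = EcgRecord(
        atrial + ventricular + other, fs, params.lead_labels, "other"
    )
    truth = AtrialGroundTruth(atrial, ventricular, r_peaks, fs, params.lead_labels)
    return record, truth


_PRESETS: dict[str, dict] = {
    # ventricle-free, disturbance-free record: the metric-chain oracle
    "clean": dict(
        f_wave_amplitude_per_lead=0.05, qrs_amplitude=0.0, t_amplitude=0.0,
        baseline_wander_amp=0.0, mains_amp=0.0, noise_sd=0.0,
        f_freq_jitter=0.05, amp_modulation_depth=0.1,
    ),
    # full composite at nominal disturbance levels
    "typical": dict(
        f_wave_amplitude_per_lead=0.05, qrs_amplitude=1.0, t_amplitude=0.3,
        baseline_wander_amp=0.05, mains_amp=0.01, noise_sd=0.005,
    ),
    "noisy": dict(
        f_wave_amplitude_per_lead=0.05, qrs_amplitude=1.0, t_amplitude=0.3,
        baseline_wander_amp=0.2, mains_amp=0.05, noise_sd=0.02,
    ),
}


def preset_params(name: str, seed: int = 0, **overrides) -> AfEcgParams:
    """Named generator presets: ``clean``, ``typical``, ``noisy``."""
    if name not in _PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return AfEcgParams(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Synthetic ablation-cohort parameters.

    ``baseline_meanfwa_*`` are (median mV, log-scale SD) of the patient-level
    lognormal amplitude factor; ``reduction_*`` are (mean %, SD %) of the
    relative fWA decrease from baseline to the end of pulmonary-vein
    isolation (negative values mean an amplitude increase).  Defaults give
    end-of-procedure group medians near 0.038 vs 0.032 mV with a small,
    non-discriminating baseline difference, a 54/26 success/failure split,
    and a handful of patients in sinus rhythm only on antiarrhythmic drugs.
    """

    n_success: int = 54
    n_failure: int = 26
    n_on_aad: int = 0
    baseline_meanfwa_success: tuple[float, float] = (0.040, 0.20)
    baseline_meanfwa_failure: tuple[float, float] = (0.038, 0.20)
    reduction_success: tuple[float, float] = (5.0, 12.0)
    reduction_failure: tuple[float, float] = (16.0, 12.0)
    lead_scaling: Mapping[str, float] | None = None
    lead_log_sd: float = 0.15
    leads: tuple[str, ...] = STANDARD_LEADS
    # recurrence model: exponential event times (months), administrative
    # horizon, plus independent random censoring
    median_event_months_failure: float = 12.0
    median_event_months_success: float = 240.0
    horizon_months: float = 36.0
    censoring_rate: float = 0.1
    p_aad_at_fu_failure: float = 11 / 26
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_success, self.n_failure, self.n_on_aad) < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        for name in ("baseline_meanfwa_success", "baseline_meanfwa_failure"):
            med, sd = getattr(self, name)
            if med <= 0 or sd < 0:
                raise ConfigurationError(f"invalid {name}: {(med, sd)}")


def _lead_scale_vector(params: CohortSimParams) -> np.ndarray:
    if params.lead_scaling is not None:
        vec = np.array([params.lead_scaling[l] for l in params.leads], dtype=float)
    else:
        vec = np.array([LEAD_FWA_MV.get(l, 0.04) for l in params.leads], dtype=float)
    return vec / vec.mean()


def simulate_cohort(params: CohortSimParams) -> CohortTable:
    """Draw a synthetic cohort with per-lead fWA at both epochs.

    Per patient: a lognormal amplitude factor around the group median is
    spread across leads by the per-lead scaling table with independent
    lognormal lead noise; the end-of-procedure amplitude applies one
    normally distributed relative reduction uniformly across leads (so a
    zero reduction SD makes every patient's relative change exactly the
    group mean).  Recurrence times are exponential with group-specific
    rates, censored at the administrative horizon and by independent
    uniform censoring.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    scale = _lead_scale_vector(params)
    groups = (
        [("SUCCESS", params.baseline_meanfwa_success, params.reduction_success,
          params.median_event_months_success, 0.0)] * params.n_success
        + [("FAILURE", params.baseline_meanfwa_failure, params.reduction_failure,
            params.median_event_months_failure, params.p_aad_at_fu_failure)] * params.n_failure
        + [("ON_AAD", params.baseline_meanfwa_success, params.reduction_success,
            params.median_event_months_success, 1.0)] * params.n_on_aad
    )
    rows = []
    for i, (label, (med, sd), (red_mu, red_sd), med_event, p_aad) in enumerate(groups):
        level = med * np.exp(sd * rng.standard_normal())
        lead_noise = np.exp(params.lead_log_sd * rng.standard_normal(len(scale)))
        baseline = level * scale * lead_noise
        reduction = red_mu + red_sd * rng.standard_normal()
        reduction = min(reduction, 95.0)  # keep end amplitudes positive
        endwpvi = baseline * (1.0 - reduction / 100.0)
        event_t = rng.exponential(med_event / np.log(2.0))
        censor_t = params.horizon_months
        if params.censoring_rate > 0 and rng.uniform() < params.censoring_rate:
            censor_t = rng.uniform(0, params.horizon_months)
        followup = min(event_t, censor_t)
        event = int(event_t <= censor_t)
        row = {
            "patient_id": f"P{i+1:03d}",
            "outcome": label,
            "followup_months": round(followup, 3),
            "event": event,
            "aad_at_fu": int(rng.uniform() < p_aad) if label != "ON_AAD" else 1,
        }
        for lead, b, e in zip(params.leads, baseline, endwpvi):
            row[f"fwa_{lead}_baseline"] = b
            row[f"fwa_{lead}_endwpvi"] = e
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(rows[0]) if rows else [
        "patient_id", "outcome", "followup_months", "event", "aad_at_fu"
    ])
    if not rows:
        raise ValidationError("cohort simulation produced no patients")
    return CohortTable(df, leads=params.leads)
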