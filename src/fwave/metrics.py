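"""f-wave amplitude (fWA) estimation from the atrial signal.

The estimator follows the envelope construction used for surface AF
analysis: local maxima and minima of the atrial signal are detected on a
100 ms sliding window, the upper and lower envelopes are obtained by
lowpass filtering each time series of local extrema, and the fWA of a lead
is the temporal average of the difference between the two envelopes (mV).
The mean over the 12 ECG leads gives meanfWA, and relative changes between
the two procedural epochs are expressed in percent of the baseline value.

One numerical subtlety: a window can fail to contain a genuine oscillation
crest (the f-wave period at 4--9 Hz is 110--250 ms, of the same order as
the window).  The raw within-window maximum then falls on a window edge
and systematically underestimates the envelope, so window extrema that are
not local extrema of the signal itself are discarded before interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .io import EcgRecord, ValidationError
from .qrst import AtrialSignal

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremaSeries", "EnvelopePair", "FwaMeasurement", "FwaChange",
    "PatientEpochPair", "detect_extrema", "estimate_envelopes",
    "compute_fwa", "measure_fwa", "mean_fwa", "relative_change",
]


@dataclass(frozen=True)
class ExtremaSeries:
    """Sliding-window local extrema of one lead: sample indices and mV
    values of the maxima and minima series."""

    max_idx: np.ndarray
    max_val: np.ndarray
    min_idx: np.ndarray
    min_val: np.ndarray
    n_windows: int


@dataclass(frozen=True)
class EnvelopePair:
    """Upper and lower envelope of the atrial signal on the uniform
    sampling grid (mV)."""

    upper: np.ndarray
    lower: np.ndarray
    lead: str = ""

    def __post_init__(self) -> None:
        if self.upper.shape != self.lower.shape:
            raise ValidationError("envelope arrays must have equal length")


@dataclass(frozen=True)
class FwaMeasurement:
    """Per-lead fWA plus meanfWA (mV) for one patient-epoch."""

    per_lead_fwa: Mapping[str, float]
    meanfwa: float
    epoch_label: str = "other"
    window_ms: float = 100.0
    envelope_lowpass_hz: float = 2.0

    def leads(self) -> tuple[str, ...]:
        return tuple(self.per_lead_fwa)


@dataclass(frozen=True)
class FwaChange:
    """Relative fWA change between epochs, in percent of baseline.

    ``delta_pct`` follows the signed convention 100*(end-baseline)/baseline
    (negative for an amplitude fall); ``decrease_pct`` is its sign-flipped,
    positive-for-a-fall counterpart used by the decision rule.
    """

    per_lead_delta_pct: Mapping[str, float]
    meanfwa_delta_pct: float

    @property
    def decrease_pct(self) -> float:
        return -self.meanfwa_delta_pct


@dataclass(frozen=True)
class PatientEpochPair:
    """Baseline and end-of-procedure measurements for one patient."""

    patient_id: str
    baseline: FwaMeasurement
    endwpvi: FwaMeasurement

    def __post_init__(self) -> None:
        if set(self.baseline.per_lead_fwa) != set(self.endwpvi.per_lead_fwa):
            raise ValidationError("epoch measurements must expose identical lead sets")


# ---------------------------------------------------------------------------

def detect_extrema(
    x: np.ndarray,
    fs: float,
    window_ms: float = 100.0,
    overlap: bool = False,
) -> ExtremaSeries:
    """Detect local maxima/minima on a sliding window.

    The window advances in full-window steps by default (``overlap=True``
    halves the step).  Within each window the extremum sample is located;
    candidates that are not local extrema of the signal (running maxima at
    a window edge) are discarded, and duplicates from adjacent windows are
    merged.
    """
    x = np.asarray(x, dtype=float)
    if window_ms <= 0:
        raise ValidationError("window_ms must be positive")
    w = round(window_ms * fs / 1000.0)
    n = len(x)
    if n < w:
        raise ValidationError(
            f"signal of {n} samples shorter than one {window_ms:g} ms window"
        )
    step = max(1, w // 2) if overlap else w
    starts = np.arange(0, n - w + 1, step)

    def _collect(sign: float) -> tuple[np.ndarray, np.ndarray]:
        s = sign * x
        idx = []
        for a in starts:
            i = a + int(np.argmax(s[a:a + w]))
            # keep only extrema that dominate a two-window neighbourhood:
            # this rejects window-edge running maxima and small harmonic
            # ripples sitting between genuine oscillation crests
            if s[i] >= s[max(0, i - w):min(n, i + w + 1)].max():
                idx.append(i)
        idx = np.unique(np.asarray(idx, dtype=int))
        return idx, x[idx]

    max_idx, max_val = _collect(+1.0)
    min_idx, min_val = _collect(-1.0)
    return ExtremaSeries(max_idx, max_val, min_idx, min_val, len(starts))


def estimate_envelopes(
    extrema: ExtremaSeries,
    n_samples: int,
    fs: float,
    lowpass_hz: float = 2.0,
    lead: str = "",
) -> EnvelopePair:
    """Interpolate each extremum series to the uniform grid and lowpass it.

    The irregularly timed extrema are linearly interpolated onto the
    sampling grid (edge values held) and then zero-phase lowpassed, giving
    envelopes that span the full record.
    """
    if len(extrema.max_idx) < 4 or len(extrema.min_idx) < 4:
        raise ValidationError(
            "need at least 4 maxima and 4 minima to estimate envelopes "
            f"(got {len(extrema.max_idx)}/{len(extrema.min_idx)})"
        )
    grid = np.arange(n_samples)
    upper = np.interp(grid, extrema.max_idx, extrema.max_val)
    lower = np.interp(grid, extrema.min_idx, extrema.min_val)
    if lowpass_hz < fs / 2:
        sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
        upper = sps.sosfiltfilt(sos, upper)
        lower = sps.sosfiltfilt(sos, lower)
    return EnvelopePair(upper, lower, lead)


def compute_fwa(env: EnvelopePair, central_frac: float = 1.0) -> float:
    """Temporal mean of (upper - lower), floored at zero (mV).

    ``central_frac`` < 1 restricts the average to the central portion of
    the record, away from filter edge effects.
    """
    diff = env.upper - env.lower
    if not 0 < central_frac <= 1:
        raise ValidationError("central_frac must lie in (0, 1]")
    if central_frac < 1.0:
        n = len(diff)
        margin = round(n * (1.0 - central_frac) / 2)
        diff = diff[margin:n - margin]
    fwa = float(np.mean(diff))
    if fwa < 0:
        logger.info("fWA for lead %s floored at 0 (raw %.4g mV)", env.lead, fwa)
        fwa = 0.0
    return fwa


def measure_fwa(
    atrial: AtrialSignal | EcgRecord,
    window_ms: float = 100.0,
    lowpass_hz: float = 2.0,
    epoch_label: str | None = None,
    central_frac: float = 1.0,
    leads: Sequence[str] | None = None,
) -> FwaMeasurement:
    """Run the full per-lead chain (extrema -> envelopes -> fWA) and
    aggregate to meanfWA."""
    if isinstance(atrial, AtrialSignal):
        signals, fs = atrial.signals, atrial.fs
        labels = atrial.lead_labels
        epoch = epoch_label or atrial.source.epoch_label
    else:
        signals, fs = atrial.signals, atrial.fs
        labels = atrial.lead_labels
        epoch = epoch_label or atrial.epoch_label
    use = tuple(leads) if leads is not None else labels
    per_lead: dict[str, float] = {}
    for lab in use:
        if lab not in labels:
            raise ValidationError(f"lead {lab!r} not present in signal")
        x = signals[:, labels.index(lab)]
        ext = detect_extrema(x, fs, window_ms)
        env = estimate_envelopes(ext, len(x), fs, lowpass_hz, lead=lab)
        per_lead[lab] = compute_fwa(env, central_frac)
    meas = FwaMeasurement(
        per_lead, float(np.mean(list(per_lead.values()))),
        epoch, window_ms, lowpass_hz,
    )
    logger.info(
        "fWA (%s): meanfWA %.4f mV over %d leads", epoch, meas.meanfwa, len(per_lead)
    )
    return meas


def mean_fwa(m: FwaMeasurement, leads: Sequence[str] | None = None) -> float:
    """Unweighted arithmetic mean of per-lead fWA over the requested leads
    (default: all leads in the measurement)."""
    use = tuple(leads) if leads is not None else m.leads()
    vals = []
    for lab in use:
        if lab not in m.per_lead_fwa:
            raise ValidationError(f"lead {lab!r} missing from measurement")
        vals.append(m.per_lead_fwa[lab])
    return float(np.mean(vals))


def relative_change(pair: PatientEpochPair) -> FwaChange:
    """Percentage deviation of end-of-procedure fWA from baseline.

    Defined only for strictly positive baseline values; a fall in
    amplitude gives a negative ``delta_pct`` and a positive
    ``decrease_pct``.
    """
    deltas: dict[str, float] = {}
    for lab, base in pair.baseline.per_lead_fwa.items():
        if base <= 0:
            raise ValidationError(f"baseline fWA on lead {lab!r} is not positive")
        deltas[lab] = 100.0 * (pair.endwpvi.per_lead_fwa[lab] - base) / base
    if pair.baseline.meanfwa <= 0:
        raise ValidationError("baseline meanfWA is not positive")
    mean_delta = 100.0 * (pair.endwpvi.meanfwa - pair.baseline.meanfwa) / pair.baseline.meanfwa
    return FwaChange(deltas, mean_delta)
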