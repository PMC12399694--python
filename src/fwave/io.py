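"""Data model and file I/O for multi-lead ECG recordings and cohort tables.

All voltages are millivolts end-to-end: readers convert from native units
(WFDB/EDF gains) on load, and every downstream stage assumes mV.  CSV is the
canonical interchange dialect (header row = lead labels, one column per lead);
WFDB and EDF are convenience readers available when the corresponding
libraries are installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard 12-lead order used throughout.  V6b is chest lead V6 relocated to
#: the patient's back (within the cardiac silhouette) to better capture
#: left-atrial activity; it is treated as an ordinary 12th lead.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6b",
)

#: Allowed long-term outcome labels in cohort tables.
OUTCOME_LABELS: tuple[str, ...] = ("SUCCESS", "FAILURE", "ON_AAD", "EXCLUDED")

EPOCH_LABELS: tuple[str, ...] = ("baseline", "endWPVI", "other")


class FwaveError(Exception):
    """Base class for package errors."""


class ValidationError(FwaveError):
    """Input data violates a documented contract."""


class ConfigurationError(FwaveError):
    """A required parameter is missing or inconsistent."""


@dataclass(frozen=True)
class EcgRecord:
    """A uniformly sampled multi-lead ECG epoch.

    Parameters
    ----------
    signals : ndarray, shape (n_samples, n_leads)
        Voltage series in mV, one column per lead.
    fs : float
        Sampling rate in Hz.  The default pipeline assumes 2000 Hz
        (a resampling operation is provided in :mod:`fwave.preprocess`).
    lead_labels : tuple of str
        Ordered, unique lead names.
    epoch_label : str
        One of ``baseline``, ``endWPVI``, ``other``.
    """

    signals: np.ndarray
    fs: float
    lead_labels: tuple[str, ...] = STANDARD_LEADS
    epoch_label: str = "other"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise ValidationError(
                f"signals must be 2-D (samples x leads), got shape {sig.shape}"
            )
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "lead_labels", tuple(self.lead_labels))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if sig.shape[1] != len(self.lead_labels):
            raise ValidationError(
                f"{sig.shape[1]} signal columns but {len(self.lead_labels)} lead labels"
            )
        if len(set(self.lead_labels)) != len(self.lead_labels):
            raise ValidationError("lead labels must be unique")
        if self.epoch_label not in EPOCH_LABELS:
            raise ValidationError(
                f"epoch_label must be one of {EPOCH_LABELS}, got {self.epoch_label!r}"
            )
        bad = ~np.isfinite(sig)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample at index {i} on lead {self.lead_labels[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, label: str) -> np.ndarray:
        """Return the voltage series (mV) of a single lead."""
        try:
            idx = self.lead_labels.index(label)
        except ValueError:
            raise KeyError(
                f"lead {label!r} not present; available: {self.lead_labels}"
            ) from None
        return self.signals[:, idx]

    def with_signals(self, signals: np.ndarray, **changes) -> "EcgRecord":
        """Copy of the record with replaced signal matrix (same leads/fs)."""
        return replace(self, signals=signals, **changes)

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# ECG readers / writers
# ---------------------------------------------------------------------------

def write_ecg(record: EcgRecord, path: str | Path, format: str = "csv") -> Path:
    """Write an ECG record; CSV is the canonical dialect.

    For CSV the sampling rate is stored in a ``# fs=<Hz>`` comment on the
    first line so that round-trips need no side channel.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={record.fs!r} epoch={record.epoch_label}\n")
            fh.write(",".join(record.lead_labels) + "\n")
            np.savetxt(fh, record.signals, delimiter=",", fmt="%.9g")
        return path
    if format == "wfdb":
        import wfdb  # optional dependency

        path.parent.mkdir(parents=True, exist_ok=True)
        wfdb.wrsamp(
            path.stem,
            fs=record.fs,
            units=["mV"] * record.n_leads,
            sig_name=list(record.lead_labels),
            p_signal=record.signals,
            write_dir=str(path.parent),
        )
        return path
    raise ConfigurationError(f"unsupported ECG write format {format!r}")


def _read_ecg_csv(path: Path, fs: float | None, epoch_label: str | None) -> EcgRecord:
    with open(path) as fh:
        first = fh.readline().strip()
        header_fs = None
        header_epoch = None
        if first.startswith("#"):
            for tok in first.lstrip("#").split():
                if tok.startswith("fs="):
                    header_fs = float(tok[3:])
                elif tok.startswith("epoch="):
                    header_epoch = tok[6:]
            labels_line = fh.readline().strip()
        else:
            labels_line = first
        labels = [s.strip() for s in labels_line.split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise ConfigurationError(
            f"{path}: sampling rate not in file header; pass fs explicitly"
        )
    epoch = epoch_label or header_epoch or "other"
    return EcgRecord(signals=data, fs=fs, lead_labels=tuple(labels), epoch_label=epoch)


def read_ecg(
    path: str | Path,
    format: str = "auto",
    fs: float | None = None,
    epoch_label: str | None = None,
) -> EcgRecord:
    """Read a multi-lead ECG recording into an :class:`EcgRecord` (mV).

    Parameters
    ----------
    format : {'auto', 'csv', 'wfdb', 'edf'}
        ``auto`` dispatches on the file suffix (.csv, .hea/.dat, .edf).
    fs : float, optional
        Required for CSV files that carry no ``# fs=`` header comment.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".hea": "wfdb", ".dat": "wfdb", ".edf": "edf"}.get(
            suffix, "csv"
        )
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        rec = _read_ecg_csv(path, fs, epoch_label)
    elif format == "wfdb":
        try:
            import wfdb
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ConfigurationError(
                "reading WFDB requires the optional 'wfdb' package"
            ) from exc
        sig, meta = wfdb.rdsamp(str(path.with_suffix("")))
        rec = EcgRecord(
            signals=np.asarray(sig, dtype=float),
            fs=float(meta["fs"]),
            lead_labels=tuple(meta["sig_name"]),
            epoch_label=epoch_label or "other",
        )
    elif format == "edf":
        try:
            import pyedflib
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ConfigurationError(
                "reading EDF requires the optional 'pyedflib' package"
            ) from exc
        with pyedflib.EdfReader(str(path)) as f:  # pragma: no cover
            labels = tuple(f.getSignalLabels())
            fs_edf = float(f.getSampleFrequency(0))
            sig = np.column_stack(
                [f.readSignal(i) for i in range(f.signals_in_file)]
            )
        rec = EcgRecord(sig, fs_edf, labels, epoch_label or "other")
    else:
        raise ConfigurationError(f"unsupported ECG read format {format!r}")
    logger.info(
        "read_ecg %s: %d leads, %.1f s at %g Hz",
        path.name, rec.n_leads, rec.duration_s, rec.fs,
    )
    return rec


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-patient feature table for cohort-level analyses.

    One row per patient with columns::

        patient_id, outcome [, followup_months, event],
        fwa_<LEAD>_baseline ..., fwa_<LEAD>_endwpvi ...,
        meanfwa_baseline, meanfwa_endwpvi

    Outcomes are restricted to ``SUCCESS`` (long-term sinus rhythm off
    antiarrhythmic drugs), ``FAILURE`` (recurrence despite durable isolation),
    ``ON_AAD`` (sinus rhythm only on drugs) and ``EXCLUDED``.  The two
    meanfwa columns are recomputed from the per-lead columns when absent.
    """

    data: pd.DataFrame
    leads: tuple[str, ...] = field(default=(), init=True)

    def __post_init__(self) -> None:
        df = self.data
        required = {"patient_id", "outcome"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated patient_id: {dup.iloc[0]!r}")
        bad = set(df["outcome"]) - set(OUTCOME_LABELS)
        if bad:
            raise ValidationError(
                f"unknown outcome label(s) {sorted(bad)}; allowed: {OUTCOME_LABELS}"
            )
        if "followup_months" in df.columns:
            t = pd.to_numeric(df["followup_months"])
            if (t.dropna() < 0).any():
                raise ValidationError("negative follow-up time")
        if not self.leads:
            leads = []
            for col in df.columns:
                if col.startswith("fwa_") and col.endswith("_baseline"):
                    leads.append(col[len("fwa_"):-len("_baseline")])
            self.leads = tuple(leads)
        for lead in self.leads:
            for ep in ("baseline", "endwpvi"):
                col = f"fwa_{lead}_{ep}"
                if col not in df.columns:
                    raise ValidationError(f"cohort table missing column {col}")
        for ep in ("baseline", "endwpvi"):
            col = f"meanfwa_{ep}"
            if col not in df.columns and self.leads:
                df[col] = df[[f"fwa_{lead}_{ep}" for lead in self.leads]].mean(axis=1)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, outcomes: Iterable[str]) -> "CohortTable":
        keep = self.data["outcome"].isin(list(outcomes))
        return CohortTable(self.data.loc[keep].reset_index(drop=True), self.leads)

    def outcome_counts(self) -> dict[str, int]:
        return self.data["outcome"].value_counts().to_dict()


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV (see :class:`CohortTable` schema)."""
    df = pd.read_csv(path)
    table = CohortTable(df)
    logger.info("read_cohort %s: %d patients, %d leads", path, len(table), len(table.leads))
    return table


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def outcome_shares(table: CohortTable, denominator: str = "analyzed") -> dict[str, float]:
    """Endpoint-assignment shares, in percent of analyzed patients.

    ``denominator='analyzed'`` counts all non-EXCLUDED rows (the study-flow
    convention: SUCCESS + ON_AAD + FAILURE); ``'grouped'`` restricts to the
    SUCCESS/FAILURE comparison groups.
    """
    if denominator == "analyzed":
        sub = table.subset(["SUCCESS", "FAILURE", "ON_AAD"])
    elif denominator == "grouped":
        sub = table.subset(["SUCCESS", "FAILURE"])
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    n = len(sub)
    if n == 0:
        raise ValidationError("no patients in denominator")
    counts = sub.outcome_counts()
    return {label: 100.0 * counts.get(label, 0) / n for label in ("SUCCESS", "ON_AAD", "FAILURE")}


def covariate_share(
    table: CohortTable, column: str, outcomes: Sequence[str] = ("SUCCESS", "FAILURE")
) -> float:
    """Percentage of patients (within the given outcome groups) with a
    positive binary covariate, e.g. antiarrhythmic-drug use at follow-up."""
    sub = table.subset(outcomes)
    if column not in sub.data.columns:
        raise ValidationError(f"cohort table has no column {column!r}")
    vals = pd.to_numeric(sub.data[column])
    return 100.0 * float(vals.sum()) / len(sub)
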