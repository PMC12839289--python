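"""Causal windowing, labeling, patient-wise splitting and class balancing.

The streaming protocol: each retained EEG channel is z-scored, the recording
is cut into fixed 128-sample (0.5 s at 256 Hz) windows with 50 % overlap
(step 64), and a window is labeled seizure when at least 20 % of its samples
fall inside a clinician-annotated (here: generator-annotated) ictal interval,
with an exact seconds-to-samples mapping.  Splitting is patient-wise — a
patient's every window lands in exactly one partition — and class balancing
touches the training partition only, so validation keeps natural prevalence.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .synthetic import EEGRecord

__all__ = [
    "LabeledWindow",
    "SplitAssignment",
    "select_eeg_channels",
    "zscore",
    "segment",
    "label_windows",
    "windows_for_record",
    "patient_split",
    "partition_windows",
    "balance_training",
    "windows_to_arrays",
    "save_windows_npz",
    "load_windows_npz",
    "read_edf_record",
    "WIN_SAMPLES",
    "STEP_SAMPLES",
    "OVERLAP_THETA",
]

logger = logging.getLogger(__name__)

WIN_SAMPLES = 128
STEP_SAMPLES = 64
OVERLAP_THETA = 0.2
SPLIT_SEED = 42
TRAIN_FRACTION = 0.7
BALANCE_MAX_RATIO = 4.0

#: Channel-label patterns dropped by default (non-EEG modalities).
DEFAULT_EXCLUSIONS = ["*ECG*", "*EKG*", "*EMG*", "*EOG*", "*PHOTIC*", "*VNS*", "-"]


@dataclass
class LabeledWindow:
    """One C x T segment with its label and provenance."""

    data: np.ndarray  # C x T
    label: int | None
    start_sample: int
    patient_id: str
    record_id: str

    def __post_init__(self) -> None:
        if not self.patient_id or not self.record_id:
            raise ValueError("provenance fields must be non-empty")


@dataclass(frozen=True)
class SplitAssignment:
    train_patients: frozenset[str]
    val_patients: frozenset[str]
    seed: int
    train_fraction: float


def select_eeg_channels(
    record: EEGRecord, exclusion_patterns: list[str] | None = None
) -> EEGRecord:
    """Drop non-EEG channels and resolve duplicate labels (first wins).

    ``exclusion_patterns`` are case-insensitive glob patterns matched against
    channel labels; channel order is otherwise preserved.
    """
    patterns = DEFAULT_EXCLUSIONS if exclusion_patterns is None else exclusion_patterns
    keep_idx: list[int] = []
    seen: set[str] = set()
    for i, lab in enumerate(record.channels):
        if any(fnmatch.fnmatch(lab.upper(), p.upper()) for p in patterns):
            continue
        if lab in seen:
            logger.info("dropping duplicate channel label %r (keeping first)", lab)
            continue
        seen.add(lab)
        keep_idx.append(i)
    if not keep_idx:
        raise ValueError("all channels excluded — empty record")
    return replace(
        record,
        channels=[record.channels[i] for i in keep_idx],
        data=record.data[keep_idx],
    )


def zscore(record: EEGRecord) -> EEGRecord:
    """Per-channel standardization to zero mean, unit (population) variance.

    Channels with standard deviation below 1e-12 map to all-zero.
    """
    if record.n_samples < 2:
        raise ValueError("need at least 2 samples to z-score")
    mu = record.data.mean(axis=1, keepdims=True)
    sd = record.data.std(axis=1, keepdims=True)  # population (1/N) convention
    out = np.where(sd < 1e-12, 0.0, (record.data - mu) / np.where(sd < 1e-12, 1.0, sd))
    return replace(record, data=out)


def segment(
    record: EEGRecord, win: int = WIN_SAMPLES, step: int = STEP_SAMPLES
) -> list[LabeledWindow]:
    """Cut the record into overlapping windows (labels unset).

    Starts form the arithmetic sequence 0, step, 2*step, ...; the window count
    is ``floor((N - win)/step) + 1`` for N >= win, else zero.
    """
    if win < 1 or not (1 <= step <= win):
        raise ValueError("need win >= 1 and 1 <= step <= win")
    N = record.n_samples
    if N < win:
        return []
    n_win = (N - win) // step + 1
    return [
        LabeledWindow(
            data=record.data[:, k * step : k * step + win],
            label=None,
            start_sample=k * step,
            patient_id=record.patient_id,
            record_id=record.record_id,
        )
        for k in range(n_win)
    ]


def label_windows(
    windows: list[LabeledWindow],
    intervals: list[tuple[float, float]],
    fs: float,
    theta: float = OVERLAP_THETA,
) -> list[LabeledWindow]:
    """Label each window 1 iff >= theta of its samples are ictal.

    Second-resolution intervals convert to half-open sample ranges
    ``[round(onset*fs), round(offset*fs))``; windows are half-open
    ``[start, start+T)``. The overlap fraction test is inclusive (>=).
    """
    sample_ivals = [(int(round(a * fs)), int(round(b * fs))) for a, b in intervals]
    out = []
    for w in windows:
        T = w.data.shape[1]
        s0, s1 = w.start_sample, w.start_sample + T
        overlap = sum(max(0, min(s1, b) - max(s0, a)) for a, b in sample_ivals)
        out.append(replace(w, label=int(overlap / T >= theta)))
    return out


def windows_for_record(
    record: EEGRecord,
    win: int = WIN_SAMPLES,
    step: int = STEP_SAMPLES,
    theta: float = OVERLAP_THETA,
) -> list[LabeledWindow]:
    """Convenience: z-score, segment and label one record."""
    rec = zscore(record)
    return label_windows(segment(rec, win, step), rec.ictal_intervals, rec.fs, theta)


def patient_split(
    cohort: list[EEGRecord],
    train_fraction: float = TRAIN_FRACTION,
    seed: int = SPLIT_SEED,
) -> SplitAssignment:
    """Patient-wise 70/30 split with a fixed shuffle seed.

    Patient ids are sorted lexicographically and then shuffled with a
    seed-determined Fisher-Yates permutation; the first
    ``round(train_fraction * P)`` go to training.
    """
    patients = sorted({r.patient_id for r in cohort})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for a patient-wise split")
    order = np.array(patients, dtype=object)
    np.random.default_rng(seed).shuffle(order)
    n_train = int(round(train_fraction * len(order)))
    if n_train == 0 or n_train == len(order):
        raise ValueError("train_fraction leaves a partition empty")
    return SplitAssignment(
        train_patients=frozenset(order[:n_train]),
        val_patients=frozenset(order[n_train:]),
        seed=seed,
        train_fraction=train_fraction,
    )


def partition_windows(
    windows: list[LabeledWindow], split: SplitAssignment
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Route each window to its patient's partition."""
    train = [w for w in windows if w.patient_id in split.train_patients]
    val = [w for w in windows if w.patient_id in split.val_patients]
    return train, val


def balance_training(
    train_windows: list[LabeledWindow],
    seed: int = 0,
    max_ratio: float = BALANCE_MAX_RATIO,
) -> list[LabeledWindow]:
    """Class-balance the *training* windows only.

    Both classes end with exactly ``n* = min(n_majority, max_ratio *
    n_minority)`` members: the minority is oversampled with replacement, the
    majority undersampled without. Window objects are reused, never modified.
    """
    pos = [w for w in train_windows if w.label == 1]
    neg = [w for w in train_windows if w.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    n_star = int(min(len(majority), max_ratio * len(minority)))
    rng = np.random.default_rng(seed)
    minority_out = (
        list(minority)
        if len(minority) == n_star
        else [minority[i] for i in rng.integers(0, len(minority), size=n_star)]
    )
    majority_out = (
        list(majority)
        if len(majority) == n_star
        else [majority[i] for i in rng.choice(len(majority), size=n_star, replace=False)]
    )
    out = minority_out + majority_out
    rng.shuffle(out)
    return out


def windows_to_arrays(windows: list[LabeledWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (B x C x T, labels) arrays for model consumption."""
    X = np.stack([w.data for w in windows]).astype(np.float64)
    y = np.array([-1 if w.label is None else w.label for w in windows], dtype=np.int64)
    return X, y


def save_windows_npz(windows: list[LabeledWindow], path: str | Path) -> None:
    """NPZ archive of the window tensor plus parallel provenance columns."""
    X, y = windows_to_arrays(windows)
    np.savez_compressed(
        path,
        data=X,
        label=y,
        start_sample=np.array([w.start_sample for w in windows], dtype=np.int64),
        patient_id=np.array([w.patient_id for w in windows], dtype=object),
        record_id=np.array([w.record_id for w in windows], dtype=object),
    )


def load_windows_npz(path: str | Path) -> list[LabeledWindow]:
    with np.load(path, allow_pickle=True) as z:
        return [
            LabeledWindow(
                data=z["data"][i],
                label=None if z["label"][i] < 0 else int(z["label"][i]),
                start_sample=int(z["start_sample"][i]),
                patient_id=str(z["patient_id"][i]),
                record_id=str(z["record_id"][i]),
            )
            for i in range(z["data"].shape[0])
        ]


def read_edf_record(
    path: str | Path,
    patient_id: str,
    ictal_intervals: list[tuple[float, float]] | None = None,
) -> EEGRecord:
    """Read an EDF recording (e.g. a CHB-MIT file) into an :class:`EEGRecord`.

    Requires the optional ``mne`` dependency.  Recordings not sampled at
    256 Hz are rejected rather than resampled.
    """
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if abs(fs - 256.0) > 1e-6:
        raise ValueError(f"expected 256 Hz EDF, got {fs} Hz (resampling is out of scope)")
    return EEGRecord(
        patient_id=patient_id,
        record_id=Path(path).stem,
        fs=fs,
        channels=list(raw.ch_names),
        data=raw.get_data(),
        ictal_intervals=ictal_intervals or [],
    )
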