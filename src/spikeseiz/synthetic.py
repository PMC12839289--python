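"""Deterministic synthetic EEG cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the detection pipeline
assumes about scalp EEG: 256 Hz multichannel recordings whose background is
1/f-shaped ("pink") Gaussian noise plus a low-amplitude ~10 Hz alpha-band
oscillation, interrupted by rare ictal epochs (< 5 % of recording time, each
at least 10 s long) in which a high-amplitude rhythmic ~3 Hz spike-and-wave
motif is superimposed on every channel.  It makes no claim of physiological
realism — no artifact, montage or volume-conduction modeling — it only gives
downstream stages (windowing, spike encoding, training, streaming alarms)
something with the right shapes, rates and separability to be tested against,
fully offline.

Determinism contract: a cohort is a pure function of its :class:`CohortSpec`.
Every record draws from its own RNG stream keyed by ``(seed, patient index,
record index)``, so records are independent and generation order is
irrelevant.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecord",
    "CohortSpec",
    "generate_background",
    "inject_seizure",
    "generate_cohort",
    "write_record_npz",
    "read_record_npz",
    "write_annotations",
    "read_annotations",
    "record_to_csv",
]

#: Default scalp montage labels (10-20 system, 23 bipolar-style channels).
DEFAULT_CHANNELS = (
    "FP1-F7 F7-T7 T7-P7 P7-O1 FP1-F3 F3-C3 C3-P3 P3-O1 FP2-F4 F4-C4 C4-P4 "
    "P4-O2 FP2-F8 F8-T8 T8-P8 P8-O2 FZ-CZ CZ-PZ P7-T7 T7-FT9 FT9-FT10 "
    "FT10-T8 T8-P8b"
).split()

EDGE_GUARD_S = 30.0  # seizures never start/end within this margin of record edges
MIN_GAP_S = 5.0  # minimum inter-seizure gap


@dataclass
class EEGRecord:
    """One continuous multichannel recording with ictal annotations.

    ``data`` is a C x N real matrix in arbitrary units (pre z-score);
    ``ictal_intervals`` are half-open ``(onset_s, offset_s)`` pairs in
    seconds, sorted and non-overlapping.
    """

    patient_id: str
    record_id: str
    fs: float
    channels: list[str]
    data: np.ndarray
    ictal_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a C x N matrix")
        C, N = self.data.shape
        if C < 1 or N < 1 or self.fs <= 0:
            raise ValueError("need C >= 1, N >= 1, fs > 0")
        if len(self.channels) != C:
            raise ValueError("channel label count must match data rows")
        dur = N / self.fs
        prev_off = -1.0
        ivals = sorted(self.ictal_intervals)
        for on, off in ivals:
            if not (0 <= on < off <= dur + 1e-9):
                raise ValueError(f"interval ({on}, {off}) outside record [0, {dur}]")
            if on < prev_off:
                raise ValueError("ictal intervals overlap")
            prev_off = off
        self.ictal_intervals = [(float(a), float(b)) for a, b in ivals]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def ictal_fraction(self) -> float:
        return sum(b - a for a, b in self.ictal_intervals) / self.duration_s


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort; fully determines its content."""

    n_patients: int = 8
    records_per_patient: int = 1
    record_duration_s: float = 240.0
    seizure_prevalence: float = 0.04
    min_seizure_s: float = 10.0
    ictal_freq_hz: float = 3.0
    ictal_amp_gain: float = 4.0
    n_channels: int = 23
    fs: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.seizure_prevalence < 1):
            raise ValueError("seizure_prevalence must lie in (0, 1)")
        if self.n_patients < 1 or self.records_per_patient < 1:
            raise ValueError("counts must be positive")
        if self.min_seizure_s <= 0 or self.record_duration_s <= 0:
            raise ValueError("durations must be positive")


def _pink_noise(rng: np.random.Generator, C: int, N: int) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((C, N))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(N)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # kill DC: zero-mean in expectation and in sample
    x = np.fft.irfft(spec * shaping, n=N, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return x / sd


def generate_background(
    C: int,
    duration_s: float,
    fs: float = 256.0,
    seed: int = 0,
    *,
    patient_id: str = "p00",
    record_id: str = "p00_r00",
    channels: list[str] | None = None,
) -> EEGRecord:
    """Generate a seizure-free background record.

    Background = pink (1/f) noise + a 10 Hz sinusoid of amplitude 0.2 with an
    independent random phase per channel; approximately zero-mean,
    unit-variance per channel before z-scoring.
    """
    if C < 1 or duration_s <= 0 or fs <= 0:
        raise ValueError("C, duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    N = int(round(duration_s * fs))
    t = np.arange(N) / fs
    # Pink (1/f) cortical-like noise plus a broadband white floor: scalp EEG
    # at 256 Hz always carries sensor/EMG broadband power, and the floor sets
    # the effective SNR seen by change-based (slope) encoders.
    w = 0.3
    x = np.sqrt(1 - w**2) * _pink_noise(rng, C, N) + w * rng.standard_normal((C, N))
    phase = rng.uniform(0, 2 * np.pi, size=(C, 1))
    x = x + 0.2 * np.sin(2 * np.pi * 10.0 * t[None, :] + phase)
    if channels is None:
        base = DEFAULT_CHANNELS
        channels = [base[i % len(base)] + ("" if i < len(base) else f"_{i}") for i in range(C)]
    return EEGRecord(patient_id, record_id, float(fs), list(channels), x, [])


def _spike_wave_motif(
    t: np.ndarray, freq_hz: float, rng: np.random.Generator, mix: float = 0.5
) -> np.ndarray:
    """Spike-and-wave-like waveform, normalized to unit variance.

    Two components at the seizure frequency whose balance is set by ``mix``:
    a sharp periodic transient (narrow von-Mises-shaped pulse, strong sample-
    to-sample changes, low duty cycle) and a smooth slow wave (sustained
    moderate-slope oscillation).  ``mix`` near 1 gives transient-dominant
    seizures, near 0 rhythmic-dominant ones — the two ictal signatures that
    change-based and amplitude-based spike codes are respectively suited to.
    Real seizures vary in morphology across episodes; drawing ``mix`` per
    seizure reproduces that variability.
    """
    phi = 2 * np.pi * freq_hz * t + rng.uniform(0, 2 * np.pi)
    sharp = np.exp(12.0 * (np.cos(phi) - 1.0))
    sharp = sharp - sharp.mean()
    sharp /= max(sharp.std(), 1e-12)
    wave = np.sin(phi - 0.5)
    wave /= max(wave.std(), 1e-12)
    motif = mix * sharp + (1.0 - mix) * wave
    sd = motif.std()
    return motif / (sd if sd > 1e-12 else 1.0)


def inject_seizure(
    record: EEGRecord,
    onset_s: float,
    duration_s: float,
    freq_hz: float = 3.0,
    gain: float = 4.0,
    mix: float | None = None,
) -> EEGRecord:
    """Return a copy of ``record`` with one ictal epoch superimposed.

    Within ``[onset, onset + duration)`` a unit-variance spike-wave motif
    scaled by ``gain`` (times a per-channel random gain in [0.7, 1.3]) is
    added to every channel; samples outside the interval are untouched, so
    within-interval variance strictly exceeds the background variance.
    ``mix`` sets the transient-vs-rhythmic morphology balance (drawn from the
    injection's own stream when None).
    """
    fs = record.fs
    offset_s = onset_s + duration_s
    if duration_s <= 0 or onset_s < 0 or offset_s > record.duration_s + 1e-9:
        raise ValueError("seizure interval lies outside the record")
    for a, b in record.ictal_intervals:
        if onset_s < b and a < offset_s:
            raise ValueError("seizure interval overlaps an existing one")
    # Deterministic per-injection stream (record identity + placement).
    key = zlib.crc32(f"{record.record_id}:{onset_s:.6f}:{duration_s:.6f}".encode())
    rng = np.random.default_rng([key, int(round(onset_s * fs))])

    i0, i1 = int(round(onset_s * fs)), int(round(offset_s * fs))
    t = np.arange(i1 - i0) / fs
    envelope = np.ones_like(t)
    ramp = min(1.0, duration_s / 4)
    nr = max(1, int(round(ramp * fs)))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    envelope[:nr] *= up
    envelope[-nr:] *= up[::-1]

    data = record.data.copy()
    ch_gain = rng.uniform(0.7, 1.3, size=(record.n_channels, 1))
    if mix is None:
        mix = float(rng.uniform(0.1, 0.9))
    motif = _spike_wave_motif(t, freq_hz, rng, mix=mix)
    data[:, i0:i1] += gain * ch_gain * (envelope * motif)[None, :]

    intervals = record.ictal_intervals + [(float(onset_s), float(offset_s))]
    return replace(record, data=data, ictal_intervals=intervals)


def _place_seizures(
    rng: np.random.Generator, spec: CohortSpec
) -> list[tuple[float, float]]:
    """Draw seizure (onset, duration) pairs for one record.

    Durations are uniform in [min_seizure_s, 1.5 min_seizure_s]; total ictal
    time per record targets prevalence x duration. Onsets are uniform subject
    to a 30 s edge guard and a 5 s inter-seizure gap.
    """
    target = spec.seizure_prevalence * spec.record_duration_s
    usable = spec.record_duration_s - 2 * EDGE_GUARD_S
    if usable < spec.min_seizure_s:
        raise ValueError(
            "record too short for one min-duration seizure inside the edge guard"
        )
    durations: list[float] = []
    remaining = target
    while remaining >= 0.5 * spec.min_seizure_s and sum(durations) < usable:
        d = float(rng.uniform(spec.min_seizure_s, 1.5 * spec.min_seizure_s))
        d = min(d, max(spec.min_seizure_s, remaining))
        durations.append(d)
        remaining -= d
    if not durations:
        durations = [spec.min_seizure_s]

    placed: list[tuple[float, float]] = []
    for d in durations:
        for _ in range(200):
            on = float(rng.uniform(EDGE_GUARD_S, spec.record_duration_s - EDGE_GUARD_S - d))
            ok = all(
                on - MIN_GAP_S >= b or a >= on + d + MIN_GAP_S for a, b in placed
            )
            if ok:
                placed.append((on, on + d))
                break
    return sorted(placed)


def generate_cohort(spec: CohortSpec) -> list[EEGRecord]:
    """Generate the full cohort described by ``spec`` (pure function of it)."""
    records: list[EEGRecord] = []
    for p in range(spec.n_patients):
        pid = f"p{p:02d}"
        for r in range(spec.records_per_patient):
            rid = f"{pid}_r{r:02d}"
            rng_key = [int(spec.seed) & 0x7FFFFFFF, p, r]
            rec = generate_background(
                spec.n_channels,
                spec.record_duration_s,
                spec.fs,
                seed=rng_key,
                patient_id=pid,
                record_id=rid,
            )
            place_rng = np.random.default_rng(rng_key + [1])
            # Alternate transient-dominant / rhythmic-dominant morphologies so
            # every record's seizures sample both ictal signatures.
            for i, (on, off) in enumerate(_place_seizures(place_rng, spec)):
                base_mix = 0.85 if i % 2 == 0 else 0.15
                mix = float(np.clip(base_mix + place_rng.uniform(-0.1, 0.1), 0.0, 1.0))
                rec = inject_seizure(
                    rec, on, off - on, spec.ictal_freq_hz, spec.ictal_amp_gain, mix=mix
                )
            records.append(rec)

    total = sum(r.duration_s for r in records)
    ictal = sum(sum(b - a for a, b in r.ictal_intervals) for r in records)
    frac = ictal / total
    rel = abs(frac - spec.seizure_prevalence) / spec.seizure_prevalence
    if rel > 0.30:
        raise ValueError(
            f"achieved ictal fraction {frac:.4f} misses the prevalence target "
            f"{spec.seizure_prevalence} by more than 30% — prevalence unreachable "
            "for this duration/min_seizure combination"
        )
    return records


# ---------------------------------------------------------------------------
# Serialization: NPZ per record + plain-text annotation files.

def write_record_npz(record: EEGRecord, path: str | Path) -> None:
    np.savez(
        path,
        data=record.data,
        fs=record.fs,
        channels=np.array(record.channels, dtype=object),
        patient_id=record.patient_id,
        record_id=record.record_id,
        ictal=np.array(record.ictal_intervals, dtype=np.float64).reshape(-1, 2),
    )


def read_record_npz(path: str | Path) -> EEGRecord:
    with np.load(path, allow_pickle=True) as z:
        return EEGRecord(
            patient_id=str(z["patient_id"]),
            record_id=str(z["record_id"]),
            fs=float(z["fs"]),
            channels=[str(c) for c in z["channels"]],
            data=z["data"],
            ictal_intervals=[tuple(map(float, row)) for row in z["ictal"]],
        )


def write_annotations(records: list[EEGRecord], path: str | Path) -> None:
    """Tab-separated ``record_id  onset_s  offset_s`` lines, one per interval."""
    with open(path, "w") as fh:
        for rec in records:
            for on, off in rec.ictal_intervals:
                # repr-precision floats so intervals round-trip exactly
                fh.write(f"{rec.record_id}\t{on!r}\t{off!r}\n")


def read_annotations(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rid, on, off = line.split("\t")
            out.setdefault(rid, []).append((float(on), float(off)))
    for rid in out:
        out[rid].sort()
    return out


def record_to_csv(record: EEGRecord, path: str | Path) -> None:
    """Dump one record as CSV (time_s + one column per channel) for inspection."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", *record.channels])
        t = np.arange(record.n_samples) / record.fs
        for i in range(record.n_samples):
            w.writerow([f"{t[i]:.6f}", *(f"{v:.6f}" for v in record.data[:, i])])
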