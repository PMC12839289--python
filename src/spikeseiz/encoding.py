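"""Signal-to-spike encoders: Delta-Sigma, stochastic rate, hybrid, latency.

Two complementary binary codes turn a normalized C x T EEG window into spike
trains:

* **Delta-Sigma (change-based).** A spike fires whenever the sample exceeds an
  adaptive reference; the reference then integrates spikes minus a fixed step:

      s(t) = 1  if x(t) > r(t) else 0
      r(t+1) = r(t) + s(t) - delta          (delta = 0.3)

  On any constant input the long-run duty cycle converges to delta (each spike
  raises r by 1 - delta, each silence lowers it by delta).

* **Stochastic rate (amplitude-based).** Each sample maps to a firing
  probability through the logistic p(t) = sigma(a*x(t) + c) and a spike is an
  independent Bernoulli(p(t)) draw. Defaults a = 1, c = 0 give the plain
  sigma(x) code; the (a, c) extension exists so sparser firing regimes can be
  dialed in, with a bisection helper to hit a target density.

The hybrid code concatenates both along the channel axis: rows 0..C-1 are
Delta-Sigma, rows C..2C-1 are rate (the raster-plot convention with channels
0-22 change-coded and 23-45 rate-coded for a 23-channel montage).

Rate-coder determinism: each channel's Bernoulli stream is keyed by
``(seed, crc32(channel samples))``, so the same signal always gets the same
spikes under a given seed, permuting input channels permutes the output rows
identically, and adding or removing channels never shifts another channel's
randomness.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "EncoderConfig",
    "SpikeBatch",
    "delta_sigma_encode",
    "delta_sigma_reference_trace",
    "rate_encode",
    "hybrid_encode",
    "latency_encode",
    "encode_windows",
    "spike_density",
    "density_to_rate",
    "calibrate_rate_offset",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder parameters; identical config + input => identical output."""

    delta: float = 0.3
    r0: float = 0.0
    rate_gain: float = 1.0
    rate_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class SpikeBatch:
    """Binary spike tensor B x C' x T with encoder provenance."""

    spikes: np.ndarray
    encoder_tag: str  # delta_sigma | rate | hybrid | latency
    fs: float = 256.0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be B x C x T")
        vals = np.unique(self.spikes)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("spike entries must be binary")


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite samples")
    return x


def _delta_sigma_batch(x: np.ndarray, delta: float, r0: float) -> np.ndarray:
    """Vectorized Delta-Sigma over the trailing time axis (loop over T only)."""
    T = x.shape[-1]
    s = np.zeros(x.shape, dtype=np.uint8)
    r = np.full(x.shape[:-1], float(r0))
    for t in range(T):
        fired = x[..., t] > r
        s[..., t] = fired
        r = r + fired - delta
    return s


def delta_sigma_encode(x: np.ndarray, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Change-based encoding of a 1-D sequence; returns a binary array of len T."""
    x = _check_finite(x)
    if x.ndim != 1:
        raise ValueError("delta_sigma_encode takes a 1-D sequence")
    return _delta_sigma_batch(x[None, :], cfg.delta, cfg.r0)[0]


def delta_sigma_reference_trace(
    x: np.ndarray, cfg: EncoderConfig = EncoderConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Return (spikes, reference trace r(0..T)) — T+1 reference values."""
    x = _check_finite(x)
    T = len(x)
    s = np.zeros(T, dtype=np.uint8)
    r = np.zeros(T + 1)
    r[0] = cfg.r0
    for t in range(T):
        s[t] = 1 if x[t] > r[t] else 0
        r[t + 1] = r[t] + s[t] - cfg.delta
    return s, r


def _rate_rng(seed: int, x: np.ndarray) -> np.random.Generator:
    """Per-channel substream keyed by seed and the channel's sample content."""
    key = zlib.crc32(np.ascontiguousarray(x, dtype=np.float64).tobytes())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def rate_encode(x: np.ndarray, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Stochastic rate encoding of a 1-D sequence: Bernoulli(sigma(a*x + c))."""
    x = _check_finite(x)
    if x.ndim != 1:
        raise ValueError("rate_encode takes a 1-D sequence")
    p = expit(cfg.rate_gain * x + cfg.rate_offset)
    u = _rate_rng(cfg.seed, x).random(len(x))
    return (u < p).astype(np.uint8)


def hybrid_encode(window: np.ndarray, cfg: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Dual code of a C x T window: rows 0..C-1 Delta-Sigma, C..2C-1 rate."""
    window = _check_finite(window)
    if window.ndim != 2 or window.shape[0] < 1:
        raise ValueError("hybrid_encode takes a C x T matrix with C >= 1")
    ds = _delta_sigma_batch(window, cfg.delta, cfg.r0)
    rt = np.stack([rate_encode(ch, cfg) for ch in window])
    return np.concatenate([ds, rt], axis=0)


def latency_encode(window: np.ndarray, threshold: float) -> np.ndarray:
    """First-crossing code: one spike per channel at the first |x| >= threshold."""
    window = _check_finite(np.atleast_2d(window))
    out = np.zeros(window.shape, dtype=np.uint8)
    hits = np.abs(window) >= threshold
    for c in range(window.shape[0]):
        idx = np.flatnonzero(hits[c])
        if idx.size:
            out[c, idx[0]] = 1
    return out


def encode_windows(
    X: np.ndarray, coder: str, cfg: EncoderConfig = EncoderConfig(), fs: float = 256.0
) -> SpikeBatch:
    """Encode a stacked B x C x T window tensor into a :class:`SpikeBatch`."""
    X = _check_finite(X)
    if X.ndim != 3:
        raise ValueError("expected B x C x T")
    if coder == "delta_sigma":
        spikes = _delta_sigma_batch(X, cfg.delta, cfg.r0)
    elif coder == "rate":
        p = expit(cfg.rate_gain * X + cfg.rate_offset)
        u = np.empty_like(p)
        for b in range(X.shape[0]):
            for c in range(X.shape[1]):
                u[b, c] = _rate_rng(cfg.seed, X[b, c]).random(X.shape[2])
        spikes = (u < p).astype(np.uint8)
    elif coder == "hybrid":
        ds = encode_windows(X, "delta_sigma", cfg, fs).spikes
        rt = encode_windows(X, "rate", cfg, fs).spikes
        spikes = np.concatenate([ds, rt], axis=1)
    else:
        raise ValueError(f"unknown coder {coder!r}")
    return SpikeBatch(spikes=spikes, encoder_tag=coder, fs=fs)


def spike_density(batch: SpikeBatch) -> float:
    """Fraction of channel-timestep bins containing a spike: rho = events/(B*C*T)."""
    if batch.spikes.size == 0:
        raise ValueError("empty spike batch")
    return float(batch.spikes.mean())


def density_to_rate(rho: float, fs: float = 256.0) -> float:
    """Equivalent firing rate rho * fs in spikes/s/channel, shown to one decimal."""
    if not (0 <= rho <= 1) or fs <= 0:
        raise ValueError("need 0 <= rho <= 1 and fs > 0")
    return round(rho * fs, 1)


def calibrate_rate_offset(
    X: np.ndarray, target_density: float, rate_gain: float = 1.0, tol: float = 1e-6
) -> float:
    """Fit the rate-coder offset c by bisection so E[sigma(a*x + c)] hits a target.

    The plain sigma(x) code on zero-mean signals fires at ~50 % of timesteps;
    this helper finds the c that brings the expected density down (or up) to
    ``target_density`` on the given sample of windows.
    """
    if not (0 < target_density < 1):
        raise ValueError("target density must be in (0, 1)")
    x = np.asarray(X, dtype=np.float64).ravel()
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = float(expit(rate_gain * x + mid).mean())
        if abs(d - target_density) < tol:
            return mid
        if d < target_density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def save_spike_batch(batch: SpikeBatch, path: str | Path) -> None:
    np.savez_compressed(
        path, spikes=batch.spikes.astype(np.uint8), tag=batch.encoder_tag, fs=batch.fs
    )


def load_spike_batch(path: str | Path) -> SpikeBatch:
    with np.load(path, allow_pickle=True) as z:
        return SpikeBatch(spikes=z["spikes"], encoder_tag=str(z["tag"]), fs=float(z["fs"]))
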