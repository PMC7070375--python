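"""Candidate heart-sound peaks from an envelope.

Three stages: every gradient sign change from positive to negative is a local
maximum; maxima below ``mean(envelope) * n`` are discarded (``n`` is the
regime-dependent threshold multiplier, with the mean taken over the current
analysis segment); and maxima closer together than the 150 ms maximal length
of a heart sound are collapsed to the largest one, which is what makes the
detector robust to split sounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import Envelope
from .exceptions import ConfigurationError, DegenerateInputError

__all__ = ["PeakSeries", "PeakConfig", "local_maxima", "apply_threshold",
           "enforce_separation", "detect_peaks"]


@dataclass
class PeakSeries:
    """Ordered peak times (s) and envelope amplitudes."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ConfigurationError("times and amplitudes must have identical shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def deltas(self) -> np.ndarray:
        """Inter-peak distances in seconds."""
        return np.diff(self.times)


@dataclass
class PeakConfig:
    """Peak-detection parameters.

    ``n_normal`` / ``n_high`` multiply the segment-mean envelope to form the
    amplitude threshold at normal and increased heart rates. Defaults are the
    optimized Hilbert-transform values (1.9 / 1.3); the smoother STFT
    envelope uses 1.0 / 0.6 (:meth:`for_method`). ``min_separation`` is the
    150 ms maximal length of a heart sound.
    """

    n_normal: float = 1.9
    n_high: float = 1.3
    min_separation: float = 0.150

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_high <= 0:
            raise ConfigurationError("threshold multipliers must be > 0")
        if self.min_separation <= 0:
            raise ConfigurationError("min_separation must be > 0")

    @classmethod
    def for_method(cls, method: str) -> "PeakConfig":
        if method.upper() == "HT":
            return cls(n_normal=1.9, n_high=1.3)
        if method.upper() == "STFT":
            return cls(n_normal=1.0, n_high=0.6)
        raise ConfigurationError(f"unknown envelope method: {method!r}")


def local_maxima(env: Envelope) -> PeakSeries:
    """All envelope samples where the gradient changes sign from + to -.

    A plateau maximum is reduced to its first sample.

    Raises
    ------
    DegenerateInputError
        If the envelope has fewer than 3 samples.
    """
    v = env.values
    if v.size < 3:
        raise DegenerateInputError("envelope must have at least 3 samples")
    sign = np.sign(np.diff(v))
    nz = np.nonzero(sign)[0]
    s = sign[nz]
    # +->- transition among consecutive nonzero gradient signs; the peak is
    # the sample right after the last rising difference.
    trans = np.nonzero((s[:-1] > 0) & (s[1:] < 0))[0]
    idx = nz[trans] + 1
    return PeakSeries(times=env.t0 + idx / env.sampling_rate, amplitudes=v[idx])


def apply_threshold(peaks: PeakSeries, env: Envelope, n: float) -> PeakSeries:
    """Keep peaks strictly above ``mean(env) * n``.

    The mean is taken over the full envelope of the current analysis segment.
    """
    if n <= 0:
        raise ConfigurationError("threshold multiplier must be > 0")
    thresh = float(np.mean(env.values)) * n
    keep = peaks.amplitudes > thresh
    return PeakSeries(times=peaks.times[keep], amplitudes=peaks.amplitudes[keep])


def enforce_separation(peaks: PeakSeries, min_separation: float = 0.150) -> PeakSeries:
    """Collapse clusters of peaks closer than ``min_separation`` seconds.

    Greedy by descending amplitude: the globally largest remaining peak is
    kept and every unresolved peak within the window around it suppressed;
    ties are broken in favor of the earlier peak. This realizes
    "global maximum within the window" without fixing an arbitrary window
    phase, and makes split sounds collapse onto their dominant component.
    The operation is idempotent.
    """
    m = len(peaks)
    if m <= 1:
        return PeakSeries(peaks.times.copy(), peaks.amplitudes.copy())
    # stable sort on (-amplitude, time): equal amplitudes resolve to earlier time
    order = np.lexsort((peaks.times, -peaks.amplitudes))
    keep = np.zeros(m, dtype=bool)
    suppressed = np.zeros(m, dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep[i] = True
        close = np.abs(peaks.times - peaks.times[i]) < min_separation
        close[i] = False
        suppressed |= close
    return PeakSeries(times=peaks.times[keep], amplitudes=peaks.amplitudes[keep])


def detect_peaks(env: Envelope, n: float, cfg: PeakConfig | None = None) -> PeakSeries:
    """Full peak detection: local maxima -> threshold ``n`` -> 150 ms separation."""
    cfg = cfg or PeakConfig()
    return enforce_separation(
        apply_threshold(local_maxima(env), env, n), cfg.min_separation
    )
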