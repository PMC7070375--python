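"""Envelope extraction from the band-passed PCG.

Two interchangeable back-ends produce the nonnegative envelope curve that all
downstream stages (peak picking, ACF timing, classification) consume:

* Hilbert transform (HT): the magnitude of the analytic signal,
  ``sqrt(x(t)^2 + H[x](t)^2)`` — appropriate for narrowband signals such as
  heart sounds and cheap to compute. Same time base as the input.
* STFT: Hamming-windowed short-time Fourier transform; the envelope is the
  per-frame maximum of the power spectral density ``|S(t, w)|^2``
  (the spectrogram). With the default 128-sample window and 96.875 % overlap
  at 4 kHz the hop is 4 samples, i.e. a 1 ms envelope time base.

Power is kept in linear units; dB scaling is for display only. The two
envelopes live on different time bases, so every downstream window is
specified in seconds and converted per envelope sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert
from scipy.signal.windows import hamming

from .exceptions import ConfigurationError, DegenerateInputError
from .signals import TimedSignal

__all__ = [
    "Envelope",
    "StftConfig",
    "Spectrogram",
    "hilbert_envelope",
    "stft",
    "stft_envelope",
]


@dataclass
class Envelope:
    """Nonnegative envelope curve on its own uniform time base."""

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    method: str = "HT"  # "HT" | "STFT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if np.any(self.values < 0):
            raise ConfigurationError("envelope values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate


@dataclass
class StftConfig:
    """STFT analysis parameters.

    ``window_len`` (b) and ``overlap`` (k, as a fraction) default to the
    optimized values 128 samples and 0.96875; the window shape is fixed to
    Hamming, the standard choice for non-stationary audio. The hop is
    ``round(b * (1 - k))`` and must be at least one sample.
    """

    window_len: int = 128
    overlap: float = 0.96875

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ConfigurationError("window_len must be >= 2 samples")
        if not 0.0 <= self.overlap < 1.0:
            raise ConfigurationError("overlap must lie in [0, 1)")
        if self.hop < 1:
            raise ConfigurationError("hop must be >= 1 sample")

    @property
    def hop(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap)))


@dataclass
class Spectrogram:
    """Power spectral density per (time frame, frequency bin)."""

    power: np.ndarray  # shape (n_frames, n_bins)
    frame_times: np.ndarray  # absolute seconds, frame centers
    bin_freqs: np.ndarray  # Hz
    frame_rate: float  # frames per second (1 / hop interval)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)


def hilbert_envelope(x: TimedSignal) -> Envelope:
    """Envelope as the magnitude of the analytic signal.

    The discrete Hilbert transform is computed over the whole segment via the
    frequency-domain analytic-signal method; segments are at most ~10 s at
    4 kHz, so no blockwise processing is needed. Edge transients are confined
    to a few tens of ms at either end.
    """
    if len(x) == 0:
        raise DegenerateInputError("empty signal")
    analytic = hilbert(x.samples)
    return Envelope(
        values=np.abs(analytic),
        sampling_rate=x.sampling_rate,
        t0=x.t0,
        method="HT",
    )


def stft(x: TimedSignal, cfg: StftConfig | None = None) -> Spectrogram:
    """Hamming-windowed STFT power (spectrogram) of ``x``.

    Frames are fully contained in the signal (incomplete edge frames are
    dropped rather than zero-padded, so no fabricated low-power frames bias
    the envelope mean) and are stamped at their window centers in absolute
    seconds.
    """
    cfg = cfg or StftConfig()
    n = len(x)
    if n < cfg.window_len:
        raise DegenerateInputError(
            f"signal ({n} samples) shorter than one STFT window ({cfg.window_len})"
        )
    win = hamming(cfg.window_len, sym=False)
    frames = sliding_window_view(x.samples, cfg.window_len)[:: cfg.hop]
    spec = np.fft.rfft(frames * win, axis=1)
    power = np.abs(spec) ** 2
    starts = np.arange(frames.shape[0]) * cfg.hop
    centers = starts + (cfg.window_len - 1) / 2.0
    return Spectrogram(
        power=power,
        frame_times=x.t0 + centers / x.sampling_rate,
        bin_freqs=np.fft.rfftfreq(cfg.window_len, 1.0 / x.sampling_rate),
        frame_rate=x.sampling_rate / cfg.hop,
    )


def stft_envelope(spec: Spectrogram) -> Envelope:
    """Envelope as the per-frame maximum of the power spectral density."""
    if spec.power.size == 0:
        raise DegenerateInputError("empty spectrogram")
    return Envelope(
        values=spec.power.max(axis=1),
        sampling_rate=spec.frame_rate,
        t0=float(spec.frame_times[0]),
        method="STFT",
    )
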