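"""Uniformly sampled waveform container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError

__all__ = ["TimedSignal"]


@dataclass
class TimedSignal:
    """A uniformly sampled real-valued signal on an absolute time axis.

    Sample ``i`` sits at time ``t0 + i / sampling_rate`` (0-based). All
    cross-channel comparisons in the package happen in absolute seconds, so a
    PCG at 4 kHz and an ECG at 500 Hz never need resampling.

    Parameters
    ----------
    samples
        Finite real samples.
    sampling_rate
        Sampling rate in Hz, > 0.
    t0
        Absolute time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigurationError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise DegenerateInputError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def shifted(self, dt: float) -> "TimedSignal":
        """Return a copy whose time axis is shifted by ``dt`` seconds."""
        return TimedSignal(self.samples.copy(), self.sampling_rate, self.t0 + dt)
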