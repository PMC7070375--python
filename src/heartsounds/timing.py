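"""Cardiac timing: heart rate, systole/diastole lengths and their tolerance bounds.

The heart rate is read off the autocorrelation function (ACF) of the PCG
envelope: the lag of the first major ACF maximum after lag 0 is the average
heart-cycle length. The average systolic length can either be taken from the
first *minor* ACF maximum (the S1-against-S2 overlap) or from an empirical
linear-in-HR formula; the empirical route is the default because it proved
the more stable of the two. A fixed ±175 ms tolerance — the ~150 ms maximal
duration of a heart sound plus a 25 ms systolic standard deviation — turns the
average systole into the [sys_min, sys_max] band the classifiers test gaps
against, and the diastole band follows by conservation of the cycle length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax

from .envelope import Envelope
from .exceptions import ConfigurationError, DegenerateInputError, EstimationFailureError

__all__ = [
    "ACF_SEARCH_WINDOW_S",
    "MIN_HEART_RATE_BPM",
    "MAX_HEART_RATE_BPM",
    "SYS_TOLERANCE_MS",
    "REGIME_THRESHOLD_BPM",
    "Acf",
    "CardiacTiming",
    "autocorrelate",
    "estimate_cycle",
    "systole_from_acf",
    "systole_empirical",
    "derive_bounds",
]

#: Length of the lag interval searched for the cycle maximum, in seconds.
#: Its reciprocal sets the lowest detectable heart rate: 60 / 1.5 = 40 bpm.
ACF_SEARCH_WINDOW_S = 1.5

#: Supported heart-rate range in beats per minute.
MIN_HEART_RATE_BPM = 60.0 / ACF_SEARCH_WINDOW_S
MAX_HEART_RATE_BPM = 200.0

#: Tolerance applied on the systolic length: maximal heart-sound duration
#: (150 ms) plus the systolic standard deviation (25 ms).
SYS_TOLERANCE_MS = 150.0 + 25.0

#: Heart rates above this are "increased" and use the amplitude classifier.
REGIME_THRESHOLD_BPM = 80.0


@dataclass
class Acf:
    """One-sided autocorrelation of an envelope.

    ``lags`` are nonnegative seconds; ``values[0]`` (zero lag) is maximal.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ConfigurationError("lags and values must have identical shape")


@dataclass
class CardiacTiming:
    """Average cardiac timing of one analysis segment, all lengths in ms."""

    heart_rate: float  # bpm
    cycle: float
    sys: float
    dia: float
    sys_min: float
    sys_max: float
    dia_min: float
    dia_max: float
    sys_method: str = "empirical"  # "empirical" | "acf"

    @property
    def regime(self) -> str:
        """"increased" above 80 bpm, "normal" otherwise (80 itself is normal)."""
        return "increased" if self.heart_rate > REGIME_THRESHOLD_BPM else "normal"


def autocorrelate(env: Envelope) -> Acf:
    """Autocorrelation of the mean-removed envelope over lags 0 .. duration/2.

    Computed via FFT (circular correlation on a zero-padded copy, which equals
    the linear autocorrelation). The envelope mean is removed first so that
    periodic structure, not the DC pedestal, dominates the lag peaks.

    Raises
    ------
    DegenerateInputError
        If the envelope is empty or has zero variance.
    """
    v = np.asarray(env.values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("empty envelope")
    x = v - v.mean()
    if not np.any(x):
        raise DegenerateInputError("constant envelope has no autocorrelation structure")
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    full = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    keep = n // 2 + 1
    lags = np.arange(keep) / env.sampling_rate
    return Acf(lags=lags, values=full[:keep])


#: Octave-error correction: a local maximum within this relative band around
#: half the candidate lag, reaching this fraction of the candidate's value,
#: is taken as the true cycle peak instead.
_HALF_LAG_BAND = (0.45, 0.55)
_HALF_LAG_FRACTION = 0.75

#: Harmonic summing: weight of the ACF value near the doubled lag in the
#: candidate score, and the relative half-width of the neighborhood searched
#: around the double (absorbs cycle-to-cycle jitter).
_HARMONIC_WEIGHT = 0.5
_HARMONIC_NEIGHBORHOOD = 0.05


def estimate_cycle(acf: Acf) -> tuple[float, float]:
    """Average heart-cycle length (ms) and heart rate (bpm) from the ACF.

    The cycle is the distance from lag 0 (the first major maximum) to the
    next major maximum inside the 1.5 s search window, which caps the
    detectable cycle at 1.5 s, i.e. a 40 bpm floor. Lags shorter than the
    cycle of the 200 bpm rate ceiling are not candidates: at very high rates
    the systole/diastole minor maxima merge into a strong peak near half the
    cycle, but they imply an impossible rate and are excluded a priori.

    Discriminating the major (full-overlap) maximum from the minor
    S1-against-S2 ones and from the two-cycle harmonic uses the standard
    guards of period estimators. Candidates are scored by harmonic summing,
    ``ACF(L) + 0.5 * max ACF near 2L``: a true cycle lag repeats at its
    double, a minor maximum does not, and the double-cycle harmonic is
    penalized because its own double is weak. As a backstop against jitter
    making the two-cycle peak win outright, the pick descends to a local
    maximum of comparable height (>= 75 % of it) near half its lag while one
    exists.

    Raises
    ------
    EstimationFailureError
        If the ACF spans less than the search window or contains no local
        maximum inside it.
    """
    if acf.lags.size < 3 or acf.lags[-1] < ACF_SEARCH_WINDOW_S:
        raise EstimationFailureError(
            f"ACF must span at least {ACF_SEARCH_WINDOW_S} s of lag"
        )
    lag_floor = 60.0 / MAX_HEART_RATE_BPM
    idx = argrelmax(acf.values)[0]
    idx = idx[(acf.lags[idx] >= lag_floor) & (acf.lags[idx] <= ACF_SEARCH_WINDOW_S)]
    if idx.size == 0:
        raise EstimationFailureError(
            "no ACF maximum within the search window (heart rate below 40 bpm?)"
        )
    n = acf.values.size
    scores = np.empty(idx.size)
    for k, i in enumerate(idx):
        lo = int(round(2 * i * (1 - _HARMONIC_NEIGHBORHOOD)))
        hi = min(int(round(2 * i * (1 + _HARMONIC_NEIGHBORHOOD))) + 1, n)
        double = acf.values[lo:hi].max() if lo < n else 0.0
        scores[k] = acf.values[i] + _HARMONIC_WEIGHT * max(double, 0.0)
    best = idx[np.argmax(scores)]
    while True:
        lo, hi = _HALF_LAG_BAND[0] * best, _HALF_LAG_BAND[1] * best
        half = idx[
            (idx >= lo) & (idx <= hi)
            & (acf.values[idx] >= _HALF_LAG_FRACTION * acf.values[best])
        ]
        if half.size == 0:
            break
        best = half[np.argmax(acf.values[half])]
    cycle_ms = acf.lags[best] * 1000.0
    return cycle_ms, 60000.0 / cycle_ms


def systole_from_acf(acf: Acf, cycle: float) -> float:
    """Average systolic length (ms) from the first minor ACF maximum.

    The minor maximum arises where the S2 bursts of the signal overlap the S1
    bursts of its lagged copy, i.e. at a lag equal to the systole. Minor
    maxima occur symmetrically before and after mid-cycle (systole and
    diastole offsets), so the search is restricted to lags strictly inside
    (0, cycle/2): the systole is the shorter phase at every supported rate.

    Falls back to :func:`systole_empirical` with a warning when no interior
    maximum exists (e.g. a one-burst-per-cycle envelope).
    """
    half = cycle / 2000.0  # s
    idx = argrelmax(acf.values)[0]
    # positive values only: the mean-removed ACF dips below zero between
    # overlaps, and numerical ripple there must not pose as a minor maximum
    idx = idx[(acf.lags[idx] > 0) & (acf.lags[idx] < half) & (acf.values[idx] > 0)]
    if idx.size == 0:
        hr = 60000.0 / cycle
        warnings.warn(
            "no minor ACF maximum before mid-cycle; falling back to the "
            "empirical systole formula",
            stacklevel=2,
        )
        return systole_empirical(hr)
    best = idx[np.argmax(acf.values[idx])]
    return acf.lags[best] * 1000.0


def systole_empirical(heart_rate: float) -> float:
    """Average systolic length in ms as a linear function of heart rate.

    Two regression branches: ``-1.14*HR + 371.55`` above 80 bpm and
    ``-6.58*HR + 766.44`` otherwise (80 bpm itself uses the latter). The
    branches disagree at the boundary (240.04 vs 280.35 ms); the strict
    reading of the condition is kept.

    Raises
    ------
    ConfigurationError
        If ``heart_rate`` is outside the supported [40, 200] bpm range.
    """
    if not MIN_HEART_RATE_BPM <= heart_rate <= MAX_HEART_RATE_BPM:
        raise ConfigurationError(
            f"heart rate {heart_rate:.1f} bpm outside supported range "
            f"[{MIN_HEART_RATE_BPM:.0f}, {MAX_HEART_RATE_BPM:.0f}]"
        )
    if heart_rate > REGIME_THRESHOLD_BPM:
        return -1.14 * heart_rate + 371.55
    return -6.58 * heart_rate + 766.44


def derive_bounds(
    heart_rate: float, sys: float, sys_method: str = "empirical"
) -> CardiacTiming:
    """Complete the timing model from heart rate (bpm) and systole (ms).

    dia = 60000/HR - sys; sys_min/max = sys -/+ 175 ms; the diastole bounds
    follow by conservation: dia_max = cycle - sys_min, dia_min = cycle -
    sys_max, so sys_min + dia_max = sys_max + dia_min = cycle exactly.

    Raises
    ------
    ConfigurationError
        If the systole is not shorter than the cycle.
    """
    cycle = 60000.0 / heart_rate
    if not sys < cycle:
        raise ConfigurationError(
            f"systole {sys:.1f} ms must be shorter than the cycle {cycle:.1f} ms"
        )
    return CardiacTiming(
        heart_rate=heart_rate,
        cycle=cycle,
        sys=sys,
        dia=cycle - sys,
        sys_min=sys - SYS_TOLERANCE_MS,
        sys_max=sys + SYS_TOLERANCE_MS,
        dia_min=cycle - (sys + SYS_TOLERANCE_MS),
        dia_max=cycle - (sys - SYS_TOLERANCE_MS),
        sys_method=sys_method,
    )
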