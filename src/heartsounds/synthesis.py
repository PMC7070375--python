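"""Synthetic PCG/ECG pairs with known ground truth.

The generator emulates the statistical structure the classification algorithm
assumes: quasi-periodic S1/S2 tone bursts in the 20-200 Hz heart-sound band,
a systole shorter than the diastole with the systolic length tied linearly to
the instantaneous heart rate, per-cycle timing jitter, optional split sounds
and S3 extra peaks, additive white noise, and an ECG whose R-peaks coincide
with the S1 onsets.

Tone bursts are Gaussian-tapered cosines: smooth, band-limited, and
narrowband — the regime in which the Hilbert envelope is a faithful amplitude
estimate. Each cycle's length is the nominal 60/HR plus zero-mean Gaussian
jitter; its systole is recomputed from the empirical formula at the
instantaneous rate, so the synthetic data stay consistent with the
classifier's timing model at every heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError
from .signals import TimedSignal
from .timing import systole_empirical

__all__ = ["SynthConfig", "GroundTruth", "generate_pcg", "generate_ecg", "inject_artifacts"]

#: S2 echoes the first sub-burst at this relative amplitude when a sound splits.
_SPLIT_REL_AMP = 0.7
#: Default S3 placement after the S2 peak, in ms (early-diastolic sound).
_S3_DELAY_MS = 150.0
#: S3 center frequency (Hz) and duration (ms): a low-pitched, short sound.
_S3_FREQ_HZ = 35.0
_S3_DURATION_MS = 60.0
#: Lead-in before the first S1 peak, seconds.
_LEAD_IN_S = 0.3


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording.

    Frequencies in Hz, durations in ms unless suffixed otherwise. S1 defaults
    to a 50 Hz, 100 ms burst and S2 to a slightly higher-pitched (70 Hz),
    shorter (80 ms) one, both inside the 20-200 Hz heart-sound band.
    ``amp_ratio_s1_s2`` is 1.0 (normal resting rates, where S1 need not
    exceed S2); increased-heart-rate scenarios should set it >= 1.8, the
    physiological regime in which S1 dominates. ``noise_sd`` and
    ``s3_amplitude`` are fractions of the S1 and S2 peak amplitude.
    """

    sampling_rate_pcg: float = 4000.0
    sampling_rate_ecg: float = 500.0
    duration: float = 60.0
    heart_rate: float = 60.0
    hr_jitter_sd: float = 20.0  # ms, per-cycle cycle-length deviation
    s1_center_freq: float = 50.0
    s2_center_freq: float = 70.0
    s1_duration: float = 100.0
    s2_duration: float = 80.0
    amp_ratio_s1_s2: float = 1.0
    amp_jitter_sd: float = 0.05  # relative, per-event amplitude deviation
    split_probability: float = 0.0
    split_gap: float = 40.0  # ms
    s3_probability: float = 0.0
    s3_amplitude: float = 0.35
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 200.0:
            raise ConfigurationError("heart_rate must lie in [40, 200] bpm")
        for name in ("sampling_rate_pcg", "sampling_rate_ecg", "duration",
                     "s1_duration", "s2_duration", "split_gap"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("split_probability", "s3_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("s1_center_freq", "s2_center_freq"):
            if not 20.0 <= getattr(self, name) <= 200.0:
                raise ConfigurationError(f"{name} must lie in the 20-200 Hz heart-sound band")
        if self.hr_jitter_sd < 0 or self.noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """True event times (seconds) and per-cycle phase lengths (ms)."""

    s1_onsets: np.ndarray
    s1_peak_times: np.ndarray
    s2_onsets: np.ndarray
    s2_peak_times: np.ndarray
    extra_event_times: np.ndarray
    r_peak_times: np.ndarray
    true_sys_lengths: np.ndarray
    true_dia_lengths: np.ndarray

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_cycles(self) -> int:
        return self.s1_peak_times.size


def _add_burst(samples: np.ndarray, fs: float, t0: float, center: float,
               freq: float, dur_s: float, amp: float) -> None:
    """Add a Gaussian-tapered cosine burst in place; taper sigma = dur/6."""
    sigma = dur_s / 6.0
    half = dur_s / 2.0
    i0 = max(0, int(np.floor((center - t0 - half) * fs)))
    i1 = min(samples.size, int(np.ceil((center - t0 + half) * fs)) + 1)
    if i1 <= i0:
        return
    t = t0 + np.arange(i0, i1) / fs
    dt = t - center
    samples[i0:i1] += amp * np.exp(-0.5 * (dt / sigma) ** 2) * np.cos(2 * np.pi * freq * dt)


def generate_pcg(config: SynthConfig) -> tuple[TimedSignal, GroundTruth]:
    """Generate a synthetic PCG and its ground truth.

    Identical seeds give bit-identical output: one seed sequence is split
    deterministically into independent sub-streams for cycle timing,
    amplitudes/artifacts and additive noise.

    Raises
    ------
    DegenerateInputError
        If ``config.duration`` is too short to contain one full cycle.
    """
    fs = config.sampling_rate_pcg
    timing_rng, artifact_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    )
    n = int(round(config.duration * fs))
    samples = np.zeros(n)

    s1_amp_nom = config.amp_ratio_s1_s2
    s2_amp_nom = 1.0
    s1_dur = config.s1_duration / 1000.0
    s2_dur = config.s2_duration / 1000.0
    nominal_cycle = 60.0 / config.heart_rate

    s1_peaks, s2_peaks, extras = [], [], []
    sys_lengths, dia_lengths = [], []

    t = _LEAD_IN_S
    while True:
        cycle = 60.0 / config.heart_rate + timing_rng.normal(0.0, config.hr_jitter_sd / 1000.0)
        cycle = max(cycle, 60.0 / 200.0)  # never faster than the supported maximum
        inst_hr = min(max(60.0 / cycle, 40.0), 200.0)
        sys_s = systole_empirical(inst_hr) / 1000.0
        s2_peak = t + sys_s
        if s2_peak + s2_dur / 2.0 > config.duration - 0.05:
            break

        s1_amp = s1_amp_nom * (1.0 + artifact_rng.normal(0.0, config.amp_jitter_sd))
        s2_amp = s2_amp_nom * (1.0 + artifact_rng.normal(0.0, config.amp_jitter_sd))
        for center, freq, dur, amp in (
            (t, config.s1_center_freq, s1_dur, s1_amp),
            (s2_peak, config.s2_center_freq, s2_dur, s2_amp),
        ):
            _add_burst(samples, fs, 0.0, center, freq, dur, amp)
            if artifact_rng.random() < config.split_probability:
                _add_burst(samples, fs, 0.0, center + config.split_gap / 1000.0,
                           freq, dur, _SPLIT_REL_AMP * amp)

        if artifact_rng.random() < config.s3_probability:
            s3_center = s2_peak + _S3_DELAY_MS / 1000.0
            if s3_center + _S3_DURATION_MS / 2000.0 < config.duration:
                _add_burst(samples, fs, 0.0, s3_center, _S3_FREQ_HZ,
                           _S3_DURATION_MS / 1000.0, config.s3_amplitude * s2_amp_nom)
                extras.append(s3_center)

        s1_peaks.append(t)
        s2_peaks.append(s2_peak)
        sys_lengths.append(sys_s * 1000.0)
        dia_lengths.append((cycle - sys_s) * 1000.0)
        t += cycle

    if not s1_peaks:
        raise DegenerateInputError(
            f"duration {config.duration} s too short for one full cycle "
            f"(~{_LEAD_IN_S + nominal_cycle:.2f} s needed)"
        )

    if config.noise_sd > 0:
        samples += noise_rng.normal(0.0, config.noise_sd * s1_amp_nom, n)

    s1_peaks = np.asarray(s1_peaks)
    s2_peaks = np.asarray(s2_peaks)
    truth = GroundTruth(
        s1_onsets=s1_peaks - s1_dur / 2.0,
        s1_peak_times=s1_peaks,
        s2_onsets=s2_peaks - s2_dur / 2.0,
        s2_peak_times=s2_peaks,
        extra_event_times=np.asarray(extras),
        r_peak_times=s1_peaks - s1_dur / 2.0,  # R-peak synchronous with S1 onset
        true_sys_lengths=np.asarray(sys_lengths),
        true_dia_lengths=np.asarray(dia_lengths),
    )
    return TimedSignal(samples, fs, 0.0), truth


def generate_ecg(truth: GroundTruth, config: SynthConfig) -> TimedSignal:
    """Synthetic single-channel ECG with an R-like spike at each R-peak time.

    Each beat is a narrow positive Gaussian R deflection flanked by small Q
    and S dips; the sample-grid maximum coincides with the true R-peak time
    within one ECG sample. An empty ground truth yields a flat signal.
    """
    fs = config.sampling_rate_ecg
    n = int(round(config.duration * fs))
    samples = np.zeros(n)
    t = np.arange(n) / fs
    for r in np.asarray(truth.r_peak_times, dtype=float):
        near = np.abs(t - r) < 0.08
        dt = t[near] - r
        samples[near] += (
            np.exp(-0.5 * (dt / 0.008) ** 2)
            - 0.12 * np.exp(-0.5 * ((dt + 0.025) / 0.006) ** 2)
            - 0.20 * np.exp(-0.5 * ((dt - 0.025) / 0.006) ** 2)
        )
    return TimedSignal(samples, fs, 0.0)


def inject_artifacts(
    pcg: TimedSignal,
    truth: GroundTruth,
    kind: str,
    config: SynthConfig | None = None,
    *,
    cycle_index: int | None = None,
    gap_ms: float = 40.0,
    delay_ms: float = _S3_DELAY_MS,
    amplitude: float = 0.35,
    sd: float = 0.0,
    seed: int = 0,
) -> tuple[TimedSignal, GroundTruth]:
    """Inject one artifact family into an existing recording.

    ``kind`` is one of ``split_s1``, ``split_s2``, ``s3``, ``white_noise``.
    Splits add a delayed sub-burst after the selected sound(s) (ground-truth
    S1/S2 times are unchanged; the envelope maximum stays on the louder first
    sub-burst). ``s3`` adds a low-pitched extra sound ``delay_ms`` after the
    selected S2(s) and records it in ``extra_event_times``. ``white_noise``
    adds Gaussian noise with standard deviation ``sd`` times the nominal S1
    amplitude. ``cycle_index=None`` applies to every cycle.

    Raises
    ------
    ConfigurationError
        If ``kind`` is not supported.
    """
    config = config or SynthConfig()
    out = pcg.samples.copy()
    fs = pcg.sampling_rate
    idx = range(truth.n_cycles) if cycle_index is None else [cycle_index]

    if kind in ("split_s1", "split_s2"):
        if kind == "split_s1":
            centers, freq, dur = truth.s1_peak_times, config.s1_center_freq, config.s1_duration
            amp = config.amp_ratio_s1_s2
        else:
            centers, freq, dur = truth.s2_peak_times, config.s2_center_freq, config.s2_duration
            amp = 1.0
        for i in idx:
            _add_burst(out, fs, pcg.t0, centers[i] + gap_ms / 1000.0,
                       freq, dur / 1000.0, _SPLIT_REL_AMP * amp)
        return TimedSignal(out, fs, pcg.t0), replace_truth(truth)

    if kind == "s3":
        extras = list(truth.extra_event_times)
        for i in idx:
            center = truth.s2_peak_times[i] + delay_ms / 1000.0
            _add_burst(out, fs, pcg.t0, center, _S3_FREQ_HZ,
                       _S3_DURATION_MS / 1000.0, amplitude)
            extras.append(center)
        return TimedSignal(out, fs, pcg.t0), replace_truth(truth, extra_event_times=np.sort(extras))

    if kind == "white_noise":
        if sd > 0:
            rng = np.random.default_rng(seed)
            out += rng.normal(0.0, sd * config.amp_ratio_s1_s2, out.size)
        return TimedSignal(out, fs, pcg.t0), replace_truth(truth)

    raise ConfigurationError(f"unknown artifact kind: {kind!r}")


def replace_truth(truth: GroundTruth, **changes: np.ndarray) -> GroundTruth:
    """Copy a GroundTruth, optionally replacing fields."""
    fields = {name: getattr(truth, name).copy() for name in truth.__dataclass_fields__}
    fields.update(changes)
    return GroundTruth(**fields)
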