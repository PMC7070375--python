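"""ECG-referenced scoring of the S1 classification.

Each reference R-peak (synchronous with the S1 onset) spawns a symmetric
tolerance window (150 ms wide by default). A classified S1 inside a
not-yet-consumed window is a true positive and consumes the window; an S1
outside every window is a false positive; an unconsumed window is a false
negative; and a detected peak not labelled S1 lying outside every window is a
true negative. Matching is one-to-one and greedy in time order, so no window
is counted twice: a duplicate S1 inside an already-consumed window is simply
ignored. From the counts the usual five event-detection metrics follow, with
0/0 reported as NaN (undefined), never as 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .classification import ClassifiedSounds
from .exceptions import ConfigurationError
from .signals import TimedSignal

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalConfig",
    "detect_r_peaks",
    "match_s1",
    "compute_metrics",
    "grid_optimize",
]

#: R-peak detector: QRS passband (Hz), refractory period (s), and the
#: fraction of the rolling maximum used as adaptive threshold.
_QRS_BAND_HZ = (5.0, 30.0)
_QRS_REFRACTORY_S = 0.250
_QRS_THRESHOLD_FRACTION = 0.3
_QRS_ROLLING_WINDOW_S = 2.0


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class Metrics:
    """The five event-detection scores; undefined ratios are NaN."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float


@dataclass
class EvalConfig:
    """Width of the tolerance window around each R-peak, seconds."""

    tolerance_window: float = 0.150

    def __post_init__(self) -> None:
        if self.tolerance_window <= 0:
            raise ConfigurationError("tolerance_window must be > 0")


def detect_r_peaks(ecg: TimedSignal) -> np.ndarray:
    """R-peak times from the reference ECG channel.

    Zero-phase band-pass to the QRS band (5-30 Hz), squaring, an adaptive
    threshold at a fraction of the rolling maximum, and a 250 ms refractory
    period. A flat signal yields an empty array with a warning.
    """
    if len(ecg) == 0 or not np.any(ecg.samples != ecg.samples[0]):
        warnings.warn("flat ECG: no R-peaks detectable", stacklevel=2)
        return np.empty(0)
    fs = ecg.sampling_rate
    sos = butter(2, _QRS_BAND_HZ, "bandpass", fs=fs, output="sos")
    sq = sosfiltfilt(sos, ecg.samples) ** 2
    roll = maximum_filter1d(sq, size=max(3, int(_QRS_ROLLING_WINDOW_S * fs)))
    height = np.maximum(_QRS_THRESHOLD_FRACTION * roll, 0.05 * sq.max())
    idx, _ = find_peaks(sq, height=height, distance=max(1, int(_QRS_REFRACTORY_S * fs)))
    return ecg.t0 + idx / fs


def match_s1(
    classified: ClassifiedSounds,
    r_times: np.ndarray,
    cfg: EvalConfig | None = None,
) -> ConfusionCounts:
    """Confusion counts of the S1 labels against reference R-peak times."""
    cfg = cfg or EvalConfig()
    half = cfg.tolerance_window / 2.0
    r = np.sort(np.asarray(r_times, dtype=float))
    consumed = np.zeros(r.size, dtype=bool)

    def window_of(t: float) -> np.ndarray:
        return np.nonzero(np.abs(r - t) <= half)[0]

    counts = ConfusionCounts()
    for e in sorted(classified.events, key=lambda e: e.time):
        inside = window_of(e.time)
        if e.label == "S1":
            free = inside[~consumed[inside]]
            if free.size:
                consumed[free[0]] = True
                counts.tp += 1
            elif inside.size == 0:
                counts.fp += 1
            # S1 inside an already-consumed window: duplicate, ignored
        else:
            if inside.size == 0:
                counts.tn += 1
    counts.fn = int((~consumed).sum())
    return counts


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy, precision and F1 from the counts."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.fp + c.tn)
    acc = _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * sens * prec / (prec + sens)
    return Metrics(sens, spec, acc, prec, f1)


def _score_corpus(recordings, cfg) -> float:
    """Mean F1 over recordings for one pipeline configuration (NaN -> 0)."""
    from .pipeline import analyze, evaluate_matches  # local import: no cycle at import time

    scores = []
    for pcg, r_times in recordings:
        result = analyze(pcg, cfg)
        counts = evaluate_matches(result, np.asarray(r_times), cfg.eval_cfg)
        f1 = compute_metrics(counts).f1
        scores.append(0.0 if np.isnan(f1) else f1)
    return float(np.mean(scores)) if scores else float("nan")


def _recording_hr(pcg: TimedSignal, cfg) -> float:
    from .pipeline import analyze

    result = analyze(pcg, cfg)
    rates = [s.timing.heart_rate for s in result.segments if s.timing is not None]
    return float(np.mean(rates)) if rates else float("nan")


def grid_optimize(
    recordings: list[tuple[TimedSignal, np.ndarray]],
    grid: dict[str, list],
    base_cfg=None,
    method: str = "HT",
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive F1-driven search over pipeline parameters.

    ``recordings`` are (PCG, reference R-peak times) pairs; ``grid`` maps
    run-configuration field names (``n_normal``, ``f_lower``, ``f_upper``,
    ``order_hp``, ``order_lp``, ``window_len``, ``overlap``, ...) to candidate
    values. Every combination is scored by the mean F1 over the corpus;
    ``n_high`` is special-cased: it only matters above 80 bpm, so it is
    optimized in a second pass restricted to the high-heart-rate recordings,
    with the other parameters held at their joint optimum.

    Returns the best parameter assignment and the full score table.

    Raises
    ------
    ConfigurationError
        If the corpus or the grid is empty.
    """
    from .pipeline import RunConfig

    if not recordings:
        raise ConfigurationError("empty corpus")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("empty grid")
    base_cfg = base_cfg or RunConfig.for_method(method)

    main_grid = {k: list(v) for k, v in grid.items() if k != "n_high"}
    rows = []
    best_params: dict = {}
    best_score = -np.inf
    names = list(main_grid)
    for combo in itertools.product(*(main_grid[k] for k in names)) if names else [()]:
        params = dict(zip(names, combo))
        score = _score_corpus(recordings, base_cfg.with_overrides(**params))
        rows.append({**params, "mean_f1": score})
        if score > best_score:
            best_score, best_params = score, params

    if "n_high" in grid:
        cfg0 = base_cfg.with_overrides(**best_params)
        high = [
            rec for rec in recordings if _recording_hr(rec[0], cfg0) > 80.0
        ]
        target = high or recordings
        best_nh, best_nh_score = None, -np.inf
        for nh in grid["n_high"]:
            score = _score_corpus(target, cfg0.with_overrides(n_high=nh))
            rows.append({**best_params, "n_high": nh, "mean_f1": score})
            if score > best_nh_score:
                best_nh_score, best_nh = score, nh
        best_params = {**best_params, "n_high": best_nh}

    return best_params, pd.DataFrame(rows)
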