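"""Orchestration: preprocessing -> envelope -> classification -> evaluation.

One :class:`RunConfig` bundles every stage's parameters with method-specific
defaults (Hilbert or STFT column of the optimization table). ``analyze`` runs
the per-segment chain on an in-memory PCG; ``run`` is the file-level driver
used by the command-line interface. Segments are processed independently —
no state crosses a segment boundary — and all event times are absolute
seconds, so results from different segments and channels compose directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hsio
from .classification import ClassifiedSounds, dispatch
from .envelope import StftConfig, hilbert_envelope, stft, stft_envelope
from .evaluation import (
    ConfusionCounts,
    EvalConfig,
    compute_metrics,
    detect_r_peaks,
    match_s1,
)
from .exceptions import ConfigurationError, HeartSoundsError
from .peaks import PeakConfig
from .preprocessing import FilterConfig, SegmentationConfig, bandpass, segment, synchronize
from .signals import TimedSignal
from .timing import CardiacTiming

__all__ = ["RunConfig", "SegmentResult", "AnalysisResult", "analyze",
           "evaluate_matches", "run"]

log = logging.getLogger("heartsounds")

#: RunConfig sub-config attribute -> flat override field names.
_FLAT_FIELDS = {
    "filter_cfg": ("f_lower", "f_upper", "order_hp", "order_lp"),
    "stft_cfg": ("window_len", "overlap"),
    "peak_cfg": ("n_normal", "n_high", "min_separation"),
    "seg_cfg": ("discard_prefix", "n_segments"),
    "eval_cfg": ("tolerance_window",),
}


@dataclass
class RunConfig:
    """Complete configuration of one analysis run."""

    method: str = "HT"  # "HT" | "STFT"
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    stft_cfg: StftConfig = field(default_factory=StftConfig)
    peak_cfg: PeakConfig = field(default_factory=PeakConfig)
    seg_cfg: SegmentationConfig = field(default_factory=SegmentationConfig)
    eval_cfg: EvalConfig = field(default_factory=EvalConfig)
    sys_method: str = "empirical"  # "empirical" | "acf"
    zero_phase: bool = False
    sync_mode: str = "none"  # "none" | "knock_artifact" | "fixed_offset"
    sync_offset: float = 0.0
    #: Overlap-save margin (s) around each segment for envelope extraction
    #: and peak detection: a heart sound cut by a segment boundary has no
    #: local envelope maximum in either half, so each segment is analysed
    #: with one maximal sound length of context and only events inside the
    #: segment proper are kept. Segment event sets stay disjoint.
    boundary_pad: float = 0.150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method.upper() not in ("HT", "STFT"):
            raise ConfigurationError(f"unknown envelope method: {self.method!r}")
        self.method = self.method.upper()

    @classmethod
    def for_method(cls, method: str, **overrides) -> "RunConfig":
        """Method-specific defaults: band 40-190 Hz and n 1.9/1.3 for the
        Hilbert route, 20-120 Hz and n 1.0/0.6 for the STFT route."""
        cfg = cls(
            method=method,
            filter_cfg=FilterConfig.for_method(method),
            peak_cfg=PeakConfig.for_method(method),
        )
        return cfg.with_overrides(**overrides) if overrides else cfg

    def with_overrides(self, **params) -> "RunConfig":
        """Copy with flat parameter overrides (e.g. ``f_lower=30, n_high=0.8``)."""
        cfg = dataclasses.replace(self)
        for key, value in params.items():
            if key in self.__dataclass_fields__:
                cfg = dataclasses.replace(cfg, **{key: value})
                continue
            for sub, names in _FLAT_FIELDS.items():
                if key in names:
                    new_sub = dataclasses.replace(getattr(cfg, sub), **{key: value})
                    cfg = dataclasses.replace(cfg, **{sub: new_sub})
                    break
            else:
                raise ConfigurationError(f"unknown configuration parameter: {key!r}")
        return cfg


@dataclass
class SegmentResult:
    """Outcome of one analysis segment."""

    index: int
    start: float
    end: float
    classified: ClassifiedSounds
    timing: CardiacTiming | None


@dataclass
class AnalysisResult:
    segments: list[SegmentResult]

    @property
    def events(self) -> list:
        return [e for s in self.segments for e in s.classified.events]

    @property
    def s1_times(self) -> np.ndarray:
        return np.asarray([e.time for e in self.events if e.label == "S1"])

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0].start, self.segments[-1].end

    def pooled(self) -> ClassifiedSounds:
        return ClassifiedSounds(sorted(self.events, key=lambda e: e.time))


def _extract_envelope(seg: TimedSignal, cfg: RunConfig):
    if cfg.method == "HT":
        return hilbert_envelope(seg)
    return stft_envelope(stft(seg, cfg.stft_cfg))


def analyze(pcg: TimedSignal, cfg: RunConfig | None = None) -> AnalysisResult:
    """Band-pass, segment and classify an in-memory PCG.

    Per-segment failures (silence, no periodicity) are logged and leave that
    segment's peaks unclassified; the run continues.
    """
    cfg = cfg or RunConfig()
    filtered = bandpass(pcg, cfg.filter_cfg, zero_phase=cfg.zero_phase)
    fs = filtered.sampling_rate
    segments = segment(filtered, cfg.seg_cfg)
    results = []
    for i, seg in enumerate(segments):
        start, end = seg.t0, seg.t0 + seg.duration
        a = max(0, int(round((start - filtered.t0 - cfg.boundary_pad) * fs)))
        b = min(len(filtered), int(round((end - filtered.t0 + cfg.boundary_pad) * fs)))
        padded = TimedSignal(filtered.samples[a:b], fs, filtered.t0 + a / fs)
        try:
            classified, timing = dispatch(
                _extract_envelope(padded, cfg), cfg.peak_cfg, cfg.sys_method
            )
        except HeartSoundsError as exc:
            log.warning("segment %d (%.2f-%.2f s) failed: %s", i, start, end, exc)
            classified, timing = ClassifiedSounds([]), None
        # keep only events inside the segment proper (the last segment keeps
        # its right endpoint), and discard events too close to the physical
        # edges of the analysed slice: a local maximum within half the peak
        # separation of an edge cannot be confirmed as a heart-sound peak
        # (its neighborhood is unobservable, and envelope edge transients
        # concentrate there). Interior boundaries are unaffected — the
        # overlap pad puts them well inside the slice.
        last = i == len(segments) - 1
        edge_margin = cfg.peak_cfg.min_separation / 2.0
        lo = padded.t0 + edge_margin
        hi = padded.t0 + padded.duration - edge_margin
        classified = ClassifiedSounds(
            [e for e in classified.events
             if (start <= e.time < end or (last and start <= e.time <= end))
             and lo <= e.time <= hi]
        )
        for e in classified.events:
            log.debug("segment %d: %.4f s amp %.4g -> %s (%s)",
                      i, e.time, e.amplitude, e.label, e.rule)
        results.append(SegmentResult(i, start, end, classified, timing))
    return AnalysisResult(results)


def evaluate_matches(
    result: AnalysisResult, r_times: np.ndarray, eval_cfg: EvalConfig | None = None
) -> ConfusionCounts:
    """Micro-averaged confusion counts for a whole recording.

    Events from all segments are pooled on the absolute time axis and matched
    against the reference R-peaks that fall inside the analyzed span
    (R-peaks in the discarded synchronization prefix are not scoreable).
    """
    start, end = result.span
    r = np.asarray(r_times, dtype=float)
    r = r[(r >= start) & (r <= end)]
    return match_s1(result.pooled(), r, eval_cfg)


def run(
    pcg_path: str | Path,
    ecg_path: str | Path | None = None,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """File-level driver: read, synchronize, analyze, score, write reports.

    Writes ``annotations.csv`` (time_s, amplitude, label, rule),
    ``timing.csv`` (per-segment cardiac timing) and, when an ECG is given,
    ``metrics.json``. Returns a summary dictionary with the same content.
    """
    cfg = cfg or RunConfig()
    pcg = hsio.read_signal(pcg_path)
    ecg = hsio.read_signal(ecg_path) if ecg_path is not None else None

    if ecg is not None and cfg.sync_mode != "none":
        pcg, ecg = synchronize(
            pcg, ecg, mode=cfg.sync_mode,
            offset=cfg.sync_offset if cfg.sync_mode == "fixed_offset" else None,
        )

    result = analyze(pcg, cfg)
    summary: dict = {
        "method": cfg.method,
        "segments": [
            {
                "index": s.index,
                "start_s": s.start,
                "end_s": s.end,
                "timing": dataclasses.asdict(s.timing) if s.timing else None,
                "counts": s.classified.counts(),
            }
            for s in result.segments
        ],
    }

    if ecg is not None:
        r_times = detect_r_peaks(ecg)
        counts = evaluate_matches(result, r_times, cfg.eval_cfg)
        metrics = compute_metrics(counts)
        summary["counts"] = dataclasses.asdict(counts)
        summary["metrics"] = dataclasses.asdict(metrics)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hsio.write_annotations(out / "annotations.csv", result.pooled())
        pd.DataFrame(
            [
                {"segment": s.index, "start_s": s.start, "end_s": s.end,
                 **(dataclasses.asdict(s.timing) if s.timing else {})}
                for s in result.segments
            ]
        ).to_csv(out / "timing.csv", index=False)
        if "metrics" in summary:
            (out / "metrics.json").write_text(
                json.dumps({"counts": summary["counts"],
                            "metrics": summary["metrics"]}, indent=2)
            )
    return summary
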