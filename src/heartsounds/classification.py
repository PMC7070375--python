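"""Rule-based S1/S2 labelling of detected envelope peaks.

Two regimes, selected by the ACF heart-rate estimate:

* Increased heart rate (> 80 bpm): systole and diastole are nearly equal, but
  S1 is reliably louder than S2, so peaks are labelled pairwise by amplitude
  (``amp_pair``): a gap shorter than sys_max whose left peak is taller makes
  an S1/S2 pair; a gap longer than sys_max marks an S1 whose S2 went
  undetected (``long_gap_s1``).

* Normal heart rate (<= 80 bpm): amplitudes are uninformative but the systole
  is clearly shorter than the diastole. Extra peaks (S3, S4, artifacts)
  inside a diastole are removed first — those that shorten the diastole below
  dia_min (``short_diastole``, ``short_diastole_missing_s2``) in one pass,
  then those sitting just before an S1 whose preceding diastole still looks
  valid (``pre_s1_extra``, ``pre_s1_extra_missing_s2``) in a second pass —
  and the surviving gaps, now true systoles and diastoles, label their
  endpoint peaks (``pairing``). A peak flanked by two gaps longer than
  sys_max is an S1 with two consecutive S2 undetected (``double_missing_s2``).

Inter-peak distances are recomputed after every removal; conditions that
index before the first or past the last gap evaluate false, so boundary
peaks can only be labelled by pairing or the missing-S2 rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .envelope import Envelope
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    EstimationFailureError,
)
from .peaks import PeakConfig, PeakSeries, detect_peaks
from .timing import (
    CardiacTiming,
    autocorrelate,
    derive_bounds,
    estimate_cycle,
    systole_empirical,
    systole_from_acf,
)

__all__ = [
    "SoundEvent",
    "ClassifiedSounds",
    "classify_increased",
    "remove_extra_peaks",
    "classify_normal",
    "dispatch",
]

LABELS = ("S1", "S2", "removed", "unclassified")
RULES = (
    "amp_pair",                  # short gap + taller left peak -> S1/S2 pair
    "long_gap_s1",               # gap > sys_max -> left peak S1, its S2 missing
    "short_diastole",            # extra peak shrinks the diastole below dia_min
    "short_diastole_missing_s2", # same, with the following S2 undetected
    "pre_s1_extra",              # extra peak just before S1, diastole still valid
    "pre_s1_extra_missing_s2",   # same, with one S2 undetected
    "double_missing_s2",         # both neighboring gaps > sys_max -> S1
    "pairing",                   # gap inside systole/diastole bounds labels ends
)


@dataclass
class SoundEvent:
    """One detected peak with its label and the rule that produced it."""

    time: float
    amplitude: float
    label: str = "unclassified"
    rule: str | None = None


@dataclass
class ClassifiedSounds:
    """Time-ordered labelled events of one analysis segment."""

    events: list[SoundEvent]

    def times(self, label: str) -> np.ndarray:
        return np.asarray([e.time for e in self.events if e.label == label])

    @property
    def s1_times(self) -> np.ndarray:
        return self.times("S1")

    @property
    def s2_times(self) -> np.ndarray:
        return self.times("S2")

    def counts(self) -> dict[str, int]:
        out = {label: 0 for label in LABELS}
        for e in self.events:
            out[e.label] += 1
        return out


def _bounds_s(timing: CardiacTiming) -> tuple[float, float, float, float]:
    """(sys_min, sys_max, dia_min, dia_max) in seconds."""
    return (
        timing.sys_min / 1000.0,
        timing.sys_max / 1000.0,
        timing.dia_min / 1000.0,
        timing.dia_max / 1000.0,
    )


def classify_increased(peaks: PeakSeries, timing: CardiacTiming) -> ClassifiedSounds:
    """Amplitude-based pairwise labelling for increased heart rates.

    Scans left to right: a gap shorter than sys_max whose left peak is taller
    than its right consumes both peaks as an S1/S2 pair; a gap longer than
    sys_max labels its left peak S1 (the S2 was not detected). A trailing
    peak is S1 when its preceding gap exceeds sys_max or completes a valid
    diastole after a labelled S2; anything else stays unclassified.
    """
    _, sys_max, dia_min, dia_max = _bounds_s(timing)
    n = len(peaks)
    events = [SoundEvent(t, a) for t, a in zip(peaks.times, peaks.amplitudes)]
    if n < 2:
        warnings.warn("fewer than 2 peaks: nothing to classify", stacklevel=2)
        return ClassifiedSounds(events)

    t, y = peaks.times, peaks.amplitudes
    i = 0
    while i < n - 1:
        dx = t[i + 1] - t[i]
        if dx < sys_max and y[i] > y[i + 1]:
            events[i].label, events[i].rule = "S1", "amp_pair"
            events[i + 1].label, events[i + 1].rule = "S2", "amp_pair"
            i += 2
        elif dx > sys_max:
            events[i].label, events[i].rule = "S1", "long_gap_s1"
            i += 1
        else:
            i += 1
    last = events[-1]
    if last.label == "unclassified":
        prev_gap = t[-1] - t[-2]
        if prev_gap > sys_max:
            last.label, last.rule = "S1", "long_gap_s1"
        elif dia_min < prev_gap < dia_max and events[-2].label == "S2":
            # completes the diastole after a full S1/S2 pair
            last.label, last.rule = "S1", "pairing"
    return ClassifiedSounds(events)


def remove_extra_peaks(
    peaks: PeakSeries, timing: CardiacTiming
) -> tuple[PeakSeries, list[SoundEvent]]:
    """Drop extra peaks that corrupt the diastole, for normal heart rates.

    Pass 1 removes peaks that make a diastole too short: the right peak of a
    gap below dia_min is dropped when the gap is preceded by a valid systole
    and followed (two gaps on) by another valid systole (``short_diastole``),
    or when a valid diastole + systole precede it with no systole following
    — the S2 after the extra peak went undetected
    (``short_diastole_missing_s2``).

    Pass 2 removes extra peaks lying just before an S1, which leave the
    preceding diastole valid: the right peak of a valid-diastole gap is
    dropped when valid systoles flank the pattern two gaps on
    (``pre_s1_extra``) or, with one S2 undetected, three gaps on
    (``pre_s1_extra_missing_s2``).

    Gaps are recomputed after every removal. At most one extra peak per
    diastole is resolved; denser clutter is left for the classifier to mark
    unclassified.
    """
    sys_min, sys_max, dia_min, dia_max = _bounds_s(timing)

    def vsys(d: float) -> bool:
        return sys_min < d < sys_max

    def vdia(d: float) -> bool:
        return dia_min < d < dia_max

    t = list(peaks.times)
    y = list(peaks.amplitudes)
    removed: list[SoundEvent] = []

    def drop(gap_idx: int, rule: str) -> None:
        j = gap_idx + 1  # right peak of the gap
        removed.append(SoundEvent(t[j], y[j], "removed", rule))
        del t[j], y[j]

    # pass 1: invalid (too short) diastoles. When an extra peak sits late in
    # the diastole, the gap from it to the next S1 can itself masquerade as a
    # valid systole and make a genuine S1->S2 gap satisfy the condition too;
    # resolving the most violating (shortest) gap first removes the extra
    # peak and dissolves the spurious context before it can do damage.
    while True:
        g = np.diff(t)
        candidates: list[tuple[float, int, str]] = []
        for i in range(g.size):
            if (
                i - 1 >= 0
                and i + 2 < g.size
                and vsys(g[i - 1])
                and g[i] < dia_min
                and vsys(g[i + 2])
                # removing the peak must restore a valid diastole — that is
                # the rule's purpose, and the guard keeps it from eating a
                # genuine S2 whose systole gap merely undercuts dia_min
                and vdia(g[i] + g[i + 1])
            ):
                candidates.append((g[i], i, "short_diastole"))
            elif (
                i - 2 >= 0
                and vdia(g[i - 2])
                and vsys(g[i - 1])
                and g[i] < dia_min
                and not (i + 2 < g.size and vsys(g[i + 2]))
            ):
                candidates.append((g[i], i, "short_diastole_missing_s2"))
        if not candidates:
            break
        _, i, rule = min(candidates)
        drop(i, rule)

    # pass 2: extra peaks shortly before an S1 (diastole still valid)
    i = 0
    while i < len(t) - 1:
        g = np.diff(t)
        rule = None
        # the defining feature of the scenario is that the extra peak sits
        # too close to the following S1: the gap from it onward must fall
        # short of sys_min. Without this guard the conditions also fire on
        # extra-free sequences (after a diastole, the gap three on is always
        # a valid systole) and on ordinary missing-S2 long gaps.
        if (
            i - 1 >= 0
            and vsys(g[i - 1])
            and vdia(g[i])
            and i + 1 < g.size
            and g[i + 1] < sys_min
        ):
            if i + 2 < g.size and vsys(g[i + 2]):
                rule = "pre_s1_extra"
            elif (
                i + 3 < g.size
                and not vsys(g[i + 2])
                and vsys(g[i + 3])
            ):
                rule = "pre_s1_extra_missing_s2"
        if rule:
            drop(i, rule)
        else:
            i += 1

    return PeakSeries(np.asarray(t), np.asarray(y)), removed


def classify_normal(peaks: PeakSeries, timing: CardiacTiming) -> ClassifiedSounds:
    """Gap-based labelling for normal heart rates (after extra-peak removal).

    A peak flanked by two gaps above sys_max is an S1 with both neighboring
    S2 undetected. Remaining gaps are then paired left to right: a gap within
    the systole bounds labels left S1 / right S2; one within the diastole
    bounds labels left S2 / right S1. Earlier labels win conflicts; a gap in
    the (possible) systole/diastole band overlap counts as a systole, the
    more stable of the two. Leftover peaks stay unclassified.
    """
    sys_min, sys_max, dia_min, dia_max = _bounds_s(timing)
    n = len(peaks)
    events = [SoundEvent(t, a) for t, a in zip(peaks.times, peaks.amplitudes)]
    if n == 0:
        return ClassifiedSounds(events)
    g = peaks.deltas

    for j in range(1, n - 1):
        if g[j - 1] > sys_max and g[j] > sys_max:
            events[j].label, events[j].rule = "S1", "double_missing_s2"

    def set_label(j: int, label: str) -> None:
        if events[j].label == "unclassified":
            events[j].label, events[j].rule = label, "pairing"

    for i in range(n - 1):
        if sys_min < g[i] < sys_max:
            # two consecutive systole-band gaps cannot both be real; when
            # the next gap is also one and is followed by a valid diastole,
            # the next gap is the true systole (the shared peak is its S1)
            # and this gap — typically a leading extra sound against the
            # first S1 — must not label anything.
            if (
                i + 2 < n - 1
                and sys_min < g[i + 1] < sys_max
                and dia_min < g[i + 2] < dia_max
            ):
                continue
            set_label(i, "S1")
            set_label(i + 1, "S2")
        elif dia_min < g[i] < dia_max:
            set_label(i, "S2")
            set_label(i + 1, "S1")
    return ClassifiedSounds(events)


def dispatch(
    env: Envelope,
    peak_cfg: PeakConfig | None = None,
    sys_method: str = "empirical",
) -> tuple[ClassifiedSounds, CardiacTiming | None]:
    """Full per-segment pipeline from envelope to labelled heart sounds.

    ACF -> heart rate -> regime -> threshold multiplier -> peak detection ->
    timing bounds (empirical or ACF systole) -> regime classifier. On an
    estimation failure (silent or aperiodic segment, rate outside 40-200 bpm)
    a warning is issued and every detectable peak is returned unclassified.
    """
    peak_cfg = peak_cfg or PeakConfig()
    if sys_method not in ("empirical", "acf"):
        raise ConfigurationError(f"unknown sys_method: {sys_method!r}")
    try:
        acf = autocorrelate(env)
        cycle, hr = estimate_cycle(acf)
        sys_ms = (
            systole_from_acf(acf, cycle)
            if sys_method == "acf"
            else systole_empirical(hr)
        )
        timing = derive_bounds(hr, sys_ms, sys_method)
    except (DegenerateInputError, EstimationFailureError, ConfigurationError) as exc:
        warnings.warn(f"cardiac timing estimation failed: {exc}", stacklevel=2)
        try:
            peaks = detect_peaks(env, peak_cfg.n_normal, peak_cfg)
        except DegenerateInputError:
            peaks = PeakSeries(np.empty(0), np.empty(0))
        return (
            ClassifiedSounds(
                [SoundEvent(t, a) for t, a in zip(peaks.times, peaks.amplitudes)]
            ),
            None,
        )

    n = peak_cfg.n_high if timing.regime == "increased" else peak_cfg.n_normal
    peaks = detect_peaks(env, n, peak_cfg)

    if timing.regime == "increased":
        classified = classify_increased(peaks, timing)
    else:
        kept, removed = remove_extra_peaks(peaks, timing)
        classified = classify_normal(kept, timing)
        classified = ClassifiedSounds(
            sorted(classified.events + removed, key=lambda e: e.time)
        )
    return classified, timing
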