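"""Shared fixtures: synthetic recordings and pipeline helpers."""

import numpy as np
import pytest

from heartsounds import (
    RunConfig,
    SynthConfig,
    analyze,
    compute_metrics,
    evaluate_matches,
    generate_pcg,
)


def make_recording(hr=60.0, duration=30.0, seed=1, **kwargs):
    """Synthetic PCG + truth; S1 dominates S2 above 80 bpm as physiology has it."""
    kwargs.setdefault("amp_ratio_s1_s2", 1.8 if hr > 80 else 1.0)
    cfg = SynthConfig(duration=duration, heart_rate=hr, seed=seed, **kwargs)
    return generate_pcg(cfg), cfg


def end_to_end_f1(pcg, truth, method="HT", **overrides):
    """F1 of the full pipeline against the ground-truth R-peak train."""
    overrides.setdefault("discard_prefix", 0.0)
    rc = RunConfig.for_method(method, **overrides)
    result = analyze(pcg, rc)
    counts = evaluate_matches(result, truth.r_peak_times, rc.eval_cfg)
    return compute_metrics(counts).f1, result


@pytest.fixture(scope="session")
def hr60_recording():
    (pcg, truth), cfg = make_recording(hr=60.0, seed=1)
    return pcg, truth, cfg


@pytest.fixture(scope="session")
def hr110_recording():
    (pcg, truth), cfg = make_recording(hr=110.0, seed=1)
    return pcg, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
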