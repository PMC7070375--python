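"""Readers and writers: WAV and CSV signals, annotations, YAML configs.

Signals travel as WAV (PCG, any integer or float encoding) or as two-column
CSV with a ``time_s,value`` header (either channel). Annotation CSVs carry
one labelled event per row. The YAML configuration file holds flat
parameter overrides applied on top of the method defaults; command-line
flags take precedence over the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .classification import ClassifiedSounds
from .exceptions import ConfigurationError
from .signals import TimedSignal
from .synthesis import GroundTruth

__all__ = [
    "read_wav", "write_wav", "read_csv_signal", "write_csv_signal",
    "read_signal", "write_annotations", "write_truth", "read_truth",
    "load_config_overrides",
]

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): 2**7}


def read_wav(path: str | Path) -> TimedSignal:
    """Read a single-channel WAV; integer encodings are scaled to [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype in _INT_SCALE:
        offset = 128 if data.dtype == np.dtype("uint8") else 0
        data = (data.astype(float) - offset) / _INT_SCALE[data.dtype]
    return TimedSignal(np.asarray(data, dtype=float), float(fs))


def write_wav(path: str | Path, sig: TimedSignal) -> None:
    """Write as 32-bit float WAV (t0 is not representable and is dropped)."""
    wavfile.write(path, int(round(sig.sampling_rate)), sig.samples.astype(np.float32))


def read_csv_signal(path: str | Path) -> TimedSignal:
    """Read a ``time_s,value`` CSV; the rate is inferred from the time column."""
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ConfigurationError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ConfigurationError(f"{path}: time column is not uniformly sampled")
    return TimedSignal(df["value"].to_numpy(dtype=float), 1.0 / float(dt.mean()), float(t[0]))


def write_csv_signal(path: str | Path, sig: TimedSignal) -> None:
    pd.DataFrame({"time_s": sig.times, "value": sig.samples}).to_csv(path, index=False)


def read_signal(path: str | Path) -> TimedSignal:
    """Dispatch on extension: .wav -> WAV reader, anything else -> CSV."""
    path = Path(path)
    return read_wav(path) if path.suffix.lower() == ".wav" else read_csv_signal(path)


def write_annotations(path: str | Path, classified: ClassifiedSounds) -> None:
    pd.DataFrame(
        [
            {"time_s": e.time, "amplitude": e.amplitude,
             "label": e.label, "rule": e.rule or ""}
            for e in classified.events
        ],
        columns=["time_s", "amplitude", "label", "rule"],
    ).to_csv(path, index=False)


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    """Ground-truth annotation CSV: event_type, onset_s, peak_s."""
    rows = []
    for onset, peak in zip(truth.s1_onsets, truth.s1_peak_times):
        rows.append({"event_type": "S1", "onset_s": onset, "peak_s": peak})
    for onset, peak in zip(truth.s2_onsets, truth.s2_peak_times):
        rows.append({"event_type": "S2", "onset_s": onset, "peak_s": peak})
    for t in truth.extra_event_times:
        rows.append({"event_type": "extra", "onset_s": t, "peak_s": t})
    for t in truth.r_peak_times:
        rows.append({"event_type": "R", "onset_s": t, "peak_s": t})
    pd.DataFrame(rows, columns=["event_type", "onset_s", "peak_s"]).sort_values(
        ["onset_s", "event_type"]
    ).to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config_overrides(path: str | Path) -> dict:
    """Flat parameter overrides from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of parameter overrides")
    return data
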