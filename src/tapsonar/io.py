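"""Readers and writers for baseband records, ground truth and reports.

Baseband I/Q goes to 2-channel WAV (channel 0 = I, channel 1 = Q; 16-bit
PCM or float32) or to CSV with header ``time,i,q``.  Ground truth and
analysis reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import TapScenario
from .types import BasebandSignal

_PCM16_SCALE = 32768.0


def write_signal(signal: BasebandSignal, path: str | Path, fmt: str | None = None,
                 subtype: str = "float32") -> None:
    """Write a baseband record to 2-channel WAV or to ``time,i,q`` CSV.

    ``fmt`` is inferred from the suffix when omitted.  WAV subtype is
    ``"float32"`` (lossless for unit-scale signals) or ``"pcm16"``
    (16-bit quantization, the acquisition precision of the hardware).
    """
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "wav")
    if fmt == "wav":
        iq = np.column_stack([signal.samples.real, signal.samples.imag])
        if subtype == "pcm16":
            scaled = np.clip(np.round(iq * _PCM16_SCALE), -32768, 32767).astype(np.int16)
            wavfile.write(path, int(round(signal.sample_rate)), scaled)
        elif subtype == "float32":
            wavfile.write(path, int(round(signal.sample_rate)), iq.astype(np.float32))
        else:
            raise ValueError(f"unknown WAV subtype {subtype!r}")
    elif fmt == "csv":
        df = pd.DataFrame({"time": signal.times(),
                           "i": signal.samples.real, "q": signal.samples.imag})
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_signal(path: str | Path, fmt: str | None = None) -> BasebandSignal:
    """Read a 2-channel (I, Q) WAV or a ``time,i,q`` CSV baseband record.

    16-bit PCM samples are rescaled to [-1, 1).  A CSV must have a
    uniform, strictly increasing timebase; shuffled or irregular rows are
    rejected rather than silently re-sorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "wav")
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError("expected a 2-channel (I, Q) WAV file")
        if data.dtype == np.int16:
            data = data.astype(np.float64) / _PCM16_SCALE
        elif data.dtype == np.int32:
            data = data.astype(np.float64) / 2147483648.0
        else:
            data = data.astype(np.float64)
        return BasebandSignal(data[:, 0] + 1j * data[:, 1], float(rate))
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"time", "i", "q"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV is missing columns: {sorted(missing)}")
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("CSV must contain at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("CSV timebase is not strictly increasing (shuffled rows?)")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("CSV timebase is not uniform")
        fs = 1.0 / dt[0]
        return BasebandSignal(df["i"].to_numpy(float) + 1j * df["q"].to_numpy(float),
                              fs, start_time=float(t[0]))
    raise ValueError(f"unknown format {fmt!r}")


def write_truth(scenario: TapScenario, path: str | Path) -> None:
    """Ground-truth sidecar JSON: tap times, displacements, parameters, seed."""
    payload = {
        "scenario": scenario.name,
        "seed": scenario.seed,
        "tap_times_s": [round(float(x), 9) for x in scenario.true_tap_times],
        "displacements_m": [round(float(x), 9) for x in scenario.true_displacements],
        "rates_hz": [round(float(x), 9) for x in scenario.true_rates],
        "params": scenario.params,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
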