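"""Signal and model file I/O.

Signals travel as two-column delimited text (time_s, value) or 16-bit PCM
WAV at a declared sampling rate; feature matrices as delimited text with a
header of canonical feature names; models, normalization constants and
coefficient tables as JSON (dyadic coefficients round-trip bit-exactly as
{"target", "m", "k"} triples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocessing import SignalStream

__all__ = [
    "write_signal_text", "read_signal_text", "write_wav", "read_wav",
    "write_features", "read_features", "save_json", "load_json",
]


def write_signal_text(path: str | Path, sig: SignalStream) -> None:
    t = np.arange(len(sig.samples)) / sig.fs
    np.savetxt(path, np.column_stack([t, sig.samples]),
               fmt=("%.6f", "%d" if np.issubdtype(sig.samples.dtype, np.integer) else "%.6f"),
               delimiter="\t", header="time_s\tvalue", comments="")


def read_signal_text(path: str | Path, fs: int | None = None) -> SignalStream:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    if fs is None:
        dt = np.median(np.diff(t))
        fs = int(round(1.0 / dt))
    if np.allclose(v, np.rint(v)):
        v = np.rint(v).astype(np.int64)
    return SignalStream(v, fs)


def write_wav(path: str | Path, sig: SignalStream) -> None:
    v = np.asarray(sig.samples)
    if not np.issubdtype(v.dtype, np.integer):
        v = np.rint(v).astype(np.int64)
    if v.max(initial=0) > 32767 or v.min(initial=0) < -32768:
        raise ValueError("samples exceed the 16-bit PCM range")
    wavfile.write(path, sig.fs, v.astype(np.int16))


def read_wav(path: str | Path) -> SignalStream:
    fs, v = wavfile.read(path)
    return SignalStream(v.astype(np.int64), int(fs))


def write_features(path: str | Path, X: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(np.asarray(X), columns=names).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(), list(df.columns)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_default) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _default(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    raise TypeError(f"not JSON-serializable: {type(v)}")
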