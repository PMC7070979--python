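"""Digital pre-processing chain for the insulated-EMG carrier.

The raw signal (10 kHz, ADC counts) is decimated by averaging to 2 kHz,
power-line interference is removed with a comb filter (zeros at 50 Hz and
harmonics), and a first-order lowpass (531 Hz) limits the band. The feature
path additionally runs a second-order highpass (60 Hz). A rectify-and-smooth
stage produces the envelope that ultimately drives the prosthesis, and a
delay line re-aligns that envelope with the (later) classifier decision.

Filters are designed by bilinear transform with pre-warping at the cutoff
and run in floating point; the comb and the envelope smoother are integer
recursions and are exact. Fixed-point variants of the recursive filters
(dyadic coefficients, 64-bit intermediates) are exposed for parity checks
with an embedded implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .fixed_point import FxCoeff, fx_scale, quantize_coeff

__all__ = [
    "SignalStream",
    "downsample_average",
    "comb_filter",
    "lowpass1",
    "highpass2",
    "rectify_smooth",
    "envelope_coeff",
    "delay_line",
    "analog_frontend_sim",
    "feature_path",
    "IirStream",
]

_VALID_FS = (10_000, 2_000, 250, 40)


@dataclass
class SignalStream:
    """A finite sampled signal with its sampling rate.

    ``samples`` holds ADC-scale values: integers on the fixed-point path,
    floats on the filtered reference path.
    """

    samples: np.ndarray
    fs: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs not in _VALID_FS:
            raise ValueError(f"fs must be one of {_VALID_FS}, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples.astype(float))):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)


def downsample_average(x: SignalStream, factor: int = 5) -> SignalStream:
    """Decimate by averaging ``factor`` consecutive samples.

    Integer inputs use floor division (integer mean); floats use the exact
    mean. A trailing remainder shorter than ``factor`` is dropped.
    """
    n = len(x.samples) // factor
    blocks = x.samples[: n * factor].reshape(n, factor)
    if np.issubdtype(x.samples.dtype, np.integer):
        out = blocks.sum(axis=1, dtype=np.int64) // factor
    else:
        out = blocks.mean(axis=1)
    return SignalStream(out, x.fs // factor)


def comb_filter(x: SignalStream, f0: int = 50) -> SignalStream:
    """FIR comb ``y_i = x_i - x_{i-fs/f0}`` with zeros at 0, f0, 2*f0, ... Hz.

    History before the first sample is taken as zero, so the first ``fs/f0``
    outputs equal the inputs.
    """
    if x.fs % f0 != 0:
        raise ValueError(f"fs={x.fs} not divisible by comb frequency {f0}")
    lag = x.fs // f0
    y = x.samples.astype(np.int64 if np.issubdtype(x.samples.dtype, np.integer) else float).copy()
    y[lag:] -= x.samples[:-lag]
    return SignalStream(y, x.fs)


def _bilinear_lowpass1(fc: float, fs: int) -> tuple[np.ndarray, np.ndarray]:
    return sps.butter(1, fc, btype="low", fs=fs)


def lowpass1(x: SignalStream, fc: float = 531.0) -> SignalStream:
    """First-order recursive lowpass, -3 dB at ``fc`` (bilinear design)."""
    b, a = _bilinear_lowpass1(fc, x.fs)
    return SignalStream(sps.lfilter(b, a, x.samples.astype(float)), x.fs)


def highpass2(x: SignalStream, fc: float = 60.0) -> SignalStream:
    """Second-order recursive highpass, -3 dB at ``fc``; zero DC gain."""
    b, a = sps.butter(2, fc, btype="high", fs=x.fs)
    return SignalStream(sps.lfilter(b, a, x.samples.astype(float)), x.fs)


def envelope_coeff(fs: int = 2000, t_target_s: float = 0.051, k_max: int = 8) -> FxCoeff:
    """Dyadic EMA coefficient whose time constant is closest to ``t_target_s``.

    The smoother follows the same accumulate-and-scale recursion as the
    features, ``env_i = (env_{i-1} + |x_i|) * b``, whose effective time
    constant is ``T = b / ((1 - b) * fs)``. The search is over the dyadic
    grid ``m / 2**k_max`` and minimizes the time-constant error, not the
    coefficient error.
    """
    best = None
    for m in range(1, 1 << k_max):
        b = m / (1 << k_max)
        err = abs(b / ((1.0 - b) * fs) - t_target_s)
        if best is None or err < best[0]:
            best = (err, m)
    assert best is not None
    return quantize_coeff(best[1] / (1 << k_max), k_max=k_max)


def rectify_smooth(x: SignalStream, b: FxCoeff | None = None) -> SignalStream:
    """Rectified, EMA-smoothed envelope on the integer feature scale.

    ``env_i = fx_scale(env_{i-1} + |x_i|, b)``; with the default coefficient
    the smoothing time constant is ~51 ms at 2 kHz. Note the recursion has
    DC gain ``b / (1 - b)``, i.e. the envelope sits well above the sample
    amplitude — the same scale convention the features use.
    """
    if b is None:
        b = envelope_coeff(x.fs)
    xs = np.rint(np.abs(x.samples)).astype(np.int64)
    env = np.empty(len(xs), dtype=np.int64)
    acc = 0
    m, k = b.m, b.k
    for i in range(len(xs)):
        acc = ((acc + int(xs[i])) * m) >> k
        env[i] = acc
    return SignalStream(env, x.fs)


def delay_line(x: SignalStream, delay_ms: float) -> SignalStream:
    """Shift the signal right by ``round(delay_ms * fs / 1000)`` samples."""
    d = int(round(delay_ms * x.fs / 1000.0))
    if d == 0:
        return SignalStream(x.samples.copy(), x.fs)
    pad = np.zeros(d, dtype=x.samples.dtype)
    return SignalStream(np.concatenate([pad, x.samples[:-d]]), x.fs)


def analog_frontend_sim(x: SignalStream, f_low: float = 11.0, f_high: float = 1064.0) -> SignalStream:
    """Emulation of the sensor's first-order analog bandpass (11–1064 Hz).

    Applied to synthetic raw signals only, so that what reaches the digital
    chain has the same band shape as the capacitively coupled sensor output.
    """
    bh, ah = sps.butter(1, f_low, btype="high", fs=x.fs)
    bl, al = sps.butter(1, f_high, btype="low", fs=x.fs)
    y = sps.lfilter(bl, al, sps.lfilter(bh, ah, x.samples.astype(float)))
    return SignalStream(y, x.fs)


def feature_path(x2k: SignalStream, fc_low: float = 531.0, fc_high: float = 60.0) -> SignalStream:
    """Comb → lowpass → highpass chain feeding the feature bank, rounded to
    integer counts (the features are integer state machines)."""
    y = comb_filter(x2k)
    y = lowpass1(SignalStream(y.samples.astype(float), y.fs), fc_low)
    y = highpass2(y, fc_high)
    return SignalStream(np.rint(y.samples).astype(np.int64), y.fs)


@dataclass
class IirStream:
    """Sample-wise IIR runner with persistent state; chunked execution is
    bit-identical to one-shot :func:`scipy.signal.lfilter` on the whole
    signal."""

    b: np.ndarray
    a: np.ndarray
    zi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.zi = np.zeros(max(len(self.b), len(self.a)) - 1)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        y, self.zi = sps.lfilter(self.b, self.a, np.asarray(chunk, dtype=float), zi=self.zi)
        return y


def lowpass1_fixed(x: SignalStream, fc: float = 531.0, k: int = 14) -> SignalStream:
    """Integer realization of :func:`lowpass1` with coefficients quantized to
    ``1/2**k`` and 64-bit intermediates; for embedded-parity checks on short
    segments (pure-Python loop)."""
    b, a = _bilinear_lowpass1(fc, x.fs)
    cb = [quantize_coeff(abs(v), k_max=16) for v in b]
    ca1 = quantize_coeff(abs(a[1]), k_max=16)
    sgn_a1 = -1 if a[1] < 0 else 1
    xs = np.rint(x.samples).astype(np.int64)
    y = np.empty(len(xs), dtype=np.int64)
    xprev = 0
    yprev = 0
    for i in range(len(xs)):
        acc = fx_scale(int(xs[i]), cb[0]) + fx_scale(xprev, cb[1])
        acc -= sgn_a1 * fx_scale(yprev, ca1)
        y[i] = acc
        xprev = int(xs[i])
        yprev = acc
    return SignalStream(y, x.fs)
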