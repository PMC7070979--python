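"""Seeded generator of labeled contraction and artifact signals.

The study's single-subject forearm recordings (musculus extensor digitorum,
insulated capacitive sensing) are not publicly available, so this module
synthesizes raw 10 kHz signals with the statistical structure the pipeline
is built for:

* **Contractions** — zero-mean Gaussian noise band-limited to 60–500 Hz
  (the dominant surface-EMG band) under a trapezoidal activation envelope.
  Subtypes: ``strong`` (reference amplitude), ``weak`` (~0.3x), and
  ``short`` — a random train of brief bursts (each <= 0.4 s, the
  co-contraction command pattern) with a low-frequency bump at each burst's
  onset and offset emulating the muscle-tissue movement artifact that
  overlays short contractions.
* **Artifacts** — ``liftoff`` (large smooth 0.5–5 Hz excursion, 3–10x the
  contraction RMS, with brief broadband "snaps" at the moments the sensor
  detaches), ``shock`` (exponentially damped oscillation bursts with sharp
  onsets), ``vibration`` (5–12 Hz narrowband tone with a weak second
  harmonic). Real artifacts bleed into the EMG band — that overlap is what
  defeats pure filtering — but their in-band energy is the spectral tail of
  an impulsive mechanical event (sharp edges, clicks), not a stationary
  EMG-like hiss; roughly half of the artifacts additionally carry a small
  stationary broadband component.

Amplitudes are on an integer ADC-count scale calibrated so that a strong
contraction has RMS ~300 counts; on that scale the feature constants
(hysteresis 242, Willison threshold 44, variance bound 4000, ...) are
meaningful. A 0.5 %-RMS white noise floor (~1.5 counts) is always present so
that small-signal window removal has something to remove while staying
below every event threshold. All randomness descends from one master seed
via per-segment child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocessing import SignalStream

__all__ = [
    "SegmentSpec",
    "GeneratorConfig",
    "gen_contraction",
    "gen_artifact",
    "gen_segment",
    "gen_corpus",
]

CONTRACTION_SUBTYPES = ("strong", "weak", "short")
ARTIFACT_SUBTYPES = ("liftoff", "shock", "vibration")


@dataclass(frozen=True)
class SegmentSpec:
    """One generated segment: class, subtype, duration and its own seed."""

    cls: int  # 1 = contraction, 0 = artifact
    subtype: str
    duration_s: float
    amplitude: float
    seed: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.cls == 1 and self.subtype not in CONTRACTION_SUBTYPES:
            raise ValueError(f"bad contraction subtype {self.subtype}")
        if self.cls == 0 and self.subtype not in ARTIFACT_SUBTYPES:
            raise ValueError(f"bad artifact subtype {self.subtype}")


@dataclass
class GeneratorConfig:
    """Corpus-level knobs; the defaults are the study conditions."""

    fs_raw: int = 10_000
    strong_rms: float = 300.0         # ADC counts; calibrates the whole scale
    weak_scale: float = 0.3
    band: tuple[float, float] = (60.0, 500.0)
    rise_fall_s: tuple[float, float] = (0.05, 0.15)
    noise_floor: float = 0.005         # fraction of strong RMS, always-on
    budget_contraction_s: float = 381.0
    budget_artifact_s: float = 489.0
    seed: int = 0
    subtype_weights_contraction: tuple[float, float, float] = (0.4, 0.3, 0.3)
    subtype_weights_artifact: tuple[float, float, float] = field(
        default=(0.4, 0.3, 0.3))


def _bandnoise(rng: np.random.Generator, n: int, fs: int, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n + fs)  # pad one second to flush the filter
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = sps.sosfilt(sos, x)[fs:]
    r = np.sqrt(np.mean(y**2))
    return y / r if r > 0 else y


def _trapezoid(n: int, fs: int, rise_s: float, fall_s: float) -> np.ndarray:
    env = np.ones(n)
    nr = min(int(rise_s * fs), n // 2)
    nf = min(int(fall_s * fs), n - nr)
    if nr > 0:
        env[:nr] = np.linspace(0.0, 1.0, nr, endpoint=False)
    if nf > 0:
        env[n - nf:] = np.linspace(1.0, 0.0, nf)
    return env


def gen_contraction(spec: SegmentSpec, config: GeneratorConfig | None = None) -> SignalStream:
    """Band-limited EMG burst under a trapezoidal envelope, at 10 kHz."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(spec.seed)
    fs = cfg.fs_raw
    n = int(round(spec.duration_s * fs))
    rms = cfg.strong_rms * spec.amplitude
    if spec.subtype == "short":
        # a train of brief bursts (each <= 0.4 s) separated by short gaps,
        # each burst flanked by a tissue-movement bump at ~30 % of the
        # envelope peak (the band noise peaks at ~3x its RMS)
        env = np.zeros(n)
        bump = np.zeros(n)
        t = np.arange(n) / fs
        i = int(rng.uniform(0.0, 0.1) * fs)
        while i < n:
            blen = int(rng.uniform(0.15, 0.4) * fs)
            b0, b1 = i, min(i + blen, n)
            env[b0:b1] = _trapezoid(b1 - b0, fs, 0.03, 0.03)
            bw = max(int(0.06 * fs), 1)
            for edge in (b0, b1):
                lo, hi = max(edge - bw, 0), min(edge + bw, n)
                bump[lo:hi] = np.hanning(2 * bw)[: hi - lo]
            i = b1 + int(rng.uniform(0.05, 0.1) * fs)
        f_b = rng.uniform(2.0, 10.0)
        x = _bandnoise(rng, n, fs, *cfg.band) * rms * env
        x = x + 0.9 * rms * np.sin(2 * np.pi * f_b * t) * bump
    else:
        rise = rng.uniform(*cfg.rise_fall_s)
        fall = rng.uniform(*cfg.rise_fall_s)
        env = _trapezoid(n, fs, rise, fall)
        x = _bandnoise(rng, n, fs, *cfg.band) * rms * env
    x = x + cfg.noise_floor * cfg.strong_rms * rng.standard_normal(n)
    return SignalStream(np.rint(x).astype(np.int64), fs)


def gen_artifact(spec: SegmentSpec, config: GeneratorConfig | None = None) -> SignalStream:
    """One motion-artifact segment at 10 kHz; shape depends on the subtype."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(spec.seed)
    fs = cfg.fs_raw
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rms = cfg.strong_rms
    amp = spec.amplitude * rms
    if spec.subtype == "liftoff":
        f0 = rng.uniform(0.5, 5.0)
        scale = rng.uniform(3.0, 10.0)
        phase = rng.uniform(0, 2 * np.pi)
        x = scale * amp * np.sin(2 * np.pi * f0 * t + phase) * _trapezoid(n, fs, 0.1, 0.1)
        # detach snaps: very brief broadband spikes when the sensor lets go
        for _ in range(rng.integers(1, 4)):
            i0 = int(rng.integers(0, max(n - fs // 50, 1)))
            tau = rng.uniform(0.002, 0.005)
            dur = min(int(6 * tau * fs), n - i0)
            x[i0:i0 + dur] += (rng.uniform(2.0, 5.0) * amp * rng.choice((-1.0, 1.0))
                               * np.exp(-np.arange(dur) / (tau * fs)))
    elif spec.subtype == "shock":
        x = np.zeros(n)
        n_bursts = max(1, int(spec.duration_s / 0.5))
        for _ in range(n_bursts):
            i0 = rng.integers(0, max(n - fs // 10, 1))
            tau = rng.uniform(0.02, 0.06)
            f0 = rng.uniform(5.0, 25.0)
            dur = min(int(5 * tau * fs), n - i0)
            tt = np.arange(dur) / fs
            x[i0:i0 + dur] += rng.uniform(4.0, 8.0) * amp * np.exp(-tt / tau) * np.sin(2 * np.pi * f0 * tt)
    else:  # vibration
        f0 = rng.uniform(5.0, 12.0)
        x = np.zeros(n)
        for h, g in ((1, 1.0), (2, 0.2)):
            x += g * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        x *= 2.0 * amp * _trapezoid(n, fs, 0.1, 0.1)
    # about half of the artifacts carry a small stationary broadband
    # component inside the EMG band on top of the event's own spectral tail
    if rng.random() < 0.5:
        x = x + rng.uniform(0.03, 0.1) * rms * _bandnoise(rng, n, fs, *cfg.band)
    x = x + cfg.noise_floor * rms * rng.standard_normal(n)
    return SignalStream(np.rint(x).astype(np.int64), fs)


def gen_segment(spec: SegmentSpec, config: GeneratorConfig | None = None) -> SignalStream:
    return (gen_contraction if spec.cls == 1 else gen_artifact)(spec, config)


def gen_corpus(config: GeneratorConfig | None = None) -> list[tuple[SignalStream, SegmentSpec]]:
    """Draw segments until both per-class duration budgets are met.

    Returns ``(signal, spec)`` pairs; per-sample labels are implied by the
    spec (generator ground truth). Reproducible from ``config.seed`` alone.
    """
    cfg = config or GeneratorConfig()
    master = np.random.default_rng(cfg.seed)
    out: list[tuple[SignalStream, SegmentSpec]] = []

    def draw(cls: int, budget_s: float) -> None:
        total = 0.0
        subtypes = CONTRACTION_SUBTYPES if cls == 1 else ARTIFACT_SUBTYPES
        weights = (cfg.subtype_weights_contraction if cls == 1
                   else cfg.subtype_weights_artifact)
        while total < budget_s:
            sub = subtypes[master.choice(3, p=np.asarray(weights) / np.sum(weights))]
            dur = float(master.uniform(1.5, 4.0))
            amp = 1.0
            if cls == 1:
                amp = cfg.weak_scale if sub == "weak" else 1.0
                if sub == "short":
                    amp = float(master.uniform(0.6, 1.0))
            seed = int(master.integers(0, 2**31 - 1))
            spec = SegmentSpec(cls=cls, subtype=sub, duration_s=dur, amplitude=amp, seed=seed)
            out.append((gen_segment(spec, cfg), spec))
            total += dur

    draw(1, cfg.budget_contraction_s)
    draw(0, cfg.budget_artifact_s)
    return out
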