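"""From labeled raw segments to classifier-ready feature matrices.

Order of operations (mirroring how the study data were prepared):

1. each raw 10 kHz segment passes the analog-front-end emulation and is
   decimated by averaging to 2 kHz;
2. segments are chopped into windows (1 s, or 0.5–1.5 s varied for the
   recurrent models so periodicity cannot be learned);
3. windows whose smoothed rectified envelope never reaches the activation
   threshold are removed — they would not drive the prosthesis either way;
4. contraction and artifact windows are strictly alternated so that every
   window boundary is a class transition and sluggish features get punished;
5. the feature bank runs over the *concatenated* window stream (state flows
   across boundaries, as it would online), features are decimated to 40 Hz
   (250 Hz for the recurrent models);
6. near-duplicate features (|Pearson r| > 0.9 on training data) are pruned,
   keeping the earlier feature in canonical order;
7. min-max normalization to [-1, +1] is fitted on training data only
   (test-range values extrapolate — there is no clip);
8. the 70/15/15 split assigns contiguous runs of windows, never single
   samples, so adjacent-sample correlation cannot leak across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureBank
from .preprocessing import (SignalStream, analog_frontend_sim,
                            downsample_average, envelope_coeff, feature_path,
                            rectify_smooth)
from .synthetic import SegmentSpec

__all__ = [
    "LabeledWindow",
    "DatasetSplit",
    "NormalizationSpec",
    "FeatureDataset",
    "assemble_alternating",
    "windows_from_segments",
    "remove_small_signal",
    "default_activation_threshold",
    "correlation_prune",
    "minmax_fit",
    "minmax_apply",
    "downsample_features",
    "stratified_contiguous_split",
    "featurize_windows",
]


@dataclass
class LabeledWindow:
    """A 2 kHz signal window with its class and subtype label."""

    samples: np.ndarray  # int64 counts @ 2 kHz
    cls: int             # 1 contraction, 0 artifact
    subtype: str
    duration_s: float


def windows_from_segments(
    segments: list[tuple[SignalStream, SegmentSpec]],
    window_s: float = 1.0,
    vary: bool = False,
    seed: int = 0,
    frontend: bool = True,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Decimate segments to 2 kHz and chop them into labeled windows.

    Returns (contraction_windows, artifact_windows), each in corpus order.
    With ``vary`` the window length is drawn uniformly from 0.5–1.5 s per
    window. Trailing samples shorter than the next window are dropped.
    """
    rng = np.random.default_rng(seed)
    pools: tuple[list[LabeledWindow], list[LabeledWindow]] = ([], [])
    for sig, spec in segments:
        s = analog_frontend_sim(sig) if frontend else sig
        s2 = downsample_average(SignalStream(np.rint(s.samples).astype(np.int64), s.fs))
        x = s2.samples
        i = 0
        while True:
            w = float(rng.uniform(0.5, 1.5)) if vary else window_s
            n = int(round(w * s2.fs))
            if i + n > len(x):
                break
            pools[spec.cls].append(
                LabeledWindow(x[i:i + n], spec.cls, spec.subtype, n / s2.fs))
            i += n
    return pools[1], pools[0]


def assemble_alternating(
    segments: list[tuple[SignalStream, SegmentSpec]],
    window_s: float = 1.0,
    vary: bool = False,
    seed: int = 0,
    activation_threshold: float | None = None,
) -> list[LabeledWindow]:
    """Full window assembly: chop, drop small-signal windows, alternate.

    The output sequence is strictly C, A, C, A, ... (truncated when one
    class runs out), so every boundary is a class transition.
    """
    contr, artf = windows_from_segments(segments, window_s, vary, seed)
    if activation_threshold is not None:
        contr = remove_small_signal(contr, activation_threshold)
        artf = remove_small_signal(artf, activation_threshold)
    out: list[LabeledWindow] = []
    for c, a in zip(contr, artf):
        out.append(c)
        out.append(a)
    return out


def default_activation_threshold(
    noise_rms: float = 1.5, fs: int = 2000, factor: float = 3.0
) -> float:
    """Activation threshold as ``factor`` times the envelope the always-on
    noise floor produces (mean rectified Gaussian times the smoother's DC
    gain)."""
    b = envelope_coeff(fs)
    gain = b.value / (1.0 - b.value)
    return factor * noise_rms * np.sqrt(2.0 / np.pi) * gain


def remove_small_signal(
    windows: list[LabeledWindow], activation_threshold: float | None = None
) -> list[LabeledWindow]:
    """Drop windows whose envelope never exceeds the activation threshold."""
    thr = activation_threshold if activation_threshold is not None else default_activation_threshold()
    kept = []
    for w in windows:
        env = rectify_smooth(SignalStream(w.samples, 2000))
        if env.samples.max(initial=0) > thr:
            kept.append(w)
    return kept


def correlation_prune(
    X: np.ndarray, threshold: float = 0.9, keep: str = "later"
) -> list[int]:
    """Drop one member of every feature pair with ``|Pearson r| > threshold``.

    The greedy scan runs in reverse canonical order, so of a correlated
    pair the *later* variant survives: within each family the specialized
    (saturated, hysteresis-tuned) variants come after their plain parents,
    and those are the ones built for fast class transitions. ``keep =
    "earlier"`` flips the scan to the plain variants. Zero-variance columns
    carry no information (and cannot be normalized) and are always dropped.
    """
    Xf = np.asarray(X, dtype=float)
    n_col = Xf.shape[1]
    std = Xf.std(axis=0)
    order = range(n_col - 1, -1, -1) if keep == "later" else range(n_col)
    retained: list[int] = []
    for j in order:
        if std[j] == 0:
            continue
        ok = True
        for i in retained:
            r = np.corrcoef(Xf[:, i], Xf[:, j])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(j)
    return sorted(retained)


@dataclass
class NormalizationSpec:
    """Per-feature training min/max mapping onto [-1, +1] (±1024 quantized)."""

    featmin: np.ndarray
    featmax: np.ndarray
    ymin: float = -1.0
    ymax: float = 1.0

    def to_dict(self) -> dict:
        return {
            "featmin": self.featmin.tolist(),
            "featmax": self.featmax.tolist(),
            "ymin": self.ymin,
            "ymax": self.ymax,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(np.asarray(d["featmin"], float), np.asarray(d["featmax"], float),
                   d.get("ymin", -1.0), d.get("ymax", 1.0))


def minmax_fit(train_features: np.ndarray) -> NormalizationSpec:
    X = np.asarray(train_features, dtype=float)
    fmin = X.min(axis=0)
    fmax = X.max(axis=0)
    if np.any(fmax <= fmin):
        bad = np.nonzero(fmax <= fmin)[0]
        raise ValueError(f"degenerate feature range in columns {bad.tolist()}; prune first")
    return NormalizationSpec(fmin, fmax)


def minmax_apply(spec: NormalizationSpec, X: np.ndarray, quantized: bool = False) -> np.ndarray:
    """Linear map of the training range onto [ymin, ymax]; out-of-range
    values extrapolate. ``quantized`` returns integers on the 1024 = 1.0
    scale, saturated at the signed 16-bit range."""
    Xf = np.asarray(X, dtype=float)
    y = (spec.ymax - spec.ymin) * (Xf - spec.featmin) / (spec.featmax - spec.featmin) + spec.ymin
    if quantized:
        q = np.rint(y * 1024.0)
        return np.clip(q, -(2**15), 2**15 - 1).astype(np.int64)
    return y


def downsample_features(F: np.ndarray, source_hz: int = 2000, target_hz: int = 40) -> np.ndarray:
    """Plain decimation (every n-th row from row 0); the EMA smoothing of
    every feature has already band-limited the stream."""
    if source_hz % target_hz != 0:
        raise ValueError(f"{source_hz} Hz not divisible by {target_hz} Hz")
    return F[:: source_hz // target_hz]


@dataclass
class DatasetSplit:
    """Window-index partitions; each partition is a union of contiguous runs."""

    train: list[int]
    val: list[int]
    test: list[int]
    subtype_of: list[str] = field(default_factory=list)

    def partitions(self) -> dict[str, list[int]]:
        return {"train": self.train, "val": self.val, "test": self.test}


def stratified_contiguous_split(
    windows: list[LabeledWindow],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    chunk: int | None = None,
) -> DatasetSplit:
    """Assign contiguous chunks of windows to train/val/test.

    Chunks (runs of ``chunk`` consecutive windows; by default sized so that
    there are at least ~15 assignable chunks) are shuffled and greedily
    assigned to whichever partition is furthest below its target share for
    the subtypes the chunk contains. Because windows alternate classes,
    every chunk carries both classes, and subtype proportions stay close to
    the corpus proportions in every partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(windows)
    if chunk is None:
        chunk = max(2, min(10, n // 15))
    rng = np.random.default_rng(seed)
    chunks = [list(range(i, min(i + chunk, n))) for i in range(0, n, chunk)]
    order = rng.permutation(len(chunks))
    keys = sorted({(w.cls, w.subtype) for w in windows})
    key_of = [(w.cls, w.subtype) for w in windows]
    totals = {k: sum(1 for kk in key_of if kk == k) for k in keys}
    counts = {p: dict.fromkeys(keys, 0) for p in range(3)}
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for ci in order:
        idxs = chunks[ci]
        # deficit of each partition w.r.t. its target share of this chunk's keys
        best_p, best_score = 0, -np.inf
        for p in range(3):
            score = 0.0
            for i in idxs:
                k = key_of[i]
                target = fractions[p] * totals[k]
                score += target - counts[p][k]
            if score > best_score:
                best_p, best_score = p, score
        parts[best_p].extend(idxs)
        for i in idxs:
            counts[best_p][key_of[i]] += 1
    return DatasetSplit(
        train=sorted(parts[0]), val=sorted(parts[1]), test=sorted(parts[2]),
        subtype_of=[w.subtype for w in windows],
    )


@dataclass
class FeatureDataset:
    """Feature samples with labels and window bookkeeping at one rate."""

    X: np.ndarray            # (n_samples, n_features) fixed-point values
    y: np.ndarray            # (n_samples,) 0/1 targets
    window_id: np.ndarray    # (n_samples,) index into the window sequence
    subtype: np.ndarray      # (n_samples,) subtype strings
    names: list[str]
    rate_hz: int

    def select_windows(self, window_ids: list[int]) -> "FeatureDataset":
        mask = np.isin(self.window_id, window_ids)
        return FeatureDataset(self.X[mask], self.y[mask], self.window_id[mask],
                              self.subtype[mask], self.names, self.rate_hz)


def featurize_windows(
    windows: list[LabeledWindow],
    bank: FeatureBank | None = None,
    rate_hz: int = 40,
    mode: str = "int",
) -> FeatureDataset:
    """Run the feature bank over the concatenated window stream.

    Feature state is continuous across window boundaries (as it is online);
    labels and window ids are carried per 2 kHz sample and then decimated
    with the features.
    """
    bank = bank or FeatureBank()
    x = np.concatenate([w.samples for w in windows])
    y = np.concatenate([np.full(len(w.samples), w.cls, dtype=np.int64) for w in windows])
    wid = np.concatenate([np.full(len(w.samples), i, dtype=np.int64)
                          for i, w in enumerate(windows)])
    sub = np.concatenate([np.full(len(w.samples), w.subtype, dtype=object) for w in windows])
    xf = feature_path(SignalStream(x, 2000))
    F = bank.run(xf.samples, mode=mode)
    step = 2000 // rate_hz
    return FeatureDataset(
        X=F[::step], y=y[::step], window_id=wid[::step], subtype=sub[::step],
        names=list(bank.names), rate_hz=rate_hz,
    )
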