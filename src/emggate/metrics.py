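"""Transition-tolerant evaluation of decision streams.

The alternating-window corpora put a class transition at every window
boundary, and every feature needs a finite settling time, so plain
per-sample accuracy would mostly measure transition sharpness. Instead,
samples inside a fixed window *after* each ground-truth transition (100 ms
during training, 150 ms on test data — matching the output signal delay)
are excluded from the count; everything later is scored. A slow model
therefore still pays for its lag, but only beyond the tolerated settling
window. Contraction is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixed_point import FxCoeff

__all__ = [
    "EvalReport",
    "transition_mask",
    "tolerant_accuracy",
    "accuracy_from_confusion",
    "ema_time_constant",
]


@dataclass
class EvalReport:
    """Confusion matrix and tolerant accuracy for one decision stream."""

    tp: int
    fn: int
    fp: int
    tn: int
    excluded: int
    per_subtype: dict = field(default_factory=dict)

    @property
    def n_test_samples(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return accuracy_from_confusion(self.tp, self.fn, self.fp, self.tn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "n_test_samples": self.n_test_samples, "excluded": self.excluded,
            "accuracy": self.accuracy, "per_subtype": self.per_subtype,
        }


def transition_mask(target: np.ndarray, tol_ms: float, rate_hz: float) -> np.ndarray:
    """Boolean mask of samples that count; ``False`` within
    ``round(tol_ms * rate / 1000)`` steps *after* each target transition."""
    t = np.asarray(target)
    k = int(round(tol_ms * rate_hz / 1000.0))
    mask = np.ones(len(t), dtype=bool)
    trans = np.nonzero(np.diff(t) != 0)[0] + 1
    for i in trans:
        mask[i:i + k] = False
    return mask


def tolerant_accuracy(
    pred: np.ndarray,
    target: np.ndarray,
    tol_ms: float = 150.0,
    rate_hz: float = 40.0,
    subtype: np.ndarray | None = None,
) -> EvalReport:
    """Score a decision stream against the target with transition tolerance."""
    pred = np.asarray(pred).astype(int)
    target = np.asarray(target).astype(int)
    if pred.shape != target.shape:
        raise ValueError("pred and target lengths differ")
    mask = transition_mask(target, tol_ms, rate_hz)
    p, t = pred[mask], target[mask]
    tp = int(np.sum((p == 1) & (t == 1)))
    fn = int(np.sum((p == 0) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    per_subtype: dict = {}
    if subtype is not None:
        sub = np.asarray(subtype)[mask]
        for s in np.unique(sub):
            m = sub == s
            per_subtype[str(s)] = float(100.0 * np.mean(p[m] == t[m]))
    return EvalReport(tp=tp, fn=fn, fp=fp, tn=tn,
                      excluded=int(len(pred) - mask.sum()), per_subtype=per_subtype)


def accuracy_from_confusion(tp: int, fn: int, fp: int, tn: int) -> float:
    """Percent accuracy, rounded half-up to two decimals."""
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    import decimal
    acc = decimal.Decimal(100 * (tp + tn)) / decimal.Decimal(n)
    return float(acc.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def ema_time_constant(b: FxCoeff | float, fs: float = 2000.0) -> float:
    """Effective time constant (ms) of the accumulate-and-scale smoother.

    ``feat_i = (feat_{i-1} + f_i) * b`` decays by ``b`` per sample, so
    ``T = b / ((1 - b) * fs)``, reported in milliseconds with the exact
    dyadic coefficient value.
    """
    bv = b.value if isinstance(b, FxCoeff) else float(b)
    if not 0 <= bv < 1:
        raise ValueError("EMA coefficient must be in [0, 1)")
    return 1000.0 * bv / ((1.0 - bv) * fs)
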