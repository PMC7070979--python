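"""The four shallow classifier families and their fixed-point quantization.

All models map a (possibly normalized) feature vector to a binary decision
(1 = contraction, 0 = artifact):

* **logreg** — L1 (lasso) feature selection, then L2 (ridge) logistic
  regression; decision ``sigmoid(w.x + b) > 0.5``.
* **tree** — greedy binary CART on Gini impurity with a cap on the number
  of splits; consumes *raw* (un-normalized) features.
* **nn** — one hidden layer, ``satlins`` activation (clamp to [-1, 1]),
  ``purelin`` (identity) output thresholded at 0.5.
* **rnn** — the same network with one recurrent hidden-to-hidden path at
  delay 1, trained by backpropagation through time on 250 Hz sequences.

The networks minimize a cross-entropy surrogate (logistic loss on the
centered purelin output, which keeps the decision threshold at 0.5) with a
full-batch Adam optimizer and the classical early-stopping rule: at most
``max_epochs`` epochs and at most 6 consecutive validation failures, after
which the best-validation weights are restored.

Quantization multiplies every real parameter by 1024 and rounds; the
quantized forward pass is pure integer arithmetic with the satlins clamp at
±1024 and the decision threshold at 512. Tree thresholds are rounded on
the raw integer feature scale, so tree quantization is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .metrics import tolerant_accuracy

__all__ = [
    "ModelConfig",
    "ModelSpec",
    "QuantizedModelSpec",
    "lasso_select",
    "train_logreg",
    "train_tree",
    "sbs_select",
    "train_nn",
    "train_rnn",
    "predict",
    "predict_quantized",
    "quantize_model",
    "cv_train",
    "contiguous_folds",
    "satlins",
]

FAMILIES = ("logreg", "tree", "nn", "rnn")
Q = 1024  # fixed-point unit: 1024 == 1.0


@dataclass
class ModelConfig:
    """Hyperparameter grids and training constants for one family."""

    family: str = "tree"
    n_features: int = 3
    hidden_units: int = 3
    max_splits_grid: tuple[int, ...] = (2, 4, 8, 16, 32)
    n_lambda: int = 30
    max_epochs_nn: int = 1000
    max_epochs_rnn: int = 100
    max_val_failures: int = 6
    cv_folds: int = 5
    tolerance_train_ms: float = 100.0
    tolerance_test_ms: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class ModelSpec:
    """A trained classifier in floating point, family-tagged.

    ``params`` holds, per family: logreg ``w`` (n_feat,), ``b``; tree
    ``nodes`` — list of ``[feature, threshold, left, right, leaf_class]``
    rows where ``feature == -1`` marks a leaf; nn ``W1`` (n_feat, H),
    ``b1`` (H,), ``W2`` (H,), ``b2``; rnn additionally ``Wr`` (H, H).
    """

    family: str
    feature_names: list[str]
    params: dict
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        return {
            "schema": 1,
            "family": self.family,
            "feature_names": self.feature_names,
            "params": {k: conv(v) for k, v in self.params.items()},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        params = {k: (np.asarray(v) if isinstance(v, list) else v)
                  for k, v in d["params"].items()}
        return cls(d["family"], list(d["feature_names"]), params, d.get("meta", {}))


@dataclass
class QuantizedModelSpec:
    """The same model with integer parameters on the 1024 = 1.0 scale."""

    family: str
    feature_names: list[str]
    params: dict
    threshold: int = Q // 2

    def to_dict(self) -> dict:
        def conv(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        return {"schema": 1, "family": self.family,
                "feature_names": self.feature_names,
                "params": {k: conv(v) for k, v in self.params.items()},
                "threshold": self.threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "QuantizedModelSpec":
        params = {k: (np.asarray(v) if isinstance(v, list) else v)
                  for k, v in d["params"].items()}
        return cls(d["family"], list(d["feature_names"]), params,
                   d.get("threshold", Q // 2))


def satlins(x: np.ndarray) -> np.ndarray:
    """Symmetric saturating linear activation: clamp(x, -1, 1)."""
    return np.clip(x, -1.0, 1.0)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training targets contain a single class")


# ---------------------------------------------------------------- selection

def lasso_select(X: np.ndarray, y: np.ndarray, n_keep: int,
                 n_lambda: int = 30, seed: int = 0) -> list[int]:
    """L1-penalized logistic path over ``n_lambda`` penalties, from dense to
    all-zero; returns the support whose size is nearest ``n_keep`` (trimmed
    to the largest-magnitude coefficients if it overshoots)."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if n_keep >= X.shape[1]:
        return list(range(X.shape[1]))
    Cs = np.logspace(-4, 2, n_lambda)
    best: tuple[int, np.ndarray] | None = None
    for C in Cs:
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 random_state=seed, max_iter=2000)
        clf.fit(X, y)
        coef = clf.coef_.ravel()
        supp = np.nonzero(coef != 0)[0]
        if best is None or abs(len(supp) - n_keep) < abs(len(best[0]) - n_keep):
            best = (supp, coef)
        if len(supp) == n_keep:
            break
    assert best is not None
    supp, coef = best
    if len(supp) > n_keep:
        order = np.argsort(-np.abs(coef[supp]))
        supp = supp[order[:n_keep]]
    elif len(supp) < n_keep:
        # pad from a dense ridge-like fit
        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(X, y)
        rest = [j for j in np.argsort(-np.abs(clf.coef_.ravel())) if j not in set(supp)]
        supp = np.concatenate([supp, rest[: n_keep - len(supp)]]).astype(int)
    return sorted(int(j) for j in supp)


def sbs_select(X: np.ndarray, y: np.ndarray, scorer: Callable[[np.ndarray, np.ndarray, list[int]], float],
               n_keep: int) -> list[int]:
    """Sequential backward selection: repeatedly drop the feature whose
    removal maximizes ``scorer(X, y, kept_indices)`` until ``n_keep`` remain."""
    kept = list(range(np.asarray(X).shape[1]))
    while len(kept) > n_keep:
        best_j, best_score = None, -np.inf
        for j in kept:
            trial = [k for k in kept if k != j]
            s = scorer(X, y, trial)
            if s > best_score:
                best_j, best_score = j, s
        kept.remove(best_j)
    return kept


# ----------------------------------------------------------------- training

def train_logreg(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                 lambdas: np.ndarray | None = None, cv: int = 5,
                 seed: int = 0) -> ModelSpec:
    """Ridge (L2) logistic regression; penalty chosen by k-fold accuracy on
    contiguous sample blocks."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    Cs = 1.0 / lambdas if lambdas is not None else np.logspace(-3, 3, 13)
    blocks = np.array_split(np.arange(len(y)), cv)
    best_C, best_acc = Cs[0], -1.0
    for C in Cs:
        accs = []
        for b in blocks:
            tr = np.setdiff1d(np.arange(len(y)), b)
            if len(np.unique(y[tr])) < 2 or len(b) == 0:
                continue
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[b], y[b]))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best_C, best_acc = C, acc
    clf = LogisticRegression(C=best_C, max_iter=2000)
    clf.fit(X, y)
    return ModelSpec("logreg", list(feature_names),
                     {"w": clf.coef_.ravel(), "b": float(clf.intercept_[0])},
                     {"C": float(best_C), "cv_accuracy": best_acc})


def _tree_to_nodes(tree) -> np.ndarray:
    """Flatten an sklearn tree into [feature, threshold, left, right, leaf_class]."""
    t = tree.tree_
    nodes = []
    for i in range(t.node_count):
        if t.children_left[i] == -1:
            cls = int(np.argmax(t.value[i][0]))
            nodes.append([-1, 0.0, -1, -1, cls])
        else:
            nodes.append([int(t.feature[i]), float(t.threshold[i]),
                          int(t.children_left[i]), int(t.children_right[i]), -1])
    return np.asarray(nodes, dtype=object)


def train_tree(X: np.ndarray, y: np.ndarray, feature_names: list[str],
               max_splits_grid: tuple[int, ...] = (2, 4, 8, 16, 32),
               cv: int = 5, seed: int = 0) -> ModelSpec:
    """Greedy Gini CART with the split count capped; the cap is chosen by
    k-fold accuracy on contiguous sample blocks."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    blocks = np.array_split(np.arange(len(y)), cv)
    best_m, best_acc = max_splits_grid[0], -1.0
    for m in max_splits_grid:
        accs = []
        for b in blocks:
            tr = np.setdiff1d(np.arange(len(y)), b)
            if len(np.unique(y[tr])) < 2 or len(b) == 0:
                continue
            clf = DecisionTreeClassifier(criterion="gini", max_leaf_nodes=m + 1,
                                         random_state=seed)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[b], y[b]))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best_m, best_acc = m, acc
    clf = DecisionTreeClassifier(criterion="gini", max_leaf_nodes=best_m + 1,
                                 random_state=seed)
    clf.fit(X, y)
    return ModelSpec("tree", list(feature_names),
                     {"nodes": _tree_to_nodes(clf)},
                     {"max_splits": int(best_m), "cv_accuracy": best_acc,
                      "n_splits": int(sum(1 for n in _tree_to_nodes(clf) if n[0] != -1))})


def _surrogate_loss_grad(out: np.ndarray, t: np.ndarray, k: float = 4.0):
    """Logistic (cross-entropy) loss on the centered purelin output.

    ``p = sigmoid(k * (out - 0.5))`` keeps the decision boundary exactly at
    ``out = 0.5`` while giving a smooth, everywhere-informative gradient.
    Returns (mean loss, dL/dout).
    """
    z = k * (out - 0.5)
    # stable log(1 + e^z)
    loss = np.mean(np.logaddexp(0.0, z) - t * z)
    p = 1.0 / (1.0 + np.exp(-z))
    grad = k * (p - t) / len(t)
    return float(loss), grad


class _Adam:
    def __init__(self, shapes, lr=0.02):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + eps))
        return out


def _satlins_grad(pre: np.ndarray) -> np.ndarray:
    """Training derivative of satlins with a small leak outside the linear
    region; a hard zero would permanently silence any unit whose
    pre-activation leaves [-1, 1] (the forward pass keeps the exact clamp)."""
    return np.where(np.abs(pre) < 1.0, 1.0, 0.05)


def _nn_forward(X, W1, b1, W2, b2):
    pre = X @ W1 + b1
    h = satlins(pre)
    return h @ W2 + b2, pre, h


def train_nn(X: np.ndarray, y: np.ndarray, feature_names: list[str],
             hidden_units: int = 3, X_val: np.ndarray | None = None,
             y_val: np.ndarray | None = None, max_epochs: int = 1000,
             max_val_failures: int = 6, seed: int = 0, lr: float = 0.02) -> ModelSpec:
    """One-hidden-layer satlins/purelin network with early stopping."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_two_classes(y)
    if X_val is None:
        n_val = max(len(y) // 7, 1)
        X, X_val = X[:-n_val], X[-n_val:]
        y, y_val = y[:-n_val], y[-n_val:]
    rng = np.random.default_rng(seed)
    H, F = hidden_units, X.shape[1]
    # pre-activations must reach the satlins knees at init, or the network
    # starts (and can stay) purely linear
    W1 = rng.normal(0, 2.0 / np.sqrt(F), (F, H))
    b1 = rng.normal(0, 0.5, H)
    W2 = rng.normal(0, 1.0 / np.sqrt(H), H)
    b2 = np.array(0.5)
    opt = _Adam([(F, H), (H,), (H,), ()], lr=lr)
    best = (np.inf, [W1, b1, W2, b2], 0)
    failures = 0
    for epoch in range(max_epochs):
        # several optimizer steps per epoch-equivalent: one first-order
        # full-batch step is much smaller than one epoch of a second-order
        # optimizer, and the validation rule assumes epoch-scale progress
        for _ in range(5):
            out, pre, h = _nn_forward(X, W1, b1, W2, b2)
            _, dout = _surrogate_loss_grad(out, y)
            gW2 = h.T @ dout
            gb2 = np.sum(dout)
            dh = np.outer(dout, W2) * _satlins_grad(pre)
            gW1 = X.T @ dh
            gb1 = dh.sum(axis=0)
            W1, b1, W2, b2 = opt.step([W1, b1, W2, b2], [gW1, gb1, gW2, np.asarray(gb2)])
        vout, _, _ = _nn_forward(np.asarray(X_val, float), W1, b1, W2, b2)
        vloss, _ = _surrogate_loss_grad(vout, np.asarray(y_val, float))
        if vloss < best[0] - 1e-9:
            best = (vloss, [W1.copy(), b1.copy(), W2.copy(), np.array(b2)], epoch)
            failures = 0
        else:
            failures += 1
            if failures > max_val_failures:
                break
    W1, b1, W2, b2 = best[1]
    return ModelSpec("nn", list(feature_names),
                     {"W1": W1, "b1": b1, "W2": W2, "b2": float(b2)},
                     {"hidden_units": hidden_units, "epochs": best[2] + 1,
                      "val_loss": best[0]})


def _rnn_forward(Xp, mask, W1, Wr, b1, W2, b2):
    """Batched forward over padded sequences Xp (B, T, F); h_{-1} = 0."""
    B, T, F = Xp.shape
    H = b1.shape[0]
    h = np.zeros((B, H))
    pres = np.empty((B, T, H))
    hs = np.empty((B, T, H))
    for t in range(T):
        pre = Xp[:, t, :] @ W1 + h @ Wr + b1
        h = satlins(pre)
        pres[:, t] = pre
        hs[:, t] = h
    outs = hs @ W2 + b2
    return outs, pres, hs


def train_rnn(sequences_X: list[np.ndarray], sequences_y: list[np.ndarray],
              feature_names: list[str], hidden_units: int = 9,
              val_fraction: float = 0.176, max_epochs: int = 100,
              max_val_failures: int = 6, seed: int = 0, lr: float = 0.02,
              sequences_w: list[np.ndarray] | None = None) -> ModelSpec:
    """Delay-1 recurrent satlins/purelin network trained by full BPTT.

    Sequences are padded to the longest and masked; the hidden state starts
    at zero for every sequence. The last ``val_fraction`` of the sequences
    serve as the early-stopping validation set. ``sequences_w`` (0/1 per
    step) drops steps from the loss — used for the post-transition training
    tolerance — while they still drive the recurrence.
    """
    seqs = [np.asarray(s, float) for s in sequences_X]
    tgts = [np.asarray(t, float) for t in sequences_y]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    B = len(seqs)
    T = max(len(s) for s in seqs)
    F = seqs[0].shape[1]
    Xp = np.zeros((B, T, F))
    Yp = np.zeros((B, T))
    mask = np.zeros((B, T), dtype=bool)
    for i, (s, t) in enumerate(zip(seqs, tgts)):
        Xp[i, :len(s)] = s
        Yp[i, :len(t)] = t
        mask[i, :len(s)] = True
        if sequences_w is not None:
            mask[i, :len(s)] &= np.asarray(sequences_w[i], dtype=bool)
    n_val = max(int(round(val_fraction * B)), 1)
    tr = slice(0, B - n_val)
    va = slice(B - n_val, B)
    rng = np.random.default_rng(seed)
    H = hidden_units
    W1 = rng.normal(0, 2.0 / np.sqrt(F), (F, H))
    Wr = rng.normal(0, 0.5 / np.sqrt(H), (H, H))
    b1 = rng.normal(0, 0.5, H)
    W2 = rng.normal(0, 1.0 / np.sqrt(H), H)
    b2 = np.array(0.5)
    opt = _Adam([(F, H), (H, H), (H,), (H,), ()], lr=lr)
    best = (np.inf, [W1, Wr, b1, W2, b2], 0)
    failures = 0

    def masked_loss_grad(outs, Y, m):
        z = 4.0 * (outs - 0.5)
        n = m.sum()
        loss = float(np.sum((np.logaddexp(0.0, z) - Y * z) * m) / n)
        p = 1.0 / (1.0 + np.exp(-z))
        return loss, 4.0 * (p - Y) * m / n

    Xtr = Xp[tr]
    for epoch in range(max_epochs):
        # several BPTT steps per epoch-equivalent (cf. the feedforward
        # trainer): the validation rule assumes epoch-scale progress
        for _ in range(5):
            outs, pres, hs = _rnn_forward(Xtr, mask[tr], W1, Wr, b1, W2, b2)
            _, dout = masked_loss_grad(outs, Yp[tr], mask[tr])
            Bt = dout.shape[0]
            gW1 = np.zeros_like(W1)
            gWr = np.zeros_like(Wr)
            gb1 = np.zeros_like(b1)
            gW2 = np.einsum("bt,bth->h", dout, hs)
            gb2 = float(dout.sum())
            dh_next = np.zeros((Bt, H))
            for t in range(T - 1, -1, -1):
                dh = np.outer(dout[:, t], W2).reshape(Bt, H) + dh_next
                dpre = dh * _satlins_grad(pres[:, t])
                gW1 += Xtr[:, t, :].T @ dpre
                gb1 += dpre.sum(axis=0)
                hprev = hs[:, t - 1] if t > 0 else np.zeros((Bt, H))
                gWr += hprev.T @ dpre
                dh_next = dpre @ Wr.T
            grads = [gW1, gWr, gb1, gW2, np.asarray(gb2)]
            gn = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if gn > 1.0:  # clip: BPTT through saturating units can spike
                grads = [g / gn for g in grads]
            W1, Wr, b1, W2, b2 = opt.step([W1, Wr, b1, W2, b2], grads)
        vouts, _, _ = _rnn_forward(Xp[va], mask[va], W1, Wr, b1, W2, b2)
        vloss, _ = masked_loss_grad(vouts, Yp[va], mask[va])
        if vloss < best[0] - 1e-9:
            best = (vloss, [W1.copy(), Wr.copy(), b1.copy(), W2.copy(), np.array(b2)], epoch)
            failures = 0
        else:
            failures += 1
            if failures > max_val_failures:
                break
    W1, Wr, b1, W2, b2 = best[1]
    return ModelSpec("rnn", list(feature_names),
                     {"W1": W1, "Wr": Wr, "b1": b1, "W2": W2, "b2": float(b2)},
                     {"hidden_units": hidden_units, "epochs": best[2] + 1,
                      "val_loss": best[0]})


# --------------------------------------------------------------- prediction

def _predict_tree_nodes(nodes, X) -> np.ndarray:
    out = np.empty(len(X), dtype=np.int64)
    for r, x in enumerate(np.asarray(X)):
        i = 0
        while nodes[i][0] != -1:
            feat, thr, left, right, _ = nodes[i]
            i = left if x[feat] <= thr else right
        out[r] = nodes[i][4]
    return out


def predict(spec: ModelSpec, X: np.ndarray, reset_state: bool = True) -> np.ndarray:
    """Binary decisions of a float model. For the RNN, rows of ``X`` are one
    time sequence (hidden state starts at zero)."""
    X = np.asarray(X, float)
    p = spec.params
    if spec.family == "logreg":
        return (X @ p["w"] + p["b"] > 0).astype(np.int64)
    if spec.family == "tree":
        return _predict_tree_nodes(p["nodes"], X)
    if spec.family == "nn":
        out, _, _ = _nn_forward(X, p["W1"], p["b1"], p["W2"], p["b2"])
        return (out > 0.5).astype(np.int64)
    if spec.family == "rnn":
        outs, _, _ = _rnn_forward(X[None, :, :], None, p["W1"], p["Wr"],
                                  p["b1"], p["W2"], p["b2"])
        return (outs[0] > 0.5).astype(np.int64)
    raise ValueError(f"unknown family {spec.family}")


def quantize_model(spec: ModelSpec) -> QuantizedModelSpec:
    """Scale every real parameter by 1024 and round to the nearest integer.

    Trees are quantized on the raw feature scale (integer thresholds on
    integer features — exact); networks and the regression run their
    forward pass in integers with products rescaled by an arithmetic right
    shift of 10 bits.
    """
    p = spec.params
    if spec.family == "tree":
        nodes = []
        for feat, thr, left, right, cls in p["nodes"]:
            nodes.append([int(feat), int(np.floor(thr)) if feat != -1 else 0,
                          int(left), int(right), int(cls)])
        q = {"nodes": np.asarray(nodes, dtype=object)}
    elif spec.family == "logreg":
        q = {"w": np.rint(p["w"] * Q).astype(np.int64),
             "b": int(round(p["b"] * Q))}
    elif spec.family in ("nn", "rnn"):
        q = {k: np.rint(np.asarray(v) * Q).astype(np.int64) if isinstance(v, np.ndarray)
             else int(round(v * Q)) for k, v in p.items()}
    else:
        raise ValueError(spec.family)
    return QuantizedModelSpec(spec.family, list(spec.feature_names), q)


def _satlins_q(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -Q, Q)


def predict_quantized(qspec: QuantizedModelSpec, Xq: np.ndarray) -> np.ndarray:
    """Integer forward pass on 1024-scale inputs (raw integers for trees)."""
    p = qspec.params
    X = np.asarray(Xq).astype(np.int64)
    if qspec.family == "tree":
        return _predict_tree_nodes(p["nodes"], X)
    if qspec.family == "logreg":
        score = (X @ p["w"]) >> 10
        return (score + p["b"] > 0).astype(np.int64)
    if qspec.family == "nn":
        pre = ((X @ p["W1"]) >> 10) + p["b1"]
        h = _satlins_q(pre)
        out = ((h @ p["W2"]) >> 10) + p["b2"]
        return (out > qspec.threshold).astype(np.int64)
    if qspec.family == "rnn":
        H = p["b1"].shape[0]
        h = np.zeros(H, dtype=np.int64)
        out = np.empty(len(X), dtype=np.int64)
        for t in range(len(X)):
            pre = ((X[t] @ p["W1"]) >> 10) + ((h @ p["Wr"]) >> 10) + p["b1"]
            h = _satlins_q(pre)
            out[t] = ((h @ p["W2"]) >> 10) + p["b2"]
        return (out > qspec.threshold).astype(np.int64)
    raise ValueError(qspec.family)


# ------------------------------------------------------------------- CV

def contiguous_folds(window_ids: list[int], k: int = 5, run: int = 4,
                     seed: int = 0) -> list[list[int]]:
    """Partition a window-id pool into ``k`` folds made of contiguous runs."""
    rng = np.random.default_rng(seed)
    runs = [window_ids[i:i + run] for i in range(0, len(window_ids), run)]
    order = rng.permutation(len(runs))
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, ri in enumerate(order):
        folds[pos % k].extend(runs[ri])
    return [sorted(f) for f in folds]


def cv_train(family: str, dataset, pool_window_ids: list[int],
             trainer: Callable, grid: list, config: ModelConfig | None = None):
    """Generic 5-fold CV over contiguous window folds.

    ``trainer(fd_train, fd_val, grid_value)`` returns a ModelSpec; each fold
    is scored with the training transition tolerance (100 ms); the grid
    value with the highest mean tolerant accuracy wins and is retrained on
    the whole pool. Returns (best_spec, report_dict).
    """
    cfg = config or ModelConfig(family=family)
    folds = contiguous_folds(pool_window_ids, k=cfg.cv_folds, seed=cfg.seed)
    report = {}
    best_val, best_g = -1.0, grid[0]
    for g in grid:
        accs = []
        for fi in range(cfg.cv_folds):
            val_ids = folds[fi]
            tr_ids = sorted(set(pool_window_ids) - set(val_ids))
            fd_tr = dataset.select_windows(tr_ids)
            fd_va = dataset.select_windows(val_ids)
            if len(np.unique(fd_tr.y)) < 2 or len(fd_va.y) == 0:
                continue
            spec = trainer(fd_tr, fd_va, g)
            pred = predict(spec, fd_va.X)
            rep = tolerant_accuracy(pred, fd_va.y, cfg.tolerance_train_ms, fd_va.rate_hz)
            accs.append(rep.accuracy)
        mean_acc = float(np.mean(accs)) if accs else -1.0
        report[str(g)] = mean_acc
        if mean_acc > best_val:
            best_val, best_g = mean_acc, g
    fd_all = dataset.select_windows(pool_window_ids)
    spec = trainer(fd_all, None, best_g)
    report["winner"] = str(best_g)
    report["cv_accuracy"] = best_val
    return spec, report
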