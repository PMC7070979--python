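"""End-to-end training/evaluation workflows and the model sweep.

Ties the pipeline together: correlation pruning and normalization are
fitted on the training partition only, features are selected per model
budget, the model is trained with its early-stopping validation set, and
the *quantized* model's debounced decisions are scored on the test
partition with the 150 ms transition tolerance. ``sweep`` repeats this for
every family x feature-count (x hidden-units) cell and tabulates percent
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import EvalReport, tolerant_accuracy, transition_mask
from .metrics import accuracy_from_confusion, ema_time_constant  # noqa: F401 (re-export)
from sklearn.tree import DecisionTreeClassifier

from .models import (ModelConfig, ModelSpec, QuantizedModelSpec, lasso_select,
                     predict, predict_quantized, quantize_model,
                     train_logreg, train_nn, train_rnn, train_tree)
from .pipeline import (DatasetSplit, FeatureDataset, NormalizationSpec,
                       correlation_prune, minmax_apply, minmax_fit)
from .runtime import debounce

__all__ = [
    "FittedModel",
    "fit_model",
    "evaluate_model",
    "sweep",
    "default_n_slope",
]


def default_n_slope(family: str, online: bool = False) -> int:
    if family == "rnn":
        return 3
    return 20 if online else 2


@dataclass
class FittedModel:
    """A trained model with everything needed to run it on new features."""

    spec: ModelSpec
    qspec: QuantizedModelSpec
    columns: list[int]            # indices into the full feature bank
    norm: NormalizationSpec | None
    rate_hz: int

    @property
    def family(self) -> str:
        return self.spec.family

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "qspec": self.qspec.to_dict(),
            "columns": list(self.columns),
            "norm": self.norm.to_dict() if self.norm is not None else None,
            "rate_hz": self.rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            qspec=QuantizedModelSpec.from_dict(d["qspec"]),
            columns=list(d["columns"]),
            norm=NormalizationSpec.from_dict(d["norm"]) if d["norm"] else None,
            rate_hz=int(d["rate_hz"]),
        )

    def inputs(self, X: np.ndarray, quantized: bool) -> np.ndarray:
        """Map raw bank features to this model's input representation."""
        Xs = np.asarray(X)[:, self.columns]
        if self.norm is None:
            return Xs.astype(np.int64) if quantized else Xs.astype(float)
        return minmax_apply(self.norm, Xs, quantized=quantized)

    def decide(self, X: np.ndarray, quantized: bool = True) -> np.ndarray:
        Z = self.inputs(X, quantized)
        if quantized:
            return predict_quantized(self.qspec, Z)
        return predict(self.spec, Z)


def _tolerance_keep(fd: FeatureDataset, ids: list[int], tol_ms: float) -> np.ndarray:
    """Keep-mask over ``fd.select_windows(ids)`` rows that excludes samples
    within ``tol_ms`` after a target transition, per contiguous run."""
    parts = [transition_mask(fd.select_windows(run).y, tol_ms, fd.rate_hz)
             for run in _runs(ids)]
    return np.concatenate(parts) if parts else np.zeros(0, dtype=bool)


def _runs(ids: list[int]) -> list[list[int]]:
    """Split a sorted id list into maximal consecutive runs."""
    runs: list[list[int]] = []
    for i in sorted(ids):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def _sequences(fd: FeatureDataset, ids: list[int], cols: np.ndarray | list[int],
               norm: NormalizationSpec | None, max_windows: int = 4,
               tol_ms: float = 100.0):
    """Contiguous-run sequences (inputs, targets, loss weights) for
    recurrent training; the weights zero out the post-transition tolerance."""
    Xs, ys, ws = [], [], []
    for run in _runs(ids):
        for i in range(0, len(run), max_windows):
            chunk = run[i:i + max_windows]
            if len(chunk) < 2:
                continue
            sel = fd.select_windows(chunk)
            Z = np.asarray(sel.X)[:, cols]
            if norm is not None:
                Z = minmax_apply(norm, Z)
            Xs.append(Z)
            ys.append(sel.y.astype(float))
            ws.append(transition_mask(sel.y, tol_ms, fd.rate_hz))
    return Xs, ys, ws


def fit_model(
    family: str,
    fd: FeatureDataset,
    split: DatasetSplit,
    n_features: int = 3,
    hidden_units: int = 3,
    config: ModelConfig | None = None,
    max_splits: int | None = None,
) -> FittedModel:
    """Prune, normalize, select features, and train one model family.

    Everything data-dependent (pruning, normalization, lasso selection) is
    fitted on the training partition; validation windows drive early
    stopping for the networks.
    """
    cfg = config or ModelConfig(family=family, n_features=n_features,
                                hidden_units=hidden_units)
    tr = fd.select_windows(split.train)
    va = fd.select_windows(split.val)
    # samples inside the training tolerance after a target transition are
    # ambiguous (features still settling) and are excluded from every fit
    keep_tr = _tolerance_keep(fd, split.train, cfg.tolerance_train_ms)
    keep_va = _tolerance_keep(fd, split.val, cfg.tolerance_train_ms)
    retained = correlation_prune(tr.X[keep_tr])
    Xtr = np.asarray(tr.X, float)[:, retained]
    norm = minmax_fit(Xtr)
    n_keep = min(n_features, len(retained))
    if family == "tree":
        # embedded selection: the split-capped CART run on all retained
        # features picks its own splits greedily; the features it uses,
        # ranked by Gini importance, are the subset (the lasso path is the
        # stated selector only for the linear model)
        ms = max_splits if max_splits is not None else max(cfg.max_splits_grid)
        probe = DecisionTreeClassifier(criterion="gini", max_leaf_nodes=ms + 1,
                                       random_state=cfg.seed)
        probe.fit(Xtr[keep_tr], tr.y[keep_tr])
        order = np.argsort(-probe.feature_importances_)
        sel = sorted(int(j) for j in order[:n_keep]
                     if probe.feature_importances_[j] > 0)
        if len(sel) < n_keep:  # tree used fewer features: pad from a deeper probe
            deep = DecisionTreeClassifier(criterion="gini", max_leaf_nodes=33,
                                          random_state=cfg.seed)
            deep.fit(Xtr[keep_tr], tr.y[keep_tr])
            for j in np.argsort(-deep.feature_importances_):
                if len(sel) == n_keep:
                    break
                if int(j) not in sel:
                    sel.append(int(j))
            sel = sorted(sel)
    else:
        # the L1 path is scale-dependent, so selection sees normalized values
        sel = lasso_select(minmax_apply(norm, Xtr[keep_tr]), tr.y[keep_tr],
                           n_keep=n_keep, seed=cfg.seed)
    cols = [retained[j] for j in sel]
    norm = (NormalizationSpec(norm.featmin[sel], norm.featmax[sel])
            if family != "tree" else None)
    names = [fd.names[c] for c in cols]

    def tr_inputs(sel_fd: FeatureDataset) -> np.ndarray:
        Z = np.asarray(sel_fd.X, float)[:, cols]
        return minmax_apply(norm, Z) if norm is not None else Z

    if family == "logreg":
        spec = train_logreg(tr_inputs(tr)[keep_tr], tr.y[keep_tr], names, seed=cfg.seed)
    elif family == "tree":
        grid = (max_splits,) if max_splits is not None else cfg.max_splits_grid
        spec = train_tree(tr_inputs(tr)[keep_tr], tr.y[keep_tr], names,
                          max_splits_grid=grid, seed=cfg.seed)
    elif family == "nn":
        spec = train_nn(tr_inputs(tr)[keep_tr], tr.y[keep_tr], names,
                        hidden_units=hidden_units,
                        X_val=tr_inputs(va)[keep_va], y_val=va.y[keep_va],
                        max_epochs=cfg.max_epochs_nn,
                        max_val_failures=cfg.max_val_failures, seed=cfg.seed)
    elif family == "rnn":
        Xs, ys, ws = _sequences(fd, split.train, cols, norm,
                                tol_ms=cfg.tolerance_train_ms)
        Xv, yv, wv = _sequences(fd, split.val, cols, norm,
                                tol_ms=cfg.tolerance_train_ms)
        spec = train_rnn(Xs + Xv, ys + yv, names, hidden_units=hidden_units,
                         val_fraction=len(Xv) / max(len(Xs) + len(Xv), 1),
                         max_epochs=cfg.max_epochs_rnn,
                         max_val_failures=cfg.max_val_failures, seed=cfg.seed,
                         sequences_w=ws + wv)
    else:
        raise ValueError(f"unknown family {family}")
    return FittedModel(spec=spec, qspec=quantize_model(spec), columns=cols,
                       norm=norm, rate_hz=fd.rate_hz)


def evaluate_model(
    fm: FittedModel,
    fd: FeatureDataset,
    window_ids: list[int],
    tol_ms: float = 150.0,
    quantized: bool = True,
    debounced: bool = True,
    n_slope: int | None = None,
) -> EvalReport:
    """Score the model's (debounced) decisions on the given windows.

    Decisions run over each maximal contiguous window run in time order;
    the recurrent hidden state and the debounce state reset per run (runs
    are independent recordings as far as the model is concerned).
    """
    ns = n_slope if n_slope is not None else default_n_slope(fm.family)
    preds, targets, subtypes = [], [], []
    for run in _runs(window_ids):
        sel = fd.select_windows(run)
        p = fm.decide(sel.X, quantized=quantized)
        if debounced:
            p = debounce(p, ns)
        preds.append(p)
        targets.append(sel.y)
        subtypes.append(sel.subtype)
    return tolerant_accuracy(np.concatenate(preds), np.concatenate(targets),
                             tol_ms=tol_ms, rate_hz=fd.rate_hz,
                             subtype=np.concatenate(subtypes))


_SWEEP_ROWS = [
    ("nn", 3), ("nn", 6), ("nn", 9),
    ("rnn", 3), ("rnn", 6), ("rnn", 9),
    ("tree", None), ("logreg", None),
]


def sweep(
    fd40: FeatureDataset,
    fd250: FeatureDataset,
    split: DatasetSplit,
    split250: DatasetSplit | None = None,
    n_features_grid: tuple[int, ...] = (3, 6, 9, 12),
    config: ModelConfig | None = None,
    quantized: bool = True,
    debounced: bool = True,
) -> pd.DataFrame:
    """Accuracy grid over all families and feature counts.

    Rows: NN and RNN at 3/6/9 hidden units, the decision tree, the logistic
    regression; columns: the feature-count budget. Cells are percent
    tolerant test accuracy of the quantized, debounced model. ``split``
    indexes the 40 Hz windows; ``split250`` the (variable-duration) 250 Hz
    windows of the recurrent models, defaulting to ``split``.
    """
    rows = {}
    for family, hidden in _SWEEP_ROWS:
        fd = fd250 if family == "rnn" else fd40
        sp = (split250 or split) if family == "rnn" else split
        label = {"nn": f"NN ({hidden} HU)", "rnn": f"RNN ({hidden} HU)",
                 "tree": "Decision Tree", "logreg": "Log. Regression"}[family]
        cells = {}
        for nf in n_features_grid:
            fm = fit_model(family, fd, sp, n_features=nf,
                           hidden_units=hidden or 3, config=config)
            rep = evaluate_model(fm, fd, sp.test, quantized=quantized,
                                 debounced=debounced)
            cells[nf] = rep.accuracy
        rows[label] = cells
    return pd.DataFrame(rows).T[list(n_features_grid)]
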