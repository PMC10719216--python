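"""Differentiable multi-class cell-type classifier.

:class:`CellTypeMLP` is a compact fully-connected network (affine layers,
ReLU hidden activations, softmax output) trained with categorical
cross-entropy and Adam. It is written directly on numpy so that the exact
gradient of the loss and of any pre-softmax class score **with respect to
the input** is available in closed form — the contract that adversarial
attacks and every attribution method in this package consume. The estimator
follows the scikit-learn API (``fit`` / ``predict`` / ``predict_proba`` /
``get_params``) and composes with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DivergenceError, LabelError, ParameterError
from .simdata import LABEL_KEY

__all__ = [
    "CellTypeMLP",
    "EvalMetrics",
    "train_classifier",
    "evaluate",
    "hyperparameter_search",
]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CellTypeMLP(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron with explicit input-gradient access.

    Parameters
    ----------
    hidden_layer_sizes : widths of the ReLU hidden layers.
    epochs, batch_size, learning_rate : Adam training schedule.
    random_state : seeds both weight initialization and batch shuffling.

    Attributes (after ``fit``)
    --------------------------
    classes_ : label vocabulary.
    coefs_, intercepts_ : per-layer weights ``W`` (in x out) and biases.
    loss_curve_ : mean training cross-entropy per epoch.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (256, 128),
        epochs: int = 30,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _init_params(self, n_features: int, n_classes: int) -> None:
        rng = np.random.default_rng(self.random_state)
        widths = [n_features, *self.hidden_layer_sizes, n_classes]
        self.coefs_ = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(widths[:-1], widths[1:])
        ]
        self.intercepts_ = [np.zeros(w) for w in widths[1:]]
        self._adam_m = [np.zeros_like(p) for p in self.coefs_ + self.intercepts_]
        self._adam_v = [np.zeros_like(p) for p in self.coefs_ + self.intercepts_]
        self._adam_t = 0
        self.loss_curve_: list[float] = []
        self._shuffle_rng = np.random.default_rng(self.random_state + 1)

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; last entry is the pre-softmax logits."""
        acts = [X]
        a = X
        n = len(self.coefs_)
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + b
            a = z if i == n - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return acts

    def _step(self, grads: list[np.ndarray]) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        params = self.coefs_ + self.intercepts_
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1**self._adam_t)
            vh = v / (1 - beta2**self._adam_t)
            p -= self.learning_rate * mh / (np.sqrt(vh) + eps)

    def _batch_grads(
        self, X: np.ndarray, onehot: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        acts = self._forward(X)
        probs = _softmax(acts[-1])
        n = X.shape[0]
        loss = float(-np.mean(np.log(np.clip(probs[onehot.astype(bool)], 1e-12, None))))
        delta = (probs - onehot) / n
        grads_W: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        for i in range(len(self.coefs_) - 1, -1, -1):
            grads_W.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.coefs_[i].T) * (acts[i] > 0)
        return loss, grads_W[::-1] + grads_b[::-1]

    def _run_epoch(self, X: np.ndarray, y_idx: np.ndarray, epoch: int) -> float:
        onehot = np.eye(len(self.classes_))[y_idx]
        order = self._shuffle_rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], self.batch_size):
            sel = order[start : start + self.batch_size]
            loss, grads = self._batch_grads(X[sel], onehot[sel])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch + 1}")
            self._step(grads)
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        self.loss_curve_.append(mean_loss)
        return mean_loss

    def fit(self, X, y):
        X = check_array(X, dtype=np.float64)
        if not np.all(np.isfinite(X)):
            raise ParameterError("features must be finite")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ParameterError("need at least 2 classes")
        self.n_features_in_ = X.shape[1]
        self._init_params(X.shape[1], len(self.classes_))
        for epoch in range(self.epochs):
            self._run_epoch(X, y_idx, epoch)
        return self

    # -------------------------------------------------------------- predict
    def decision_function(self, X) -> np.ndarray:
        """Pre-softmax class scores (logits), cells x classes."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self._forward(X)[-1]

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    # ------------------------------------------------------ gradient contract
    def _label_indices(self, y: np.ndarray) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.array([lookup[v] for v in np.asarray(y)])
        except KeyError as exc:  # pragma: no cover - message formatting
            raise LabelError(f"unknown label {exc.args[0]!r}") from exc

    def _backprop_input(self, acts: list[np.ndarray], delta: np.ndarray) -> np.ndarray:
        """Propagate an output-layer sensitivity back to the input."""
        for i in range(len(self.coefs_) - 1, -1, -1):
            delta = delta @ self.coefs_[i].T
            if i > 0:
                delta = delta * (acts[i] > 0)
        return delta

    def gradient_loss(self, X, y) -> np.ndarray:
        """d/dx of the per-sample cross-entropy loss; same shape as X."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=np.float64)
        y_idx = self._label_indices(y)
        acts = self._forward(X)
        probs = _softmax(acts[-1])
        delta = probs.copy()
        delta[np.arange(X.shape[0]), y_idx] -= 1.0
        return self._backprop_input(acts, delta)

    def gradient_score(self, X, class_index: int) -> np.ndarray:
        """d/dx of the pre-softmax score of one class; same shape as X."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=np.float64)
        if not 0 <= class_index < len(self.classes_):
            raise LabelError(f"class index {class_index} out of range")
        delta = np.zeros((X.shape[0], len(self.classes_)))
        delta[:, class_index] = 1.0
        return self._backprop_input(self._forward(X), delta)

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "coefs_")
        return int(sum(W.size for W in self.coefs_) + sum(b.size for b in self.intercepts_))


@dataclass
class EvalMetrics:
    """Held-out classification metrics."""

    accuracy: float
    macro_f1: float
    per_class: pd.DataFrame  # precision, recall, f1, support per class
    confusion: pd.DataFrame  # rows = true, columns = predicted


def _get_xy(data: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(data.X, dtype=np.float64), data.obs[LABEL_KEY].to_numpy().astype(str)


def train_classifier(
    train: ad.AnnData,
    arch: tuple[int, ...] = (256, 128),
    epochs: int = 30,
    seed: int = 0,
    **kwargs,
) -> CellTypeMLP:
    """Fit the default classifier on a labeled expression matrix."""
    X, y = _get_xy(train)
    model = CellTypeMLP(
        hidden_layer_sizes=tuple(arch), epochs=epochs, random_state=seed, **kwargs
    )
    return model.fit(X, y)


def evaluate(model: CellTypeMLP, test: ad.AnnData) -> EvalMetrics:
    """Accuracy, macro-F1, per-class scores and the confusion matrix."""
    X, y = _get_xy(test)
    if X.shape[0] == 0:
        raise ParameterError("test set is empty")
    known = set(model.classes_)
    unseen = sorted(set(y) - known)
    if unseen:
        raise LabelError(f"labels {unseen} never seen in training")
    pred = model.predict(X)
    classes = [str(c) for c in model.classes_]
    prec, rec, f1, support = precision_recall_fscore_support(
        y, pred, labels=classes, zero_division=0
    )
    cm = confusion_matrix(y, pred, labels=classes)
    return EvalMetrics(
        accuracy=float(np.mean(pred == y)),
        macro_f1=float(np.mean(f1)),
        per_class=pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=classes,
        ),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
    )


def hyperparameter_search(
    train: ad.AnnData,
    n_layers_grid: tuple[int, ...] = (1, 2),
    n_nodes_grid: tuple[int, ...] = (64, 128, 256),
    epochs: int = 30,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[tuple[int, ...], pd.DataFrame]:
    """Grid search over depth and width on a stratified validation split.

    The best architecture maximizes validation accuracy; ties go to the
    model with fewer parameters, then to grid order.
    """
    if not n_layers_grid or not n_nodes_grid:
        raise ParameterError("search grid must be non-empty")
    X, y = _get_xy(train)
    idx_tr, idx_val = train_test_split(
        np.arange(X.shape[0]),
        test_size=val_fraction,
        stratify=y,
        random_state=seed,
    )
    rows = []
    for n_layers in n_layers_grid:
        for n_nodes in n_nodes_grid:
            arch = tuple([n_nodes] * n_layers)
            model = CellTypeMLP(
                hidden_layer_sizes=arch, epochs=epochs, random_state=seed
            ).fit(X[idx_tr], y[idx_tr])
            acc = float(np.mean(model.predict(X[idx_val]) == y[idx_val]))
            rows.append(
                {
                    "arch": arch,
                    "n_layers": n_layers,
                    "n_nodes": n_nodes,
                    "n_parameters": model.n_parameters_,
                    "val_accuracy": acc,
                }
            )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["val_accuracy", "n_parameters"],
        ascending=[False, True],
        kind="stable",
    ).iloc[0]
    return tuple(best["arch"]), table
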