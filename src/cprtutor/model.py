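"""Recurrent sequence classifiers over compression feature tensors.

One network per target indicator: an LSTM layer (default 128 units) read
out at the last timestep into a dense softmax layer sized to the number of
classes, trained with sparse categorical cross-entropy.  The network is
implemented directly on numpy (forward pass, backpropagation through time,
Adam) so it runs on the plain scientific stack; gradients are verified
against numerical differentiation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score as _sk_roc_auc_score

__all__ = [
    "ClassifierConfig",
    "TrainingHistory",
    "EvalReport",
    "LSTMClassifier",
    "split_train_test",
    "train_classifier",
    "detect_overfit_epoch",
    "evaluate",
]


@dataclass
class ClassifierConfig:
    """Training configuration (defaults replicate the reference setup)."""

    n_classes: int = 2
    hidden_units: int = 128
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    test_fraction: float = 0.33
    seed: int = 0
    #: optional early exit once validation accuracy reaches this level;
    #: None (the default) trains the full epoch budget with no early stopping
    stop_at_val_accuracy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class EvalReport:
    accuracy: float
    loss: float
    roc_auc: Optional[float]  # None == "n.a." (ternary target or degenerate test set)
    confusion: np.ndarray  # rows = actual, columns = predicted
    overfit_epoch: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "roc_auc": self.roc_auc if self.roc_auc is not None else "n.a.",
            "confusion": self.confusion.tolist(),
            "overfit_epoch": self.overfit_epoch,
        }


def split_train_test(tensor: np.ndarray, labels: np.ndarray, config: ClassifierConfig):
    """Random shuffled split; test size = round(test_fraction * N).

    Returns ``(X_train, y_train), (X_test, y_test)``.  Partitions are
    disjoint and exhaustive and the shuffle is seeded.  A class absent from
    the training partition triggers a warning (no stratification, matching
    the reference protocol).
    """
    tensor = np.asarray(tensor)
    labels = np.asarray(labels)
    n = tensor.shape[0]
    if labels.shape[0] != n:
        raise ValueError(f"{n} samples but {labels.shape[0]} labels")
    n_test = int(round(config.test_fraction * n))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    test_idx, train_idx = order[:n_test], order[n_test:]
    y_train = labels[train_idx]
    missing = set(np.unique(labels)) - set(np.unique(y_train))
    if missing:
        warnings.warn(f"class(es) {sorted(missing)} absent from training partition")
    return (tensor[train_idx], y_train), (tensor[test_idx], labels[test_idx])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LSTMClassifier:
    """LSTM (single hidden layer) + dense softmax head, on numpy.

    Gate pre-activations are computed jointly as ``x @ Wx + h @ Wh + b``
    split into input/forget/cell/output quarters; the forget-gate bias is
    initialised to 1.  The classifier reads out the final hidden state.
    """

    def __init__(self, n_features: int, hidden_units: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        h, q, c = hidden_units, n_features, n_classes
        scale_x = 1.0 / np.sqrt(q)
        scale_h = 1.0 / np.sqrt(h)
        self.Wx = rng.uniform(-scale_x, scale_x, (q, 4 * h))
        self.Wh = rng.uniform(-scale_h, scale_h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget gate bias
        self.Wo = rng.uniform(-scale_h, scale_h, (h, c))
        self.bo = np.zeros(c)
        self.hidden_units = h
        self.n_features = q
        self.n_classes = c

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Run the recurrence; returns (probs, cache) for backprop."""
        B, T, Q = X.shape
        H = self.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev_cache = h
            h = o * tc
            cache.append((x_t, h_prev_cache, c_prev, i, f, g, o, c, tc))
        logits = h @ self.Wo + self.bo
        return _softmax(logits), (cache, h)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, dtype=float))
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- loss & gradients --------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(X)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean sparse categorical cross-entropy and its parameter gradients."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        B, T, Q = X.shape
        H = self.hidden_units
        probs, (cache, h_last) = self._forward(X)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        gWo = h_last.T @ dlogits
        gbo = dlogits.sum(axis=0)

        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        dh = dlogits @ self.Wo.T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.empty((B, 4 * H))
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            gWx += x_t.T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        grads = {"Wx": gWx, "Wh": gWh, "b": gb, "Wo": gWo, "bo": gbo}
        return loss, grads

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b, "Wo": self.Wo, "bo": self.bo}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_classifier(
    train_set: tuple[np.ndarray, np.ndarray],
    config: ClassifierConfig,
    validation_set: Optional[tuple[np.ndarray, np.ndarray]] = None,
):
    """Train an LSTM classifier; returns ``(model, TrainingHistory)``.

    Train-side history entries are batch-weighted running averages over the
    epoch (as the usual framework convention); validation metrics are full
    passes over ``validation_set``.  With ``config.stop_at_val_accuracy``
    set, training exits early once validation accuracy reaches the level;
    otherwise the full epoch budget runs (no early stopping).
    """
    X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    observed = np.unique(y)
    if observed.min() < 0 or observed.max() >= config.n_classes:
        raise ValueError(
            f"labels {observed.tolist()} incompatible with n_classes={config.n_classes}"
        )
    model = LSTMClassifier(X.shape[2], config.hidden_units, config.n_classes, seed=config.seed)
    optimizer = _Adam(model.parameters, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            loss, grads = model.loss_and_grads(xb, yb)
            optimizer.step(model.parameters, grads)
            loss_sum += loss * len(idx)
            correct += int((model.predict(xb) == yb).sum())
        history.train_loss.append(loss_sum / n)
        history.train_accuracy.append(correct / n)
        if validation_set is not None:
            xv, yv = validation_set
            probs = model.predict_proba(xv)
            history.val_loss.append(
                float(-np.mean(np.log(probs[np.arange(len(yv)), yv] + 1e-12)))
            )
            val_acc = float((probs.argmax(axis=1) == yv).mean())
            history.val_accuracy.append(val_acc)
            if (
                config.stop_at_val_accuracy is not None
                and val_acc >= config.stop_at_val_accuracy
            ):
                break
    return model, history


def detect_overfit_epoch(history: TrainingHistory) -> int:
    """1-based epoch of minimum validation loss (earliest on ties).

    This is the point past which training loss keeps decreasing while
    validation loss no longer improves.  Falls back to the training loss
    when no validation series was recorded.
    """
    series = history.val_loss if history.val_loss else history.train_loss
    if not series:
        raise ValueError("empty history")
    return int(np.argmin(series)) + 1


def evaluate(
    model: LSTMClassifier,
    test_set: tuple[np.ndarray, np.ndarray],
    overfit_epoch: Optional[int] = None,
) -> EvalReport:
    """Accuracy, loss, ROC-AUC (binary only) and the confusion matrix.

    ROC-AUC uses the class-1 scores and is reported as ``None`` ("n.a.")
    for ternary targets or when the test set holds a single class.  The
    confusion matrix has actual classes on rows, predictions on columns.
    """
    X, y = test_set
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(X)
    predictions = probs.argmax(axis=1)
    accuracy = float((predictions == y).mean())
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))
    roc_auc = None
    if model.n_classes == 2 and len(np.unique(y)) == 2:
        roc_auc = float(_sk_roc_auc_score(y, probs[:, 1]))
    confusion = _sk_confusion_matrix(y, predictions, labels=np.arange(model.n_classes))
    return EvalReport(
        accuracy=accuracy,
        loss=loss,
        roc_auc=roc_auc,
        confusion=confusion,
        overfit_epoch=overfit_epoch,
    )
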