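"""Shallow feed-forward classifiers, training algorithms and evaluation.

The classifiers are single-hidden-layer pattern-recognition networks
(tanh hidden units, softmax outputs) trained to minimize the mean squared
error between the softmax outputs and one-hot targets — the configuration
classically used for gait-based screening.  Four full-batch training
algorithms are provided:

* ``RPROP`` — resilient backpropagation (iRprop-): per-weight step sizes
  adapted from gradient signs (eta+ 1.2, eta- 0.5, initial step 0.07,
  maximum step 50);
* ``LM`` — Levenberg-Marquardt: damped Gauss-Newton on the residual
  Jacobian, well suited to networks with a few hundred weights;
* ``GDM`` — gradient descent with momentum 0.9;
* ``SCG`` — Moller's scaled conjugate gradient.

Inputs are scaled per feature to [-1, 1] from the training minima/maxima.
Early stopping monitors a held-out validation split and restores the best
validation weights after ``patience`` consecutive increases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import (
    KFold,
    LeaveOneOut,
    StratifiedKFold,
    train_test_split,
)

ALGORITHMS = ("RPROP", "LM", "GDM", "SCG")

# Rprop constants (Riedmiller & Braun)
RPROP_ETA_PLUS = 1.2
RPROP_ETA_MINUS = 0.5
RPROP_DELTA0 = 0.07
RPROP_DELTA_MAX = 50.0
RPROP_DELTA_MIN = 1e-9


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Architecture and training hyper-parameters of one network."""

    n_hidden: int = 25
    algorithm: str = "RPROP"
    max_epochs: int = 1000
    val_fraction: float = 0.15
    patience: int = 6
    seed: int = 0
    loss: str = "mse"             # "mse" | "cross_entropy"
    learning_rate: float = 0.05   # GDM only
    momentum: float = 0.9         # GDM only
    n_inputs: int | None = None   # inferred from data when None
    n_outputs: int | None = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError("loss must be 'mse' or 'cross_entropy'")
        if self.algorithm == "LM" and self.loss != "mse":
            raise ValueError("Levenberg-Marquardt operates on the MSE objective")


@dataclass
class MinMaxScaler:
    """Per-feature linear map sending the training min/max to -1/+1.

    Constant training features map to 0 (warned); unseen data may exceed
    [-1, 1] and is deliberately not clipped.
    """

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.lo[nz]) / span[nz] - 1.0
        return out


def fit_scaler(X: np.ndarray) -> MinMaxScaler:
    """Fit the [-1, 1] min-max scaler on training data."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi == lo):
        warnings.warn(
            f"{int(np.sum(hi == lo))} constant feature(s) map to 0", stacklevel=2
        )
    return MinMaxScaler(lo=lo, hi=hi)


def apply_scaler(scaler: MinMaxScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


@dataclass
class TrainedNet:
    """A fitted network with its scaler and training history."""

    config: NetConfig
    classes: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    scaler: MinMaxScaler | None
    train_curve: list[tuple[float, float]]   # (train MSE-loss, val loss)
    stopped_epoch: int


@dataclass
class ConfusionMatrix:
    """Class-count matrix with rows = predicted, columns = target."""

    counts: np.ndarray
    class_labels: list

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Binary panel (one-vs-rest for multiclass) plus per-class rates.

    Undefined ratios (zero denominator) are ``None``, never silently 0.
    """

    acc: float
    err: float
    sn: float | None
    sp: float | None
    prec: float | None
    fpr: float | None
    per_class: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Per-fold and pooled cross-validation outcomes."""

    scheme: str
    fold_mse: list[float]
    fold_accuracy: list[float]
    confusion: ConfusionMatrix
    mean_mse: float
    mean_accuracy: float
    pooled_accuracy: float


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _one_hot(y_idx: np.ndarray, c: int) -> np.ndarray:
    T = np.zeros((len(y_idx), c))
    T[np.arange(len(y_idx)), y_idx] = 1.0
    return T


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


class _Net:
    """Flat-parameter view of the 1-hidden-layer network used in training."""

    def __init__(self, p: int, h: int, c: int, rng: np.random.Generator):
        self.p, self.h, self.c = p, h, c
        scale1 = 1.0 / np.sqrt(p)
        scale2 = 1.0 / np.sqrt(h)
        self.W1 = rng.uniform(-scale1, scale1, size=(h, p))
        self.b1 = rng.uniform(-scale1, scale1, size=h)
        self.W2 = rng.uniform(-scale2, scale2, size=(c, h))
        self.b2 = rng.uniform(-scale2, scale2, size=c)

    # -- flat parameter vector ------------------------------------------------
    def get_theta(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def set_theta(self, theta: np.ndarray) -> None:
        p, h, c = self.p, self.h, self.c
        i = 0
        self.W1 = theta[i:i + h * p].reshape(h, p); i += h * p
        self.b1 = theta[i:i + h].copy(); i += h
        self.W2 = theta[i:i + c * h].reshape(c, h); i += c * h
        self.b2 = theta[i:i + c].copy()

    @property
    def n_weights(self) -> int:
        return self.h * (self.p + 1) + self.c * (self.h + 1)

    # -- forward / loss / gradient -------------------------------------------
    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A1 = np.tanh(X @ self.W1.T + self.b1)
        P = _softmax(A1 @ self.W2.T + self.b2)
        return A1, P

    def loss(self, X: np.ndarray, T: np.ndarray, kind: str) -> float:
        _, P = self.forward(X)
        return _loss_value(P, T, kind)

    def loss_grad(
        self, X: np.ndarray, T: np.ndarray, kind: str
    ) -> tuple[float, np.ndarray]:
        n, c = T.shape
        A1, P = self.forward(X)
        if kind == "mse":
            G = 2.0 * (P - T) / (n * c)                       # dL/dP
            dZ2 = P * (G - (G * P).sum(axis=1, keepdims=True))  # through softmax
            value = float(np.mean((P - T) ** 2))
        else:  # cross-entropy with softmax
            dZ2 = (P - T) / n
            value = _loss_value(P, T, kind)
        gW2 = dZ2.T @ A1
        gb2 = dZ2.sum(axis=0)
        dA1 = dZ2 @ self.W2
        dZ1 = dA1 * (1.0 - A1 ** 2)
        gW1 = dZ1.T @ X
        gb1 = dZ1.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return value, grad

    def residual_jacobian(
        self, X: np.ndarray, T: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Residuals r = (P - T)/sqrt(nc) and their Jacobian wrt all weights."""
        n, c = T.shape
        h, p = self.h, self.p
        A1, P = self.forward(X)
        scale = 1.0 / np.sqrt(n * c)
        r = (P - T).ravel() * scale
        # softmax Jacobian per sample: S[i,j] = P_i (delta_ij - P_j)
        S = P[:, :, None] * (np.eye(c)[None, :, :] - P[:, None, :])
        # output layer
        J_W2 = (S[:, :, :, None] * A1[:, None, None, :]).reshape(n, c, c * h)
        J_b2 = S                                        # (n, c, c)
        # hidden layer
        M = S @ self.W2                                 # (n, c, h)
        Q = M * (1.0 - A1 ** 2)[:, None, :]             # (n, c, h)
        J_W1 = (Q[:, :, :, None] * X[:, None, None, :]).reshape(n, c, h * p)
        J_b1 = Q
        J = np.concatenate(
            [J_W1, J_b1, J_W2.reshape(n, c, c * h), J_b2], axis=2
        ).reshape(n * c, self.n_weights) * scale
        return r, J


def _loss_value(P: np.ndarray, T: np.ndarray, kind: str) -> float:
    if kind == "mse":
        return float(np.mean((P - T) ** 2))
    eps = 1e-12
    return float(-np.mean(np.sum(T * np.log(P + eps), axis=1)))


# ---------------------------------------------------------------------------
# training algorithms (full-batch, one update per epoch)
# ---------------------------------------------------------------------------

def _train_loop(net, X, T, Xv, Tv, config: NetConfig):
    """Shared epoch loop with early stopping; the per-epoch step is chosen
    by the configured algorithm."""
    theta = net.get_theta()
    best_theta = theta.copy()
    best_val = net.loss(Xv, Tv, config.loss)
    curve: list[tuple[float, float]] = []
    fails = 0
    stopped = 0

    # per-algorithm state
    delta = np.full(theta.shape, RPROP_DELTA0)
    grad_prev = np.zeros_like(theta)
    velocity = np.zeros_like(theta)
    mu = 1e-3                     # LM damping
    scg = None                    # lazy SCG state

    for epoch in range(1, config.max_epochs + 1):
        if config.algorithm == "RPROP":
            train_loss, grad = net.loss_grad(X, T, config.loss)
            sign_change = grad * grad_prev
            delta[sign_change > 0] = np.minimum(
                delta[sign_change > 0] * RPROP_ETA_PLUS, RPROP_DELTA_MAX
            )
            delta[sign_change < 0] = np.maximum(
                delta[sign_change < 0] * RPROP_ETA_MINUS, RPROP_DELTA_MIN
            )
            grad = grad.copy()
            grad[sign_change < 0] = 0.0       # iRprop-
            theta = theta - np.sign(grad) * delta
            grad_prev = grad
            net.set_theta(theta)
        elif config.algorithm == "GDM":
            train_loss, grad = net.loss_grad(X, T, config.loss)
            velocity = config.momentum * velocity - config.learning_rate * grad
            theta = theta + velocity
            net.set_theta(theta)
        elif config.algorithm == "LM":
            train_loss, theta, mu, ok = _lm_step(net, X, T, theta, mu, config.loss)
            if not ok:
                stopped = epoch
                curve.append((train_loss, best_val))
                break
        else:  # SCG
            if scg is None:
                scg = _SCGState(net, X, T, config.loss)
            train_loss, theta, done = scg.step()
            if done:
                stopped = epoch
                curve.append((train_loss, scg.f_now))
                break

        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        val_loss = net.loss(Xv, Tv, config.loss)
        curve.append((train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails > config.patience:
                stopped = epoch
                break
        stopped = epoch

    net.set_theta(best_theta)
    return curve, stopped


def _lm_step(net, X, T, theta, mu, loss_kind):
    """One accepted Levenberg-Marquardt update (or a signal to stop)."""
    r, J = net.residual_jacobian(X, T)
    f0 = float(r @ r)
    JtJ = J.T @ J
    Jtr = J.T @ r
    eye = np.eye(len(theta))
    for _ in range(30):
        try:
            step = np.linalg.solve(JtJ + mu * eye, Jtr)
        except np.linalg.LinAlgError:
            mu *= 10.0
            continue
        cand = theta - step
        net.set_theta(cand)
        f1 = net.loss(X, T, "mse") if loss_kind == "mse" else net.loss(X, T, loss_kind)
        if f1 < f0:
            return f1, cand, max(mu * 0.1, 1e-12), True
        mu *= 10.0
        if mu > 1e10:
            break
    net.set_theta(theta)
    return f0, theta, mu, False


class _SCGState:
    """Moller's scaled conjugate gradient, one CG step per epoch."""

    def __init__(self, net, X, T, loss_kind, sigma0=5e-5, lam=5e-7):
        self.net, self.X, self.T, self.kind = net, X, T, loss_kind
        self.sigma0 = sigma0
        self.lam = lam
        self.lam_bar = 0.0
        self.theta = net.get_theta()
        self.f_now, grad = net.loss_grad(X, T, loss_kind)
        self.r = -grad
        self.p = self.r.copy()
        self.success = True
        self.delta = 0.0

    def step(self):
        net, X, T = self.net, self.X, self.T
        p_norm2 = float(self.p @ self.p)
        if p_norm2 < 1e-24:
            return self.f_now, self.theta, True
        if self.success:
            sigma = self.sigma0 / np.sqrt(p_norm2)
            net.set_theta(self.theta + sigma * self.p)
            _, grad_plus = net.loss_grad(X, T, self.kind)
            net.set_theta(self.theta)
            _, grad_now = net.loss_grad(X, T, self.kind)
            self.delta = float(self.p @ (grad_plus - grad_now)) / sigma
        delta = self.delta + (self.lam - self.lam_bar) * p_norm2
        if delta <= 0:
            self.lam_bar = 2.0 * (self.lam - delta / p_norm2)
            delta = -delta + self.lam * p_norm2
            self.lam = self.lam_bar
        mu = float(self.p @ self.r)
        alpha = mu / delta
        cand = self.theta + alpha * self.p
        net.set_theta(cand)
        f_cand = net.loss(X, T, self.kind)
        comparison = 2.0 * delta * (self.f_now - f_cand) / (mu ** 2)
        if comparison >= 0:
            self.theta = cand
            f_prev = self.f_now
            self.f_now, grad = net.loss_grad(X, T, self.kind)
            r_new = -grad
            self.lam_bar = 0.0
            self.success = True
            beta = (float(r_new @ r_new) - float(r_new @ self.r)) / mu
            self.p = r_new + beta * self.p
            self.r = r_new
            if comparison >= 0.75:
                self.lam = max(self.lam * 0.25, 1e-15)
            done = abs(f_prev - self.f_now) < 1e-14
            return self.f_now, self.theta, done
        else:
            net.set_theta(self.theta)
            self.lam_bar = self.lam
            self.success = False
        if comparison < 0.25:
            self.lam = min(self.lam + delta * (1 - comparison) / p_norm2, 1e15)
        return self.f_now, self.theta, False


# ---------------------------------------------------------------------------
# public training / prediction API
# ---------------------------------------------------------------------------

def train_mlp(
    X: np.ndarray,
    y: Sequence,
    config: NetConfig,
    X_val: np.ndarray | None = None,
    y_val: Sequence | None = None,
    scale: bool = True,
) -> TrainedNet:
    """Train one network; deterministic for fixed (data, config.seed).

    When ``X_val``/``y_val`` are omitted a stratified ``val_fraction`` of the
    training rows is held out internally for early stopping.  ``scale=True``
    fits the [-1, 1] scaler on the training rows and stores it on the net.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if config.n_outputs is not None and len(classes) != config.n_outputs:
        raise ValueError(
            f"y holds {len(classes)} classes but config expects {config.n_outputs}"
        )
    counts = np.array([(y == c).sum() for c in classes])
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 training rows")

    scaler = fit_scaler(X) if scale else None
    Xs = scaler.transform(X) if scaler else X

    y_idx = np.searchsorted(classes, y)
    if X_val is None:
        strat = y_idx if np.all(counts * config.val_fraction >= 1) else None
        tr, va = train_test_split(
            np.arange(len(y_idx)),
            test_size=config.val_fraction,
            random_state=config.seed % (2 ** 31),
            stratify=strat,
        )
        X_tr, X_va = Xs[tr], Xs[va]
        ytr_idx, yva_idx = y_idx[tr], y_idx[va]
    else:
        X_tr, ytr_idx = Xs, y_idx
        X_va = scaler.transform(np.asarray(X_val, dtype=float)) if scaler else np.asarray(X_val, float)
        yva_idx = np.searchsorted(classes, np.asarray(y_val))

    c = len(classes)
    T_tr = _one_hot(ytr_idx, c)
    T_va = _one_hot(yva_idx, c)
    rng = np.random.default_rng(config.seed)
    net = _Net(Xs.shape[1], config.n_hidden, c, rng)
    curve, stopped = _train_loop(net, X_tr, T_tr, X_va, T_va, config)
    return TrainedNet(
        config=config,
        classes=classes,
        W1=net.W1, b1=net.b1, W2=net.W2, b2=net.b2,
        scaler=scaler,
        train_curve=curve,
        stopped_epoch=stopped,
    )


def predict(net: TrainedNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities; ties go to the lower class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.W1.shape[1]:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"network expects {net.W1.shape[1]}"
        )
    Xs = net.scaler.transform(X) if net.scaler else X
    A1 = np.tanh(Xs @ net.W1.T + net.b1)
    P = _softmax(A1 @ net.W2.T + net.b2)
    labels = net.classes[np.argmax(P, axis=1)]
    return labels, P


def mse_on(net: TrainedNet, X: np.ndarray, y: Sequence) -> float:
    """Mean squared error of the softmax outputs against one-hot targets."""
    _, P = predict(net, X)
    y_idx = np.searchsorted(net.classes, np.asarray(y))
    return float(np.mean((P - _one_hot(y_idx, len(net.classes))) ** 2))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion(y_true, y_pred, class_labels: Sequence) -> ConfusionMatrix:
    """Count matrix with counts[r][c] = #(predicted r AND target c)."""
    labels = list(class_labels)
    lut = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        t = t.item() if hasattr(t, "item") else t
        p = p.item() if hasattr(p, "item") else p
        if t not in lut or p not in lut:
            raise ValueError(f"label {t!r}/{p!r} outside class_labels {labels}")
        counts[lut[p], lut[t]] += 1
    return ConfusionMatrix(counts, labels)


def _safe_div(a: float, b: float) -> float | None:
    return None if b == 0 else a / b


def metrics(cm: ConfusionMatrix, positive_class=None) -> MetricsReport:
    """Accuracy/error plus the sensitivity/specificity/precision/FPR panel.

    For multiclass matrices the scalar panel is one-vs-rest for
    ``positive_class``; ``per_class`` carries precision and recall for every
    class either way.
    """
    counts = cm.counts
    n = cm.n
    acc = float(np.trace(counts)) / n if n else 0.0
    labels = cm.class_labels
    if positive_class is None:
        positive_class = labels[0]
    if positive_class not in labels:
        raise ValueError(f"{positive_class!r} not among {labels}")
    p = labels.index(positive_class)
    tp = float(counts[p, p])
    fp = float(counts[p, :].sum() - tp)   # predicted positive, target other
    fn = float(counts[:, p].sum() - tp)   # target positive, predicted other
    tn = float(n - tp - fp - fn)
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    per_class = {}
    for i, lab in enumerate(labels):
        tpi = float(counts[i, i])
        per_class[lab] = {
            "precision": _safe_div(tpi, float(counts[i, :].sum())),
            "recall": _safe_div(tpi, float(counts[:, i].sum())),
        }
    return MetricsReport(
        acc=acc,
        err=1.0 - acc,
        sn=sn,
        sp=sp,
        prec=_safe_div(tp, tp + fp),
        fpr=_safe_div(fp, fp + tn),
        per_class=per_class,
    )


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    config: NetConfig,
    scheme: str = "KFOLD",
    k: int = 5,
    seed: int | None = None,
    smote_amounts: Mapping[Hashable, int] | None = None,
    smote_k_neighbors: int = 5,
) -> CVResult:
    """Cross-validate the network; SMOTE (if any) is applied inside each
    training fold only, never to test rows.

    ``HOLDOUT`` is a single stratified 70/15/15 train/validation/test split;
    ``KFOLD`` is stratified when every class holds at least k members;
    ``LOO`` is leave-one-out.  The pooled confusion matrix aggregates every
    test prediction.
    """
    from .balance import LabeledFeatureMatrix, smote as _smote

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if seed is None:
        seed = config.seed
    seed = int(seed) % (2 ** 31)
    classes = np.unique(y)
    scheme = scheme.upper()

    y_codes = np.searchsorted(classes, y)  # splitters want categorical labels
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "HOLDOUT":
        idx = np.arange(len(y))
        trval, test = train_test_split(
            idx, test_size=0.15, random_state=seed, stratify=y_codes
        )
        folds.append((trval, test))
    elif scheme == "KFOLD":
        if k < 2 or k > len(y):
            raise ValueError("KFOLD needs 2 <= k <= n")
        min_count = min((y == c).sum() for c in classes)
        splitter = (
            StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            if min_count >= k
            else KFold(n_splits=k, shuffle=True, random_state=seed)
        )
        folds = [(tr, te) for tr, te in splitter.split(X, y_codes)]
    elif scheme == "LOO":
        folds = [(tr, te) for tr, te in LeaveOneOut().split(X)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    fold_mse: list[float] = []
    fold_acc: list[float] = []
    y_true_all: list = []
    y_pred_all: list = []
    for f, (tr, te) in enumerate(folds):
        y_tr = y[tr]
        if len(np.unique(y_tr)) < len(classes):
            warnings.warn(f"fold {f}: a class is absent from training; skipped",
                          stacklevel=2)
            continue
        X_tr = X[tr]
        if smote_amounts:
            amounts = {c: a for c, a in smote_amounts.items() if np.any(y_tr == c)}
            lab = LabeledFeatureMatrix(X_tr, y_tr, feature_names=[
                f"f{i}" for i in range(X.shape[1])
            ])
            bal = _smote(lab, amounts, k_neighbors=smote_k_neighbors, seed=seed + f)
            X_tr, y_tr = bal.X, bal.y
        overrides: dict = {"seed": config.seed + f}
        if scheme == "HOLDOUT":
            # 15% of all rows for validation out of the 85% kept for training
            overrides["val_fraction"] = 0.15 / 0.85
        cfg = NetConfig(**{**asdict(config), **overrides})
        net = train_mlp(X_tr, y_tr, cfg)
        pred, _ = predict(net, X[te])
        fold_mse.append(mse_on(net, X[te], y[te]))
        fold_acc.append(float(np.mean(pred == y[te])))
        y_true_all.extend(y[te].tolist())
        y_pred_all.extend(pred.tolist())

    cm = confusion(y_true_all, y_pred_all, classes.tolist())
    return CVResult(
        scheme=f"{scheme}({k})" if scheme == "KFOLD" else scheme,
        fold_mse=fold_mse,
        fold_accuracy=fold_acc,
        confusion=cm,
        mean_mse=float(np.mean(fold_mse)),
        mean_accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=float(np.mean(np.asarray(y_pred_all) == np.asarray(y_true_all))),
    )


def architecture_search(
    X: np.ndarray,
    y: Sequence,
    hidden_grid: Sequence[int],
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    base_config: NetConfig | None = None,
) -> tuple[NetConfig, list[dict]]:
    """Grid search over (algorithm, hidden units) with hold-out validation.

    Every cell trains once on a stratified 70/15/15 split and is scored by
    its best validation loss; the winner is the lowest validation loss with
    ties broken toward fewer hidden units.  Returns (best config, table).
    """
    if not hidden_grid:
        raise ValueError("hidden_grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    idx = np.arange(len(y))
    trval, test = train_test_split(idx, test_size=0.15, random_state=seed,
                                   stratify=np.searchsorted(classes, y))
    base = base_config or NetConfig()
    table: list[dict] = []
    for alg in algorithms:
        for h in hidden_grid:
            cfg = NetConfig(**{**asdict(base),
                               "algorithm": alg, "n_hidden": int(h), "seed": seed})
            net = train_mlp(X[trval], y[trval], cfg)
            val_mse = min(v for _, v in net.train_curve) if net.train_curve else np.inf
            test_pred, _ = predict(net, X[test])
            table.append({
                "algorithm": alg,
                "n_hidden": int(h),
                "val_mse": float(val_mse),
                "test_accuracy": float(np.mean(test_pred == y[test])),
            })
    best_row = min(table, key=lambda r: (r["val_mse"], r["n_hidden"]))
    best = NetConfig(**{**asdict(base),
                        "algorithm": best_row["algorithm"],
                        "n_hidden": best_row["n_hidden"],
                        "seed": seed})
    return best, table


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_net(net: TrainedNet, path: str | Path) -> None:
    """Serialize a trained network (weights, scaler, config) to JSON."""
    blob = {
        "config": asdict(net.config),
        "classes": net.classes.tolist(),
        "W1": net.W1.tolist(), "b1": net.b1.tolist(),
        "W2": net.W2.tolist(), "b2": net.b2.tolist(),
        "scaler": None if net.scaler is None else
                  {"lo": net.scaler.lo.tolist(), "hi": net.scaler.hi.tolist()},
        "train_curve": net.train_curve,
        "stopped_epoch": net.stopped_epoch,
    }
    Path(path).write_text(json.dumps(blob))


def load_net(path: str | Path) -> TrainedNet:
    blob = json.loads(Path(path).read_text())
    scaler = blob["scaler"]
    return TrainedNet(
        config=NetConfig(**blob["config"]),
        classes=np.asarray(blob["classes"]),
        W1=np.asarray(blob["W1"]), b1=np.asarray(blob["b1"]),
        W2=np.asarray(blob["W2"]), b2=np.asarray(blob["b2"]),
        scaler=None if scaler is None else
               MinMaxScaler(np.asarray(scaler["lo"]), np.asarray(scaler["hi"])),
        train_curve=[tuple(t) for t in blob["train_curve"]],
        stopped_epoch=blob["stopped_epoch"],
    )
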