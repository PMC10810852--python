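"""Hypernetwork-weighted adaptive logistic regression (NN-log-reg).

The classifier is a logistic regression over a cell's expression vector
``x`` whose per-gene weights are produced, for that same cell, by a
hypernetwork:

    output = sigmoid(bias_D + w_D * (hypernet(x)^T x))
    hypernet(x) = softmax(sigmoid(bias_C + W_C tanh(bias_B + W_B tanh(bias_A + W_A x))))

The softmax runs over the gene axis, so ``hypernet(x)`` is a per-cell
probability vector of adaptive (attention) weights — one weight per gene,
summing to one — which doubles as the per-cell feature-importance vector.

Everything here is plain numpy: forward passes, analytic backpropagation,
Adam, early stopping. A standard feed-forward SELU network of the same
training contract is provided as a baseline.

The statsmodels-style entry points are :class:`AdaptiveLogisticRegression`
and :class:`StandardANN`; both ``.fit()`` into a :class:`FitResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .data import LabeledDataset, split_by_donor

__all__ = [
    "HyperNetParams",
    "TrainConfig",
    "RocResult",
    "FitResults",
    "AdaptiveLogisticRegression",
    "StandardANN",
    "hypernet_forward",
    "model_forward",
    "bce_loss",
    "predict_proba",
    "roc",
]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


# ---------------------------------------------------------------------------
# parameters and configuration


@dataclass
class HyperNetParams:
    """All weights and biases of the NN-log-reg.

    Shapes: ``W_A (H, G)``, ``W_B (H, H)``, ``W_C (G, H)``, biases matching
    their layer widths, and a scalar affine head ``w_D``/``bias_D``.
    """

    W_A: np.ndarray
    bias_A: np.ndarray
    W_B: np.ndarray
    bias_B: np.ndarray
    W_C: np.ndarray
    bias_C: np.ndarray
    w_D: float
    bias_D: float

    def __post_init__(self) -> None:
        for name in ("W_A", "bias_A", "W_B", "bias_B", "W_C", "bias_C"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        h, g = self.W_A.shape
        expected = {
            "bias_A": (h,),
            "W_B": (h, h),
            "bias_B": (h,),
            "W_C": (g, h),
            "bias_C": (g,),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise ValueError(f"{name} has shape {actual}, expected {shape}")

    @property
    def n_genes(self) -> int:
        return self.W_A.shape[1]

    @property
    def hidden(self) -> int:
        return self.W_A.shape[0]

    @classmethod
    def zeros(cls, n_genes: int, hidden: int) -> "HyperNetParams":
        return cls(
            W_A=np.zeros((hidden, n_genes)),
            bias_A=np.zeros(hidden),
            W_B=np.zeros((hidden, hidden)),
            bias_B=np.zeros(hidden),
            W_C=np.zeros((n_genes, hidden)),
            bias_C=np.zeros(n_genes),
            w_D=0.0,
            bias_D=0.0,
        )

    @classmethod
    def init_random(
        cls,
        n_genes: int,
        hidden: int,
        rng: np.random.Generator,
        input_scale: float = 1.0,
    ) -> "HyperNetParams":
        """Fan-in-scaled uniform initialisation, seeded.

        ``input_scale`` (the RMS of the training inputs) additionally damps
        the first layer so its tanh units start in the linear regime for
        raw normalised expression values, which are far from unit scale.
        """

        def layer(fan_out: int, fan_in: int, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
            bound = 1.0 / (np.sqrt(fan_in) * scale)
            w = rng.uniform(-bound, bound, size=(fan_out, fan_in))
            b = rng.uniform(-bound, bound, size=fan_out)
            return w, b

        W_A, bias_A = layer(hidden, n_genes, max(input_scale, 1.0))
        W_B, bias_B = layer(hidden, hidden)
        W_C, bias_C = layer(n_genes, hidden)
        w_D = float(rng.uniform(-1.0, 1.0))
        bias_D = 0.0
        return cls(W_A, bias_A, W_B, bias_B, W_C, bias_C, w_D, bias_D)

    def to_dict(self) -> dict[str, np.ndarray | float]:
        return {
            "W_A": self.W_A,
            "bias_A": self.bias_A,
            "W_B": self.W_B,
            "bias_B": self.bias_B,
            "W_C": self.W_C,
            "bias_C": self.bias_C,
            "w_D": self.w_D,
            "bias_D": self.bias_D,
        }

    def copy(self) -> "HyperNetParams":
        return HyperNetParams(
            self.W_A.copy(), self.bias_A.copy(), self.W_B.copy(), self.bias_B.copy(),
            self.W_C.copy(), self.bias_C.copy(), float(self.w_D), float(self.bias_D),
        )


@dataclass
class TrainConfig:
    """Training hyperparameters; every field is overridable from config files.

    Defaults: full-batch Adam at learning rate 1e-2, at most 300 epochs
    with early stopping (patience 100 without improvement of the selection
    metric), donor split 0.6/0.2/0.2, expression values used as given
    (``log1p=False``). Parameters are returned from the epoch with the best
    validation ROC AUC (``selection="auc"``); ``selection="loss"`` selects
    on validation cross-entropy instead.

    ``hypernet_decay`` is an L2 penalty restricted to the input-side weight
    matrices (the hypernetwork's W_A and W_B; the hidden layers of the
    baseline network). It damps the cell-fingerprint memorisation pathway
    while leaving the per-gene attention parameters (W_C, bias_C) free, and
    is the main regulariser at single-cell sample sizes.
    """

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    epochs: int = 300
    learning_rate: float = 1e-2
    batch_size: int | None = None
    seed: int = 0
    patience: int = 100
    selection: str = "auc"
    log1p: bool = False
    weight_decay: float = 0.0
    hypernet_decay: float = 10.0
    clamp: float = 1e-12

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1) > 1e-9:
            raise ValueError(f"split fractions must be positive and sum to 1: {self.fractions}")
        if self.epochs < 1 or self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("epochs, learning_rate and patience must be positive")
        if self.selection not in ("auc", "loss"):
            raise ValueError(f"selection must be 'auc' or 'loss', got {self.selection!r}")


# ---------------------------------------------------------------------------
# numerics


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(u: np.ndarray) -> np.ndarray:
    shifted = u - u.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _hypernet_cache(params: HyperNetParams, X: np.ndarray):
    """Forward pass keeping intermediates for backprop."""
    H1 = np.tanh(X @ params.W_A.T + params.bias_A)
    H2 = np.tanh(H1 @ params.W_B.T + params.bias_B)
    U = _sigmoid(H2 @ params.W_C.T + params.bias_C)
    A = _softmax(U)
    return H1, H2, U, A


def hypernet_forward(params: HyperNetParams, x: np.ndarray) -> np.ndarray:
    """Adaptive weights ``softmax(sigmoid(...))`` for one cell or a batch.

    Returns a vector (or row-wise matrix) of strictly positive weights
    summing to one over the gene axis.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.n_genes:
        raise ValueError(f"input has {X.shape[1]} genes, model expects {params.n_genes}")
    A = _hypernet_cache(params, X)[3]
    return A[0] if single else A


def model_forward(params: HyperNetParams, x: np.ndarray) -> float | np.ndarray:
    """Malignancy probability ``sigmoid(bias_D + w_D * hypernet(x)^T x)``."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    A = hypernet_forward(params, X)
    p = _sigmoid(params.bias_D + params.w_D * np.sum(A * X, axis=1))
    return float(p[0]) if single else p


def predict_proba(params: HyperNetParams, matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`model_forward` over a cells x genes matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != params.n_genes:
        raise ValueError(
            f"matrix shape {matrix.shape} incompatible with G={params.n_genes}"
        )
    return model_forward(params, matrix)


def bce_loss(p: np.ndarray, y: np.ndarray, clamp: float = 1e-12) -> float:
    """Mean binary cross-entropy, with probabilities clamped away from 0/1."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probabilities vs {y.shape} targets")
    pc = np.clip(p, clamp, 1.0 - clamp)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def _loss_and_grads(params: HyperNetParams, X: np.ndarray, y: np.ndarray, clamp: float = 1e-12):
    """Mean BCE and its analytic gradients w.r.t. every parameter."""
    n = X.shape[0]
    H1, H2, U, A = _hypernet_cache(params, X)
    t = np.sum(A * X, axis=1)
    p = _sigmoid(params.bias_D + params.w_D * t)
    loss = bce_loss(p, y, clamp)

    dz = (p - y) / n                                   # dL/dz, z the pre-sigmoid head
    g_bias_D = float(dz.sum())
    g_w_D = float(dz @ t)
    dA = (dz * params.w_D)[:, None] * X                # through the weighted sum
    dU = A * (dA - np.sum(dA * A, axis=1, keepdims=True))   # softmax Jacobian
    dS = dU * U * (1.0 - U)                            # sigmoid
    g_W_C = dS.T @ H2
    g_bias_C = dS.sum(axis=0)
    dH2 = dS @ params.W_C
    dP2 = dH2 * (1.0 - H2 * H2)                        # tanh
    g_W_B = dP2.T @ H1
    g_bias_B = dP2.sum(axis=0)
    dH1 = dP2 @ params.W_B
    dP1 = dH1 * (1.0 - H1 * H1)
    g_W_A = dP1.T @ X
    g_bias_A = dP1.sum(axis=0)

    grads = {
        "W_A": g_W_A, "bias_A": g_bias_A,
        "W_B": g_W_B, "bias_B": g_bias_B,
        "W_C": g_W_C, "bias_C": g_bias_C,
        "w_D": g_w_D, "bias_D": g_bias_D,
    }
    return loss, grads


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    """A receiver operating characteristic curve and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores: np.ndarray, targets: np.ndarray) -> RocResult:
    """ROC curve and AUC; AUC is the probability a random positive outscores
    a random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=np.float64)
    targets = np.asarray(targets)
    classes = np.unique(targets)
    if len(classes) != 2:
        raise ValueError(f"ROC needs both classes present, got classes {classes}")
    fpr, tpr, thresholds = roc_curve(targets, scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds,
                     auc=float(roc_auc_score(targets, scores)))


# ---------------------------------------------------------------------------
# optimiser


class _Adam:
    """Adam with optional decoupled (AdamW-style) weight decay on the
    matrix-valued parameters; biases and scalars are never decayed."""

    def __init__(self, shapes: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decayed = {k for k, v in shapes.items() if np.ndim(v) == 2}
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in shapes.items()}
        self.t = 0

    def step(self, values: dict, grads: dict) -> dict:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        out = {}
        for k, val in values.items():
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            new = val - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k in self.decayed:
                new = new - self.lr * self.weight_decay * val
            out[k] = new
        return out


def _run_training(forward_loss_grads, params_dict, apply_fn, X_tr, y_tr,
                  X_val, y_val, config: TrainConfig, rng: np.random.Generator):
    """Generic Adam loop with early stopping on validation loss.

    ``forward_loss_grads(params_dict, X, y) -> (loss, grads)`` and
    ``apply_fn(params_dict, X) -> probabilities`` abstract over the two
    architectures. Returns (best params_dict, history DataFrame, best_epoch).
    """
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class; cannot fit")
    opt = _Adam(params_dict, lr=config.learning_rate, weight_decay=config.weight_decay)
    best = {k: np.copy(v) for k, v in params_dict.items()}
    best_metric = np.inf  # lower is better for both selection modes
    best_epoch = 0
    rows = []
    stale = 0
    n = X_tr.shape[0]
    for epoch in range(1, config.epochs + 1):
        if config.batch_size is None or config.batch_size >= n:
            loss, grads = forward_loss_grads(params_dict, X_tr, y_tr)
            params_dict = opt.step(params_dict, grads)
            train_loss = loss
        else:
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, grads = forward_loss_grads(params_dict, X_tr[idx], y_tr[idx])
                params_dict = opt.step(params_dict, grads)
                losses.append(loss)
            train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"training loss diverged (non-finite) at epoch {epoch}")
        row = {"epoch": epoch, "train_loss": train_loss}
        if X_val is not None and len(X_val):
            p_val = apply_fn(params_dict, X_val)
            val_loss = bce_loss(p_val, y_val, config.clamp)
            row["val_loss"] = val_loss
            if config.selection == "auc" and len(np.unique(y_val)) == 2:
                val_auc = float(roc_auc_score(y_val, p_val))
                row["val_auc"] = val_auc
                metric = -val_auc
            else:
                metric = val_loss
            if metric < best_metric - 1e-12:
                best_metric = metric
                best = {k: np.copy(v) for k, v in params_dict.items()}
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    rows.append(row)
                    break
        else:
            best = {k: np.copy(v) for k, v in params_dict.items()}
            best_epoch = epoch
        rows.append(row)
    return best, pd.DataFrame(rows), best_epoch


# ---------------------------------------------------------------------------
# model / results objects


class AdaptiveLogisticRegression:
    """NN-log-reg model over a labeled expression dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        Full dataset; TCR genes should already be excluded
        (:func:`clonomark.data.drop_tcr_genes`).
    hidden : int
        Hypernetwork hidden width H (1000 at full scale; small widths are
        fine at desk scale).

    ``fit`` splits donors into train/validation/test, minimises binary
    cross-entropy with Adam, and returns a :class:`FitResults`.
    """

    baseline = False

    def __init__(self, dataset: LabeledDataset, hidden: int = 1000):
        self.dataset = dataset
        self.hidden = int(hidden)

    def _init_params(self, n_genes: int, rng: np.random.Generator,
                     input_scale: float = 1.0) -> dict:
        params = HyperNetParams.init_random(n_genes, self.hidden, rng, input_scale).to_dict()
        # start with near-uniform attention: any top-rank structure that
        # develops is then learned signal, not initialisation noise
        params["W_C"] = params["W_C"] * 0.01
        params["bias_C"] = params["bias_C"] * 0.01
        return params

    @staticmethod
    def _wrap(params_dict: dict) -> HyperNetParams:
        return HyperNetParams(**params_dict)

    def _loss_grads(self, params_dict: dict, X, y):
        return _loss_and_grads(self._wrap(params_dict), X, y)

    def _apply(self, params_dict: dict, X):
        return predict_proba(self._wrap(params_dict), X)

    def _decay_keys(self) -> tuple[str, ...]:
        return ("W_A", "W_B")

    @staticmethod
    def _calibrate_head(params_dict: dict, X, y) -> None:
        """Start the affine head at the class prior.

        ``w_D`` begins small and positive and ``bias_D`` offsets the nearly
        constant attention-weighted input so that initial predictions sit at
        the training base rate; without this the optimiser spends most of
        its budget walking the head into calibration while the attention
        parameters receive no usable gradient.
        """
        ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        params_dict["w_D"] = 1.0
        params_dict["bias_D"] = float(np.log(ybar / (1 - ybar)) - X.mean())

    def fit(
        self,
        config: TrainConfig | None = None,
        *,
        splits: tuple[LabeledDataset, LabeledDataset, LabeledDataset] | None = None,
    ) -> "FitResults":
        config = config or TrainConfig()
        if splits is None:
            splits = split_by_donor(self.dataset, config.fractions, seed=config.seed)
        train_ds, val_ds, test_ds = splits
        tf = np.log1p if config.log1p else (lambda m: m)
        X_tr, y_tr = tf(train_ds.matrix), train_ds.targets.astype(np.float64)
        X_val = tf(val_ds.matrix) if val_ds.n_cells else None
        y_val = val_ds.targets.astype(np.float64) if val_ds.n_cells else None
        rng = np.random.default_rng(config.seed)
        input_scale = float(np.sqrt(np.mean(X_tr**2)))
        params_dict = self._init_params(X_tr.shape[1], rng, input_scale)
        self._calibrate_head(params_dict, X_tr, y_tr)

        decay_keys = self._decay_keys()
        base_loss_grads = self._loss_grads

        def loss_grads(p, X, y):
            loss, grads = base_loss_grads(p, X, y)
            if config.hypernet_decay:
                for k in decay_keys:
                    grads[k] = grads[k] + config.hypernet_decay * p[k]
            return loss, grads

        best, history, best_epoch = _run_training(
            loss_grads, params_dict, self._apply,
            X_tr, y_tr, X_val, y_val, config, rng,
        )
        return FitResults(
            model=self,
            params=self._wrap(best) if not self.baseline else best,
            history=history,
            best_epoch=best_epoch,
            config=config,
            train=train_ds,
            validation=val_ds,
            test=test_ds,
        )


class StandardANN(AdaptiveLogisticRegression):
    """Baseline feed-forward classifier with the same training contract.

    Five linear layers (widths 1000, 1000, 1000, 32 and 1 by default) with
    SELU activations between hidden layers and a final sigmoid. Unlike the
    NN-log-reg it yields no per-gene adaptive weights.
    """

    baseline = True

    def __init__(self, dataset: LabeledDataset, widths: tuple[int, ...] = (1000, 1000, 1000, 32)):
        self.dataset = dataset
        self.widths = tuple(int(w) for w in widths)

    def _init_params(self, n_genes: int, rng: np.random.Generator,
                     input_scale: float = 1.0) -> dict:
        sizes = [n_genes, *self.widths, 1]
        params = {}
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = 1.0 / (np.sqrt(fan_in) * (max(input_scale, 1.0) if i == 0 else 1.0))
            params[f"W{i}"] = rng.uniform(-bound, bound, size=(fan_out, fan_in))
            params[f"b{i}"] = rng.uniform(-bound, bound, size=fan_out)
        return params

    @property
    def _n_layers(self) -> int:
        return len(self.widths) + 1

    def _decay_keys(self) -> tuple[str, ...]:
        return tuple(f"W{i}" for i in range(self._n_layers - 1))

    @staticmethod
    def _calibrate_head(params_dict: dict, X, y) -> None:
        ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        last = max(int(k[1:]) for k in params_dict if k.startswith("b"))
        params_dict[f"b{last}"][:] = np.log(ybar / (1 - ybar))

    def _forward_cache(self, params: dict, X: np.ndarray):
        acts = [X]  # post-activation of each layer, acts[0] the input
        pres = []
        a = X
        for i in range(self._n_layers):
            z = a @ params[f"W{i}"].T + params[f"b{i}"]
            pres.append(z)
            if i < self._n_layers - 1:
                a = _selu(z)
            else:
                a = _sigmoid(z)
            acts.append(a)
        return pres, acts

    def _apply(self, params: dict, X):
        X = np.asarray(X, dtype=np.float64)
        return self._forward_cache(params, X)[1][-1][:, 0]

    def _loss_grads(self, params: dict, X, y):
        n = X.shape[0]
        pres, acts = self._forward_cache(params, X)
        p = acts[-1][:, 0]
        loss = bce_loss(p, y)
        grads = {}
        delta = ((p - y) / n)[:, None]  # through sigmoid+BCE
        for i in reversed(range(self._n_layers)):
            grads[f"W{i}"] = delta.T @ acts[i]
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ params[f"W{i}"]) * _selu_grad(pres[i - 1])
        return loss, grads


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


@dataclass
class FitResults:
    """A fitted classifier: parameters at the best validation loss, the
    loss history, the donor splits it was fitted on, and evaluation helpers."""

    model: AdaptiveLogisticRegression
    params: HyperNetParams | dict
    history: pd.DataFrame
    best_epoch: int
    config: TrainConfig
    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset

    # -- prediction ---------------------------------------------------------

    def _transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.log1p(matrix) if self.config.log1p else np.asarray(matrix, dtype=np.float64)

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Malignancy probabilities for a cells x genes matrix."""
        X = self._transform(matrix)
        if isinstance(self.params, HyperNetParams):
            return predict_proba(self.params, X)
        return self.model._apply(self.params, X)

    def adaptive_weights(self, matrix: np.ndarray) -> np.ndarray:
        """Per-cell adaptive (attention) weight vectors; NN-log-reg only."""
        if not isinstance(self.params, HyperNetParams):
            raise AttributeError("the baseline network has no adaptive weights")
        return hypernet_forward(self.params, self._transform(matrix))

    # -- evaluation ---------------------------------------------------------

    def roc(self, which: str = "test") -> RocResult:
        ds = {"train": self.train, "validation": self.validation, "test": self.test}[which]
        return roc(self.predict(ds.matrix), ds.targets)

    def aucs(self) -> dict[str, float]:
        out = {}
        for which in ("train", "validation", "test"):
            try:
                out[which] = self.roc(which).auc
            except ValueError:
                out[which] = float("nan")
        return out

    def plot_roc(self, ax=None, which=("train", "validation", "test")):
        """ROC curves for the fitted splits on a matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for w in which:
            try:
                r = self.roc(w)
            except ValueError:
                continue
            ax.plot(r.fpr, r.tpr, label=f"{w} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text fit summary table."""
        kind = "StandardANN" if self.model.baseline else "AdaptiveLogisticRegression"
        aucs = self.aucs()
        lines = [
            f"{kind} fit results",
            "=" * 48,
            f"{'cells (train/val/test)':<28}"
            f"{self.train.n_cells}/{self.validation.n_cells}/{self.test.n_cells}",
            f"{'donors (train/val/test)':<28}"
            f"{len(set(self.train.donor_ids))}/{len(set(self.validation.donor_ids))}/"
            f"{len(set(self.test.donor_ids))}",
            f"{'genes':<28}{self.train.n_genes}",
            f"{'epochs run':<28}{len(self.history)}",
            f"{'best epoch (selection)':<28}{self.best_epoch}",
            f"{'final train loss':<28}{self.history['train_loss'].iloc[-1]:.6f}",
        ]
        if "val_loss" in self.history:
            lines.append(f"{'best val loss':<28}{self.history['val_loss'].min():.6f}")
        for which in ("train", "validation", "test"):
            lines.append(f"{'AUC ' + which:<28}{aucs[which]:.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialise parameters, gene names and config to one ``.npz`` archive."""
        if isinstance(self.params, HyperNetParams):
            arrays = {k: np.asarray(v) for k, v in self.params.to_dict().items()}
            arrays["__kind__"] = np.array("nn_logreg")
        else:
            arrays = {k: np.asarray(v) for k, v in self.params.items()}
            arrays["__kind__"] = np.array("standard_ann")
        arrays["__genes__"] = np.array(self.train.gene_names)
        arrays["__config__"] = np.array(json.dumps({
            "log1p": self.config.log1p,
            "seed": self.config.seed,
            "learning_rate": self.config.learning_rate,
            "epochs": self.config.epochs,
            "patience": self.config.patience,
        }))
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)


def load_params(path) -> tuple[HyperNetParams | dict, list[str], dict]:
    """Load a serialised model archive; returns (params, gene_names, config)."""
    with np.load(path, allow_pickle=False) as npz:
        kind = str(npz["__kind__"])
        genes = [str(g) for g in npz["__genes__"]]
        cfg = json.loads(str(npz["__config__"]))
        arrays = {k: npz[k] for k in npz.files if not k.startswith("__")}
    if kind == "nn_logreg":
        arrays["w_D"] = float(arrays["w_D"])
        arrays["bias_D"] = float(arrays["bias_D"])
        return HyperNetParams(**arrays), genes, cfg
    return arrays, genes, cfg
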