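"""The classifier suite and its shared training protocol.

Four model kinds span the linear/non-linear divide on equal footing:

* ``logreg`` — ridge logistic regression (single affine map, softmax
  cross-entropy, L2 via weight decay);
* ``linear_svm`` — an affine map trained with a one-vs-rest hinge loss
  by the same mini-batch optimizer (not a dual/kernel solver);
* ``mlp3`` — a three-layer fully connected network, hidden widths
  2500 and 1250, ReLU and dropout 0.5;
* ``mlp5`` — a five-layer network, hidden widths 2500/2500/2500/1250,
  ReLU, dropout 0.5 and batch normalization on every hidden layer.

All four share one protocol: at most 50 epochs of mini-batch gradient
descent with Adam, inverse-class-frequency loss weighting, global
gradient-norm clipping, and early stopping on a held-out set with the
best-epoch weights restored. Everything — initialization, batch order,
dropout masks — is a pure function of the seeds, so a full train +
predict run is bit-for-bit reproducible, and two identically initialized
copies of a model are obtained by building twice with the same seed.

The stack is implemented directly on NumPy arrays (float32 matmuls
dominate the cost) with hand-written backward passes for the affine,
ReLU, dropout and batch-norm layers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rng import substream

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainConfig",
    "HyperparameterGrid",
    "build_model",
    "train",
    "predict",
    "nested_cv_select",
    "parameter_count",
    "write_training_log",
    "save_checkpoint",
    "load_checkpoint",
]

MODEL_KINDS = ("logreg", "linear_svm", "mlp3", "mlp5")

_HIDDEN = {
    "logreg": (),
    "linear_svm": (),
    "mlp3": (2500, 1250),
    "mlp5": (2500, 2500, 2500, 1250),
}

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice. Hidden widths, dropout and batch norm are
    implied by ``kind`` and not independently tunable."""

    kind: str
    input_dim: int
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.input_dim < 1 or self.n_classes < 2:
            raise ValueError("need input_dim >= 1 and n_classes >= 2")

    @property
    def hidden_dims(self) -> tuple:
        return _HIDDEN[self.kind]

    @property
    def dropout_p(self) -> float:
        return 0.5 if self.hidden_dims else 0.0

    @property
    def batch_norm(self) -> bool:
        return self.kind == "mlp5"

    @property
    def is_linear(self) -> bool:
        return not self.hidden_dims


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the fixed training protocol (defaults noted in docs/methods)."""

    max_epochs: int = 50
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    early_stopping_patience: int = 10
    gradient_clip_norm: float = 1.0
    class_weighting: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")
        if self.gradient_clip_norm <= 0:
            raise ValueError("gradient_clip_norm must be positive")


@dataclass(frozen=True)
class HyperparameterGrid:
    learning_rates: tuple = (1e-4, 1e-3, 1e-2)
    weight_decays: tuple = (0.0, 1e-4, 1e-2)

    def points(self) -> list[tuple[float, float]]:
        if not self.learning_rates or not self.weight_decays:
            raise ValueError("hyperparameter grid must be non-empty")
        return [(lr, wd) for lr in self.learning_rates for wd in self.weight_decays]


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------


class _Affine:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, scale: float):
        if scale == 0.0:
            self.W = np.zeros((n_in, n_out), dtype=_DTYPE)
        else:
            self.W = (rng.normal(size=(n_in, n_out)) * scale).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def buffers(self):
        return []


class _ReLU:
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def buffers(self):
        return []


class _Dropout:
    """Inverted dropout: active only in training mode, identity at eval."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(_DTYPE) / _DTYPE(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []

    def buffers(self):
        return []


class _BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=_DTYPE)
        self.beta = np.zeros(dim, dtype=_DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim, dtype=_DTYPE)
        self.running_var = np.ones(dim, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_DTYPE)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._istd
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, dout):
        m = dout.shape[0]
        self.dgamma[...] = (dout * self._xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (
            self._istd / m * (m * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))
        ).astype(_DTYPE)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def set_buffers(self, arrays):
        self.running_mean, self.running_var = arrays


class Model:
    """A parameterized map from feature vectors to per-class scores."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = substream(seed, f"init/{spec.kind}")
        dims = (spec.input_dim, *spec.hidden_dims)
        self.layers: list = []
        for i in range(len(spec.hidden_dims)):
            # He initialization for ReLU hidden layers
            self.layers.append(_Affine(rng, dims[i], dims[i + 1], np.sqrt(2.0 / dims[i])))
            if spec.batch_norm:
                self.layers.append(_BatchNorm(dims[i + 1]))
            self.layers.append(_ReLU())
            self.layers.append(_Dropout(spec.dropout_p))
        # the output layer starts at zero: initial class scores are uniform,
        # so the first optimizer steps follow the systematic class signal
        # instead of first having to erase random initial logits
        self.layers.append(_Affine(rng, dims[-1], spec.n_classes, 0.0))

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        out = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dscores: np.ndarray) -> None:
        dout = dscores.astype(_DTYPE)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def params(self):
        return [pg for layer in self.layers for pg in layer.params()]

    def state_arrays(self) -> list[np.ndarray]:
        out = [p for p, _ in self.params()]
        for layer in self.layers:
            out.extend(layer.buffers())
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(own, arrays):
            dst[...] = src

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Initialize a model; a pure function of (spec, seed)."""
    return Model(spec, seed)


def parameter_count(spec: ModelSpec) -> int:
    """Trainable parameter count implied by the spec (batch-norm gains and
    biases included)."""
    return build_model(spec, 0).n_parameters()


# --------------------------------------------------------------------------
# losses (value + gradient w.r.t. the score matrix)
# --------------------------------------------------------------------------


def _softmax_xent(scores, y, sample_w):
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(y)
    wsum = sample_w.sum()
    loss = -(sample_w * logp[np.arange(n), y]).sum() / wsum
    dz = np.exp(logp)
    dz[np.arange(n), y] -= 1.0
    dz *= (sample_w / wsum)[:, None]
    return float(loss), dz


def _ovr_hinge(scores, y, sample_w):
    n, L = scores.shape
    t = -np.ones((n, L), dtype=scores.dtype)
    t[np.arange(n), y] = 1.0
    margin = 1.0 - t * scores
    active = margin > 0
    wsum = sample_w.sum()
    loss = ((margin * active).sum(axis=1) * sample_w).sum() / wsum
    dz = (-t * active) * (sample_w / wsum)[:, None]
    return float(loss), dz


def _loss_fn(kind: str):
    return _ovr_hinge if kind == "linear_svm" else _softmax_xent


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.params):
            grad = g + self.wd * p if self.wd else g
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad**2
            p -= (self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)).astype(p.dtype)


def _clip_gradients(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for _, g in params))
    if total > max_norm:
        scale = _DTYPE(max_norm / (total + 1e-12))
        for _, g in params:
            g *= scale


def _class_weights(y: np.ndarray, n_classes: int, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones(n_classes, dtype=_DTYPE)
    counts = np.bincount(y, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = len(y) / (n_classes * counts)
    return w.astype(_DTYPE)


def train(
    model: Model,
    train_data: tuple[np.ndarray, np.ndarray],
    early_stop_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[Model, list[dict]]:
    """Fit ``model`` in place under the shared protocol; returns (model, log).

    ``train_data`` and ``early_stop_data`` are ``(X, y)`` pairs with
    integer class codes in ``[0, n_classes)``; they must be disjoint sets
    drawn from the same training side of the outer split. Per-class loss
    weights are inverse class frequencies in the training data. Training
    stops at ``max_epochs`` or once the early-stop loss has not improved
    for ``early_stopping_patience`` epochs, and the parameters of the
    best early-stop epoch are restored. The log has one entry per epoch
    with the mean training loss and the early-stop loss.
    """
    config.validate()
    X, y = train_data
    Xe, ye = early_stop_data
    X = np.asarray(X, dtype=_DTYPE)
    Xe = np.asarray(Xe, dtype=_DTYPE)
    y = np.asarray(y, dtype=int)
    ye = np.asarray(ye, dtype=int)
    if len(X) == 0 or len(Xe) == 0:
        raise ValueError("training and early-stop sets must be non-empty")
    missing = set(np.unique(ye)) - set(np.unique(y))
    if missing:
        raise ValueError(f"class {sorted(missing)[0]} present in early-stop data "
                         "but absent from training data")

    weights = _class_weights(y, model.spec.n_classes, config.class_weighting)
    loss_fn = _loss_fn(model.spec.kind)
    optimizer = _Adam(model.params(), config.learning_rate, config.weight_decay)
    rng = substream(config.seed, "train")

    best_loss = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    stale = 0
    log: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            scores = model.forward(X[idx], training=True, rng=rng)
            loss, dz = loss_fn(scores, y[idx], weights[y[idx]])
            model.backward(dz)
            _clip_gradients(model.params(), config.gradient_clip_norm)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        val_loss, _ = loss_fn(model.forward(Xe), ye, weights[ye])
        log.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": float(val_loss)}
        )
        if val_loss < best_loss - 1e-7:
            best_loss = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    model.set_state(best_state)
    return model, log


def predict(model: Model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) with dropout inactive and batch-norm in eval mode.

    Labels are score argmaxes; exact ties resolve to the lowest class
    index. Deterministic: repeated calls return identical output.
    """
    X = np.asarray(X, dtype=_DTYPE)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"expected feature dimension {model.spec.input_dim}, got {X.shape[-1] if X.ndim else 0}"
        )
    scores = model.forward(X)
    return scores.argmax(axis=1), scores


def nested_cv_select(
    spec: ModelSpec,
    grid: HyperparameterGrid,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    inner_k: int = 2,
    base_config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[float, float]:
    """Choose (learning_rate, weight_decay) by inner cross-validation.

    The outer training data is split into ``inner_k`` group-respecting
    inner folds; each grid point is scored by its mean inner-validation
    balanced accuracy and the argmax returned. Ties break toward the
    smaller learning rate, then the larger weight decay (the more
    strongly regularized choice).
    """
    from .evaluate import balanced_accuracy  # local import to avoid a cycle

    points = grid.points()
    if len(points) == 1:
        return points[0]
    if inner_k < 2:
        raise ValueError("nested selection needs at least two inner folds")
    y = np.asarray(y, dtype=int)
    if groups is None:
        groups = np.arange(len(y))
    # same greedy group k-fold scheme as the outer split
    from .splits import group_fold_assignment

    fold = group_fold_assignment(np.asarray(groups), inner_k, seed, stream="nested_cv")

    scores = []
    for lr, wd in points:
        accs = []
        for f in range(inner_k):
            tr, va = np.flatnonzero(fold != f), np.flatnonzero(fold == f)
            if len(set(y[tr])) < spec.n_classes or va.size == 0:
                continue
            cfg = dataclasses.replace(base_config, learning_rate=lr, weight_decay=wd, seed=seed)
            model = build_model(spec, seed)
            train(model, (X[tr], y[tr]), (X[va], y[va]), cfg)
            pred, _ = predict(model, X[va])
            accs.append(balanced_accuracy(y[va], pred))
        scores.append(np.mean(accs) if accs else 0.0)
    ranked = sorted(zip(scores, points), key=lambda s: (-s[0], s[1][0], -s[1][1]))
    return ranked[0][1]


def write_training_log(log: list[dict], path) -> None:
    """Write a per-epoch training log as tab-separated text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\n")
        for entry in log:
            fh.write(f"{entry['epoch']}\t{entry['train_loss']!r}\t{entry['val_loss']!r}\n")


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------


def save_checkpoint(model: Model, stem, config: TrainConfig | None = None) -> None:
    """Write ``<stem>.npz`` (parameter/buffer arrays) + ``<stem>.json`` manifest."""
    stem = Path(stem)
    arrays = {f"array_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(stem.with_suffix(".npz"), **arrays)
    manifest = {
        "spec": dataclasses.asdict(model.spec),
        "seed": model.seed,
        "config": None if config is None else dataclasses.asdict(config),
        "n_parameters": model.n_parameters(),
    }
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(stem) -> Model:
    stem = Path(stem)
    manifest = json.loads(stem.with_suffix(".json").read_text())
    spec = ModelSpec(**manifest["spec"])
    model = build_model(spec, manifest["seed"])
    with np.load(stem.with_suffix(".npz")) as data:
        model.set_state([data[f"array_{i}"] for i in range(len(data.files))])
    return model
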