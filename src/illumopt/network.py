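"""Neural-network optimization of lighting weights via a rendering layer.

The illuminant mixing weights ``x`` sit inside the network as the first,
trainable layer: a batch of per-pixel A-matrices (shape p x p x Nch x NL)
is linearly combined along the sub-light axis into a rendered p x p x Nch
image, which feeds an ordinary classifier head.  Because the rendering is
linear in ``x``, the whole model is end-to-end differentiable and ``x``
is updated by the same backpropagated gradients as the classifier weights
- the two forms

    f_NN(A | x, W)  =  f_NN'(A x | W)

(explicit rendering inside the net vs. a classifier on pre-rendered
images) are a single computation here.

Two heads are provided: an FCL-only model for 1 x 1 pixel inputs, and a
small CNN (two valid 3 x 3 convolutions, which reduce a 5 x 5 patch to
1 x 1) for patch inputs.  Training minimizes softmax cross-entropy with
minibatch Adam; everything is plain NumPy with hand-written gradients, so
the layers double as a reference implementation that finite-difference
checks can be run against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import binary_metrics
from .spectral import SPD, SubLightSet, approximate_illuminant, render
from .synthetic import PatchDataset

__all__ = [
    "NNConfig",
    "TrainedModel",
    "cross_entropy",
    "init_lighting",
    "build_model",
    "train",
    "grid_search",
    "table2_grid",
    "NeuralLightingClassifier",
]


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class RenderingLayer:
    """Trainable illuminant mixing: output = A @ x along the sub-light axis.

    The gradient of the output w.r.t. ``x_i`` is exactly the i-th
    sub-light's channel block of the input, so d(loss)/dx is the input
    contracted with the upstream gradient over all other axes.
    """

    def __init__(self, x0: np.ndarray, trainable: bool = True):
        self.x = np.asarray(x0, dtype=float).copy()
        self.trainable = trainable
        self.grad_x = np.zeros_like(self.x)

    def forward(self, A: np.ndarray, train: bool = False) -> np.ndarray:
        self._A = A
        return render(A, self.x)

    def backward(self, grad: np.ndarray) -> None:
        if self.trainable:
            flat_A = self._A.reshape(-1, self.x.size)
            self.grad_x = flat_A.T @ grad.reshape(-1)
        else:
            self.grad_x = np.zeros_like(self.x)

    def params(self):
        if self.trainable:
            yield self.x, self.grad_x


class Standardize:
    """Fixed per-channel affine normalization of rendered images.

    Rendered intensities carry a large common (DC) component relative to
    the class contrast, which destabilizes training of the head; this
    layer subtracts a per-channel mean and divides by a per-channel scale,
    both computed once from the rendered *training* data under the initial
    lighting weights and then frozen.  It holds no trainable parameters,
    and being affine it passes gradients straight through to the lighting
    weights.
    """

    def __init__(self, n_channels: int):
        self.mu = np.zeros(n_channels)
        self.sd = np.ones(n_channels)
        self.calibrated = False

    def calibrate(self, rendered: np.ndarray) -> None:
        axes = tuple(range(rendered.ndim - 1))
        self.mu = rendered.mean(axis=axes)
        sd = rendered.std(axis=axes)
        self.sd = np.where(sd > 0, sd, 1.0)
        self.calibrated = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return (x - self.mu) / self.sd

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad / self.sd

    def params(self):
        return iter(())


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style scaling, suitable for ReLU and harmless without
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.grad_W = np.zeros_like(self.W)
        self.grad_b = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grad_W = self._x.T @ grad
        self.grad_b = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        yield self.W, self.grad_W
        yield self.b, self.grad_b


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return iter(())


class Dropout:
    """Inverted dropout; identity at inference and when p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return iter(())


class Conv2d:
    """Valid 2-D convolution on NHWC input, via im2col."""

    def __init__(
        self,
        n_in: int,
        n_filters: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        fan_in = kernel * kernel * n_in
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, n_in, n_filters)
        )
        self.b = np.zeros(n_filters)
        self.kernel = kernel
        self.stride = stride
        self.grad_W = np.zeros_like(self.W)
        self.grad_b = np.zeros_like(self.b)

    def _cols(self, x: np.ndarray):
        n, h, w, c = x.shape
        k, s = self.kernel, self.stride
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        cols = np.empty((n, oh, ow, k, k, c))
        for i in range(oh):
            for j in range(ow):
                cols[:, i, j] = x[:, i * s : i * s + k, j * s : j * s + k]
        return cols, oh, ow

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        self._cols_cache, oh, ow = self._cols(x)
        out = (
            np.einsum("nijklc,klcf->nijf", self._cols_cache, self.W) + self.b
        )
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grad_W = np.einsum("nijklc,nijf->klcf", self._cols_cache, grad)
        self.grad_b = grad.sum(axis=(0, 1, 2))
        n, h, w, c = self._shape
        k, s = self.kernel, self.stride
        dx = np.zeros(self._shape)
        dcols = np.einsum("nijf,klcf->nijklc", grad, self.W)
        for i in range(grad.shape[1]):
            for j in range(grad.shape[2]):
                dx[:, i * s : i * s + k, j * s : j * s + k] += dcols[:, i, j]
        return dx

    def params(self):
        yield self.W, self.grad_W
        yield self.b, self.grad_b


class Flatten:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def params(self):
        return iter(())


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def cross_entropy(scores, target) -> float:
    """Softmax cross-entropy of logits against one-hot targets.

    Accepts a single logit vector (C,) with one-hot target, or batches
    (N, C); batches return the mean.  Stabilized with log-sum-exp, so
    extreme logits neither overflow nor underflow.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if scores.shape != target.shape:
        raise ValueError("scores and target shapes differ")
    shifted = scores - scores.max(axis=1, keepdims=True)
    log_softmax = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-(target * log_softmax).sum(axis=1).mean())


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# model container
# --------------------------------------------------------------------------

class Sequential:
    """A rendering layer followed by a classifier head."""

    def __init__(self, rendering: RenderingLayer, head: list):
        self.rendering = rendering
        self.head = head

    @property
    def layers(self):
        return [self.rendering, *self.head]

    def forward(self, A: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits from A-matrix batches (explicit rendering inside)."""
        out = self.rendering.forward(A, train)
        return self.forward_from_rendered(out, train)

    def forward_from_rendered(
        self, rendered: np.ndarray, train: bool = False
    ) -> np.ndarray:
        """Logits from pre-rendered images - the f_NN'(Ax | W) form."""
        out = rendered
        for layer in self.head:
            out = layer.forward(out, train)
        return out

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = grad_logits
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        self.rendering.backward(grad)

    def loss_and_backward(self, A, y_onehot, train: bool = False) -> float:
        logits = self.forward(A, train)
        loss = cross_entropy(logits, y_onehot)
        grad = (_softmax(logits) - y_onehot) / len(A)
        self.backward(grad)
        return loss

    def parameters(self):
        for layer in self.layers:
            yield from layer.params()

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def predict_proba(self, A: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(A, train=False))


# --------------------------------------------------------------------------
# configuration and construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NNConfig:
    """Hyperparameters of the lighting-optimizing network.

    ``n_layers`` counts hidden layers consuming the rendered image: for the
    FCL model they are all fully connected; for the CNN the first two are
    the 3 x 3 convolutions and the remaining ``n_layers - 2`` are fully
    connected.  The grid-searched values are n_layers in {3, 5, 7},
    n_units in {10, 15, 20} and activation in {relu, none}; dropout
    p = 0.3 after each hidden FC layer.
    """

    model_kind: str = "fcl"  # {"fcl", "cnn"}
    n_layers: int = 3
    n_units: int = 10
    activation: str = "relu"  # {"relu", "none"}
    conv_filters: int = 10
    conv_kernel: int = 3
    conv_stride: int = 1
    dropout_p: float = 0.3
    init_scheme: str = "random_pm1"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in ("fcl", "cnn"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.model_kind == "cnn" and self.n_layers < 2:
            raise ValueError("cnn needs n_layers >= 2 (two conv layers)")


@dataclass
class TrainedModel:
    """A fitted network plus its provenance."""

    model: Sequential
    config: NNConfig
    loss_history: list = field(default_factory=list)

    @property
    def x(self) -> np.ndarray:
        """The learned lighting weights."""
        return self.model.rendering.x


def init_lighting(
    scheme: str,
    n_lights: int,
    sublights: SubLightSet | None = None,
    reference_spd: SPD | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Initial lighting weights.

    Schemes: ``random_pm1`` (iid uniform [-1, 1]), ``random_01`` (iid
    uniform [0, 1]), ``d65_approx`` (pseudo-inverse weights reproducing the
    reference SPD), ``uniform_ones`` (all ones).
    """
    rng = np.random.default_rng(seed)
    if scheme == "random_pm1":
        return rng.uniform(-1.0, 1.0, size=n_lights)
    if scheme == "random_01":
        return rng.uniform(0.0, 1.0, size=n_lights)
    if scheme == "uniform_ones":
        return np.ones(n_lights)
    if scheme == "d65_approx":
        if sublights is None or reference_spd is None:
            raise ValueError(
                "d65_approx needs sublights and a reference SPD"
            )
        approx = approximate_illuminant(sublights, reference_spd)
        return approx.x_approx
    raise ValueError(f"unknown init scheme {scheme!r}")


def build_model(
    config: NNConfig,
    patch_size: int,
    n_channels: int,
    n_lights: int,
    x0: np.ndarray | None = None,
    trainable_lighting: bool = True,
) -> TrainedModel:
    """Assemble an untrained model for the given input geometry.

    FCL head (patch_size must be 1): flatten -> ``n_layers`` FC layers of
    ``n_units`` (+activation, +dropout) -> 2-unit output.  CNN head
    (patch_size >= 3): two valid ``conv_kernel`` convolutions with
    ``conv_filters`` filters (+activation) -> flatten -> ``n_layers - 2``
    FC layers -> 2-unit output.  Softmax is applied in the loss / in
    ``predict_proba``, never doubled.
    """
    if config.model_kind == "fcl" and patch_size != 1:
        raise ValueError("fcl model requires patch_size = 1")
    if config.model_kind == "cnn" and patch_size < config.conv_kernel:
        raise ValueError(
            f"cnn model requires patch_size >= {config.conv_kernel}"
        )
    rng = np.random.default_rng(config.seed)
    if x0 is None:
        x0 = init_lighting(config.init_scheme, n_lights, seed=config.seed)
    rendering = RenderingLayer(x0, trainable=trainable_lighting)
    act = (lambda: ReLU()) if config.activation == "relu" else None
    head: list = [Standardize(n_channels)]
    if config.model_kind == "fcl":
        head.append(Flatten())
        width = n_channels
        n_fc = config.n_layers
    else:
        spatial = patch_size
        ch = n_channels
        for _ in range(2):
            head.append(
                Conv2d(ch, config.conv_filters, config.conv_kernel,
                       config.conv_stride, rng)
            )
            if act:
                head.append(act())
            spatial = (spatial - config.conv_kernel) // config.conv_stride + 1
            ch = config.conv_filters
        if spatial < 1:
            raise ValueError("patch too small for two convolutions")
        head.append(Flatten())
        width = spatial * spatial * ch
        n_fc = config.n_layers - 2
    for _ in range(n_fc):
        head.append(Dense(width, config.n_units, rng))
        if act:
            head.append(act())
        head.append(Dropout(config.dropout_p, rng))
        width = config.n_units
    head.append(Dense(width, 2, rng))
    return TrainedModel(Sequential(rendering, head), config)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    trained: TrainedModel, dataset: PatchDataset, config: NNConfig | None = None
) -> TrainedModel:
    """Minibatch Adam on the cross-entropy loss, jointly over W and x.

    Deterministic given ``config.seed`` (shuffling and dropout share one
    generator).  In-place on the model; returns it with ``loss_history``
    holding one mean-batch-loss entry per epoch.
    """
    config = config or trained.config
    y01 = dataset.y01
    if np.unique(y01).size < 2:
        raise ValueError("training data must contain both classes")
    onehot = dataset.one_hot()
    model = trained.model
    rng = np.random.default_rng(config.seed + 1)
    for layer in model.head:
        if isinstance(layer, Dropout):
            layer.rng = rng
        elif isinstance(layer, Standardize) and not layer.calibrated:
            layer.calibrate(model.rendering.forward(dataset.A))
    opt = _Adam(model.parameters(), config.learning_rate)
    # grads are reassigned each backward pass; refresh references per step
    n = dataset.n_samples
    bs = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            loss = model.loss_and_backward(
                dataset.A[idx], onehot[idx], train=True
            )
            opt.params = list(model.parameters())
            opt.step()
            losses.append(loss)
        trained.loss_history.append(float(np.mean(losses)))
    return trained


def table2_grid(model_kind: str, **overrides) -> list:
    """The 18 grid-searched configurations per model kind:
    n_layers x n_units x activation = 3 x 3 x 2."""
    return [
        NNConfig(
            model_kind=model_kind,
            n_layers=nl,
            n_units=nu,
            activation=act,
            **overrides,
        )
        for nl, nu, act in itertools.product(
            (3, 5, 7), (10, 15, 20), ("relu", "none")
        )
    ]


def grid_search(
    dataset: PatchDataset,
    grid: list,
    k_folds: int = 5,
    fold_seed: int = 0,
):
    """Cross-validated hyperparameter search.

    For every config: k-fold CV mean F1 (folds from ``dataset.fold_ids``
    if present, else freshly stratified).  The best config is retrained on
    the full dataset.  Returns ``(best TrainedModel, table)`` where the
    table is a list of dicts (config, per-fold F1s, mean F1), one row per
    config, so the argmax is auditable.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    from .synthetic import assign_folds

    ds = dataset
    if ds.fold_ids is None:
        ds = assign_folds(ds, k_folds, fold_seed)
    table = []
    for config in grid:
        f1s = []
        for fold in range(int(ds.fold_ids.max()) + 1):
            tr = ds.subset(ds.fold_ids != fold)
            te = ds.subset(ds.fold_ids == fold)
            tm = build_model(
                config, ds.patch_size, ds.n_channels, ds.n_lights
            )
            train(tm, tr, config)
            y_hat = np.where(
                tm.model.predict_proba(te.A)[:, 1] >= 0.5, 1, -1
            )
            f1, _, _ = binary_metrics(te.y, y_hat)
            f1s.append(f1)
        table.append(
            {"config": config, "fold_f1": f1s, "mean_f1": float(np.mean(f1s))}
        )
    best_row = max(table, key=lambda r: r["mean_f1"])
    best = build_model(
        best_row["config"], ds.patch_size, ds.n_channels, ds.n_lights
    )
    train(best, ds, best_row["config"])
    return best, table


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class NeuralLightingClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest classifier with a trainable illuminant rendering layer.

    Scikit-learn estimator around :func:`build_model` + :func:`train`.
    ``X`` may be the native patch array (N, p, p, n_channels, n_lights) or
    a flat 2-D array (N, p*p*n_channels*n_lights) when ``patch_size``,
    ``n_channels`` and ``n_lights`` are given.

    Attributes
    ----------
    x_ : ndarray of shape (n_lights,)
        Learned lighting weights.
    model_ : TrainedModel
        The fitted network (``model_.loss_history`` has per-epoch loss).
    """

    def __init__(
        self,
        model_kind: str = "fcl",
        n_layers: int = 3,
        n_units: int = 10,
        activation: str = "relu",
        dropout_p: float = 0.3,
        init_scheme: str = "random_pm1",
        learning_rate: float = 1e-3,
        epochs: int = 200,
        batch_size: int = 64,
        train_lighting: bool = True,
        x0=None,
        patch_size: int = 1,
        n_channels: int | None = None,
        n_lights: int | None = None,
        random_state: int = 0,
    ):
        self.model_kind = model_kind
        self.n_layers = n_layers
        self.n_units = n_units
        self.activation = activation
        self.dropout_p = dropout_p
        self.init_scheme = init_scheme
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.train_lighting = train_lighting
        self.x0 = x0
        self.patch_size = patch_size
        self.n_channels = n_channels
        self.n_lights = n_lights
        self.random_state = random_state

    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if self.n_channels is None or self.n_lights is None:
                raise ValueError(
                    "2-D X requires patch_size, n_channels and n_lights"
                )
            X = X.reshape(
                len(X),
                self.patch_size,
                self.patch_size,
                self.n_channels,
                self.n_lights,
            )
        if X.ndim != 5:
            raise ValueError(f"X must be (N, p, p, Nch, NL); got {X.shape}")
        return X

    def _config(self) -> NNConfig:
        return NNConfig(
            model_kind=self.model_kind,
            n_layers=self.n_layers,
            n_units=self.n_units,
            activation=self.activation,
            dropout_p=self.dropout_p,
            init_scheme=self.init_scheme,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )

    def fit(self, X, y):
        A = self._coerce(X)
        y = np.where(np.asarray(y) > 0, 1, -1)
        ds = PatchDataset(A, y, A.shape[1], target_class=1)
        config = self._config()
        x0 = None if self.x0 is None else np.asarray(self.x0, dtype=float)
        tm = build_model(
            config,
            A.shape[1],
            A.shape[3],
            A.shape[4],
            x0=x0,
            trainable_lighting=self.train_lighting,
        )
        train(tm, ds, config)
        self.model_ = tm
        self.x_ = tm.x
        self.loss_history_ = tm.loss_history
        self.classes_ = np.array([-1, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.model.predict_proba(self._coerce(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.where(proba[:, 1] >= 0.5, 1, -1)
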