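"""A small 20-layer convolutional network for 4-class severity grading.

The architecture is fixed by construction: an image input layer, three
[conv 3x3 -> batch norm -> ReLU -> max pool 2x2/2] blocks with 8/16/32
filters, a fourth conv(64) -> batch norm -> ReLU block without pooling,
a 50% dropout layer, a fully-connected layer with one unit per class,
softmax, and a classification (cross-entropy) output layer — 20 layers
in total: 4 convolutional, 4 normalization, 4 activation, 3 pooling.

The network is implemented directly in numpy (im2col convolutions,
hand-written backward passes, plain mini-batch SGD) so training is fully
deterministic given a seed and runs anywhere numpy does.  It is sized
for small 2-D grayscale inputs (default 64x64), not for GPU-scale work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabeledDataset, rescale, stratified_split


@dataclass
class LayerSpec:
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class CNNArchitectureSpec:
    layers: list
    input_size: tuple = (64, 64, 1)
    n_classes: int = 4
    dropout_rate: float = 0.5

    def count(self, kind: str) -> int:
        return sum(1 for layer in self.layers if layer.kind == kind)


@dataclass
class TrainConfig:
    """Mini-batch SGD settings.  ``stop_at_train_accuracy`` ends training
    early once the running training accuracy reaches the given level
    (set to None to always run all epochs)."""

    epochs: int = 100
    train_fraction: float = 0.7
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    batch_size: int = 10
    seed: int = 0
    momentum: float = 0.9
    stop_at_train_accuracy: float | None = 1.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def build_architecture(input_size=(64, 64, 1), n_classes: int = 4) -> CNNArchitectureSpec:
    """The fixed 20-layer architecture for a square grayscale input.

    Requires input side >= 32 so the three 2x2 poolings stay valid.
    """
    h, w = input_size[0], input_size[1]
    if h != w or h < 32:
        raise ValueError("input must be square with side >= 32")
    if h % 8 != 0:
        raise ValueError("input side must be divisible by 8 (three 2x2 poolings)")
    filters = (8, 16, 32, 64)
    layers = [LayerSpec("input", {"size": tuple(input_size)})]
    for i, nf in enumerate(filters):
        layers.append(LayerSpec("conv", {"filters": nf, "kernel": 3}))
        layers.append(LayerSpec("batchnorm", {}))
        layers.append(LayerSpec("relu", {}))
        if i < 3:
            layers.append(LayerSpec("maxpool", {"size": 2, "stride": 2}))
    layers.append(LayerSpec("dropout", {"rate": 0.5}))
    layers.append(LayerSpec("dense", {"units": n_classes}))
    layers.append(LayerSpec("softmax", {}))
    layers.append(LayerSpec("classification", {}))
    assert len(layers) == 20
    return CNNArchitectureSpec(layers, tuple(input_size), n_classes, 0.5)


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

def _im2col(x, k):
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same-padding of k//2."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i:i + h, j:j + w]
    return cols.transpose(0, 3, 4, 1, 2).reshape(n * h * w, c * k * k)


def _col2im(cols, x_shape, k):
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, h, w, c, k * k).transpose(0, 3, 4, 1, 2)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i * k + j]
    return xp[:, :, p:p + h, p:p + w]


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x, train):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        n, c, h, w = x.shape
        out = self.cols @ self.W.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c_out, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dW = g.T @ self.cols
        self.db = g.sum(axis=0)
        dcols = g @ self.W
        return _col2im(dcols, self.x_shape, self.k)

    def step(self, lr, mom, state):
        for name in ("W", "b"):
            g = getattr(self, "d" + name)
            v = state.setdefault(id(self), {}).setdefault(name, np.zeros_like(g))
            v *= mom
            v -= lr * g
            setattr(self, name, getattr(self, name) + v)


class _BatchNorm:
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)[None, :, None, None]
        self.xhat = (x - mean[None, :, None, None]) / self.std
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = np.sum(grad * self.xhat, axis=(0, 2, 3))
        self.dbeta = np.sum(grad, axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        return (g - g.mean(axis=(0, 2, 3), keepdims=True)
                - self.xhat * (g * self.xhat).mean(axis=(0, 2, 3), keepdims=True)) / self.std

    def step(self, lr, mom, state):
        for name in ("gamma", "beta"):
            g = getattr(self, "d" + name)
            v = state.setdefault(id(self), {}).setdefault(name, np.zeros_like(g))
            v *= mom
            v -= lr * g
            setattr(self, name, getattr(self, name) + v)


class _ReLU:
    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask

    def step(self, lr, mom, state):
        pass


class _MaxPool:
    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self.x_shape = x.shape
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self.argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self.x_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self.argmax[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)

    def step(self, lr, mom, state):
        pass


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask

    def step(self, lr, mom, state):
        pass


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self.in_shape = x.shape
        self.x = x.reshape(x.shape[0], -1)
        return self.x @ self.W + self.b

    def backward(self, grad):
        self.dW = self.x.T @ grad
        self.db = grad.sum(axis=0)
        return (grad @ self.W.T).reshape(self.in_shape)

    def step(self, lr, mom, state):
        for name in ("W", "b"):
            g = getattr(self, "d" + name)
            v = state.setdefault(id(self), {}).setdefault(name, np.zeros_like(g))
            v *= mom
            v -= lr * g
            setattr(self, name, getattr(self, name) + v)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNNClassifier:
    """The 20-layer network with fit/predict over labelled image datasets.

    Images are bilinearly rescaled to the architecture's input size.
    Training is plain mini-batch SGD (with momentum) on the softmax
    cross-entropy; weight init, shuffling and dropout all draw from one
    seeded generator, so runs are bit-reproducible.
    """

    def __init__(self, arch: CNNArchitectureSpec | None = None,
                 config: TrainConfig | None = None):
        self.arch = arch or build_architecture()
        self.config = config or TrainConfig()

    # -- construction -------------------------------------------------
    def _build(self, rng):
        side = self.arch.input_size[0]
        c = self.arch.input_size[2]
        net, spatial = [], side
        for spec in self.arch.layers:
            if spec.kind == "input":
                continue
            if spec.kind == "conv":
                nf = spec.params["filters"]
                net.append(_Conv(c, nf, spec.params["kernel"], rng))
                c = nf
            elif spec.kind == "batchnorm":
                net.append(_BatchNorm(c))
            elif spec.kind == "relu":
                net.append(_ReLU())
            elif spec.kind == "maxpool":
                net.append(_MaxPool())
                spatial //= 2
            elif spec.kind == "dropout":
                net.append(_Dropout(spec.params["rate"], rng))
            elif spec.kind == "dense":
                net.append(_Dense(c * spatial * spatial, spec.params["units"], rng))
            # softmax / classification are realised in the loss
        self.net_ = net

    def _forward(self, x, train):
        for layer in self.net_:
            x = layer.forward(x, train)
        return x

    def _prepare(self, images):
        side = self.arch.input_size[0]
        x = np.stack([rescale(img, (side, side)) for img in images])
        return x[:, None, :, :].astype(float)

    # -- training ------------------------------------------------------
    def fit(self, ds: LabeledDataset):
        """Train on all images of ``ds``; returns self.

        Per-epoch mean loss and training accuracy are recorded in
        ``history_`` (dict of lists).
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        present = np.unique(ds.labels)
        self.classes_ = np.arange(1, self.arch.n_classes + 1)
        if len(present) < self.arch.n_classes:
            raise ValueError("a class is absent from the training data")
        self._build(rng)
        x = self._prepare(ds.images)
        t = np.searchsorted(self.classes_, ds.labels)
        n = len(t)
        state: dict = {}
        self.history_ = {"epoch": [], "loss": [], "accuracy": []}
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(x[idx], train=True)
                probs = _softmax(logits)
                losses.append(float(-np.mean(np.log(probs[np.arange(len(idx)), t[idx]] + 1e-12))))
                correct += int(np.sum(np.argmax(probs, axis=1) == t[idx]))
                grad = probs.copy()
                grad[np.arange(len(idx)), t[idx]] -= 1.0
                grad /= len(idx)
                for layer in reversed(self.net_):
                    grad = layer.backward(grad)
                for layer in self.net_:
                    layer.step(cfg.learning_rate, cfg.momentum, state)
            acc = correct / n
            self.history_["epoch"].append(epoch + 1)
            self.history_["loss"].append(float(np.mean(losses)))
            self.history_["accuracy"].append(acc)
            if (cfg.stop_at_train_accuracy is not None
                    and acc >= cfg.stop_at_train_accuracy):
                break
        return self

    # -- inference -----------------------------------------------------
    def predict_proba(self, images):
        x = self._prepare(images)
        out = []
        for start in range(0, len(x), 64):
            out.append(_softmax(self._forward(x[start:start + 64], train=False)))
        return np.vstack(out)

    def predict(self, images):
        probs = self.predict_proba(images)
        return self.classes_[np.argmax(probs, axis=1)]

    # -- persistence ----------------------------------------------------
    def save_weights(self, path):
        arrays = {}
        for i, layer in enumerate(self.net_):
            for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                if hasattr(layer, name):
                    arrays[f"{i}_{name}"] = getattr(layer, name)
        np.savez(path, **arrays)

    def load_weights(self, path):
        if not hasattr(self, "net_"):
            self._build(np.random.default_rng(self.config.seed))
            self.classes_ = np.arange(1, self.arch.n_classes + 1)
        data = np.load(path)
        for i, layer in enumerate(self.net_):
            for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                key = f"{i}_{name}"
                if key in data:
                    setattr(layer, name, data[key])


def train_cnn(ds: LabeledDataset, arch: CNNArchitectureSpec | None = None,
              cfg: TrainConfig | None = None):
    """Stratified-split training: fit on the train fraction, return the
    model plus its training history and the held-out test split."""
    cfg = cfg or TrainConfig()
    train, test = stratified_split(ds, cfg.train_fraction, cfg.seed)
    model = SmallCNNClassifier(arch, cfg).fit(train)
    return model, model.history_, test


def predict_cnn(model: SmallCNNClassifier, images):
    """Labels and per-class softmax scores for a batch of images."""
    probs = model.predict_proba(images)
    return model.classes_[np.argmax(probs, axis=1)], probs
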