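"""1D convolutional classifier for pore-former detection.

Architecture (fixed layer sequence, sizes configurable):

    input (L positions x C channels)
    -> conv (25 filters, kernel 100) -> ReLU -> max-pool (5)
    -> conv (25 filters, kernel 50)  -> ReLU -> max-pool (5)
    -> dropout (0.25) -> flatten -> dense(1) -> sigmoid

The sigmoid output is the probability that the input protein is a pore
former, in [0, 1]. Training minimizes mean squared error between the
sigmoid output and the 0/1 label, with the Adam optimizer. All randomness
(weight init, batch shuffling, dropout masks) flows from a single seed, so
training is bit-reproducible on a given platform.

Implemented directly on NumPy: convolutions run as im2col + matmul, with
hand-derived backward passes for every layer.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from os import PathLike
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    conv1_filters: int = 25
    conv1_kernel: int = 100
    conv2_filters: int = 25
    conv2_kernel: int = 50
    pool_size: int = 5
    dropout_rate: float = 0.25
    activation: str = "relu"
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.activation != "relu":
            raise ValueError("only the rectified-linear activation is supported")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.train_loss)


def layer_dimensions(config: ModelConfig, input_shape: tuple[int, int]) -> dict[str, int]:
    """Spatial sizes after each stage; raises if a kernel outruns its input."""
    length, channels = input_shape
    if config.conv1_kernel > length:
        raise ValueError(
            f"conv1 kernel {config.conv1_kernel} exceeds input length {length}"
        )
    conv1_out = length - config.conv1_kernel + 1
    pool1_out = conv1_out // config.pool_size
    if config.conv2_kernel > pool1_out:
        raise ValueError(
            f"conv2 kernel {config.conv2_kernel} exceeds post-pooling length "
            f"{pool1_out}; reduce the kernel or the pool size"
        )
    conv2_out = pool1_out - config.conv2_kernel + 1
    pool2_out = conv2_out // config.pool_size
    if pool2_out < 1:
        raise ValueError("second pooling stage collapses to zero length")
    return {
        "conv1_out": conv1_out,
        "pool1_out": pool1_out,
        "conv2_out": conv2_out,
        "pool2_out": pool2_out,
        "flat": pool2_out * config.conv2_filters,
    }


def parameter_count(config: ModelConfig, input_shape: tuple[int, int]) -> int:
    """Total trainable parameters: (k*c_in + 1)*f per conv, (flat + 1) for dense."""
    dims = layer_dimensions(config, input_shape)
    _, channels = input_shape
    n = (config.conv1_kernel * channels + 1) * config.conv1_filters
    n += (config.conv2_kernel * config.conv1_filters + 1) * config.conv2_filters
    n += dims["flat"] + 1
    return n


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int):
    # x: (n, length, c_in); w: (kernel*c_in, f); returns (n, l_out, f) + cols cache
    n, length, c_in = x.shape
    l_out = length - kernel + 1
    windows = sliding_window_view(x, kernel, axis=1)      # (n, l_out, c_in, kernel)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(n, l_out, kernel * c_in)
    return cols @ w + b, cols


def _conv_backward(d_out, cols, w, kernel, c_in, input_length):
    n, l_out, f = d_out.shape
    dw = cols.reshape(-1, cols.shape[-1]).T @ d_out.reshape(-1, f)
    db = d_out.sum(axis=(0, 1))
    d_cols = (d_out @ w.T).reshape(n, l_out, kernel, c_in)
    dx = np.zeros((n, input_length, c_in), dtype=d_out.dtype)
    for k in range(kernel):
        dx[:, k : k + l_out, :] += d_cols[:, :, k, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, pool: int):
    # non-overlapping windows; a trailing remainder shorter than pool is dropped
    n, length, f = x.shape
    l_out = length // pool
    blocks = x[:, : l_out * pool, :].reshape(n, l_out, pool, f)
    argmax = blocks.argmax(axis=2)
    out = np.take_along_axis(blocks, argmax[:, :, None, :], axis=2).squeeze(2)
    return out, argmax


def _pool_backward(d_out, argmax, pool, input_length):
    n, l_out, f = d_out.shape
    d_blocks = np.zeros((n, l_out, pool, f), dtype=d_out.dtype)
    np.put_along_axis(d_blocks, argmax[:, :, None, :], d_out[:, :, None, :], axis=2)
    dx = np.zeros((n, input_length, f), dtype=d_out.dtype)
    dx[:, : l_out * pool, :] = d_blocks.reshape(n, l_out * pool, f)
    return dx


class _Network:
    """Parameter container with forward/backward passes and Adam updates."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int],
                 rng: np.random.Generator):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.dims = layer_dimensions(config, input_shape)
        length, c_in = input_shape
        k1, f1 = config.conv1_kernel, config.conv1_filters
        k2, f2 = config.conv2_kernel, config.conv2_filters
        flat = self.dims["flat"]
        self.params = {
            "w1": _glorot(rng, k1 * c_in, f1, (k1 * c_in, f1)),
            "b1": np.zeros(f1, dtype=np.float32),
            "w2": _glorot(rng, k2 * f1, f2, (k2 * f1, f2)),
            "b2": np.zeros(f2, dtype=np.float32),
            "w3": _glorot(rng, flat, 1, (flat, 1)),
            "b3": np.zeros(1, dtype=np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        cfg, p = self.config, self.params
        cache: dict = {}
        z1, cache["cols1"] = _conv_forward(x, p["w1"], p["b1"], cfg.conv1_kernel)
        a1 = np.maximum(z1, 0.0)
        p1, cache["argmax1"] = _pool_forward(a1, cfg.pool_size)
        z2, cache["cols2"] = _conv_forward(p1, p["w2"], p["b2"], cfg.conv2_kernel)
        a2 = np.maximum(z2, 0.0)
        p2, cache["argmax2"] = _pool_forward(a2, cfg.pool_size)
        if train and cfg.dropout_rate > 0:
            assert rng is not None
            mask = (rng.random(p2.shape) >= cfg.dropout_rate).astype(p2.dtype)
            d = p2 * mask / (1.0 - cfg.dropout_rate)
            cache["dropout_mask"] = mask
        else:
            d = p2
            cache["dropout_mask"] = None
        flat = d.reshape(d.shape[0], -1)
        logits = flat @ p["w3"] + p["b3"]
        prob = 1.0 / (1.0 + np.exp(-logits))
        cache.update(z1=z1, a1_shape=a1.shape, p1=p1, z2=z2, a2_shape=a2.shape,
                     p2_shape=p2.shape, flat=flat, prob=prob)
        return prob[:, 0], cache

    def backward(self, x: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        cfg, p = self.config, self.params
        n = x.shape[0]
        prob = cache["prob"]
        # MSE through the sigmoid: dL/dz = 2(p - y) p (1 - p) / n
        d_logits = (2.0 / n) * (prob[:, 0] - y) * prob[:, 0] * (1.0 - prob[:, 0])
        d_logits = d_logits[:, None].astype(np.float32)
        grads = {}
        grads["w3"] = cache["flat"].T @ d_logits
        grads["b3"] = d_logits.sum(axis=0)
        d_flat = d_logits @ p["w3"].T
        d_d = d_flat.reshape(cache["p2_shape"])
        if cache["dropout_mask"] is not None:
            d_d = d_d * cache["dropout_mask"] / (1.0 - cfg.dropout_rate)
        d_a2 = _pool_backward(d_d, cache["argmax2"], cfg.pool_size, cache["a2_shape"][1])
        d_z2 = d_a2 * (cache["z2"] > 0)
        d_p1, grads["w2"], grads["b2"] = _conv_backward(
            d_z2, cache["cols2"], p["w2"], cfg.conv2_kernel,
            cfg.conv1_filters, cache["p1"].shape[1])
        d_a1 = _pool_backward(d_p1, cache["argmax1"], cfg.pool_size, cache["a1_shape"][1])
        d_z1 = d_a1 * (cache["z1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(
            d_z1, cache["cols1"], p["w1"], cfg.conv1_kernel,
            self.input_shape[1], x.shape[1])
        return grads

    def adam_step(self, grads: dict, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            g = g.astype(np.float32)
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            self.params[key] -= lr * m_hat / (np.sqrt(v_hat) + eps)


class TrainedClassifier:
    """A fitted scorer mapping encoded tensors to pore-former probabilities."""

    def __init__(self, network: _Network, scheme: Optional[str] = None):
        self._network = network
        self.config = network.config
        self.input_shape = network.input_shape
        self.scheme = scheme

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self._network.params.values()))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Scores in [0, 1], one per input tensor; deterministic (no dropout)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected tensors of shape (n, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), received {x.shape}"
            )
        out = []
        for start in range(0, x.shape[0], 256):
            scores, _ = self._network.forward(x[start : start + 256], train=False)
            out.append(scores)
        return np.concatenate(out) if out else np.empty(0)

    def save(self, path: str | PathLike) -> None:
        meta = {
            "format_version": FORMAT_VERSION,
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "scheme": self.scheme,
        }
        buf = _io.BytesIO()
        np.savez(buf, **self._network.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | PathLike) -> "TrainedClassifier":
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("meta.json"))
                params = np.load(_io.BytesIO(zf.read("params.npz")))
                loaded = {k: params[k] for k in params.files}
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"not a valid model archive: {path}") from exc
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"model format version {meta.get('format_version')} is not "
                f"supported (expected {FORMAT_VERSION})"
            )
        config = ModelConfig(**meta["config"])
        network = _Network(config, tuple(meta["input_shape"]),
                           np.random.default_rng(0))
        for key in network.params:
            network.params[key] = loaded[key].astype(np.float32)
        return cls(network, scheme=meta.get("scheme"))


def build_model(config: ModelConfig, input_shape: tuple[int, int],
                scheme: Optional[str] = None) -> TrainedClassifier:
    """Construct an untrained classifier for tensors of *input_shape*."""
    rng = np.random.default_rng(config.seed)
    return TrainedClassifier(_Network(config, input_shape, rng), scheme=scheme)


def _metrics(classifier: TrainedClassifier, x: np.ndarray, y: np.ndarray):
    scores = classifier.predict(x)
    loss = float(np.mean((scores - y) ** 2))
    accuracy = float(np.mean((scores >= 0.5) == (y == 1)))
    return loss, accuracy


def train(
    classifier: TrainedClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    config: Optional[ModelConfig] = None,
) -> tuple[TrainedClassifier, TrainingHistory]:
    """Fit by mini-batch Adam on the MSE loss; returns the fitted classifier
    and per-epoch train/validation loss and accuracy."""
    config = config or classifier.config
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float32)
    if set(np.unique(y_train)) - {0.0, 1.0}:
        raise ValueError("labels must be 0 or 1")
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class; cannot learn a discrimination")
    network = classifier._network
    rng = np.random.default_rng(config.seed + 1)  # shuffling + dropout stream
    history = TrainingHistory()
    n = x_train.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            _, cache = network.forward(xb, train=True, rng=rng)
            grads = network.backward(xb, yb, cache)
            network.adam_step(grads, config.learning_rate)
        loss, acc = _metrics(classifier, x_train, y_train)
        history.train_loss.append(loss)
        history.train_accuracy.append(acc)
        if x_val is not None and len(x_val):
            vloss, vacc = _metrics(classifier, np.asarray(x_val, np.float32),
                                   np.asarray(y_val, np.float32))
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
    return classifier, history


def predict(classifier: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    return classifier.predict(x)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call per score: 1 iff score >= threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be within [0, 1]")
    scores = np.asarray(scores)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return (scores >= threshold).astype(int)


def save_model(classifier: TrainedClassifier, path: str | PathLike) -> None:
    classifier.save(path)


def load_model(path: str | PathLike) -> TrainedClassifier:
    return TrainedClassifier.load(path)
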