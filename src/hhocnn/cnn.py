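"""Small convolutional network for binary tumor classification.

The architecture is the smallest network matching the layer list
input → convolution → ReLU → max-pool → fully connected → sigmoid:
one convolution layer (``n_filters`` kernels of side ``kernel``, valid
cross-correlation, stride 1), element-wise rectification, non-overlapping
``pool x pool`` max pooling, and a single fully connected sigmoid unit
producing a class probability in [0, 1].  Labels are thresholded at 0.5
(a probability of exactly 0.5 maps to label 1).

Training minimizes the mean-squared error between the sigmoid output and
the 0/1 label by mini-batch gradient descent; a second, optional stage
refines the final-layer weights with the population metaheuristic in
:mod:`hhocnn.hho`, accepting the refined weights only when the training
loss does not increase.

Everything is plain ``numpy``; the backward pass is exact (verified against
central finite differences in the test suite).  Model files are JSON
(architecture header plus flat weight list), which round-trips float64
exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

from . import hho
from .hho import mse_loss

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "CNNModel",
    "conv_forward",
    "train_gd",
    "refine_hho",
    "predict",
    "prepare_images",
]


def conv_forward(
    inputs: np.ndarray, kernel: np.ndarray, stride: int = 1, padding: int = 0
) -> np.ndarray:
    """Single-output-plane convolution (cross-correlation convention).

    *inputs* is ``(H, W)`` or ``(P, H, W)``; *kernel* matches with shape
    ``(kh, kw)`` or ``(P, kh, kw)``.  The pre-activation at output site
    ``(i, j)`` is ``sum_{p,m,n} V[p,m,n] * T[p, i*s+m, j*s+n]`` after
    zero-padding by *padding* on each side.
    """
    x = np.asarray(inputs, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if k.ndim == 2:
        k = k[None]
    if x.ndim != 3 or k.ndim != 3 or x.shape[0] != k.shape[0]:
        raise ValueError(f"incompatible shapes {inputs.shape} and {kernel.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    P, H, W = x.shape
    _, kh, kw = k.shape
    if kh > H or kw > W:
        raise ValueError("kernel larger than (padded) input")
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (P, Ho, Wo, kh, kw)
    return np.tensordot(windows, k, axes=([0, 3, 4], [0, 1, 2]))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class CNNConfig:
    """Architecture hyperparameters."""

    input_side: int = 64
    n_filters: int = 8
    kernel: int = 3
    pool: int = 2
    seed: int = 0

    @property
    def conv_out(self) -> int:
        return self.input_side - self.kernel + 1

    @property
    def pooled_out(self) -> int:
        return self.conv_out // self.pool

    @property
    def fc_dim(self) -> int:
        return self.n_filters * self.pooled_out**2


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent and refinement hyperparameters."""

    learning_rate: float = 0.1
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    refine_population: int = 8
    refine_iterations: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


class CNNModel:
    """Conv → ReLU → max-pool → fully-connected sigmoid classifier."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        cfg = self.config
        if cfg.conv_out < cfg.pool:
            raise ValueError("input too small for the configured kernel and pool")
        rng = np.random.default_rng(cfg.seed)
        # He initialization for the rectified conv layer, Glorot-ish for the
        # sigmoid output unit.
        self.conv_w = rng.normal(0.0, np.sqrt(2.0 / cfg.kernel**2), size=(cfg.n_filters, cfg.kernel, cfg.kernel))
        self.conv_b = np.zeros(cfg.n_filters)
        self.fc_w = rng.normal(0.0, 1.0 / np.sqrt(cfg.fc_dim), size=cfg.fc_dim)
        self.fc_b = 0.0

    # -- forward / backward ------------------------------------------------

    def _check_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        side = self.config.input_side
        if X.ndim != 3 or X.shape[1:] != (side, side):
            raise ValueError(f"expected (n, {side}, {side}) input, got {X.shape}")
        return X

    def forward(self, X: np.ndarray, cache: bool = False):
        """Class probability for a batch of ``(n, side, side)`` inputs in [0, 1]."""
        X = self._check_batch(X)
        cfg = self.config
        k, pool = cfg.kernel, cfg.pool
        cols = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(1, 2))
        s1 = np.tensordot(cols, self.conv_w, axes=([3, 4], [1, 2]))  # (n,Ho,Wo,F)
        s1 = s1 + self.conv_b
        t1 = np.maximum(s1, 0.0)
        n, Ho, Wo, F = t1.shape
        Hp, Wp = Ho // pool, Wo // pool
        r = t1[:, : Hp * pool, : Wp * pool, :]
        r = r.reshape(n, Hp, pool, Wp, pool, F).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, Hp, Wp, F, pool * pool)
        amax = r.argmax(axis=-1)
        pooled = np.take_along_axis(r, amax[..., None], axis=-1)[..., 0]
        flat = pooled.reshape(n, -1)
        z = flat @ self.fc_w + self.fc_b
        p = _sigmoid(z)
        if cache:
            return p, {"cols": cols, "s1": s1, "amax": amax, "flat": flat, "z": z}
        return p

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        return mse_loss(np.asarray(y, dtype=np.float64), self.forward(X))

    def gradients(self, X: np.ndarray, y: np.ndarray):
        """MSE loss and its gradients w.r.t. every weight, for one batch."""
        X = self._check_batch(X)
        y = np.asarray(y, dtype=np.float64)
        cfg = self.config
        pool = cfg.pool
        p, c = self.forward(X, cache=True)
        n = X.shape[0]
        loss = float(np.mean((p - y) ** 2))
        dz = (2.0 / n) * (p - y) * p * (1.0 - p)
        d_fc_w = c["flat"].T @ dz
        d_fc_b = float(dz.sum())
        dflat = np.outer(dz, self.fc_w)
        Hp = Wp = cfg.pooled_out
        F = cfg.n_filters
        dpooled = dflat.reshape(n, Hp, Wp, F)
        dr = np.zeros((n, Hp, Wp, F, pool * pool))
        np.put_along_axis(dr, c["amax"][..., None], dpooled[..., None], axis=-1)
        dr = dr.reshape(n, Hp, Wp, F, pool, pool).transpose(0, 1, 4, 2, 5, 3)
        dt1 = np.zeros_like(c["s1"])
        dt1[:, : Hp * pool, : Wp * pool, :] = dr.reshape(n, Hp * pool, Wp * pool, F)
        ds1 = dt1 * (c["s1"] > 0)
        d_conv_w = np.tensordot(ds1, c["cols"], axes=([0, 1, 2], [0, 1, 2]))
        d_conv_b = ds1.sum(axis=(0, 1, 2))
        return loss, {
            "conv_w": d_conv_w,
            "conv_b": d_conv_b,
            "fc_w": d_fc_w,
            "fc_b": d_fc_b,
        }

    # -- weight vector packing (for the metaheuristic and serialization) ---

    def get_fc_vector(self) -> np.ndarray:
        return np.concatenate([self.fc_w, [self.fc_b]])

    def set_fc_vector(self, v: np.ndarray) -> None:
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (self.config.fc_dim + 1,):
            raise ValueError("wrong fully-connected vector length")
        self.fc_w = v[:-1].copy()
        self.fc_b = float(v[-1])

    def get_all_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.conv_w.ravel(), self.conv_b, self.fc_w, [self.fc_b]]
        )

    def set_all_vector(self, v: np.ndarray) -> None:
        cfg = self.config
        sizes = [self.conv_w.size, cfg.n_filters, cfg.fc_dim, 1]
        if v.shape != (sum(sizes),):
            raise ValueError("wrong weight vector length")
        off = 0
        self.conv_w = v[off : off + sizes[0]].reshape(self.conv_w.shape).copy()
        off += sizes[0]
        self.conv_b = v[off : off + sizes[1]].copy()
        off += sizes[1]
        self.fc_w = v[off : off + sizes[2]].copy()
        self.fc_b = float(v[-1])

    def copy(self) -> "CNNModel":
        clone = CNNModel(self.config)
        clone.set_all_vector(self.get_all_vector())
        return clone

    # -- serialization -----------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "architecture": asdict(self.config),
            "weights": self.get_all_vector().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CNNModel":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(CNNConfig(**payload["architecture"]))
        model.set_all_vector(np.asarray(payload["weights"], dtype=np.float64))
        return model


def prepare_images(images, side: int) -> np.ndarray:
    """Resize 8-bit images to ``side x side`` and scale intensities to [0, 1]."""
    out = np.empty((len(images), side, side))
    for i, img in enumerate(images):
        arr = np.asarray(img, dtype=np.float64)
        if arr.shape != (side, side):
            arr = _sk_resize(arr, (side, side), preserve_range=True, anti_aliasing=True)
        out[i] = arr / 255.0
    return out


def train_gd(
    model: CNNModel, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> list[float]:
    """Mini-batch gradient descent on the MSE loss; returns per-epoch losses.

    Modifies *model* in place.  Deterministic given ``config.seed`` (the
    seed drives the per-epoch shuffling only).
    """
    config = config or TrainConfig()
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    n = len(y)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, grads = model.gradients(X[idx], y[idx])
            model.conv_w -= config.learning_rate * grads["conv_w"]
            model.conv_b -= config.learning_rate * grads["conv_b"]
            model.fc_w -= config.learning_rate * grads["fc_w"]
            model.fc_b -= config.learning_rate * grads["fc_b"]
        history.append(model.loss(X, y))
    return history


def refine_hho(
    model: CNNModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    scope: str = "fc",
    seed: int | None = None,
    bound_width: float = 0.5,
) -> tuple[CNNModel, dict]:
    """Refine weights with the population metaheuristic (model-level elitism).

    The weight vector of the chosen *scope* (``"fc"``: final layer only,
    the default to keep the search dimension small; ``"all"``: every
    weight) becomes the search position, bounded in a box of half-width
    *bound_width* around the incumbent values, which also seed the initial
    population.  The refined weights are adopted only when the training
    loss does not increase.  A zero refinement budget returns the model
    unchanged.
    """
    config = config or TrainConfig()
    y = np.asarray(y, dtype=np.float64)
    if config.refine_population < 2 or config.refine_iterations < 1:
        return model.copy(), {"accepted": False, "evaluations": 0}
    getter, setter = (
        (CNNModel.get_fc_vector, CNNModel.set_fc_vector)
        if scope == "fc"
        else (CNNModel.get_all_vector, CNNModel.set_all_vector)
    )
    work = model.copy()
    w0 = getter(work)
    bounds = np.stack([w0 - bound_width, w0 + bound_width], axis=1)

    def objective(v: np.ndarray) -> float:
        setter(work, v)
        return work.loss(X, y)

    baseline = model.loss(X, y)
    result = hho.optimize(
        objective,
        bounds,
        f=config.refine_population,
        iterations=config.refine_iterations,
        seed=config.seed if seed is None else seed,
        init=w0,
    )
    refined = model.copy()
    info = {
        "accepted": result.best_fitness <= baseline,
        "baseline_loss": baseline,
        "refined_loss": result.best_fitness,
        "evaluations": result.n_evaluations,
    }
    if info["accepted"]:
        setter(refined, result.best_position)
    return refined, info


def predict(model: CNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-image probabilities and 0/1 labels (threshold 0.5; ties → 1)."""
    if len(X) == 0:
        return np.array([], dtype=int), np.array([])
    probs = model.forward(X)
    labels = (probs >= 0.5).astype(int)
    return labels, probs
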