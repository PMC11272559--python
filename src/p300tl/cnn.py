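"""Six-layer convolutional network for P300 vs non-P300 epochs, in numpy.

Architecture (input is one epoch, T samples x C channels):

    batch-norm (per channel)
    -> convolution: K kernels of shape [kernel_height x C], temporal stride S
    -> batch-norm (per kernel) -> ReLU
    -> dense f units -> ReLU          (the "deep feature" layer)
    -> dense 2 units -> softmax

Training is plain stochastic gradient descent with momentum, L2 weight decay
on the weight matrices, and cross-entropy loss; the model returned is the one
with the best validation loss (early stopping).  Transfer learning freezes
the early layers (both batch-norms and the convolution): frozen layers use
their stored running statistics, receive no gradient updates, and are
bit-identical after fine-tuning.

Everything is implemented directly on numpy arrays: the convolution kernel
spans all channels, so it reduces to an im2col patch extraction followed by a
matrix product, and the whole backward pass is written out analytically
(validated against finite differences in the test suite).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import EpochSet, FeatureSet

BN_EPS = 1e-5
BN_MOMENTUM = 0.1

#: layers frozen during fine-tuning: the generic feature-extraction front-end
FROZEN_FRONT_END = ("bn0", "conv", "bn1")

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "CNNModel",
    "build_cnn",
    "train_cnn",
    "fine_tune",
    "extract_features",
    "predict_proba",
]


@dataclass(frozen=True)
class CNNConfig:
    """Network geometry for a T x C epoch.

    ``kernel_height`` defaults to round(T/10) and the stride S equals K in
    the canonical configurations: 160x64 epochs use K = S = 16 with f = 128;
    45x8 epochs use K = S = 5 with f = 36.
    """

    T: int
    C: int
    K: int
    kernel_height: int
    S: int
    f: int
    classes: int = 2

    def __post_init__(self) -> None:
        if min(self.T, self.C, self.K, self.kernel_height, self.S, self.f) < 1:
            raise ValueError("all CNN dimensions must be positive")
        if self.kernel_height > self.T:
            raise ValueError("kernel_height exceeds epoch length")
        if self.positions < 1:
            raise ValueError("convolution produces no output positions")
        if self.K * self.positions < self.f:
            raise ValueError("flattened conv output is narrower than the feature layer")

    @property
    def positions(self) -> int:
        return (self.T - self.kernel_height) // self.S + 1

    @property
    def flat_dim(self) -> int:
        return self.K * self.positions

    @classmethod
    def for_speller(cls) -> "CNNConfig":
        """160x64 epochs (665 ms at 240 Hz, 64 channels)."""
        return cls(T=160, C=64, K=16, kernel_height=16, S=16, f=128)

    @classmethod
    def for_rsvp(cls) -> "CNNConfig":
        """45x8 epochs (0.7 s at 64 Hz, 8 channels)."""
        return cls(T=45, C=8, K=5, kernel_height=5, S=5, f=36)

    @classmethod
    def for_shape(cls, T: int, C: int, K: int, f: int) -> "CNNConfig":
        """K kernels of height round(T/10) with stride S = K."""
        return cls(T=T, C=C, K=K, kernel_height=max(1, round(T / 10)), S=K, f=f)


@dataclass
class TrainConfig:
    """SGD hyperparameters: lr 0.01, momentum 0.9, L2 5e-4 on weights."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


def _init_params(cfg: CNNConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    kdim = cfg.kernel_height * cfg.C

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    return {
        "bn0_gamma": np.ones(cfg.C), "bn0_beta": np.zeros(cfg.C),
        "bn0_mean": np.zeros(cfg.C), "bn0_var": np.ones(cfg.C),
        "conv_W": he((cfg.K, kdim), kdim), "conv_b": np.zeros(cfg.K),
        "bn1_gamma": np.ones(cfg.K), "bn1_beta": np.zeros(cfg.K),
        "bn1_mean": np.zeros(cfg.K), "bn1_var": np.ones(cfg.K),
        "fc1_W": he((cfg.f, cfg.flat_dim), cfg.flat_dim), "fc1_b": np.zeros(cfg.f),
        "fc2_W": he((cfg.classes, cfg.f), cfg.f), "fc2_b": np.zeros(cfg.classes),
    }


_LAYER_PARAMS = {
    "bn0": ("bn0_gamma", "bn0_beta", "bn0_mean", "bn0_var"),
    "conv": ("conv_W", "conv_b"),
    "bn1": ("bn1_gamma", "bn1_beta", "bn1_mean", "bn1_var"),
    "fc1": ("fc1_W", "fc1_b"),
    "fc2": ("fc2_W", "fc2_b"),
}
_DECAYED = ("conv_W", "fc1_W", "fc2_W")


@dataclass
class CNNModel:
    """Parameter container plus forward/backward passes."""

    config: CNNConfig
    params: dict[str, np.ndarray]
    frozen: frozenset[str] = frozenset()
    history: dict[str, list] = field(default_factory=dict)

    # ---------------------------------------------------------------- forward

    def _patches(self, x: np.ndarray) -> np.ndarray:
        """(n, T, C) -> (n, P, kernel_height*C) im2col view copy."""
        cfg = self.config
        idx = (np.arange(cfg.positions) * cfg.S)[:, None] + np.arange(cfg.kernel_height)[None, :]
        return x[:, idx, :].reshape(x.shape[0], cfg.positions, cfg.kernel_height * cfg.C)

    def _bn_forward(self, name: str, x: np.ndarray, axes: tuple, train: bool, cache: dict):
        p = self.params
        use_batch = train and name not in self.frozen
        if use_batch:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = int(np.prod([x.shape[a] for a in axes]))
            p[name + "_mean"][...] = (1 - BN_MOMENTUM) * p[name + "_mean"] + BN_MOMENTUM * mean
            unbiased = var * m / max(m - 1, 1)
            p[name + "_var"][...] = (1 - BN_MOMENTUM) * p[name + "_var"] + BN_MOMENTUM * unbiased
        else:
            mean = p[name + "_mean"]
            var = p[name + "_var"]
        ivstd = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean) * ivstd
        cache[name] = {"x": x, "xhat": xhat, "ivstd": ivstd, "axes": axes, "batch": use_batch}
        return p[name + "_gamma"] * xhat + p[name + "_beta"]

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, dict]:
        """Run the network; returns (class probabilities, cache)."""
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.T or x.shape[2] != cfg.C:
            raise ValueError(f"expected epochs of shape (n, {cfg.T}, {cfg.C}), got {x.shape}")
        p = self.params
        cache: dict = {}
        h0 = self._bn_forward("bn0", x, (0, 1), train, cache)
        patches = self._patches(h0)
        cache["patches"] = patches
        z1 = patches @ p["conv_W"].T + p["conv_b"]           # (n, P, K)
        h1 = self._bn_forward("bn1", z1, (0, 1), train, cache)
        a1 = np.maximum(h1, 0.0)
        cache["a1_mask"] = h1 > 0
        flat = a1.reshape(len(x), cfg.flat_dim)
        cache["flat"] = flat
        z2 = flat @ p["fc1_W"].T + p["fc1_b"]
        a2 = np.maximum(z2, 0.0)
        cache["a2_mask"] = z2 > 0
        cache["a2"] = a2
        z3 = a2 @ p["fc2_W"].T + p["fc2_b"]
        z3 -= z3.max(axis=1, keepdims=True)
        ez = np.exp(z3)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    # --------------------------------------------------------------- backward

    def _bn_backward(self, name: str, dy: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
        p = self.params
        c = cache[name]
        axes = c["axes"]
        grads[name + "_gamma"] = (dy * c["xhat"]).sum(axis=axes)
        grads[name + "_beta"] = dy.sum(axis=axes)
        dxhat = dy * p[name + "_gamma"]
        if not c["batch"]:
            return dxhat * c["ivstd"]
        m = np.prod([c["x"].shape[a] for a in axes])
        xc = c["x"] - c["x"].mean(axis=axes)
        dvar = (dxhat * xc * -0.5 * c["ivstd"] ** 3).sum(axis=axes)
        dmean = (-dxhat * c["ivstd"]).sum(axis=axes) + dvar * (-2.0 / m) * xc.sum(axis=axes)
        return dxhat * c["ivstd"] + dvar * 2.0 * xc / m + dmean / m

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, weight_decay: float = 0.0, train: bool = True
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy (+ L2 on weight matrices) and its gradients."""
        cfg = self.config
        p = self.params
        n = len(x)
        probs, cache = self.forward(x, train=train)
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        if weight_decay > 0:
            loss += 0.5 * weight_decay * sum(float((p[k] ** 2).sum()) for k in _DECAYED)

        grads: dict[str, np.ndarray] = {}
        dz3 = probs.copy()
        dz3[np.arange(n), y] -= 1.0
        dz3 /= n
        grads["fc2_W"] = dz3.T @ cache["a2"]
        grads["fc2_b"] = dz3.sum(axis=0)
        da2 = dz3 @ p["fc2_W"]
        dz2 = da2 * cache["a2_mask"]
        grads["fc1_W"] = dz2.T @ cache["flat"]
        grads["fc1_b"] = dz2.sum(axis=0)
        dflat = dz2 @ p["fc1_W"]
        da1 = dflat.reshape(n, cfg.positions, cfg.K) * cache["a1_mask"]
        dz1 = self._bn_backward("bn1", da1, cache, grads)
        grads["conv_W"] = np.einsum("npk,npd->kd", dz1, cache["patches"])
        grads["conv_b"] = dz1.sum(axis=(0, 1))
        dpatch = dz1 @ p["conv_W"]                           # (n, P, kh*C)
        dh0 = np.zeros((n, cfg.T, cfg.C))
        dpatch = dpatch.reshape(n, cfg.positions, cfg.kernel_height, cfg.C)
        for pos in range(cfg.positions):
            dh0[:, pos * cfg.S : pos * cfg.S + cfg.kernel_height, :] += dpatch[:, pos]
        self._bn_backward("bn0", dh0, cache, grads)

        if weight_decay > 0:
            for k in _DECAYED:
                grads[k] = grads[k] + weight_decay * p[k]
        return float(loss), grads

    # ------------------------------------------------------------------ misc

    def trainable_keys(self) -> list[str]:
        keys = []
        for layer, names in _LAYER_PARAMS.items():
            if layer in self.frozen:
                continue
            keys.extend(k for k in names if not k.endswith(("_mean", "_var")))
        return keys

    def copy(self) -> "CNNModel":
        return CNNModel(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            frozen=self.frozen,
            history=copy.deepcopy(self.history),
        )

    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "frozen": sorted(self.frozen)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "CNNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(config=CNNConfig(**meta["config"]), params=params, frozen=frozenset(meta["frozen"]))


def build_cnn(cfg: CNNConfig, seed: int = 0) -> CNNModel:
    """Fresh network with seed-determined He-scaled initial weights."""
    return CNNModel(config=cfg, params=_init_params(cfg, seed))


def _evaluate_loss(model: CNNModel, x: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
    total = 0.0
    for i in range(0, len(x), batch):
        probs, _ = model.forward(x[i : i + batch], train=False)
        total += -np.log(probs[np.arange(len(probs)), y[i : i + batch]] + 1e-12).sum()
    return total / len(x)


def train_cnn(model: CNNModel, data: EpochSet, cfg: TrainConfig) -> CNNModel:
    """SGD training with early stopping on a held-out validation split.

    Returns a new model holding the parameters with the best validation loss
    seen during training; the input model is not modified.  Frozen layers of
    ``model`` stay untouched throughout.
    """
    x = data.epochs
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)

    n = len(x)
    perm = rng.permutation(n)
    n_val = int(round(n * cfg.validation_fraction))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training data")
    x_val, y_val = (x[val_idx], y[val_idx]) if n_val else (x[train_idx], y[train_idx])

    keys = model.trainable_keys()
    velocity = {k: np.zeros_like(model.params[k]) for k in keys}
    best = model.copy()
    best_loss = np.inf
    history = {"train_loss": [], "val_loss": []}
    stall = 0

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = train_idx[order[start : start + cfg.batch_size]]
            loss, grads = model.loss_and_grads(x[idx], y[idx], cfg.weight_decay, train=True)
            epoch_loss += loss * len(idx)
            for k in keys:
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * grads[k]
                model.params[k] += velocity[k]
        history["train_loss"].append(epoch_loss / len(train_idx))
        val_loss = _evaluate_loss(model, x_val, y_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best = model.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    best.history = history
    return best


def fine_tune(pretrained: CNNModel, target_data: EpochSet, cfg: TrainConfig) -> CNNModel:
    """Adapt a pre-trained network to a new subject with the front-end frozen.

    Both batch-norm layers and the convolution keep their pre-trained
    parameters and running statistics bit-for-bit; only the two dense layers
    are updated on the target data.
    """
    t, c = target_data.shape_tc
    if (t, c) != (pretrained.config.T, pretrained.config.C):
        raise ValueError("target epochs do not match the pretrained input shape")
    if target_data.n_epochs == 0:
        raise ValueError("target data is empty")
    model = pretrained.copy()
    model.frozen = frozenset(FROZEN_FRONT_END)
    return train_cnn(model, target_data, cfg)


def extract_features(model: CNNModel, data: EpochSet, layer: str = "fc1") -> FeatureSet:
    """Deep features for each epoch: post-ReLU activations of ``layer``.

    ``layer="fc1"`` (default) gives the f-dimensional first-dense-layer
    features used by alignment and classification; ``layer="conv"`` gives the
    flattened post-ReLU convolution output instead.
    """
    if layer not in ("fc1", "conv"):
        raise ValueError("layer must be 'fc1' or 'conv'")
    feats = []
    for i in range(0, data.n_epochs, 512):
        _, cache = model.forward(data.epochs[i : i + 512], train=False)
        feats.append(cache["a2"] if layer == "fc1" else cache["flat"])
    return FeatureSet(features=np.vstack(feats), meta=data.meta.copy())


def predict_proba(model: CNNModel, data: EpochSet) -> np.ndarray:
    """Per-epoch target-class probability from the softmax output."""
    out = []
    for i in range(0, data.n_epochs, 512):
        probs, _ = model.forward(data.epochs[i : i + 512], train=False)
        out.append(probs[:, 1])
    return np.concatenate(out)
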