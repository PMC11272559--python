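"""Discriminative restricted Boltzmann machine for two-class feature vectors.

A joint RBM over (input x, one-hot label y, binary hidden units h) has energy

    E(y, x, h) = -h^T W x - c^T h - b_y - h^T U e_y .

Marginalizing the hidden layer analytically gives an exact, tractable
conditional,

    p(y | x)  proportional to  exp( b_y + sum_j softplus(c_j + U_{jy} + W_j x) ),

so the model can be trained *discriminatively* by gradient ascent on
mean log p(y|x) with the exact analytic gradient — no Gibbs sampling or
contrastive divergence is involved.  Inputs are used as real-valued features
(the conditional only ever multiplies x by W, so binary visible units are not
required).  The default hidden-layer size is 10.

A generative-objective mixing weight ``alpha`` is exposed for API
compatibility with hybrid discriminative/generative training, but only the
pure discriminative objective (alpha = 0) is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .containers import FeatureSet

__all__ = ["DRBMParams", "drbm_conditional", "train_drbm", "predict_proba", "predict_proba_batch"]


@dataclass
class DRBMParams:
    """Weights of a two-class DRBM with H hidden units."""

    W: np.ndarray  # (H, f) input-to-hidden
    c: np.ndarray  # (H,) hidden biases
    U: np.ndarray  # (H, classes) class-to-hidden
    b: np.ndarray  # (classes,) class biases

    def __post_init__(self) -> None:
        for a in (self.W, self.c, self.U, self.b):
            if not np.all(np.isfinite(a)):
                raise ValueError("DRBM parameters must be finite")
        if self.W.shape[0] != self.c.shape[0] or self.U.shape != (self.W.shape[0], self.b.shape[0]):
            raise ValueError("inconsistent DRBM parameter shapes")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_classes(self) -> int:
        return self.b.shape[0]

    @classmethod
    def init(cls, f: int, n_hidden: int = 10, n_classes: int = 2, seed: int = 0) -> "DRBMParams":
        rng = np.random.default_rng(seed)
        return cls(
            W=rng.normal(0.0, 0.01, size=(n_hidden, f)),
            c=np.zeros(n_hidden),
            U=rng.normal(0.0, 0.01, size=(n_hidden, n_classes)),
            b=np.zeros(n_classes),
        )

    def save(self, path) -> None:
        meta = {"n_hidden": self.n_hidden, "n_classes": self.n_classes}
        np.savez(path, W=self.W, c=self.c, U=self.U, b=self.b,
                 __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "DRBMParams":
        with np.load(path) as d:
            return cls(W=d["W"], c=d["c"], U=d["U"], b=d["b"])


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _class_free_energies(params: DRBMParams, x: np.ndarray) -> np.ndarray:
    """(n, classes) matrix F_y(x) = b_y + sum_j softplus(c_j + U_jy + W_j x)."""
    pre = x @ params.W.T + params.c            # (n, H)
    # (n, H, classes) broadcast of the per-class hidden pre-activations
    z = pre[:, :, None] + params.U[None, :, :]
    return params.b[None, :] + _softplus(z).sum(axis=1)


def drbm_conditional(params: DRBMParams, x: np.ndarray) -> np.ndarray:
    """Exact p(y|x) for one feature vector, via log-sum-exp."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if x.shape[0] != params.W.shape[1]:
        raise ValueError("input dimension does not match DRBM")
    f = _class_free_energies(params, x[None, :])[0]
    f -= f.max()
    p = np.exp(f)
    return p / p.sum()


def _objective_and_grads(params: DRBMParams, x: np.ndarray, y: np.ndarray):
    """Mean log p(y|x) and its exact analytic gradient over a batch."""
    n, _ = x.shape
    fe = _class_free_energies(params, x)                    # (n, classes)
    fe_shift = fe - fe.max(axis=1, keepdims=True)
    expf = np.exp(fe_shift)
    post = expf / expf.sum(axis=1, keepdims=True)           # p(y'|x)
    obj = float(np.mean(fe_shift[np.arange(n), y] - np.log(expf.sum(axis=1))))

    pre = x @ params.W.T + params.c                         # (n, H)
    sig = 1.0 / (1.0 + np.exp(-(pre[:, :, None] + params.U[None, :, :])))  # (n, H, classes)

    onehot = np.zeros_like(post)
    onehot[np.arange(n), y] = 1.0
    coef = onehot - post                                    # (n, classes)

    grad_b = coef.mean(axis=0)
    grad_U = np.einsum("nhc,nc->hc", sig, coef) / n
    # d/dc_j and d/dW_j collapse the class axis with the same coefficients
    sig_coef = np.einsum("nhc,nc->nh", sig, coef)           # (n, H)
    grad_c = sig_coef.mean(axis=0)
    grad_W = sig_coef.T @ x / n
    return obj, {"W": grad_W, "c": grad_c, "U": grad_U, "b": grad_b}


def train_drbm(
    data: FeatureSet,
    n_hidden: int = 10,
    learning_rate: float = 0.05,
    max_epochs: int = 200,
    batch_size: int = 128,
    alpha: float = 0.0,
    seed: int = 0,
) -> DRBMParams:
    """Fit the DRBM by stochastic gradient ascent on mean log p(y|x).

    ``alpha`` weights an additional generative objective in hybrid training;
    only alpha = 0 (pure discriminative) is implemented.
    """
    if alpha != 0.0:
        raise NotImplementedError("only the pure discriminative objective (alpha=0) is implemented")
    x = data.features
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    params = DRBMParams.init(f=x.shape[1], n_hidden=n_hidden, seed=seed)
    rng = np.random.default_rng(seed)
    for _epoch in range(max_epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            _, grads = _objective_and_grads(params, x[idx], y[idx])
            params.W += learning_rate * grads["W"]
            params.c += learning_rate * grads["c"]
            params.U += learning_rate * grads["U"]
            params.b += learning_rate * grads["b"]
    return params


def predict_proba_batch(params: DRBMParams, x: np.ndarray) -> np.ndarray:
    """Target-class probability p(y=1|x) for each row of x."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] != params.W.shape[1]:
        raise ValueError("feature dimension does not match DRBM")
    fe = _class_free_energies(params, x)
    fe -= fe.max(axis=1, keepdims=True)
    expf = np.exp(fe)
    return expf[:, 1] / expf.sum(axis=1)


def predict_proba(params: DRBMParams, feats: FeatureSet) -> np.ndarray:
    """Per-epoch target probability for a feature set."""
    return predict_proba_batch(params, feats.features)
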