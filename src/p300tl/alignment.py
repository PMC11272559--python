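"""Euclidean alignment of feature sets.

Each subject's features are whitened by the inverse square root of their
reference matrix — the mean outer product of the feature vectors,

    R_bar = (1/N) * sum_n y_n y_n^T,        y_tilde_n = R_bar^(-1/2) y_n,

so that aligned features from any subject share an identity second moment.
This removes affine cross-subject distribution shift without using labels.
The reference can be computed offline from all trials at once, or updated
online one unlabeled trial at a time via the running-mean identity
R_new = (n R + y y^T)/(n + 1); after the full stream both routes give the
same matrix.

ReLU features are nonnegative and often correlated, so R_bar can be
rank-deficient; a scale-aware ridge eps = 1e-6 * trace(R)/f is added to the
diagonal before inversion (it vanishes relative to the spectrum in the
well-conditioned limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureSet

#: relative ridge applied to the reference diagonal before inversion
DEFAULT_EPS_SCALE = 1e-6

__all__ = ["AlignmentReference", "inv_sqrt", "compute_reference", "align", "online_update"]


def _check_symmetric(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric")
    return 0.5 * (m + m.T)


def inv_sqrt(m: np.ndarray, eps: float) -> np.ndarray:
    """Symmetric inverse square root of ``m + eps*I`` via eigendecomposition.

    Eigenvalues are floored at ``eps`` so the result is well defined for
    nonnegative-definite input with numerically negative eigenvalues.
    """
    if not eps > 0:
        raise ValueError("eps must be positive")
    m = _check_symmetric(m)
    vals, vecs = np.linalg.eigh(m + eps * np.eye(len(m)))
    vals = np.maximum(vals, eps)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


@dataclass
class AlignmentReference:
    """Reference matrix R_bar with its cached regularized inverse square root."""

    R: np.ndarray
    n_seen: int
    eps: float
    W: np.ndarray

    @property
    def dim(self) -> int:
        return self.R.shape[0]

    def save(self, path) -> None:
        np.savez(path, R=self.R, n_seen=self.n_seen, eps=self.eps, W=self.W)

    @classmethod
    def load(cls, path) -> "AlignmentReference":
        with np.load(path) as d:
            return cls(R=d["R"], n_seen=int(d["n_seen"]), eps=float(d["eps"]), W=d["W"])

    @classmethod
    def empty(cls, dim: int, eps_scale: float = DEFAULT_EPS_SCALE) -> "AlignmentReference":
        """Zero-trial reference (identity map) for online accumulation."""
        eps = max(eps_scale, np.finfo(np.float64).tiny)
        return cls(R=np.zeros((dim, dim)), n_seen=0, eps=eps, W=np.eye(dim))


def _finalize(r: np.ndarray, n_seen: int, eps: float | None) -> AlignmentReference:
    if eps is None:
        trace = float(np.trace(r))
        eps = max(DEFAULT_EPS_SCALE * trace / len(r), np.finfo(np.float64).tiny)
    return AlignmentReference(R=r, n_seen=n_seen, eps=eps, W=inv_sqrt(r, eps))


def compute_reference(feats: FeatureSet, eps: float | None = None) -> AlignmentReference:
    """Offline reference: mean outer product over all N feature vectors."""
    y = feats.features
    if len(y) == 0:
        raise ValueError("cannot compute a reference from an empty feature set")
    r = (y.T @ y) / len(y)
    return _finalize(r, len(y), eps)


def align(feats: FeatureSet, ref: AlignmentReference) -> FeatureSet:
    """Map every feature vector through the whitening transform W."""
    if feats.dim != ref.dim:
        raise ValueError(f"feature dimension {feats.dim} does not match reference {ref.dim}")
    return FeatureSet(features=feats.features @ ref.W.T, meta=feats.meta.copy())


def online_update(ref: AlignmentReference, y: np.ndarray) -> AlignmentReference:
    """Fold one unlabeled trial into the reference (running mean of outer products)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != ref.dim:
        raise ValueError("trial dimension does not match reference")
    if not np.all(np.isfinite(y)):
        raise ValueError("trial contains non-finite values")
    n = ref.n_seen
    r_new = (n * ref.R + np.outer(y, y)) / (n + 1)
    # keep the eps policy consistent with the offline path (scale-aware ridge)
    return _finalize(r_new, n + 1, None)
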