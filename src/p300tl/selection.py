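"""Source data selection for transfer learning.

Two complementary strategies:

* distance-based source *sample* selection — average the (aligned) target
  features into a reference vector r, rank every source sample by its
  Euclidean distance to r, and keep the k closest.  Dropping the most
  dissimilar source samples mitigates negative transfer.
* performance-based source *subject* selection — train one classifier per
  candidate source subject and keep the subject whose classifier scores
  highest on a held-out slice of the target subject's training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .containers import EpochSet, FeatureSet

__all__ = ["SelectionResult", "select_source_samples", "select_source_subject"]


@dataclass
class SelectionResult:
    """k selected source indices, their distances (ascending) and the target reference."""

    indices: np.ndarray
    distances: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.indices) != len(self.distances):
            raise ValueError("indices and distances must have equal length")


def select_source_samples(target_feats: FeatureSet, source_feats: FeatureSet, k: int) -> SelectionResult:
    """Keep the k source samples closest (Euclidean) to the target mean feature.

    Distance ties are broken toward the lower source index (stable sort), so
    the selection is deterministic.
    """
    if len(target_feats) == 0:
        raise ValueError("target feature set is empty")
    if target_feats.dim != source_feats.dim:
        raise ValueError("target and source feature dimensions differ")
    n_s = len(source_feats)
    if not 1 <= k <= n_s:
        raise ValueError(f"k must lie in [1, {n_s}], got {k}")
    r = target_feats.features.mean(axis=0)
    d = np.linalg.norm(source_feats.features - r, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return SelectionResult(indices=order, distances=d[order], reference=r)


def select_source_subject(
    candidates: Sequence[tuple[EpochSet, int]],
    target_train: EpochSet,
    eval_fraction: float,
    trainer: Callable[[EpochSet], Callable[[EpochSet], np.ndarray]],
) -> int:
    """Pick the source subject whose classifier transfers best to the target.

    ``trainer`` maps an EpochSet to a fitted predictor returning per-epoch
    target probabilities.  Each candidate's classifier is trained on that
    candidate's full data and evaluated (accuracy at threshold 0.5) on the
    last ``eval_fraction`` of the target training trials in session order.
    Ties go to the lowest subject id.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate source subjects")
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError("eval_fraction must lie strictly in (0, 1)")
    n_eval = int(round(target_train.n_epochs * eval_fraction))
    if n_eval < 1:
        raise ValueError("eval_fraction leaves no evaluation trials")
    eval_set = target_train.subset(np.arange(target_train.n_epochs - n_eval, target_train.n_epochs))

    best_id, best_acc = None, -np.inf
    for data, subject_id in sorted(candidates, key=lambda c: c[1]):
        predict = trainer(data)
        proba = np.asarray(predict(eval_set))
        acc = float(((proba >= 0.5).astype(int) == eval_set.labels).mean())
        if acc > best_acc:
            best_id, best_acc = subject_id, acc
    return best_id
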