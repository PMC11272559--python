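"""End-to-end orchestration of the transfer-learning pipeline.

Training stage: pre-train the CNN on the source subject, fine-tune it on the
target subject's (small) calibration set with the front-end frozen, extract
deep features from both subjects, Euclidean-align each subject's features
with its own reference, select the source samples closest to the target
reference, and train the DRBM on the union of selected source features and
target features.

Test stage: extract features of unseen target trials with the fine-tuned
CNN, align them into the same space — offline (reference from all test
trials at once) or online (reference updated one unlabeled trial at a
time) — classify with the DRBM, and decode speller characters per
repetition budget.

Ablation switches (``use_finetune``, ``use_alignment``, ``use_selection``)
reproduce the comparison variants: a scratch CNN trained on the target only;
fine-tuning alone (classifier sees target features only); fine-tuning plus
alignment (classifier sees aligned source + target features); and the full
pipeline with source sample selection.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentReference, align, compute_reference, online_update
from .cnn import CNNConfig, CNNModel, TrainConfig, build_cnn, extract_features, fine_tune, train_cnn
from .containers import EpochSet, FeatureSet, concat_features
from .decoding import SpellerResult, decode_session
from .drbm import DRBMParams, predict_proba_batch, train_drbm
from .selection import SelectionResult, select_source_samples

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "TrainedArtifacts", "TestOutput", "run_training_stage", "run_test_stage"]


@dataclass
class PipelineConfig:
    """Everything that determines a pipeline run (together with the seed)."""

    cnn: CNNConfig
    train: TrainConfig = field(default_factory=TrainConfig)
    k: int | None = None          # source samples kept; None -> 50%, 0 -> target-only
    eps: float | None = None      # alignment ridge; None -> scale-aware default
    ea_mode: str = "offline"
    use_finetune: bool = True
    use_alignment: bool = True
    use_selection: bool = True
    drbm_hidden: int = 10
    drbm_learning_rate: float = 0.05
    drbm_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ea_mode not in ("offline", "online"):
            raise ValueError("ea_mode must be 'offline' or 'online'")
        if self.use_selection and not self.use_alignment:
            raise ValueError("source sample selection requires alignment (shared feature space)")


@dataclass
class TrainedArtifacts:
    """Serialized outcome of the training stage."""

    config: PipelineConfig
    source_model: CNNModel | None
    target_model: CNNModel
    source_ref: AlignmentReference | None
    target_ref: AlignmentReference | None
    selection: SelectionResult | None
    drbm: DRBMParams
    stages: list[str] = field(default_factory=list)


@dataclass
class TestOutput:
    """Per-epoch target probabilities and, for speller sessions, decoded characters."""

    probabilities: np.ndarray
    scores: pd.DataFrame
    speller: SpellerResult | None


def _stage(name: str, stages: list[str], fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as e:  # noqa: BLE001 - annotate failures with the stage name
        raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
    stages.append(name)
    logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
    return out


def run_training_stage(
    cfg: PipelineConfig, source: EpochSet | None, target_train: EpochSet
) -> TrainedArtifacts:
    """Run pre-train -> fine-tune -> extract -> align -> select -> train-DRBM."""
    stages: list[str] = []
    source_model = None

    if cfg.use_finetune:
        if source is None:
            raise ValueError("fine-tuning requires a source epoch set")
        if source.shape_tc != target_train.shape_tc:
            raise ValueError("source and target epoch shapes differ")
        source_model = _stage(
            "pretrain", stages,
            lambda: train_cnn(build_cnn(cfg.cnn, cfg.seed), source, cfg.train),
        )
        target_model = _stage(
            "finetune", stages,
            lambda: fine_tune(source_model, target_train, cfg.train),
        )
    else:
        target_model = _stage(
            "scratch", stages,
            lambda: train_cnn(build_cnn(cfg.cnn, cfg.seed), target_train, cfg.train),
        )

    def _extract():
        tgt = extract_features(target_model, target_train)
        src = extract_features(source_model, source) if (cfg.use_alignment and source_model) else None
        return tgt, src

    target_feats, source_feats = _stage("extract", stages, _extract)

    source_ref = target_ref = None
    if cfg.use_alignment:
        def _align():
            t_ref = compute_reference(target_feats, cfg.eps)
            t_al = align(target_feats, t_ref)
            if source_feats is not None:
                s_ref = compute_reference(source_feats, cfg.eps)
                s_al = align(source_feats, s_ref)
            else:
                s_ref, s_al = None, None
            return t_ref, t_al, s_ref, s_al

        target_ref, target_al, source_ref, source_al = _stage("align", stages, _align)
    else:
        target_al, source_al = target_feats, None

    selection = None
    if cfg.use_selection and source_al is not None:
        k = cfg.k if cfg.k is not None else len(source_al) // 2
        if k > 0:
            selection = _stage(
                "select", stages,
                lambda: select_source_samples(target_al, source_al, min(k, len(source_al))),
            )

    def _train_drbm():
        train_set = target_al
        if source_al is not None:
            src = source_al.subset(selection.indices) if selection is not None else source_al
            if cfg.k == 0:
                src = None  # degenerate configuration: target-only training
            if src is not None:
                train_set = concat_features(src, target_al)
        return train_drbm(
            train_set,
            n_hidden=cfg.drbm_hidden,
            learning_rate=cfg.drbm_learning_rate,
            max_epochs=cfg.drbm_epochs,
            seed=cfg.seed,
        )

    drbm = _stage("train_drbm", stages, _train_drbm)
    return TrainedArtifacts(
        config=cfg, source_model=source_model, target_model=target_model,
        source_ref=source_ref, target_ref=target_ref, selection=selection,
        drbm=drbm, stages=stages,
    )


def run_test_stage(artifacts: TrainedArtifacts, test_epochs: EpochSet, mode: str | None = None) -> TestOutput:
    """Classify unseen target trials and decode characters where applicable.

    ``mode`` overrides the configured alignment mode: "offline" computes the
    test reference from all trials before classification; "online" folds one
    unlabeled trial at a time into the reference and aligns each trial with
    the reference current at that point in the stream.
    """
    if test_epochs.n_epochs == 0:
        raise ValueError("test epoch set is empty")
    cfg = artifacts.config
    mode = mode or cfg.ea_mode
    if mode not in ("offline", "online"):
        raise ValueError("mode must be 'offline' or 'online'")

    feats = extract_features(artifacts.target_model, test_epochs)
    if cfg.use_alignment:
        if mode == "offline":
            ref = compute_reference(feats, cfg.eps)
            aligned = align(feats, ref).features
        else:
            ref = AlignmentReference.empty(feats.dim)
            aligned = np.empty_like(feats.features)
            for i, y in enumerate(feats.features):
                ref = online_update(ref, y)
                aligned[i] = ref.W @ y
    else:
        aligned = feats.features

    probs = predict_proba_batch(artifacts.drbm, aligned)
    scores = feats.meta.copy()
    scores["score"] = probs

    speller = None
    if (scores["code"] > 0).all() and (scores["character_index"] >= 0).all():
        speller = decode_session(scores)
    return TestOutput(probabilities=probs, scores=scores, speller=speller)
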