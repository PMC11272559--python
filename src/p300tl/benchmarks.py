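"""Reproducible two-subject benchmark scenarios for the full pipeline.

These scenarios are the package's standard test bed: they fix the synthetic
study conditions (sample sizes, noise levels, cross-subject shifts) once, so
that pipeline-level claims — noise-free decodability, offline vs online
agreement, and the ablation ordering of the transfer-learning stages — are
evaluated under the same conditions everywhere (test suite, scripts, docs).

Two scenarios are provided:

* ``noise_free_speller_benchmark`` — a zero-noise, zero-jitter matrix-speller
  pair of subjects.  With a clean ERP template the full pipeline must decode
  every test character at the maximum repetition budget.

* ``rsvp_transfer_benchmark`` — a noisy RSVP pair of subjects built to probe
  each pipeline stage.  The target subject has only a short calibration block
  (200 trials at a 1:9 target ratio, i.e. ~20 target examples), so a
  classifier trained on target data alone is starved.  The source session is
  half clean, half corrupted: the corrupted block emulates an inattentive,
  artifact-laden recording stretch — no P300 in its target-labeled trials and
  three-fold background noise.  Its mislabeled trials hurt any classifier
  that consumes them (negative transfer), while its elevated noise makes the
  whole block an outlier cloud in feature space that distance-based source
  selection can prune.

Both scenarios use a scaled-down montage (8 channels) and network (f = 16
features for the speller variant) so a full multi-seed ablation runs in
seconds per seed on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import compute_reference, align
from .cnn import CNNConfig, TrainConfig, build_cnn, extract_features, fine_tune, train_cnn
from .containers import EpochSet, concat_features
from .decoding import SPELLER_ALPHABET, bca, confusion_counts
from .drbm import train_drbm, predict_proba_batch
from .preprocessing import bandpass_filter, epoch_extract
from .selection import select_source_samples
from .synthetic import (
    ERPTemplate,
    RSVPConfig,
    SpellerConfig,
    SubjectShift,
    simulate_rsvp_session,
    simulate_speller_session,
)

ABLATION_VARIANTS = ("scratch", "finetune", "finetune_ea", "finetune_ea_sss")

#: scaled-down speller network: 80x8 epochs (665 ms at 120 Hz), 8 kernels
SMALL_SPELLER_CNN = CNNConfig(T=80, C=8, K=8, kernel_height=8, S=8, f=16)


def _speller_epochs(cfg: SpellerConfig, template: ERPTemplate, shift, truth=None) -> EpochSet:
    rec = simulate_speller_session(cfg, template, shift, truth)
    rec = bandpass_filter(rec, 0.1, 30.0)
    return epoch_extract(rec, (0.0, 0.665))


def _rsvp_epochs(cfg: RSVPConfig, template: ERPTemplate, shift) -> EpochSet:
    rec = simulate_rsvp_session(cfg, template, shift)
    rec = bandpass_filter(rec, 0.15, 28.0)
    return epoch_extract(rec, (0.0, 0.7))


def noise_free_speller_benchmark(
    seed: int = 0,
    n_source_chars: int = 4,
    n_train_chars: int = 2,
    n_test_chars: int = 3,
    n_repetitions: int = 15,
) -> tuple[EpochSet, EpochSet, EpochSet, str]:
    """Zero-noise speller pair: (source, target_train, target_test, test truth)."""
    template = ERPTemplate(amplitude=5.0)
    base = dict(
        n_repetitions=n_repetitions, n_channels=8, fs=120.0,
        noise_scale=0.0, latency_jitter_sd=0.0,
    )
    rng = np.random.default_rng(seed)
    source = _speller_epochs(
        SpellerConfig(n_characters=n_source_chars, subject_seed=seed * 11 + 1, **base),
        template, None,
    )
    n_tgt = n_train_chars + n_test_chars
    truth = "".join(rng.choice(list(SPELLER_ALPHABET), size=n_tgt))
    target = _speller_epochs(
        SpellerConfig(n_characters=n_tgt, subject_seed=seed * 11 + 2, **base),
        template, None, truth,
    )
    ci = target.meta["character_index"].to_numpy()
    train = target.subset(np.flatnonzero(ci < n_train_chars))
    test = target.subset(np.flatnonzero(ci >= n_train_chars))
    return source, train, test, truth[n_train_chars:]


def rsvp_transfer_benchmark(
    seed: int,
    source_noise: float = 5.0,
    target_noise: float = 8.0,
    n_clean: int = 600,
    n_corrupted: int = 600,
    n_calibration: int = 200,
    n_test: int = 480,
) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Noisy RSVP pair: (source, target_calibration, target_test).

    The source session concatenates a clean block and a corrupted block
    (inattentive: no ERP under its target labels, three-fold noise).  Source
    and target subjects differ by a mild rotation of the channel topography
    and an up-to-4x gain difference.
    """
    template = ERPTemplate(amplitude=5.0)
    absent = ERPTemplate(amplitude=0.0)
    src_shift = SubjectShift.mild(8, seed=seed * 7 + 1)
    tgt_shift = SubjectShift.mild(8, seed=seed * 7 + 2)

    clean = _rsvp_epochs(
        RSVPConfig(n_trials=n_clean, subject_seed=seed * 11 + 3, noise_scale=source_noise),
        template, src_shift,
    )
    corrupted = _rsvp_epochs(
        RSVPConfig(n_trials=n_corrupted, subject_seed=seed * 11 + 4, noise_scale=3.0 * source_noise),
        absent, src_shift,
    )
    source = EpochSet(
        np.concatenate([clean.epochs, corrupted.epochs]),
        clean.fs,
        pd.concat([clean.meta, corrupted.meta], ignore_index=True),
    )
    target = _rsvp_epochs(
        RSVPConfig(n_trials=n_calibration + n_test, subject_seed=seed * 11 + 5, noise_scale=target_noise),
        template, tgt_shift,
    )
    idx = np.arange(target.n_epochs)
    return source, target.subset(idx[:n_calibration]), target.subset(idx[n_calibration:])


def run_ablation_variant(
    source: EpochSet,
    target_train: EpochSet,
    target_test: EpochSet,
    variant: str,
    seed: int,
    cnn_config: CNNConfig | None = None,
    train_config: TrainConfig | None = None,
) -> float:
    """Balanced accuracy (percent) of one pipeline variant on the test block.

    Variants: ``scratch`` (target-only CNN, no transfer), ``finetune``
    (pre-train + frozen-front-end fine-tune, classifier on target features
    only), ``finetune_ea`` (adds Euclidean-aligned source features to the
    classifier) and ``finetune_ea_sss`` (adds distance-based source sample
    selection, keeping the closest 50%).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    t, c = target_train.shape_tc
    cnn_config = cnn_config or (CNNConfig.for_rsvp() if (t, c) == (45, 8) else SMALL_SPELLER_CNN)
    train_config = train_config or TrainConfig(max_epochs=40, patience=8, seed=seed)

    if variant == "scratch":
        source_model = None
        target_model = train_cnn(build_cnn(cnn_config, seed), target_train, train_config)
    else:
        source_model = train_cnn(build_cnn(cnn_config, seed), source, train_config)
        target_model = fine_tune(source_model, target_train, train_config)

    target_feats = extract_features(target_model, target_train)
    test_feats = extract_features(target_model, target_test)

    if variant in ("scratch", "finetune"):
        train_set = target_feats
        test_x = test_feats.features
    else:
        target_aligned = align(target_feats, compute_reference(target_feats))
        source_feats = extract_features(source_model, source)
        source_aligned = align(source_feats, compute_reference(source_feats))
        if variant == "finetune_ea_sss":
            keep = select_source_samples(target_aligned, source_aligned, len(source_aligned) // 2)
            source_aligned = source_aligned.subset(keep.indices)
        train_set = concat_features(source_aligned, target_aligned)
        test_x = align(test_feats, compute_reference(test_feats)).features

    params = train_drbm(train_set, seed=seed)
    predicted = (predict_proba_batch(params, test_x) >= 0.5).astype(int)
    return 100.0 * bca(confusion_counts(target_test.labels, predicted))


def ablation_bca(seeds, **scenario_kwargs) -> pd.DataFrame:
    """Run all four variants over the given seeds; one row per seed."""
    rows = {}
    for seed in seeds:
        source, train, test = rsvp_transfer_benchmark(seed, **scenario_kwargs)
        rows[seed] = {
            v: run_ablation_variant(source, train, test, v, seed) for v in ABLATION_VARIANTS
        }
    return pd.DataFrame(rows).T
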