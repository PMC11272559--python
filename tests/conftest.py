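import numpy as np
import pandas as pd
import pytest

from p300tl import ERPTemplate, EpochSet, FeatureSet, SpellerConfig, simulate_speller_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return ERPTemplate(duration=0.6, peak_latency=0.3, peak_width=0.2, amplitude=5.0)


@pytest.fixture
def tiny_speller_recording(template):
    """Two characters, three repetitions, 8 channels at 120 Hz."""
    cfg = SpellerConfig(
        n_characters=2, n_repetitions=3, n_channels=8, fs=120.0,
        noise_scale=2.0, latency_jitter_sd=0.0, subject_seed=7,
    )
    return simulate_speller_session(cfg, template, None, "AB")


def make_feature_set(features: np.ndarray, labels=None) -> FeatureSet:
    n = len(features)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    meta = pd.DataFrame(
        {"label": labels, "code": np.zeros(n, dtype=int),
         "character_index": -np.ones(n, dtype=int), "repetition_index": -np.ones(n, dtype=int)}
    )
    return FeatureSet(features=np.asarray(features, dtype=float), meta=meta)


def make_epoch_set(epochs: np.ndarray, labels, fs: float = 120.0) -> EpochSet:
    n = len(epochs)
    meta = pd.DataFrame(
        {"label": np.asarray(labels), "code": np.zeros(n, dtype=int),
         "character_index": -np.ones(n, dtype=int), "repetition_index": -np.ones(n, dtype=int)}
    )
    return EpochSet(epochs=np.asarray(epochs, dtype=float), fs=fs, meta=meta)
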