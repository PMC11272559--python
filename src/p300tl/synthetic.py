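"""Synthetic P300 session generator for the matrix speller and RSVP paradigms.

Every downstream stage of the transfer-learning pipeline (filtering, epoching,
CNN feature extraction, Euclidean alignment, source selection, DRBM) is
testable against sessions generated here, with controllable ERP amplitude,
latency jitter, background noise and cross-subject shift, and with bit-exact
reproducibility from a seed.

The speller paradigm follows the classic 6x6 row/column design: each
repetition flashes the 6 rows (codes 1-6) and 6 columns (codes 7-12) once in
random order, so exactly 2 of the 12 flashes per repetition are targets.  The
RSVP paradigm presents a rapid stream of single stimuli with a rare-target
ratio of about 1:9.

Background activity is modelled as per-channel AR(1) noise (coefficient 0.95,
giving a 1/f-like low-frequency-heavy spectrum) plus white noise, both scaled
so the summed standard deviation equals ``noise_scale`` microvolts.  The
cross-subject shift is a random orthogonal channel mixing times a scalar gain
plus a template latency offset — invertible and energy-preserving, emulating
the distribution shift that Euclidean alignment is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContinuousRecording
from .decoding import SPELLER_ALPHABET, char_to_rowcol

N_CODES = 12  # 6 rows + 6 columns per repetition
AR_COEFF = 0.95

__all__ = [
    "ERPTemplate",
    "SpellerConfig",
    "RSVPConfig",
    "SubjectShift",
    "make_erp_template",
    "simulate_speller_session",
    "simulate_rsvp_session",
]


@dataclass
class ERPTemplate:
    """Stereotyped target response: a positive Gaussian-shaped deflection.

    The peak sits at ``peak_latency`` seconds after stimulus onset (the P300
    nominally peaks near 0.3 s); ``peak_width`` is the full width at half
    maximum; ``channel_weights`` scales the deflection per channel (scalp
    topography stand-in).
    """

    duration: float = 0.6
    peak_latency: float = 0.3
    peak_width: float = 0.2
    amplitude: float = 5.0
    channel_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.channel_weights is not None:
            self.channel_weights = np.asarray(self.channel_weights, dtype=np.float64)


@dataclass
class SpellerConfig:
    """6x6 matrix-speller session layout.

    Defaults mirror the standard competition paradigm: 64 channels at 240 Hz,
    15 repetitions of 12 intensifications per character, and a stimulus onset
    asynchrony of 0.175 s (0.100 s flash + 0.075 s gap).  ``pre_char_gap`` is
    the pause before each character block (the 2.5 s selection time).
    """

    n_characters: int = 85
    n_repetitions: int = 15
    n_channels: int = 64
    fs: float = 240.0
    soa: float = 0.175
    pre_char_gap: float = 2.5
    noise_scale: float = 5.0
    latency_jitter_sd: float = 0.020
    subject_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_repetitions <= 15:
            raise ValueError("n_repetitions must lie in [1, 15]")
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")


@dataclass
class RSVPConfig:
    """Rapid serial visual presentation stream (rare targets among distractors)."""

    n_trials: int = 500
    target_fraction: float = 0.1
    n_channels: int = 8
    fs: float = 64.0
    rate: float = 5.0
    noise_scale: float = 5.0
    latency_jitter_sd: float = 0.020
    subject_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must lie strictly in (0, 1)")
        if self.rate <= 0 or self.fs <= 0:
            raise ValueError("rate and fs must be positive")


@dataclass
class SubjectShift:
    """Cross-subject linear distortion: channel mixing x gain + latency offset."""

    mixing: np.ndarray
    gain: float = 1.0
    latency_shift: float = 0.0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.mixing.ndim != 2 or self.mixing.shape[0] != self.mixing.shape[1]:
            raise ValueError("mixing must be a square matrix")
        if np.linalg.cond(self.mixing) > 1e6:
            raise ValueError("mixing is ill-conditioned (not reliably invertible)")

    @classmethod
    def identity(cls, n_channels: int) -> "SubjectShift":
        return cls(mixing=np.eye(n_channels))

    @classmethod
    def random(
        cls,
        n_channels: int,
        seed: int,
        gain_range: tuple[float, float] = (0.7, 1.4),
        latency_sd: float = 0.02,
    ) -> "SubjectShift":
        """Random orthogonal mixing with a per-subject gain and latency offset."""
        rng = np.random.default_rng(seed)
        q, r = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
        q *= np.sign(np.diag(r))  # fix the QR sign ambiguity -> Haar orthogonal
        gain = rng.uniform(*gain_range)
        latency = rng.normal(0.0, latency_sd)
        return cls(mixing=q, gain=gain, latency_shift=latency)

    @classmethod
    def mild(
        cls,
        n_channels: int,
        seed: int,
        angle: float = 0.3,
        gain_range: tuple[float, float] = (0.5, 2.0),
        latency_sd: float = 0.02,
    ) -> "SubjectShift":
        """Small-rotation mixing (exp of a scaled skew matrix) with a gain.

        Emulates subjects sharing electrode montage and similar anatomy:
        channel topographies rotate by at most ``angle`` radians while the
        overall gain can differ substantially.
        """
        from scipy.linalg import expm

        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n_channels, n_channels))
        a = 0.5 * (a - a.T)
        a /= np.linalg.norm(a, 2)
        return cls(
            mixing=expm(angle * a),
            gain=rng.uniform(*gain_range),
            latency_shift=rng.normal(0.0, latency_sd),
        )


def make_erp_template(template: ERPTemplate, fs: float, n_channels: int | None = None) -> np.ndarray:
    """Render the ERP template to a (T, C) waveform at sampling rate ``fs``.

    The waveform is a Gaussian bump with its maximum within one sample of
    ``peak_latency`` and zero outside the template support.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(template.duration * fs))
    if n < 2:
        raise ValueError("template support must span at least 2 samples")
    if template.channel_weights is not None:
        weights = template.channel_weights
        if n_channels is not None and len(weights) != n_channels:
            raise ValueError("channel_weights length does not match channel count")
    else:
        weights = np.ones(n_channels if n_channels is not None else 1)
    t = np.arange(n) / fs
    sigma = template.peak_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd
    bump = template.amplitude * np.exp(-0.5 * ((t - template.peak_latency) / sigma) ** 2)
    return bump[:, None] * weights[None, :]


def _background_noise(rng: np.random.Generator, n: int, c: int, scale: float) -> np.ndarray:
    """AR(1) + white noise per channel, total sd ~= scale microvolts."""
    if scale == 0:
        return np.zeros((n, c))
    white = rng.standard_normal((n, c))
    innov = rng.standard_normal((n, c))
    ar = np.empty((n, c))
    ar[0] = innov[0]
    for i in range(1, n):
        ar[i] = AR_COEFF * ar[i - 1] + innov[i]
    ar *= np.sqrt(1.0 - AR_COEFF**2)  # unit stationary variance
    return scale * (ar + white) / np.sqrt(2.0)


def _add_template(signal: np.ndarray, onset: int, waveform: np.ndarray) -> None:
    """Add ``waveform`` into ``signal`` starting at sample ``onset`` (clipped)."""
    start = max(onset, 0)
    stop = min(onset + len(waveform), len(signal))
    if stop > start:
        signal[start:stop] += waveform[start - onset : stop - onset]


def simulate_speller_session(
    cfg: SpellerConfig,
    template: ERPTemplate,
    shift: SubjectShift | None = None,
    truth: str | None = None,
) -> ContinuousRecording:
    """Simulate a full matrix-speller session for one subject.

    Each of ``cfg.n_characters`` characters of ``truth`` is spelled with
    ``cfg.n_repetitions`` repetitions; each repetition flashes codes 1-12 in a
    fresh random order.  Target flashes (the truth character's row and column)
    receive the ERP template, jittered in latency per flash.  Returns the
    continuous recording with its full event table.
    """
    rng = np.random.default_rng(cfg.subject_seed)
    if shift is None:
        shift = SubjectShift.identity(cfg.n_channels)
    if shift.mixing.shape[0] != cfg.n_channels:
        raise ValueError("shift mixing size does not match n_channels")
    if truth is None:
        truth = "".join(rng.choice(list(SPELLER_ALPHABET), size=cfg.n_characters))
    if len(truth) != cfg.n_characters:
        raise ValueError("truth length does not match n_characters")
    target_codes = []
    for ch in truth:
        row, col = char_to_rowcol(ch)  # raises for characters outside the matrix
        target_codes.append((row + 1, col + 7))

    char_span = cfg.pre_char_gap + cfg.n_repetitions * N_CODES * cfg.soa
    tail = template.duration + 0.5
    n_samples = int(round((cfg.n_characters * char_span + tail) * cfg.fs))
    waveform = make_erp_template(template, cfg.fs, cfg.n_channels)

    erp = np.zeros((n_samples, cfg.n_channels))
    rows = []
    for ci in range(cfg.n_characters):
        char_t0 = ci * char_span + cfg.pre_char_gap
        for rep in range(cfg.n_repetitions):
            order = rng.permutation(N_CODES) + 1
            for pos, code in enumerate(order):
                t = char_t0 + (rep * N_CODES + pos) * cfg.soa
                onset = int(round(t * cfg.fs))
                is_target = int(code in target_codes[ci])
                rows.append((onset, int(code), is_target, ci, rep))
                if is_target:
                    jitter = rng.normal(0.0, cfg.latency_jitter_sd) if cfg.latency_jitter_sd > 0 else 0.0
                    lag = int(round((shift.latency_shift + jitter) * cfg.fs))
                    _add_template(erp, onset + lag, waveform)
    events = pd.DataFrame(rows, columns=["sample_index", "code", "is_target", "character_index", "repetition_index"])

    signal = shift.gain * (erp @ shift.mixing.T)
    signal += _background_noise(rng, n_samples, cfg.n_channels, cfg.noise_scale)
    return ContinuousRecording(signal=signal, fs=cfg.fs, events=events)


def simulate_rsvp_session(
    cfg: RSVPConfig,
    template: ERPTemplate,
    shift: SubjectShift | None = None,
) -> ContinuousRecording:
    """Simulate an RSVP stream: ``n_trials`` stimuli at ``rate`` per second.

    Exactly ``round(n_trials * target_fraction)`` stimuli, placed uniformly at
    random, are targets carrying the ERP template.  Event codes are 1 for
    targets and 0 for non-targets; character/repetition indices are -1.
    """
    rng = np.random.default_rng(cfg.subject_seed)
    if shift is None:
        shift = SubjectShift.identity(cfg.n_channels)
    if shift.mixing.shape[0] != cfg.n_channels:
        raise ValueError("shift mixing size does not match n_channels")

    isi = 1.0 / cfg.rate
    lead_in = 1.0
    n_samples = int(round((lead_in + cfg.n_trials * isi + template.duration + 0.5) * cfg.fs))
    waveform = make_erp_template(template, cfg.fs, cfg.n_channels)

    n_targets = int(round(cfg.n_trials * cfg.target_fraction))
    target_idx = set(rng.choice(cfg.n_trials, size=n_targets, replace=False).tolist())

    erp = np.zeros((n_samples, cfg.n_channels))
    rows = []
    for i in range(cfg.n_trials):
        onset = int(round((lead_in + i * isi) * cfg.fs))
        is_target = int(i in target_idx)
        rows.append((onset, is_target, is_target, -1, -1))
        if is_target:
            jitter = rng.normal(0.0, cfg.latency_jitter_sd) if cfg.latency_jitter_sd > 0 else 0.0
            lag = int(round((shift.latency_shift + jitter) * cfg.fs))
            _add_template(erp, onset + lag, waveform)
    events = pd.DataFrame(rows, columns=["sample_index", "code", "is_target", "character_index", "repetition_index"])

    signal = shift.gain * (erp @ shift.mixing.T)
    signal += _background_noise(rng, n_samples, cfg.n_channels, cfg.noise_scale)
    return ContinuousRecording(signal=signal, fs=cfg.fs, events=events)
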