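"""Band-pass filtering, decimation and stimulus-locked epoching.

Filtering uses a 4th-order Butterworth applied forward-backward
(zero-phase), the standard ERP choice: it leaves the P300 latency
untouched.  Downsampling applies an FIR anti-aliasing filter via polyphase
resampling and remaps event onsets by the decimation factor.  Epoching cuts
the half-open window [0, duration) after each event onset; epochs running
past the end of the recording are dropped (and counted in a log message).
No baseline correction or artifact rejection is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ContinuousRecording, EpochSet

logger = logging.getLogger(__name__)

__all__ = ["bandpass_filter", "downsample", "epoch_extract"]


def bandpass_filter(rec: ContinuousRecording, low: float, high: float, order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass, e.g. 0.1-30 Hz for speller EEG."""
    nyq = rec.fs / 2.0
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    # the low cutoff sets the slowest transient (~1/low seconds); pad generously
    # so the reflected edges have settled before the signal proper begins
    padlen = min(rec.n_samples - 1, int(3 * rec.fs / low))
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=0, padlen=padlen)
    return ContinuousRecording(signal=filtered, fs=rec.fs, events=rec.events)


def downsample(rec: ContinuousRecording, target_fs: float) -> ContinuousRecording:
    """Anti-aliased integer-factor decimation with event-onset remapping."""
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {rec.fs} is not an integer multiple of target_fs {target_fs}")
    factor = int(round(factor))
    if factor == 1:
        return rec
    out = sps.resample_poly(rec.signal, up=1, down=factor, axis=0)
    events = rec.events.copy()
    events["sample_index"] = (
        np.round(events["sample_index"].to_numpy() / factor).astype(np.int64).clip(0, len(out) - 1)
    )
    return ContinuousRecording(signal=out, fs=target_fs, events=events)


def epoch_extract(rec: ContinuousRecording, window: tuple[float, float]) -> EpochSet:
    """Cut fixed-length epochs time-locked to each event.

    ``window`` is (start, end) in seconds relative to event onset; the epoch
    spans T = round((end - start) * fs) samples.  Events whose window exceeds
    the recording bounds are dropped with a logged count.
    """
    start_s, end_s = window
    length = end_s - start_s
    if length <= 0:
        raise ValueError("window length must be positive")
    if len(rec.events) == 0:
        raise ValueError("recording has no events to epoch")
    n_t = int(round(length * rec.fs))
    offset = int(round(start_s * rec.fs))

    onsets = rec.events["sample_index"].to_numpy() + offset
    keep = (onsets >= 0) & (onsets + n_t <= rec.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("epoch_extract: dropped %d events whose window exceeds the recording", n_dropped)
    if not keep.any():
        raise ValueError("no epochs survive the requested window")

    kept = rec.events[keep].reset_index(drop=True)
    idx = onsets[keep][:, None] + np.arange(n_t)[None, :]
    epochs = rec.signal[idx]  # (n, T, C)
    meta = pd.DataFrame(
        {
            "label": kept["is_target"].to_numpy(),
            "code": kept["code"].to_numpy(),
            "character_index": kept["character_index"].to_numpy(),
            "repetition_index": kept["repetition_index"].to_numpy(),
        }
    )
    return EpochSet(epochs=epochs, fs=rec.fs, meta=meta)
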