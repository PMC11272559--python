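"""Speller character decoding and BCI performance metrics (ITR, BCA).

Character decoding follows the row/column intersection rule: for each of the
12 flash codes, target-class probabilities are summed over the first ``Nr``
repetitions; the predicted row is the argmax over codes 1-6, the predicted
column the argmax over codes 7-12, and the character is the corresponding
cell of the 6x6 matrix.  Ties are broken toward the lowest code.

The information transfer rate (bits per minute) uses the standard Wolpaw
formula for an N-symbol selection,

    bits = log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1)),

with the per-character selection time T = 2.5 s + (0.100 s + 0.075 s) * 12 * Nr
for the matrix speller, and ITR = 60 * bits / T.

Balanced classification accuracy (BCA) is the mean of per-class accuracies,
robust to the heavy target/non-target imbalance of oddball paradigms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Row-major 6x6 speller matrix: letters A-Z then digits 0-9.
SPELLER_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

#: Per-character selection time constants: 2.5 s pause + 12 flashes of
#: (0.100 s flash + 0.075 s gap) per repetition.
PAUSE_S = 2.5
FLASH_S = 0.100
GAP_S = 0.075

__all__ = [
    "SPELLER_ALPHABET",
    "char_to_rowcol",
    "rowcol_to_char",
    "SpellerResult",
    "ConfusionCounts",
    "decode_character",
    "decode_session",
    "accuracy_curve",
    "itr",
    "bca",
    "confusion_counts",
]


def char_to_rowcol(ch: str, alphabet: str = SPELLER_ALPHABET) -> tuple[int, int]:
    """Map a speller character to its 0-based (row, column) in the 6x6 matrix."""
    idx = alphabet.find(ch)
    if idx < 0:
        raise ValueError(f"character {ch!r} is not in the speller matrix")
    return idx // 6, idx % 6


def rowcol_to_char(row: int, col: int, alphabet: str = SPELLER_ALPHABET) -> str:
    if not (0 <= row < 6 and 0 <= col < 6):
        raise ValueError("row and column must lie in 0..5")
    return alphabet[row * 6 + col]


@dataclass
class SpellerResult:
    """Decoded symbols per character for every repetition budget Nr.

    ``predictions[nr]`` is the list of decoded characters using the first
    ``nr`` repetitions (1-based keys, 1..max repetitions available).
    """

    predictions: dict[int, list[str]]

    @property
    def nr_values(self) -> list[int]:
        return sorted(self.predictions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"Nr={nr}": preds for nr, preds in sorted(self.predictions.items())})


@dataclass
class ConfusionCounts:
    """Binary confusion summary: true/correct counts per class."""

    m1: int  # true targets
    n1: int  # correctly classified targets
    m2: int  # true non-targets
    n2: int  # correctly classified non-targets

    def __post_init__(self) -> None:
        if not (0 <= self.n1 <= self.m1 and 0 <= self.n2 <= self.m2):
            raise ValueError("correct counts must lie within true counts")


def decode_character(scores: pd.DataFrame, nr: int, alphabet: str = SPELLER_ALPHABET) -> str:
    """Decode one character from per-flash target probabilities.

    ``scores`` has one row per flash with columns ``code`` (1-12),
    ``repetition_index`` (0-based) and ``score`` (target probability).  All
    12 codes must be present for every repetition 0..nr-1.
    """
    sub = scores[scores["repetition_index"] < nr]
    summed = sub.groupby("code")["score"].sum()
    if sorted(summed.index) != list(range(1, 13)):
        raise ValueError("scores must cover codes 1..12 for the requested repetitions")
    counts = sub.groupby("code").size()
    if (counts != nr).any():
        raise ValueError(f"each code must appear exactly once per repetition (Nr={nr})")
    row_scores = summed.loc[1:6].to_numpy()
    col_scores = summed.loc[7:12].to_numpy()
    row = int(np.argmax(row_scores))  # argmax takes the first (lowest-code) tie
    col = int(np.argmax(col_scores))
    return rowcol_to_char(row, col, alphabet)


def decode_session(
    scores: pd.DataFrame,
    nr_values=None,
    alphabet: str = SPELLER_ALPHABET,
) -> SpellerResult:
    """Decode every character of a session at each repetition budget.

    ``scores`` needs columns ``character_index``, ``repetition_index``,
    ``code`` and ``score`` (one row per flash epoch).
    """
    max_rep = int(scores["repetition_index"].max()) + 1
    if nr_values is None:
        nr_values = range(1, max_rep + 1)
    chars = sorted(scores["character_index"].unique())
    predictions: dict[int, list[str]] = {}
    for nr in nr_values:
        predictions[int(nr)] = [
            decode_character(scores[scores["character_index"] == ci], int(nr), alphabet)
            for ci in chars
        ]
    return SpellerResult(predictions=predictions)


def accuracy_curve(result: SpellerResult, truth: str) -> dict[int, float]:
    """Percent of correctly decoded characters per repetition budget."""
    curve: dict[int, float] = {}
    for nr, preds in result.predictions.items():
        if len(preds) != len(truth):
            raise ValueError("prediction and truth lengths differ")
        correct = sum(p == t for p, t in zip(preds, truth))
        curve[nr] = 100.0 * correct / len(truth)
    return curve


def itr(p: float, nr: int, n_symbols: int = 36) -> float:
    """Information transfer rate in bits per minute for the matrix speller.

    ``p`` is the character recognition accuracy (proportion), ``nr`` the
    number of repetitions used per character.  The 0*log(0) convention is
    applied at p = 0 and p = 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy p must lie in [0, 1]")
    if not 1 <= nr <= 15:
        raise ValueError("nr must lie in [1, 15]")
    bits = float(np.log2(n_symbols))
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n_symbols - 1))
    t = PAUSE_S + (FLASH_S + GAP_S) * 12 * nr
    return bits * 60.0 / t


def bca(counts: ConfusionCounts) -> float:
    """Balanced classification accuracy: mean of per-class accuracies."""
    if counts.m1 < 1 or counts.m2 < 1:
        raise ValueError("both classes need at least one true trial")
    return 0.5 * (counts.n1 / counts.m1 + counts.n2 / counts.m2)


def confusion_counts(labels: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    """Tally a binary prediction against 0/1 labels (1 = target)."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions must have the same shape")
    tgt = labels == 1
    return ConfusionCounts(
        m1=int(tgt.sum()),
        n1=int((predicted[tgt] == 1).sum()),
        m2=int((~tgt).sum()),
        n2=int((predicted[~tgt] == 0).sum()),
    )
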