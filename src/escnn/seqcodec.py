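"""Sequence encoding and decoding of overlapping epoch windows.

Encoding slides a window of L consecutive epochs over a night with a
stride of one epoch, turning a (P, M) recording into a
(P - L + 1, L, M) tensor; window i at position j holds absolute epoch
i + j (0-based).  After a classifier emits per-position stage
probabilities, decoding L1-normalizes each (window, position) row,
sums all rows that refer to the same absolute epoch, and takes the
per-epoch argmax.  Each epoch is therefore voted on by up to L
overlapping windows, which smooths out single-window errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import EpochedRecording, INT_TO_STAGE, N_STAGES, StageLabels

__all__ = [
    "SequenceTensor",
    "ProbTensor",
    "ConsolidatedProbs",
    "StagePredictions",
    "encode_sequences",
    "encode_labels",
    "decode_consolidate",
    "predict_stages",
    "coverage_counts",
    "save_sequences",
    "load_sequences",
]

DEFAULT_WINDOW_LEN = 10


@dataclass
class SequenceTensor:
    """Sliding-window view of a night: (P - L + 1, L, M)."""

    data: np.ndarray
    L: int
    epoch_index_offset: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != self.L:
            raise ValueError(f"bad sequence tensor shape {self.data.shape}")

    @property
    def n_windows(self) -> int:
        return int(self.data.shape[0])

    @property
    def P(self) -> int:
        return self.n_windows + self.L - 1


@dataclass
class ProbTensor:
    """Per-window, per-position stage probabilities: (P - L + 1, L, C)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 3:
            raise ValueError("probs must be (windows, L, C)")
        if np.any(self.probs < 0) or not np.all(np.isfinite(self.probs)):
            raise ValueError("probabilities must be finite and nonnegative")


@dataclass
class ConsolidatedProbs:
    """Per-epoch summed normalized scores and window coverage counts."""

    scores: np.ndarray           # (P, C)
    coverage: np.ndarray         # (P,)


@dataclass
class StagePredictions:
    stages: np.ndarray           # (P,) int codes

    def tokens(self) -> np.ndarray:
        return np.array([INT_TO_STAGE[int(c)] for c in self.stages],
                        dtype=object)


def encode_sequences(rec, L: int = DEFAULT_WINDOW_LEN) -> SequenceTensor:
    """Stack L-epoch sliding windows (stride one epoch) of a night.

    ``rec`` may be an :class:`EpochedRecording` or a plain (P, M) array.
    """
    X = rec.X if isinstance(rec, EpochedRecording) else np.asarray(rec)
    P = X.shape[0]
    if L < 1:
        raise ValueError(f"window length must be >= 1, got {L}")
    if P < L:
        raise ValueError(f"night has P={P} epochs, shorter than window L={L}")
    win = np.lib.stride_tricks.sliding_window_view(X, L, axis=0)
    # sliding_window_view puts the window axis last: (P-L+1, M, L)
    return SequenceTensor(data=np.ascontiguousarray(win.transpose(0, 2, 1)),
                          L=L)


def encode_labels(labels, L: int = DEFAULT_WINDOW_LEN) -> np.ndarray:
    """Per-position integer labels aligned with :func:`encode_sequences`."""
    codes = labels.codes() if isinstance(labels, StageLabels) \
        else np.asarray(labels)
    if codes.size < L:
        raise ValueError(f"{codes.size} labels, shorter than window L={L}")
    return np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(codes, L)
    )


def coverage_counts(P: int, L: int) -> np.ndarray:
    """Number of windows covering each absolute epoch m (0-based)."""
    m = np.arange(P)
    return np.minimum.reduce([m + 1, np.full(P, L), np.full(P, P - L + 1),
                              P - m])


def decode_consolidate(probs) -> ConsolidatedProbs:
    """Normalize per-position probabilities and sum them per epoch.

    Each (window, position) row is divided by its sum (rows summing to
    zero are replaced by a uniform distribution, with a warning); rows
    with the same absolute epoch index window+position are then added.
    """
    Y = probs.probs if isinstance(probs, ProbTensor) else np.asarray(probs)
    Y = ProbTensor(np.asarray(Y, dtype=float)).probs
    n_win, L, C = Y.shape
    P = n_win + L - 1

    row_sums = Y.sum(axis=2, keepdims=True)
    zero = row_sums[..., 0] <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero probability row(s) replaced "
                      "by uniform", RuntimeWarning)
    Yn = np.where(zero[..., None], 1.0 / C, Y / np.where(row_sums > 0,
                                                         row_sums, 1.0))

    scores = np.zeros((P, C))
    for j in range(L):
        scores[j:j + n_win] += Yn[:, j, :]
    return ConsolidatedProbs(scores=scores, coverage=coverage_counts(P, L))


def predict_stages(scores) -> StagePredictions:
    """Per-epoch argmax; exact ties go to the lower stage index."""
    S = scores.scores if isinstance(scores, ConsolidatedProbs) \
        else np.asarray(scores)
    if not np.all(np.isfinite(S)):
        raise ValueError("scores must be finite")
    return StagePredictions(stages=S.argmax(axis=1).astype(np.int8))


def save_sequences(seq: SequenceTensor, path) -> None:
    """Store an encoded night as HDF5 dataset ``Xseq`` with L/P/M attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("Xseq", data=seq.data.astype(np.float32))
        d.attrs["L"] = seq.L
        d.attrs["P"] = seq.P
        d.attrs["M"] = seq.data.shape[2]


def load_sequences(path) -> SequenceTensor:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["Xseq"]
        return SequenceTensor(data=d[()], L=int(d.attrs["L"]))
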