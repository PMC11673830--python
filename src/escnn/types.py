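"""Core containers for single-channel sleep EEG processing.

Conventions used throughout the package:

* A recording is one subject's single EEG channel for a whole night,
  in microvolts, at its native sampling rate ``fs``.
* Sleep is scored in fixed 30 s epochs.  Scored stages follow the AASM
  five-class scheme (Wake, N1, N2, N3, REM); epochs that cannot be
  scored (movement time, unknown) carry the sentinel ``UNSCORED``.
* Hypnograms parsed from files may still contain R&K tokens
  (S1--S4); :func:`escnn.edf_io.map_stages` converts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: AASM stage vocabulary, in fixed index order.  Ties in argmax-style
#: decisions are always broken toward the lower index.
STAGES: tuple[str, ...] = ("Wake", "N1", "N2", "N3", "REM")
N_STAGES: int = len(STAGES)
UNSCORED: str = "UNSCORED"

STAGE_TO_INT: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
INT_TO_STAGE: dict[int, str] = {i: s for i, s in enumerate(STAGES)}

#: Tokens a hypnogram may legally contain before AASM remapping.
RK_TOKENS: tuple[str, ...] = (
    "Wake", "S1", "S2", "S3", "S4", "REM", "MOVEMENT", "UNKNOWN",
    "N1", "N2", "N3", UNSCORED,
)

DEFAULT_EPOCH_LEN_S: float = 30.0


@dataclass
class RawRecording:
    """One subject's raw (or preprocessed) single-channel EEG signal."""

    samples: np.ndarray          # 1-D, microvolts
    fs: float                    # Hz
    channel: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class StageLabels:
    """Per-epoch sleep-stage labels (strings from :data:`RK_TOKENS`)."""

    stages: np.ndarray           # 1-D array of stage tokens
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object).ravel()
        if self.stages.size < 1:
            raise ValueError("need at least one stage label")
        bad = sorted({s for s in self.stages if s not in RK_TOKENS})
        if bad:
            raise ValueError(f"unknown stage tokens: {bad}")

    def __len__(self) -> int:
        return int(self.stages.size)

    def codes(self) -> np.ndarray:
        """Integer AASM codes; raises if non-AASM tokens remain."""
        try:
            return np.array([STAGE_TO_INT[s] for s in self.stages], dtype=np.int8)
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ValueError(f"label {exc} is not an AASM stage; run map_stages first")


@dataclass
class EpochedRecording:
    """A night reshaped into P scored epochs of M samples each."""

    X: np.ndarray                # (P, M) float
    labels: StageLabels          # length P, AASM tokens only
    fs: float
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float32))
        if self.X.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.X.shape[0]} epochs but {len(self.labels)} labels"
            )
        m_expected = int(round(self.labels.epoch_len_s * self.fs))
        if self.X.shape[1] != m_expected:
            raise ValueError(
                f"epoch length {self.X.shape[1]} samples does not match "
                f"epoch_len_s*fs = {m_expected}"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_samples_per_epoch(self) -> int:
        return int(self.X.shape[1])

    def stage_codes(self) -> np.ndarray:
        return self.labels.codes()
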