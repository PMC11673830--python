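"""Seeded synthetic sleep-EEG cohorts.

Each synthetic night is built from textbook stage signatures: a Markov
chain over the five AASM stages produces a hypnogram, and every epoch
is a sum of band-limited noise components whose relative powers follow
the stage's profile (Wake alpha/beta-dominant, N1 theta, N2 theta plus
13 Hz spindle bursts, N3 delta, REM mixed theta/beta), plus a broadband
noise floor.  Cohorts contain two or more spectral subgroups obtained
by multiplicatively boosting the alpha/beta weights of one group, which
shifts the fast/slow-wave ratio axis the subject clusterer operates on.

Everything is reproducible from a single cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .edf_io import write_edf
from .types import (DEFAULT_EPOCH_LEN_S, EpochedRecording, STAGES,
                    StageLabels)

__all__ = ["StageProfile", "CohortSpec", "DEFAULT_PROFILES",
           "DEFAULT_TRANSITION", "markov_hypnogram", "synth_epoch",
           "synth_cohort", "write_edf_fixture"]

_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 30.0),
               "gamma": (30.0, 35.0)}
_BAND_NAMES = tuple(_BAND_EDGES)


@dataclass
class StageProfile:
    """Relative power budget of one sleep stage.

    ``band_powers`` holds the five band weights (delta, theta, alpha,
    beta, gamma); together with ``noise_floor`` (broadband white
    component) and ``spindle_weight`` (13 Hz amplitude-modulated bursts,
    N2 only) the budget sums to one.
    """

    band_powers: dict[str, float]
    noise_floor: float
    spindle_weight: float = 0.0
    spindle_bursts: int = 0

    def __post_init__(self) -> None:
        vals = np.array([self.band_powers[b] for b in _BAND_NAMES])
        if np.any(vals < 0) or self.noise_floor < 0 or self.spindle_weight < 0:
            raise ValueError("power weights must be nonnegative")
        total = vals.sum() + self.noise_floor + self.spindle_weight
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"power budget sums to {total}, expected 1")


DEFAULT_PROFILES: dict[str, StageProfile] = {
    "Wake": StageProfile({"delta": 0.05, "theta": 0.10, "alpha": 0.35,
                          "beta": 0.30, "gamma": 0.05}, noise_floor=0.15),
    "N1": StageProfile({"delta": 0.10, "theta": 0.55, "alpha": 0.10,
                        "beta": 0.05, "gamma": 0.02}, noise_floor=0.18),
    "N2": StageProfile({"delta": 0.15, "theta": 0.40, "alpha": 0.08,
                        "beta": 0.05, "gamma": 0.02}, noise_floor=0.12,
                       spindle_weight=0.18, spindle_bursts=2),
    "N3": StageProfile({"delta": 0.70, "theta": 0.12, "alpha": 0.04,
                        "beta": 0.02, "gamma": 0.02}, noise_floor=0.10),
    "REM": StageProfile({"delta": 0.10, "theta": 0.35, "alpha": 0.10,
                         "beta": 0.30, "gamma": 0.05}, noise_floor=0.10),
}

#: Diagonal-heavy stage transition matrix giving bout lengths of a few
#: epochs, loosely shaped like adult overnight sleep architecture.
DEFAULT_TRANSITION: np.ndarray = np.array([
    # Wake   N1     N2     N3     REM
    [0.850, 0.120, 0.020, 0.005, 0.005],   # Wake
    [0.050, 0.700, 0.200, 0.020, 0.030],   # N1
    [0.010, 0.050, 0.800, 0.100, 0.040],   # N2
    [0.005, 0.005, 0.140, 0.840, 0.010],   # N3
    [0.030, 0.050, 0.100, 0.020, 0.800],   # REM
])


@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-subject cohort."""

    n_subjects_per_group: int = 3
    n_groups: int = 2
    group_shift: float = 1.5
    epochs_per_subject: int = 200
    fs: float = 100.0
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S
    transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy())
    profiles: dict[str, StageProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        _check_stochastic(self.transition)
        if min(self.n_subjects_per_group, self.n_groups,
               self.epochs_per_subject) < 1:
            raise ValueError("all counts must be >= 1")


def _check_stochastic(T: np.ndarray) -> None:
    if T.shape != (5, 5) or np.any(T < 0):
        raise ValueError("transition matrix must be 5x5 nonnegative")
    if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must sum to 1")


def markov_hypnogram(transition: np.ndarray, n: int, seed=0,
                     epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> StageLabels:
    """Sample an n-epoch hypnogram from a stage transition chain.

    The night starts in Wake; ``seed`` may be an int or a Generator.
    """
    T = np.asarray(transition, dtype=float)
    _check_stochastic(T)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = 0
    for i in range(1, n):
        states[i] = rng.choice(5, p=T[states[i - 1]])
    toks = np.array([STAGES[s] for s in states], dtype=object)
    return StageLabels(toks, epoch_len_s=epoch_len_s)


def _band_sos(lo: float, hi: float, fs: float):
    return sps.butter(4, [lo, min(hi, fs / 2 * 0.99)], btype="bandpass",
                      fs=fs, output="sos")


def _scaled(x: np.ndarray, target_power: float) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12 or target_power <= 0:
        return np.zeros_like(x)
    return x * (np.sqrt(target_power) / sd)


def _spindle_train(m: int, fs: float, n_bursts: int,
                   rng: np.random.Generator) -> np.ndarray:
    """1 s Hann-windowed 13 Hz bursts at random positions in the epoch."""
    out = np.zeros(m)
    blen = int(fs)
    t = np.arange(blen) / fs
    burst = np.sin(2 * np.pi * 13.0 * t) * np.hanning(blen)
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(m - blen, 1)))
        out[start:start + blen] += burst
    return out


def synth_epoch(profile: StageProfile, fs: float,
                epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
                seed=0) -> np.ndarray:
    """One epoch of band-structured noise with unit total variance."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    m = int(round(epoch_len_s * fs))
    pad = int(2 * fs)                    # filter warm-up, trimmed off
    x = np.zeros(m)
    for band in _BAND_NAMES:
        w = profile.band_powers[band]
        if w <= 0:
            continue
        lo, hi = _BAND_EDGES[band]
        noise = rng.standard_normal(m + 2 * pad)
        comp = sps.sosfiltfilt(_band_sos(lo, hi, fs), noise)[pad:pad + m]
        x += _scaled(comp, w)
    if profile.noise_floor > 0:
        x += _scaled(rng.standard_normal(m), profile.noise_floor)
    if profile.spindle_weight > 0 and profile.spindle_bursts > 0:
        x += _scaled(_spindle_train(m, fs, profile.spindle_bursts, rng),
                     profile.spindle_weight)
    return x


def _shift_profile(profile: StageProfile, shift: float) -> StageProfile:
    """Boost alpha/beta weights multiplicatively and renormalize."""
    bp = dict(profile.band_powers)
    bp["alpha"] *= shift
    bp["beta"] *= shift
    total = sum(bp.values()) + profile.noise_floor + profile.spindle_weight
    return StageProfile({b: v / total for b, v in bp.items()},
                        noise_floor=profile.noise_floor / total,
                        spindle_weight=profile.spindle_weight / total,
                        spindle_bursts=profile.spindle_bursts)


def synth_cohort(spec: CohortSpec,
                 ) -> tuple[list[EpochedRecording], dict[str, int]]:
    """Generate a cohort of synthetic nights with ground-truth groups.

    Returns ``(recordings, groups)`` where ``groups`` maps subject id to
    its spectral subgroup index.  Per-band noise is synthesized for the
    whole night in one filtering pass and rescaled epoch-by-epoch to the
    stage's power budget, so the spectrum is stage-faithful while the
    signal stays continuous across epoch boundaries.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_groups * spec.n_subjects_per_group
    child_seeds = ss.spawn(n_total)

    group_profiles = []
    for g in range(spec.n_groups):
        shift = spec.group_shift ** g
        group_profiles.append({
            s: _shift_profile(p, shift) for s, p in spec.profiles.items()})

    m = int(round(spec.epoch_len_s * spec.fs))
    P = spec.epochs_per_subject
    recordings, groups = [], {}
    si = 0
    for g in range(spec.n_groups):
        for j in range(spec.n_subjects_per_group):
            rng = np.random.default_rng(child_seeds[si])
            si += 1
            sid = f"g{g}s{j}"
            labels = markov_hypnogram(spec.transition, P, seed=rng,
                                      epoch_len_s=spec.epoch_len_s)
            codes = labels.codes()
            profiles = group_profiles[g]

            X = np.zeros((P, m))
            pad = int(2 * spec.fs)
            for band in _BAND_NAMES:
                noise = rng.standard_normal(P * m + 2 * pad)
                comp = sps.sosfiltfilt(_band_sos(*_BAND_EDGES[band], spec.fs),
                                       noise)[pad:pad + P * m].reshape(P, m)
                for p in range(P):
                    w = profiles[STAGES[codes[p]]].band_powers[band]
                    X[p] += _scaled(comp[p], w)
            floor_noise = rng.standard_normal((P, m))
            for p in range(P):
                prof = profiles[STAGES[codes[p]]]
                X[p] += _scaled(floor_noise[p], prof.noise_floor)
                if prof.spindle_weight > 0 and prof.spindle_bursts > 0:
                    X[p] += _scaled(
                        _spindle_train(m, spec.fs, prof.spindle_bursts, rng),
                        prof.spindle_weight)
            rec = EpochedRecording(X=X, labels=labels, fs=spec.fs,
                                   subject_id=sid, meta={"group": g})
            recordings.append(rec)
            groups[sid] = g
    return recordings, groups


_AASM_TO_CSV = {"Wake": "W", "N1": "N1", "N2": "N2", "N3": "N3", "REM": "R"}
_AASM_TO_EDF = {"Wake": "Sleep stage W", "N1": "Sleep stage N1",
                "N2": "Sleep stage N2", "N3": "Sleep stage N3",
                "REM": "Sleep stage R"}


def write_edf_fixture(rec: EpochedRecording, edf_path, hypnogram_csv=None,
                      channel: str = "Fpz-Cz",
                      with_annotations: bool = False) -> None:
    """Write a synthetic night as a tiny EDF (+ optional CSV hypnogram).

    Synthetic-fixture helper: the epochs are concatenated back into a
    continuous signal and stored as one 16-bit EDF channel; stage
    annotations can be embedded as an EDF+ annotation track and/or
    written as a ``epoch,stage`` CSV.
    """
    signal = rec.X.reshape(-1)
    ann = None
    if with_annotations:
        ann = []
        elen = rec.labels.epoch_len_s
        start = 0
        toks = rec.labels.stages
        i = 0
        while i < len(toks):   # run-length encode consecutive equal stages
            j = i
            while j < len(toks) and toks[j] == toks[i]:
                j += 1
            ann.append((i * elen, (j - i) * elen, _AASM_TO_EDF[toks[i]]))
            i = j
    write_edf(edf_path, {channel: signal}, fs=rec.fs, annotations=ann)
    if hypnogram_csv is not None:
        import pandas as pd

        pd.DataFrame({
            "epoch": np.arange(rec.n_epochs),
            "stage": [_AASM_TO_CSV[s] for s in rec.labels.stages],
        }).to_csv(hypnogram_csv, index=False)
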