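"""Subject-level spectral features and their PCA reduction.

Each subject is summarised by 13 numbers derived from the classic EEG
bands delta (0.5-4 Hz), theta (4-8 Hz), alpha (8-13 Hz), beta (13-30 Hz)
and gamma (30-35 Hz): the absolute power in each band, the mean spectral
density in each band, and three fast/slow-wave ratios (alpha/delta,
beta/theta, (alpha+beta)/(delta+theta)).  The 13-vector is the average
of per-epoch features over every scored epoch of the night, so it
captures a subject's overall spectral fingerprint rather than any single
stage.

The feature matrix of a cohort is z-scored column-wise and reduced by
PCA; the retention of information (ROI) of a U-component model is the
fraction of total eigenvalue mass kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .types import EpochedRecording

__all__ = [
    "BANDS",
    "FEATURE_NAMES",
    "welch_psd",
    "band_features",
    "epoch_feature_matrix",
    "subject_features",
    "cohort_feature_matrix",
    "SubjectFeaturizer",
    "SpectralPCA",
    "PCAModel",
    "fit_pca",
    "roi",
    "transform",
    "SubjectFeatureVector",
]

#: (name, low Hz, high Hz) of the five canonical bands.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 35.0),
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"power_{b}" for b, *_ in BANDS]
    + [f"density_{b}" for b, *_ in BANDS]
    + ["ratio_alpha_delta", "ratio_beta_theta", "ratio_fast_slow"]
)

_EPS = 1e-12


@dataclass
class SubjectFeatureVector:
    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.feature_names):
            raise ValueError("values/feature_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def welch_psd(epoch: np.ndarray, fs: float, nperseg_s: float = 4.0):
    """One-sided Welch spectral density (Hann, 50 % overlap).

    Returns ``(freqs, psd)`` with density scaling, so the integral of the
    PSD approximates the signal variance.
    """
    x = np.asarray(epoch, dtype=float).ravel()
    if x.size < 256:
        raise ValueError(f"need at least 256 samples, got {x.size}")
    nperseg = min(int(round(nperseg_s * fs)), x.size)
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, scaling="density",
                           detrend=False)
    return freqs, psd


def band_features(freqs: np.ndarray, psd: np.ndarray,
                  subject_id: str = "") -> SubjectFeatureVector:
    """The 13 band features of a single spectrum.

    Band powers are trapezoidal integrals of the density with the band
    edges interpolated onto the frequency grid; band densities are
    power / bandwidth; ratios use a 1e-12 denominator floor.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs[0] > BANDS[0][1] or freqs[-1] < BANDS[-1][2]:
        raise ValueError(
            f"spectrum covers {freqs[0]:.2f}-{freqs[-1]:.2f} Hz but the "
            f"bands require 0.5-35 Hz"
        )
    powers, densities = {}, {}
    for name, lo, hi in BANDS:
        grid = np.concatenate(([lo], freqs[(freqs > lo) & (freqs < hi)], [hi]))
        vals = np.interp(grid, freqs, psd)
        powers[name] = float(np.trapezoid(vals, grid))
        densities[name] = powers[name] / (hi - lo)

    def ratio(num: float, den: float) -> float:
        return num / max(den, _EPS)

    values = (
        [powers[b] for b, *_ in BANDS]
        + [densities[b] for b, *_ in BANDS]
        + [
            ratio(powers["alpha"], powers["delta"]),
            ratio(powers["beta"], powers["theta"]),
            ratio(powers["alpha"] + powers["beta"],
                  powers["delta"] + powers["theta"]),
        ]
    )
    return SubjectFeatureVector(np.array(values), FEATURE_NAMES, subject_id)


def epoch_feature_matrix(rec: EpochedRecording) -> np.ndarray:
    """Per-epoch band features of a night: (P, 13)."""
    feats = np.empty((rec.n_epochs, len(FEATURE_NAMES)))
    for i in range(rec.n_epochs):
        f, p = welch_psd(rec.X[i], rec.fs)
        feats[i] = band_features(f, p).values
    return feats


def _state_balanced_mean(feats: np.ndarray, n_states: int = 5,
                         seed: int = 0) -> np.ndarray:
    """Equal-weight average over unsupervised spectral states.

    Epochs are z-scored and clustered into up to ``n_states`` spectral
    states (k-means, seeded); the subject vector is the mean of the
    per-state mean feature vectors.  Averaging states with equal weight
    removes the stage-mix composition of the night from the subject
    fingerprint, which a plain epoch mean is dominated by; it needs no
    stage labels, so it applies identically to unscored test subjects.
    """
    from sklearn.cluster import KMeans

    P = feats.shape[0]
    if P == 1:
        return feats[0].copy()
    mu, sd = feats.mean(axis=0), np.maximum(feats.std(axis=0), _EPS)
    Z = (feats - mu) / sd
    k = min(n_states, np.unique(Z.round(9), axis=0).shape[0])
    if k < 2:
        return feats.mean(axis=0)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(Z)
    state_means = np.vstack([feats[km.labels_ == c].mean(axis=0)
                             for c in range(k)])
    return state_means.mean(axis=0)


def subject_features(rec: EpochedRecording,
                     aggregate: str = "state_balanced",
                     ) -> SubjectFeatureVector:
    """One 13-vector spectral fingerprint per subject.

    ``aggregate="state_balanced"`` (default) averages per-epoch features
    with equal weight over unsupervised spectral states, so the
    fingerprint reflects the subject's spectra rather than how much of
    the night each stage occupied; ``aggregate="mean"`` is the plain
    epoch average.
    """
    feats = epoch_feature_matrix(rec)
    if aggregate == "mean":
        values = feats.mean(axis=0)
    elif aggregate == "state_balanced":
        values = _state_balanced_mean(feats)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return SubjectFeatureVector(values, FEATURE_NAMES, rec.subject_id)


def cohort_feature_matrix(recordings, aggregate: str = "state_balanced",
                          ) -> np.ndarray:
    """Stack :func:`subject_features` for a cohort into an (S, 13) array."""
    return np.vstack([subject_features(r, aggregate=aggregate).values
                      for r in recordings])


class SubjectFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of epoched recordings -> (S, 13) matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return cohort_feature_matrix(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Frozen z-score + PCA basis for the subject feature space."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray     # (U, T)
    eigenvalues: np.ndarray    # all T eigenvalues, descending
    U: int
    roi: float
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)


def roi(eigenvalues: np.ndarray, U: int) -> float:
    """Retention of information: fraction of eigenvalue mass in the top U."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 1 or np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be nonnegative")
    if not (1 <= U <= lam.size):
        raise ValueError(f"U={U} out of range 1..{lam.size}")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    return float(lam[:U].sum() / total)


class SpectralPCA(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring followed by PCA on the covariance matrix.

    Parameters
    ----------
    n_components : int, default 3
        Number of principal components U kept for clustering.

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : per-feature centering and scaling (scale floored at
        1e-12 for constant columns, with a warning).
    components_ : (U, T) eigenvector rows, eigenvalue-descending.
    eigenvalues_ : all T covariance eigenvalues, descending.
    roi_ : retention of information at U components.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an (S, T) matrix with S >= 2 subjects")
        S, T = X.shape
        U = int(self.n_components)
        if not (1 <= U <= T):
            raise ValueError(f"n_components={U} out of range 1..{T}")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd < _EPS):
            warnings.warn("constant feature column(s); scale floored at 1e-12",
                          RuntimeWarning)
        self.scale_ = np.maximum(sd, _EPS)
        Z = (X - self.mean_) / self.scale_
        cov = np.cov(Z, rowvar=False, ddof=1)
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam = np.clip(lam[order], 0.0, None)
        vec = vec[:, order]
        self.eigenvalues_ = lam
        self.components_ = vec[:, :U].T
        self.roi_ = roi(lam, U)
        self.n_features_in_ = T
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"expected {self.mean_.size} features, got {X.shape[1]}"
            )
        return ((X - self.mean_) / self.scale_) @ self.components_.T

    def to_model(self) -> PCAModel:
        return PCAModel(mean=self.mean_, scale=self.scale_,
                        components=self.components_,
                        eigenvalues=self.eigenvalues_,
                        U=int(self.n_components), roi=self.roi_)


def fit_pca(features: np.ndarray, U: int = 3) -> PCAModel:
    """Functional wrapper over :class:`SpectralPCA`."""
    return SpectralPCA(n_components=U).fit(features).to_model()


def transform(model: PCAModel, features) -> np.ndarray:
    """Project one subject's features onto a fitted PCA basis."""
    values = features.values if isinstance(features, SubjectFeatureVector) \
        else np.asarray(features, dtype=float)
    values = values.ravel()
    if values.size != model.mean.size:
        raise ValueError(
            f"expected {model.mean.size} features, got {values.size}"
        )
    return ((values - model.mean) / model.scale) @ model.components.T
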