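"""Ensemble fusion of per-subgroup models and LOSO evaluation.

One sequential CNN is trained per spectral subgroup of the training
cohort.  For a test subject the distance to each subgroup (mean
Euclidean distance to its members in PCA space) is converted to fusion
weights proportional to the inverse squared distance, normalized to sum
to one; the subgroup models' consolidated stage scores are combined as
that convex mixture before the final per-epoch argmax.  Subjects whose
spectra resemble a subgroup therefore lean almost entirely on that
subgroup's specialist model, while borderline subjects blend several.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cluster import (DEFAULT_K_RANGE, SubjectClusterer, cluster_distances)
from .features import SpectralPCA, cohort_feature_matrix, subject_features
from .metrics import evaluate
from .scnn import SCNNClassifier, SCNNConfig, forward, train_scnn
from .seqcodec import (ConsolidatedProbs, StagePredictions, decode_consolidate,
                       encode_sequences, predict_stages)
from .types import EpochedRecording

__all__ = ["EnsembleWeights", "fusion_weights", "ensemble_predict",
           "EnsembleSleepStager", "LOSOConfig", "loso_run"]

_D_EPS = 1e-9


@dataclass
class EnsembleWeights:
    """Normalized inverse-squared-distance fusion weights."""

    weights: np.ndarray
    distances: np.ndarray


def fusion_weights(distances) -> EnsembleWeights:
    """w_i = (1/D_i^2) / sum_j (1/D_j^2).

    A zero (or < 1e-9) distance wins all the weight, split uniformly
    among exact ties; weights always sum to one and never increase with
    distance.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size < 1:
        raise ValueError("need at least one distance")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    w = np.zeros_like(d)
    if np.any(d < _D_EPS):
        ties = d < _D_EPS
        w[ties] = 1.0 / ties.sum()
    else:
        inv = 1.0 / d ** 2
        w = inv / inv.sum()
    return EnsembleWeights(weights=w, distances=d.copy())


def ensemble_predict(models, weights: EnsembleWeights, seq,
                     ) -> tuple[StagePredictions, ConsolidatedProbs]:
    """Decode each model's probabilities and fuse them convexly."""
    models = list(models)
    if len(models) != weights.weights.size:
        raise ValueError(f"{len(models)} models but "
                         f"{weights.weights.size} weights")
    fused = None
    coverage = None
    for w, model in zip(weights.weights, models):
        decoded = decode_consolidate(forward(model, seq))
        coverage = decoded.coverage
        fused = w * decoded.scores if fused is None else fused + w * decoded.scores
    consolidated = ConsolidatedProbs(scores=fused, coverage=coverage)
    return predict_stages(consolidated), consolidated


class EnsembleSleepStager(BaseEstimator):
    """Full E-SCNN pipeline as a single estimator.

    ``fit`` takes a list of epoched recordings (one per training
    subject): it extracts subject spectral features, fits the PCA basis
    and the subject clusterer, and trains one SCNN per subgroup.
    ``predict`` stages a held-out recording with distance-weighted
    fusion of the subgroup models.

    Parameters
    ----------
    L : window length in epochs for the sequence codec.
    n_components : PCA components used for clustering.
    k : subgroup count, or "auto" for silhouette selection over k_range.
    scnn : SCNNConfig shared by all subgroup models (seed offset per
        subgroup).
    distance_mode : "members" (mean distance to subgroup members) or
        "centroid".
    """

    def __init__(self, L: int = 10, n_components: int = 3, k="auto",
                 k_range=DEFAULT_K_RANGE, scnn: SCNNConfig | None = None,
                 distance_mode: str = "members", random_state: int = 0):
        self.L = L
        self.n_components = n_components
        self.k = k
        self.k_range = k_range
        self.scnn = scnn
        self.distance_mode = distance_mode
        self.random_state = random_state

    def fit(self, recordings: list[EpochedRecording], y=None):
        if len(recordings) < 2:
            raise ValueError("need at least two training subjects")
        cfg = self.scnn if self.scnn is not None else SCNNConfig(
            fs=recordings[0].fs)
        feats = cohort_feature_matrix(recordings)
        self.pca_ = SpectralPCA(n_components=self.n_components).fit(feats)
        pts = self.pca_.transform(feats)

        k_range = [k for k in self.k_range if k <= len(recordings)]
        if not k_range:
            raise ValueError(
                f"no usable k in {tuple(self.k_range)} for "
                f"{len(recordings)} subjects")
        clusterer = SubjectClusterer(
            k=self.k if self.k != "auto" else "auto",
            k_range=k_range or [2], random_state=self.random_state)
        self.clusterer_ = clusterer.fit(pts)
        self.cluster_model_ = clusterer.to_model()
        self.points_ = pts
        self.subject_ids_ = [r.subject_id for r in recordings]

        self.models_ = []
        for c in range(self.clusterer_.k_):
            idx = np.flatnonzero(self.clusterer_.labels_ == c)
            members = [recordings[i] for i in idx]
            cfg_c = SCNNConfig(**{**cfg.__dict__,
                                  "seed": cfg.seed + 1000 * (c + 1)})
            model = SCNNClassifier(config=cfg_c)
            train_scnn(model, members, valid=None, L=self.L)
            self.models_.append(model)
        return self

    def subject_weights(self, rec: EpochedRecording) -> EnsembleWeights:
        point = self.pca_.transform(
            subject_features(rec).values[None, :])[0]
        d = cluster_distances(self.cluster_model_, point,
                              mode=self.distance_mode)
        return fusion_weights(d)

    def predict(self, rec: EpochedRecording,
                ) -> tuple[StagePredictions, ConsolidatedProbs, EnsembleWeights]:
        w = self.subject_weights(rec)
        seq = encode_sequences(rec, self.L)
        pred, cons = ensemble_predict(self.models_, w, seq)
        return pred, cons, w


# ---------------------------------------------------------------------------
# leave-one-subject-out protocol

@dataclass
class LOSOConfig:
    """Settings for a leave-one-subject-out run."""

    L: int = 10
    n_components: int = 3
    k: object = "auto"
    k_range: tuple = DEFAULT_K_RANGE
    scnn: SCNNConfig = field(default_factory=SCNNConfig)
    distance_mode: str = "members"
    include_pooled: bool = True
    seed: int = 0


def loso_run(cohort: list[EpochedRecording], config: LOSOConfig | None = None,
             ) -> dict:
    """Leave-one-subject-out evaluation of the ensemble.

    For every held-out subject, PCA and clustering are refitted on the
    remaining subjects (no leakage of the test subject into the
    subgroup structure), one SCNN is trained per subgroup, and the
    fused prediction is scored.  With ``include_pooled=True`` a single
    SCNN trained on all remaining subjects is scored as an ablation.
    A fold whose clustering degenerates falls back to the pooled model
    with a warning.

    Returns a dict with ``reports`` / ``pooled_reports`` (lists of
    :class:`MetricsReport`), ``manifests`` (per-fold train/test subject
    ids and subgroup assignment) and ``table`` (DataFrame).
    """
    if len(cohort) < 3:
        raise ValueError("LOSO needs at least three subjects")
    config = config or LOSOConfig()
    reports, pooled_reports, manifests = [], [], []

    for t, test_rec in enumerate(cohort):
        train_recs = [r for i, r in enumerate(cohort) if i != t]
        manifest = {"test": test_rec.subject_id,
                    "train": [r.subject_id for r in train_recs]}
        stager = None
        try:
            stager = EnsembleSleepStager(
                L=config.L, n_components=config.n_components, k=config.k,
                k_range=config.k_range, scnn=config.scnn,
                distance_mode=config.distance_mode,
                random_state=config.seed).fit(train_recs)
        except ValueError as exc:
            warnings.warn(f"fold {test_rec.subject_id}: clustering failed "
                          f"({exc}); falling back to pooled model",
                          RuntimeWarning)

        pooled_model = None
        if config.include_pooled or stager is None:
            pooled_model = SCNNClassifier(config=SCNNConfig(
                **{**config.scnn.__dict__, "seed": config.scnn.seed + 500}))
            train_scnn(pooled_model, train_recs, valid=None, L=config.L)

        seq = encode_sequences(test_rec, config.L)
        if stager is not None:
            pred, cons, w = stager.predict(test_rec)
            manifest["assignment"] = {
                sid: int(c) for sid, c in zip(stager.subject_ids_,
                                              stager.clusterer_.labels_)}
            manifest["k"] = int(stager.clusterer_.k_)
            manifest["weights"] = w.weights.tolist()
        else:
            decoded = decode_consolidate(forward(pooled_model, seq))
            pred, cons = predict_stages(decoded), decoded
            manifest["assignment"] = None
        rep = evaluate(pred, test_rec.labels, cons,
                       subject_id=test_rec.subject_id)
        reports.append(rep)

        if pooled_model is not None and config.include_pooled:
            decoded = decode_consolidate(forward(pooled_model, seq))
            pooled_reports.append(
                evaluate(predict_stages(decoded), test_rec.labels, decoded,
                         subject_id=test_rec.subject_id))
        manifests.append(manifest)

    rows = []
    for rep in reports:
        row = rep.as_row()
        row["model"] = "E-SCNN"
        rows.append(row)
    for rep in pooled_reports:
        row = rep.as_row()
        row["model"] = "SCNN-pooled"
        rows.append(row)
    return {"reports": reports, "pooled_reports": pooled_reports,
            "manifests": manifests, "table": pd.DataFrame(rows)}
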