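"""Subject clustering into spectral subgroups.

Subjects are partitioned in PCA space with Euclidean k-means; the
subgroup count is chosen by the mean silhouette coefficient over a
candidate range (default 2-5), ties going to the smaller k.  For a new
subject the distance to each subgroup is the *mean Euclidean distance
to that subgroup's members* (not to its centroid, although a centroid
mode is available); these distances later set the ensemble weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterModel",
    "SubjectClusterer",
    "fit_clusters",
    "silhouette",
    "select_k",
    "cluster_distances",
]

DEFAULT_K_RANGE: tuple[int, ...] = (2, 3, 4, 5)


@dataclass
class ClusterModel:
    """A fitted subject partition in PCA space."""

    centers: np.ndarray           # (k, U)
    assignment: np.ndarray        # (S,) subgroup index in 0..k-1
    k: int
    silhouette: float
    points: np.ndarray            # (S, U) training points (the members)
    members: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = {
                c: np.flatnonzero(self.assignment == c) for c in range(self.k)
            }
        for c, idx in self.members.items():
            if idx.size == 0:
                raise ValueError(f"subgroup {c} is empty")


def silhouette(points: np.ndarray, assignment: np.ndarray) -> float:
    """Mean silhouette coefficient of a partition (Euclidean).

    For each point, a is the mean distance to the other members of its
    own cluster and b the smallest mean distance to any other cluster;
    the point's score is (b - a)/max(a, b), zero for singletons.
    """
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    n_clusters = np.unique(assignment).size
    if n_clusters < 2:
        raise ValueError("silhouette requires at least two clusters")
    if n_clusters == points.shape[0]:
        return 0.0                      # all singletons: every point scores 0
    return float(silhouette_score(points, assignment, metric="euclidean"))


class SubjectClusterer(BaseEstimator):
    """K-means subject clusterer with silhouette-based model selection.

    Parameters
    ----------
    k : int or "auto", default "auto"
        Fixed subgroup count, or "auto" to pick the silhouette argmax
        over ``k_range`` (ties -> smallest k).
    k_range : iterable of int, default (2, 3, 4, 5)
    n_init : int, default 10
        Seeded k-means restarts; the best inertia wins.
    random_state : int, default 0

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_, labels_, k_, silhouette_, silhouette_table_
    (dict k -> silhouette, only for k="auto"), points_.
    """

    def __init__(self, k="auto", k_range=DEFAULT_K_RANGE, n_init: int = 10,
                 random_state: int = 0):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def _fit_one(self, X: np.ndarray, k: int) -> tuple[KMeans, np.ndarray]:
        km = KMeans(n_clusters=k, n_init=self.n_init,
                    random_state=self.random_state)
        labels = km.fit_predict(X)
        return km, labels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected an (S, U) point matrix")
        S = X.shape[0]
        if np.ptp(X, axis=0).max() < 1e-12:
            raise ValueError("degenerate data: all points identical")

        self.silhouette_table_ = {}
        if self.k == "auto":
            ks = sorted(int(k) for k in self.k_range)
            if not ks:
                raise ValueError("empty k_range")
            for k in ks:
                if not (2 <= k <= S):
                    raise ValueError(f"k={k} not in 2..{S}")
            best = None
            for k in ks:
                km, labels = self._fit_one(X, k)
                s = silhouette(X, labels)
                self.silhouette_table_[k] = s
                if best is None or s > best[0] + 1e-12:
                    best = (s, k, km, labels)
            _, k, km, labels = best
        else:
            k = int(self.k)
            if k < 2:
                raise ValueError(f"k must be >= 2, got {k}")
            if k > S:
                raise ValueError(f"k={k} exceeds {S} subjects")
            km, labels = self._fit_one(X, k)
            self.silhouette_table_[k] = silhouette(X, labels)

        self.k_ = k
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = labels
        self.silhouette_ = self.silhouette_table_[k]
        self.points_ = X
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.cluster_centers_[None], axis=2)
        return d.argmin(axis=1)

    def to_model(self) -> ClusterModel:
        return ClusterModel(centers=self.cluster_centers_,
                            assignment=self.labels_, k=self.k_,
                            silhouette=self.silhouette_, points=self.points_)


def fit_clusters(points: np.ndarray, k: int, seed: int = 0,
                 n_init: int = 10) -> ClusterModel:
    """K-means with ``n_init`` seeded restarts; deterministic given seed."""
    return SubjectClusterer(k=k, n_init=n_init, random_state=seed) \
        .fit(points).to_model()


def select_k(points: np.ndarray, k_range=DEFAULT_K_RANGE, seed: int = 0,
             n_init: int = 10) -> tuple[int, dict[int, float]]:
    """Silhouette-argmax subgroup count over ``k_range`` (ties -> smallest)."""
    clu = SubjectClusterer(k="auto", k_range=k_range, n_init=n_init,
                           random_state=seed).fit(points)
    return clu.k_, dict(clu.silhouette_table_)


def cluster_distances(model: ClusterModel, point: np.ndarray,
                      mode: str = "members") -> np.ndarray:
    """Distance from a query point to each subgroup.

    ``mode="members"`` (default): mean Euclidean distance to the
    subgroup's member points.  ``mode="centroid"``: distance to the
    k-means center.
    """
    point = np.asarray(point, dtype=float).ravel()
    if mode == "centroid":
        return np.linalg.norm(model.centers - point[None, :], axis=1)
    if mode != "members":
        raise ValueError(f"unknown mode {mode!r}")
    out = np.empty(model.k)
    for c in range(model.k):
        idx = model.members[c]
        if idx.size == 0:
            raise ValueError(f"subgroup {c} is empty")
        out[c] = np.linalg.norm(model.points[idx] - point[None, :],
                                axis=1).mean()
    return out
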