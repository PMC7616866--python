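"""Phenogroup derivation: K-means on embeddings, elbow selection of K,
fixed-centroid transfer to external cohorts, and 2-D visualization.

Clustering operates on all embedding coordinates without dimensionality
reduction or (by default) standardization.  Centroids fitted on a
derivation cohort are frozen; external cohorts are labelled by nearest
centroid only, never by refitting.  Phenogroup letters are assigned by
observed cohort mortality: B is the highest-event-rate cluster, C the
lowest, A the remainder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = ["Phenogrouper", "ElbowResult", "select_k_elbow", "project_2d",
           "pca_reduce"]

#: Normalized-curvature value below which the inertia curve is considered
#: to have no pronounced knee.
KNEE_STRENGTH_THRESHOLD = 0.1


@dataclass
class ElbowResult:
    k: int
    inertias: dict[int, float]          # includes k=1 for curvature anchoring
    curvature: dict[int, float]
    knee_strength: float
    has_knee: bool


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_init: int,
                max_iter: int = 300) -> KMeans:
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                max_iter=max_iter)
    km.fit(X)
    return km


def select_k_elbow(X: np.ndarray, k_range=range(2, 10), seed: int = 0,
                   n_init: int = 10) -> ElbowResult:
    """Choose K at the maximum discrete curvature of the inertia curve.

    Inertia is computed for k=1 (total sum of squares) through max(k_range),
    min-max normalized, and the second difference taken at each interior k;
    the selected K maximizes it over ``k_range``.  ``knee_strength`` is that
    maximum on the normalized scale — a well-separated clustering gives
    values near 0.5, a structureless cloud values near 0, flagged via
    ``has_knee``.
    """
    X = np.asarray(X, dtype=float)
    ks = sorted(k_range)
    if ks[0] < 2:
        raise ValueError("k_range minimum must be >= 2")
    if X.shape[0] < ks[-1]:
        raise ValueError("fewer points than the largest k scanned")
    all_ks = [1] + ks
    inertias = {1: float(((X - X.mean(axis=0)) ** 2).sum())}
    for k in ks:
        inertias[k] = float(_fit_kmeans(X, k, seed, n_init).inertia_)
    vals = np.array([inertias[k] for k in all_ks])
    span = vals.max() - vals.min()
    norm = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
    curvature: dict[int, float] = {}
    for i in range(1, len(all_ks) - 1):
        curvature[all_ks[i]] = float(norm[i - 1] - 2 * norm[i] + norm[i + 1])
    candidates = [k for k in ks if k in curvature]
    k_sel = max(candidates, key=lambda k: curvature[k])
    strength = curvature[k_sel]
    return ElbowResult(k=k_sel, inertias=inertias, curvature=curvature,
                       knee_strength=strength,
                       has_knee=strength >= KNEE_STRENGTH_THRESHOLD)


def pca_reduce(X: np.ndarray, n_components: int = 50,
               seed: int = 0) -> np.ndarray:
    """Project onto the top principal components (orthonormal basis)."""
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_components, random_state=seed).fit_transform(X)


def project_2d(X: np.ndarray, seed: int = 0, n_pcs: int = 50,
               perplexity: float = 30.0) -> np.ndarray:
    """PCA to the top 50 components, then 2-D t-SNE.  For plots only."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points to project")
    reduced = pca_reduce(X, n_pcs, seed)
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, init="pca",
              perplexity=perplexity)
    return ts.fit_transform(reduced)


class Phenogrouper(ClusterMixin, BaseEstimator):
    """K-means phenogrouping with fixed-centroid external assignment.

    Parameters
    ----------
    k : int or "elbow"
        Number of clusters, or elbow selection over ``k_range``.
    k_range : iterable of int
        Scanned range when ``k == "elbow"``.
    n_init : int
        k-means++ restarts; the best inertia is kept.
    standardize : bool
        Optional z-scoring of features before clustering (off by default:
        the derivation uses the raw embedding coordinates).

    Fitted attributes: ``cluster_centers_``, ``labels_``, ``inertia_``,
    ``k_``, ``elbow_`` (when selected), ``letter_map_`` (after
    :meth:`map_letters_by_mortality`).
    """

    def __init__(self, k: int | str = 3, k_range=range(2, 10),
                 n_init: int = 10, standardize: bool = False,
                 random_state: int = 0):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _prepare(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("embeddings must be a 2-D array")
        if not fitting:
            if X.shape[1] != self.cluster_centers_.shape[1]:
                raise ValueError(
                    f"embedding dimension {X.shape[1]} does not match "
                    f"centroid dimension {self.cluster_centers_.shape[1]}")
        if self.standardize:
            if fitting:
                self.scale_mean_ = X.mean(axis=0)
                self.scale_sd_ = X.std(axis=0)
                self.scale_sd_[self.scale_sd_ == 0] = 1.0
            X = (X - self.scale_mean_) / self.scale_sd_
        return X

    def fit(self, X, y=None):
        Xp = self._prepare(X, fitting=True)
        if self.k == "elbow":
            self.elbow_ = select_k_elbow(Xp, self.k_range,
                                         seed=self.random_state,
                                         n_init=self.n_init)
            k = self.elbow_.k
        else:
            k = int(self.k)
        km = _fit_kmeans(Xp, k, self.random_state, self.n_init)
        self.k_ = k
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.labels_ = self.predict(X)  # nearest-centroid with our tie rule
        self.letter_map_ = None
        return self

    def _distances(self, X) -> np.ndarray:
        Xp = self._prepare(X, fitting=False)
        return cdist(Xp, self.cluster_centers_)

    def transform(self, X) -> np.ndarray:
        """Distance of each subject to each centroid."""
        return self._distances(X)

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid labels; ties go to the lowest centroid index."""
        return np.argmin(self._distances(X), axis=1)

    # ------------------------------------------------------------------

    def map_letters_by_mortality(self, event_rates: dict[int, float]) -> dict[int, str]:
        """Assign phenogroup letters by descending observed event rate.

        With three clusters: B = highest mortality, C = lowest, A = middle
        — matching the naming semantics of the derivation analysis.  For
        other K, letters continue alphabetically after the B/.../C rule.
        """
        order = sorted(event_rates, key=lambda c: -event_rates[c])
        k = len(order)
        if k == 1:
            letters = ["A"]
        else:
            # highest -> B, lowest -> C, middles -> A, D, E, ... in rate order
            letters = ["B"] + (["A"] + [chr(ord("D") + i) for i in range(k - 3)])[:k - 2] + ["C"]
        self.letter_map_ = {c: letters[i] for i, c in enumerate(order)}
        return self.letter_map_

    def assign(self, X, subject_ids=None) -> pd.DataFrame:
        """Fixed-centroid assignment table: label, letter, per-centroid distance."""
        d = self._distances(X)
        labels = np.argmin(d, axis=1)
        n = d.shape[0]
        ids = [f"S{i}" for i in range(n)] if subject_ids is None else list(subject_ids)
        out = pd.DataFrame({"subject_id": ids, "cluster": labels})
        if self.letter_map_ is not None:
            out["phenogroup"] = [self.letter_map_[c] for c in labels]
        for j in range(d.shape[1]):
            out[f"dist_{j}"] = d[:, j]
        return out

    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {"k": self.k_, "random_state": self.random_state,
                "standardize": self.standardize,
                "letter_map": ({str(k): v for k, v in self.letter_map_.items()}
                               if self.letter_map_ else None)}
        payload = {"centroids": self.cluster_centers_,
                   "meta": np.frombuffer(json.dumps(meta).encode(), np.uint8)}
        if self.standardize:
            payload["scale_mean"] = self.scale_mean_
            payload["scale_sd"] = self.scale_sd_
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> "Phenogrouper":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        est = cls(k=meta["k"], standardize=meta["standardize"],
                  random_state=meta["random_state"])
        est.k_ = meta["k"]
        est.cluster_centers_ = data["centroids"]
        est.inertia_ = float("nan")
        est.letter_map_ = ({int(k): v for k, v in meta["letter_map"].items()}
                           if meta["letter_map"] else None)
        if meta["standardize"]:
            est.scale_mean_ = data["scale_mean"]
            est.scale_sd_ = data["scale_sd"]
        return est
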