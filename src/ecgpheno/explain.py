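"""Cluster-adapted class-activation saliency for 1-D ECG signals.

Standard gradient-weighted class activation mapping attributes a class
score to the last convolutional feature maps.  Phenogroups have no class
score, so the scalar used here is a soft-assignment log-probability over
negative squared centroid distances,

    score_j(e) = -||e - c_j||^2 - log sum_k exp(-||e - c_k||^2),

which is differentiable, bounded above by 0, and reduces to a one-hot
assignment (score ~ 0) when the clusters are far apart.  Because the
embedding is the flattened final feature maps, the gradient of the score
with respect to those maps is the reshaped embedding gradient; channel
weights are its temporal means, and the map is the rectified weighted sum
of feature maps, linearly upsampled to the 4096-sample input grid and
broadcast across the 12 leads (the flattened embedding mixes leads, so a
single temporal map is the honest resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import ECGResNet

__all__ = ["SaliencyMap", "cluster_score", "cluster_score_grad",
           "gradcam", "average_saliency"]


@dataclass
class SaliencyMap:
    """Nonnegative per-lead, per-sample importance, normalized to sum 1."""

    values: np.ndarray          # (12, input_len)
    cluster: int
    n_averaged: int = 1

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("saliency values must be nonnegative")
        if abs(float(self.values.sum()) - 1.0) > 1e-6:
            raise ValueError("saliency must be normalized to sum 1")


def _sq_dists(e: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return ((centroids - e[None, :]) ** 2).sum(axis=1)


def _check_target(centroids: np.ndarray, target: int) -> None:
    if not 0 <= target < centroids.shape[0]:
        raise ValueError(f"unknown cluster index {target}")


def _temperature(d2: np.ndarray, temperature) -> float:
    if temperature == "auto":
        return float(max(d2.mean(), 1e-12))
    t = float(temperature)
    if t <= 0:
        raise ValueError("temperature must be > 0")
    return t


def cluster_score(embedding: np.ndarray, centroids: np.ndarray,
                  target_cluster: int, temperature: float | str = 1.0) -> float:
    """Soft-assignment log-probability of the target cluster.

    ``temperature`` divides the squared distances before the softmax;
    ``"auto"`` uses their mean, which keeps the assignment soft (and its
    gradient alive) when embeddings live far from every centroid.
    """
    e = np.asarray(embedding, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if e.shape[0] != centroids.shape[1]:
        raise ValueError("embedding and centroid dimensions differ")
    _check_target(centroids, target_cluster)
    d2 = _sq_dists(e, centroids)
    a = -d2 / _temperature(d2, temperature)
    amax = a.max()
    lse = amax + np.log(np.exp(a - amax).sum())
    return float(a[target_cluster] - lse)


def cluster_score_grad(embedding: np.ndarray, centroids: np.ndarray,
                       target_cluster: int,
                       temperature: float | str = 1.0) -> np.ndarray:
    """Analytic gradient of :func:`cluster_score` w.r.t. the embedding."""
    e = np.asarray(embedding, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    _check_target(centroids, target_cluster)
    d2 = _sq_dists(e, centroids)
    t = _temperature(d2, temperature)
    a = -d2 / t
    p = np.exp(a - a.max())
    p /= p.sum()
    grad = (-2.0 / t) * (e - centroids[target_cluster])
    grad += (2.0 / t) * (p[:, None] * (e[None, :] - centroids)).sum(axis=0)
    return grad


def _upsample(coarse: np.ndarray, out_len: int) -> np.ndarray:
    """Linear interpolation from coarse bin centers to the sample grid."""
    T = len(coarse)
    stride = out_len / T
    centers = (np.arange(T) + 0.5) * stride - 0.5
    return np.interp(np.arange(out_len), centers, coarse)


def gradcam(net: ECGResNet, signal: np.ndarray, centroids: np.ndarray,
            target_cluster: int,
            temperature: float | str = "auto") -> SaliencyMap:
    """Saliency of one preprocessed record for a target phenogroup.

    Channel weights are the temporal average of the cluster-score gradient
    with respect to the final feature maps; the raw map is the rectified
    weighted sum of those maps.  An all-zero raw map (possible when
    rectification removes everything) falls back to a uniform map.
    """
    x = np.asarray(signal, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    maps = net.feature_maps(x, train=False)[0]          # (C, T)
    emb = maps.reshape(-1)
    g = cluster_score_grad(emb, centroids, target_cluster,
                           temperature=temperature)
    g = g.reshape(maps.shape)                           # (C, T)
    weights = g.mean(axis=1)
    raw = np.maximum(weights @ maps, 0.0)               # (T,)
    up = _upsample(raw, net.arch.input_len)
    full = np.tile(up, (net.arch.n_leads, 1))
    total = full.sum()
    if total <= 0:
        full = np.full_like(full, 1.0 / full.size)
    else:
        full = full / total
    return SaliencyMap(values=full, cluster=int(target_cluster))


def average_saliency(net: ECGResNet, signals: np.ndarray,
                     centroids: np.ndarray, cluster: int,
                     n: int = 1000,
                     embeddings: np.ndarray | None = None,
                     assignments: np.ndarray | None = None) -> SaliencyMap:
    """Average map over the ``n`` cluster members nearest its centroid.

    When the cluster has fewer than ``n`` members all of them are used and
    the actual count is recorded in ``n_averaged``.  Precomputed embeddings
    or assignments may be passed to avoid redundant forward passes.
    """
    signals = np.asarray(signals, dtype=np.float32)
    centroids = np.asarray(centroids, dtype=float)
    _check_target(centroids, cluster)
    if embeddings is None:
        embeddings = np.concatenate(
            [net.embed(signals[i:i + 64]) for i in range(0, len(signals), 64)])
    if assignments is None:
        d_all = ((embeddings[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        assignments = np.argmin(d_all, axis=1)
    members = np.flatnonzero(assignments == cluster)
    if members.size == 0:
        raise ValueError(f"cluster {cluster} is empty")
    dist = ((embeddings[members] - centroids[cluster]) ** 2).sum(axis=1)
    chosen = members[np.argsort(dist, kind="stable")[:n]]
    acc = None
    for idx in chosen:
        m = gradcam(net, signals[idx], centroids, cluster).values
        acc = m if acc is None else acc + m
    acc /= acc.sum()
    return SaliencyMap(values=acc, cluster=int(cluster),
                       n_averaged=len(chosen))
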