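"""DAB-positive region segmentation by k-means clustering.

Tissue pixels of the DAB single-stain image are clustered on their z-scored
RGB values; the number of clusters (1 to 3) is chosen with the
Davies-Bouldin index, clusters are ordered by their mean DAB-grayscale
intensity, and the darkest cluster forms the DAB-positive mask.  The
summary statistic is percent DAB occupancy: the DAB mask area as a
percentage of the tissue area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Difference between darkest and next cluster mean (gray levels) below
#: which the segmentation is flagged low-contrast.
LOW_CONTRAST_DELTA = 10.0


@dataclass(frozen=True)
class ClusteringParams:
    """k-means and model-selection settings."""

    k_min: int = 1
    k_max: int = 3
    n_init: int = 5
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max <= 3:
            raise ValueError("require 1 <= k_min <= k_max <= 3")


@dataclass
class SegmentationResult:
    """Cluster labels, darkest-first ordering and the DAB mask."""

    k: int
    labels: np.ndarray  # H x W ints, 0 = non-tissue, 1..k = clusters
    cluster_order: list[int]  # cluster ids, darkest first
    dab_mask: np.ndarray
    dab_percent: float
    low_contrast: bool = field(default=False)


def build_feature_matrix(
    dab_rgb: np.ndarray, tissue: np.ndarray
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-scored RGB features of tissue pixels plus their (row, col) index map.

    Each channel is standardized with the mean and population std over
    tissue pixels; a zero-spread channel is set to 0 with a warning.
    """
    tissue = np.asarray(tissue, bool)
    if not tissue.any():
        raise ValueError("empty tissue mask")
    idx = np.nonzero(tissue)
    x = np.asarray(dab_rgb, float)[idx]
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    if not ok.all():
        logger.warning("zero-variance feature channel(s) %s set to 0",
                       np.nonzero(~ok)[0].tolist())
    return out, idx


def davies_bouldin_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (scatter_i + scatter_j) / centroid_distance_ij ratio (lower is better).

    Scatter is the mean Euclidean distance of members to their centroid.
    Coincident centroids give an infinite index.  Requires k >= 2 and no
    empty cluster.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    k = ids.size
    if k < 2:
        raise ValueError("DB undefined for fewer than 2 clusters")
    centroids = np.stack([features[labels == i].mean(axis=0) for i in ids])
    scatter = np.array(
        [
            np.linalg.norm(features[labels == i] - centroids[n], axis=1).mean()
            for n, i in enumerate(ids)
        ]
    )
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / d
    ratio[np.isnan(ratio)] = np.inf  # coincident centroids with zero scatter
    np.fill_diagonal(ratio, -np.inf)
    return float(np.nanmax(ratio, axis=1).mean())


def kmeans_cluster(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 300,
) -> np.ndarray:
    """Seeded k-means (k-means++ init, best of ``n_init`` restarts)."""
    features = np.asarray(features, float)
    if features.shape[0] < k:
        raise ValueError("fewer points than clusters")
    if k == 1:
        return np.zeros(features.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, max_iter=max_iter)
    return km.fit_predict(features)


def _inertia(features: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for i in np.unique(labels):
        pts = features[labels == i]
        tot += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return tot


def select_k(
    features: np.ndarray, params: ClusteringParams = ClusteringParams()
) -> int:
    """Choose k in [k_min, k_max] with the Davies-Bouldin index.

    DB is undefined at k = 1, so candidates k >= 2 are compared by DB and
    k = 1 is adopted only when splitting into two clusters improves the
    total within-cluster variance by less than 1%.
    """
    features = np.asarray(features, float)
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to select k")
    inertia1 = float(((features - features.mean(axis=0)) ** 2).sum())
    candidates = [k for k in range(max(2, params.k_min), params.k_max + 1) if k <= n]
    if params.k_max == 1 or not candidates:
        return 1
    labels2 = kmeans_cluster(features, 2, params.seed, params.n_init, params.max_iter)
    if params.k_min == 1:
        if inertia1 <= 0 or (inertia1 - _inertia(features, labels2)) / inertia1 < 0.01:
            return 1
    best_k, best_db = None, np.inf
    for k in candidates:
        labels = (
            labels2
            if k == 2
            else kmeans_cluster(features, k, params.seed, params.n_init, params.max_iter)
        )
        if np.unique(labels).size < k:
            continue  # degenerate solution; skip
        db = davies_bouldin_index(features, labels)
        if db < best_db:
            best_k, best_db = k, db
    return best_k if best_k is not None else 1


def extract_dab_mask(
    labels: np.ndarray,
    dab_gray: np.ndarray,
    tissue: np.ndarray,
    k: int,
) -> tuple[np.ndarray, float]:
    """Darkest-mean cluster as the DAB mask, plus percent DAB occupancy.

    ``labels`` is the flat cluster assignment of tissue pixels (order of
    ``np.nonzero(tissue)``); the cluster with the lowest mean DAB-grayscale
    intensity becomes the mask and ``dab_percent = 100 * |mask| / |tissue|``.
    """
    tissue = np.asarray(tissue, bool)
    idx = np.nonzero(tissue)
    vals = np.asarray(dab_gray, float)[idx]
    labels = np.asarray(labels)
    means = np.array([vals[labels == i].mean() for i in range(k)])
    darkest = int(np.argmin(means))
    mask = np.zeros_like(tissue)
    mask[idx[0][labels == darkest], idx[1][labels == darkest]] = True
    percent = 100.0 * mask.sum() / tissue.sum()
    return mask, float(percent)


def segment_dab(
    dab_rgb: np.ndarray,
    dab_gray: np.ndarray,
    tissue: np.ndarray,
    params: ClusteringParams = ClusteringParams(),
) -> SegmentationResult:
    """Full segmentation: features, model selection, clustering, DAB mask."""
    features, idx = build_feature_matrix(dab_rgb, tissue)
    k = select_k(features, params)
    labels = kmeans_cluster(features, k, params.seed, params.n_init, params.max_iter)
    dab_mask, dab_percent = extract_dab_mask(labels, dab_gray, tissue, k)
    vals = np.asarray(dab_gray, float)[idx]
    means = np.sort([vals[labels == i].mean() for i in range(k)])
    low_contrast = bool(k >= 2 and (means[1] - means[0]) < LOW_CONTRAST_DELTA)
    order = list(np.argsort([vals[labels == i].mean() for i in range(k)]))
    label_img = np.zeros(tissue.shape, dtype=int)
    label_img[idx] = labels + 1
    return SegmentationResult(
        k=k,
        labels=label_img,
        cluster_order=[int(i) for i in order],
        dab_mask=dab_mask,
        dab_percent=dab_percent,
        low_contrast=low_contrast,
    )


def draw_overlay(original: np.ndarray, dab_mask: np.ndarray) -> np.ndarray:
    """Copy of the original with a 1-px pure red contour of each DAB region.

    The contour is the 8-connected inner boundary (mask minus its erosion
    by a 3x3 square); interior pixels are untouched.
    """
    original = np.asarray(original)
    mask = np.asarray(dab_mask, bool)
    if original.shape[:2] != mask.shape:
        raise ValueError("overlay frames are not aligned")
    out = original.copy()
    if not mask.any():
        return out
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    boundary = mask & ~interior
    out[boundary] = (255, 0, 0)
    return out
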