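"""Voxel-wise entropy maps, super-voxel vectors, and habitat clustering.

Each WVOI voxel is summarized by a two-channel "super-voxel" vector
(gray-level intensity, local first-order entropy).  K-means on these
vectors partitions the WVOI into habitats; the cluster count k is chosen
cohort-wide from internal quality metrics (mean Silhouette score, with
the Davies-Bouldin index reported alongside), and clusters are ranked by
mean raw intensity so habitat 1 is always the brightest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_samples

from .geometry import ImageVolume, RegionMask

logger = logging.getLogger(__name__)

#: Sentinel Davies-Bouldin value for degenerate (coincident-cluster) cases.
DB_SENTINEL = 1e6


@dataclass(frozen=True)
class EntropyConfig:
    """Settings for the voxel-wise first-order entropy map.

    ``n_bins`` is the histogram bin count N_g shared by every kernel of a
    subject (bins span the WVOI-wide intensity range); ``epsilon`` guards
    the logarithm; ``kernel_radius_voxels`` is the half-width of the cubic
    neighborhood (1 -> 3x3x3).
    """

    n_bins: int = 25
    epsilon: float = 2.2e-16
    kernel_radius_voxels: int = 1

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.kernel_radius_voxels < 1:
            raise ValueError("kernel_radius_voxels must be >= 1")


@dataclass(frozen=True)
class EntropyMap:
    """Entropy (bits) for each WVOI voxel; NaN outside the WVOI."""

    values: np.ndarray
    config: EntropyConfig


@dataclass(frozen=True)
class SuperVoxelTable:
    """Per-WVOI-voxel feature rows used for clustering.

    ``standardized`` holds z-scored (intensity, entropy) columns fed to
    K-means; ``raw`` the original values (used for habitat ranking);
    ``coords`` the voxel indices.
    """

    standardized: np.ndarray
    raw: np.ndarray
    coords: np.ndarray
    channel_means: np.ndarray
    channel_stds: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.standardized.shape[0]


@dataclass(frozen=True)
class HabitatLabeling:
    """Cluster assignment per WVOI voxel, ranked so habitat 1 is brightest."""

    k: int
    labels: np.ndarray  # 1..k per super-voxel row
    cluster_mean_intensity: np.ndarray  # descending, index c-1 -> habitat c
    silhouette: float
    db_index: float
    seed: int


def entropy_map(
    volume: ImageVolume, wvoi: RegionMask, cfg: EntropyConfig | None = None
) -> EntropyMap:
    """Compute the voxel-based first-order entropy feature map on the WVOI.

    For every WVOI voxel, intensities of the WVOI voxels inside its cubic
    kernel neighborhood are binned into ``n_bins`` equal-width bins over
    the WVOI-wide min-max range; with normalized histogram p(i) the voxel
    value is  H = -sum_i p(i) * log2(p(i) + eps)  in bits.  Empty bins
    contribute zero.  A constant region yields entropies ~0.
    """
    cfg = cfg or EntropyConfig()
    mask = wvoi.values
    if not mask.any():
        raise ValueError("WVOI mask is empty")
    if not wvoi.same_grid(volume):
        raise ValueError("volume and WVOI are on different grids")

    vals = volume.values
    inside = vals[mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi > lo:
        # Right-edge values land in the last bin.
        bin_idx = np.minimum(
            ((vals - lo) / (hi - lo) * cfg.n_bins).astype(np.int64), cfg.n_bins - 1
        )
    else:
        bin_idx = np.zeros(vals.shape, dtype=np.int64)

    size = 2 * cfg.kernel_radius_voxels + 1
    # Per-bin local counts via box sums restricted to the WVOI.
    counts = np.empty((cfg.n_bins,) + vals.shape, dtype=np.float64)
    for b in range(cfg.n_bins):
        indicator = ((bin_idx == b) & mask).astype(np.float64)
        counts[b] = ndimage.uniform_filter(indicator, size=size, mode="constant")
    total = ndimage.uniform_filter(
        mask.astype(np.float64), size=size, mode="constant"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total[None]
    p = np.nan_to_num(p, nan=0.0, posinf=0.0, neginf=0.0)
    with np.errstate(invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p + cfg.epsilon), 0.0)
    h = -term.sum(axis=0)

    out = np.full(vals.shape, np.nan)
    out[mask] = h[mask]
    return EntropyMap(values=out, config=cfg)


def build_supervoxels(
    volume: ImageVolume, emap: EntropyMap, wvoi: RegionMask
) -> SuperVoxelTable:
    """Assemble the (intensity, entropy) super-voxel table for a WVOI.

    Both channels are z-standardized across the WVOI before clustering;
    a zero-variance channel maps to all-zero.
    """
    mask = wvoi.values
    if volume.values.shape != mask.shape or emap.values.shape != mask.shape:
        raise ValueError("volume, entropy map and WVOI grids differ")
    coords = np.argwhere(mask)
    raw = np.column_stack([volume.values[mask], emap.values[mask]])
    means = raw.mean(axis=0)
    stds = raw.std(axis=0)
    # relative tolerance: float noise on a constant channel is not variance
    degenerate = stds <= 1e-12 * np.maximum(np.abs(means), 1.0)
    safe = np.where(degenerate, 1.0, stds)
    standardized = (raw - means) / safe
    standardized[:, degenerate] = 0.0
    return SuperVoxelTable(
        standardized=standardized,
        raw=raw,
        coords=coords,
        channel_means=means,
        channel_stds=stds,
    )


def _kmeans_fit(x: np.ndarray, k: int, seed: int, max_retries: int = 5) -> KMeans:
    for attempt in range(max_retries):
        km = KMeans(
            n_clusters=k,
            n_init=10,
            tol=1e-6,
            random_state=seed + attempt,
        ).fit(x)
        if len(np.unique(km.labels_)) == k:
            return km
    raise RuntimeError(f"K-means produced an empty cluster in {max_retries} retries")


def _quality(x: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mean silhouette (singleton samples scored 0) and DB index."""
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        return 0.0, DB_SENTINEL
    sil = silhouette_samples(x, labels)
    if np.any(counts == 1):
        logger.warning("singleton cluster: silhouette of its voxel set to 0")
        sil = sil.copy()
        for u in uniq[counts == 1]:
            sil[labels == u] = 0.0
    centroids = np.stack([x[labels == u].mean(axis=0) for u in uniq])
    if np.any(
        np.linalg.norm(centroids[:, None] - centroids[None], axis=-1)
        [~np.eye(len(uniq), dtype=bool)] < 1e-12
    ):
        return float(sil.mean()), DB_SENTINEL
    return float(sil.mean()), float(davies_bouldin_score(x, labels))


def cluster_habitats(sv: SuperVoxelTable, k: int, seed: int = 0) -> HabitatLabeling:
    """K-means the super-voxel vectors into k habitats, brightest first.

    Clusters are relabeled by descending mean *raw* intensity, so habitat 1
    always has the highest mean gray level; ranking ties break by original
    cluster index.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if sv.n_voxels < k:
        raise ValueError(f"only {sv.n_voxels} super-voxels for k={k}")
    km = _kmeans_fit(sv.standardized, k, seed)
    raw_int = sv.raw[:, 0]
    means = np.array([raw_int[km.labels_ == c].mean() for c in range(k)])
    # stable sort keeps cluster-index order on ties
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    sil, db = _quality(sv.standardized, km.labels_)
    return HabitatLabeling(
        k=k,
        labels=labels,
        cluster_mean_intensity=means[order],
        silhouette=sil,
        db_index=db,
        seed=seed,
    )


def habitat_mask(
    labeling: HabitatLabeling, sv: SuperVoxelTable, wvoi: RegionMask, habitat: int
) -> RegionMask:
    """Binary mask of one habitat on the WVOI grid."""
    values = np.zeros(wvoi.shape, dtype=bool)
    rows = labeling.labels == habitat
    idx = sv.coords[rows]
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return RegionMask(values, wvoi.spacing_mm, wvoi.origin)


def select_k(
    tables: list[SuperVoxelTable],
    candidates: tuple[int, ...] = (2, 3, 4),
    seed: int = 0,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Choose the cohort-wide cluster count from internal quality metrics.

    For every candidate k, each subject's super-voxels are clustered and
    mean Silhouette / Davies-Bouldin are averaged over the cohort.  The
    winner is the k with the highest mean Silhouette; if the DB index
    disagrees the disagreement is logged (Silhouette wins).

    Returns ``(k_star, metrics)`` where metrics[k] has keys
    ``silhouette_mean``, ``silhouette_sd``, ``db_mean``, ``db_sd``.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if not tables:
        raise ValueError("no super-voxel tables given")
    metrics: dict[int, dict[str, float]] = {}
    for k in candidates:
        sils, dbs = [], []
        for i, sv in enumerate(tables):
            lab = cluster_habitats(sv, k, seed=seed + 1000 * i)
            sils.append(lab.silhouette)
            dbs.append(lab.db_index)
        metrics[k] = {
            "silhouette_mean": float(np.mean(sils)),
            "silhouette_sd": float(np.std(sils)),
            "db_mean": float(np.mean(dbs)),
            "db_sd": float(np.std(dbs)),
        }
    k_star = max(candidates, key=lambda k: metrics[k]["silhouette_mean"])
    k_db = min(candidates, key=lambda k: metrics[k]["db_mean"])
    if k_db != k_star:
        logger.warning(
            "Silhouette prefers k=%d but Davies-Bouldin prefers k=%d; "
            "using the Silhouette choice",
            k_star,
            k_db,
        )
    return k_star, metrics
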