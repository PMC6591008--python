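"""Per-cell, per-frame immune-synapse metrics.

Turns segmented cluster sets into the quantities used to describe antigen
gathering at the B cell-APC interface: how the total clustered antigen
fluorescence is distributed among microclusters, whether a cell has formed a
cSMAC (central supramolecular activation cluster, operationalized as >90% of
the clustered antigen fluorescence residing in at most two clusters), how far
microclusters sit from the synapse centre, cluster sizes, the cell footprint
and total searched area from an F-actin channel, and kymographs along a line
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segmentation import ClusterSet, IntensityImage

__all__ = [
    "CellFrameMetrics",
    "CellTimeSeries",
    "cluster_fractions",
    "is_csmac",
    "clusters_to_quantile",
    "csmac_fraction",
    "mean_distance_to_center",
    "normalize_distance_series",
    "mean_cluster_size",
    "summarize_frame",
    "summarize_time_series",
    "cell_footprint",
    "searched_area",
    "build_kymograph",
]


@dataclass(frozen=True)
class CellFrameMetrics:
    """Synapse metrics of one cell at one frame."""

    time_s: float | None
    n_clusters: int
    mean_cluster_area_um2: float
    total_ag_intensity: float
    fractions: tuple[float, ...]
    largest_fraction: float
    top2_fraction: float
    clusters_to_q90: int
    mean_distance_um: float
    is_csmac: bool


@dataclass(frozen=True)
class CellTimeSeries:
    """Ordered per-frame metrics for one cell plus the normalized distance
    series (each frame's mean microcluster distance divided by the cell's
    maximum over the video)."""

    frames: tuple[CellFrameMetrics, ...]
    normalized_distance: tuple[float, ...]


def cluster_fractions(cluster_set: ClusterSet) -> np.ndarray:
    """Per-cluster share of the total clustered intensity, sorted descending.

    Raises
    ------
    ValueError
        If the set is empty or its grand total is not positive.
    """
    totals = cluster_set.totals
    grand = totals.sum()
    if totals.size == 0 or grand <= 0:
        raise ValueError("cluster_fractions requires a positive total intensity")
    return np.sort(totals / grand)[::-1]


def is_csmac(fractions, threshold: float = 0.9, max_clusters: int = 2) -> bool:
    """True iff the top ``max_clusters`` fractions sum to strictly more than
    ``threshold`` — the operational definition of a formed cSMAC."""
    f = np.sort(np.asarray(fractions, dtype=float))[::-1]
    return bool(f[:max_clusters].sum() > threshold)


def clusters_to_quantile(fractions, q: float = 0.9) -> int:
    """Smallest number of (largest) clusters whose fractions sum to >= ``q``."""
    f = np.sort(np.asarray(fractions, dtype=float))[::-1]
    csum = np.cumsum(f)
    idx = np.searchsorted(csum, q - 1e-12)
    return int(min(idx, f.size - 1)) + 1


def csmac_fraction(flags) -> float:
    """Percent of cells flagged as having formed a cSMAC."""
    flags = list(flags)
    if not flags:
        raise ValueError("csmac_fraction requires a non-empty list")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def mean_distance_to_center(cluster_set: ClusterSet) -> float:
    """Unweighted mean distance of cluster centroids from the synapse centre.

    The centre is the intensity-weighted centroid of all clustered
    fluorescence (centre of mass of the antigen signal); the average over
    clusters is unweighted.
    """
    if not cluster_set.clusters:
        raise ValueError("mean_distance_to_center requires >= 1 cluster")
    centroids = cluster_set.centroids_um
    weights = cluster_set.totals
    if weights.sum() > 0:
        center = (weights[:, None] * centroids).sum(axis=0) / weights.sum()
    else:
        center = centroids.mean(axis=0)
    return float(np.linalg.norm(centroids - center, axis=1).mean())


def normalize_distance_series(distances) -> np.ndarray:
    """Divide a per-frame mean-distance series by its maximum (all zeros if
    the maximum is zero)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    m = d.max()
    return d / m if m > 0 else np.zeros_like(d)


def mean_cluster_size(cluster_set: ClusterSet) -> float:
    """Mean per-cluster area in µm²; NaN for an empty set (not 0)."""
    areas = cluster_set.areas_um2
    return float(areas.mean()) if areas.size else float("nan")


def summarize_frame(
    cluster_set: ClusterSet,
    time_s: float | None = None,
    csmac_threshold: float = 0.9,
    csmac_max_clusters: int = 2,
) -> CellFrameMetrics:
    """Collect all per-frame metrics for one cell."""
    n = len(cluster_set)
    if n == 0:
        return CellFrameMetrics(
            time_s, 0, float("nan"), 0.0, (), 0.0, 0.0, 0, float("nan"), False
        )
    fr = cluster_fractions(cluster_set)
    return CellFrameMetrics(
        time_s=time_s,
        n_clusters=n,
        mean_cluster_area_um2=mean_cluster_size(cluster_set),
        total_ag_intensity=float(cluster_set.totals.sum()),
        fractions=tuple(float(f) for f in fr),
        largest_fraction=float(fr[0]),
        top2_fraction=float(fr[:2].sum()),
        clusters_to_q90=clusters_to_quantile(fr),
        mean_distance_um=mean_distance_to_center(cluster_set),
        is_csmac=is_csmac(fr, csmac_threshold, csmac_max_clusters),
    )


def summarize_time_series(
    cluster_sets: list[ClusterSet],
    times_s: list[float] | None = None,
    csmac_threshold: float = 0.9,
    csmac_max_clusters: int = 2,
) -> CellTimeSeries:
    """Per-frame metrics for one cell's video plus normalized distances."""
    if not cluster_sets:
        raise ValueError("summarize_time_series requires >= 1 frame")
    if times_s is None:
        times_s = [None] * len(cluster_sets)
    frames = tuple(
        summarize_frame(cs, t, csmac_threshold, csmac_max_clusters)
        for cs, t in zip(cluster_sets, times_s)
    )
    distances = np.array(
        [f.mean_distance_um if np.isfinite(f.mean_distance_um) else 0.0 for f in frames]
    )
    normalized = normalize_distance_series(distances)
    return CellTimeSeries(frames, tuple(float(v) for v in normalized))


def cell_footprint(image: IntensityImage) -> tuple[np.ndarray, float]:
    """Cell mask and area from an F-actin channel.

    Otsu-thresholds the channel, keeps the largest connected component and
    fills holes.  A blank (constant) image yields an empty mask and area 0.
    """
    from skimage.filters import threshold_otsu

    px = image.pixels
    if np.all(px == px.flat[0]):
        return np.zeros(image.shape, dtype=bool), 0.0
    mask = px > threshold_otsu(px)
    if not mask.any():
        return mask, 0.0
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)
    filled = ndi.binary_fill_holes(largest)
    area = float(filled.sum()) * image.pixel_size_um**2
    return filled, area


def searched_area(footprints: list[np.ndarray], pixel_size_um: float) -> float:
    """Area of the pixel-wise union of per-frame cell footprints (µm²)."""
    if not footprints:
        raise ValueError("searched_area requires >= 1 mask")
    shape = footprints[0].shape
    union = np.zeros(shape, dtype=bool)
    for m in footprints:
        if m.shape != shape:
            raise ValueError("all footprints must share one shape")
        union |= m.astype(bool)
    return float(union.sum()) * pixel_size_um**2


def build_kymograph(
    series: list[IntensityImage],
    p0_um: tuple[float, float],
    p1_um: tuple[float, float],
    width_px: int = 1,
) -> np.ndarray:
    """Space × time intensity array along a line segment.

    For each frame the intensity is sampled every pixel along the segment
    from ``p0_um`` to ``p1_um`` (bilinear interpolation), averaging
    ``width_px`` parallel samples offset perpendicular to the segment.
    Rows are positions along the segment, columns are frames.
    """
    if len(series) < 2:
        raise ValueError("kymograph requires >= 2 frames")
    px = series[0].pixel_size_um
    shape = series[0].shape
    p0 = np.array(p0_um, dtype=float) / px  # (x, y) in pixels
    p1 = np.array(p1_um, dtype=float) / px
    for p in (p0, p1):
        if not (0 <= p[0] <= shape[1] - 1 and 0 <= p[1] <= shape[0] - 1):
            raise ValueError("segment endpoint outside image")
    length = float(np.linalg.norm(p1 - p0))
    n_samples = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)
    line = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    direction = (p1 - p0) / (length if length > 0 else 1.0)
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    kymo = np.empty((n_samples, len(series)))
    for j, img in enumerate(series):
        if img.shape != shape:
            raise ValueError("all frames must share one shape")
        acc = np.zeros(n_samples)
        for off in offsets:
            pts = line + off * normal[None, :]
            # map_coordinates wants (row, col) = (y, x)
            coords = np.vstack([pts[:, 1], pts[:, 0]])
            acc += ndi.map_coordinates(img.pixels, coords, order=1, mode="nearest")
        kymo[:, j] = acc / width_px
    return kymo
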