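"""Voronoi-tessellation segmentation of localization point clouds.

Each localization is assigned its Voronoi polygon; the polygon area is an
inverse density proxy, so thresholding the cell area selects localizations
in dense regions.  Retained localizations are grouped into clusters via
connected components of the Voronoi adjacency graph (localizations whose
cells share an edge), and each cluster's boundary and area are taken from
the alpha-shape of its member points.

Defaults follow common practice for tissue DNA-PAINT data: an inclusive
cell-area threshold, a minimum of 10 localizations per retained object, and
a 0.05 µm alpha radius.  Cell-area thresholds must be matched to the
localization density of the data; the presets in
:data:`VORONOI_THRESHOLD_PRESETS` cover the density regimes of the tissue
cohorts this pipeline was built around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import QhullError, Voronoi

from .errors import DegenerateGeometryError
from .geometry import alpha_shape, polygon_area
from .loc_io import FieldOfView

logger = logging.getLogger(__name__)

#: Published per-cohort Voronoi cell-area threshold ranges (µm²), keyed by
#: tau-burden regime; shipped for use on comparable tissue data.
VORONOI_THRESHOLD_PRESETS: dict[str, tuple[float, float]] = {
    "part_braak_1_3": (0.00018, 0.0003),
    "ad_braak_4": (0.001, 0.002),
    "ad_braak_6": (0.002, np.inf),
}


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters (all lengths/areas in µm / µm²)."""

    voronoi_area_threshold: float = 2e-3
    min_locs: int = 10
    alpha_radius: float = 0.05

    def __post_init__(self) -> None:
        if self.voronoi_area_threshold <= 0:
            raise ValueError("voronoi_area_threshold must be positive")
        if self.min_locs < 1:
            raise ValueError("min_locs must be >= 1")
        if self.alpha_radius <= 0:
            raise ValueError("alpha_radius must be positive")


@dataclass
class Tessellation:
    """Per-localization Voronoi cells plus the cell adjacency graph."""

    points: np.ndarray  # (n, 2)
    areas: np.ndarray  # (n,), np.inf for unbounded cells
    bounded: np.ndarray  # (n,) bool
    adjacency: np.ndarray  # (m, 2) int pairs of cell-edge neighbors

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class Cluster:
    """A segmented aggregate: member localizations + alpha-shape boundary."""

    id: int
    indices: np.ndarray  # indices into the source FieldOfView table
    points: np.ndarray  # (k, 2) member coordinates (µm)
    channels: np.ndarray  # (k,) channel labels (object; None if single-color)
    boundary: object  # shapely geometry
    area: float  # alpha-shape area, µm²
    centroid: tuple[float, float]
    size_class: object | None = None
    channel_counts: dict = field(default_factory=dict)
    enrichment: float | None = None
    category: object | None = None
    overlap_score: float | None = None

    @property
    def n_locs(self) -> int:
        return len(self.indices)


def _cell_area(vor: Voronoi, region: list[int]) -> float:
    verts = vor.vertices[region]
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(
        np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    )


def compute_voronoi(fov: FieldOfView | np.ndarray) -> Tessellation:
    """Voronoi tessellation of a field of view (or a raw (n, 2) array).

    Cells of localizations on the convex hull of the point set are unbounded
    (they touch the field boundary) and are flagged with infinite area;
    bounded cell areas are positive and finite.  Raises
    :class:`DegenerateGeometryError` for < 3 points or collinear input.
    """
    pts = fov.points() if isinstance(fov, FieldOfView) else np.asarray(fov, float)
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"Voronoi tessellation needs >= 3 localizations, got {len(pts)}"
        )
    try:
        vor = Voronoi(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "degenerate localization geometry (collinear points?)"
        ) from exc

    n = len(pts)
    areas = np.full(n, np.inf)
    bounded = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) >= 3 and -1 not in region:
            bounded[i] = True
            areas[i] = _cell_area(vor, region)
    adjacency = np.asarray(vor.ridge_points, dtype=np.int64)
    return Tessellation(pts, areas, bounded, adjacency)


def retained_mask(tess: Tessellation, params: SegmentationParams) -> np.ndarray:
    """Localizations passing the density criterion.

    A localization is retained when its Voronoi cell is bounded and its area
    is at most the threshold (inclusive).  Unbounded cells have undefined
    area and always fail.
    """
    return tess.bounded & (tess.areas <= params.voronoi_area_threshold)


def _components(adjacency: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Connected-component label per point (-1 where mask is False)."""
    n = len(mask)
    labels = np.full(n, -1, dtype=np.int64)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return labels
    remap = np.full(n, -1, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    if len(adjacency):
        keep = mask[adjacency[:, 0]] & mask[adjacency[:, 1]]
        edges = adjacency[keep]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    i = remap[edges[:, 0]]
    j = remap[edges[:, 1]]
    m = len(idx)
    graph = coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(m, m)
    )
    _, comp = connected_components(graph, directed=False)
    labels[idx] = comp
    return labels


def _make_cluster(
    cid: int,
    member_idx: np.ndarray,
    points: np.ndarray,
    channels: np.ndarray | None,
    alpha_radius: float,
) -> Cluster:
    mpts = points[member_idx]
    shape = alpha_shape(mpts, alpha_radius)
    mch = (
        channels[member_idx]
        if channels is not None
        else np.full(len(member_idx), None, dtype=object)
    )
    counts: dict = {}
    for c in mch:
        if c is not None and not (isinstance(c, float) and np.isnan(c)):
            counts[c] = counts.get(c, 0) + 1
    return Cluster(
        id=cid,
        indices=np.asarray(member_idx, dtype=np.int64),
        points=mpts,
        channels=mch,
        boundary=shape,
        area=polygon_area(shape),
        centroid=(float(mpts[:, 0].mean()), float(mpts[:, 1].mean())),
        channel_counts=counts,
    )


def threshold_and_cluster(
    tess: Tessellation,
    params: SegmentationParams,
    channels: np.ndarray | None = None,
) -> list[Cluster]:
    """Density-threshold the tessellation and group retained localizations.

    Clusters are connected components of the Voronoi adjacency restricted to
    retained localizations; each cluster's boundary/area is the alpha-shape
    of its members.  An empty result is allowed.
    """
    mask = retained_mask(tess, params)
    labels = _components(tess.adjacency, mask)
    clusters: list[Cluster] = []
    for cid in range(labels.max() + 1 if labels.size else 0):
        member_idx = np.flatnonzero(labels == cid)
        clusters.append(
            _make_cluster(cid, member_idx, tess.points, channels, params.alpha_radius)
        )
    return clusters


def filter_min_locs(
    clusters: Sequence[Cluster], min_locs: int = 10
) -> list[Cluster]:
    """Discard clusters with fewer than ``min_locs`` members (inclusive keep)."""
    return [c for c in clusters if c.n_locs >= min_locs]


def segment_fov(
    fov: FieldOfView, params: SegmentationParams | None = None
) -> list[Cluster]:
    """Full single-color segmentation: tessellate, threshold, cluster, filter."""
    params = params or SegmentationParams()
    tess = compute_voronoi(fov)
    channels = fov.channels()
    clusters = threshold_and_cluster(tess, params, channels)
    kept = filter_min_locs(clusters, params.min_locs)
    logger.info(
        "segment_fov: %d localizations -> %d retained -> %d clusters -> "
        "%d clusters after min-locs filter",
        tess.n,
        int(retained_mask(tess, params).sum()),
        len(clusters),
        len(kept),
    )
    return kept
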