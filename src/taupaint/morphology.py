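"""Morphological descriptors, PCA embedding, and group-footprint overlap.

Every segmented aggregate is profiled by a fixed registry of 67 shape
descriptors computed directly from its raw localization point cloud (no
rendering): point/density statistics, geometric and moment descriptors of
the alpha-shape boundary, boundary curvature statistics on an
arc-length-resampled outline, medial-axis skeleton descriptors, fractal /
heterogeneity estimates, and composite shape indices.

Groups of aggregates are compared by PCA after unit-variance scaling; the
overlap of two groups in a principal-component plane is the Jaccard index
(intersection over union) of their footprint polygons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import DescriptorError
from .geometry import alpha_shape, convex_hull, largest_polygon
from .segmentation import Cluster, compute_voronoi

logger = logging.getLogger(__name__)

_BOUNDARY_SAMPLES = 128
_SKELETON_GRID = 96

# ---------------------------------------------------------------------------
# Descriptor registry: 67 named features in fixed order, with the length
# exponent of each (value scales as s**exponent under uniform dilation by s).

_REGISTRY: list[tuple[str, str, int]] = [
    # --- point / density (8)
    ("n_locs", "point", 0),
    ("loc_density", "point", -2),
    ("nn_dist_mean", "point", 1),
    ("nn_dist_std", "point", 1),
    ("nn_dist_min", "point", 1),
    ("nn_dist_max", "point", 1),
    ("centroid_dist_mean", "point", 1),
    ("centroid_dist_std", "point", 1),
    # --- geometric (16)
    ("area", "geometric", 2),
    ("perimeter", "geometric", 1),
    ("circularity", "geometric", 0),
    ("equivalent_diameter", "geometric", 1),
    ("major_axis", "geometric", 1),
    ("minor_axis", "geometric", 1),
    ("aspect_ratio", "geometric", 0),
    ("eccentricity", "geometric", 0),
    ("orientation", "geometric", 0),
    ("hull_area", "geometric", 2),
    ("hull_perimeter", "geometric", 1),
    ("solidity", "geometric", 0),
    ("convexity", "geometric", 0),
    ("extent", "geometric", 0),
    ("bbox_width", "geometric", 1),
    ("bbox_height", "geometric", 1),
    # --- moment (12)
    ("hu_1", "moment", 0),
    ("hu_2", "moment", 0),
    ("hu_3", "moment", 0),
    ("hu_4", "moment", 0),
    ("hu_5", "moment", 0),
    ("hu_6", "moment", 0),
    ("hu_7", "moment", 0),
    ("radius_gyration", "moment", 1),
    ("mu20", "moment", 2),
    ("mu02", "moment", 2),
    ("mu11", "moment", 2),
    ("cov_anisotropy", "moment", 0),
    # --- boundary (12)
    ("radial_mean", "boundary", 1),
    ("radial_std", "boundary", 1),
    ("radial_min", "boundary", 1),
    ("radial_max", "boundary", 1),
    ("radial_cv", "boundary", 0),
    ("curvature_mean", "boundary", -1),
    ("curvature_std", "boundary", -1),
    ("curvature_max", "boundary", -1),
    ("curvature_min", "boundary", -1),
    ("bending_energy", "boundary", -1),
    ("curvature_zero_crossings", "boundary", 0),
    ("boundary_vertex_count", "boundary", 0),
    # --- skeleton (10)
    ("skeleton_length", "skeleton", 1),
    ("branch_count", "skeleton", 0),
    ("branch_point_count", "skeleton", 0),
    ("endpoint_count", "skeleton", 0),
    ("branch_length_mean", "skeleton", 1),
    ("branch_length_max", "skeleton", 1),
    ("tortuosity", "skeleton", 0),
    ("skeleton_area_ratio", "skeleton", -1),
    ("longest_path_length", "skeleton", 1),
    ("cycle_count", "skeleton", 0),
    # --- fractal / heterogeneity (4)
    ("boundary_boxdim", "fractal", 0),
    ("cloud_boxdim", "fractal", 0),
    ("correlation_dim", "fractal", 0),
    ("lacunarity", "fractal", 0),
    # --- composite (5)
    ("elongation", "composite", 0),
    ("compactness", "composite", 0),
    ("radius_gyration_norm", "composite", 0),
    ("voronoi_cell_area_mean", "composite", 2),
    ("voronoi_cell_area_cv", "composite", 0),
]

DESCRIPTOR_NAMES: list[str] = [name for name, _, _ in _REGISTRY]
DESCRIPTOR_FAMILIES: dict[str, str] = {n: f for n, f, _ in _REGISTRY}
DESCRIPTOR_LENGTH_EXPONENTS: dict[str, int] = {n: e for n, _, e in _REGISTRY}

assert len(DESCRIPTOR_NAMES) == 67


# ---------------------------------------------------------------------------
# Helpers


def _hu_moments(u: np.ndarray, v: np.ndarray, scale: float) -> np.ndarray:
    """Seven Hu invariants of a centered point set.

    Central moments are normalized by ``scale`` (the shape's equivalent
    radius; image-moment µ00 normalization carries no length scale for a
    point set), making the invariants translation-, rotation- and
    scale-invariant for point clouds.
    """
    n = float(len(u))
    rg = scale or 1.0

    def eta(p: int, q: int) -> float:
        return float(np.sum((u / rg) ** p * (v / rg) ** q)) / n

    e20, e02, e11 = eta(2, 0), eta(0, 2), eta(1, 1)
    e30, e03 = eta(3, 0), eta(0, 3)
    e21, e12 = eta(2, 1), eta(1, 2)
    h1 = e20 + e02
    h2 = (e20 - e02) ** 2 + 4 * e11**2
    h3 = (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2
    h4 = (e30 + e12) ** 2 + (e21 + e03) ** 2
    h5 = (e30 - 3 * e12) * (e30 + e12) * (
        (e30 + e12) ** 2 - 3 * (e21 + e03) ** 2
    ) + (3 * e21 - e03) * (e21 + e03) * (
        3 * (e30 + e12) ** 2 - (e21 + e03) ** 2
    )
    h6 = (e20 - e02) * ((e30 + e12) ** 2 - (e21 + e03) ** 2) + 4 * e11 * (
        e30 + e12
    ) * (e21 + e03)
    h7 = (3 * e21 - e03) * (e30 + e12) * (
        (e30 + e12) ** 2 - 3 * (e21 + e03) ** 2
    ) - (e30 - 3 * e12) * (e21 + e03) * (
        3 * (e30 + e12) ** 2 - (e21 + e03) ** 2
    )
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def _resample_ring(poly, n: int) -> np.ndarray:
    """Arc-length resampling of a polygon exterior (closed, n samples)."""
    ring = poly.exterior
    length = ring.length
    d = np.linspace(0.0, length, n, endpoint=False)
    return np.array([[ring.interpolate(t).x, ring.interpolate(t).y] for t in d])


def _curvature(closed: np.ndarray) -> tuple[np.ndarray, float]:
    """Signed curvature along a closed, ~uniformly sampled curve.

    Returns (kappa per sample, arc-length step h)."""
    seg = np.linalg.norm(np.roll(closed, -1, axis=0) - closed, axis=1)
    h = float(seg.mean())
    d1 = (np.roll(closed, -1, axis=0) - np.roll(closed, 1, axis=0)) / (2 * h)
    d2 = (np.roll(closed, -1, axis=0) - 2 * closed + np.roll(closed, 1, axis=0)) / h**2
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 0, num / den, 0.0)
    return kappa, h


def _box_count_dim(points: np.ndarray, scale_fracs=(0.5, 0.25, 0.125, 0.0625)) -> float:
    """Box-counting dimension with box sizes relative to the point extent."""
    lo = points.min(axis=0)
    span = float(max(np.ptp(points, axis=0).max(), 1e-12))
    logs, logn = [], []
    for f in scale_fracs:
        s = span * f
        cells = np.floor((points - lo) / s).astype(np.int64)
        n_occ = len(np.unique(cells, axis=0))
        logs.append(math.log(1.0 / f))
        logn.append(math.log(n_occ))
    slope = np.polyfit(logs, logn, 1)[0]
    return float(slope)


def _correlation_dim(points: np.ndarray, max_points: int = 600) -> float:
    pts = points
    if len(pts) > max_points:
        step = len(pts) // max_points + 1
        pts = pts[::step]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    iu = np.triu_indices(len(pts), k=1)
    dists = d[iu]
    span = float(max(dists.max(), 1e-12))
    radii = span * np.array([0.05, 0.1, 0.2, 0.4])
    logs, logc = [], []
    for r in radii:
        c = float(np.mean(dists < r))
        if 0 < c < 1:
            logs.append(math.log(r / span))
            logc.append(math.log(c))
    if len(logs) < 2:
        return 0.0
    return float(np.polyfit(logs, logc, 1)[0])


def _lacunarity(points: np.ndarray, n_boxes: int = 8) -> float:
    lo = points.min(axis=0)
    span = float(max(np.ptp(points, axis=0).max(), 1e-12))
    s = span / n_boxes
    cells = np.floor((points - lo) / s).astype(np.int64)
    cells = np.clip(cells, 0, n_boxes - 1)
    counts = np.zeros((n_boxes, n_boxes))
    np.add.at(counts, (cells[:, 0], cells[:, 1]), 1)
    masses = counts.ravel()
    mean = masses.mean()
    if mean == 0:
        return 1.0
    return float(masses.var() / mean**2 + 1.0)


def _skeleton_features(poly, area: float) -> dict[str, float]:
    """Medial-axis skeleton statistics from a rasterized polygon."""
    minx, miny, maxx, maxy = poly.bounds
    span = max(maxx - minx, maxy - miny, 1e-12)
    pad = 2.0 * span / _SKELETON_GRID
    x0, y0 = minx - pad, miny - pad
    px = (span + 2 * pad) / _SKELETON_GRID
    xs = x0 + (np.arange(_SKELETON_GRID) + 0.5) * px
    ys = y0 + (np.arange(_SKELETON_GRID) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    mask = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    zero = {
        "skeleton_length": 0.0,
        "branch_count": 0.0,
        "branch_point_count": 0.0,
        "endpoint_count": 0.0,
        "branch_length_mean": 0.0,
        "branch_length_max": 0.0,
        "tortuosity": 0.0,
        "skeleton_area_ratio": 0.0,
        "longest_path_length": 0.0,
        "cycle_count": 0.0,
    }
    if len(coords) == 0:
        return zero
    g = nx.Graph()
    index = {tuple(c): i for i, c in enumerate(coords)}
    g.add_nodes_from(index.values())
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=math.hypot(dr, dc) * px)
    total = sum(w for _, _, w in g.edges(data="weight"))
    deg = dict(g.degree())
    endpoints = [n for n, d in deg.items() if d == 1]
    branch_nodes = [n for n, d in deg.items() if d >= 3]
    # branches: components of the skeleton minus its branch points, with the
    # edges that attach them back to branch points counted once
    sub = g.copy()
    sub.remove_nodes_from(branch_nodes)
    branch_lengths = []
    for comp in nx.connected_components(sub):
        length = 0.0
        seen = set()
        for n in comp:
            for nb in g.neighbors(n):
                e = (min(n, nb), max(n, nb))
                if e not in seen and (nb in comp or nb in branch_nodes):
                    seen.add(e)
                    length += g.edges[n, nb]["weight"]
        branch_lengths.append(length)
    if not branch_lengths and g.number_of_nodes():
        branch_lengths = [total]
    # weighted diameter of the largest component via double sweep
    comp = max(nx.connected_components(g), key=len)
    start = next(iter(comp))
    dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    far1 = max(dist, key=dist.get)
    dist2 = nx.single_source_dijkstra_path_length(g, far1, weight="weight")
    far2 = max(dist2, key=dist2.get)
    longest = dist2[far2]
    euclid = float(np.linalg.norm((coords[far1] - coords[far2]) * px))
    tort = longest / euclid if euclid > 0 else 1.0
    n_comp = nx.number_connected_components(g)
    cycles = g.number_of_edges() - g.number_of_nodes() + n_comp
    return {
        "skeleton_length": float(total),
        "branch_count": float(len(branch_lengths)),
        "branch_point_count": float(len(branch_nodes)),
        "endpoint_count": float(len(endpoints)),
        "branch_length_mean": float(np.mean(branch_lengths)) if branch_lengths else 0.0,
        "branch_length_max": float(np.max(branch_lengths)) if branch_lengths else 0.0,
        "tortuosity": float(tort),
        "skeleton_area_ratio": float(total / area) if area > 0 else 0.0,
        "longest_path_length": float(longest),
        "cycle_count": float(cycles),
    }


# ---------------------------------------------------------------------------
# Descriptor computation


def compute_descriptors(
    cluster: Cluster | np.ndarray, alpha_radius: float = 0.05
) -> pd.Series:
    """All 67 descriptors of one aggregate's raw localization point cloud.

    Boundary, skeleton and most geometric descriptors derive from the
    alpha-shape polygon of the points; all values are finite for clusters
    with >= 10 localizations and non-degenerate geometry.
    """
    pts = cluster.points if isinstance(cluster, Cluster) else np.asarray(cluster, float)
    if len(pts) < 10:
        raise DescriptorError(
            f"descriptors need >= 10 localizations, got {len(pts)}", family="point"
        )
    d: dict[str, float] = {}

    shape = alpha_shape(pts, alpha_radius)
    if shape.area == 0:
        raise DescriptorError(
            "degenerate (collinear?) point cloud: alpha-shape has zero area",
            family="geometric",
        )
    poly = largest_polygon(shape)
    area = float(shape.area)
    perim = float(shape.length)

    # point / density
    n = len(pts)
    tree = cKDTree(pts)
    nn = tree.query(pts, k=2)[0][:, 1]
    cen = pts.mean(axis=0)
    cdist = np.linalg.norm(pts - cen, axis=1)
    d["n_locs"] = float(n)
    d["loc_density"] = n / area
    d["nn_dist_mean"] = float(nn.mean())
    d["nn_dist_std"] = float(nn.std())
    d["nn_dist_min"] = float(nn.min())
    d["nn_dist_max"] = float(nn.max())
    d["centroid_dist_mean"] = float(cdist.mean())
    d["centroid_dist_std"] = float(cdist.std())

    # geometric
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    lam2, lam1 = float(max(evals[0], 0.0)), float(max(evals[1], 1e-300))
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    vmax = evecs[:, 1]
    orientation = math.atan2(vmax[1], vmax[0])
    if orientation < -math.pi / 2:
        orientation += math.pi
    elif orientation >= math.pi / 2:
        orientation -= math.pi
    hull = convex_hull(pts)
    minx, miny, maxx, maxy = shape.bounds
    bw, bh = maxx - minx, maxy - miny
    d["area"] = area
    d["perimeter"] = perim
    d["circularity"] = 4 * math.pi * area / perim**2
    d["equivalent_diameter"] = math.sqrt(4 * area / math.pi)
    d["major_axis"] = major
    d["minor_axis"] = minor
    d["aspect_ratio"] = major / minor if minor > 0 else float(n)
    d["eccentricity"] = math.sqrt(max(1 - lam2 / lam1, 0.0))
    d["orientation"] = orientation
    d["hull_area"] = float(hull.area)
    d["hull_perimeter"] = float(hull.length)
    d["solidity"] = area / hull.area if hull.area > 0 else 1.0
    d["convexity"] = hull.length / perim if perim > 0 else 1.0
    d["extent"] = area / (bw * bh) if bw * bh > 0 else 1.0
    d["bbox_width"] = float(bw)
    d["bbox_height"] = float(bh)

    # moments
    u = pts[:, 0] - cen[0]
    v = pts[:, 1] - cen[1]
    hu = _hu_moments(u, v, math.sqrt(area / math.pi))
    for i in range(7):
        d[f"hu_{i + 1}"] = float(hu[i])
    d["radius_gyration"] = float(np.sqrt(np.mean(u**2 + v**2)))
    d["mu20"] = float(np.mean(u**2))
    d["mu02"] = float(np.mean(v**2))
    d["mu11"] = float(np.mean(u * v))
    d["cov_anisotropy"] = (lam1 - lam2) / (lam1 + lam2) if (lam1 + lam2) > 0 else 0.0

    # boundary (arc-length resampled exterior of the largest polygon)
    ring = _resample_ring(poly, _BOUNDARY_SAMPLES)
    pc = np.array([poly.centroid.x, poly.centroid.y])
    rad = np.linalg.norm(ring - pc, axis=1)
    kappa, h = _curvature(ring)
    # deadband: ignore near-zero curvature when counting sign changes, so
    # the count reflects real concave/convex alternation, not jitter
    band = 0.05 * float(np.max(np.abs(kappa))) if len(kappa) else 0.0
    signs = np.where(np.abs(kappa) > band, np.sign(kappa), 0.0)
    nz = signs[signs != 0]
    crossings = int(np.sum(nz != np.roll(nz, 1))) if len(nz) else 0
    d["radial_mean"] = float(rad.mean())
    d["radial_std"] = float(rad.std())
    d["radial_min"] = float(rad.min())
    d["radial_max"] = float(rad.max())
    d["radial_cv"] = float(rad.std() / rad.mean()) if rad.mean() > 0 else 0.0
    d["curvature_mean"] = float(kappa.mean())
    d["curvature_std"] = float(kappa.std())
    d["curvature_max"] = float(kappa.max())
    d["curvature_min"] = float(kappa.min())
    d["bending_energy"] = float(np.sum(kappa**2) * h)
    d["curvature_zero_crossings"] = float(crossings)
    d["boundary_vertex_count"] = float(len(poly.exterior.coords) - 1)

    # skeleton
    d.update(_skeleton_features(poly, area))

    # fractal / heterogeneity
    d["boundary_boxdim"] = _box_count_dim(ring)
    d["cloud_boxdim"] = _box_count_dim(pts)
    d["correlation_dim"] = _correlation_dim(pts)
    d["lacunarity"] = _lacunarity(pts)

    # composite
    d["elongation"] = 1.0 - minor / major if major > 0 else 0.0
    d["compactness"] = d["equivalent_diameter"] / major if major > 0 else 1.0
    req = d["equivalent_diameter"] / 2.0
    d["radius_gyration_norm"] = d["radius_gyration"] / req if req > 0 else 0.0
    try:
        tess = compute_voronoi(pts)
        cell = tess.areas[tess.bounded]
    except Exception:  # degenerate member geometry
        cell = np.empty(0)
    if len(cell):
        d["voronoi_cell_area_mean"] = float(cell.mean())
        d["voronoi_cell_area_cv"] = (
            float(cell.std() / cell.mean()) if cell.mean() > 0 else 0.0
        )
    else:
        d["voronoi_cell_area_mean"] = area / n
        d["voronoi_cell_area_cv"] = 0.0

    return pd.Series([d[name] for name in DESCRIPTOR_NAMES], index=DESCRIPTOR_NAMES)


def compute_descriptor_table(
    clusters: Sequence[Cluster], alpha_radius: float = 0.05
) -> pd.DataFrame:
    """Descriptor matrix (one row per cluster, 67 columns)."""
    rows = {c.id: compute_descriptors(c, alpha_radius) for c in clusters}
    return pd.DataFrame.from_dict(rows, orient="index")[DESCRIPTOR_NAMES]


# ---------------------------------------------------------------------------
# PCA embedding and group overlap


@dataclass
class GroupEmbedding:
    """Unit-variance-scaled PCA embedding of descriptor vectors."""

    feature_names: list[str]
    dropped_features: list[str]
    means: np.ndarray
    stds: np.ndarray
    loadings: np.ndarray  # (k, p) rows are principal axes
    scores: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray
    labels: np.ndarray  # (n,) group label per observation


def run_pca(
    vectors: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
) -> GroupEmbedding:
    """Center, scale to unit variance, and diagonalize the descriptor matrix.

    Zero-variance features are dropped (logged).  Component signs are fixed
    by making each loading's largest-magnitude entry positive, so the
    embedding is deterministic.
    """
    if isinstance(vectors, pd.DataFrame):
        names = list(vectors.columns)
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.asarray(vectors, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 observations")
    stds0 = X.std(axis=0)
    keep = stds0 > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.info("run_pca: dropping %d zero-variance features: %s", len(dropped), dropped)
    Xk = X[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    scaler = StandardScaler()
    Z = scaler.fit_transform(Xk)
    pca = PCA(n_components=min(len(X) - 1, Z.shape[1]) or 1)
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry of each axis is positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    lab = np.asarray(labels if labels is not None else [""] * len(X), dtype=object)
    return GroupEmbedding(
        feature_names=kept_names,
        dropped_features=dropped,
        means=scaler.mean_,
        stds=scaler.scale_,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        labels=lab,
    )


@dataclass
class OverlapResult:
    """Jaccard overlap of two group footprints in an embedding plane."""

    pair: tuple[str, str]
    footprints: tuple
    jaccard: float


def _footprint(
    pts: np.ndarray, boundary_method: str, trim_fraction: float
):
    """Footprint polygon of projected scores.

    Trims the most extreme ``trim_fraction`` of points (distance from the
    group median) to stabilize the outline, then takes an alpha-shape with a
    data-adaptive radius (hull fallback).
    """
    k = int(np.floor(trim_fraction * len(pts)))
    if k > 0:
        dist = np.linalg.norm(pts - np.median(pts, axis=0), axis=1)
        pts = pts[np.argsort(dist)[: len(pts) - k]]
    if boundary_method == "hull":
        return convex_hull(pts)
    if boundary_method == "alpha":
        tree = cKDTree(pts)
        nn = tree.query(pts, k=2)[0][:, 1]
        alpha = 5.0 * float(np.median(nn))
        return alpha_shape(pts, alpha)
    raise ValueError(f"unknown boundary_method {boundary_method!r}")


def jaccard_of_polygons(a, b, mode: str = "union") -> float:
    """Intersection-over-union of two polygons.

    ``mode="sum"`` gives the literal intersection / (area_a + area_b)
    variant instead of the standard union denominator.
    """
    inter = a.intersection(b).area
    if mode == "union":
        den = a.union(b).area
    elif mode == "sum":
        den = a.area + b.area
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(inter / den) if den > 0 else 0.0


def group_overlap_jaccard(
    embedding: GroupEmbedding,
    pair: tuple[str, str],
    plane: tuple[int, int] = (0, 1),
    boundary_method: str = "alpha",
    trim_fraction: float = 0.01,
    mode: str = "union",
) -> OverlapResult:
    """Jaccard index of two groups' footprints in a PC plane.

    Both groups need >= 3 points; the default plane is PC1–PC2.
    """
    i, j = plane
    polys = []
    for g in pair:
        sel = embedding.labels == g
        if sel.sum() < 3:
            raise ValueError(f"group {g!r} has < 3 points in the embedding")
        pts = embedding.scores[np.ix_(sel, [i, j])]
        polys.append(_footprint(pts, boundary_method, trim_fraction))
    return OverlapResult(
        pair=tuple(pair),
        footprints=tuple(polys),
        jaccard=jaccard_of_polygons(polys[0], polys[1], mode),
    )


def descriptor_summaries(
    vectors: pd.DataFrame,
    group_labels: Sequence,
    features: Sequence[str],
    replicate_labels: Sequence | None = None,
    log10: bool = True,
) -> pd.DataFrame:
    """Per-group distribution summaries for selected descriptors.

    Values are log10-transformed when requested (standard presentation for
    circularity, major axis, and area).  When replicate labels are given the
    summary also carries per-replicate means (one row per group × replicate
    × feature, ``level="replicate"``) alongside the pooled group rows.
    """
    for f in features:
        if f not in vectors.columns:
            raise KeyError(f"unknown descriptor {f!r}")
    df = vectors.loc[:, list(features)].copy()
    if log10:
        df = np.log10(df)
    df["group"] = np.asarray(group_labels, dtype=object)
    rows = []
    for (g,), sub in df.groupby(["group"]):
        for f in features:
            vals = sub[f]
            rows.append(
                {
                    "level": "group",
                    "group": g,
                    "replicate": None,
                    "feature": f,
                    "mean": vals.mean(),
                    "median": vals.median(),
                    "q25": vals.quantile(0.25),
                    "q75": vals.quantile(0.75),
                    "n": len(vals),
                }
            )
    if replicate_labels is not None:
        df["replicate"] = np.asarray(replicate_labels, dtype=object)
        for (g, r), sub in df.groupby(["group", "replicate"]):
            for f in features:
                rows.append(
                    {
                        "level": "replicate",
                        "group": g,
                        "replicate": r,
                        "feature": f,
                        "mean": sub[f].mean(),
                        "median": sub[f].median(),
                        "q25": sub[f].quantile(0.25),
                        "q75": sub[f].quantile(0.75),
                        "n": len(sub),
                    }
                )
    return pd.DataFrame(rows)
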