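"""Two-color aggregate analysis: merged segmentation, overlap QC, enrichment.

The two channels of a dual-color acquisition are pooled into one reference
point cloud and segmented exactly like a single-color image, so both marks
share one consistent set of aggregates.  Quality control then checks, per
aggregate, how well the two channels' alpha-shapes overlap: channel-pure
structures that merely sit close together merge spuriously in the reference
and show low overlap, and are re-segmented per channel.  Finally each
aggregate's composition is scored by the enrichment score

    score = (n_A − n_B) / (n_A + n_B)  ∈ [−1, 1]

(±1 = the aggregate carries a single mark, 0 = equal mix), and thresholded
at ±0.8 into singly-/dually-modified categories.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError
from .filters import BackgroundThreshold, classify_size
from .geometry import alpha_shape, polygon_area
from .loc_io import FieldOfView
from .segmentation import (
    Cluster,
    SegmentationParams,
    compute_voronoi,
    filter_min_locs,
    segment_fov,
    threshold_and_cluster,
)

logger = logging.getLogger(__name__)

DEFAULT_ENRICHMENT_CUTOFF = 0.8
DEFAULT_OVERLAP_CUTOFF = 30.0  # percent
MICRO_AREA_CUTOFF = 0.15  # µm²


class ModificationCategory(enum.Enum):
    SINGLY_A = "SINGLY_A"
    SINGLY_B = "SINGLY_B"
    DUALLY = "DUALLY"


@dataclass
class OverlapScore:
    """Directional alpha-shape overlaps of the two channels in one aggregate.

    ``a_in_b`` is the percentage of channel A's alpha-shape area covered by
    channel B's alpha-shape (and vice versa); the reported ``score`` is the
    minimum of the two, used for the re-segmentation gate.  Aggregates with
    fewer than 3 localizations in either channel get score 0 and are
    flagged as undefined.
    """

    aggregate_id: int
    a_in_b: float
    b_in_a: float
    defined: bool = True

    @property
    def score(self) -> float:
        return min(self.a_in_b, self.b_in_a)


@dataclass
class EnrichmentRecord:
    """Per-aggregate two-channel composition."""

    aggregate_id: int
    n_a: int
    n_b: int
    score: float
    category: ModificationCategory
    size_class: object | None = None
    cutoff: float = DEFAULT_ENRICHMENT_CUTOFF


def merge_fovs(fov_a: FieldOfView, fov_b: FieldOfView) -> FieldOfView:
    """Pool two single-channel FOVs into one two-channel reference FOV."""
    if fov_a.extent != fov_b.extent:
        raise ValueError(
            f"extent mismatch: {fov_a.extent} vs {fov_b.extent}"
        )
    la = fov_a.locs.copy()
    lb = fov_b.locs.copy()
    la["channel"] = "A"
    lb["channel"] = "B"
    merged = pd.concat([la, lb], ignore_index=True)
    meta = {**fov_b.metadata, **fov_a.metadata}
    return FieldOfView(merged, fov_a.extent, meta)


def merge_and_segment(
    fov_a: FieldOfView,
    fov_b: FieldOfView | None,
    params: SegmentationParams | None = None,
) -> list[Cluster]:
    """Segment the merged two-channel reference exactly like single-color.

    ``fov_b=None`` (or empty) degenerates to single-color segmentation of
    channel A.  Per-channel member counts are retained on every cluster.
    """
    params = params or SegmentationParams()
    if fov_b is None or fov_b.n_locs == 0:
        la = fov_a.locs.copy()
        la["channel"] = "A"
        fov = FieldOfView(la, fov_a.extent, dict(fov_a.metadata))
        return segment_fov(fov, params)
    merged = merge_fovs(fov_a, fov_b)
    return segment_fov(merged, params)


def _channel_points(cluster: Cluster, channel: str) -> np.ndarray:
    return cluster.points[np.asarray(cluster.channels, dtype=object) == channel]


def overlap_score(cluster: Cluster, alpha_radius: float = 0.05) -> OverlapScore:
    """Directional alpha-shape overlap percentages of channels A and B."""
    pa = _channel_points(cluster, "A")
    pb = _channel_points(cluster, "B")
    if len(pa) < 3 or len(pb) < 3:
        return OverlapScore(cluster.id, 0.0, 0.0, defined=False)
    sa = alpha_shape(pa, alpha_radius)
    sb = alpha_shape(pb, alpha_radius)
    area_a, area_b = polygon_area(sa), polygon_area(sb)
    if area_a == 0 or area_b == 0:
        return OverlapScore(cluster.id, 0.0, 0.0, defined=False)
    inter = sa.intersection(sb).area
    return OverlapScore(
        cluster.id,
        a_in_b=100.0 * inter / area_a,
        b_in_a=100.0 * inter / area_b,
    )


def _resegment_channel(
    points: np.ndarray, params: SegmentationParams
) -> list[np.ndarray]:
    """Split one channel's members spatially; never drops a localization.

    Runs the standard density segmentation on the channel's own points and
    attaches every unassigned point to the nearest resulting sub-cluster
    (all points stay in one piece when segmentation finds no sub-cluster).
    """
    if len(points) < max(4, params.min_locs):
        return [np.arange(len(points))]
    try:
        tess = compute_voronoi(points)
    except Exception:
        return [np.arange(len(points))]
    subs = filter_min_locs(
        threshold_and_cluster(tess, params), params.min_locs
    )
    if not subs:
        return [np.arange(len(points))]
    groups = [list(s.indices) for s in subs]
    assigned = np.concatenate([s.indices for s in subs])
    leftovers = np.setdiff1d(np.arange(len(points)), assigned)
    if len(leftovers):
        centroids = np.array([points[g].mean(axis=0) for g in groups])
        for i in leftovers:
            j = int(
                np.argmin(np.linalg.norm(centroids - points[i], axis=1))
            )
            groups[j].append(int(i))
    return [np.asarray(sorted(g), dtype=np.int64) for g in groups]


def resegment_low_overlap(
    clusters: Sequence[Cluster],
    params: SegmentationParams | None = None,
    threshold: BackgroundThreshold | float | None = None,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    micro_area_cutoff: float = MICRO_AREA_CUTOFF,
    alpha_radius: float | None = None,
) -> list[Cluster]:
    """Split spuriously merged reference aggregates.

    Micro-sized aggregates (area > ``micro_area_cutoff``) pass through
    untouched (the area gate is applied first).  A smaller aggregate is
    split only when *both* directional overlaps fall below
    ``overlap_cutoff`` percent — the signature of two channel-pure
    structures merged in the reference — so a singly-modified aggregate
    whose minor channel occupies a small footprint inside the major one is
    left intact.  Splitting re-runs single-channel segmentation per channel;
    fragments below ``params.min_locs`` are re-attached to the nearest
    substantive piece, and pieces are re-classified by area when a
    background ``threshold`` is supplied.  The output clusters partition
    exactly the input localizations.
    """
    params = params or SegmentationParams()
    alpha = alpha_radius if alpha_radius is not None else params.alpha_radius
    out: list[Cluster] = []
    next_id = max((c.id for c in clusters), default=-1) + 1
    n_split = 0
    for c in clusters:
        ov = overlap_score(c, alpha)
        c.overlap_score = ov.score
        if c.area > micro_area_cutoff or max(ov.a_in_b, ov.b_in_a) >= overlap_cutoff:
            out.append(c)
            continue
        ch_arr = np.asarray(c.channels, dtype=object)
        pieces: list[tuple[str, np.ndarray]] = []  # (channel, member indices)
        for channel in ("A", "B"):
            sel = np.flatnonzero(ch_arr == channel)
            if len(sel) == 0:
                continue
            for local_idx in _resegment_channel(c.points[sel], params):
                pieces.append((channel, sel[local_idx]))
        large = [p for p in pieces if len(p[1]) >= params.min_locs]
        if len(large) < 2:
            # nothing to separate: one-channel cluster or only fragments
            out.append(c)
            continue
        small = [p for p in pieces if len(p[1]) < params.min_locs]
        groups = [list(m) for _, m in large]
        centroids = [c.points[m].mean(axis=0) for _, m in large]
        for _, m in small:
            cen = c.points[m].mean(axis=0)
            j = int(np.argmin([np.linalg.norm(g - cen) for g in centroids]))
            groups[j].extend(m)
        n_split += 1
        for g in groups:
            member = np.asarray(sorted(g), dtype=np.int64)
            pts = c.points[member]
            shape = alpha_shape(pts, alpha)
            counts: dict = {}
            for ch in ch_arr[member]:
                counts[ch] = counts.get(ch, 0) + 1
            piece = Cluster(
                id=next_id,
                indices=c.indices[member],
                points=pts,
                channels=ch_arr[member],
                boundary=shape,
                area=polygon_area(shape),
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                channel_counts=counts,
            )
            piece.overlap_score = overlap_score(piece, alpha).score
            if threshold is not None:
                try:
                    piece.size_class = classify_size(piece, threshold)
                except ValueError:
                    piece.size_class = None  # now sub-background sized
            out.append(piece)
            next_id += 1
    logger.info(
        "resegment_low_overlap: %d clusters in, %d split, %d out",
        len(clusters),
        n_split,
        len(out),
    )
    return out


def enrichment_score(n_a: int, n_b: int) -> float:
    """(n_A − n_B) / (n_A + n_B); undefined when both counts are zero."""
    if n_a < 0 or n_b < 0:
        raise ValueError("channel counts must be non-negative")
    total = n_a + n_b
    if total == 0:
        raise UndefinedScoreError("enrichment score undefined for 0 localizations")
    return (n_a - n_b) / total


def classify_modification(
    score: float, cutoff: float = DEFAULT_ENRICHMENT_CUTOFF
) -> ModificationCategory:
    """Singly/dually category from the enrichment score.

    |score| > cutoff → singly modified (sign picks the channel); scores in
    [−cutoff, cutoff] — boundary inclusive — are dually modified.
    """
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"enrichment score {score} outside [-1, 1]")
    if score > cutoff:
        return ModificationCategory.SINGLY_A
    if score < -cutoff:
        return ModificationCategory.SINGLY_B
    return ModificationCategory.DUALLY


def score_clusters(
    clusters: Sequence[Cluster], cutoff: float = DEFAULT_ENRICHMENT_CUTOFF
) -> list[EnrichmentRecord]:
    """Enrichment records (score + category) for segmented two-channel clusters.

    Clusters with zero localizations in both channels are skipped (logged);
    the score and category are also written back onto each cluster.
    """
    records: list[EnrichmentRecord] = []
    for c in clusters:
        n_a = int(c.channel_counts.get("A", 0))
        n_b = int(c.channel_counts.get("B", 0))
        if n_a + n_b == 0:
            logger.warning("cluster %d has no channel-assigned localizations", c.id)
            continue
        s = enrichment_score(n_a, n_b)
        cat = classify_modification(s, cutoff)
        c.enrichment = s
        c.category = cat
        records.append(
            EnrichmentRecord(
                aggregate_id=c.id,
                n_a=n_a,
                n_b=n_b,
                score=s,
                category=cat,
                size_class=c.size_class,
                cutoff=cutoff,
            )
        )
    return records


def analyze_dual_color(
    fov_a: FieldOfView,
    fov_b: FieldOfView,
    params: SegmentationParams | None = None,
    threshold: BackgroundThreshold | None = None,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    enrichment_cutoff: float = DEFAULT_ENRICHMENT_CUTOFF,
) -> tuple[list[Cluster], list[EnrichmentRecord]]:
    """Full two-color pipeline on a pair of single-channel FOVs.

    Merged segmentation → artifact/background filtering + classification
    (when a threshold is given) → overlap QC with re-segmentation →
    enrichment scoring.
    """
    from .filters import filter_and_classify

    params = params or SegmentationParams()
    clusters = merge_and_segment(fov_a, fov_b, params)
    if threshold is not None:
        clusters = filter_and_classify(clusters, threshold)
    for c in clusters:
        c.overlap_score = overlap_score(c, params.alpha_radius).score
    clusters = resegment_low_overlap(
        clusters, params, threshold, overlap_cutoff
    )
    records = score_clusters(clusters, enrichment_cutoff)
    return clusters, records
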