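"""Artifact removal, background filtering, and size classification.

Three post-segmentation steps, applied in order:

1. **Artifact removal** — segmented objects obey a positive power-law trend
   between alpha-shape area and localization count; objects far off that
   trend (tiny area / huge count or vice versa) are imaging artifacts.  The
   trend is fit robustly in log10–log10 space (Theil–Sen slope) and objects
   with absolute residual above ``cutoff_k`` robust standard deviations
   (scaled MAD) are removed.

2. **Background removal** — an area threshold calibrated on negative-control
   (secondary-antibody-only) images removes residual background puncta.
   Fixed per-dye defaults: 0.004 µm² for Cy3b-type imagers, 0.006 µm² for
   ATTO655-type; alternatively the threshold is the area quantile of
   negative-control objects at a target removal fraction (default 0.97,
   i.e. >97 % of negative-control objects removed).

3. **Size classification** — surviving aggregates fall into three
   contiguous area windows: NANO [background_threshold, 0.017), INTERMEDIATE
   [0.017, 0.15), MICRO [0.15, ∞) µm².  Windows are half-open so every area
   gets exactly one class.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import theilslopes

from .errors import CalibrationError
from .segmentation import Cluster

logger = logging.getLogger(__name__)

#: Fixed background area thresholds (µm²) per imager dye family.
DYE_BACKGROUND_THRESHOLDS: dict[str, float] = {
    "cy3b": 0.004,
    "atto655": 0.006,
}

#: Class window upper bounds (µm²): NANO < 0.017 <= INTERMEDIATE < 0.15 <= MICRO.
NANO_UPPER = 0.017
INTERMEDIATE_UPPER = 0.15


class SizeClass(enum.Enum):
    NANO = "NANO"
    INTERMEDIATE = "INTERMEDIATE"
    MICRO = "MICRO"


@dataclass
class ArtifactModel:
    """Fitted robust area–count trend (log10 space)."""

    slope: float
    intercept: float
    residual_scale: float  # scaled MAD of residuals
    cutoff_k: float = 3.0

    def residuals(self, areas: np.ndarray, n_locs: np.ndarray) -> np.ndarray:
        la = np.log10(areas)
        ln = np.log10(n_locs)
        return ln - (self.intercept + self.slope * la)

    def is_artifact(self, areas: np.ndarray, n_locs: np.ndarray) -> np.ndarray:
        return np.abs(self.residuals(areas, n_locs)) > (
            self.cutoff_k * self.residual_scale
        )


@dataclass
class BackgroundThreshold:
    """Area threshold (µm²) separating aggregates from background puncta."""

    dye_label: str
    area_threshold: float
    mode: str = "fixed"  # fixed | percentile

    def __post_init__(self) -> None:
        if self.area_threshold <= 0:
            raise ValueError("area_threshold must be positive")


#: Floor on the robust residual scale (log10 units).  With few objects the
#: MAD underestimates the true scatter and a 3-MAD cut starts clipping the
#: tails of ordinary count variation; 0.1 dex keeps the minimum cut at a
#: factor of 2 in localization count, while true imaging artifacts deviate
#: by orders of magnitude.
MIN_RESIDUAL_SCALE_DEX = 0.1


def fit_artifact_model(
    clusters: Sequence[Cluster],
    cutoff_k: float = 3.0,
    min_scale: float = MIN_RESIDUAL_SCALE_DEX,
) -> ArtifactModel:
    """Robust log–log fit of localization count vs alpha-shape area."""
    areas = np.array([c.area for c in clusters], dtype=float)
    counts = np.array([c.n_locs for c in clusters], dtype=float)
    ok = areas > 0
    la, ln = np.log10(areas[ok]), np.log10(counts[ok])
    slope, intercept, _, _ = theilslopes(ln, la)
    resid = ln - (intercept + slope * la)
    scale = max(
        1.4826 * float(np.median(np.abs(resid - np.median(resid)))), min_scale
    )
    return ArtifactModel(float(slope), float(intercept), float(scale), cutoff_k)


def remove_artifacts(
    clusters: Sequence[Cluster],
    cutoff_k: float = 3.0,
    min_fit: int = 10,
) -> tuple[list[Cluster], list[Cluster]]:
    """Partition clusters into (kept, removed-artifacts).

    With fewer than ``min_fit`` clusters the trend cannot be fit robustly;
    the filter is skipped (all kept) with a warning.
    """
    clusters = list(clusters)
    if len(clusters) < min_fit:
        logger.warning(
            "artifact filter skipped: %d clusters < %d needed for the fit",
            len(clusters),
            min_fit,
        )
        return clusters, []
    model = fit_artifact_model(clusters, cutoff_k)
    areas = np.array([c.area for c in clusters], dtype=float)
    counts = np.array([c.n_locs for c in clusters], dtype=float)
    bad = model.is_artifact(np.clip(areas, 1e-12, None), counts)
    kept = [c for c, b in zip(clusters, bad) if not b]
    removed = [c for c, b in zip(clusters, bad) if b]
    logger.info("artifact filter: kept %d, removed %d", len(kept), len(removed))
    return kept, removed


def calibrate_background_threshold(
    negative_control_clusters: Sequence[Cluster] | None = None,
    dye_label: str = "cy3b",
    mode: str = "fixed",
    target_removal: float = 0.97,
) -> BackgroundThreshold:
    """Background area threshold for a dye.

    ``fixed`` mode returns the per-dye default; ``percentile`` mode returns
    the ``target_removal`` area quantile of negative-control cluster areas
    (quantile taken from above, so applying the threshold removes at least
    that fraction of negative-control objects).
    """
    if mode == "fixed":
        key = dye_label.lower()
        if key not in DYE_BACKGROUND_THRESHOLDS:
            raise KeyError(
                f"no fixed background threshold for dye {dye_label!r}; "
                f"known: {sorted(DYE_BACKGROUND_THRESHOLDS)}"
            )
        return BackgroundThreshold(dye_label, DYE_BACKGROUND_THRESHOLDS[key], "fixed")
    if mode == "percentile":
        if not negative_control_clusters:
            raise CalibrationError(
                "percentile calibration needs non-empty negative-control clusters"
            )
        areas = np.array([c.area for c in negative_control_clusters], dtype=float)
        thr = float(np.quantile(areas, target_removal, method="higher"))
        return BackgroundThreshold(dye_label, max(thr, np.finfo(float).tiny), "percentile")
    raise ValueError(f"unknown calibration mode {mode!r}")


def apply_background_filter(
    clusters: Sequence[Cluster], threshold: BackgroundThreshold
) -> tuple[list[Cluster], list[Cluster]]:
    """Keep clusters with area >= threshold (inclusive boundary)."""
    kept = [c for c in clusters if c.area >= threshold.area_threshold]
    removed = [c for c in clusters if c.area < threshold.area_threshold]
    logger.info(
        "background filter (>= %.4g µm²): kept %d, removed %d",
        threshold.area_threshold,
        len(kept),
        len(removed),
    )
    return kept, removed


def classify_size(
    cluster: Cluster | float, threshold: BackgroundThreshold | float
) -> SizeClass:
    """Area-window class of one aggregate.

    The lower NANO bound is the dye-specific background threshold; an area
    below it violates the contract that background was already filtered.
    """
    area = cluster.area if isinstance(cluster, Cluster) else float(cluster)
    lo = (
        threshold.area_threshold
        if isinstance(threshold, BackgroundThreshold)
        else float(threshold)
    )
    if area < lo:
        raise ValueError(
            f"area {area:.4g} µm² below background threshold {lo:.4g}; "
            "background filtering must run first"
        )
    if area < NANO_UPPER:
        return SizeClass.NANO
    if area < INTERMEDIATE_UPPER:
        return SizeClass.INTERMEDIATE
    return SizeClass.MICRO


def classify_clusters(
    clusters: Sequence[Cluster], threshold: BackgroundThreshold | float
) -> list[Cluster]:
    """Assign ``size_class`` to every cluster in place; returns the list."""
    out = list(clusters)
    for c in out:
        c.size_class = classify_size(c, threshold)
    return out


def filter_and_classify(
    clusters: Sequence[Cluster],
    threshold: BackgroundThreshold,
    cutoff_k: float = 3.0,
) -> list[Cluster]:
    """Standard post-segmentation chain: artifacts → background → classes."""
    kept, _ = remove_artifacts(clusters, cutoff_k=cutoff_k)
    kept, _ = apply_background_filter(kept, threshold)
    return classify_clusters(kept, threshold)
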