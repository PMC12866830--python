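"""Cohort-level summaries and statistics.

Tabulates segmented aggregates over the acquisition hierarchy
(group → replicate/tissue section → field of view), computes densities per
unit area and class/modification percentages, and runs the rank-sum
comparisons used for group inference.  Inference always operates on
per-replicate means, never on per-FOV values, so fields of view within a
section are not treated as independent samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dualcolor import EnrichmentRecord
from .filters import SizeClass
from .loc_io import FieldOfView
from .segmentation import Cluster

logger = logging.getLogger(__name__)

_CLASS_ORDER = [c.name for c in SizeClass]


def density_per_unit_area(
    aggregates: Sequence, fov: FieldOfView | tuple[float, float]
) -> float:
    """Aggregate count divided by field area (µm⁻²)."""
    if isinstance(fov, FieldOfView):
        area = fov.area
    else:
        area = float(fov[0]) * float(fov[1])
    if area <= 0:
        raise ValueError("field-of-view area must be positive")
    return len(aggregates) / area


def cohort_table(
    per_fov: Sequence[tuple[FieldOfView, Sequence[Cluster]]]
) -> pd.DataFrame:
    """Tidy per-FOV table: one row per (group, replicate, fov, size class).

    Rows carry the aggregate count and the density (count / FOV area); every
    size class appears for every FOV (zero-filled) so downstream means are
    not biased toward FOVs that happened to contain a class.
    """
    rows = []
    for fov, clusters in per_fov:
        meta = fov.metadata
        counts = {c: 0 for c in _CLASS_ORDER}
        for cl in clusters:
            name = getattr(cl.size_class, "name", cl.size_class)
            if name in counts:
                counts[name] += 1
        for cls, n in counts.items():
            rows.append(
                {
                    "group": meta.get("group"),
                    "replicate": meta.get("replicate"),
                    "fov": meta.get("fov"),
                    "mark": meta.get("mark"),
                    "size_class": cls,
                    "count": n,
                    "density": n / fov.area,
                }
            )
    return pd.DataFrame(rows)


def replicate_means(
    table: pd.DataFrame, value: str = "density"
) -> pd.DataFrame:
    """Mean of ``value`` over the FOVs of each (group, replicate, class)."""
    return (
        table.groupby(["group", "replicate", "size_class"], dropna=False)[value]
        .mean()
        .reset_index()
    )


def class_percentages(
    table: pd.DataFrame, level: str = "replicate"
) -> pd.DataFrame:
    """Per-group percentage of nano / intermediate / micro aggregates.

    Counts are first averaged per case (``level="replicate"``) or pooled per
    group, then converted to percentages over the three classes; each output
    row sums to 100.  Groups with zero aggregates in every class are omitted
    with a log entry.
    """
    if level == "replicate":
        base = (
            table.groupby(["group", "replicate", "size_class"])["count"]
            .mean()
            .groupby(["group", "size_class"])
            .mean()
        )
    elif level == "group":
        base = table.groupby(["group", "size_class"])["count"].mean()
    else:
        raise ValueError(f"unknown level {level!r}")
    rows = []
    for g, sub in base.groupby(level=0):
        counts = sub.droplevel(0).reindex(_CLASS_ORDER).fillna(0.0)
        total = counts.sum()
        if total == 0:
            logger.warning("class_percentages: group %r has no aggregates", g)
            continue
        row = {"group": g}
        row.update({c: 100.0 * counts[c] / total for c in _CLASS_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(
    records: Sequence[EnrichmentRecord], group_labels: Sequence | None = None
) -> pd.DataFrame:
    """Enrichment records as a tidy DataFrame."""
    df = pd.DataFrame(
        {
            "aggregate_id": [r.aggregate_id for r in records],
            "n_a": [r.n_a for r in records],
            "n_b": [r.n_b for r in records],
            "score": [r.score for r in records],
            "category": [r.category.name for r in records],
            "size_class": [
                getattr(r.size_class, "name", r.size_class) for r in records
            ],
        }
    )
    if group_labels is not None:
        df["group"] = np.asarray(group_labels, dtype=object)
    return df


def modification_percentages(
    records: Sequence[EnrichmentRecord] | pd.DataFrame,
    by: Sequence[str] = ("size_class",),
) -> pd.DataFrame:
    """Singly-A / singly-B / dually percentages per grouping.

    Rows sum to 100; empty strata are omitted with a log entry.
    """
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    cats = ["SINGLY_A", "SINGLY_B", "DUALLY"]
    rows = []
    for keys, sub in df.groupby(list(by), dropna=False):
        if len(sub) == 0:
            logger.info("modification_percentages: empty stratum %r omitted", keys)
            continue
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        frac = sub["category"].value_counts(normalize=True)
        for c in cats:
            row[c] = 100.0 * float(frac.get(c, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RankSumResult:
    statistic: float  # Mann–Whitney U of the first group
    p_value: float
    method: str  # exact | asymptotic
    alternative: str


def ranksum_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Unpaired rank-sum test on per-replicate means.

    Exact small-sample p-values (full enumeration of rank assignments) when
    both groups have at most 8 tie-free values; the normal approximation
    with tie correction otherwise.  One-sided alternatives follow scipy
    semantics (``"less"``: first group tends smaller).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicate means")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (not ties) and max(len(a), len(b)) <= 8
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        alternative=alternative,
    )


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    defined: bool = True


def channel_correlation(clusters: Sequence[Cluster]) -> CorrelationResult:
    """Correlation of per-channel localization counts across aggregates.

    A positive correlation is the expected signature of both marks scaling
    with aggregate size; steric hindrance between the two antibody stacks
    would instead produce a negative correlation.  Zero variance in either
    count yields an undefined (flagged) result.
    """
    if len(clusters) < 3:
        raise ValueError("channel_correlation needs >= 3 clusters")
    n_a = np.array([c.channel_counts.get("A", 0) for c in clusters], dtype=float)
    n_b = np.array([c.channel_counts.get("B", 0) for c in clusters], dtype=float)
    if n_a.std() == 0 or n_b.std() == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(clusters), False)
    pr = stats.pearsonr(n_a, n_b)
    sr = stats.spearmanr(n_a, n_b)
    return CorrelationResult(
        float(pr.statistic),
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
        len(clusters),
    )


def single_vs_dual_counts(
    single_run: Sequence[Cluster],
    dual_run: Sequence[Cluster],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-class comparison of localization counts between run modes.

    For every size class present in both runs, the per-aggregate
    localization counts are compared by rank-sum; a drop in the dual-color
    counts would indicate steric hindrance between the two labels.  Classes
    absent from either run are omitted.
    """
    rows = []
    for cls in _CLASS_ORDER + [None]:
        xs = [
            c.n_locs
            for c in single_run
            if getattr(c.size_class, "name", c.size_class) == cls
        ]
        ys = [
            c.n_locs
            for c in dual_run
            if getattr(c.size_class, "name", c.size_class) == cls
        ]
        if len(xs) < 2 or len(ys) < 2:
            continue
        res = ranksum_compare(xs, ys, alternative)
        rows.append(
            {
                "size_class": cls,
                "n_single": len(xs),
                "n_dual": len(ys),
                "median_single": float(np.median(xs)),
                "median_dual": float(np.median(ys)),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def pairwise_ranksum(
    means: pd.DataFrame,
    value: str = "density",
    group_col: str = "group",
) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests between groups of a means table."""
    rows = []
    groups = list(pd.unique(means[group_col]))
    for g1, g2 in itertools.combinations(groups, 2):
        x = means.loc[means[group_col] == g1, value].to_numpy()
        y = means.loc[means[group_col] == g2, value].to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        res = ranksum_compare(x, y)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
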