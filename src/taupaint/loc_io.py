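"""Localization-table I/O and channel demultiplexing.

A DNA-PAINT acquisition yields one CSV of fitted emitter positions (one row
per localization).  The canonical in-memory container is a
:class:`FieldOfView`: a pandas DataFrame of localizations (columns ``x``,
``y`` in µm, integer ``frame``, nullable ``channel`` and ``precision``) plus
the field extent and free-form metadata (case / group / replicate labels,
imager dye).

Two-color acquisitions alternate the excitation laser in fixed frame blocks
(200 frames per block in the acquisitions this package models, 68000 frames
total); :func:`demux_channels` recovers the channel of every localization
from its frame index when the export carries no channel column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FrameRangeError,
    LocalizationFormatError,
    LocalizationParseError,
)

logger = logging.getLogger(__name__)

#: Default CSV header (ONI-style export: frame index, coordinates, photon
#: count, localization precision).  Override via ``column_map``.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "frame": "frame",
    "x": "x",
    "y": "y",
    "precision": "precision",
    "channel": "channel",
}

LOC_COLUMNS = ["x", "y", "frame", "channel", "precision"]


@dataclass
class ChannelProgram:
    """Frame-block laser alternation program for two-color imaging."""

    block_length: int = 200
    channel_order: tuple[str, ...] = ("A", "B")
    total_frames: int = 68000

    def __post_init__(self) -> None:
        if self.block_length <= 0:
            raise ValueError("block_length must be positive")
        if self.total_frames % self.block_length != 0:
            raise ValueError("total_frames must be divisible by block_length")

    def channel_of(self, frame: np.ndarray | int):
        """Channel identifier(s) for the given frame index/indices."""
        block = np.asarray(frame) // self.block_length
        idx = block % len(self.channel_order)
        return np.asarray(self.channel_order, dtype=object)[idx]


@dataclass
class FieldOfView:
    """One imaged field: localization table + extent (µm) + metadata."""

    locs: pd.DataFrame
    extent: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        for col in LOC_COLUMNS:
            if col not in self.locs.columns:
                if col in ("channel", "precision"):
                    self.locs[col] = pd.Series(
                        [None] * len(self.locs), dtype=object
                    )
                elif col == "frame":
                    self.locs[col] = 0
                else:
                    raise LocalizationFormatError(f"missing column: {col}")

    @property
    def n_locs(self) -> int:
        return len(self.locs)

    @property
    def area(self) -> float:
        return float(self.extent[0] * self.extent[1])

    def points(self) -> np.ndarray:
        return self.locs[["x", "y"]].to_numpy(dtype=float)

    def channels(self) -> np.ndarray:
        return self.locs["channel"].to_numpy(dtype=object)


_UNIT_SCALE = {"nm": 1e-3, "um": 1.0, "µm": 1.0}


def read_localizations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit: str = "um",
    extent: tuple[float, float] | None = None,
    metadata: dict | None = None,
) -> FieldOfView:
    """Read a localization CSV into a :class:`FieldOfView`.

    Parameters
    ----------
    path : path to the CSV file.
    column_map : mapping from canonical names (``x``, ``y``, ``frame``,
        optionally ``channel``, ``precision``) to the file's column headers.
        Defaults to :data:`DEFAULT_COLUMN_MAP`.
    unit : ``"nm"`` or ``"um"`` — unit of the coordinate (and precision)
        columns in the file.  Internally everything is µm.
    extent : field-of-view (width, height) in µm; inferred from the data
        maxima when omitted.
    """
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unit must be 'nm' or 'um', got {unit!r}")
    scale = _UNIT_SCALE[unit]
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path)
    for key in ("x", "y", "frame"):
        if cmap[key] not in raw.columns:
            raise LocalizationFormatError(
                f"required column {cmap[key]!r} (for {key!r}) not found in {path}"
            )

    out = pd.DataFrame()
    for key in ("x", "y"):
        col = pd.to_numeric(raw[cmap[key]], errors="coerce")
        bad = col.isna() & raw[cmap[key]].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LocalizationParseError(
                f"non-numeric {key} coordinate at row {row}", row=row
            )
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise LocalizationParseError(
                f"missing {key} coordinate at row {row}", row=row
            )
        out[key] = col.to_numpy(dtype=float) * scale

    frames = pd.to_numeric(raw[cmap["frame"]], errors="coerce")
    if frames.isna().any():
        row = int(np.flatnonzero(frames.isna().to_numpy())[0])
        raise LocalizationParseError(f"bad frame index at row {row}", row=row)
    out["frame"] = frames.to_numpy(dtype=np.int64)
    if (out["frame"] < 0).any():
        raise LocalizationParseError("negative frame index")

    if cmap.get("channel") and cmap["channel"] in raw.columns:
        out["channel"] = raw[cmap["channel"]].astype(object)
    else:
        out["channel"] = pd.Series([None] * len(out), dtype=object)
    if cmap.get("precision") and cmap["precision"] in raw.columns:
        out["precision"] = (
            pd.to_numeric(raw[cmap["precision"]], errors="coerce") * scale
        )
    else:
        out["precision"] = pd.Series([None] * len(out), dtype=object)

    if extent is None:
        if len(out):
            extent = (
                float(np.ceil(out["x"].max())) or 1.0,
                float(np.ceil(out["y"].max())) or 1.0,
            )
        else:
            extent = (1.0, 1.0)
    fov = FieldOfView(out, extent, dict(metadata or {}))
    logger.info("read %d localizations from %s", len(out), path)
    return fov


def write_localizations(
    fov: FieldOfView, path: str | Path, unit: str = "um"
) -> None:
    """Write a FieldOfView back to CSV (canonical header, stated unit)."""
    scale = 1.0 / _UNIT_SCALE[unit]
    df = fov.locs.copy()
    df["x"] = df["x"] * scale
    df["y"] = df["y"] * scale
    df.to_csv(path, index=False)


def demux_channels(fov: FieldOfView, program: ChannelProgram) -> FieldOfView:
    """Assign each localization a channel from its frame-block position.

    The laser program alternates channels every ``block_length`` frames
    cycling through ``channel_order``; localizations must not already carry
    a channel and all frames must lie below ``total_frames``.
    """
    ch = fov.locs["channel"]
    if ch.notna().any():
        raise ValueError("demux_channels requires unset channel column")
    frames = fov.locs["frame"].to_numpy()
    if len(frames) and frames.max() >= program.total_frames:
        raise FrameRangeError(
            f"frame {int(frames.max())} >= total_frames {program.total_frames}"
        )
    locs = fov.locs.copy()
    locs["channel"] = program.channel_of(frames) if len(frames) else ch
    out = FieldOfView(locs, fov.extent, dict(fov.metadata))
    counts = locs["channel"].value_counts().to_dict()
    logger.info("demultiplexed channels: %s", counts)
    return out


# ---------------------------------------------------------------------------
# Aggregate tables

AGGREGATE_COLUMNS = [
    "aggregate_id",
    "n_locs",
    "area_um2",
    "size_class",
    "centroid_x",
    "centroid_y",
]


def aggregates_to_frame(aggregates: Sequence) -> pd.DataFrame:
    """Tidy one-row-per-aggregate table (see ``segmentation.Cluster``).

    Per-channel localization counts become ``n_<channel>`` columns; the
    enrichment score and singly/dually category are included when present.
    """
    rows = []
    for agg in aggregates:
        row = {
            "aggregate_id": agg.id,
            "n_locs": agg.n_locs,
            "area_um2": agg.area,
            "size_class": getattr(agg.size_class, "name", agg.size_class),
            "centroid_x": agg.centroid[0],
            "centroid_y": agg.centroid[1],
        }
        for ch, n in sorted((agg.channel_counts or {}).items()):
            row[f"n_{ch}"] = n
        if getattr(agg, "enrichment", None) is not None:
            row["enrichment_score"] = agg.enrichment
        if getattr(agg, "category", None) is not None:
            row["category"] = getattr(agg.category, "name", agg.category)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=AGGREGATE_COLUMNS)
    return df


def write_aggregates(aggregates: Sequence, path: str | Path) -> None:
    """Write an aggregate table CSV (one row per aggregate, header always)."""
    aggregates_to_frame(aggregates).to_csv(path, index=False)


def read_aggregates(path: str | Path) -> pd.DataFrame:
    """Read an aggregate table CSV back into a DataFrame."""
    return pd.read_csv(path)
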