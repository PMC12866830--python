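"""Synthetic DNA-PAINT field-of-view generator with planted ground truth.

The generator emulates the statistical structure of tissue DNA-PAINT point
clouds: fields of view containing planted aggregates of three size classes
(nano ≈ 90 nm discs, intermediate ≈ 500 nm ellipses, micro ≈ 1.6 µm
fibrils / ellipses / amorphous blobs), localization counts proportional to
aggregate area at a fixed target density, isotropic Gaussian localization
jitter, a uniform background of spurious localizations, and sparse small
noise clusters mimicking negative-control (secondary-antibody-only) images.

Two-color composition is controlled per aggregate by ``channel_fraction``
(the fraction of localizations carrying channel A).  Exactly
``round(fraction * n_locs)`` localizations are allocated to channel A — a
randomly chosen subset — so the planted enrichment ``2·fraction − 1`` is an
exact property of the aggregate and downstream recovery error measures the
analysis pipeline rather than label-sampling noise.

Everything is deterministic given a seed; cohort generation derives
independent per-field seeds from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError
from .loc_io import ChannelProgram, FieldOfView

__all__ = [
    "PlantedAggregate",
    "NoiseModel",
    "GroundTruth",
    "GroupSpec",
    "CLASS_SIZE_MODELS",
    "TARGET_DENSITY",
    "sample_aggregate",
    "draw_planted_aggregate",
    "generate_fov",
    "generate_cohort",
    "dual_mix",
]

#: Localizations per µm² inside an aggregate (sets n_locs ∝ area).
TARGET_DENSITY: float = 16000.0

#: Default localization jitter (µm), a typical DNA-PAINT precision.
DEFAULT_JITTER: float = 0.01

NANO, INTERMEDIATE, MICRO = "NANO", "INTERMEDIATE", "MICRO"


@dataclass(frozen=True)
class SizeModel:
    """Truncated-normal characteristic-size distribution for one class."""

    mean: float  # µm (diameter for discs, major axis otherwise)
    sd: float
    lo: float
    hi: float
    shapes: tuple[str, ...]  # candidate shape kinds

    def draw(self, rng: np.random.Generator) -> float:
        while True:
            s = rng.normal(self.mean, self.sd)
            if self.lo <= s <= self.hi:
                return float(s)


#: Class-average sizes follow the three observed aggregate classes
#: (≈ 90 nm diameter, ≈ 500 nm major axis, ≈ 1.6 µm major axis); the spread
#: around each average is a generator choice (see docs/methods.md).
CLASS_SIZE_MODELS: dict[str, SizeModel] = {
    NANO: SizeModel(0.095, 0.008, 0.08, 0.12, ("disc",)),
    INTERMEDIATE: SizeModel(0.50, 0.05, 0.38, 0.58, ("ellipse",)),
    MICRO: SizeModel(1.6, 0.2, 1.2, 2.0, ("fibril-chain", "ellipse", "amorphous-blob")),
}

_ELLIPSE_AXIS_RATIO = 2.2
_FIBRIL_TRANSVERSE_SIGMA = 0.05  # µm
_FIBRIL_SEGMENTS = 6
_FIBRIL_TURN_SIGMA = 0.45  # rad


@dataclass
class PlantedAggregate:
    """Ground-truth record for one planted aggregate."""

    center: tuple[float, float]
    shape: str  # disc | ellipse | fibril-chain | amorphous-blob
    target_class: str  # NANO | INTERMEDIATE | MICRO
    characteristic_size: float  # µm, diameter or major axis
    n_locs: int
    channel_fraction: float = 1.0
    aggregate_id: int = 0

    def __post_init__(self) -> None:
        if self.n_locs < 1:
            raise ValueError("n_locs must be >= 1")
        if not 0.0 <= self.channel_fraction <= 1.0:
            raise ValueError("channel_fraction must be in [0, 1]")

    @property
    def true_enrichment(self) -> float:
        """Planted enrichment score, exactly 2·channel_fraction − 1."""
        return 2.0 * self.channel_fraction - 1.0


@dataclass
class NoiseModel:
    """Background model matching negative-control image behavior.

    Uniform localizations plus small, dim noise clusters whose localization
    counts stay strictly below the min-locs segmentation filter by default,
    so the standard filters remove them.
    """

    uniform_rate: float = 2.0  # localizations / µm²
    noise_cluster_rate: float = 0.02  # clusters / µm²
    noise_cluster_locs: tuple[int, int] = (4, 9)  # inclusive count range
    noise_cluster_sigma: float = 0.015  # µm, isotropic cluster scale

    def __post_init__(self) -> None:
        if self.uniform_rate < 0 or self.noise_cluster_rate < 0:
            raise ValueError("noise rates must be >= 0")


@dataclass
class GroundTruth:
    """Per-localization labels + per-aggregate planted records.

    ``labels[i]`` is the planted aggregate id of localization ``i`` (row
    order of the FieldOfView table) or −1 for background/noise;
    ``noise_cluster_ids[i]`` distinguishes planted noise clusters (≥ 0)
    from uniform background (−1) among the noise localizations.
    """

    labels: np.ndarray
    aggregates: list[PlantedAggregate]
    noise_cluster_ids: np.ndarray

    @property
    def n_noise_clusters(self) -> int:
        ids = self.noise_cluster_ids
        return int(ids.max() + 1) if len(ids) and ids.max() >= 0 else 0


# ---------------------------------------------------------------------------
# Shape samplers


def _sample_disc(n: int, diameter: float, rng: np.random.Generator) -> np.ndarray:
    r = 0.5 * diameter * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _sample_ellipse(n: int, major: float, rng: np.random.Generator) -> np.ndarray:
    a = major / 2.0
    b = a / _ELLIPSE_AXIS_RATIO
    pts = _sample_disc(n, 2.0, rng)  # unit disc
    pts[:, 0] *= a
    pts[:, 1] *= b
    phi = rng.uniform(0, np.pi)
    c, s = np.cos(phi), np.sin(phi)
    return pts @ np.array([[c, s], [-s, c]])


def _fibril_polyline(length: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random polyline of total arc length ``length``."""
    seg = length / _FIBRIL_SEGMENTS
    heading = rng.uniform(0, 2 * np.pi)
    pts = [np.zeros(2)]
    for _ in range(_FIBRIL_SEGMENTS):
        heading += rng.normal(0.0, _FIBRIL_TURN_SIGMA)
        step = seg * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pts[-1] + step)
    poly = np.asarray(pts)
    return poly - poly.mean(axis=0)


def _sample_fibril(n: int, length: float, rng: np.random.Generator) -> np.ndarray:
    poly = _fibril_polyline(length, rng)
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = rng.uniform(0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, t) - 1, 0, len(seg_len) - 1)
    frac = (t - cum[idx]) / seg_len[idx]
    base = poly[idx] + frac[:, None] * seg_vec[idx]
    # transverse Gaussian spread around the backbone
    normals = np.column_stack([-seg_vec[idx, 1], seg_vec[idx, 0]])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    offset = rng.normal(0.0, _FIBRIL_TRANSVERSE_SIGMA, n)
    return base + offset[:, None] * normals


def _sample_blob(n: int, size: float, rng: np.random.Generator) -> np.ndarray:
    """Amorphous blob: mixture of overlapping sub-discs."""
    k = int(rng.integers(3, 6))
    centers = _sample_disc(k, 2 * size / 3.0, rng)
    sub = rng.integers(0, k, n)
    pts = _sample_disc(n, size / 2.0, rng)
    return pts + centers[sub]


_SHAPE_SAMPLERS = {
    "disc": _sample_disc,
    "ellipse": _sample_ellipse,
    "fibril-chain": _sample_fibril,
    "amorphous-blob": _sample_blob,
}


def nominal_area(shape: str, size: float) -> float:
    """Expected alpha-shape area of a planted shape, used to scale n_locs.

    The leading factors calibrate the geometric area of each shape to the
    area its sampled point cloud realizes under the default alpha-shape
    boundary (0.05 µm radius) and localization jitter, so the localization
    density is uniform across shapes as measured by the pipeline itself.
    """
    if shape == "disc":
        return 1.32 * np.pi * (size / 2.0) ** 2
    if shape == "ellipse":
        a = size / 2.0
        return 1.11 * np.pi * a * (a / _ELLIPSE_AXIS_RATIO)
    if shape == "fibril-chain":
        return size * 5.2 * _FIBRIL_TRANSVERSE_SIGMA
    if shape == "amorphous-blob":
        return 1.22 * 2.2 * np.pi * (size / 4.0) ** 2
    raise ValueError(f"unknown shape kind: {shape!r}")


def sample_aggregate(
    spec: PlantedAggregate,
    jitter_sigma: float = DEFAULT_JITTER,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw the localizations of one planted aggregate.

    Exactly ``spec.n_locs`` points are drawn uniformly within the shape,
    perturbed by isotropic Gaussian jitter, and assigned channels so that
    exactly ``round(channel_fraction * n_locs)`` carry channel ``"A"`` (the
    rest ``"B"``).  Deterministic given the rng/seed.
    """
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    if spec.shape not in _SHAPE_SAMPLERS:
        raise ValueError(f"unknown shape kind: {spec.shape!r}")
    rng = np.random.default_rng(rng)
    pts = _SHAPE_SAMPLERS[spec.shape](spec.n_locs, spec.characteristic_size, rng)
    if jitter_sigma > 0:
        pts = pts + rng.normal(0.0, jitter_sigma, pts.shape)
    pts = pts + np.asarray(spec.center)

    n_a = int(round(spec.channel_fraction * spec.n_locs))
    channels = np.full(spec.n_locs, "B", dtype=object)
    channels[rng.permutation(spec.n_locs)[:n_a]] = "A"
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "channel": channels})


#: Log10 scatter of per-aggregate localization counts around the
#: density × area expectation (labeling efficiency / binding-site variation).
COUNT_JITTER_DEX: float = 0.08


def draw_planted_aggregate(
    target_class: str,
    center: tuple[float, float],
    rng: np.random.Generator,
    density: float = TARGET_DENSITY,
    channel_fraction: float = 1.0,
    aggregate_id: int = 0,
    count_jitter_dex: float = COUNT_JITTER_DEX,
) -> PlantedAggregate:
    """Draw a class-consistent size/shape and derive n_locs ∝ area.

    Counts scatter log-normally (``count_jitter_dex`` in log10) around the
    linear density × area expectation.
    """
    model = CLASS_SIZE_MODELS[target_class]
    size = model.draw(rng)
    shape = model.shapes[int(rng.integers(len(model.shapes)))]
    expected = density * nominal_area(shape, size)
    n_locs = max(
        12, int(round(expected * 10 ** rng.normal(0.0, count_jitter_dex)))
    )
    return PlantedAggregate(
        center=center,
        shape=shape,
        target_class=target_class,
        characteristic_size=size,
        n_locs=n_locs,
        channel_fraction=channel_fraction,
        aggregate_id=aggregate_id,
    )


# ---------------------------------------------------------------------------
# Field-of-view generation


def _place_centers(
    sizes: Sequence[float],
    extent: tuple[float, float],
    rng: np.random.Generator,
    max_attempts: int = 5000,
) -> np.ndarray:
    """Rejection-place centers with size-dependent minimum separation."""
    w, h = extent
    centers: list[np.ndarray] = []
    for i, size in enumerate(sizes):
        margin = size / 2.0 + 0.2
        if 2 * margin >= min(w, h):
            raise PlacementError(f"aggregate of size {size} does not fit extent")
        for attempt in range(max_attempts):
            cand = rng.uniform([margin, margin], [w - margin, h - margin])
            ok = True
            for j, prev in enumerate(centers):
                min_sep = 0.6 * (size + sizes[j]) + 0.3
                if np.linalg.norm(cand - prev) < min_sep:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place aggregate {i} after {max_attempts} attempts"
            )
    return np.asarray(centers) if centers else np.empty((0, 2))


def _assign_frames(
    channels: np.ndarray,
    program: ChannelProgram | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frames consistent with the laser block program of each channel."""
    n = len(channels)
    if program is None:
        return rng.integers(0, 34000, n)
    n_blocks = program.total_frames // program.block_length
    order = list(program.channel_order)
    frames = np.zeros(n, dtype=np.int64)
    for ch in set(channels):
        idx = np.flatnonzero(channels == ch)
        if ch in order:
            ch_blocks = np.arange(order.index(ch), n_blocks, len(order))
        else:  # unknown / None channel: any block
            ch_blocks = np.arange(n_blocks)
        blocks = rng.choice(ch_blocks, size=len(idx))
        frames[idx] = blocks * program.block_length + rng.integers(
            0, program.block_length, len(idx)
        )
    return frames


def generate_fov(
    n_per_class: tuple[int, int, int] = (15, 5, 2),
    noise: NoiseModel | None = None,
    extent: tuple[float, float] = (50.0, 50.0),
    enrichment_mix: Callable[[np.random.Generator], float] | None = None,
    density: float = TARGET_DENSITY,
    jitter_sigma: float = DEFAULT_JITTER,
    seed: np.random.Generator | int | None = 0,
    metadata: dict | None = None,
    program: ChannelProgram | None = None,
) -> tuple[FieldOfView, GroundTruth]:
    """Generate one synthetic field of view with ground truth.

    Parameters
    ----------
    n_per_class : planted aggregate counts for (nano, intermediate, micro).
    noise : background model; defaults to :class:`NoiseModel` defaults.
    extent : field width/height in µm.
    enrichment_mix : callable drawing a channel-A fraction per aggregate;
        ``None`` leaves all localizations channel-less (single-color run).
    density : in-aggregate localization density (locs/µm²).
    seed : integer seed or Generator.
    program : when given, frames are drawn from the channel's laser blocks.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    classes = [NANO] * n_per_class[0] + [INTERMEDIATE] * n_per_class[1] + [
        MICRO
    ] * n_per_class[2]

    # draw specs first (sizes needed for placement)
    specs: list[PlantedAggregate] = []
    for k, cls in enumerate(classes):
        frac = enrichment_mix(rng) if enrichment_mix is not None else 1.0
        specs.append(
            draw_planted_aggregate(
                cls, (0.0, 0.0), rng, density=density,
                channel_fraction=frac, aggregate_id=k,
            )
        )
    centers = _place_centers([s.characteristic_size for s in specs], extent, rng)

    frames_chunks: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []
    noise_ids: list[np.ndarray] = []
    dual = enrichment_mix is not None
    for k, spec in enumerate(specs):
        spec = replace(spec, center=tuple(centers[k]))
        specs[k] = spec
        df = sample_aggregate(spec, jitter_sigma, rng)
        if not dual:
            df["channel"] = None
        frames_chunks.append(df)
        labels.append(np.full(len(df), k, dtype=np.int64))
        noise_ids.append(np.full(len(df), -1, dtype=np.int64))

    w, h = extent
    area = w * h
    # uniform background
    n_bg = rng.poisson(noise.uniform_rate * area)
    if n_bg:
        bg = pd.DataFrame(
            {
                "x": rng.uniform(0, w, n_bg),
                "y": rng.uniform(0, h, n_bg),
                "channel": (
                    rng.choice(["A", "B"], n_bg).astype(object) if dual else None
                ),
            }
        )
        frames_chunks.append(bg)
        labels.append(np.full(n_bg, -1, dtype=np.int64))
        noise_ids.append(np.full(n_bg, -1, dtype=np.int64))
    # small noise clusters (sub-min-locs by construction)
    n_nc = rng.poisson(noise.noise_cluster_rate * area)
    lo, hi = noise.noise_cluster_locs
    for j in range(n_nc):
        m = int(rng.integers(lo, hi + 1))
        c = rng.uniform([0, 0], [w, h])
        pts = c + rng.normal(0.0, noise.noise_cluster_sigma, (m, 2))
        nc = pd.DataFrame(
            {
                "x": pts[:, 0],
                "y": pts[:, 1],
                "channel": (
                    rng.choice(["A", "B"], m).astype(object) if dual else None
                ),
            }
        )
        frames_chunks.append(nc)
        labels.append(np.full(m, -1, dtype=np.int64))
        noise_ids.append(np.full(m, j, dtype=np.int64))

    locs = pd.concat(frames_chunks, ignore_index=True) if frames_chunks else (
        pd.DataFrame(columns=["x", "y", "channel"])
    )
    locs["x"] = locs["x"].clip(0, w)
    locs["y"] = locs["y"].clip(0, h)
    channels = locs["channel"].to_numpy(dtype=object)
    locs["frame"] = _assign_frames(channels, program, rng)
    locs["precision"] = jitter_sigma
    fov = FieldOfView(locs, extent, dict(metadata or {}))
    gt = GroundTruth(
        labels=np.concatenate(labels) if labels else np.empty(0, dtype=np.int64),
        aggregates=specs,
        noise_cluster_ids=(
            np.concatenate(noise_ids) if noise_ids else np.empty(0, dtype=np.int64)
        ),
    )
    return fov, gt


def dual_mix(
    p_dually: float = 0.6,
    p_singly_a: float | None = None,
) -> Callable[[np.random.Generator], float]:
    """Channel-fraction mixture for two-color cohorts.

    With probability ``p_dually`` the fraction is uniform in [0.15, 0.85]
    (enrichment well inside the dually-modified band); the remaining mass is
    split between channel-pure ends (fractions in [0.95, 1] or [0, 0.05]).
    """
    if not 0 <= p_dually <= 1:
        raise ValueError("p_dually must be in [0, 1]")
    p_a = (1 - p_dually) / 2 if p_singly_a is None else p_singly_a
    p_b = 1 - p_dually - p_a
    if p_b < -1e-12:
        raise ValueError("probabilities exceed 1")

    def draw(rng: np.random.Generator) -> float:
        u = rng.random()
        if u < p_dually:
            return float(rng.uniform(0.15, 0.85))
        if u < p_dually + p_a:
            return float(rng.uniform(0.95, 1.0))
        return float(rng.uniform(0.0, 0.05))

    return draw


@dataclass
class GroupSpec:
    """Per-group generator settings for cohort simulation."""

    n_per_class: tuple[int, int, int] = (15, 5, 2)
    noise: NoiseModel = field(default_factory=NoiseModel)
    enrichment_mix: Callable[[np.random.Generator], float] | None = None
    density: float = TARGET_DENSITY


def generate_cohort(
    groups: dict[str, GroupSpec],
    n_fov_per_replicate: int = 4,
    n_replicates: int = 4,
    extent: tuple[float, float] = (50.0, 50.0),
    seed: int = 0,
    program: ChannelProgram | None = None,
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Hierarchical cohort: groups × replicates (tissue sections) × FOVs.

    Per-FOV seeds are spawned deterministically from the master seed, so a
    fixed seed reproduces the cohort exactly.
    """
    ss = np.random.SeedSequence(seed)
    out: list[tuple[FieldOfView, GroundTruth]] = []
    children = iter(ss.spawn(len(groups) * n_replicates * n_fov_per_replicate))
    for gname, gspec in groups.items():
        for rep in range(n_replicates):
            for f in range(n_fov_per_replicate):
                child = next(children)
                fov, gt = generate_fov(
                    n_per_class=gspec.n_per_class,
                    noise=gspec.noise,
                    extent=extent,
                    enrichment_mix=gspec.enrichment_mix,
                    density=gspec.density,
                    seed=np.random.default_rng(child),
                    metadata={"group": gname, "replicate": rep, "fov": f},
                    program=program,
                )
                out.append((fov, gt))
    return out
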