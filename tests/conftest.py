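"""Shared fixtures: small synthetic fields and point clouds."""

import numpy as np
import pandas as pd
import pytest

from taupaint.loc_io import FieldOfView
from taupaint.simulate import PlantedAggregate, sample_aggregate


@pytest.fixture(scope="session")
def disc_points() -> np.ndarray:
    """500 localizations uniform in a 90 nm disc (no jitter)."""
    spec = PlantedAggregate(
        center=(5.0, 5.0),
        shape="disc",
        target_class="NANO",
        characteristic_size=0.09,
        n_locs=500,
    )
    return sample_aggregate(spec, jitter_sigma=0.0, rng=1)[["x", "y"]].to_numpy()


@pytest.fixture()
def grid_fov() -> FieldOfView:
    """Regular 20x20 square grid, spacing 0.1 µm."""
    xs, ys = np.meshgrid(np.arange(20) * 0.1, np.arange(20) * 0.1)
    locs = pd.DataFrame({"x": xs.ravel() + 0.05, "y": ys.ravel() + 0.05})
    return FieldOfView(locs, extent=(2.0, 2.0))


def two_blob_fov(
    seed: int = 0,
    n_per_blob: int = 60,
    sigma: float = 0.02,
    centers=((1.0, 1.0), (3.0, 3.0)),
    n_background: int = 30,
    extent=(4.0, 4.0),
):
    """Two dense Gaussian blobs in sparse uniform background, with labels."""
    rng = np.random.default_rng(seed)
    chunks, labels = [], []
    for k, c in enumerate(centers):
        pts = rng.normal(c, sigma, (n_per_blob, 2))
        chunks.append(pts)
        labels.append(np.full(n_per_blob, k))
    bg = rng.uniform([0, 0], list(extent), (n_background, 2))
    chunks.append(bg)
    labels.append(np.full(n_background, -1))
    pts = np.vstack(chunks)
    locs = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
    return FieldOfView(locs, extent=extent), np.concatenate(labels)


@pytest.fixture()
def blob_fov():
    return two_blob_fov()
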