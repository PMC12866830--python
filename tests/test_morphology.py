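"""Descriptor registry, invariances, PCA determinism, Jaccard footprints."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon
from sklearn.metrics import silhouette_score

from taupaint.errors import DescriptorError
from taupaint.morphology import (
    DESCRIPTOR_FAMILIES,
    DESCRIPTOR_LENGTH_EXPONENTS,
    DESCRIPTOR_NAMES,
    compute_descriptors,
    descriptor_summaries,
    group_overlap_jaccard,
    jaccard_of_polygons,
    run_pca,
)
from taupaint.simulate import PlantedAggregate, sample_aggregate


def sample_shape(shape, size, n, seed, target="NANO", jitter=0.0):
    spec = PlantedAggregate(
        center=(0.0, 0.0),
        shape=shape,
        target_class=target,
        characteristic_size=size,
        n_locs=n,
    )
    return sample_aggregate(spec, jitter, rng=seed)[["x", "y"]].to_numpy()


class TestDescriptorRegistry:
    def test_registry_has_67_descriptors(self):
        assert len(DESCRIPTOR_NAMES) == 67
        assert len(set(DESCRIPTOR_NAMES)) == 67

    def test_family_sizes(self):
        counts = pd.Series(list(DESCRIPTOR_FAMILIES.values())).value_counts()
        assert counts.to_dict() == {
            "geometric": 16,
            "moment": 12,
            "boundary": 12,
            "skeleton": 10,
            "point": 8,
            "fractal": 4,
            "composite": 5,
        }

    def test_vector_matches_registry_order(self, disc_points):
        d = compute_descriptors(disc_points)
        assert list(d.index) == DESCRIPTOR_NAMES
        assert np.isfinite(d.to_numpy(dtype=float)).all()


class TestDescriptorValues:
    def test_disc_is_nearly_circular(self, disc_points):
        d = compute_descriptors(disc_points)
        assert d["circularity"] >= 0.9
        assert d["circularity"] <= 1.0 + 1e-9
        assert d["solidity"] > 0.95
        # area close to the geometric disc area (π·0.045²)
        assert d["area"] == pytest.approx(math.pi * 0.045**2, rel=0.15)

    def test_fibril_is_elongated_and_less_circular(self):
        pts = sample_shape("fibril-chain", 1.6, 3000, seed=2, target="MICRO")
        d = compute_descriptors(pts)
        assert d["eccentricity"] > 0.9
        assert d["circularity"] < 0.6
        assert d["major_axis"] > 5 * d["minor_axis"] / 2

    def test_translation_invariance_of_every_descriptor(self, disc_points):
        d0 = compute_descriptors(disc_points)
        d1 = compute_descriptors(disc_points + np.array([10.0, -4.0]))
        np.testing.assert_allclose(
            d0.to_numpy(float), d1.to_numpy(float), rtol=1e-6, atol=1e-9
        )

    def test_dilation_scales_with_registered_exponents(self, disc_points):
        s = 3.0
        d0 = compute_descriptors(disc_points)
        d1 = compute_descriptors(disc_points * s, alpha_radius=0.05 * s)
        for name in DESCRIPTOR_NAMES:
            expected = d0[name] * s ** DESCRIPTOR_LENGTH_EXPONENTS[name]
            assert d1[name] == pytest.approx(expected, rel=0.02, abs=1e-9), name

    def test_circularity_of_regular_ngon_increases_toward_one(self):
        prev = 0.0
        for n in (5, 8, 16, 64):
            th = 2 * np.pi * np.arange(n) / n
            ring = np.column_stack([np.cos(th), np.sin(th)])
            # fill with interior points so descriptors are defined
            rng = np.random.default_rng(0)
            inner = rng.random((300, 1)) ** 0.5 * ring[rng.integers(0, n, 300)] * 0.999
            pts = np.vstack([ring, inner])
            d = compute_descriptors(pts, alpha_radius=5.0)
            assert d["circularity"] > prev
            prev = d["circularity"]
        assert prev <= 1.0 + 1e-9

    def test_too_few_points_raises_descriptor_error(self):
        with pytest.raises(DescriptorError):
            compute_descriptors(np.random.default_rng(0).random((5, 2)))

    def test_collinear_cloud_raises_naming_geometry(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 2 * t])
        with pytest.raises(DescriptorError) as exc:
            compute_descriptors(pts)
        assert exc.value.family == "geometric"


class TestRunPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 40)
        X = np.column_stack([t, 2 * t, -t, 3 * t + 1])
        emb = run_pca(X)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_reconstruct_scaled_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        emb = run_pca(X)
        Z = (X - emb.means) / emb.stds
        np.testing.assert_allclose(emb.scores @ emb.loadings, Z, atol=1e-8)

    def test_duplicating_observations_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 5))
        emb1 = run_pca(X)
        emb2 = run_pca(np.vstack([X, X]))
        k = min(len(emb1.loadings), len(emb2.loadings))
        np.testing.assert_allclose(
            emb1.loadings[:k], emb2.loadings[:k], atol=1e-8
        )

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        X[:, 2] = 7.0
        emb = run_pca(pd.DataFrame(X, columns=list("abcd")))
        assert emb.dropped_features == ["c"]
        assert emb.feature_names == ["a", "b", "d"]

    def test_explained_variance_non_increasing_and_sums_to_at_most_one(self):
        rng = np.random.default_rng(3)
        emb = run_pca(rng.normal(size=(40, 8)))
        evr = emb.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((1, 3)))


class TestGroupOverlap:
    def _embedding(self, shift, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 4))
        b = rng.normal(size=(n, 4)) + shift
        return run_pca(np.vstack([a, b]), labels=["a"] * n + ["b"] * n)

    def test_identical_groups_have_jaccard_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        emb = run_pca(np.vstack([X, X]), labels=["a"] * 30 + ["b"] * 30)
        res = group_overlap_jaccard(emb, ("a", "b"), boundary_method="hull",
                                    trim_fraction=0.0)
        assert res.jaccard == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_groups_have_jaccard_zero(self):
        emb = self._embedding(shift=50.0)
        res = group_overlap_jaccard(emb, ("a", "b"))
        assert res.jaccard == 0.0

    def test_jaccard_symmetric_in_pair(self):
        emb = self._embedding(shift=1.0)
        j_ab = group_overlap_jaccard(emb, ("a", "b")).jaccard
        j_ba = group_overlap_jaccard(emb, ("b", "a")).jaccard
        assert j_ab == pytest.approx(j_ba)

    def test_overlap_decreases_as_groups_separate(self):
        js = [self._embedding(shift=s, seed=4) for s in (0.0, 0.5, 1.0)]
        vals = [group_overlap_jaccard(e, ("a", "b")).jaccard for e in js]
        assert vals[0] > vals[1] > vals[2]

    def test_offset_unit_squares_give_one_third(self):
        sq1 = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        sq2 = Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)])
        assert jaccard_of_polygons(sq1, sq2) == pytest.approx(1 / 3)
        # the literal intersection-over-sum variant
        assert jaccard_of_polygons(sq1, sq2, mode="sum") == pytest.approx(0.25)

    def test_small_group_rejected(self):
        emb = self._embedding(shift=0.0)
        emb.labels[:] = "a"
        emb.labels[0] = "b"
        with pytest.raises(ValueError):
            group_overlap_jaccard(emb, ("a", "b"))

    def test_pca_separates_two_morphological_populations(self):
        """Discs vs fibrils separate in descriptor PCA space (PC1-PC2)."""
        rows, labels = [], []
        for seed in range(12):
            rows.append(compute_descriptors(sample_shape("disc", 0.09, 200, seed)))
            labels.append("disc")
            rows.append(
                compute_descriptors(
                    sample_shape("fibril-chain", 0.5, 400, seed, target="INTERMEDIATE")
                )
            )
            labels.append("fibril")
        emb = run_pca(pd.DataFrame(rows), labels=labels)
        sil = silhouette_score(emb.scores[:, :2], labels)
        assert sil > 0


class TestDescriptorSummaries:
    def _table(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(12, 3)),
            columns=["area", "circularity", "major_axis"],
        )
        return df

    def test_single_group_mean_matches_input(self):
        df = self._table().iloc[:1]
        out = descriptor_summaries(df, ["g"], ["area"], log10=False)
        assert out.loc[0, "mean"] == pytest.approx(df["area"].iloc[0])

    def test_log10_transform(self):
        df = pd.DataFrame({"area": [0.01]})
        out = descriptor_summaries(df, ["g"], ["area"], log10=True)
        assert out.loc[0, "mean"] == pytest.approx(-2.0)

    def test_unknown_feature_is_lookup_error(self):
        with pytest.raises(KeyError):
            descriptor_summaries(self._table(), ["g"] * 12, ["volume"])

    def test_replicate_means_present_when_labels_given(self):
        df = self._table()
        out = descriptor_summaries(
            df,
            ["g"] * 12,
            ["area"],
            replicate_labels=[i // 4 for i in range(12)],
            log10=False,
        )
        reps = out[out.level == "replicate"]
        assert len(reps) == 3
        np.testing.assert_allclose(
            sorted(reps["mean"]),
            sorted(df.groupby([i // 4 for i in range(12)])["area"].mean()),
        )
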