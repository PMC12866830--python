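"""Cohort tables, percentages, rank-sum inference, and control analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import Point

from taupaint.dualcolor import EnrichmentRecord, ModificationCategory
from taupaint.filters import SizeClass
from taupaint.loc_io import FieldOfView
from taupaint.report import (
    channel_correlation,
    class_percentages,
    cohort_table,
    density_per_unit_area,
    modification_percentages,
    ranksum_compare,
    replicate_means,
    single_vs_dual_counts,
)
from taupaint.segmentation import Cluster


def stub_cluster(cid, size_class, n_locs=20, n_a=None, n_b=None):
    counts = {}
    if n_a is not None:
        counts["A"] = n_a
    if n_b is not None:
        counts["B"] = n_b
    return Cluster(
        id=cid,
        indices=np.arange(n_locs),
        points=np.zeros((n_locs, 2)),
        channels=np.full(n_locs, None, dtype=object),
        boundary=Point(0, 0).buffer(0.05),
        area=0.01,
        centroid=(0.0, 0.0),
        size_class=size_class,
        channel_counts=counts,
    )


def enumeration_pvalue(x, y, alternative):
    """Brute-force rank-sum p-value over all rank assignments (oracle)."""
    m = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - m * (m + 1) / 2
            for comb in itertools.combinations(range(len(ranks)), m)
        ]
    )
    ge, le = np.mean(us >= u_obs), np.mean(us <= u_obs)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestDensity:
    def test_count_over_area(self):
        fov = FieldOfView(pd.DataFrame({"x": [], "y": []}), (50.0, 50.0))
        assert density_per_unit_area(range(5), fov) == pytest.approx(0.002)
        assert density_per_unit_area([], fov) == 0.0

    def test_doubling_area_halves_density(self):
        d1 = density_per_unit_area(range(8), (10.0, 10.0))
        d2 = density_per_unit_area(range(8), (20.0, 10.0))
        assert d2 == pytest.approx(d1 / 2)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            density_per_unit_area([], (0.0, 10.0))


class TestCohortTable:
    def _per_fov(self):
        out = []
        for rep in range(2):
            for f in range(2):
                fov = FieldOfView(
                    pd.DataFrame({"x": [], "y": []}),
                    (10.0, 10.0),
                    {"group": "g", "replicate": rep, "fov": f},
                )
                clusters = [stub_cluster(0, SizeClass.NANO)] * (rep + 1)
                out.append((fov, clusters))
        return out

    def test_density_is_count_over_fov_area(self):
        table = cohort_table(self._per_fov())
        nano = table[table.size_class == "NANO"]
        np.testing.assert_allclose(nano["density"], nano["count"] / 100.0)

    def test_replicate_mean_is_mean_of_its_fovs(self):
        table = cohort_table(self._per_fov())
        means = replicate_means(table, "count")
        nano = means[means.size_class == "NANO"].set_index("replicate")["count"]
        assert nano[0] == pytest.approx(1.0)
        assert nano[1] == pytest.approx(2.0)


class TestClassPercentages:
    def _table(self, counts_by_class):
        rows = []
        for cls, n in counts_by_class.items():
            rows.append(
                {"group": "g", "replicate": 0, "fov": 0, "mark": None,
                 "size_class": cls, "count": n, "density": n / 100.0}
            )
        return pd.DataFrame(rows)

    def test_percentages_match_count_shares(self):
        out = class_percentages(
            self._table({"NANO": 90, "INTERMEDIATE": 8, "MICRO": 2})
        )
        row = out.iloc[0]
        assert row["NANO"] == pytest.approx(90.0)
        assert row["INTERMEDIATE"] == pytest.approx(8.0)
        assert row["MICRO"] == pytest.approx(2.0)

    def test_single_class_gives_100(self):
        out = class_percentages(self._table({"NANO": 7}))
        assert out.iloc[0]["NANO"] == pytest.approx(100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in "ab":
            for rep in range(3):
                for cls in ("NANO", "INTERMEDIATE", "MICRO"):
                    rows.append(
                        {"group": g, "replicate": rep, "fov": 0, "mark": None,
                         "size_class": cls, "count": int(rng.integers(0, 50)),
                         "density": 0.0}
                    )
        out = class_percentages(pd.DataFrame(rows))
        sums = out[["NANO", "INTERMEDIATE", "MICRO"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_all_zero_group_omitted(self, caplog):
        with caplog.at_level("WARNING"):
            out = class_percentages(self._table({"NANO": 0}))
        assert len(out) == 0


class TestModificationPercentages:
    def _records(self, cats, size_class=SizeClass.NANO):
        return [
            EnrichmentRecord(i, 10, 10, 0.0, c, size_class) for i, c in enumerate(cats)
        ]

    def test_all_dually_gives_100_percent(self):
        out = modification_percentages(
            self._records([ModificationCategory.DUALLY] * 5)
        )
        assert out.iloc[0]["DUALLY"] == pytest.approx(100.0)

    def test_rows_sum_to_100(self):
        cats = [
            ModificationCategory.DUALLY,
            ModificationCategory.SINGLY_A,
            ModificationCategory.SINGLY_B,
            ModificationCategory.DUALLY,
        ]
        out = modification_percentages(self._records(cats))
        total = out[["SINGLY_A", "SINGLY_B", "DUALLY"]].sum(axis=1)
        np.testing.assert_allclose(total, 100.0, atol=1e-9)
        assert out.iloc[0]["DUALLY"] == pytest.approx(50.0)


class TestRanksumCompare:
    def test_identical_groups_p_is_one(self):
        res = ranksum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_two_sided_symmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(1.0, 1.0, size=6)
        assert ranksum_compare(x, y).p_value == pytest.approx(
            ranksum_compare(y, x).p_value
        )

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m, n = rng.integers(2, 8, 2)
            x = rng.normal(size=int(m))
            y = rng.normal(size=int(n))
            res = ranksum_compare(x, y, alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                enumeration_pvalue(x, y, alternative), abs=1e-12
            )

    def test_one_sided_detects_planted_decrease(self):
        rng = np.random.default_rng(1)
        high = rng.normal(10, 1, 6)
        low = rng.normal(5, 1, 6)
        res = ranksum_compare(low, high, alternative="less")
        assert res.p_value < 0.05

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([1.0], [1.0, 2.0])


class TestChannelCorrelation:
    def test_proportional_counts_give_r_one(self):
        clusters = [
            stub_cluster(i, SizeClass.NANO, n_a=n, n_b=2 * n)
            for i, n in enumerate([10, 20, 30, 40])
        ]
        res = channel_correlation(clusters)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antiproportional_counts_give_r_minus_one(self):
        clusters = [
            stub_cluster(i, SizeClass.NANO, n_a=n, n_b=100 - n)
            for i, n in enumerate([10, 20, 30, 40])
        ]
        assert channel_correlation(clusters).pearson_r == pytest.approx(-1.0)

    def test_independent_counts_near_zero_at_n_200(self):
        rng = np.random.default_rng(0)
        clusters = [
            stub_cluster(i, SizeClass.NANO,
                         n_a=int(rng.integers(10, 100)),
                         n_b=int(rng.integers(10, 100)))
            for i in range(200)
        ]
        res = channel_correlation(clusters)
        assert abs(res.pearson_r) < 2.5 / np.sqrt(200)

    def test_zero_variance_flagged(self):
        clusters = [stub_cluster(i, SizeClass.NANO, n_a=10, n_b=i) for i in range(5)]
        res = channel_correlation(clusters)
        assert not res.defined

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError):
            channel_correlation([stub_cluster(0, SizeClass.NANO, n_a=1, n_b=2)])


class TestSingleVsDualCounts:
    def _clusters(self, counts, size_class=SizeClass.NANO):
        return [stub_cluster(i, size_class, n_locs=c) for i, c in enumerate(counts)]

    def test_identical_runs_show_no_difference(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(20, 200, 10).tolist()
        out = single_vs_dual_counts(self._clusters(counts), self._clusters(counts))
        assert (out["p_value"] > 0.9).all()

    def test_planted_50_percent_reduction_detected(self):
        rng = np.random.default_rng(1)
        single = rng.integers(100, 140, 10).tolist()
        dual = [c // 2 for c in single]
        out = single_vs_dual_counts(self._clusters(single), self._clusters(dual))
        assert (out["p_value"] < 0.05).all()

    def test_class_missing_from_one_run_omitted(self):
        single = self._clusters([30, 40, 50], SizeClass.MICRO)
        dual = self._clusters([30, 40, 50], SizeClass.NANO)
        out = single_vs_dual_counts(single, dual)
        assert len(out) == 0
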