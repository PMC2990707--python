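import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from cnvdosage.io import RegionConfig
from cnvdosage.flank import (
    _mean_nn_distance,
    breakpoint_distance_correlation,
    clustering_test,
    direction_concordance,
    dosage_summary,
    expression_level_comparison,
    platform_concordance,
    tissue_breadth_comparison,
)
from cnvdosage.simulate import REARRANGED, generate_dataset


class TestDosageSummary:
    def test_noiseless_ratios_exact(self, noiseless_dataset):
        ds = noiseless_dataset
        summary = dosage_summary(ds.matrix, ds.samples, ds.annot)
        for g, expected in (("1n", 0.66), ("2n_cis", 1.02), ("3n", 1.38)):
            assert summary.ratio(g) == pytest.approx(expected, abs=1e-9)
        # anchors are reported apart, grouped by active copy number
        assert summary.ratio("2n_cis", "anchor_1cp") == pytest.approx(0.66, abs=1e-9)
        assert summary.ratio("2n_cis", "anchor_3cp") == pytest.approx(1.38, abs=1e-9)
        assert summary.ratio("3n", "anchor_2cp") == pytest.approx(1.0, abs=1e-9)

    def test_all_effects_off_means_unity(self, small_config):
        cfg = dataclasses.replace(small_config.null(), noise_sd=0.0)
        ds = generate_dataset(cfg)
        summary = dosage_summary(ds.matrix, ds.samples, ds.annot)
        for g in REARRANGED:
            assert summary.ratio(g) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self, small_dataset):
        """Adding a constant to every sample of one tissue leaves ratios unchanged."""
        ds = small_dataset
        before = dosage_summary(ds.matrix, ds.samples, ds.annot)
        shifted = ds.matrix.copy()
        cols = ds.samples.index[ds.samples["tissue"] == "heart"]
        shifted[cols] += 3.7
        after = dosage_summary(shifted, ds.samples, ds.annot)
        pd.testing.assert_frame_equal(before.table, after.table)

    def test_empty_interval_errors(self, small_dataset):
        annot = small_dataset.annot[small_dataset.annot["region_class"] != "interval"]
        with pytest.raises(ValueError, match="interval"):
            dosage_summary(small_dataset.matrix, small_dataset.samples, annot)


class TestDirectionConcordance:
    def _contrasts(self, fc):
        return {g: pd.Series(fc[i], index=[f"p{j}" for j in range(len(fc[i]))])
                for i, g in enumerate(REARRANGED)}

    def test_identical_vectors_fully_concordant(self):
        con = self._contrasts([[0.5, -1.0, 2.0]] * 3)
        res = direction_concordance(con, ["p0", "p1", "p2"])
        assert res.threeway == 1.0 and all(v == 1.0 for v in res.pairwise.values())

    def test_enumerated_pairwise_fraction(self):
        """Signs (+,+,-) vs (+,-,-) agree on two of three probes."""
        con = self._contrasts([[1, 1, -1], [1, 1, 1], [1, -1, -1]])
        res = direction_concordance(con, ["p0", "p1", "p2"])
        assert res.pairwise[("1n", "3n")] == pytest.approx(2 / 3)

    def test_zero_fold_changes_excluded(self):
        con = self._contrasts([[1, 0.0], [1, 1], [1, -1]])
        res = direction_concordance(con, ["p0", "p1"])
        assert res.n_used == 1 and res.n_excluded == 1

    def test_invariant_to_positive_rescaling(self):
        fc = np.random.default_rng(0).normal(size=(3, 50))
        a = direction_concordance(self._contrasts(list(fc)), [f"p{j}" for j in range(50)])
        b = direction_concordance(self._contrasts(list(fc * 7.3)), [f"p{j}" for j in range(50)])
        assert a.threeway == b.threeway and a.pairwise == b.pairwise

    def test_threeway_bounded_by_pairwise(self):
        fc = np.random.default_rng(1).normal(size=(3, 200))
        res = direction_concordance(self._contrasts(list(fc)), [f"p{j}" for j in range(200)])
        assert res.threeway <= min(res.pairwise.values()) + 1e-12

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            direction_concordance(self._contrasts([[1], [1], [1]]), [])


def _exact_clustering_p(n, k, s_obs):
    """Brute force: enumerate every placement of k affected genes among n ranks."""
    hits = total = 0
    for ranks in itertools.combinations(range(1, n + 1), k):
        s = float(_mean_nn_distance(np.array([ranks]))[0])
        total += 1
        hits += s <= s_obs + 1e-12
    return hits / total


class TestClusteringTest:
    def test_adjacent_pair_small_instance(self):
        """n=5 genes, affected at ranks {1,2}: S=1, exact p = 4/10."""
        positions = np.array([100, 200, 300, 400, 500])
        affected = np.array([True, True, False, False, False])
        res = clustering_test(positions, affected, b=20_000, seed=0)
        assert res.statistic == 1.0
        assert _exact_clustering_p(5, 2, 1.0) == pytest.approx(0.4)
        se = np.sqrt(0.4 * 0.6 / res.b)
        assert abs(res.p_value - 0.4) < 3 * se + 1e-3

    def test_rank_space_ignores_physical_spacing(self):
        # wildly uneven base-pair gaps, same rank structure -> same statistic
        positions = np.array([1, 2, 3_000_000, 90_000_000, 90_000_001])
        affected = np.array([True, True, False, False, False])
        res = clustering_test(positions, affected, b=100, seed=0)
        assert res.statistic == 1.0

    def test_all_affected_p_one(self):
        res = clustering_test(np.arange(6), np.ones(6, bool), b=100, seed=0)
        assert res.p_value == 1.0 and res.statistic == 1.0

    def test_too_few_affected_errors(self):
        with pytest.raises(ValueError, match="clustering undefined"):
            clustering_test(np.arange(5), np.array([True, False, False, False, False]))

    def test_matches_enumeration_on_small_instances(self):
        rng = np.random.default_rng(3)
        for n, k in [(6, 2), (7, 3), (8, 4)]:
            affected = np.zeros(n, bool)
            affected[rng.choice(n, k, replace=False)] = True
            res = clustering_test(np.arange(n) * 10, affected, b=40_000, seed=5)
            exact = _exact_clustering_p(n, k, res.statistic)
            se = np.sqrt(exact * (1 - exact) / res.b)
            assert abs(res.p_value - exact) < 3 * se + 1e-3


REGION = RegionConfig("chr11", 1000, 2000)


def _annot_at_distances(distances):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(distances))],
            "chromosome": "chr11",
            "midpoint": [2000 + d for d in distances],
            "region_class": "flank_cnv_chr",
        }
    ).set_index("probe_id", drop=False)


class TestBreakpointDistanceCorrelation:
    def test_perfectly_linear(self):
        annot = _annot_at_distances([10, 20, 30, 40])
        fc = pd.Series([0.1, 0.2, 0.3, 0.4], index=annot.index)
        res = breakpoint_distance_correlation(fc, annot, REGION)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        annot = _annot_at_distances([1, 2, 3])
        fc = pd.Series([1.0, 3.0, 2.0], index=annot.index)
        res = breakpoint_distance_correlation(fc, annot, REGION)
        assert res.r == pytest.approx(0.5)

    def test_magnitude_not_sign_is_used(self):
        annot = _annot_at_distances([10, 20, 30, 40])
        fc = pd.Series([-0.1, 0.2, -0.3, 0.4], index=annot.index)
        res = breakpoint_distance_correlation(fc, annot, REGION)
        assert res.r == pytest.approx(1.0)

    def test_constant_input_flagged_undefined(self):
        annot = _annot_at_distances([10, 20, 30])
        fc = pd.Series([0.5, 0.5, 0.5], index=annot.index)
        res = breakpoint_distance_correlation(fc, annot, REGION)
        assert not res.defined and np.isnan(res.r)

    def test_too_few_points_errors(self):
        annot = _annot_at_distances([10, 20])
        with pytest.raises(ValueError):
            breakpoint_distance_correlation(pd.Series([1.0, 2.0], index=annot.index), annot, REGION)

    def test_distance_uses_nearer_breakpoint(self):
        annot = _annot_at_distances([0])  # midpoint exactly at the right breakpoint
        annot.loc["p0", "midpoint"] = 990  # 10 left of interval start
        fc = pd.Series([1.0], index=annot.index)
        from cnvdosage.flank import breakpoint_distance

        assert breakpoint_distance(annot, REGION).iloc[0] == 10


class TestTissueBreadthComparison:
    def test_separated_groups_exact(self):
        breadth = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
        res = tissue_breadth_comparison(breadth, ["a", "b", "c"])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_groups_not_significant(self):
        breadth = pd.Series([1, 2, 3, 1, 2, 3], index=list("abcdef"), dtype=float)
        res = tissue_breadth_comparison(breadth, ["a", "b", "c"])
        assert res.p_value >= 0.99

    def test_empty_group_errors(self):
        breadth = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            tissue_breadth_comparison(breadth, [])


class TestExpressionLevelComparison:
    def test_constructed_separation_detected(self, small_dataset):
        ds = small_dataset
        wt_cols = ds.samples.index[
            (ds.samples.tissue == "heart") & (ds.samples.genotype == "2n_trans")
        ]
        level = ds.matrix[wt_cols.to_list()].mean(axis=1)
        top_decile = level.nlargest(len(level) // 10).index
        res = expression_level_comparison(ds.matrix, ds.samples, top_decile, "heart")
        assert res.comparison.p_value < 1e-6
        assert res.comparison.mean_a > res.comparison.mean_b

    def test_smooth_table_shape(self, small_dataset):
        ds = small_dataset
        stat = pd.Series(
            np.random.default_rng(0).random(len(ds.matrix)), index=ds.matrix.index
        )
        res = expression_level_comparison(
            ds.matrix, ds.samples, list(ds.matrix.index[:30]), "heart", stat
        )
        assert list(res.smooth.columns) == ["level", "statistic", "smoothed"]
        assert len(res.smooth) == len(ds.matrix)
        assert res.smooth["level"].is_monotonic_increasing


class TestPlatformConcordance:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert platform_concordance(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_r_squared(self):
        assert platform_concordance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        assert platform_concordance(rng.normal(size=1000), rng.normal(size=1000)) < 0.01

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            platform_concordance([1, 2, 3], [1, 2])
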