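"""Group t-maps, cluster labeling, Monte-Carlo extent null, correction."""

import numpy as np
import pytest
from scipy import stats as spstats

from hemiconn.inference import (asymmetry_within_group_mask, correct_map,
                                extent_to_mm3, label_clusters,
                                one_sample_tmap, paired_tmap,
                                simulate_cluster_null, two_sample_tmap)
from hemiconn.rsfc import StatMap
from hemiconn.stats import one_sample_t, pooled_two_sample_t

SHAPE = (6, 5, 4)


def _maps(rng, n, shape=SHAPE):
    return [rng.standard_normal(shape) for _ in range(n)]


class TestOneSampleTmap:
    def test_hand_computed_value(self):
        """Values {1,2,3} at a voxel: t = 2/(1/sqrt(3)) = 3.4641."""
        maps = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
        out = one_sample_tmap(maps)
        assert out.values[0, 0, 0] == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert out.df == 2

    def test_zero_variance_rule(self):
        maps = [np.full((1, 1, 2), 5.0)] * 4
        out = one_sample_tmap(maps)
        assert (out.values == 0).all()
        assert out.meta["n_zero_variance"] == 2

    def test_sign_flip_negates_map(self, rng):
        maps = _maps(rng, 6)
        a = one_sample_tmap(maps).values
        b = one_sample_tmap([-m for m in maps]).values
        assert np.allclose(a, -b, atol=1e-12)

    def test_matches_scipy_oracle(self, rng):
        maps = _maps(rng, 8)
        got = one_sample_tmap(maps).values
        oracle = spstats.ttest_1samp(np.stack(maps), 0.0, axis=0).statistic
        assert np.allclose(got, oracle, atol=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            one_sample_tmap(_maps(rng, 2))


class TestPairedTmap:
    def test_equal_inputs_give_zero(self, rng):
        maps = _maps(rng, 5)
        out = paired_tmap(maps, [m.copy() for m in maps])
        assert (out.values == 0).all()

    def test_constant_differences_engage_zero_variance_rule(self, rng):
        # integer-valued maps keep the per-subject differences exactly 1
        a = [rng.integers(-5, 5, SHAPE).astype(float) for _ in range(4)]
        b = [m - 1.0 for m in a]
        out = paired_tmap(a, b)
        assert (out.values == 0).all()
        assert out.meta["n_zero_variance"] == np.prod(SHAPE)

    def test_identical_to_one_sample_on_differences(self, rng):
        a, b = _maps(rng, 7), _maps(rng, 7)
        diff = [x - y for x, y in zip(a, b)]
        assert np.array_equal(paired_tmap(a, b).values,
                              one_sample_tmap(diff).values)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal counts"):
            paired_tmap(_maps(rng, 3), _maps(rng, 4))


class TestTwoSampleTmap:
    def test_group_swap_negates_map(self, rng):
        g1, g2 = _maps(rng, 5), _maps(rng, 7)
        a = two_sample_tmap(g1, g2).values
        b = two_sample_tmap(g2, g1).values
        assert np.allclose(a, -b, atol=1e-12)

    def test_matches_per_voxel_formula_oracle(self, rng):
        """Pooled t equals the direct formula (and scipy) to 1e-10."""
        g1, g2 = _maps(rng, 6), _maps(rng, 9)
        out = two_sample_tmap(g1, g2)
        oracle = spstats.ttest_ind(np.stack(g1), np.stack(g2), axis=0)
        assert np.allclose(out.values, oracle.statistic, atol=1e-10)
        assert out.df == 13

    def test_printed_fa_summary_reproduces_p(self):
        """Right anterior cingulum FA: 0.471+/-0.064 (n=29) vs
        0.433+/-0.038 (n=24) gives pooled two-tailed p = 0.014."""
        res = pooled_two_sample_t(0.471, 0.064, 29, 0.433, 0.038, 24)
        assert round(res.p, 3) == 0.014

    def test_welch_option(self, rng):
        g1, g2 = _maps(rng, 6), _maps(rng, 9)
        out = two_sample_tmap(g1, g2, variance_rule="welch")
        oracle = spstats.ttest_ind(np.stack(g1), np.stack(g2), axis=0,
                                   equal_var=False)
        assert np.allclose(out.values, oracle.statistic, atol=1e-10)

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_tmap(_maps(rng, 1), _maps(rng, 4))


class TestLabelClusters:
    def test_face_sharing_voxels_form_one_cluster(self):
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = v[0, 0, 1] = 1.0
        table, _ = label_clusters(v, connectivity="faces")
        assert len(table) == 1
        assert table.loc[0, "extent_voxels"] == 2

    def test_edge_sharing_depends_on_connectivity(self):
        """Two voxels sharing only an edge: separate under faces,
        merged under faces+edges (3x3x3 toy-grid enumeration)."""
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = v[0, 1, 1] = 1.0
        faces, _ = label_clusters(v, connectivity="faces")
        edges, _ = label_clusters(v, connectivity="faces+edges")
        assert len(faces) == 2 and len(edges) == 1

    def test_full_mask_single_cluster(self):
        table, _ = label_clusters(np.ones(SHAPE))
        assert len(table) == 1
        assert table.loc[0, "extent_voxels"] == np.prod(SHAPE)

    def test_signs_labeled_separately(self):
        v = np.zeros((4, 1, 1))
        v[0, 0, 0] = v[1, 0, 0] = 2.0
        v[2, 0, 0] = v[3, 0, 0] = -2.0
        table, _ = label_clusters(v, connectivity="faces")
        assert len(table) == 2
        assert sorted(table["sign"]) == [-1, 1]

    def test_empty_map_empty_table(self):
        table, labels = label_clusters(np.zeros(SHAPE))
        assert len(table) == 0 and (labels == 0).all()

    def test_extent_mm3_column(self):
        v = np.zeros(SHAPE)
        v[0, 0, :3] = 1.0
        table, _ = label_clusters(v, voxel_volume_mm3=27.0)
        assert table.loc[0, "extent_mm3"] == 81.0


class TestVoxelVolume:
    @pytest.mark.parametrize("extent,mm3", [(14, 378.0), (13, 351.0), (10, 270.0)])
    def test_printed_extent_volume_pairs(self, extent, mm3):
        assert extent_to_mm3(extent) == mm3


class TestCorrectMap:
    def _blob_tmap(self, big=8.0):
        t = np.zeros((10, 10, 10))
        t[2:7, 3:7, 4] = big  # 5*4 = 20-voxel slab
        return StatMap(t, kind="t", df=29)

    def test_all_zero_map_gives_empty_table(self):
        tmap = StatMap(np.zeros((5, 5, 5)), kind="t", df=20)
        out, table = correct_map(tmap, 0.001, 14)
        assert len(table) == 0 and (out.values == 0).all()

    def test_planted_blob_survives_extent_threshold(self):
        out, table = correct_map(self._blob_tmap(), 0.001, 14)
        assert len(table) == 1
        assert table.loc[0, "extent_voxels"] == 20
        assert table.loc[0, "extent_mm3"] == 540.0
        assert np.count_nonzero(out.values) == 20

    def test_strict_inequality_at_boundary(self):
        """A 20-voxel cluster is removed when min_extent=20 (survival
        requires extent strictly greater than the cutoff)."""
        out, table = correct_map(self._blob_tmap(), 0.001, 20)
        assert len(table) == 0 and (out.values == 0).all()

    def test_analysis_mask_zeroes_outside(self):
        tmap = self._blob_tmap()
        mask = np.zeros((10, 10, 10), bool)
        mask[2:7, 3:5, 4] = True  # 10 voxels of the blob
        out, table = correct_map(tmap, 0.001, 5, analysis_mask=mask)
        assert np.count_nonzero(out.values) == 10

    def test_missing_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            correct_map(StatMap(np.zeros((2, 2, 2)), kind="t"), 0.001, 10)


class TestClusterNull:
    def test_voxel_p_one_saturates_and_returns_sentinel(self):
        mask = np.ones((4, 4, 4), bool)
        null = simulate_cluster_null(mask, fwhm_mm=0.0, voxel_p=1.0,
                                     n_iter=200, seed=0)
        assert null.extent_counts == {64: 200}
        assert null.k_star(0.05) is None

    def test_unsmoothed_null_matches_binomial_oracle(self):
        """fwhm=0, 50 voxels, voxel_p=0.001: P(any suprathreshold voxel)
        = 1 - 0.999^50 = 0.0488 by independence; the empirical rate and
        the derived extent thresholds agree with this closed form."""
        mask = np.ones((50, 1, 1), bool)
        null = simulate_cluster_null(mask, fwhm_mm=0.0, voxel_p=0.001,
                                     n_iter=2000, seed=1)
        p_any = 1.0 - 0.999 ** 50
        assert null.p_max_ge(1) == pytest.approx(p_any, abs=0.015)
        assert null.k_star(0.10) == 1   # 0.0488 <= 0.10 robustly
        assert null.k_star(0.01) == 2   # adjacent-pair probability ~5e-5

    def test_extent_threshold_monotone_in_voxel_p(self):
        mask = np.ones((12, 12, 12), bool)
        loose = simulate_cluster_null(mask, 6.0, 0.01, n_iter=300, seed=3)
        strict = simulate_cluster_null(mask, 6.0, 0.001, n_iter=300, seed=3)
        k_loose, k_strict = loose.k_star(0.05), strict.k_star(0.05)
        assert k_loose is not None and k_strict is not None
        assert k_loose >= k_strict

    def test_alpha_monotonicity_of_k_star(self):
        mask = np.ones((12, 12, 12), bool)
        null = simulate_cluster_null(mask, 6.0, 0.01, n_iter=300, seed=4)
        ks = [null.k_star(a) for a in (0.01, 0.05, 0.10, 0.2)]
        ks = [k for k in ks if k is not None]
        assert ks == sorted(ks, reverse=True)

    def test_invalid_inputs_rejected(self):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="n_iter"):
            simulate_cluster_null(mask, 6.0, 0.001, n_iter=50)
        with pytest.raises(ValueError, match="voxel_p"):
            simulate_cluster_null(mask, 6.0, 1.5, n_iter=200)
        with pytest.raises(ValueError, match="empty"):
            simulate_cluster_null(np.zeros((4, 4, 4), bool), 6.0, 0.001,
                                  n_iter=200)


class TestAsymmetryMask:
    def _binary(self, values):
        return StatMap(values.astype(np.uint8), kind="binary")

    def _tmap_like(self, values):
        return StatMap(values, kind="t", df=10)

    def test_empty_union_gives_empty_result(self):
        zero = self._tmap_like(np.zeros(SHAPE))
        paired = self._tmap_like(np.ones(SHAPE))
        out = asymmetry_within_group_mask(zero, zero, paired)
        assert (out.values == 0).all()

    def test_cluster_inside_union_retained_intact(self):
        union = np.zeros(SHAPE)
        union[1:4, 1:4, 1:3] = 3.0
        paired = np.zeros(SHAPE)
        paired[2:4, 2:4, 1:3] = 4.0
        out = asymmetry_within_group_mask(
            self._tmap_like(union), self._tmap_like(np.zeros(SHAPE)),
            self._tmap_like(paired))
        assert np.array_equal(out.values.astype(bool), paired != 0)

    def test_straddling_cluster_trimmed_to_overlap(self):
        """Voxels of a paired-t cluster outside the within-group union
        are dropped; the remainder is kept without re-checking extent."""
        lacc = np.zeros(SHAPE)
        lacc[0:2] = 2.0
        paired = np.zeros(SHAPE)
        paired[1:4] = 5.0
        out = asymmetry_within_group_mask(
            self._tmap_like(lacc), self._tmap_like(np.zeros(SHAPE)),
            self._tmap_like(paired))
        expected = np.zeros(SHAPE, bool)
        expected[1] = True
        assert np.array_equal(out.values.astype(bool), expected)


class TestSummaryStats:
    def test_printed_ai_summaries_give_p_below_point001(self):
        """One-sample t on the printed AI summaries: both groups show
        leftward FA asymmetry at p < 0.001."""
        controls = one_sample_t(-0.105, 0.144, 29)
        patients = one_sample_t(-0.135, 0.078, 24)
        assert controls.p < 0.001
        assert patients.p < 0.001
        assert controls.t < 0 and patients.t < 0

    def test_one_sample_matches_scipy(self, rng):
        x = rng.standard_normal(20) + 0.3
        res = one_sample_t(x.mean(), x.std(ddof=1), len(x))
        oracle = spstats.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_pooled_matches_scipy(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
        res = pooled_two_sample_t(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        oracle = spstats.ttest_ind(a, b)
        assert res.t == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)
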