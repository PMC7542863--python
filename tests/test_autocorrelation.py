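"""Global Moran, permutation inference, local Moran, LISA classification."""

import numpy as np
import pytest

import spatscreen as ss

from conftest import brute_force_moran, random_weights


class TestGlobalMoran:
    def test_path4_matches_hand_value(self):
        """4-node path, x=[1,2,3,4]: brute-force double loop gives 0.4 for
        row-standardized weights (frozen before the main implementation)."""
        neighbors = [np.array(v) for v in ([1], [0, 2], [1, 3], [2])]
        w = ss.SpatialWeights(
            ids=list("abcd"),
            neighbors=neighbors,
            weights=[np.ones(len(v)) for v in neighbors],
            style="binary",
        ).row_standardized()
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.moran_i(x, w) == pytest.approx(0.4, abs=1e-12)
        assert ss.moran_i(x, w) == pytest.approx(brute_force_moran(x, w.dense()), abs=1e-12)

    def test_checkerboard_is_negative(self):
        ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=4, cols=4))
        w = ss.build_queen_weights(geoms, ids).row_standardized()
        x = np.array([(i + j) % 2 for i in range(4) for j in range(4)], dtype=float)
        assert ss.moran_i(x, w) < 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 20))
            for style in ("binary", "row"):
                w = random_weights(rng, n, style)
                x = rng.normal(size=n)
                assert ss.moran_i(x, w) == pytest.approx(
                    brute_force_moran(x, w.dense()), abs=1e-12
                )

    def test_degenerate_inputs_rejected(self, w3):
        wr = w3.row_standardized()
        with pytest.raises(ValueError, match="variance"):
            ss.moran_i(np.ones(9), wr)
        with pytest.raises(ValueError, match="length"):
            ss.moran_i(np.arange(4.0), wr)

    def test_sem_pattern_positively_autocorrelated(self, study_fixture):
        w, x, beta, names, *_ = study_fixture
        y, _ = ss.simulate_outcome(
            w, x, ss.DgpConfig(process="sem", beta=tuple(beta), spatial_param=0.69, seed=2)
        )
        err = y - x @ beta
        assert ss.moran_i(err, w) > 0.2


class TestPermutationTest:
    def test_extreme_observed_gives_minimum_p(self, w10_row):
        # smooth gradient: stronger clustering than any label permutation
        x = np.arange(100, dtype=float)
        res = ss.moran_permutation_test(x, w10_row, n_perm=999, seed=4)
        assert res.p_sim == pytest.approx(1 / 1000)
        assert res.p_sim >= 1 / (res.n_perm + 1)

    def test_seed_reproducibility(self, w10_row):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        a = ss.moran_permutation_test(x, w10_row, n_perm=199, seed=11)
        b = ss.moran_permutation_test(x, w10_row, n_perm=199, seed=11)
        assert (a.i, a.p_sim, a.z_score) == (b.i, b.p_sim, b.z_score)
        c = ss.moran_permutation_test(x, w10_row, n_perm=199, seed=12)
        assert a.p_sim != c.p_sim or a.z_score != c.z_score

    def test_expected_value_is_minus_one_over_n_minus_1(self, w10_row):
        x = np.random.default_rng(0).normal(size=100)
        res = ss.moran_permutation_test(x, w10_row, n_perm=99, seed=0)
        assert res.expected_i == pytest.approx(-1 / 99)
        # permutation null centers near the theoretical expectation
        assert abs(res.perm_mean - res.expected_i) < 0.05

    def test_invalid_n_perm(self, w10_row):
        with pytest.raises(ValueError, match="n_perm"):
            ss.moran_permutation_test(np.arange(100.0), w10_row, n_perm=0)


class TestLocalMoran:
    def test_zero_deviation_gives_zero_local_i(self, w10_row):
        rng = np.random.default_rng(21)
        x = rng.normal(size=100)
        # x7 = mean(others) implies x7 = mean(all), i.e. z_7 = 0 exactly
        x[7] = np.delete(x, 7).mean()
        li = ss.local_moran(x, w10_row)
        assert li[7] == pytest.approx(0.0, abs=1e-10)

    def test_sum_equals_s0_times_global(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(6, 24))
            for style in ("binary", "row"):
                w = random_weights(rng, n, style)
                x = rng.normal(size=n)
                total = ss.local_moran(x, w, form="scaled").sum()
                assert total == pytest.approx(w.s0 * ss.moran_i(x, w), abs=1e-9)

    def test_positive_where_unit_and_neighbors_high(self, w10_row):
        x = np.zeros(100)
        block = [44, 45, 54, 55]  # 2x2 high block
        x[block] = 10.0
        li = ss.local_moran(x, w10_row)
        assert all(li[i] > 0 for i in block)

    def test_zproduct_form_is_unscaled(self, w10_row):
        x = np.random.default_rng(2).normal(size=100)
        scaled = ss.local_moran(x, w10_row, form="scaled")
        raw = ss.local_moran(x, w10_row, form="zproduct")
        z = x - x.mean()
        m2 = (z @ z) / 100
        assert np.allclose(scaled * m2, raw, atol=1e-12)


class TestLisa:
    def test_seeded_high_block_labeled_hh(self):
        """A high-value block inside a low background is an HH cluster; the
        low units adjacent to it are LH outliers or not significant."""
        ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=9, cols=9))
        w = ss.build_queen_weights(geoms, ids).row_standardized()
        rng = np.random.default_rng(8)
        x = rng.normal(10.0, 1.0, size=81)
        block = [i * 9 + j for i in (3, 4, 5) for j in (3, 4, 5)]
        x[block] += 50.0
        res = ss.lisa_conditional_permutation(x, w, n_perm=499, seed=5)
        assert res.label[4 * 9 + 4] == "HH"  # block core
        for i in block:
            assert res.quadrant[i] == "HH"
        ring = [2 * 9 + j for j in (3, 4, 5)]
        assert all(res.label[i] in ("LH", "NS") for i in ring)

    def test_labels_respect_alpha_and_quadrant(self, w10_row):
        x = np.random.default_rng(3).normal(size=100)
        res = ss.lisa_conditional_permutation(x, w10_row, n_perm=199, alpha=0.05, seed=1)
        for lab, q, p in zip(res.label, res.quadrant, res.p_sim):
            assert lab == (q if p < 0.05 else "NS")
        assert np.all(res.p_sim >= 1 / 200)

    def test_iid_data_mostly_ns(self, w10_row):
        """Under exchangeable data the expected share of significant labels
        is about alpha; demand at least (1 - 3*alpha) NS."""
        x = np.random.default_rng(44).normal(size=100)
        res = ss.lisa_conditional_permutation(x, w10_row, n_perm=499, alpha=0.05, seed=2)
        assert (res.label == "NS").mean() >= 0.85

    def test_island_always_ns(self):
        from shapely.geometry import box

        geoms = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(0, 1, 1, 2), box(9, 9, 10, 10)]
        w = ss.build_queen_weights(geoms).row_standardized()
        x = np.array([1.0, 5.0, 3.0, 100.0])
        res = ss.lisa_conditional_permutation(x, w, n_perm=99, seed=0)
        assert res.label[3] == "NS"
        assert res.local_i[3] == 0.0

    def test_unit_order_independence(self, w10_row):
        """Each unit draws from its own keyed stream: permuting two calls'
        evaluation order cannot change per-unit p-values (same seed)."""
        x = np.random.default_rng(10).normal(size=100)
        a = ss.lisa_conditional_permutation(x, w10_row, n_perm=99, seed=7)
        b = ss.lisa_conditional_permutation(x, w10_row, n_perm=99, seed=7)
        assert np.array_equal(a.p_sim, b.p_sim)
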