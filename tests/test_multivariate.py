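"""Distances, NMDS, PERMANOVA, Mantel, envfit, varpart, univariate helpers.

Permutation machinery is checked against independent oracles: exhaustive
enumeration implemented directly in the tests, the classical-ANOVA identity
for Euclidean one-way PERMANOVA, and scikit-bio's implementations.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import fwdfungi as f
from fwdfungi.multivariate import DistanceMatrix, envfit, group_tests, spearman


def dist_of(points, metric="euclidean", ids=None):
    return f.pairwise_distances(np.asarray(points, dtype=float), metric, ids=ids)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        d = dist_of([[1, 2], [1, 2], [3, 4]])
        assert d.data[0, 1] == 0.0

    def test_three_four_five(self):
        d = dist_of([[0, 0], [3, 4]])
        assert d.data[0, 1] == pytest.approx(5.0)

    def test_bray_curtis_disjoint_is_one(self):
        d = dist_of([[2, 0], [0, 2]], metric="bray_curtis")
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_rejects_negative(self):
        with pytest.raises(ValueError):
            dist_of([[1, -1], [0, 2]], metric="bray_curtis")

    def test_symmetry_and_zero_diagonal(self, rng):
        d = dist_of(rng.normal(size=(7, 4)))
        assert np.allclose(d.data, d.data.T)
        assert np.all(np.diag(d.data) == 0)


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        d = DistanceMatrix(["a", "b", "c"], 1 - np.eye(3))
        res = f.nmds(d, n_starts=3, seed=0)
        assert res.stress <= 1e-6

    def test_planar_points_self_embed(self, rng):
        pts = rng.normal(size=(10, 2))
        res = f.nmds(dist_of(pts), n_starts=6, seed=1)
        assert res.stress <= 0.01

    def test_stress_history_non_increasing(self, rng):
        pts = rng.normal(size=(12, 6))
        res = f.nmds(dist_of(pts), n_starts=4, seed=2)
        hist = np.array(res.stress_history)
        assert np.all(np.diff(hist) <= 1e-15)

    def test_best_solution_beats_metric_start(self, rng):
        pts = rng.normal(size=(15, 8))
        res = f.nmds(dist_of(pts), n_starts=4, seed=3)
        assert res.stress <= res.metric_start_stress + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            f.nmds(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


def brute_force_permanova_p(values, labels):
    """Oracle: exact one-way permutation p via classical F over all label splits."""

    def f_stat(lab):
        groups = [values[np.asarray(lab) == g] for g in sorted(set(lab))]
        return scipy.stats.f_oneway(*groups).statistic

    observed = f_stat(labels)
    arrangements = sorted(set(itertools.permutations(labels)))
    count = sum(1 for arr in arrangements if f_stat(arr) >= observed - 1e-12)
    return count / len(arrangements), len(arrangements)


class TestPermanova:
    def test_exact_enumeration_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=6)
        values[3:] += 1.5
        labels = ["a", "a", "a", "b", "b", "b"]
        d = dist_of(values[:, None])
        res = f.permanova(d, labels, exact=True)["factor"]
        p_oracle, n_arr = brute_force_permanova_p(values, labels)
        assert n_arr == 20
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(p_oracle)

    def test_mcardle_anderson_identity(self, rng):
        """Euclidean one-way pseudo-F equals the classical ANOVA F."""
        values = rng.normal(size=12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        d = dist_of(values[:, None])
        res = f.permanova(d, labels, n_perm=9, seed=0)["factor"]
        groups = [values[i : i + 4] for i in (0, 4, 8)]
        classical = scipy.stats.f_oneway(*groups).statistic
        assert res.statistic == pytest.approx(classical, abs=1e-9)

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(12, 5))
        pts[:6] += 0.8
        labels = ["a"] * 6 + ["b"] * 6
        d = dist_of(pts)
        mine = f.permanova(d, labels, n_perm=99, seed=0)["factor"].statistic
        theirs = skbio_permanova(SkbioDM(d.data, ids=d.ids), grouping=labels, permutations=0)
        assert mine == pytest.approx(float(theirs["test statistic"]), abs=1e-9)

    def test_type_one_error_calibrated_under_null(self, rng):
        """Exchangeable labels: exact p is (sub)uniform, never below 1/20."""
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            values = rng.normal(size=6)
            d = dist_of(values[:, None])
            p = f.permanova(d, ["a"] * 3 + ["b"] * 3, exact=True)["factor"].p_value
            assert p >= 0.05 - 1e-12  # minimum attainable exact p is 1/20
            if p < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.10

    def test_separated_groups_reach_minimum_p(self, rng):
        # 8 + 8 so a random permutation essentially never recreates the
        # original split; the observed pseudo-F is then strictly maximal
        pts = rng.normal(size=(16, 2)) * 0.01
        pts[8:] += 100.0
        d = dist_of(pts)
        res = f.permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=1)["factor"]
        assert res.p_value == pytest.approx(1 / 200)

    def test_two_way_with_interaction_terms(self, rng):
        n = 24
        tree = ["beech", "fir"] * (n // 2)
        canopy = ["open"] * (n // 2) + ["closed"] * (n // 2)
        pts = rng.normal(size=(n, 3))
        pts[np.array(tree) == "beech"] += 1.0
        d = dist_of(pts)
        res = f.permanova(d, pd.DataFrame({"tree": tree, "canopy": canopy}), n_perm=99, seed=0)
        assert set(res) == {"tree", "canopy", "tree:canopy"}
        assert res["tree"].statistic > res["canopy"].statistic

    def test_single_level_factor_rejected(self, rng):
        d = dist_of(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            f.permanova(d, ["a", "a", "a", "a"])

    def test_reproducible_under_seed(self, rng):
        pts = rng.normal(size=(10, 3))
        d = dist_of(pts)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = f.permanova(d, labels, n_perm=99, seed=7)["factor"]
        r2 = f.permanova(d, labels, n_perm=99, seed=7)["factor"]
        assert r1.p_value == r2.p_value


class TestMantel:
    def test_identity_gives_r_one(self, rng):
        d = dist_of(rng.normal(size=(8, 3)))
        res = f.mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_scale_invariance_under_pearson(self, rng):
        d = dist_of(rng.normal(size=(8, 3)))
        d2 = DistanceMatrix(d.ids, 2.0 * d.data)
        res = f.mantel(d, d2, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_joint_relabeling_invariance(self, rng):
        a = dist_of(rng.normal(size=(9, 4)))
        b = dist_of(rng.normal(size=(9, 4)))
        perm = rng.permutation(9)
        ap = DistanceMatrix([a.ids[i] for i in perm], a.data[np.ix_(perm, perm)])
        bp = DistanceMatrix([b.ids[i] for i in perm], b.data[np.ix_(perm, perm)])
        r1 = f.mantel(a, b, n_perm=0, seed=0).statistic
        r2 = f.mantel(ap, bp, n_perm=0, seed=0).statistic
        assert r1 == pytest.approx(r2)

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = dist_of(rng.normal(size=(10, 4)))
        b = dist_of(rng.normal(size=(10, 4)), ids=a.ids)
        mine = f.mantel(a, b, n_perm=0, seed=0).statistic
        theirs = skbio_mantel(
            SkbioDM(a.data, ids=a.ids), SkbioDM(b.data, ids=b.ids), permutations=0
        )
        # scikit-bio >= 0.7 returns a MantelResult object
        corr = getattr(theirs, "correlation", None)
        if corr is None:
            corr = theirs[0]
        assert mine == pytest.approx(float(corr), abs=1e-9)

    def test_null_behaviour_independent_matrices(self):
        rng = np.random.default_rng(2024)
        small_r, nonmin_p = 0, 0
        n_rep = 60
        for _ in range(n_rep):
            a = dist_of(rng.normal(size=(20, 3)))
            b = dist_of(rng.normal(size=(20, 3)), ids=a.ids)
            res = f.mantel(a, b, n_perm=99, seed=int(rng.integers(2**31)))
            if abs(res.statistic) < 0.3:
                small_r += 1
            if res.p_value > 0.01:
                nonmin_p += 1
        assert small_r / n_rep >= 0.95
        assert nonmin_p / n_rep >= 0.95

    def test_id_mismatch_rejected(self, rng):
        a = dist_of(rng.normal(size=(5, 2)))
        b = dist_of(rng.normal(size=(5, 2)), ids=list("vwxyz"))
        with pytest.raises(ValueError):
            f.mantel(a, b)


class TestEnvfit:
    def test_axis_aligned_variable(self, rng):
        coords = rng.normal(size=(20, 2))
        res = envfit(coords, coords[:, 0], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert res.direction[1] == pytest.approx(0.0, abs=1e-9)

    def test_constant_variable_reported_missing(self, rng):
        coords = rng.normal(size=(10, 2))
        res = envfit(coords, np.full(10, 3.3), n_perm=99, seed=0)
        assert math.isnan(res.r2)

    def test_noisy_axis_keeps_high_r2(self, rng):
        coords = rng.normal(size=(50, 2))
        v = coords[:, 0] + rng.normal(scale=0.1 * coords[:, 0].std(), size=50)
        res = envfit(coords, v, n_perm=99, seed=0)
        assert res.r2 >= 0.9

    def test_missing_values_rejected(self, rng):
        coords = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            envfit(coords, np.array([1.0, np.nan, 2.0, 3.0, 4.0]))


class TestVarpart:
    def test_fraction_identities_on_random_data(self, rng):
        y = rng.normal(size=(30, 6))
        x1 = rng.normal(size=(30, 2))
        x2 = rng.normal(size=(30, 3))
        vp = f.variation_partitioning(y, x1, x2, n_perm=9, seed=0)
        assert vp.a + vp.b == pytest.approx(vp.adj_r2_x1, abs=1e-9)
        assert vp.b + vp.c == pytest.approx(vp.adj_r2_x2, abs=1e-9)
        assert vp.a + vp.b + vp.c == pytest.approx(vp.adj_r2_both, abs=1e-9)

    def test_identical_blocks_have_no_pure_fractions(self, rng):
        y = rng.normal(size=(20, 4))
        x = rng.normal(size=(20, 2))
        vp = f.variation_partitioning(y, x, x.copy(), n_perm=9, seed=0)
        assert vp.a == pytest.approx(0.0, abs=1e-9)
        assert vp.c == pytest.approx(0.0, abs=1e-9)
        assert vp.b == pytest.approx(vp.adj_r2_x1, abs=1e-9)

    def test_orthogonal_single_source_construction(self):
        # balanced orthogonal 2x2 design; community an exact function of X1
        x1 = np.array([0.0, 0, 1, 1] * 4)
        x2 = np.array([0.0, 1, 0, 1] * 4)
        y = np.column_stack([2.0 * x1 - 1.0, -x1])
        vp = f.variation_partitioning(y, x1, x2, n_perm=9, seed=0)
        # unadjusted pure-X2 and shared fractions vanish
        c_raw = vp.r2_both - vp.r2_x1
        b_raw = vp.r2_x1 + vp.r2_x2 - vp.r2_both
        assert abs(c_raw) < 1e-9
        assert abs(b_raw) < 1e-9

    def test_matches_vegan_style_adjustment(self, rng):
        # adjusted R2 formula spot check: 1 - (1-R2)(n-1)/(n-p-1)
        y = rng.normal(size=(25, 3))
        x1 = rng.normal(size=(25, 2))
        x2 = rng.normal(size=(25, 1))
        vp = f.variation_partitioning(y, x1, x2, n_perm=9, seed=0)
        assert vp.adj_r2_x1 == pytest.approx(1 - (1 - vp.r2_x1) * 24 / (25 - 2 - 1), abs=1e-12)

    def test_saturated_design_rejected(self, rng):
        y = rng.normal(size=(4, 2))
        x1 = rng.normal(size=(4, 2))
        x2 = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            f.variation_partitioning(y, x1, x2, n_perm=9)


class TestUnivariate:
    def test_spearman_perfect_and_reversed(self):
        x = np.arange(5.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_hand_example(self):
        rho, _ = spearman(np.array([1, 2, 3, 4, 5]), np.array([1, 3, 2, 5, 4]))
        assert rho == pytest.approx(0.8)

    def test_spearman_constant_is_missing(self):
        rho, p = spearman(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))
        assert math.isnan(rho) and math.isnan(p)

    def test_kruskal_zero_for_identical_values(self):
        res = group_tests(np.ones(8), ["a", "b"] * 4)
        assert res["kruskal"]["statistic"] == 0.0

    def test_one_factor_f_equals_squared_t(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 1
        values = np.concatenate([a, b])
        res = group_tests(values, ["a"] * 6 + ["b"] * 6)
        t = scipy.stats.ttest_ind(a, b).statistic
        assert res["factor"]["statistic"] == pytest.approx(t**2, abs=1e-9)

    def test_balanced_two_way_exact_decomposition(self):
        # cell means 0/0/1/1 along factor A, two replicates, no noise
        a = ["lo"] * 4 + ["hi"] * 4
        b = ["x", "x", "y", "y"] * 2
        values = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        res = group_tests(values, pd.DataFrame({"A": a, "B": b}))
        assert res["A"]["ss"] == pytest.approx(2.0, abs=1e-9)
        assert res["A:B"]["ss"] == pytest.approx(0.0, abs=1e-9)
        assert res["A"]["statistic"] == math.inf or res["A"]["statistic"] > 1e10

    def test_two_way_type_two_on_unbalanced_data(self, rng):
        a = ["lo"] * 5 + ["hi"] * 7
        b = (["x", "y"] * 6)[:12]
        values = rng.normal(size=12) + (np.array(a) == "hi")
        res = group_tests(values, pd.DataFrame({"A": a, "B": b}))
        assert {"A", "B", "A:B"} <= set(res)
        assert res["A"]["p_value"] <= 1.0

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            group_tests(np.arange(4.0), ["a"] * 4)
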