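"""Statistical battery: df bookkeeping, oracle equivalences, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from palasym.stats import (
    bonferroni,
    dispersion_homogeneity,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    oneway_anova,
    permanova,
    procrustes_anova_symmetry,
    spearman_matrix,
    tukey_hsd,
)


class TestProcrustesAnova:
    def _paired(self, rng, n, asym=0.0):
        base = rng.normal(size=(n, 10, 3))
        shift = np.zeros((10, 3))
        shift[0, 0] = asym
        O = base + shift / 2
        R = base - shift / 2 + 0.05 * rng.normal(size=(n, 10, 3))
        return O, R

    @pytest.mark.parametrize("n, df", [(5, 4), (82, 81)])
    def test_df_structure(self, rng, n, df):
        O, R = self._paired(rng, n)
        tab = procrustes_anova_symmetry(O, R, n_perm=9, seed=0)
        assert tab.set_index("effect")["df"].to_dict() == {
            "Ind": df, "Reflections": 1, "Ind X Reflections": df,
        }

    def test_perfectly_symmetric_data_has_zero_reflection_ss(self, rng):
        base = rng.normal(size=(6, 10, 3))
        tab = procrustes_anova_symmetry(base, base.copy(), n_perm=9, seed=0)
        assert tab.loc[tab.effect == "Reflections", "SS"].item() == pytest.approx(0.0, abs=1e-20)
        assert tab.loc[tab.effect == "Ind X Reflections", "SS"].item() == pytest.approx(0.0, abs=1e-20)

    def test_ss_matches_brute_force_cell_mean_decomposition(self, rng):
        O, R = self._paired(rng, 7, asym=0.3)
        tab = procrustes_anova_symmetry(O, R, n_perm=9, seed=0).set_index("effect")
        Y = np.stack([O.reshape(7, -1), R.reshape(7, -1)])  # (side, ind, coord)
        grand = Y.mean(axis=(0, 1))
        ind_mean = Y.mean(axis=0)
        side_mean = Y.mean(axis=1)
        ss_ind = 2 * ((ind_mean - grand) ** 2).sum()
        ss_side = 7 * ((side_mean - grand) ** 2).sum()
        resid = Y - ind_mean[None] - side_mean[:, None] + grand
        ss_inter = (resid**2).sum()
        assert tab.loc["Ind", "SS"] == pytest.approx(ss_ind, abs=1e-10)
        assert tab.loc["Reflections", "SS"] == pytest.approx(ss_side, abs=1e-10)
        assert tab.loc["Ind X Reflections", "SS"] == pytest.approx(ss_inter, abs=1e-10)

    def test_strong_asymmetry_is_detected(self, rng):
        O, R = self._paired(rng, 12, asym=2.0)
        tab = procrustes_anova_symmetry(O, R, n_perm=199, seed=1)
        assert tab.loc[tab.effect == "Reflections", "p"].item() == pytest.approx(1 / 200)

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        O, R = self._paired(rng, 10, asym=3.0)
        tab = procrustes_anova_symmetry(O, R, n_perm=499, seed=2)
        assert tab["p"].min() >= 1 / 500

    def test_single_individual_raises(self, rng):
        O, R = self._paired(rng, 1)
        with pytest.raises(ValueError):
            procrustes_anova_symmetry(O, R)


class TestOnewayAnova:
    def test_df_for_six_groups_of_41(self, rng):
        vals = rng.normal(size=246)
        labs = np.repeat([f"g{i}" for i in range(6)], 41)
        tab = oneway_anova(vals, labs)
        assert list(tab["df"]) == [5, 240]

    def test_all_equal_values_give_zero_f(self):
        tab = oneway_anova(np.ones(12), np.repeat(["a", "b", "c"], 4))
        assert tab.loc[0, "SS"] == 0.0 and tab.loc[0, "F"] == 0.0

    def test_hand_worked_three_group_example(self):
        vals = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        labs = np.repeat(["a", "b", "c"], 3)
        tab = oneway_anova(vals, labs)
        # means 2,3,4; grand 3; SSB = 3*(1+0+1) = 6; SSW = 6; F = (6/2)/(6/6)
        assert tab.loc[0, "SS"] == pytest.approx(6.0, abs=1e-12)
        assert tab.loc[1, "SS"] == pytest.approx(6.0, abs=1e-12)
        assert tab.loc[0, "F"] == pytest.approx(3.0, abs=1e-9)
        assert tab.loc[0, "p"] == pytest.approx(float(sps.f.sf(3.0, 2, 6)), abs=1e-12)

    def test_empty_label_raises(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 2.0], ["a", "a"])


class TestTukey:
    def test_identical_groups(self, rng):
        g = rng.normal(size=8)
        tab = tukey_hsd(np.concatenate([g, g]), np.repeat(["a", "b"], 8))
        assert tab.loc[0, "diff"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc[0, "p_adj"] > 0.99

    def test_six_groups_give_fifteen_pairs(self, rng):
        vals = rng.normal(size=60)
        labs = np.repeat([f"g{i}" for i in range(6)], 10)
        assert len(tukey_hsd(vals, labs)) == 15

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = rng.normal(size=24)
        vals[8:16] += 1.0
        labs = np.repeat(["g1", "g2", "g3"], 8)
        mine = tukey_hsd(vals, labs)
        sm = pairwise_tukeyhsd(vals, labs)
        ref = np.array(sm.summary().data[1:], dtype=object)
        for row, (g1, g2, diff, p, lwr, upr, _) in zip(mine.itertuples(), ref):
            assert row.pair == f"{g2}-{g1}"
            assert row.diff == pytest.approx(float(diff), abs=1e-4)
            assert row.lwr == pytest.approx(float(lwr), abs=1e-4)
            assert row.upr == pytest.approx(float(upr), abs=1e-4)
            assert row.p_adj == pytest.approx(float(p), abs=1e-4)


class TestPermanova:
    def test_univariate_pseudo_f_equals_classical_f(self, rng):
        vals = rng.normal(size=30)
        labs = np.repeat(["a", "b", "c"], 10)
        D = np.abs(vals[:, None] - vals[None, :])
        pf = permanova(D, labs, n_perm=9, seed=0).f
        cf = oneway_anova(vals, labs).loc[0, "F"]
        assert pf == pytest.approx(cf, rel=1e-10)

    def test_matches_skbio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(24, 4))
        X[12:] += 0.7
        labs = np.array(["a"] * 12 + ["b"] * 12)
        D = squareform(pdist(X))
        mine = permanova(D, labs, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(skbio.DistanceMatrix(D), labs, permutations=99)
        assert mine.f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_separated_clusters_hit_the_p_floor(self, rng):
        X = rng.normal(size=(30, 3))
        X[15:] += 50.0
        labs = np.array(["a"] * 15 + ["b"] * 15)
        res = permanova(squareform(pdist(X)), labs, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_label_length_mismatch(self, rng):
        D = squareform(pdist(rng.normal(size=(10, 2))))
        with pytest.raises(ValueError):
            permanova(D, ["a"] * 9, n_perm=9, seed=0)

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(20, 3))
        labs = np.repeat(["a", "b"], 10)
        D = squareform(pdist(X))
        p1 = permanova(D, labs, n_perm=199, seed=7).p
        p2 = permanova(D, labs, n_perm=199, seed=7).p
        assert p1 == p2


class TestDispersion:
    def test_identical_internal_geometry_not_significant(self, rng):
        X = rng.normal(size=(15, 4))
        Y = X + 10.0  # translated copy: identical dispersion
        D = squareform(pdist(np.vstack([X, Y])))
        labs = np.repeat(["a", "b"], 15)
        res = dispersion_homogeneity(D, labs, n_perm=199, seed=0)
        assert res.f == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_scaled_group_is_detected(self, rng):
        X = rng.normal(size=(30, 4))
        Y = 3.0 * rng.normal(size=(30, 4))
        D = squareform(pdist(np.vstack([X, Y])))
        labs = np.repeat(["a", "b"], 30)
        res = dispersion_homogeneity(D, labs, n_perm=199, seed=1)
        assert res.p <= 0.05
        assert res.group_dispersion["b"] > res.group_dispersion["a"]

    def test_pcoa_embedding_reproduces_euclidean_distances(self, rng):
        from palasym.stats import _pcoa_embedding

        X = rng.normal(size=(12, 5))
        D = squareform(pdist(X))
        pos, neg = _pcoa_embedding(D)
        assert neg.shape[1] == 0
        D2 = squareform(pdist(pos))
        np.testing.assert_allclose(D2, D, atol=1e-8)


class TestKruskalWallis:
    def test_hand_worked_small_example(self):
        # ranks 1..6, groups {1,2},{3,4},{5,6}: H = 12/(6*7) * (2*(1.5-3.5)^2
        #   + 2*(3.5-3.5)^2 + 2*(5.5-3.5)^2) / 1 -> 12/42 * 16 = 32/7
        vals = [1.0, 2.0, 10.0, 11.0, 20.0, 21.0]
        labs = ["a", "a", "b", "b", "c", "c"]
        h, df, p = kruskal_wallis(vals, labs)
        assert df == 2
        assert h == pytest.approx(32.0 / 7.0, abs=1e-9)

    def test_two_groups_equal_z_squared(self, rng):
        vals = rng.normal(size=20)
        labs = np.repeat(["a", "b"], 10)
        h, _, _ = kruskal_wallis(vals, labs)
        z = dunn_posthoc(vals, labs).loc[0, "Z"]
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_all_tied_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="tied"):
            h, df, p = kruskal_wallis([1.0] * 9, ["a", "b", "c"] * 3)
        assert h == 0.0 and p == 1.0


class TestDunn:
    def test_41_labels_give_820_pairs(self, rng):
        vals = rng.normal(size=41 * 6)
        labs = np.repeat([str(i) for i in range(1, 42)], 6)
        assert len(dunn_posthoc(vals, labs)) == 41 * 40 // 2

    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=10)
        tab = dunn_posthoc(np.concatenate([g, g + 1e-9]), np.repeat(["a", "b"], 10))
        assert abs(tab.loc[0, "Z"]) < 1.0 and tab.loc[0, "p_adj"] > 0.3

    def test_matches_independent_rank_computation(self, rng):
        vals = rng.normal(size=18)
        labs = np.repeat(["a", "b", "c"], 6)
        tab = dunn_posthoc(vals, labs).set_index("pair")
        order = np.argsort(np.argsort(vals)) + 1.0  # no ties: plain ranks
        N = len(vals)
        var = N * (N + 1) / 12.0
        for a, b in itertools.combinations(["a", "b", "c"], 2):
            ra = order[np.array(labs) == a].mean()
            rb = order[np.array(labs) == b].mean()
            z = (ra - rb) / np.sqrt(var * (1 / 6 + 1 / 6))
            assert tab.loc[f"{a}-{b}", "Z"] == pytest.approx(z, abs=1e-9)
            p = 2 * sps.norm.sf(abs(z))
            assert tab.loc[f"{a}-{b}", "p_adj"] == pytest.approx(min(1.0, 3 * p), abs=1e-9)


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        row = rng.normal(size=41)
        m = spearman_matrix(np.vstack([row, row]))
        assert m.iloc[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        a = np.arange(41, dtype=float)
        m = spearman_matrix(np.vstack([a, a[::-1]]))
        assert m.iloc[0, 1] == pytest.approx(-1.0)

    def test_equals_pearson_on_midranks(self, rng):
        X = rng.normal(size=(4, 41))
        X[1, :5] = X[1, 5]  # force ties -> midranks
        m = spearman_matrix(X)
        for i, j in itertools.combinations(range(4), 2):
            ri = sps.rankdata(X[i])
            rj = sps.rankdata(X[j])
            ref = np.corrcoef(ri, rj)[0, 1]
            assert m.iloc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_constant_profile_flagged(self, rng):
        X = np.vstack([np.ones(41), rng.normal(size=41)])
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(X)
        assert np.isnan(m.iloc[0, 1])


class TestMannWhitney:
    def test_fully_separated_n3_exact_p(self):
        u, p, method = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert method == "exact"
        assert p == pytest.approx(0.1)  # 2 extreme of C(6,3)=20 arrangements

    def test_identical_samples_tie_handling(self):
        u, p, method = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert method == "asymptotic"  # ties force the approximation
        assert p == pytest.approx(1.0)

    def test_exact_matches_full_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        u_obs, p_obs, method = mann_whitney(x, y)
        assert method == "exact"
        pooled = np.concatenate([x, y])
        n, m = len(x), len(y)
        stats = []
        for comb in itertools.combinations(range(n + m), n):
            xs = pooled[list(comb)]
            ys = np.delete(pooled, list(comb))
            u = sum((xi > yj) for xi in xs for yj in ys)
            stats.append(u)
        stats = np.array(stats, dtype=float)
        mu = n * m / 2.0
        p_enum = np.mean(np.abs(stats - mu) >= abs(u_obs - mu) - 1e-12)
        assert p_obs == pytest.approx(p_enum, abs=1e-12)

    def test_large_sample_matches_normal_formula(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=35) + 0.3
        u, p, method = mann_whitney(x, y)
        assert method == "asymptotic"
        n, m = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        r1 = ranks[:n].sum()
        u1 = r1 - n * (n + 1) / 2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        N = n + m
        tie = ((counts**3 - counts).sum()) / (N * (N - 1))
        sd = np.sqrt(n * m / 12 * (N + 1 - tie))
        z = (abs(u1 - n * m / 2) - 0.5) / sd
        assert p == pytest.approx(2 * sps.norm.sf(z), abs=1e-9)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5], m=3), [1.0])
        np.testing.assert_allclose(bonferroni([0.2, 0.7]), [0.4, 1.0])
        np.testing.assert_allclose(bonferroni([0.3], m=1), [0.3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])
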