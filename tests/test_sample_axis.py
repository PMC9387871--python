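import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from nmfomics.containers import SampleSheet
from nmfomics.sample_axis import (anova_across_clusters, cluster_group_chi2,
                                  information_gain, kmeans_clusters,
                                  logistic_auc, mann_whitney_per_factor,
                                  rank_auc)


def _sheet(n_case, n_control):
    ids = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    return SampleSheet(pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * n_control},
        index=pd.Index(ids, name="sample_id")))


def _H(rows, sheet):
    return pd.DataFrame(rows, index=[f"LF{i+1}" for i in range(len(rows))],
                        columns=sheet.samples)


def brute_force_mwu_p(x, y):
    """Exact two-sided MWU p by enumerating all group labelings (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    u_obs = min(u_obs, n1 * len(y) - u_obs)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum((xi > yj) for xi in xs for yj in ys)
        us.append(min(u, n1 * len(ys) - u))
    us = np.array(us)
    return float(np.mean(us <= u_obs))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        sheet = _sheet(3, 3)
        tests = mann_whitney_per_factor(_H([[4, 5, 6, 1, 2, 3]], sheet), sheet)
        assert tests[0].U == 0
        assert tests[0].p_value == pytest.approx(0.1)
        assert tests[0].direction == 1

    def test_all_ties(self):
        sheet = _sheet(3, 3)
        tests = mann_whitney_per_factor(_H([[2, 2, 2, 2, 2, 2]], sheet), sheet)
        assert tests[0].U == 9 / 2
        assert tests[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 5, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            sheet = _sheet(n1, n2)
            t = mann_whitney_per_factor(_H([np.concatenate([x, y])], sheet), sheet)[0]
            assert t.p_value == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        sheet = _sheet(10, 12)
        vals = rng.normal(size=22)
        p1 = mann_whitney_per_factor(_H([vals], sheet), sheet)[0].p_value
        p2 = mann_whitney_per_factor(_H([np.exp(vals)], sheet), sheet)[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        sheet = _sheet(1, 5)
        with pytest.raises(ValueError, match="2 samples per group"):
            mann_whitney_per_factor(_H([np.arange(6.0)], sheet), sheet)


class TestLogisticAuc:
    def test_perfect_separation_auc_one(self):
        sheet = _sheet(5, 5)
        H = _H([[3, 4, 5, 3.5, 4.5, 0, 1, 2, 0.5, 1.5]], sheet)
        _, auc = logistic_auc(H, sheet)
        assert auc == 1.0

    def test_constant_scores_auc_half(self):
        assert rank_auc(np.ones(10), np.array([True] * 4 + [False] * 6)) == 0.5

    def test_auc_equals_rank_statistic_of_scores(self, rng):
        sheet = _sheet(12, 9)
        H = _H(rng.uniform(0, 2, size=(3, 21)), sheet)
        coef, auc = logistic_auc(H, sheet)
        # recompute scores from coefficients; AUC must equal U/(n1 n2)
        X = H.to_numpy().T
        eta = coef["coef"].iloc[0] + X @ coef["coef"].iloc[1:].to_numpy()
        y = sheet.group.to_numpy() == "case"
        u = ss.mannwhitneyu(eta[y], eta[~y], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (y.sum() * (~y).sum()))

    def test_coefficients_match_statsmodels_when_well_conditioned(self, rng):
        import statsmodels.api as sm

        sheet = _sheet(40, 40)
        x = np.concatenate([rng.normal(0.8, 1, 40), rng.normal(-0.2, 1, 40)])
        H = _H([np.abs(x) + 0.1, rng.uniform(0, 1, 80)], sheet)
        H.iloc[0] = x - x.min() + 0.1  # keep non-negative, keep signal
        coef, _ = logistic_auc(H, sheet)
        y = (sheet.group == "case").astype(float).to_numpy()
        X = sm.add_constant(H.to_numpy().T)
        fit = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(coef["coef"], fit.params, rtol=1e-3, atol=1e-4)
        np.testing.assert_allclose(coef["p"], fit.pvalues, rtol=1e-2, atol=1e-4)


class TestKMeans:
    def test_separated_blobs_recovered(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.vstack([r.normal(0, 0.3, size=(10, 3)),
                             r.normal(8, 0.3, size=(12, 3))])
            X = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(22)])
            labels = kmeans_clusters(X, 2, seed=seed)
            first, second = labels.iloc[:10], labels.iloc[10:]
            assert first.nunique() == 1 and second.nunique() == 1
            assert first.iloc[0] != second.iloc[0]

    def test_k_equals_n_gives_singletons(self, rng):
        X = pd.DataFrame(rng.uniform(size=(2, 6)), columns=list("abcdef"))
        labels = kmeans_clusters(X, 6, seed=0)
        assert labels.nunique() == 6

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.uniform(size=(3, 15)))
        a = kmeans_clusters(X, 3, seed=5)
        b = kmeans_clusters(X, 3, seed=5)
        assert (a == b).all()


class TestInformationGain:
    def test_single_cluster_zero(self):
        sheet = _sheet(4, 4)
        a = pd.Series(0, index=sheet.samples)
        assert information_gain(a, sheet) == pytest.approx(0.0)

    def test_pure_balanced_clusters_one_bit(self):
        sheet = _sheet(4, 4)
        a = pd.Series([0] * 4 + [1] * 4, index=sheet.samples)
        assert information_gain(a, sheet) == pytest.approx(1.0)

    def test_hand_contingency(self):
        # clusters {3 case,1 control} and {1 case,3 control}: 1 - H(0.75)
        sheet = _sheet(4, 4)
        a = pd.Series([0, 0, 0, 1, 0, 1, 1, 1], index=sheet.samples)
        expected = 1.0 - (-(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)))
        assert information_gain(a, sheet) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1887, abs=2e-4)

    def test_relabeling_invariance_and_bounds(self, rng):
        sheet = _sheet(6, 9)
        a = pd.Series(rng.integers(0, 3, size=15), index=sheet.samples)
        b = a.map({0: "x", 1: "y", 2: "z"})
        ga, gb = information_gain(a, sheet), information_gain(b, sheet)
        assert ga == pytest.approx(gb)
        h_group = -(6 / 15) * np.log2(6 / 15) - (9 / 15) * np.log2(9 / 15)
        assert -1e-12 <= ga <= h_group + 1e-12


class TestChi2:
    def test_perfect_split(self):
        tab = pd.DataFrame([[10, 0], [0, 10]])
        chi2, p = cluster_group_chi2(tab)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(ss.chi2.sf(20, 1), rel=1e-6)
        assert p == pytest.approx(7.7e-6, abs=1e-6)

    def test_proportional_table_null(self):
        tab = pd.DataFrame([[10, 20], [5, 10], [1, 2]])
        chi2, p = cluster_group_chi2(tab)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            tab = rng.integers(1, 30, size=(4, 2)).astype(float)
            chi2, _ = cluster_group_chi2(pd.DataFrame(tab))
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            oracle = ((tab - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_zero_margin_row_dropped(self, caplog):
        tab = pd.DataFrame([[5, 5], [0, 0], [4, 6]])
        with caplog.at_level("WARNING", logger="nmfomics"):
            chi2, p = cluster_group_chi2(tab)
        assert "empty cluster" in caplog.text
        assert np.isfinite(chi2)


class TestAnova:
    def test_equal_means_f_zero(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        a = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        F, p = anova_across_clusters(v, a)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_clusters_f_equals_t_squared(self, rng):
        v = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        a = pd.Series([0] * 5 + [1] * 7, index=v.index)
        F, p = anova_across_clusters(v, a)
        t, pt = ss.ttest_ind(v[a == 0], v[a == 1], equal_var=True)
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_hand_computation(self):
        v = pd.Series([1, 2, 3, 11, 12, 13, 21, 22, 23],
                      index=[f"s{i}" for i in range(9)], dtype=float)
        a = pd.Series([0] * 3 + [1] * 3 + [2] * 3, index=v.index)
        F, p = anova_across_clusters(v, a)
        assert F == pytest.approx(300.0)
        assert p < 1e-5

    def test_small_cluster_excluded(self, caplog):
        v = pd.Series([1, 2, 3, 4, 9.0], index=list("abcde"))
        a = pd.Series([0, 0, 1, 1, 2], index=v.index)
        with caplog.at_level("WARNING", logger="nmfomics"):
            F, _ = anova_across_clusters(v, a)
        assert "excluded" in caplog.text


class TestProfileComparison:
    def test_latent_vs_single_omics_information_gain_machinery(self):
        """The three stratification profiles (latent H, 5 expression PCs,
        5 methylation PCs) are all scored by the same information-gain
        machinery; on a planted-group cohort the latent profile carries real
        group information (mean gain over k = 4..7 well above zero and within
        the entropy bound)."""
        import nmfomics as nm
        from nmfomics.sample_axis import cluster_and_test
        from nmfomics.simulate import SimulationDesign, simulate_cohort

        d = SimulationDesign(seed=2, n_genes=200, n_cpgs=700)
        expr, beta, sheet, annot, truth = simulate_cohort(d)
        ef, _ = nm.mean_variance_filter(nm.normalize_expression(expr), 1.25, 0.1)
        bf, _ = nm.mean_variance_filter(beta, 0.05, 0.005)
        A = nm.concatenate_and_scale(ef, bf)
        model = nm.nmf_fit(A, 5, n_runs=3, max_iter=500, seed=2)
        h_group = 1.0  # upper bound for a two-group label in bits
        for profile, use_pca in ((model.H, False), (ef.data, True), (bf.data, True)):
            gains = [cluster_and_test(profile, sheet, k, seed=2,
                                      use_pca=use_pca).information_gain
                     for k in (4, 5, 6, 7)]
            assert all(-1e-12 <= g <= h_group for g in gains)
        latent_gains = [cluster_and_test(model.H, sheet, k, seed=2).information_gain
                        for k in (4, 5, 6, 7)]
        assert np.mean(latent_gains) > 0.05
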