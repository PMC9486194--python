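"""Unit and property tests for the statistical primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from cmskit import stats as st

# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------


class TestLmm:
    def test_zero_noise_equal_means_gives_zero_estimate(self, paired_design):
        patients, arms = paired_design
        values = np.repeat(np.arange(5.0), 6)  # patient effects only
        fit = st.lmm_random_intercept(values, patients, arms)
        assert fit.estimate == pytest.approx(0.0, abs=1e-10)
        assert fit.n_patients == 5
        assert fit.n_observations == 30

    def test_reduces_to_pooled_t_test_when_patient_variance_is_zero(self, paired_design, rng):
        # construct patients with exactly equal means so the REML variance
        # component is estimated at its boundary (zero)
        patients, arms = paired_design
        noise = rng.standard_normal(30)
        for pid in np.unique(patients):
            noise[patients == pid] -= noise[patients == pid].mean()
        y = noise + 0.8 * (arms == "POST")
        fit = st.lmm_random_intercept(y, patients, arms)
        t_oracle = sps.ttest_ind(y[arms == "POST"], y[arms == "PRE"])
        assert fit.intercept_sd == pytest.approx(0.0, abs=1e-4)
        assert fit.p_value == pytest.approx(t_oracle.pvalue, abs=1e-6)

    def test_recovers_planted_shift(self, paired_design):
        patients, arms = paired_design
        post = (arms == "POST").astype(float)
        estimates = []
        for s in range(200):
            r = np.random.default_rng(s)
            y = np.repeat(r.standard_normal(5), 6) + r.standard_normal(30) + 2.0 * post
            estimates.append(-st.lmm_random_intercept(y, patients, arms).estimate)
        assert abs(np.mean(estimates) - 2.0) < 0.1

    def test_translation_equivariance(self, paired_design, rng):
        patients, arms = paired_design
        y = rng.standard_normal(30)
        a = st.lmm_random_intercept(y, patients, arms)
        b = st.lmm_random_intercept(y + 57.3, patients, arms)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-8)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-8)

    def test_rejects_single_condition(self, paired_design, rng):
        patients, _ = paired_design
        with pytest.raises(ValueError, match="condition"):
            st.lmm_random_intercept(rng.standard_normal(30), patients, ["PRE"] * 30)


# ---------------------------------------------------------------------------
# clustered correlation
# ---------------------------------------------------------------------------


class TestClusteredCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = st.marginal_pearson_clustered(x, x, np.repeat([0, 1], 5))
        assert res.rho == pytest.approx(1.0)

    def test_singleton_clusters_reduce_to_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = st.marginal_pearson_clustered(x, y, np.arange(40))
        oracle = sps.pearsonr(x, y)
        assert res.rho == pytest.approx(oracle.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            st.marginal_pearson_clustered([1, 1, 1], [1, 2, 3], [0, 1, 2])

    def test_robust_p_reflects_cluster_dependence(self, rng):
        # duplicating every pair into a cluster adds no information; the
        # cluster-robust p should stay near the independent-pairs p, while a
        # naive pooled test would treat 2n points as independent
        x = rng.standard_normal(30)
        y = 0.6 * x + rng.standard_normal(30)
        xx, yy = np.repeat(x, 2), np.repeat(y, 2)
        res = st.marginal_pearson_clustered(xx, yy, np.repeat(np.arange(30), 2))
        assert res.n_clusters == 30
        assert res.rho == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-8)


# ---------------------------------------------------------------------------
# ANOVA screens
# ---------------------------------------------------------------------------


class TestAnovaDe:
    def test_equal_group_values_give_p_one(self):
        block = np.random.default_rng(3).standard_normal((50, 4))
        mat = pd.DataFrame(np.hstack([block, block]))  # group B copies group A
        table = st.anova_de(mat, ["A"] * 4 + ["B"] * 4)
        assert np.allclose(table["p"], 1.0)
        assert not table["significant"].any()

    def test_q_dominates_p_and_flags_monotone(self, rng):
        mat = pd.DataFrame(rng.standard_normal((200, 12)))
        mat.iloc[:10, 6:] += 5.0
        table = st.anova_de(mat, ["A"] * 6 + ["B"] * 6)
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table.loc[table["significant"], "q"].max() <= 0.001

    def test_planted_genes_recovered_with_direction(self, rng):
        mat = pd.DataFrame(rng.standard_normal((500, 20)))
        mat.iloc[:40, 10:] += 4.0
        mat.iloc[40:80, 10:] -= 4.0
        table = st.anova_de(mat, ["A"] * 10 + ["B"] * 10)
        up = table.iloc[:40]
        down = table.iloc[40:80]
        assert up["significant"].mean() >= 0.95
        assert (up.loc[up["significant"], "direction"] == "up").all()
        assert (down.loc[down["significant"], "direction"] == "down").all()

    def test_zero_within_variance_flagged(self):
        mat = pd.DataFrame([[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0]])
        table = st.anova_de(mat, ["A", "A", "B", "B"])
        assert table["degenerate"].tolist() == [True, True]
        assert table["p"].tolist() == [0.0, 1.0]


class TestSignatureBonferroni:
    def test_single_signature_equals_raw_p(self, rng):
        scores = pd.DataFrame({"sig": rng.standard_normal(20)})
        groups = ["A"] * 10 + ["B"] * 10
        table = st.signature_anova_bonferroni(scores, groups)
        f, p = sps.f_oneway(scores["sig"][:10], scores["sig"][10:])
        assert table.loc["sig", "p_bonferroni"] == pytest.approx(p)

    def test_planted_signature_flagged_among_fifty(self, rng):
        # mirrors a 50-signature hallmark comparison with one true effect
        flagged_right = 0
        for s in range(40):
            r = np.random.default_rng(s)
            scores = pd.DataFrame(
                r.standard_normal((20, 50)), columns=[f"H{j:02d}" for j in range(50)]
            )
            scores.iloc[10:, 7] += 5.0
            table = st.signature_anova_bonferroni(scores, ["A"] * 10 + ["B"] * 10)
            flagged = set(table.index[table["significant"]])
            flagged_right += flagged == {"H07"}
        assert flagged_right >= 38  # >= 95% of seeds

    def test_null_flags_nothing(self, rng):
        scores = pd.DataFrame(rng.standard_normal((30, 50)))
        table = st.signature_anova_bonferroni(scores, ["A"] * 15 + ["B"] * 15)
        assert table["significant"].sum() == 0


# ---------------------------------------------------------------------------
# contingency and rank tests
# ---------------------------------------------------------------------------


class TestContingency:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[18, 11], [18, 2]], 0.047),  # MSI by CMS4 status
            ([[32, 0], [17, 6]], 0.003),  # primary anastomosis by CMS4 status
        ],
    )
    def test_fisher_reproduces_printed_study_tables(self, table, expected):
        _, p = st.contingency_test(table, method="fisher")
        assert round(p, 3) == expected

    def test_chi2_heterogeneity_table_below_printed_bound(self):
        # biopsy-level CMS4 heterogeneity by tumor call (6/39 vs 14/24)
        _, p = st.contingency_test([[6, 33], [14, 10]], method="chi2")
        assert p <= 0.001

    def test_uniform_table_p_one(self):
        _, p = st.contingency_test([[1, 1], [1, 1]], method="fisher")
        assert p == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            st.contingency_test([[0, 0], [1, 2]])

    def test_auto_uses_fisher_for_sparse_2x2(self):
        _, p_auto = st.contingency_test([[2, 8], [9, 1]], method="auto")
        _, p_fisher = st.contingency_test([[2, 8], [9, 1]], method="fisher")
        assert p_auto == p_fisher

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.integers(min_value=0, max_value=15), min_size=4, max_size=4)
    )
    def test_fisher_matches_enumeration_oracle(self, cells):
        from cmskit.benchmarks import fisher_enumeration_oracle

        table = np.array(cells).reshape(2, 2)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return
        _, p = st.contingency_test(table, method="fisher")
        assert p == pytest.approx(fisher_enumeration_oracle(table), abs=1e-10)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert st.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        # complete separation of 3 vs 3: 2 of C(6,3)=20 orderings as extreme
        assert st.wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_power_under_shift(self):
        hits = 0
        for s in range(50):
            r = np.random.default_rng(s)
            x = r.standard_normal(50)
            y = r.standard_normal(50) + 1.0
            hits += st.wilcoxon_rank_sum(x, y) < 0.05
        assert hits / 50 > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        curve = st.km_estimate(times, np.ones(5))
        # S(t) after k-th of 5 events = 1 - k/5
        assert curve.at(2.5) == pytest.approx(0.6)
        assert curve.at(5.0) == pytest.approx(0.0)
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_all_censored_curve_stays_at_one(self):
        curve = st.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.survival.min() == pytest.approx(1.0)

    def test_glivenko_cantelli_against_exponential(self):
        rng = np.random.default_rng(7)
        lam = 0.1
        times = rng.exponential(1 / lam, size=2000)
        curve = st.km_estimate(times, np.ones(2000))
        sup = np.max(np.abs(curve.survival - np.exp(-lam * curve.times)))
        assert sup < 0.05

    def test_greenwood_variance_nonnegative_and_zero_at_start(self):
        rng = np.random.default_rng(8)
        curve = st.km_estimate(rng.exponential(10, 100), rng.random(100) < 0.7)
        assert (curve.variance >= 0).all()


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        events = np.ones(10)
        groups = np.repeat(["a", "b"], 5)
        stat, p = st.log_rank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            st.log_rank([1.0, 2.0], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# BH adjustment vs brute-force oracle
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j) / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    hst.lists(
        hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=1000,
    )
)
def test_bh_matches_step_up_oracle(pvals):
    adjusted = st.benjamini_hochberg(pvals)
    assert np.allclose(adjusted, _bh_oracle(pvals), atol=1e-12)
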