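import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from dgephys import stats as st
from dgephys.model import ValidationError
from dgephys.stats import GroupSummary


class TestGroupCI:
    def test_reference_group_interval(self):
        """(mean 38.71, SEM 1.42, n 17) -> 95% CI (35.70, 41.72)."""
        lo, hi = GroupSummary("WT", 17, 38.71, 1.42).ci()
        assert round(lo, 2) == 35.70
        assert round(hi, 2) == 41.72

    def test_zero_sem_degenerate(self):
        lo, hi = GroupSummary("g", 5, 10.0, 0.0).ci()
        assert lo == hi == 10.0

    def test_t_quantile_against_quadrature(self):
        """t(0.975, 16) = 2.1199, checked by integrating the t density."""
        df = 16
        tcrit = sps.t.ppf(0.975, df)

        def density(x):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi)
                                            * math.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        mass, _ = integrate.quad(density, -np.inf, tcrit)
        assert mass == pytest.approx(0.975, abs=1e-9)
        assert tcrit == pytest.approx(2.1199, abs=5e-5)


class TestWelch:
    @pytest.mark.parametrize("s1, s2, lo, hi", [
        # statistical-table rows recomputed from printed (mean, SEM, n);
        # upper bounds near zero inherit the rounding of the printed
        # means, so only the v50 row pins both ends
        ((17, 41.28, 1.50), (16, 45.79, 1.46), -8.80, -0.23),   # PPI v50
        ((9, 167.5, 14.9), (10, 223.0, 25.6), -118.9, None),    # input R
        ((17, 164.7, 13.40), (16, 206.3, 19.16), -89.51, None),  # spike onset
        ((17, 38.71, 1.42), (16, 42.75, 1.55), -8.32, None),    # 50% IPI
    ])
    def test_printed_confidence_intervals(self, s1, s2, lo, hi):
        res = st.welch_t(GroupSummary("WT", *s1), GroupSummary("KO", *s2))
        assert res.ci_low == pytest.approx(lo, abs=max(0.005 * abs(lo), 0.03))
        if hi is not None:
            assert res.ci_high == pytest.approx(
                hi, abs=max(0.005 * abs(hi), 0.03))

    def test_identical_summaries(self):
        s = GroupSummary("a", 10, 5.0, 0.4)
        res = st.welch_t(s, s)
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_raw_equals_summary_route(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        r_raw = st.welch_t(a, b)
        r_sum = st.welch_t(GroupSummary.from_sample(a, "a"),
                           GroupSummary.from_sample(b, "b"))
        assert r_raw.p_value == pytest.approx(r_sum.p_value, rel=1e-12)
        assert r_raw.ci_low == pytest.approx(r_sum.ci_low, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 3, 11)
        res = st.welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            st.welch_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestNormality:
    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            st.dagostino_pearson(np.arange(10.0))

    def test_type_one_error_calibration(self):
        """Rejection rate at alpha 0.05 on normal samples of n = 50."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 10_000))
        _, p = sps.normaltest(x, axis=0)
        rate = np.mean(p < 0.05)
        assert rate == pytest.approx(0.05, abs=0.01)
        # spot-check our wrapper agrees with the vectorised reference
        k2, p0 = st.dagostino_pearson(x[:, 0])
        assert p0 == pytest.approx(p[0], rel=1e-12)


def _enumeration_p(x, y):
    """Independent oracle: two-sided exact p over all group labelings."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mu)
    total = extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        extreme += abs(u_of(comb) - mu) >= obs - 1e-12
    return extreme / total


class TestMannWhitney:
    def test_hodges_lehmann_small_example(self):
        """A=[1,2,3], B=[2,3,4]: the 9 pairwise differences have median -1."""
        res = st.mann_whitney([1, 2, 3], [2, 3, 4])
        assert res.estimate == pytest.approx(-1.0)

    def test_identical_samples_p_one(self):
        res = st.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (5, 5), (6, 4), (6, 6)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        res = st.mann_whitney(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_equals_enumeration(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 5.0, 6.0, 6.0]
        res = st.mann_whitney(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    def test_exact_ci_matches_reference_implementation(self):
        """Frozen from R wilcox.test(conf.int=TRUE, exact=TRUE)."""
        r = st.mann_whitney([1.1, 2.3, 3.5, 4.2], [2.0, 3.1, 4.4, 5.5, 6.1])
        assert r.p_value == pytest.approx(0.2857143, abs=1e-6)
        assert r.estimate == pytest.approx(-1.6, abs=1e-9)
        assert (r.ci_low, r.ci_high) == pytest.approx((-4.4, 1.5), abs=1e-9)
        r2 = st.mann_whitney([38.7, 41.1, 35.2, 40.0, 42.2, 37.5],
                             [42.7, 45.3, 39.9, 44.1, 46.8, 41.0])
        assert r2.p_value == pytest.approx(0.04112554, abs=1e-6)
        assert (r2.ci_low, r2.ci_high) == pytest.approx((-7.8, -0.5), abs=1e-9)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 7)
            r = st.mann_whitney(x, y)
            assert r.ci_low <= r.estimate <= r.ci_high


class TestChi2:
    def test_reference_contingency_table(self):
        chi2, p, expected = st.chi2_independence([[7, 2], [10, 0]])
        assert round(chi2, 1) == 2.5
        assert round(p, 2) == 0.12
        np.testing.assert_allclose(expected.ravel(),
                                   [8.05, 0.95, 8.95, 1.05], atol=0.005)

    def test_perfect_independence(self):
        chi2, p, _ = st.chi2_independence([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_transpose_and_row_swap_invariance(self):
        t = [[7, 2], [10, 0]]
        c0, _, _ = st.chi2_independence(t)
        c1, _, _ = st.chi2_independence(np.transpose(t))
        c2, _, _ = st.chi2_independence(t[::-1])
        assert c0 == pytest.approx(c1) == pytest.approx(c2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            st.chi2_independence([[0, 0], [5, 3]])


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 20, 0.2),
        (0.04, 1, 0.04),
        (0.2, 10, 1.0),
    ])
    def test_adjustment(self, p, m, expected):
        assert st.bonferroni([p], m)[0] == pytest.approx(expected)

    def test_m_must_cover_all(self):
        with pytest.raises(ValidationError):
            st.bonferroni([0.1, 0.2, 0.3], m=2)


def _balanced_frame(seed=3, n_per_group=8, k=5, effect=0.0, subj_sd=2.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("WT", "KO"):
        for s in range(n_per_group):
            u = rng.normal(0, subj_sd)
            for w in range(k):
                rows.append({"y": (effect if g == "KO" else 0.0) + 0.8 * w
                             + u + rng.normal(0, 1),
                             "geno": g, "ipi": w, "subj": f"{g}{s}"})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_additive_zero_noise_interaction_f_zero(self):
        rows = []
        for g, ge in (("WT", 0.0), ("KO", 1.0)):
            for s in range(4):
                for w in range(3):
                    rows.append({"y": ge + 2.0 * w + 0.1 * s, "geno": g,
                                 "ipi": w, "subj": f"{g}{s}"})
        res = st.two_way_anova(pd.DataFrame(rows), "y", "geno", "ipi", "subj",
                               posthoc=False)
        assert res.model_kind == "rm_anova"
        assert res.f_for("interaction") == pytest.approx(0.0, abs=1e-9)

    def test_matches_pingouin_on_complete_data(self):
        import pingouin as pg
        df = _balanced_frame()
        mine = st.two_way_anova(df, "y", "geno", "ipi", "subj", posthoc=False)
        ref = pg.mixed_anova(data=df, dv="y", within="ipi", subject="subj",
                             between="geno")
        ref_f = dict(zip(["group", "within", "interaction"], ref["F"]))
        ref_p = dict(zip(["group", "within", "interaction"], ref["p_unc"]))
        for term in ("group", "within", "interaction"):
            assert mine.f_for(term) == pytest.approx(ref_f[term], rel=1e-9)
            assert mine.p_for(term) == pytest.approx(ref_p[term], rel=1e-9)

    def test_mixed_model_equals_rm_anova_on_complete_data(self):
        """REML compound-symmetry Wald F equals the classical F within
        1e-6 on complete balanced data."""
        df = _balanced_frame()
        classical = st.two_way_anova(df, "y", "geno", "ipi", "subj",
                                     posthoc=False)
        mixed = st._cs_mixed_reml(df, "y", "geno", "ipi", "subj")
        for term in ("group", "within", "interaction"):
            f_ref = classical.f_for(term)
            f_mix = float(mixed.loc[mixed["term"] == term, "F"].iloc[0])
            assert abs(f_mix - f_ref) < 1e-6

    def test_missing_cells_route_to_mixed_model(self):
        df = _balanced_frame().drop(index=[3, 17, 40]).reset_index(drop=True)
        res = st.two_way_anova(df, "y", "geno", "ipi", "subj", posthoc=False)
        assert res.model_kind == "cs_mixed_reml"
        assert set(res.terms["term"]) == {"group", "within", "interaction"}
        assert (res.terms["p"].between(0, 1)).all()

    def test_posthoc_bonferroni_per_within_level(self):
        df = _balanced_frame(effect=3.0)
        res = st.two_way_anova(df, "y", "geno", "ipi", "subj",
                               orientation=("WT", "KO"))
        assert len(res.posthoc) == 5
        np.testing.assert_allclose(
            res.posthoc["p_bonferroni"],
            np.minimum(1.0, 5 * res.posthoc["p_raw"]))

    def test_single_level_factor_rejected(self):
        df = _balanced_frame()
        with pytest.raises(ValidationError):
            st.two_way_anova(df[df["geno"] == "WT"], "y", "geno", "ipi",
                             "subj")
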