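"""The study's statistics layer.

Mirrors the reporting conventions of the quantification chain this
package reimplements: D'Agostino-Pearson normality screening, Welch's
unpaired t test with the 95% CI of the mean difference (computable from
raw samples or from printed mean/SEM/n summaries), the exact
Mann-Whitney test with the Hodges-Lehmann median difference and its
exact confidence interval, the uncorrected chi-square test of
independence for 2x2 tables, two-way (repeated-measures) ANOVA with a
compound-symmetry REML mixed-model variant for incomplete data, and
Bonferroni-corrected post-tests.  Group differences are oriented first
group minus second group (WT - KO in the reference design).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ValidationError

ALPHA = 0.05
NORMALITY_MIN_N = 20


@dataclass
class GroupSummary:
    """Mean +/- SEM summary of one group, as printed in results tables."""

    label: str
    n: int
    mean: float
    sem: float

    @classmethod
    def from_sample(cls, sample: Sequence[float], label: str = "") -> "GroupSummary":
        a = np.asarray(sample, dtype=float)
        return cls(label=label, n=a.size, mean=float(a.mean()),
                   sem=float(a.std(ddof=1) / math.sqrt(a.size)))

    def ci(self, level: float = 0.95) -> Tuple[float, float]:
        """t-based confidence interval of the mean."""
        if self.n < 2:
            raise ValidationError("need n >= 2 for a CI")
        tcrit = sps.t.ppf(0.5 + level / 2, self.n - 1)
        return (self.mean - tcrit * self.sem, self.mean + tcrit * self.sem)


def group_ci(summary: GroupSummary, level: float = 0.95) -> Tuple[float, float]:
    return summary.ci(level)


@dataclass
class StatResult:
    """One statistical comparison, shaped like a statistical-table row."""

    test_name: str
    estimate: float               # difference, group1 - group2
    ci_low: float
    ci_high: float
    statistic: float
    df: Optional[float]
    p_value: float
    exact: bool = False


SampleOrSummary = Union[Sequence[float], GroupSummary]


def _as_summary(x: SampleOrSummary, label: str) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_sample(x, label)


def welch_t(group1: SampleOrSummary, group2: SampleOrSummary,
            level: float = 0.95) -> StatResult:
    """Welch's unpaired two-tailed t test with the CI of the difference.

    Accepts raw samples or (mean, SEM, n) summaries; both routes give
    identical results for samples having those summaries, because the
    statistic depends on the data only through them.
    """
    s1 = _as_summary(group1, "group1")
    s2 = _as_summary(group2, "group2")
    if s1.n < 2 or s2.n < 2:
        raise ValidationError("need n >= 2 per group")
    se2 = s1.sem ** 2 + s2.sem ** 2
    if se2 == 0:
        raise ValidationError("both groups have zero variance")
    diff = s1.mean - s2.mean
    se = math.sqrt(se2)
    df = se2 ** 2 / (s1.sem ** 4 / (s1.n - 1) + s2.sem ** 4 / (s2.n - 1))
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.5 + level / 2, df)
    return StatResult(test_name="Welch t (two-tailed)", estimate=diff,
                      ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
                      statistic=t, df=float(df), p_value=float(p))


def dagostino_pearson(sample: Sequence[float]) -> Tuple[float, float]:
    """D'Agostino-Pearson omnibus K^2 normality test.

    K^2 combines the transformed skewness and kurtosis Z scores; p comes
    from chi-square with 2 df.  The test is unreliable below n = 20 —
    smaller samples raise, directing callers to the nonparametric branch.
    """
    a = np.asarray(sample, dtype=float)
    if a.size < NORMALITY_MIN_N:
        raise ValidationError(
            f"normality test needs n >= {NORMALITY_MIN_N} (got {a.size}); "
            "use the nonparametric branch for small samples")
    k2, p = sps.normaltest(a)
    return float(k2), float(p)


# ---------------------------------------------------------------------------
# Mann-Whitney with Hodges-Lehmann estimate and exact CI

def _exact_u_cdf_table(n1: int, n2: int) -> np.ndarray:
    """Counts of labelings per U value (no-tie null distribution).

    Classic recursion: c[n1][u] over items added one at a time.
    """
    max_u = n1 * n2
    # f[k][u]: number of ways to choose k of the combined ranks with
    # rank-sum statistic u; built by the standard partition recurrence
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            fi = f[k - 1].copy()
            shift = i - k  # adding element i as the k-th member
            if shift <= max_u:
                f[k, shift:] += fi[: max_u + 1 - shift]
    return f[n1]


def _exact_p_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group labelings (handles ties)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = sps.rankdata(pooled)
    u_obs = sps.rankdata(pooled)[:n1].sum()  # placeholder, recomputed below
    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2.0
    u_obs = u_of(range(n1))
    mu = x.size * y.size / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney(sample1: Sequence[float], sample2: Sequence[float],
                 level: float = 0.95) -> StatResult:
    """Mann-Whitney test with Hodges-Lehmann estimate and exact CI.

    p value: exact for n1+n2 <= 25 without ties (shift algorithm), exact
    by direct enumeration for tied data up to n1+n2 <= 16, otherwise the
    normal approximation with mid-rank tie correction.  The estimate is
    the Hodges-Lehmann median of all pairwise differences (sample1 -
    sample2); its CI uses the ordered pairwise differences at the exact
    (or approximate) U quantiles.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need n >= 2 per group")
    n1, n2 = x.size, y.size
    ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    u_stat = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").statistic)
    exact = False
    if n1 + n2 <= 25 and not ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue)
        exact = True
    elif ties and n1 + n2 <= 16:
        p = _exact_p_bruteforce(x, y)
        exact = True
    else:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)

    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    # critical U for the CI rank positions
    alpha = 1 - level
    if n1 + n2 <= 25 and not ties:
        counts = _exact_u_cdf_table(n1, n2)
        cdf = np.cumsum(counts) / counts.sum()
        # largest k with P(U <= k) <= alpha/2
        ks = np.nonzero(cdf <= alpha / 2 + 1e-12)[0]
        k = int(ks[-1]) if ks.size else -1
    else:
        z = sps.norm.ppf(1 - alpha / 2)
        mu, sd = n1 * n2 / 2.0, math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        k = int(math.floor(mu - z * sd - 0.5))
    # CI endpoints at the ordered pairwise differences: the (k+1)-th
    # smallest and largest, where P(U <= k) <= alpha/2 < P(U <= k+1)
    k_eff = max(k, 0)
    lo = diffs[k_eff]
    hi = diffs[n1 * n2 - k_eff - 1]
    return StatResult(test_name="Mann-Whitney (two-tailed)", estimate=hl,
                      ci_low=float(lo), ci_high=float(hi), statistic=u_stat,
                      df=None, p_value=p, exact=exact)


def chi2_independence(table: Sequence[Sequence[float]],
                      ) -> Tuple[float, float, np.ndarray]:
    """Uncorrected chi-square test of independence for a 2x2 table.

    Returns (chi2, p, expected).  No Yates continuity correction — the
    reference analysis reports the uncorrected statistic.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValidationError("table must hold nonnegative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("zero row or column margin")
    chi2, p, _, expected = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), expected


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ValidationError("m must be at least the number of p values")
    return np.minimum(1.0, m_eff * p)


# ---------------------------------------------------------------------------
# two-way (repeated-measures) ANOVA / compound-symmetry mixed model

@dataclass
class AnovaResult:
    """Two-way (mixed-design) ANOVA: between-subject group factor crossed
    with a within-subject repeated factor."""

    model_kind: str                 # 'rm_anova' or 'cs_mixed_reml'
    terms: pd.DataFrame             # term, F, df1, df2, p
    posthoc: Optional[pd.DataFrame] = None

    def p_for(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])

    def f_for(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["F"].iloc[0])


def _posthoc_by_level(data: pd.DataFrame, dv: str, between: str, within: str,
                      orientation: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Bonferroni-corrected two-sample comparisons at each within level."""
    levels = sorted(data[within].unique())
    groups = list(orientation) if orientation is not None \
        else sorted(data[between].unique())
    if len(groups) != 2:
        raise ValidationError("post-tests expect exactly two groups")
    rows = []
    for lv in levels:
        sub = data[data[within] == lv]
        a = sub.loc[sub[between] == groups[0], dv].to_numpy()
        b = sub.loc[sub[between] == groups[1], dv].to_numpy()
        res = welch_t(a, b)
        rows.append({"level": lv, "difference": res.estimate,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(), m=len(levels))
    return out


def _rm_anova(data: pd.DataFrame, dv: str, between: str, within: str,
              subject: str) -> pd.DataFrame:
    """Classical split-plot sums-of-squares decomposition (complete data).

    Between-subjects factor tested against the subject-within-group mean
    square; within factor and interaction against the residual.
    """
    piv = data.pivot_table(index=[subject, between], columns=within,
                           values=dv, aggfunc="mean")
    if piv.isna().any().any():
        raise ValidationError("incomplete data: use the mixed model")
    y = piv.to_numpy()
    subj_group = piv.index.get_level_values(between).to_numpy()
    groups = np.unique(subj_group)
    a, k = groups.size, y.shape[1]
    n_subj = y.shape[0]
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    group_means = {g: y[subj_group == g].mean() for g in groups}
    time_means = y.mean(axis=0)
    ss_between = sum(k * (subj_group == g).sum() * (group_means[g] - grand) ** 2
                     for g in groups)
    ss_subj_within = k * sum((subj_means[i] - group_means[subj_group[i]]) ** 2
                             for i in range(n_subj))
    ss_within_factor = n_subj * ((time_means - grand) ** 2).sum()
    cell_means = np.vstack([y[subj_group == g].mean(axis=0) for g in groups])
    ss_cells = sum(k_count * ((cell_means[gi] - grand) ** 2).sum()
                   for gi, g in enumerate(groups)
                   for k_count in [(subj_group == g).sum()])
    ss_inter = ss_cells - ss_between - ss_within_factor
    ss_resid = ss_total - ss_between - ss_subj_within - ss_within_factor - ss_inter

    df_between = a - 1
    df_subj = n_subj - a
    df_within = k - 1
    df_inter = (a - 1) * (k - 1)
    df_resid = df_subj * (k - 1)

    def row(term, ss, df1, ms_err, df2):
        # guard exact-zero terms and zero error variance (degenerate
        # noise-free constructions): a vanishing term SS means F = 0
        ss = max(float(ss), 0.0)
        if ss <= 1e-12 * max(ss_total, 1.0):
            return {"term": term, "F": 0.0, "df1": df1, "df2": df2, "p": 1.0}
        F = (ss / df1) / ms_err if ms_err > 0 else float("inf")
        return {"term": term, "F": F, "df1": df1, "df2": df2,
                "p": float(sps.f.sf(F, df1, df2))}

    ms_subj = ss_subj_within / df_subj
    ms_resid = ss_resid / df_resid
    return pd.DataFrame([
        row("group", ss_between, df_between, ms_subj, df_subj),
        row("within", ss_within_factor, df_within, ms_resid, df_resid),
        row("interaction", ss_inter, df_inter, ms_resid, df_resid),
    ])


def _cs_mixed_reml(data: pd.DataFrame, dv: str, between: str, within: str,
                   subject: str) -> pd.DataFrame:
    """Compound-symmetry mixed model (random subject intercept, REML).

    Missing cells are allowed.  Wald F statistics use ANOVA-style
    (containment) denominator df, which reproduces the repeated-measures
    ANOVA exactly on complete balanced data.
    """
    import statsmodels.formula.api as smf
    d = data.rename(columns={dv: "_y", between: "_g", within: "_w",
                             subject: "_s"}).copy()
    d["_g"] = d["_g"].astype(str)
    d["_w"] = d["_w"].astype(str)
    # sum-to-zero coding so each term's Wald slice tests the marginal
    # (type III) hypothesis, matching the classical decomposition
    model = smf.mixedlm("_y ~ C(_g, Sum) * C(_w, Sum)", d, groups=d["_s"],
                        re_formula="1")
    fit = model.fit(reml=True, method="lbfgs", maxiter=2000)
    fit = model.fit(reml=True, method="powell", maxiter=5000,
                    start_params=fit.params_object)
    design_info = model.data.design_info
    n_subj = d["_s"].nunique()
    a = d["_g"].nunique()
    k = d["_w"].nunique()
    n_obs = len(d)
    df_subj = n_subj - a
    df_resid = n_obs - n_subj - (k - 1) * a
    term_map = {"C(_g, Sum)": ("group", df_subj),
                "C(_w, Sum)": ("within", df_resid),
                "C(_g, Sum):C(_w, Sum)": ("interaction", df_resid)}
    k_fe = len(fit.fe_params)
    rows = []
    for term_name, (label, df2) in term_map.items():
        sl = design_info.slice(term_name)
        idx = list(range(sl.start, sl.stop))
        L = np.zeros((len(idx), k_fe))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        beta = fit.fe_params.to_numpy()
        cov = fit.cov_params().to_numpy()[:k_fe, :k_fe]
        Lb = L @ beta
        W = float(Lb @ np.linalg.solve(L @ cov @ L.T, Lb))
        df1 = len(idx)
        F = W / df1
        rows.append({"term": label, "F": F, "df1": df1, "df2": df2,
                     "p": float(sps.f.sf(F, df1, df2))})
    order = {"group": 0, "within": 1, "interaction": 2}
    return (pd.DataFrame(rows).sort_values(by="term", key=lambda s: s.map(order))
            .reset_index(drop=True))


def two_way_anova(data: pd.DataFrame, dv: str, between: str, within: str,
                  subject: str, posthoc: bool = True,
                  orientation: Optional[Sequence[str]] = None) -> AnovaResult:
    """Two-way repeated-measures ANOVA, or its compound-symmetry REML
    mixed-model variant when cells are missing.

    ``between`` is the group factor (e.g. genotype), ``within`` the
    repeated factor (e.g. interpulse interval) measured on every
    ``subject``.  Complete data take the classical sums-of-squares
    route; incomplete data are fit as a random-intercept (compound
    symmetry) mixed model by REML.  Bonferroni-corrected two-sample
    post-tests are run at each within-factor level.
    """
    for col in (dv, between, within, subject):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from data")
    if data[between].nunique() < 2 or data[within].nunique() < 2:
        raise ValidationError("each factor needs at least 2 levels")
    counts = data.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="count")
    complete = not counts.isna().any().any() and (counts == 1).all().all()
    if complete:
        terms = _rm_anova(data, dv, between, within, subject)
        kind = "rm_anova"
    else:
        terms = _cs_mixed_reml(data, dv, between, within, subject)
        kind = "cs_mixed_reml"
    ph = _posthoc_by_level(data, dv, between, within, orientation) if posthoc else None
    return AnovaResult(model_kind=kind, terms=terms, posthoc=ph)
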