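"""Statistical primitives for paired-biopsy and cohort comparisons.

Implements the statistics the downstream analyses rest on, each behind a
small typed result:

* random-intercept linear mixed model for paired pre/post biopsies clustered
  within patients (REML fit, Wald test on the condition contrast);
* marginal Pearson correlation for clustered data (pooled point estimate,
  cluster-robust sandwich variance for inference);
* per-gene one-way ANOVA with Benjamini-Hochberg FDR, and a signature-level
  ANOVA with Bonferroni correction;
* 2x2 Fisher exact / r x c Pearson chi-square contingency tests and the
  Wilcoxon rank-sum test;
* Kaplan-Meier estimation with Greenwood variance and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LmmFit",
    "ClusteredCorrelation",
    "SurvivalCurve",
    "lmm_random_intercept",
    "marginal_pearson_clustered",
    "anova_de",
    "signature_anova_bonferroni",
    "contingency_test",
    "wilcoxon_rank_sum",
    "km_estimate",
    "log_rank",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    """Condition contrast from ``value ~ condition + (1 | patient)``."""

    estimate: float
    se: float
    p_value: float
    intercept_sd: float
    residual_sd: float
    n_patients: int
    n_observations: int


def lmm_random_intercept(values, patients, conditions) -> LmmFit:
    """REML fit of a two-condition contrast with a random intercept per patient.

    ``conditions`` must hold exactly two levels; the contrast reported is
    second level minus first (levels sorted). The p-value is a Wald test on
    the fixed-effect contrast against a t reference with residual degrees of
    freedom (n_obs - 2), so the fit reduces exactly to the pooled two-sample
    t-test when the between-patient variance is estimated at zero.
    """
    values = np.asarray(values, dtype=float)
    patients = np.asarray(patients)
    conditions = np.asarray(conditions)
    if values.ndim != 1 or len(values) != len(patients) or len(values) != len(conditions):
        raise ValueError("values, patients and conditions must be equal-length 1-D")
    levels = np.unique(conditions)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition levels, got {list(levels)}")
    if len(np.unique(patients)) < 2:
        raise ValueError("need >=2 patients")
    x = (conditions == levels[1]).astype(float)
    exog = np.column_stack([np.ones_like(x), x])
    if np.linalg.matrix_rank(exog) < 2:
        raise ValueError("singular design: condition is constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(values, exog, groups=patients)
        fit = model.fit(reml=True)
        # the default optimizer can stall off the tau^2 = 0 boundary;
        # keep whichever solution has the better restricted likelihood
        refit = MixedLM(values, exog, groups=patients).fit(reml=True, method="powell")
        if refit.llf > fit.llf + 1e-10:
            fit = refit
    est = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    df = len(values) - 2
    if se > 0:
        p = float(2.0 * sps.t.sf(abs(est / se), df=df))
    else:
        p = 0.0 if est != 0 else 1.0
    return LmmFit(
        estimate=est,
        se=se,
        p_value=p,
        intercept_sd=float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(max(fit.scale, 0.0))),
        n_patients=int(len(np.unique(patients))),
        n_observations=int(len(values)),
    )


# ---------------------------------------------------------------------------
# marginal Pearson correlation for clustered data
# ---------------------------------------------------------------------------


@dataclass
class ClusteredCorrelation:
    """Pooled Pearson correlation with cluster-robust inference."""

    rho: float
    p_value: float
    n_clusters: int
    n_pairs: int


def marginal_pearson_clustered(x, y, clusters) -> ClusteredCorrelation:
    """Marginal (pooled) Pearson correlation with within-cluster dependence.

    The point estimate is the ordinary Pearson correlation over all pairs.
    Inference uses the sandwich variance of the correlation estimating
    equation with cluster-summed influence functions; when every cluster is a
    singleton the test reduces exactly to the classical Pearson t test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    n = len(x)
    if n != len(y) or n != len(clusters):
        raise ValueError("x, y, clusters must have equal length")
    if n < 3:
        raise ValueError("need >=3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")

    uniq, inv = np.unique(clusters, return_inverse=True)
    n_clusters = len(uniq)
    r = float(np.corrcoef(x, y)[0, 1])

    if n_clusters == n:
        # independent pairs: classical exact Pearson test
        p = float(sps.pearsonr(x, y).pvalue)
        return ClusteredCorrelation(rho=r, p_value=p, n_clusters=n_clusters, n_pairs=n)

    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    # influence function of the Pearson correlation
    psi = xs * ys - 0.5 * r * (xs**2 + ys**2)
    cluster_sums = np.bincount(inv, weights=psi)
    var = float(np.sum(cluster_sums**2)) / n**2
    if var <= 0:
        p = 0.0 if r != 0 else 1.0
    else:
        z = r / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return ClusteredCorrelation(rho=r, p_value=p, n_clusters=n_clusters, n_pairs=n)


# ---------------------------------------------------------------------------
# ANOVA screens
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p_values = np.asarray(p_values, dtype=float)
    return multipletests(p_values, method="fdr_bh")[1]


def anova_de(matrix: pd.DataFrame, groups, q_cutoff: float = 0.001) -> pd.DataFrame:
    """Per-gene one-way ANOVA across ``groups`` with BH adjustment.

    ``matrix`` is genes x samples; ``groups`` labels its columns. Direction is
    the sign of (second group mean - first group mean), groups in sorted
    order. Genes with zero within-group variance get the limiting F: p = 0
    when group means differ, p = 1 when the gene is globally constant; such
    genes are flagged in the ``degenerate`` column.
    """
    groups = np.asarray(groups)
    if matrix.shape[1] != len(groups):
        raise ValueError("group labels must match matrix columns")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    blocks = [matrix.to_numpy()[:, groups == g] for g in levels]
    if any(b.shape[1] < 2 for b in blocks):
        raise ValueError("need >=2 samples per group")

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p_raw = sps.f_oneway(*blocks, axis=1)
    group_means = np.column_stack([b.mean(axis=1) for b in blocks])
    between = np.ptp(group_means, axis=1) > 0
    f_stat = np.where(np.abs(f_stat) < 1e-12, 0.0, f_stat)  # rounding fuzz
    degenerate = ~np.isfinite(f_stat) | ~np.isfinite(p_raw)
    p_raw = np.where(degenerate, np.where(between, 0.0, 1.0), p_raw)
    f_stat = np.where(np.isfinite(f_stat), f_stat, np.where(between, np.inf, 0.0))
    p_raw = np.where((f_stat == 0.0) & ~degenerate, 1.0, p_raw)

    q = benjamini_hochberg(p_raw)
    direction = np.where(group_means[:, 1] >= group_means[:, 0], "up", "down")
    table = pd.DataFrame(
        {
            "F": f_stat,
            "p": p_raw,
            "q": q,
            "significant": q <= q_cutoff,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=matrix.index,
    )
    for i, g in enumerate(levels):
        table[f"mean_{g}"] = group_means[:, i]
    return table


def signature_anova_bonferroni(
    scores: pd.DataFrame, groups, cutoff: float = 0.001
) -> pd.DataFrame:
    """Per-signature ANOVA with Bonferroni correction across signatures.

    ``scores`` is samples x signatures. The Bonferroni p is raw p times the
    number of signatures, capped at 1; a signature is flagged at ``<= cutoff``.
    """
    groups = np.asarray(groups)
    if scores.shape[0] != len(groups):
        raise ValueError("group labels must match score rows")
    levels = np.unique(groups)
    m = scores.shape[1]
    rows = []
    for sig in scores.columns:
        blocks = [scores.loc[groups == g, sig].to_numpy() for g in levels]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = sps.f_oneway(*blocks)
        if not np.isfinite(p):
            p = 0.0 if np.ptp([b.mean() for b in blocks]) > 0 else 1.0
            f = np.inf if p == 0.0 else 0.0
        p_bonf = min(p * m, 1.0)
        rows.append((sig, float(f), float(p), float(p_bonf), p_bonf <= cutoff))
    return pd.DataFrame(
        rows, columns=["signature", "F", "p", "p_bonferroni", "significant"]
    ).set_index("signature")


# ---------------------------------------------------------------------------
# contingency and rank tests
# ---------------------------------------------------------------------------


def contingency_test(table, method: str = "auto") -> tuple[float, float]:
    """Contingency test on a count table; returns ``(statistic, p_value)``.

    * ``fisher``: two-sided Fisher exact test (point-probability rule), 2x2
      only; the statistic is the odds ratio.
    * ``chi2``: Pearson chi-square without continuity correction.
    * ``auto``: Fisher for a 2x2 table when any expected count is < 5,
      otherwise chi-square.
    """
    table = np.asarray(table)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("contingency table has an empty margin")

    if method == "auto":
        expected = sps.contingency.expected_freq(table)
        method = "fisher" if table.shape == (2, 2) and (expected < 5).any() else "chi2"
    if method == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher exact test requires a 2x2 table")
        res = sps.fisher_exact(table, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "chi2":
        res = sps.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration when the combined sample size is <= 20 and ties are
    absent; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; at tied times events precede censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    # drop the t=0 anchor row unless deaths occur at 0
    surv = kmf.survival_function_["KM_estimate"]
    t = tbl.index.to_numpy(dtype=float)
    d = tbl["observed"].to_numpy(dtype=float)
    n = tbl["at_risk"].to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n > 0) & (n > d), d / (n * (n - d)), np.where(d > 0, np.inf, 0.0))
    greenwood = s**2 * np.cumsum(inc)
    greenwood = np.where(np.isfinite(greenwood), greenwood, 0.0)
    return SurvivalCurve(times=t, survival=s, variance=greenwood, at_risk=n)


def log_rank(times, events, groups) -> tuple[float, float]:
    """k-sample log-rank test; returns ``(chi2 statistic, two-sided p)``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >=2 groups")
    if events.sum() == 0:
        raise ValueError("zero events: log-rank test undefined")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)
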