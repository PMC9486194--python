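"""Signature-based cohort stratification and survival comparison.

A treatment-induced gene set is used to split a large cohort into LOW and
HIGH expression subgroups by 2-means clustering on z-scored genes; the CMS
composition of the strata is compared by chi-square and survival (stage
II-III by default) by Kaplan-Meier curves with a two-sided log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportion_confint

from . import stats as st
from .io import ExpressionMatrix

LOW, HIGH = "LOW", "HIGH"


def kmeans_split(
    expr: ExpressionMatrix, genes, seed: int = 0, n_restarts: int = 10
) -> tuple[pd.Series, np.ndarray]:
    """k=2 k-means on z-scored genes; HIGH = cluster with larger mean score.

    Samples are ordered by sorted id before fitting so the split is invariant
    to the input sample order; genes absent from the matrix are dropped.
    Returns per-sample LOW/HIGH labels and the 2 x n_genes cluster centers
    (row 0 = LOW, row 1 = HIGH).
    """
    genes = [g for g in genes if g in expr.data.index]
    if not genes:
        raise ValueError("no stratification gene present in the matrix")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to split")
    sub = expr.data.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.empty:
        raise ValueError("all stratification genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    order = np.argsort(expr.samples.to_numpy().astype(str))
    x = z.to_numpy().T[order]
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    means = np.array([x[raw == k].mean() for k in (0, 1)])
    high_cluster = int(np.argmax(means))
    labels_sorted = np.where(raw == high_cluster, HIGH, LOW)
    labels = pd.Series(index=expr.samples[order], data=labels_sorted, name="stratum")
    labels = labels.reindex(expr.samples)
    centers = km.cluster_centers_[[1 - high_cluster, high_cluster]]
    return labels, centers


def stratum_cms_composition(
    strata: pd.Series, cms_calls: pd.Series
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """CMS-by-stratum contingency table, chi-square p, per-stratum CMS4 share.

    Returns ``(table, p_value, proportions)`` where proportions carries the
    CMS4 fraction per stratum with a 95% Wilson binomial CI.
    """
    strata, cms_calls = strata.align(cms_calls, join="inner")
    if strata.empty:
        raise ValueError("strata and CMS calls share no samples")
    if strata.nunique() < 2:
        raise ValueError("empty stratum: need both LOW and HIGH")
    table = pd.crosstab(strata, cms_calls)
    if min(table.shape) < 2:
        raise ValueError("degenerate contingency table: a single CMS level")
    _, p = st.contingency_test(table.to_numpy(), method="chi2")
    rows = []
    for stratum, row in table.iterrows():
        n = int(row.sum())
        k = int(row.get("CMS4", 0))
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((stratum, k, n, k / n, lo, hi))
    props = pd.DataFrame(
        rows, columns=["stratum", "n_cms4", "n", "prop_cms4", "ci_low", "ci_high"]
    ).set_index("stratum")
    return table, float(p), props


@dataclass
class StratumSurvival:
    """Per-endpoint KM curves by stratum plus the log-rank comparison."""

    curves: dict[str, st.SurvivalCurve]
    statistic: float
    p_value: float
    n_per_stratum: dict[str, int]


def stratum_survival(
    strata: pd.Series,
    survival: pd.DataFrame,
    stage_filter=("II", "III"),
) -> dict[str, StratumSurvival]:
    """Stage-filtered KM + log-rank per endpoint across LOW/HIGH strata.

    ``survival`` is a long table with columns (endpoint, time, event, stage)
    indexed by sample id; a single-endpoint table may omit the endpoint
    column (endpoint name defaults to "overall").
    """
    df = survival.copy()
    if "endpoint" not in df:
        df["endpoint"] = "overall"
    if stage_filter is not None:
        df = df[df["stage"].astype(str).isin([str(s) for s in stage_filter])]
        if df.empty:
            raise ValueError("no samples after stage filter")
    out = {}
    for endpoint, grp in df.groupby("endpoint"):
        aligned = grp.join(strata.rename("stratum"), how="inner")
        if aligned["stratum"].nunique() < 2:
            raise ValueError(f"endpoint {endpoint}: need both strata after filtering")
        stat, p = st.log_rank(
            aligned["time"].to_numpy(),
            aligned["event"].to_numpy(),
            aligned["stratum"].to_numpy(),
        )
        curves = {
            s: st.km_estimate(g["time"].to_numpy(), g["event"].to_numpy())
            for s, g in aligned.groupby("stratum")
        }
        out[endpoint] = StratumSurvival(
            curves=curves,
            statistic=stat,
            p_value=p,
            n_per_stratum=aligned["stratum"].value_counts().to_dict(),
        )
    return out


def run_stratification(
    expr: ExpressionMatrix,
    induced_genes,
    cms_calls: pd.Series,
    survival: pd.DataFrame,
    stage_filter=("II", "III"),
    seed: int = 0,
):
    """Full stratify pipeline: split, composition, survival.

    Returns ``(strata, composition_table, composition_p, proportions,
    survival_results)``.
    """
    strata, _ = kmeans_split(expr, induced_genes, seed=seed)
    table, p, props = stratum_cms_composition(strata, cms_calls)
    surv = stratum_survival(strata, survival, stage_filter=stage_filter)
    return strata, table, p, props, surv
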