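"""Pre/post treatment phenotype-shift analysis.

Given paired biopsies (patient id, PRE/POST arm), this module quantifies the
mesenchymal-to-epithelial shift: per-signature and per-gene contrasts with a
random-intercept mixed model (patients cluster their biopsies), genome-wide
differential expression with BH FDR, multi-class CMS calls per arm via the
piggyback classifier, and an all-gene PCA showing arm segregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from . import stats as st
from .classify import piggyback_classify
from .io import ExpressionMatrix
from .screen import signature_score
from .classify import size_factor_normalize

logger = logging.getLogger(__name__)

ARMS = ("PRE", "POST")


@dataclass
class ShiftReport:
    """Bundled outputs of the pre/post analysis."""

    signature_fits: pd.DataFrame
    gene_fits: pd.DataFrame
    de_table: pd.DataFrame
    de_up: list[str]
    de_down: list[str]
    cms_calls: pd.DataFrame
    cms_distribution: pd.DataFrame
    transitions: pd.DataFrame = field(default_factory=pd.DataFrame)
    pca_coords: pd.DataFrame = field(default_factory=pd.DataFrame)
    pca_var_explained: np.ndarray = field(default_factory=lambda: np.array([]))


def _check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient", "arm"):
        if col not in annotation:
            raise ValueError(f"annotation needs a '{col}' column")
    bad = set(annotation["arm"].unique()) - set(ARMS)
    if bad:
        raise ValueError(f"arm labels must be PRE/POST, got {sorted(bad)}")
    if annotation["patient"].nunique() < 2:
        raise ValueError("need >= 2 patients")
    return annotation


def pca_arm_segregation(expr: ExpressionMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """All-gene PCA on z-scored genes with a deterministic sign convention.

    Each component is flipped, if needed, so its largest-magnitude gene
    loading is positive; coordinates are then invariant to gene order up to
    that convention.
    """
    data = expr.data
    sd = data.std(axis=1, ddof=1)
    z = data.loc[sd > 0]
    z = z.sub(z.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    n_components = min(n_components, min(z.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z.to_numpy().T)
    for j in range(coords.shape[1]):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] = -coords[:, j]
    cols = [f"PC{j + 1}" for j in range(coords.shape[1])]
    return pd.DataFrame(coords, index=expr.samples, columns=cols), pca.explained_variance_ratio_


def cms_shift_summary(
    calls_pre: pd.Series, calls_post: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CMS call distribution per arm plus per-id transitions.

    ``calls_pre``/``calls_post`` map an identifier (patient or sample) to a
    call. The distribution counts every entry; transitions join ids present
    in both arms, and ids present in only one arm are listed with the other
    side missing (excluded from the transition list proper).
    """
    if calls_pre.empty or calls_post.empty:
        raise ValueError("call vectors must be nonempty")
    levels = sorted(set(calls_pre) | set(calls_post))
    dist = pd.DataFrame(
        {
            "PRE": calls_pre.value_counts().reindex(levels, fill_value=0),
            "POST": calls_post.value_counts().reindex(levels, fill_value=0),
        }
    )
    dist.index.name = "call"
    dist["PRE_prop"] = dist["PRE"] / dist["PRE"].sum()
    dist["POST_prop"] = dist["POST"] / dist["POST"].sum()
    shared = calls_pre.index.intersection(calls_post.index)
    transitions = pd.DataFrame(
        {"pre_call": calls_pre.loc[shared], "post_call": calls_post.loc[shared]}
    )
    transitions.index.name = "id"
    only_one = calls_pre.index.symmetric_difference(calls_post.index)
    if len(only_one):
        transitions.attrs["unmatched"] = list(only_one)
    return dist, transitions


def proliferation_inverse_check(
    expr: ExpressionMatrix, cms4_signature, cell_cycle_signature
) -> tuple[float, float]:
    """Cohort-level Pearson r (two-sided p) between the two signature scores."""
    a = signature_score(expr, cms4_signature)
    b = signature_score(expr, cell_cycle_signature)
    res = sps.pearsonr(a.to_numpy(), b.to_numpy())
    return float(res.statistic), float(res.pvalue)


def run_shift_analysis(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    genesets: dict[str, list[str]],
    reference: ExpressionMatrix,
    reference_labels: pd.Series,
    genes_of_interest: list[str] | None = None,
    q_cutoff: float = 0.001,
    seed: int = 0,
) -> ShiftReport:
    """Full pre/post analysis on paired biopsies.

    Normalizes counts if needed, scores every configured gene set, fits the
    random-intercept mixed model per signature and per gene of interest
    (POST minus PRE contrast), runs the genome-wide ANOVA/FDR DE screen,
    calls CMS per sample by pooling with the labeled reference, tabulates the
    call distribution by arm with per-patient transitions, and computes the
    all-gene PCA.
    """
    annotation = _check_annotation(annotation.loc[expr.samples])
    if expr.is_counts:
        normed, _ = size_factor_normalize(expr)
        expr = ExpressionMatrix(np.log2(normed.data + 1.0), is_counts=False)

    patients = annotation["patient"].to_numpy()
    arms = annotation["arm"].to_numpy()

    sig_rows = []
    scores = {}
    for name, genes in genesets.items():
        if not any(g in expr.data.index for g in genes):
            logger.warning("gene set %s has no gene in the matrix, skipped", name)
            continue
        score = signature_score(expr, genes)
        scores[name] = score
        fit = st.lmm_random_intercept(score.to_numpy(), patients, arms)
        sig_rows.append((name, fit.estimate, fit.se, fit.p_value, fit.intercept_sd))
    signature_fits = pd.DataFrame(
        sig_rows, columns=["signature", "estimate", "se", "p", "intercept_sd"]
    ).set_index("signature")
    # POST-minus-PRE orientation (levels sort POST < PRE, so flip)
    signature_fits["estimate"] *= -1.0

    gene_rows = []
    for g in genes_of_interest or []:
        if g not in expr.data.index:
            continue
        fit = st.lmm_random_intercept(expr.data.loc[g].to_numpy(), patients, arms)
        gene_rows.append((g, -fit.estimate, fit.se, fit.p_value))
    gene_fits = pd.DataFrame(gene_rows, columns=["gene", "estimate", "se", "p"]).set_index(
        "gene"
    ) if gene_rows else pd.DataFrame(columns=["estimate", "se", "p"])

    de = st.anova_de(expr.data, arms, q_cutoff=q_cutoff)
    # anova_de orders groups alphabetically (POST first): "up" there means
    # higher in PRE, so the POST-vs-PRE direction is the reverse.
    post_higher = de["mean_POST"] > de["mean_PRE"]
    de["direction"] = np.where(post_higher, "up", "down")
    de_up = de.index[de["significant"] & (de["direction"] == "up")].tolist()
    de_down = de.index[de["significant"] & (de["direction"] == "down")].tolist()

    cms = piggyback_classify(expr, reference, reference_labels, seed=seed)
    cms_calls = cms.join(annotation[["patient", "arm"]])
    dist, _ = cms_shift_summary(
        cms_calls.loc[cms_calls["arm"] == "PRE", "call"],
        cms_calls.loc[cms_calls["arm"] == "POST", "call"],
    )
    # per-patient transitions use each patient's modal call within an arm
    modal = (
        cms_calls.groupby(["patient", "arm"])["call"]
        .agg(lambda s: s.mode().iloc[0])
        .unstack("arm")
    )
    _, transitions = cms_shift_summary(
        modal["PRE"].dropna(), modal["POST"].dropna()
    )
    coords, var_explained = pca_arm_segregation(expr)

    return ShiftReport(
        signature_fits=signature_fits,
        gene_fits=gene_fits,
        de_table=de,
        de_up=de_up,
        de_down=de_down,
        cms_calls=cms_calls,
        cms_distribution=dist,
        transitions=transitions,
        pca_coords=coords.join(annotation[["arm"]]),
        pca_var_explained=var_explained,
    )
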