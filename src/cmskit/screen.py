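"""Expression-based kinase-target screen and Kd selectivity ranking.

The screen identifies candidate subtype-targeting kinase inhibitors in two
stages: (1) correlate each kinome gene's expression with the per-sample CMS4
signature score in each cohort, keeping kinases that are positively
correlated below a stringent p threshold in every cohort; (2) rank inhibitors
by selectivity — the fraction of tested kinases bound below a Kd cutoff —
among inhibitors hitting at least one screen kinase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_KD_CUTOFF_UM = 3.0


def signature_score(matrix: ExpressionMatrix, geneset) -> pd.Series:
    """Per-sample mean of gene-wise z-scores over a gene set.

    Genes absent from the matrix or with zero variance across samples are
    excluded with a logged warning; at least one usable gene is required.
    """
    geneset = list(geneset)
    present = [g for g in geneset if g in matrix.data.index]
    absent = sorted(set(geneset) - set(present))
    if absent:
        logger.warning("signature genes absent from matrix, dropped: %s", absent)
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = matrix.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        logger.warning("zero-variance signature genes excluded: %s", flat)
        sub = sub.drop(index=flat)
        sd = sd.drop(index=flat)
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("signature_score")


def correlate_kinome(
    matrix: ExpressionMatrix,
    cms4_signature,
    kinome_genes,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Pearson correlation of each kinase gene against the signature score.

    One cohort at a time. The p-value is one-sided for positive correlation
    (t reference with n-2 df); a kinase passes when r > 0 and p < threshold.
    Kinases absent from the matrix are omitted with a warning.
    """
    if matrix.shape[1] < 10:
        raise ValueError("need >= 10 samples for the kinome screen")
    score = signature_score(matrix, cms4_signature).to_numpy()
    n = len(score)
    rows = []
    for kid in kinome_genes:
        if kid not in matrix.data.index:
            logger.warning("kinase %s absent from matrix, omitted", kid)
            continue
        x = matrix.data.loc[kid].to_numpy()
        if x.std() == 0 or score.std() == 0:
            r, p = 0.0, 1.0
        else:
            r = float(np.corrcoef(x, score)[0, 1])
            t = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
            p = float(sps.t.sf(t, df=n - 2))
        rows.append((kid, r, p, bool(r > 0 and p < p_threshold)))
    return pd.DataFrame(rows, columns=["kinase", "r", "p", "passed"]).set_index("kinase")


def intersect_cohorts(
    results_per_cohort: list[pd.DataFrame], kinase_classes: pd.Series | None = None
) -> pd.DataFrame:
    """Kinases passing the screen in every cohort.

    ``kinase_classes`` optionally maps kinase id -> tyrosine-kinase flag;
    unknown kinases get ``is_tk = False``. An empty intersection is a valid
    (empty) result.
    """
    if len(results_per_cohort) < 2:
        raise ValueError("need >= 2 cohorts to intersect")
    pass_sets = [set(res.index[res["passed"]]) for res in results_per_cohort]
    hits = sorted(set.intersection(*pass_sets))
    out = pd.DataFrame(index=pd.Index(hits, name="kinase"))
    for i, res in enumerate(results_per_cohort):
        out[f"r_cohort{i + 1}"] = res["r"].reindex(hits)
    if kinase_classes is not None:
        out["is_tk"] = kinase_classes.reindex(hits).fillna(False).astype(bool)
    else:
        out["is_tk"] = False
    return out


@dataclass
class SelectivityScore:
    """Fraction of tested kinases bound below the Kd cutoff."""

    score: float
    n_hits: int
    n_tested: int


def selectivity_score(kd_profile: pd.Series, kd_cutoff: float = DEFAULT_KD_CUTOFF_UM) -> SelectivityScore:
    """Selectivity S = (# kinases with Kd strictly < cutoff) / (# tested).

    Missing values mean 'not tested' and are excluded from both numerator and
    denominator.
    """
    tested = kd_profile.dropna()
    if tested.empty:
        raise ValueError("inhibitor never tested")
    n_hits = int((tested < kd_cutoff).sum())
    return SelectivityScore(score=n_hits / len(tested), n_hits=n_hits, n_tested=len(tested))


def rank_inhibitors(
    kd: pd.DataFrame, cms4_kinases, kd_cutoff: float = DEFAULT_KD_CUTOFF_UM
) -> pd.DataFrame:
    """Rank inhibitors hitting >=1 screen kinase, most selective first.

    Selectivity is computed over all tested kinases; ranking is ascending in
    S (rank 1 = most selective), ties broken by more screen-kinase hits, then
    by inhibitor id.
    """
    cms4_kinases = [k for k in cms4_kinases if k in kd.columns]
    if not cms4_kinases:
        raise ValueError("no screen kinase present in the Kd matrix")
    rows = []
    for inh, profile in kd.iterrows():
        if profile.dropna().empty:
            continue
        sub = profile[cms4_kinases].dropna()
        targets_hit = sorted(sub.index[sub < kd_cutoff])
        if not targets_hit:
            continue
        s = selectivity_score(profile, kd_cutoff)
        rows.append((inh, s.score, s.n_hits, s.n_tested, len(targets_hit), targets_hit))
    if not rows:
        logger.warning("no inhibitor hits any screen kinase below %g uM", kd_cutoff)
        return pd.DataFrame(
            columns=["selectivity", "n_hits", "n_tested", "n_cms4_hits", "cms4_targets_hit", "rank"]
        )
    out = pd.DataFrame(
        rows,
        columns=["inhibitor", "selectivity", "n_hits", "n_tested", "n_cms4_hits", "cms4_targets_hit"],
    ).set_index("inhibitor")
    out = (
        out.reset_index()
        .sort_values(
            by=["selectivity", "n_cms4_hits", "inhibitor"], ascending=[True, False, True]
        )
        .set_index("inhibitor")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def run_screen(
    cohorts: list[ExpressionMatrix],
    cms4_signature,
    kinome_genes,
    kd: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    kd_cutoff: float = DEFAULT_KD_CUTOFF_UM,
    kinase_classes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screen: correlate per cohort, intersect, rank inhibitors.

    Returns ``(screen_kinases, inhibitor_ranking)``.
    """
    results = [
        correlate_kinome(c, cms4_signature, kinome_genes, p_threshold) for c in cohorts
    ]
    hits = intersect_cohorts(results, kinase_classes)
    ranking = rank_inhibitors(kd, list(hits.index), kd_cutoff) if len(hits) else pd.DataFrame()
    return hits, ranking
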