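"""CMS classification: 4-gene CMS4 scoring, multi-biopsy tumor calls, and
piggyback multi-class calling.

Two classifiers live here. The 4-gene scorer mirrors the diagnostic RT-qPCR
test on PDGFRA/PDGFRB/PDGFC/KIT: a logistic model on z-scored expression with
non-negative gene weights, so raising any panel gene can never lower the CMS4
probability. The multi-class path pools query samples with a balanced labeled
reference ("piggyback" pooling), normalizes jointly, and trains a
random-forest probability model on the reference labels; a sample whose
maximum subtype probability does not exceed 0.5 is called indeterminate.

Tumor-level calls average per-biopsy CMS4 probabilities (weighted, QC-passing
biopsies only); a tumor is CMS4 iff the weighted mean is strictly above 0.5,
and is flagged heterogeneous when its biopsies' binary calls disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix

FOUR_GENES = ("PDGFRA", "PDGFRB", "PDGFC", "KIT")
SUBTYPES = ("CMS1", "CMS2", "CMS3", "CMS4")
INDETERMINATE = "indeterminate"
CALL_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# 4-gene CMS4 scorer
# ---------------------------------------------------------------------------


@dataclass
class FourGeneScorer:
    """Monotone logistic CMS4 scorer on the 4-gene panel.

    Gene weights are constrained non-negative, so the score is monotone
    non-decreasing in each gene. Query values are z-scored with the training
    means/SDs.
    """

    genes: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    intercept: float

    def predict_proba(self, matrix: ExpressionMatrix) -> pd.Series:
        missing = [g for g in self.genes if g not in matrix.data.index]
        if missing:
            raise ValueError(f"panel genes absent from matrix: {missing}")
        x = matrix.data.loc[list(self.genes)].to_numpy().T
        z = (x - self.means) / self.sds
        return pd.Series(
            expit(z @ self.weights + self.intercept), index=matrix.samples, name="p_cms4"
        )


def train_four_gene_scorer(
    reference: ExpressionMatrix, labels: pd.Series, genes=FOUR_GENES
) -> FourGeneScorer:
    """Fit the non-negative-weight logistic scorer on a labeled reference.

    ``labels`` flags CMS4 (truthy) vs not per reference sample; both classes
    must be present. The fit minimizes the ridge-regularized logistic loss
    with L-BFGS-B bounds (weights >= 0, free intercept), which is convex and
    deterministic.
    """
    genes = tuple(genes)
    missing = [g for g in genes if g not in reference.data.index]
    if missing:
        raise ValueError(f"panel genes absent from reference: {missing}")
    y = labels.reindex(reference.samples).to_numpy().astype(bool)
    if y.all() or not y.any():
        raise ValueError("reference must contain both CMS4 and non-CMS4 samples")

    x = reference.data.loc[list(genes)].to_numpy().T
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError("zero-variance panel gene in reference")
    z = (x - means) / sds
    yf = y.astype(float)
    alpha = 1e-3  # small ridge keeps the separable case finite

    def loss(theta):
        w, b = theta[:-1], theta[-1]
        eta = z @ w + b
        # stable log(1 + exp(eta)) - y*eta
        nll = np.logaddexp(0.0, eta) - yf * eta
        grad_eta = expit(eta) - yf
        grad_w = z.T @ grad_eta + alpha * w
        grad_b = grad_eta.sum()
        return nll.sum() + 0.5 * alpha * w @ w, np.append(grad_w, grad_b)

    theta0 = np.zeros(len(genes) + 1)
    bounds = [(0.0, None)] * len(genes) + [(None, None)]
    res = minimize(loss, theta0, jac=True, method="L-BFGS-B", bounds=bounds)
    return FourGeneScorer(
        genes=genes,
        means=means,
        sds=sds,
        weights=res.x[:-1],
        intercept=float(res.x[-1]),
    )


# ---------------------------------------------------------------------------
# multi-biopsy tumor aggregation
# ---------------------------------------------------------------------------


@dataclass
class TumorCall:
    """Weighted-mean CMS4 call over a tumor's QC-passing biopsies."""

    tumor: str
    mean_probability: float
    call: str  # "CMS4" | "not-CMS4"
    n_biopsies_used: int
    heterogeneous: bool


def aggregate_tumor(biopsies: pd.DataFrame, tumor: str = "") -> TumorCall:
    """Aggregate per-biopsy CMS4 probabilities into one tumor call.

    ``biopsies`` needs a ``p_cms4`` column; optional ``weight`` (default 1)
    and ``qc_pass`` (default True). The weighted mean over QC-passing
    biopsies is compared strictly against 0.5; the heterogeneity flag records
    whether the biopsies' individual binary calls (p > 0.5) disagree.
    """
    df = biopsies.copy()
    if "weight" not in df:
        df["weight"] = 1.0
    if "qc_pass" not in df:
        df["qc_pass"] = True
    if (df["weight"] < 0).any():
        raise ValueError("biopsy weights must be >= 0")
    used = df[df["qc_pass"].astype(bool)]
    used = used[used["weight"] > 0]
    if used.empty:
        raise ValueError(f"tumor {tumor or '?'} unevaluable: no QC-passing biopsy")
    w = used["weight"].to_numpy(dtype=float)
    p = used["p_cms4"].to_numpy(dtype=float)
    mean_p = float(np.sum(w * p) / np.sum(w))
    binary = p > CALL_THRESHOLD
    return TumorCall(
        tumor=tumor,
        mean_probability=mean_p,
        call="CMS4" if mean_p > CALL_THRESHOLD else "not-CMS4",
        n_biopsies_used=int(len(used)),
        heterogeneous=bool(binary.any() and not binary.all()),
    )


def aggregate_tumors(biopsies: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`aggregate_tumor` per tumor id; returns one row per tumor."""
    if "tumor" not in biopsies:
        raise ValueError("annotation needs a 'tumor' column")
    rows = []
    for tid, grp in biopsies.groupby("tumor", sort=True):
        call = aggregate_tumor(grp, tumor=str(tid))
        rows.append(
            (tid, call.mean_probability, call.call, call.n_biopsies_used, call.heterogeneous)
        )
    return pd.DataFrame(
        rows, columns=["tumor", "mean_p_cms4", "call", "n_biopsies_used", "heterogeneous"]
    ).set_index("tumor")


# ---------------------------------------------------------------------------
# size-factor normalization
# ---------------------------------------------------------------------------


def size_factor_normalize(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization of a count matrix.

    The per-gene reference is the geometric mean across samples over genes
    with no zero count; each sample's factor is the median ratio of its
    counts to the reference over those genes; counts are divided by the
    factor.
    """
    counts.validate()
    if not counts.is_counts:
        raise ValueError("size-factor normalization expects raw counts")
    mat = counts.data.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no reference genes: every gene has a zero count in some sample")
    log_ref = np.log(mat[all_nonzero]).mean(axis=1)
    log_ratios = np.log(mat[all_nonzero]) - log_ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    norm = counts.data / factors
    return (
        ExpressionMatrix(norm, is_counts=False),
        pd.Series(factors, index=counts.samples, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# piggyback multi-class classification
# ---------------------------------------------------------------------------


def _joint_normalize(pooled: ExpressionMatrix) -> pd.DataFrame:
    """Size factors (if counts) then log2 and per-gene z-score across the pool."""
    if pooled.is_counts:
        normed, _ = size_factor_normalize(pooled)
        data = np.log2(normed.data + 1.0)
    else:
        data = pooled.data
    sd = data.std(axis=1, ddof=1)
    keep = sd > 0
    data = data.loc[keep]
    return data.sub(data.mean(axis=1), axis=0).div(sd[keep], axis=0)


def piggyback_classify(
    query: ExpressionMatrix,
    reference: ExpressionMatrix,
    reference_labels: pd.Series,
    seed: int = 0,
    n_estimators: int = 500,
) -> pd.DataFrame:
    """Pool query with a balanced labeled reference and call CMS per sample.

    Query and reference are concatenated on their shared gene panel, jointly
    normalized (size factors when counts, then per-gene z-scores over the
    pool), and a random forest is trained on the reference labels. Each query
    sample gets a probability vector over CMS1..CMS4 and a call: the argmax
    subtype when its probability is strictly above 0.5, else indeterminate.
    """
    ref_labels = reference_labels.reindex(reference.samples)
    present = set(ref_labels.dropna().unique())
    missing = [s for s in SUBTYPES if s not in present]
    if missing:
        raise ValueError(f"unbalanced reference: missing subtypes {missing}")
    shared = reference.genes.intersection(query.genes)
    if len(shared) == 0:
        raise ValueError("query and reference share no genes")
    if query.is_counts != reference.is_counts:
        raise ValueError("query and reference must both be counts or both normalized")

    overlap = query.samples.intersection(reference.samples)
    if len(overlap):
        raise ValueError(f"query/reference sample id collision: {list(overlap[:3])}")
    pooled = ExpressionMatrix(
        pd.concat([query.data.loc[shared], reference.data.loc[shared]], axis=1),
        is_counts=query.is_counts,
    )
    z = _joint_normalize(pooled)
    labeled = ref_labels[ref_labels.isin(SUBTYPES)].index
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(z[labeled].to_numpy().T, ref_labels.loc[labeled].to_numpy())
    probs = clf.predict_proba(z[query.samples].to_numpy().T)
    out = pd.DataFrame(probs, index=query.samples, columns=clf.classes_)
    out = out.reindex(columns=list(SUBTYPES), fill_value=0.0)
    top = out.max(axis=1)
    call = out.idxmax(axis=1).where(top > CALL_THRESHOLD, INDETERMINATE)
    out["call"] = call
    return out
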