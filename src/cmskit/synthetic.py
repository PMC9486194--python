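"""Synthetic cohorts with planted ground truth.

Every generator here emulates one input of the analysis chain and returns its
ground truth alongside the data, so recovery can be tested end-to-end without
patient data:

* a 4-subtype reference cohort (CMS1-4) with subtype-specific marker genes on
  a Gaussian log2 scale;
* a kinome layer whose genes correlate with the CMS4 signature score at
  controlled strengths;
* an inhibitor x kinase Kd matrix with one planted selective inhibitor;
* multi-region tumor biopsies (4-gene panel) with controlled intra-tumor
  subtype heterogeneity;
* paired pre/post treatment samples with patient random intercepts and a
  planted mesenchymal-down / epithelial-up shift;
* exponential survival with a group hazard ratio and independent censoring.

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

SUBTYPES = ("CMS1", "CMS2", "CMS3", "CMS4")
UNLABELED = "UNLABELED"
FOUR_GENES = ("PDGFRA", "PDGFRB", "PDGFC", "KIT")

BASELINE_LOG2 = 7.0  # typical log2 expression of a moderately expressed gene


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reference cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Reference cohort layout.

    ``subtype_proportions`` may sum to less than 1; the shortfall becomes
    unlabeled background samples carrying no marker shift. ``effect_size`` is
    the mean log2 shift of a subtype's markers within that subtype.
    """

    n_samples: int = 3232
    subtype_proportions: tuple[float, float, float, float] = (0.14, 0.37, 0.13, 0.23)
    n_genes: int = 2000
    signature_sizes: tuple[int, int, int, int] = (30, 30, 30, 30)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.subtype_proportions, dtype=float)
        if len(p) != 4 or (p < 0).any():
            raise ValueError("subtype_proportions must be 4 non-negative values")
        if p.sum() > 1 + 1e-9:
            raise ValueError(f"subtype proportions sum to {p.sum():.6f} > 1")
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if any(s <= 0 for s in self.signature_sizes):
            raise ValueError("signature sizes must be positive")
        if sum(self.signature_sizes) > self.n_genes:
            raise ValueError("signatures exceed the gene universe")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def marker_genes(spec: CohortSpec) -> dict[str, list[str]]:
    """Per-subtype marker gene ids as laid out by :func:`generate_reference_cohort`."""
    out = {}
    for k, subtype in enumerate(SUBTYPES):
        out[subtype] = [f"{subtype}_M{j:03d}" for j in range(spec.signature_sizes[k])]
    return out


def generate_reference_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Gaussian log2 cohort with subtype-shifted marker genes.

    Returns the matrix and the true subtype label per sample (``UNLABELED``
    for background samples when the proportions sum to < 1).
    """
    rng = _rng(spec.seed)
    p = np.asarray(spec.subtype_proportions, dtype=float)
    labels_pool = list(SUBTYPES) + [UNLABELED]
    probs = np.append(p, max(0.0, 1.0 - p.sum()))
    probs = probs / probs.sum()
    labels = rng.choice(labels_pool, size=spec.n_samples, p=probs)

    markers = marker_genes(spec)
    gene_ids = [g for genes in markers.values() for g in genes]
    gene_ids += [f"G{j:05d}" for j in range(spec.n_genes - len(gene_ids))]
    samples = [f"S{j:05d}" for j in range(spec.n_samples)]

    values = BASELINE_LOG2 + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_samples)
    )
    data = pd.DataFrame(values, index=gene_ids, columns=samples)
    label_s = pd.Series(labels, index=samples, name="subtype")
    for subtype, genes in markers.items():
        mask = (label_s == subtype).to_numpy()
        data.loc[genes, mask] += spec.effect_size
    return ExpressionMatrix(data, is_counts=False), label_s


def as_counts(matrix: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Poisson count layer over a log2 matrix (lambda = 2^x), for count-path tests."""
    rng = _rng(seed)
    lam = np.exp2(matrix.data.to_numpy())
    counts = rng.poisson(lam).astype(np.int64)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=matrix.genes, columns=matrix.samples), is_counts=True
    )


# ---------------------------------------------------------------------------
# kinome layer
# ---------------------------------------------------------------------------


def plant_kinome_layer(
    matrix: ExpressionMatrix,
    cms4_signature: list[str],
    kinase_specs: list[tuple[str, float]],
    seed: int = 0,
    kinase_sd: float = 1.0,
) -> ExpressionMatrix:
    """Add kinase genes correlating with the CMS4 signature score.

    Each planted kinase row is ``rho * z(score) + sqrt(1 - rho^2) * noise``
    rescaled to expression units, so its Pearson correlation with the mean
    z-score of ``cms4_signature`` converges to the target rho. Existing
    (non-kinase) rows are untouched.
    """
    missing = [g for g in cms4_signature if g not in matrix.data.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    for kid, rho in kinase_specs:
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"target correlation for {kid} outside [-1, 1]: {rho}")

    rng = _rng(seed)
    sig = matrix.data.loc[cms4_signature]
    z = sig.sub(sig.mean(axis=1), axis=0).div(sig.std(axis=1, ddof=1), axis=0)
    score = z.mean(axis=0).to_numpy()
    zscore = (score - score.mean()) / score.std()

    n = matrix.shape[1]
    rows = {}
    for kid, rho in kinase_specs:
        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std()
        # residualize so the empirical correlation is exactly rho up to scaling
        noise = noise - zscore * np.dot(noise, zscore) / np.dot(zscore, zscore)
        if noise.std() > 0:
            noise = noise / noise.std()
        latent = rho * zscore + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        rows[kid] = BASELINE_LOG2 + kinase_sd * latent
    kin = pd.DataFrame(rows, index=matrix.samples).T
    data = pd.concat([matrix.data.drop(index=kin.index, errors="ignore"), kin])
    return ExpressionMatrix(data, is_counts=matrix.is_counts)


# ---------------------------------------------------------------------------
# Kd matrix
# ---------------------------------------------------------------------------


def generate_kd_matrix(
    n_inhibitors: int,
    n_kinases: int,
    planted: tuple[str, list[str], float, float],
    fraction_tested: float = 1.0,
    seed: int = 0,
    kinase_ids: list[str] | None = None,
    background_median_kd: float = 10.0,
    background_log_sd: float = 1.5,
) -> pd.DataFrame:
    """Inhibitor x kinase Kd table (µM) with one planted selective inhibitor.

    ``planted = (inhibitor_id, target_kinases, on_target_kd, off_target_kd)``.
    The planted inhibitor is always tested on its targets (Kd = on_target_kd)
    and carries off_target_kd on every other tested kinase. Background
    inhibitors draw log-normal Kd values. Untested cells are NaN; each cell is
    tested independently with probability ``fraction_tested``.
    """
    inh_id, targets, on_kd, off_kd = planted
    if not 0 < fraction_tested <= 1:
        raise ValueError("fraction_tested must be in (0, 1]")
    if on_kd >= off_kd:
        raise ValueError("on_target_kd must be < off_target_kd")
    if kinase_ids is None:
        kinase_ids = [f"K{j:04d}" for j in range(n_kinases)]
    if len(kinase_ids) != n_kinases:
        raise ValueError("kinase_ids length must equal n_kinases")
    absent = set(targets) - set(kinase_ids)
    if absent:
        raise ValueError(f"planted targets not among kinases: {sorted(absent)}")

    rng = _rng(seed)
    inhibitors = [inh_id] + [f"INH{j:03d}" for j in range(n_inhibitors - 1)]
    kd = rng.lognormal(mean=np.log(background_median_kd), sigma=background_log_sd,
                       size=(n_inhibitors, n_kinases))
    tested = rng.random((n_inhibitors, n_kinases)) < fraction_tested
    # every inhibitor must be tested somewhere
    for i in range(n_inhibitors):
        if not tested[i].any():
            tested[i, rng.integers(n_kinases)] = True
    df = pd.DataFrame(np.where(tested, kd, np.nan), index=inhibitors, columns=kinase_ids)
    df.loc[inh_id] = np.where(tested[0], off_kd, np.nan)
    df.loc[inh_id, targets] = on_kd
    return df


# ---------------------------------------------------------------------------
# multi-region biopsies
# ---------------------------------------------------------------------------


def generate_multibiopsy_tumors(
    n_tumors: int,
    biopsies_per_tumor: int = 3,
    cms4_fraction: float = 0.38,
    heterogeneity_rate: float = 0.0,
    seed: int = 0,
    separation: float = 3.0,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Multi-region 4-gene biopsies with controlled intra-tumor heterogeneity.

    Each tumor carries a true binary label (CMS4 with probability
    ``cms4_fraction``). With probability ``heterogeneity_rate`` a tumor is
    heterogeneous: 1..(b-1) of its biopsies are drawn from the opposite
    class's 4-gene distribution (CMS4 biopsies have the panel genes shifted up
    by ``separation`` log2 units). Returns the biopsy matrix, a per-biopsy
    annotation (tumor id, true biopsy label), and the true tumor labels.
    """
    if biopsies_per_tumor < 1:
        raise ValueError("biopsies_per_tumor must be >= 1")
    if not 0 <= cms4_fraction <= 1 or not 0 <= heterogeneity_rate <= 1:
        raise ValueError("rates must be in [0, 1]")

    rng = _rng(seed)
    tumor_ids = [f"T{j:04d}" for j in range(n_tumors)]
    tumor_cms4 = rng.random(n_tumors) < cms4_fraction

    rows = []
    for t, tid in enumerate(tumor_ids):
        flips = np.zeros(biopsies_per_tumor, dtype=bool)
        if biopsies_per_tumor >= 2 and rng.random() < heterogeneity_rate:
            k = int(rng.integers(1, biopsies_per_tumor))
            flips[rng.choice(biopsies_per_tumor, size=k, replace=False)] = True
        for b in range(biopsies_per_tumor):
            is_cms4 = bool(tumor_cms4[t]) ^ bool(flips[b])
            rows.append((f"{tid}_B{b}", tid, is_cms4))
    ann = pd.DataFrame(rows, columns=["biopsy", "tumor", "biopsy_is_cms4"]).set_index("biopsy")

    mu = BASELINE_LOG2 + separation * ann["biopsy_is_cms4"].to_numpy(dtype=float)
    values = mu[:, None] + noise_sd * rng.standard_normal((len(ann), len(FOUR_GENES)))
    expr = ExpressionMatrix(
        pd.DataFrame(values.T, index=list(FOUR_GENES), columns=ann.index)
    )
    tumor_truth = pd.Series(tumor_cms4, index=tumor_ids, name="tumor_is_cms4")
    return expr, ann, tumor_truth


# ---------------------------------------------------------------------------
# paired treatment design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Planted pre/post treatment effect.

    ``down_genes`` (mesenchymal program) are shifted by -``shift`` and
    ``up_genes`` (epithelial junction / proliferation / TOP targets) by
    +``shift`` in post-treatment samples, on the log2 scale. Patients share a
    random intercept (SD ``patient_sd``) across their PRE and POST biopsies.
    """

    down_genes: tuple[str, ...]
    up_genes: tuple[str, ...]
    shift: float = 2.0
    n_patients: int = 5
    biopsies_per_arm: int = 3
    patient_sd: float = 1.0
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        overlap = set(self.down_genes) & set(self.up_genes)
        if overlap:
            raise ValueError(f"up/down gene sets overlap: {sorted(overlap)}")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.n_patients < 1 or self.biopsies_per_arm < 1:
            raise ValueError("design sizes must be positive")
        if self.patient_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")


def generate_paired_treatment(
    spec: TreatmentEffectSpec, base_cohort: ExpressionMatrix
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Paired PRE/POST biopsies over the base cohort's gene universe.

    Per-gene baselines are the base cohort means; each patient draws one
    random intercept shared by all their biopsies; POST samples receive the
    planted signed shifts. Returns the matrix and an annotation table
    (sample, patient, arm).
    """
    universe = set(base_cohort.genes)
    missing = (set(spec.down_genes) | set(spec.up_genes)) - universe
    if missing:
        raise ValueError(f"planted genes absent from base cohort: {sorted(missing)}")

    rng = _rng(spec.seed)
    baseline = base_cohort.data.mean(axis=1)
    genes = base_cohort.genes
    effect = pd.Series(0.0, index=genes)
    effect.loc[list(spec.down_genes)] = -spec.shift
    effect.loc[list(spec.up_genes)] = spec.shift

    records = []
    columns = {}
    for i in range(spec.n_patients):
        pid = f"P{i:02d}"
        intercept = spec.patient_sd * rng.standard_normal()
        for arm in ("PRE", "POST"):
            for b in range(spec.biopsies_per_arm):
                sid = f"{pid}_{arm}_{b}"
                vals = (
                    baseline.to_numpy()
                    + intercept
                    + (effect.to_numpy() if arm == "POST" else 0.0)
                    + spec.residual_sd * rng.standard_normal(len(genes))
                )
                columns[sid] = vals
                records.append((sid, pid, arm))
    data = pd.DataFrame(columns, index=genes)
    ann = pd.DataFrame(records, columns=["sample", "patient", "arm"]).set_index("sample")
    return ExpressionMatrix(data, is_counts=False), ann


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival with a planted group hazard ratio.

    ``baseline_hazard`` and ``censor_rate`` are per-month rates; flagged
    samples have their hazard multiplied by ``exp(log_hazard_ratio)``.
    Censoring is independent exponential truncated at ``max_follow_up``.
    """

    baseline_hazard: float = 0.02
    log_hazard_ratio: float = 0.0
    censor_rate: float = 0.005
    max_follow_up: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0 or self.max_follow_up <= 0:
            raise ValueError("censoring parameters must be positive")


def generate_survival(
    groups, spec: SurvivalSpec, stages=None
) -> pd.DataFrame:
    """Survival records (time in months, event flag, stage, group) per sample.

    ``groups`` flags the samples whose hazard is scaled by the hazard ratio
    (any truthy encoding).
    """
    flags = np.asarray(groups).astype(bool)
    n = len(flags)
    if n == 0:
        raise ValueError("groups must be nonempty")
    rng = _rng(spec.seed)
    hazard = spec.baseline_hazard * np.exp(spec.log_hazard_ratio * flags)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_time = np.minimum(rng.exponential(1.0 / spec.censor_rate, n), spec.max_follow_up)
    else:
        censor_time = np.full(n, spec.max_follow_up)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    if stages is None:
        stages = rng.choice(["II", "III"], size=n)
    return pd.DataFrame(
        {
            "time": time,
            "event": event.astype(int),
            "stage": np.asarray(stages),
            "group": flags,
        },
        index=[f"S{j:05d}" for j in range(n)],
    )
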