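"""Planted-truth recovery and calibration experiments.

Each function here runs one of the package's validation experiments on the
synthetic generators: plant a known structure, run the corresponding analysis
path, and measure how well the truth is recovered (or how well a null test is
calibrated). They are used both by the test suite and by the reproduction
script, with the problem sizes they were designed at as defaults.

All randomness is controlled by a single ``seed``; child seeds are spawned
deterministically and stay below 2**31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import classify as cl
from . import screen as sc
from . import stats as st
from . import stratify as strat
from . import synthetic as syn


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# target screen: planted selective inhibitor
# ---------------------------------------------------------------------------


def screen_recovery(
    n_seeds: int = 100,
    n_samples: int = 500,
    n_true_kinases: int = 10,
    n_null_kinases: int = 20,
    kinase_rho: float = 0.5,
    seed: int = 0,
) -> dict:
    """Full-screen recovery: does the planted selective inhibitor rank 1?

    Per replicate: two independent cohorts with a CMS4 marker signature, a
    kinome layer with ``n_true_kinases`` genes correlated at ``kinase_rho``
    with the CMS4 signature score plus uncorrelated null kinases, and a Kd
    matrix whose planted inhibitor binds four of the true kinases in the low
    nanomolar range and everything else weakly. Reports the fraction of
    replicates with the planted inhibitor at rank 1, plus kinase-level
    recovery and false-positive counts.
    """
    true_k = [f"TRUEK{j:02d}" for j in range(n_true_kinases)]
    null_k = [f"NULLK{j:02d}" for j in range(n_null_kinases)]
    kinome = true_k + null_k
    extra_k = [f"XK{j:03d}" for j in range(40)]

    rank1 = 0
    recovered = []
    false_pos = []
    for s in _child_seeds(seed, n_seeds):
        cohorts = []
        spec0 = syn.CohortSpec(
            n_samples=n_samples,
            n_genes=120,
            subtype_proportions=(0.25, 0.25, 0.25, 0.25),
            signature_sizes=(15, 15, 15, 15),
            seed=int(s),
        )
        sig = syn.marker_genes(spec0)["CMS4"]
        for j in (0, 1):
            spec = syn.CohortSpec(
                n_samples=n_samples,
                n_genes=120,
                subtype_proportions=(0.25, 0.25, 0.25, 0.25),
                signature_sizes=(15, 15, 15, 15),
                seed=int(s) + j,
            )
            cohort, _ = syn.generate_reference_cohort(spec)
            specs = [(k, kinase_rho) for k in true_k] + [(k, 0.0) for k in null_k]
            cohorts.append(syn.plant_kinome_layer(cohort, sig, specs, seed=int(s) + 10 + j))
        kd = syn.generate_kd_matrix(
            n_inhibitors=40,
            n_kinases=len(kinome) + len(extra_k),
            planted=("PLANTED", true_k[:4], 0.01, 100.0),
            fraction_tested=0.9,
            seed=int(s) + 99,
            kinase_ids=kinome + extra_k,
        )
        hits, ranking = sc.run_screen(cohorts, sig, kinome, kd)
        recovered.append(len(set(hits.index) & set(true_k)))
        false_pos.append(len(set(hits.index) - set(true_k)))
        if len(ranking) and ranking.index[0] == "PLANTED":
            rank1 += 1
    return {
        "rank1_rate": rank1 / n_seeds,
        "mean_true_kinases_recovered": float(np.mean(recovered)),
        "mean_false_positive_kinases": float(np.mean(false_pos)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# multi-biopsy tumor calls vs heterogeneity
# ---------------------------------------------------------------------------


def tumor_call_accuracy(
    heterogeneity_rates=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_tumors: int = 1500,
    biopsies_per_tumor: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Tumor-call accuracy across an intra-tumor heterogeneity grid.

    The 4-gene scorer is trained on an independent homogeneous reference and
    applied to test cohorts generated at each heterogeneity rate; accuracy is
    the agreement of the weighted-mean tumor call with the true tumor label.
    """
    ref_expr, ref_ann, _ = syn.generate_multibiopsy_tumors(
        n_tumors=300, biopsies_per_tumor=biopsies_per_tumor, heterogeneity_rate=0.0,
        seed=seed + 1,
    )
    scorer = cl.train_four_gene_scorer(ref_expr, ref_ann["biopsy_is_cms4"])
    acc = {}
    for i, rate in enumerate(heterogeneity_rates):
        expr, ann, truth = syn.generate_multibiopsy_tumors(
            n_tumors=n_tumors,
            biopsies_per_tumor=biopsies_per_tumor,
            heterogeneity_rate=rate,
            seed=seed + 100 + i,
        )
        biopsies = scorer.predict_proba(expr).to_frame().join(ann)
        calls = cl.aggregate_tumors(biopsies)
        acc[rate] = float((calls["call"].eq("CMS4") == truth).mean())
    return pd.Series(acc, name="accuracy")


# ---------------------------------------------------------------------------
# mixed-model calibration and recovery
# ---------------------------------------------------------------------------


def lmm_calibration(
    n_null: int = 2000,
    n_effect: int = 500,
    n_patients: int = 5,
    biopsies_per_arm: int = 3,
    shift: float = 2.0,
    patient_sd: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error under the null and bias under a planted shift.

    The design mirrors the paired study: ``n_patients`` patients with
    ``biopsies_per_arm`` PRE and POST biopsies each, patient random
    intercepts, unit residual noise.
    """
    n = n_patients * biopsies_per_arm * 2
    patients = np.repeat([f"P{i}" for i in range(n_patients)], biopsies_per_arm * 2)
    arms = np.tile(["PRE"] * biopsies_per_arm + ["POST"] * biopsies_per_arm, n_patients)
    post = (arms == "POST").astype(float)

    rng_seeds = _child_seeds(seed, n_null + n_effect)
    rejected = 0
    for s in rng_seeds[:n_null]:
        rng = np.random.default_rng(int(s))
        y = np.repeat(patient_sd * rng.standard_normal(n_patients), biopsies_per_arm * 2)
        y = y + rng.standard_normal(n)
        if st.lmm_random_intercept(y, patients, arms).p_value < alpha:
            rejected += 1

    estimates = np.empty(n_effect)
    for i, s in enumerate(rng_seeds[n_null:]):
        rng = np.random.default_rng(int(s))
        y = np.repeat(patient_sd * rng.standard_normal(n_patients), biopsies_per_arm * 2)
        y = y + rng.standard_normal(n) + shift * post
        fit = st.lmm_random_intercept(y, patients, arms)
        # contrast is second-sorted-level minus first (PRE - POST); flip
        estimates[i] = -fit.estimate
    return {
        "type1_error": rejected / n_null,
        "mean_estimate": float(estimates.mean()),
        "bias": float(estimates.mean() - shift),
        "n_null": n_null,
        "n_effect": n_effect,
    }


# ---------------------------------------------------------------------------
# clustered correlation recovery
# ---------------------------------------------------------------------------


def clustered_correlation_recovery(
    n_seeds: int = 500,
    rho: float = 0.8,
    n_clusters: int = 20,
    cluster_size: int = 10,
    cluster_share: float = 0.4,
    seed: int = 0,
) -> dict:
    """Bias of the pooled marginal correlation on clustered bivariate data.

    Cluster and individual components both carry correlation ``rho`` so the
    marginal correlation is exactly ``rho``; ``cluster_share`` is the
    fraction of total variance contributed by the cluster component.
    """
    cov = np.array([[1.0, rho], [rho, 1.0]])
    l_c = np.linalg.cholesky(cluster_share * cov)
    l_e = np.linalg.cholesky((1 - cluster_share) * cov)
    clusters = np.repeat(np.arange(n_clusters), cluster_size)
    estimates = np.empty(n_seeds)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        rng = np.random.default_rng(int(s))
        cl_fx = rng.standard_normal((n_clusters, 2)) @ l_c.T
        ind = rng.standard_normal((n_clusters * cluster_size, 2)) @ l_e.T
        xy = ind + cl_fx[clusters]
        res = st.marginal_pearson_clustered(xy[:, 0], xy[:, 1], clusters)
        estimates[i] = res.rho
    return {
        "mean_rho": float(estimates.mean()),
        "bias": float(estimates.mean() - rho),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# differential expression screen
# ---------------------------------------------------------------------------


def de_screen_performance(
    n_null_seeds: int = 500,
    n_power_seeds: int = 25,
    n_genes: int = 2000,
    n_per_group: int = 10,
    n_planted: int = 100,
    planted_shift_sd: float = 4.0,
    q_cutoff: float = 0.001,
    seed: int = 0,
) -> dict:
    """False discoveries under a global null and recovery of planted genes.

    Null: Gaussian noise, counts discoveries at ``q <= q_cutoff`` (mean over
    seeds). Power: ``n_planted`` genes shifted by ``planted_shift_sd`` SDs in
    the second group; reports mean recovery fraction and the fraction of
    recovered genes with the correct (up) direction.
    """
    groups = np.repeat(["A", "B"], n_per_group)
    seeds = _child_seeds(seed, n_null_seeds + n_power_seeds)

    null_discoveries = np.empty(n_null_seeds)
    for i, s in enumerate(seeds[:n_null_seeds]):
        rng = np.random.default_rng(int(s))
        mat = pd.DataFrame(rng.standard_normal((n_genes, 2 * n_per_group)))
        table = st.anova_de(mat, groups, q_cutoff=q_cutoff)
        null_discoveries[i] = int(table["significant"].sum())

    recovery = np.empty(n_power_seeds)
    correct_dir = np.empty(n_power_seeds)
    for i, s in enumerate(seeds[n_null_seeds:]):
        rng = np.random.default_rng(int(s))
        mat = pd.DataFrame(rng.standard_normal((n_genes, 2 * n_per_group)))
        mat.iloc[:n_planted, n_per_group:] += planted_shift_sd
        table = st.anova_de(mat, groups, q_cutoff=q_cutoff)
        hit = table["significant"].iloc[:n_planted]
        recovery[i] = hit.mean()
        dirs = table["direction"].iloc[:n_planted][hit]
        # group B (second sorted level) minus A: planted genes are up
        correct_dir[i] = float((dirs == "up").mean()) if len(dirs) else 1.0
    return {
        "null_mean_discoveries": float(null_discoveries.mean()),
        "recovery_rate": float(recovery.mean()),
        "direction_correct_rate": float(correct_dir.mean()),
        "n_null_seeds": n_null_seeds,
        "n_power_seeds": n_power_seeds,
    }


# ---------------------------------------------------------------------------
# survival calibration and power
# ---------------------------------------------------------------------------


def survival_calibration(
    n_null_seeds: int = 1000,
    n_power_seeds: int = 100,
    n_per_arm_null: int = 100,
    n_per_arm_power: int = 500,
    hazard_ratio: float = 2.0,
    seed: int = 0,
) -> dict:
    """Log-rank null calibration (KS vs uniform) and power at a planted HR."""
    seeds = _child_seeds(seed, n_null_seeds + n_power_seeds)
    groups_null = np.repeat([False, True], n_per_arm_null)
    p_null = np.empty(n_null_seeds)
    for i, s in enumerate(seeds[:n_null_seeds]):
        spec = syn.SurvivalSpec(log_hazard_ratio=0.0, seed=int(s))
        rec = syn.generate_survival(groups_null, spec)
        _, p_null[i] = st.log_rank(rec["time"], rec["event"], rec["group"])
    ks_p = float(sps.kstest(p_null, "uniform").pvalue)

    groups_pow = np.repeat([False, True], n_per_arm_power)
    sig = 0
    for s in seeds[n_null_seeds:]:
        spec = syn.SurvivalSpec(log_hazard_ratio=float(np.log(hazard_ratio)), seed=int(s))
        rec = syn.generate_survival(groups_pow, spec)
        _, p = st.log_rank(rec["time"], rec["event"], rec["group"])
        sig += p < 0.001
    return {
        "null_ks_p": ks_p,
        "power": sig / n_power_seeds,
        "n_null_seeds": n_null_seeds,
        "n_power_seeds": n_power_seeds,
    }


# ---------------------------------------------------------------------------
# Fisher exact vs enumeration oracle
# ---------------------------------------------------------------------------


def fisher_enumeration_oracle(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (within a relative
    slack for float ties).
    """
    table = np.asarray(table)
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = sps.hypergeom.pmf(k, n, r1, c1)
        if pk <= obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def fisher_oracle_agreement(n_tables: int = 1000, max_margin: int = 60, seed: int = 0) -> dict:
    """Fraction of random small tables where the implementation matches the oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    max_dev = 0.0
    checked = 0
    while checked < n_tables:
        tbl = rng.integers(0, max_margin // 4 + 1, size=(2, 2))
        if tbl.sum(axis=0).min() == 0 or tbl.sum(axis=1).min() == 0 or tbl.sum() > max_margin:
            continue
        checked += 1
        _, p_impl = st.contingency_test(tbl, method="fisher")
        p_oracle = fisher_enumeration_oracle(tbl)
        dev = abs(p_impl - p_oracle)
        max_dev = max(max_dev, dev)
        agree += bool(dev < 1e-10)
    return {
        "agreement_rate": float(agree / n_tables),
        "max_abs_deviation": float(max_dev),
        "n_tables": n_tables,
    }


# ---------------------------------------------------------------------------
# end-to-end stratification
# ---------------------------------------------------------------------------


def stratification_recovery(
    n_seeds: int = 100,
    n_samples: int = 400,
    induced_shift: float = 2.0,
    hazard_ratio: float = 2.0,
    seed: int = 0,
) -> dict:
    """End-to-end stratify pipeline on a planted anti-correlated structure.

    Per replicate: a 4-subtype cohort in which an "induced" gene set is
    expressed lower in CMS4 tumors and CMS4 carries a higher death hazard.
    Success requires the HIGH stratum to show a lower CMS4 proportion, a
    log-rank p < 0.05, and the HIGH survival curve above LOW at the median
    follow-up time.
    """
    success = 0
    for s in _child_seeds(seed, n_seeds):
        spec = syn.CohortSpec(
            n_samples=n_samples,
            n_genes=200,
            subtype_proportions=(0.15, 0.35, 0.15, 0.35),
            signature_sizes=(20, 20, 20, 20),
            seed=int(s),
        )
        cohort, labels = syn.generate_reference_cohort(spec)
        induced = [f"G{j:05d}" for j in range(30)]  # filler genes, re-purposed
        is_cms4 = (labels == "CMS4").to_numpy()
        cohort.data.loc[induced, is_cms4] -= induced_shift

        surv_spec = syn.SurvivalSpec(log_hazard_ratio=float(np.log(hazard_ratio)), seed=int(s) + 1)
        survival = syn.generate_survival(is_cms4, surv_spec)
        survival.index = cohort.samples

        strata, _, _, props, surv = strat.run_stratification(
            cohort, induced, labels.rename("call"), survival, seed=int(s)
        )
        res = surv["overall"]
        t_med = float(np.median(survival["time"]))
        ok = (
            props.loc["HIGH", "prop_cms4"] < props.loc["LOW", "prop_cms4"]
            and res.p_value < 0.05
            and res.curves["HIGH"].at(t_med) > res.curves["LOW"].at(t_med)
        )
        success += bool(ok)
    return {"success_rate": success / n_seeds, "n_seeds": n_seeds}
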