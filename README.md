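# cmskit

Toolkit for CMS4-directed colorectal-cancer transcriptomics: an
expression-based kinase-target / drug-selectivity screen, multi-region CMS
classification with intra-tumor heterogeneity handling, paired pre/post
treatment phenotype-shift statistics, and gene-signature cohort
stratification with survival comparison.

## Who this is for

Computational biologists analyzing colorectal cancer expression data in the
Consensus Molecular Subtype (CMS) framework — in particular the mesenchymal
CMS4 subtype, which carries the worst prognosis and is the natural target
for subtype-switching therapy. The package implements the full analysis
chain as a tested library plus a thin CLI, and ships synthetic-data
generators with planted ground truth so every stage can be validated without
patient data.

## The core methods

- **Selectivity score.** For an inhibitor with Kd values (µM) over a kinase
  panel, S = #{kinases with Kd < 3 µM} / #{kinases tested}; untested kinases
  count in neither term. Candidate subtype-targeting inhibitors are those
  hitting ≥1 screen kinase below the cutoff, ranked ascending in S (lower =
  more selective). Screen kinases are those with positive Pearson
  correlation to the CMS4 signature score at p < 10⁻⁶ in **every** cohort.
- **Weighted multi-biopsy call.** With per-biopsy CMS4 probabilities pᵢ and
  weights wᵢ over QC-passing biopsies, P̄ = Σwᵢpᵢ/Σwᵢ; the tumor is CMS4
  iff P̄ > 0.5, and is flagged heterogeneous when the biopsies' binary calls
  disagree. Per-biopsy probabilities come from a monotone (non-negative
  weight) logistic model on the z-scored 4-gene panel PDGFRA, PDGFRB,
  PDGFC, KIT.
- **Piggyback CMS calling.** Query samples are pooled with a balanced
  labeled reference, jointly normalized, and classified by a random forest;
  a sample is *indeterminate* unless some subtype's probability exceeds 0.5.
- **Paired contrasts.** Pre/post effects are estimated by a linear mixed
  model, value ~ condition + (1 | patient), REML, Wald t test — plus
  genome-wide one-way ANOVA with Benjamini–Hochberg FDR (q ≤ 0.001), and
  marginal Pearson correlation with cluster-robust inference for
  patient-clustered scatter.
- **Stratification.** k-means (k = 2) on z-scored expression of an induced
  gene set splits a cohort into LOW/HIGH strata; CMS composition is compared
  by χ² and stage II–III survival by Kaplan–Meier + two-sided log-rank.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
conventions.

## Worked example

Simulate a labeled cohort, run the inhibitor screen against a Kd table with
one planted selective compound, then call CMS4 on multi-region biopsies:

```python
import numpy as np
from cmskit import synthetic as syn, screen as sc, classify as cl

# 1. two reference cohorts with a CMS4 marker signature and a kinome layer
spec = syn.CohortSpec(n_samples=500, n_genes=200, subtype_proportions=(0.25,)*4,
                      signature_sizes=(15,)*4, effect_size=2.0, seed=42)
cohort, labels = syn.generate_reference_cohort(spec)
cms4_sig = syn.marker_genes(spec)["CMS4"]
kinome = [f"TK{j:02d}" for j in range(12)]
plants = [(k, 0.5) for k in kinome[:6]] + [(k, 0.0) for k in kinome[6:]]
cohort_a = syn.plant_kinome_layer(cohort, cms4_sig, plants, seed=1)
spec_b = syn.CohortSpec(n_samples=500, n_genes=200, subtype_proportions=(0.25,)*4,
                        signature_sizes=(15,)*4, effect_size=2.0, seed=43)
cohort_b = syn.plant_kinome_layer(syn.generate_reference_cohort(spec_b)[0],
                                  cms4_sig, plants, seed=2)

# 2. Kd table with a planted selective inhibitor; run the screen
kd = syn.generate_kd_matrix(30, 50, ("imatinib_like", kinome[:3], 0.01, 100.0),
                            fraction_tested=0.9, seed=3,
                            kinase_ids=kinome + [f"K{j:03d}" for j in range(38)])
hits, ranking = sc.run_screen([cohort_a, cohort_b], cms4_sig, kinome, kd)
print("screen kinases passing both cohorts:", list(hits.index))
print(ranking[["selectivity", "n_hits", "n_tested", "rank"]].head(3))

# 3. multi-region biopsies -> weighted tumor calls
expr, ann, truth = syn.generate_multibiopsy_tumors(n_tumors=60,
                                                   heterogeneity_rate=0.2, seed=4)
scorer = cl.train_four_gene_scorer(expr, ann["biopsy_is_cms4"])
biopsies = scorer.predict_proba(expr).to_frame().join(ann)
calls = cl.aggregate_tumors(biopsies)
print(f"tumor-call accuracy vs planted truth: "
      f"{(calls['call'].eq('CMS4') == truth).mean():.3f}")
print(f"heterogeneous tumors flagged: {int(calls['heterogeneous'].sum())}/60")
```

Output:

```
screen kinases passing both cohorts: ['TK00', 'TK01', 'TK02', 'TK03', 'TK04', 'TK05']
               selectivity  n_hits  n_tested  rank
inhibitor
imatinib_like     0.066667       3        45     1
INH002            0.113636       5        44     2
INH022            0.148936       7        47     3
tumor-call accuracy vs planted truth: 0.867
heterogeneous tumors flagged: 13/60
```

All six kinases planted at correlation 0.5 pass the p < 10⁻⁶ screen in both
cohorts (the six null kinases do not). The planted inhibitor binds 3 of 45
tested kinases below 3 µM (S = 0.067) — the most selective qualifying
compound, so it ranks 1. At a 20% heterogeneity rate the weighted-mean rule
still calls 87% of tumors correctly and flags 13 tumors whose biopsies
disagree.

The same stages are available from the shell:

```bash
cmskit simulate --seed 3 --out sim/
cmskit screen --expr cohortA.tsv --expr cohortB.tsv --signature sig.gmt \
              --kinome kinome.txt --kd kd.csv --out screen/
cmskit classify --mode four-gene --expr biopsies.tsv ... --out calls/
cmskit shift --expr paired.tsv --annotation ann.csv ... --out shift/
cmskit stratify --expr cohort.tsv --genes induced.gmt ... --out strata/
```

Every run writes its resolved configuration and a log (seed, config hash,
per-stage wall time) into the output directory; identical config + seed
reproduce outputs byte-for-byte.

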