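# sexconn

Sex-stratified tumor transcriptomics and permutation-calibrated
differential connectivity mapping.

Patient sex shapes tumor biology and treatment response, yet most
transcriptomic and drug-repurposing analyses pool the sexes. `sexconn` is
a reusable pipeline for asking, from a gene x sample expression matrix
with sex and tissue labels: which genes and pathways behave differently in
male and female tumors, and which perturbagens (drugs or genetic
reagents) are predicted to help one sex more than the other. It is aimed
at computational biologists who have bulk expression cohorts (e.g.
TCGA-style normalized RNA-seq) and a connectivity-map-style reference
library of ranked perturbagen profiles.

## What it computes

1. **Sex-differential expression** within tumors: per-gene Wilcoxon
   rank-sum tests (male vs. female), Benjamini-Hochberg FDR, median fold
   changes, counts normalized by sample size, and a two-proportion test
   for sex-chromosome enrichment among significant genes. Per-cohort
   p-values combine into pan-cancer values by Fisher's method.
2. **Multivariate sex classification**: L1-regularized (LASSO) logistic
   regression with 10-fold stratified cross-validation; reports pooled
   held-out AUC and the active transcripts, and contrasts tumor vs.
   normal feature selection (the XIST-like tumor/normal asymmetry).
3. **Pathway over-representation** of sex-stratified tumor-vs-normal
   significant genes (hypergeometric test against a GMT collection), a
   four-way male-only / female-only / both / neither call per pathway,
   and the *discordance proportion* — among pathways enriched in at least
   one sex, the fraction enriched in exactly one.
4. **Signature construction**: per sex, the *resistance* signature (top
   `cap` significant genes over-expressed in tumor, ranked by tumor/normal
   fold change) and the *sensitivity* signature (top `cap` over-expressed
   in normal), default cap 250.
5. **Connectivity scoring**: an in-repo CMap-lineage scorer. For each
   perturbagen replicate (a complete ranking of the gene universe), the
   two-sided connectivity score is

   `WTCS = (ES_up - ES_down) / 2` if sign(ES_up) != sign(ES_down), else 0,

   where ES is the signed Kolmogorov-Smirnov enrichment of the query set
   in the ranking. Replicate means map to a signed percentile score in
   [-100, 100].
6. **Permutation-calibrated Type I/II/III calls**: sex labels are
   permuted N times (default 1,000), signatures and scores are re-derived
   each time, and each perturbagen's male-female connectivity difference
   gets a two-sided empirical p-value and BH value. Type I = significant
   difference with positive male / negative female score
   (male-sensitive); Type II = the mirror (female-sensitive); Type III =
   no significant difference and scores >= 90 in both sexes (sensitive in
   both).

A seeded synthetic-data module (`sexconn.synth`) generates four-arm
(sex x tissue) cohorts with planted sex-chromosome structure, sex-DE and
tumor-DE effects, and perturbagen libraries with planted Type I/II/III
members, so the whole pipeline is testable without any external download.

## Worked example

```python
from sexconn import (CohortConfig, LibraryConfig, Thresholds,
                     build_signatures, differential_connectivity,
                     fit_sex_classifier, generate_cohort, generate_library,
                     tumor_vs_normal_de)

cohort = generate_cohort(CohortConfig(
    n_genes=500, n_autosomal=480, n_x=15, n_y=5,
    n_male_tumor=25, n_female_tumor=25,
    n_male_normal=25, n_female_normal=25,
    n_sex_de=20, n_tumor_de_shared=60,
    n_tumor_de_male_only=60, n_tumor_de_female_only=60,
    effect_size=6.0, shared_effect_size=4.5, dispersion=1.0, seed=11))

clf = fit_sex_classifier(cohort.subset(tissue="tumor"), seed=11)
print(f"sex classifier: cv_auc={clf.cv_auc:.3f}, "
      f"{clf.n_active} active transcripts")

signatures = {sex: build_signatures(tumor_vs_normal_de(cohort, sex),
                                    sex, size_cap=15)
              for sex in ("male", "female")}
planted = tuple((f"{t}_{i}", t) for t in ("I", "II", "III")
                for i in range(1, 5))
library = generate_library(
    LibraryConfig(n_perturbagens=232, n_replicates_per_perturbagen=2,
                  planted=planted, mimic_strength=0.95, seed=3),
    signatures, cohort.gene_ids)

result = differential_connectivity(
    cohort, library,
    Thresholds(n_permutations=150, signature_cap=15, seed=5))
print(result.tally())
print(result.table.query("planted_type == 'I'")
      [["male_score", "female_score", "bh", "type"]].round(2))
```

prints

```
sex classifier: cv_auc=0.971, 20 active transcripts
{'I': 4, 'II': 5, 'III': 4, 'none': 219, 'total_sex_specific': 9}
             male_score  female_score   bh type
perturbagen
I_1               95.96        -98.75  0.0    I
I_2               94.95       -100.00  0.0    I
I_3              100.00        -97.50  0.0    I
I_4               96.97        -96.25  0.0    I
```

All 12 planted perturbagens are recovered at their intended type: the
four planted Type I members score strongly positive in males and strongly
negative in females with a permutation BH value of 0 (one extra Type II
call is a false positive among the 220 unconnected perturbagens). The
classifier's held-out AUC of 0.97 on this deliberately small 50-tumor
cohort rises above 0.99 at realistic cohort sizes (see below).

## Command line

Every stage is also a `sexconn` subcommand (`simulate`, `diffexp`,
`classify-sex`, `pathways`, `signatures`, `connect`, `permtest`,
`run-all`, `report`), driven by GCT/GMT/TSV files and a single YAML
config for `run-all`; outputs are TSV tables plus a scatter export of
male vs. female scores per perturbagen.

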