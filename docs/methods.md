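# Methods

## Overview

`sexconn` treats a cohort as a nonnegative gene x sample expression
matrix with three label tracks: sample sex (male/female), sample tissue
(tumor/normal), and gene chromosome class (autosome/X/Y). Every inference
in the pipeline is rank-based or count-based, which makes the results
invariant to monotone per-gene transformations of expression and robust
to the heavy tails of normalized RNA-seq values.

## Univariate statistics

* **Wilcoxon rank-sum test.** Exact mode enumerates the tie-free null by
  a dynamic program over rank sums (used when both groups have <= 10
  samples and no ties); otherwise the normal approximation with tie and
  continuity correction is used. Two-sided p-values are twice the smaller
  tail, capped at 1. All-tied inputs return p = 1. The vectorized cohort
  path uses the approximate mode uniformly: the permutation machinery
  re-tests every gene thousands of times and needs one consistent,
  O(genes) test.
* **Benjamini-Hochberg.** Step-up adjustment (via statsmodels); the same
  routine serves gene-level FDR and the perturbagen-level permutation BH
  values, so there is a single implementation to validate.
* **Fold change** is the ratio of group medians with a pseudocount
  (default 1.0) added to numerator and denominator; normalized-count data
  can have zero medians and the pseudocount keeps ratios finite. With
  pseudocount -> 0 the tumor/normal orientation inverts exactly under
  swapping the arms.
* **Sex-chromosome enrichment** compares the X+Y fraction among
  significant genes to the fraction in the whole universe with a
  chi-square two-proportion test with continuity correction (Fisher's
  exact test available for small tables).
* **Fisher's method** combines per-cohort p-values; X = -2 sum(ln p) is
  referred to chi-square with 2k df. Zero inputs (possible for
  permutation p-values) raise by default or clamp to the smallest
  positive double with a logged warning.

## Sex classifier

L1-penalized logistic regression on standardized expression (so the
penalty is comparable across genes of different scale). Folds are
stratified by sex; the held-out AUC pools out-of-fold predicted
probabilities, so no sample is scored by a model that trained on it. The
penalty is selected on a log-spaced grid by the one-standard-error rule
on cross-validated misclassification error: the sparsest model whose
error is within one fold-to-fold standard error of the best. Deviance
minimization was rejected because on strongly separable data (a
near-binary Y-linked marker) held-out deviance decreases monotonically
with model confidence and always selects the densest model; the
misclassification criterion recovers the sparse sex-chromosome model that
the problem structure implies. The reported active transcripts come from
one final all-sample fit at the selected penalty. Pan-cohort models pool
samples naively; no batch adjustment is attempted.

## Pathways

Over-representation of a gene set among the significant tumor-vs-normal
genes of one sex is the upper-tail hypergeometric probability of the
observed-or-greater overlap, computed against the measured-gene universe.
A proprietary commercial pathway engine used for the original analyses
cannot be reproduced; the hypergeometric test is the standard open
substitute, and everything downstream (the male-only / female-only /
both / neither call and the discordance proportion) depends only on
having one enrichment p-value per sex. A p-value exactly at alpha counts
as not significant. Pathway p-values are reported raw by default (an
optional BH flag exists); the discordance proportion is displayed at two
decimals.

## Signatures

Within one sex, significant genes (BH < alpha) split by fold-change
orientation: resistance = top `cap` by descending tumor/normal fold
change, sensitivity = top `cap` by ascending. Ties break by smaller BH,
then lexicographic gene id, making signatures a deterministic function of
the DE table. If fewer than `cap` genes qualify, all are taken with a
logged warning; an empty side blocks downstream querying. Pan-cancer
signatures use Fisher-combined (BH-adjusted) significance and rank by the
geometric mean of per-cohort fold changes. Signature genes absent from a
library's universe are dropped with a logged report before querying.

## Connectivity scoring

Profiles are complete rankings of the universe (rank 1 = most
up-regulated by the perturbagen). The enrichment score of a query set is
the signed extremum of the unweighted Kolmogorov-Smirnov hit/miss walk;
with sorted hit positions p_1 < ... < p_n among N genes the walk after
hit j is j/n - (p_j - j)/(N - n), and the candidate minima just before
each hit are (j-1)/n - (p_j - j)/(N - n). Ties between the positive and
negative extremum resolve positive. A query equal to the whole universe
is degenerate and scores 0 with a warning.

The two-sided score is WTCS = (ES_up - ES_down)/2 when the component
enrichments disagree in sign and 0 otherwise; it is exactly antisymmetric
under exchanging the up and down sets. Replicate raw scores average per
perturbagen, and the normalized score is sign(mean) x 100 x the
rank-percentile of |mean| among same-sign perturbagens (average ranks on
ties). This keeps reported scores on the familiar [-100, 100] scale,
makes the strongest positive connection in a library score exactly 100,
and preserves antisymmetry exactly because the two sign classes swap
wholesale under query exchange.

## Permutation calibration and Type I/II/III calls

Sex labels are permuted uniformly across samples (sex counts fixed,
tissue labels untouched); each permutation re-derives both sexes'
signatures and re-scores the whole library. A permutation that empties a
signature contributes a zero difference with a logged warning rather than
aborting the run.

**The null statistic is the male-female difference of replicate-mean raw
WTCS, not of the normalized score.** The percentile transform is
scale-free: under a permuted labeling whose signature retains even a
slight sex tilt, any genuinely connected perturbagen still out-ranks the
unconnected bulk and saturates to +/-100, so percentile-scale null
differences reach the observed magnitude with high probability and the
test loses essentially all power for sex-specific connections. The raw
scale carries magnitude — diluted permuted signatures produce
proportionally smaller differences — and restores the intended
calibration. Reported male/female scores and the Type III score floor
remain on the normalized scale.

The empirical p-value is two-sided on magnitude, p = #{|null| >= |obs|}/N
(default; the (r+1)/(N+1) variant is a flag). Zero is attainable and is
passed to BH as-is. BH is applied per cohort across perturbagens.

Classification (defaults): Type I = BH < 0.05 with male score > 0 and
female score < 0; Type II the mirror; Type III = BH above the Type III
floor with both scores >= 90. A sex-significant perturbagen whose scores
agree in sign is "none", as are exact boundary BH values. The Type III
BH floor defaults to 0.05 — i.e. Type III requires the sex difference to
be *not* significant plus the score floor — with the floor exposed as a
configuration value for stricter null-consistency requirements (e.g.
0.95).

Because the null is composite, two caveats hold and are visible in the
synthetic experiments: (i) p-values of perturbagens scored under one
cohort share the observed signature draw and the permutation set, so
they are mutually correlated even though each is marginally uniform
under a sex-null cohort; calibration should be judged across independent
cohorts. (ii) When genuine sex signal exists, permuted signatures are
mixtures and overlap each other more than the observed pair does, which
makes sex-specific calls slightly liberal for unconnected perturbagens.

## Synthetic data

Expression is log-normal around per-gene baselines (log-mean ~ N(4, 1))
with multiplicative planted effects and a per-sample log-scale noise of
`dispersion` (default 0.5). Since the pipeline is rank-based, the
distributional family is a convenience, not a claim of RNA-seq realism:
library-size artifacts, count discreteness, batch effects and copy-number
structure are deliberately out of scope, so green tests certify the
statistical machinery, not robustness to those phenomena.

Structure planted by `generate_cohort`:

* Y-partition genes are depleted by e^6 in females (near-silent), mimicking
  Y-linked markers such as ZFY/EIF1AY/DDX3Y/RPS4Y1.
* One designated X gene plays the XIST role: +/-2.8 log-units between
  female and male tumors, sex-concordant in normals by default
  (switchable to constitutively divergent).
* `n_sex_de` autosomal genes carry a constitutive sex effect of
  `effect_size`, random direction.
* Tumor-vs-normal effects come in three classes — shared, male-only,
  female-only — each a multiplicative `effect_size` (shared class can use
  a separate `shared_effect_size`), random direction, on disjoint
  autosomal gene sets. Ground truth is recorded in the gene table and
  round-trips through the GCT/TSV writers.

`generate_library` builds each replicate by ranking per-gene scores
m x target + ((1-m) + 1e-6) x N(0,1), where `target` is +1/-1 on the
genes a planted type pushes to the profile extremes (Type I reverses the
male signature pair and anti-reverses the female pair; Type II mirrored;
Type III reverses both) and m is `mimic_strength`. m = 0 (and every
unplanted perturbagen) yields uniform random rankings; m = 1 pins the
signature genes to the extremes with an infinitesimal jitter keeping the
ranking strict.

A note on interacting defaults, learned from calibrating the permutation
test on this generator: because signatures rank by median fold change,
a permuted group with a majority of one sex reproduces a binary planted
effect's full fold change (medians flip at majority composition). For
sex-specific planted effects to be *detectable* against the permutation
null, the cohort must give the sex-specific genes a larger effect than a
competing pool of shared tumor genes and enough noise (dispersion ~ 1)
that permuted mixtures interpolate below the shared pool's fold change
and drop out of the capped signature. The planted-recovery experiment in
the test suite (500 genes, 25 samples per arm, 60 shared at fold change
4.5, 60+60 sex-specific at 6, signature cap 15) was designed this way.

## Problem sizes in the shipped experiments

Chosen as the package's own desk-scale defaults: calibration pools 10
independent sex-null cohorts (300 genes, 15 per arm, 60 shared effects)
of 10 perturbagens x 6 replicates at 200 permutations; recovery uses one
cohort as above with a 232-perturbagen library (4 planted per type at
mimic strength 0.95) at 150 permutations; the classifier benchmark uses
2,000 genes and 100 tumors per sex. Six replicates in the calibration
experiment keep the WTCS same-sign zero atom (raw score exactly 0) from
collecting empirical p-values at 1; the bound signature cap (25 of ~30
candidates per side) prevents the two sexes' queries from coinciding
exactly, which would make every observed difference identically zero.

## Known limitations

* The connectivity scorer is a documented stand-in for the original
  online service's unpublished scoring; absolute score values are not
  comparable to that service's, only the scale and semantics.
* The permutation test's liberal behavior for unconnected perturbagens
  in the presence of real sex signal (see above) is inherent to the
  composite null, not an implementation artifact.
* Patient pairing (tumor and normal from the same patient) is not
  modeled; samples permute independently.
* The pathway stage's results are entirely gene-set-collection dependent.
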