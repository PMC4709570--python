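"""Seeded synthetic cohorts and perturbagen libraries.

The generator emulates the statistical structure the downstream analyses
assume, without pretending to be a realistic RNA-seq count model:

* expression is log-normal around per-gene baselines (nonnegative, like
  normalized RNA-seq counts) with multiplicative planted effects — every
  downstream statistic is rank-based, so the distribution family is free;
* genes are partitioned into autosomal / X / Y classes; Y-linked genes are
  expressed in males and near-silent in females (emulating markers such as
  ZFY, EIF1AY, DDX3Y, RPS4Y1), and one designated X gene mimics XIST:
  strongly female-high in tumors but, by default, sex-concordant in normal
  tissue;
* sex-differential and tumor-vs-normal effects (shared or sex-specific)
  are planted on disjoint autosomal gene sets with random up/down
  directions, and the truth is recorded in the gene annotation table;
* perturbagen profiles are rankings of per-gene scores: a planted
  perturbagen biases its target signature genes toward the extremes of the
  ranking, with noise scaled by (1 - mimic_strength), giving a continuous
  dial from null (uniform random permutation) to a perfect signature
  reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .connectivity import MANIFEST_COLUMNS, PerturbagenLibrary
from .dataset import ExpressionDataset
from .signatures import SignaturePair

BASELINE_LOG_MEAN = 4.0
BASELINE_LOG_SD = 1.0
Y_SILENCING_LOG = 6.0   # log-scale depletion of Y-linked genes in females
XIST_LOG_SHIFT = 2.8    # half the log-scale male/female gap of the XIST-like gene
TIE_BREAK_NOISE = 1e-6  # keeps profiles strict rankings at mimic_strength 1

PLANTED_TYPES = ("I", "II", "III", "null")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic four-arm (sex x tissue) expression cohort."""

    n_genes: int
    n_autosomal: int
    n_x: int
    n_y: int
    n_male_tumor: int
    n_female_tumor: int
    n_male_normal: int
    n_female_normal: int
    n_sex_de: int = 0
    n_tumor_de_shared: int = 0
    n_tumor_de_male_only: int = 0
    n_tumor_de_female_only: int = 0
    effect_size: float = 4.0
    shared_effect_size: float | None = None
    dispersion: float = 0.5
    seed: int = 0
    xist_tumor_divergent: bool = True
    cancer_label: str = "SYNTH"

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_autosomal, self.n_x, self.n_y,
                  self.n_male_tumor, self.n_female_tumor,
                  self.n_male_normal, self.n_female_normal,
                  self.n_sex_de, self.n_tumor_de_shared,
                  self.n_tumor_de_male_only, self.n_tumor_de_female_only)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.n_autosomal + self.n_x + self.n_y != self.n_genes:
            raise ValueError("chromosome partition must sum to n_genes")
        n_planted = (self.n_sex_de + self.n_tumor_de_shared
                     + self.n_tumor_de_male_only + self.n_tumor_de_female_only)
        if n_planted > self.n_autosomal:
            raise ValueError("planted genes exceed the autosomal pool")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.shared_effect_size is not None and self.shared_effect_size <= 1:
            raise ValueError("shared_effect_size must exceed 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate_cohort(config: CohortConfig) -> ExpressionDataset:
    """Draw one seeded cohort; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    chrom = np.array(["autosome"] * config.n_autosomal
                     + ["X"] * config.n_x + ["Y"] * config.n_y)
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]

    arms = [("male", "tumor", config.n_male_tumor),
            ("female", "tumor", config.n_female_tumor),
            ("male", "normal", config.n_male_normal),
            ("female", "normal", config.n_female_normal)]
    sex = np.array([s for s, _, n in arms for _ in range(n)])
    tissue = np.array([t for _, t, n in arms for _ in range(n)])
    n_samples = sex.size
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]

    base = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, n_genes)
    log_expr = base[:, None] + config.dispersion * rng.standard_normal(
        (n_genes, n_samples))

    female = sex == "female"
    tumor = tissue == "tumor"

    y_genes = chrom == "Y"
    if y_genes.any() and female.any():
        log_expr[np.ix_(y_genes, female)] -= Y_SILENCING_LOG

    is_xist = np.zeros(n_genes, dtype=bool)
    if config.n_x > 0:
        xi = config.n_autosomal  # first X gene plays the XIST role
        is_xist[xi] = True
        log_expr[xi, female & tumor] += XIST_LOG_SHIFT
        log_expr[xi, ~female & tumor] -= XIST_LOG_SHIFT
        if not config.xist_tumor_divergent:
            log_expr[xi, female & ~tumor] += XIST_LOG_SHIFT
            log_expr[xi, ~female & ~tumor] -= XIST_LOG_SHIFT

    # planted effects live on disjoint autosomal gene sets
    log_fc = np.log(config.effect_size)
    n_planted = (config.n_sex_de + config.n_tumor_de_shared
                 + config.n_tumor_de_male_only + config.n_tumor_de_female_only)
    auto_idx = np.where(chrom == "autosome")[0]
    picks = rng.choice(auto_idx, size=n_planted, replace=False)
    signs = rng.choice([-1, 1], size=n_planted)
    cursor = 0

    def take(n: int) -> tuple[np.ndarray, np.ndarray]:
        nonlocal cursor
        sel = picks[cursor:cursor + n]
        sgn = signs[cursor:cursor + n]
        cursor += n
        return sel, sgn

    sex_de = np.zeros(n_genes, dtype=bool)
    sex_de_sign = np.zeros(n_genes, dtype=int)
    tumor_de_class = np.full(n_genes, "none", dtype=object)
    tumor_de_sign = np.zeros(n_genes, dtype=int)

    sel, sgn = take(config.n_sex_de)
    sex_de[sel] = True
    sex_de_sign[sel] = sgn  # +1: higher in females (both tissues)
    log_expr[np.ix_(sel, female)] += sgn[:, None] * log_fc

    shared_log_fc = np.log(config.shared_effect_size) \
        if config.shared_effect_size is not None else log_fc
    for cls, n_cls, mask, lfc in (
            ("shared", config.n_tumor_de_shared, tumor, shared_log_fc),
            ("male_only", config.n_tumor_de_male_only, tumor & ~female, log_fc),
            ("female_only", config.n_tumor_de_female_only, tumor & female, log_fc)):
        sel, sgn = take(n_cls)
        tumor_de_class[sel] = cls
        tumor_de_sign[sel] = sgn  # +1: up in tumor (fold change > 1)
        log_expr[np.ix_(sel, mask)] += sgn[:, None] * lfc

    matrix = pd.DataFrame(np.exp(log_expr), index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame({"sex": sex, "tissue": tissue},
                           index=pd.Index(sample_ids, name="sample_id"))
    genes = pd.DataFrame({"chromosome": chrom, "is_xist_like": is_xist,
                          "sex_de": sex_de, "sex_de_sign": sex_de_sign,
                          "tumor_de_class": tumor_de_class,
                          "tumor_de_sign": tumor_de_sign},
                         index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionDataset(matrix, samples, genes, config.cancer_label)


@dataclass(frozen=True)
class LibraryConfig:
    """Design of a synthetic perturbagen reference library."""

    n_perturbagens: int
    n_replicates_per_perturbagen: int = 2
    planted: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    mimic_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturbagens < 1:
            raise ValueError("need at least one perturbagen")
        if self.n_replicates_per_perturbagen < 1:
            raise ValueError("need at least one replicate per perturbagen")
        if not 0.0 <= self.mimic_strength <= 1.0:
            raise ValueError("mimic_strength must lie in [0, 1]")
        if len(self.planted) > self.n_perturbagens:
            raise ValueError("more planted perturbagens than perturbagens")
        for _, ptype in self.planted:
            if ptype not in PLANTED_TYPES:
                raise ValueError(f"unknown planted type {ptype!r}")


def _type_target(ptype: str, n_genes: int, pos: pd.Series,
                 male: SignaturePair, female: SignaturePair) -> np.ndarray:
    """Per-gene bias: +1 pushes a gene toward the profile top (up-regulated).

    A Type I perturbagen reverses the male tumor state (male sensitivity up,
    male resistance down) and anti-reverses the female one; Type II is the
    mirror image; Type III reverses both. Overlapping memberships sum.
    """
    target = np.zeros(n_genes)
    plan = {
        "I": ((male.sensitivity, +1), (male.resistance, -1),
              (female.sensitivity, -1), (female.resistance, +1)),
        "II": ((male.sensitivity, -1), (male.resistance, +1),
               (female.sensitivity, +1), (female.resistance, -1)),
        "III": ((male.sensitivity, +1), (male.resistance, -1),
                (female.sensitivity, +1), (female.resistance, -1)),
        "null": (),
    }[ptype]
    for genes, direction in plan:
        np.add.at(target, pos.loc[list(genes)].to_numpy(), direction)
    return target


def generate_library(config: LibraryConfig,
                     target_signatures: dict[str, SignaturePair],
                     universe: list[str]) -> PerturbagenLibrary:
    """Draw a seeded library whose planted members reverse given signatures.

    ``target_signatures`` maps "male"/"female" to the signature pair each
    planted perturbagen type acts on. Null perturbagens (and all
    perturbagens at mimic_strength 0) are uniform random rankings.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = len(universe)
    pos = pd.Series(range(n_genes), index=universe)
    for sex in ("male", "female"):
        if sex not in target_signatures:
            raise ValueError(f"target_signatures lacks the {sex} pair")
        pair = target_signatures[sex]
        missing = [g for g in (*pair.sensitivity, *pair.resistance)
                   if g not in pos.index]
        if missing:
            raise ValueError(f"{sex} signature genes absent from universe: "
                             f"{missing}")

    male, female = target_signatures["male"], target_signatures["female"]
    planted = list(config.planted)
    n_null = config.n_perturbagens - len(planted)
    perturbagens = planted + [(f"null{i:04d}", "null") for i in range(1, n_null + 1)]

    targets = {ptype: _type_target(ptype, n_genes, pos, male, female)
               for ptype in PLANTED_TYPES}
    m = config.mimic_strength
    noise_scale = (1.0 - m) + TIE_BREAK_NOISE

    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for i, (pid, ptype) in enumerate(perturbagens):
        reagent = "genetic" if (ptype != "null" or i % 2 == 0) else "chemical"
        for rep in range(1, config.n_replicates_per_perturbagen + 1):
            score = m * targets[ptype] + noise_scale * rng.standard_normal(n_genes)
            profile_id = f"{pid}|r{rep}"
            columns[profile_id] = rankdata(-score, method="ordinal")
            manifest_rows.append((profile_id, pid, rep, reagent, ptype))
    ranks = pd.DataFrame(columns, index=pd.Index(universe, name="gene_id"),
                         dtype=int)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["profile_id", *MANIFEST_COLUMNS]).set_index("profile_id")
    return PerturbagenLibrary(universe, ranks, manifest)


def generate_gene_sets(dataset: ExpressionDataset, n_random_sets: int = 15,
                       set_size: int = 25, seed: int = 0,
                       ) -> dict[str, list[str]]:
    """Gene-set collection for pathway analysis on a synthetic cohort.

    Builds one set per planted tumor-effect class (enriched by
    construction, padded with random genes) plus random background sets.
    """
    rng = np.random.default_rng(seed)
    genes = dataset.genes
    universe = np.array(dataset.gene_ids)
    sets: dict[str, list[str]] = {}
    for cls in ("shared", "male_only", "female_only"):
        members = list(genes.index[genes["tumor_de_class"] == cls])
        if not members:
            continue
        members = members[:set_size]
        pad = rng.choice(universe[~np.isin(universe, members)],
                         size=max(0, set_size - len(members)), replace=False)
        sets[f"planted_{cls}"] = sorted([*members, *pad])
    for i in range(1, n_random_sets + 1):
        sets[f"random_{i:02d}"] = sorted(
            rng.choice(universe, size=min(set_size, len(universe)),
                       replace=False))
    return sets
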