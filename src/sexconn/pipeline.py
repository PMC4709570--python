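"""End-to-end orchestration of a reproducible run.

A run is described by one YAML config (paths or synthetic-generation
parameters, stage toggles, thresholds, a master seed) and produces a
directory of stage TSVs plus a machine-readable summary. The master seed
deterministically derives every stage seed, so re-running an unchanged
config reproduces every output file.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, io, pathways, permclass, sexclf, signatures, synth
from .connectivity import PerturbagenLibrary, score_library
from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

STAGES = ("diffexp", "sexclf", "pathways", "signatures", "connectivity",
          "permclass")
FLOAT_FMT = "%.4f"


@dataclass
class RunConfig:
    """Validated run description; see ``RunConfig.from_yaml``."""

    outdir: Path
    seed: int = 0
    cancer_label: str = "SYNTH"
    cohort_path: str | None = None          # prefix of GCT + sidecars
    cohort_synth: dict | None = None        # CohortConfig keyword arguments
    library_gct: str | None = None
    library_manifest: str | None = None
    library_synth: dict | None = None       # LibraryConfig kwargs (+ planted counts)
    gene_sets_path: str | None = None
    stages: dict = field(default_factory=dict)
    thresholds: permclass.Thresholds = field(
        default_factory=permclass.Thresholds)

    def stage_on(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = permclass.Thresholds(**raw.get("thresholds", {}))
        cohort = raw.get("cohort", {}) or {}
        library = raw.get("library", {}) or {}
        cfg = cls(outdir=Path(raw.get("outdir", "sexconn_out")),
                  seed=int(raw.get("seed", 0)),
                  cancer_label=raw.get("cancer_label", "SYNTH"),
                  cohort_path=cohort.get("path"),
                  cohort_synth=cohort.get("synth"),
                  library_gct=library.get("gct"),
                  library_manifest=library.get("manifest"),
                  library_synth=library.get("synth"),
                  gene_sets_path=raw.get("gene_sets"),
                  stages=raw.get("stages", {}) or {},
                  thresholds=thr)
        for key in ("cohort_path", "library_gct", "library_manifest",
                    "gene_sets_path"):
            value = getattr(cfg, key)
            if value is not None and key != "cohort_path" \
                    and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value}")
        return cfg


def _derive_seed(master: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([master, tag])
               .generate_state(1)[0] % (2**31))


def _load_cohort(config: RunConfig) -> ExpressionDataset:
    if config.cohort_path:
        return ExpressionDataset.read(config.cohort_path,
                                      cancer_label=config.cancer_label)
    if config.cohort_synth is None:
        raise ValueError("config needs either cohort.path or cohort.synth")
    kwargs = dict(config.cohort_synth)
    kwargs.setdefault("seed", _derive_seed(config.seed, "cohort"))
    kwargs.setdefault("cancer_label", config.cancer_label)
    return synth.generate_cohort(synth.CohortConfig(**kwargs))


def _build_library(config: RunConfig, sig_pairs: dict,
                   universe: list[str]) -> PerturbagenLibrary:
    if config.library_gct:
        return PerturbagenLibrary.read(config.library_gct,
                                       config.library_manifest)
    if config.library_synth is None:
        raise ValueError("config needs either library.gct or library.synth")
    kwargs = dict(config.library_synth)
    planted_counts = kwargs.pop("planted_counts", {})
    planted = tuple((f"{ptype}_{i:02d}", ptype)
                    for ptype, n in planted_counts.items()
                    for i in range(1, int(n) + 1))
    kwargs.setdefault("seed", _derive_seed(config.seed, "library"))
    lib_cfg = synth.LibraryConfig(planted=planted, **kwargs)
    return synth.generate_library(lib_cfg, sig_pairs, universe)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write their outputs under ``outdir``.

    Returns a dict of the in-memory stage results keyed by stage name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}
    thr = config.thresholds

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, timings[name])

    dataset = _load_cohort(config)
    if config.cohort_path is None:
        dataset.write(out / "cohort")
    results["cohort"] = dataset

    de_tables: dict[str, pd.DataFrame] = {}
    if config.stage_on("diffexp"):
        def _diffexp():
            table, summary = diffexp.sex_de(dataset, alpha=thr.alpha_de,
                                            pseudocount=thr.pseudocount)
            io.write_tsv(table, out / "sex_de.tsv", FLOAT_FMT)
            io.write_tsv(pd.DataFrame([summary]).set_index("cancer_label"),
                         out / "sex_de_summary.tsv", FLOAT_FMT)
            sig = table.index[table["significant"]]
            enrich = None
            if len(sig):
                prop_sig, prop_bg, p = diffexp.sex_chromosome_enrichment(
                    sig, dataset)
                enrich = {"prop_significant_on_sex_chrom": prop_sig,
                          "prop_background_on_sex_chrom": prop_bg, "p": p}
                io.write_tsv(pd.DataFrame([enrich]),
                             out / "sex_chromosome_enrichment.tsv",
                             "%.6g", index=False)
            for which_sex in ("male", "female"):
                de_tables[which_sex] = diffexp.tumor_vs_normal_de(
                    dataset, which_sex, alpha=thr.alpha_de,
                    pseudocount=thr.pseudocount,
                    min_per_arm=thr.min_per_arm)
                io.write_tsv(de_tables[which_sex],
                             out / f"tumor_vs_normal_{which_sex}.tsv",
                             FLOAT_FMT)
            return {"sex_de": table, "summary": summary, "enrichment": enrich,
                    "tumor_vs_normal": dict(de_tables)}
        run_stage("diffexp", _diffexp)

    if config.stage_on("sexclf"):
        def _sexclf():
            res = sexclf.fit_sex_classifier(
                dataset.subset(tissue="tumor"),
                seed=_derive_seed(config.seed, "sexclf"))
            report = res.active.copy()
            report["chromosome"] = dataset.genes.loc[
                report["gene"], "chromosome"].to_numpy()
            io.write_tsv(report, out / "sex_classifier_active.tsv", "%.6g",
                         index=False)
            io.write_tsv(pd.DataFrame([{"cancer_label": config.cancer_label,
                                        "cv_auc": res.cv_auc,
                                        "n_active": res.n_active}]),
                         out / "sex_classifier_summary.tsv", FLOAT_FMT,
                         index=False)
            return res
        run_stage("sexclf", _sexclf)

    sig_pairs: dict[str, signatures.SignaturePair] = {}
    if config.stage_on("signatures") or config.stage_on("connectivity") \
            or config.stage_on("permclass"):
        def _signatures():
            for which_sex in ("male", "female"):
                if which_sex not in de_tables:
                    de_tables[which_sex] = diffexp.tumor_vs_normal_de(
                        dataset, which_sex, alpha=thr.alpha_de,
                        pseudocount=thr.pseudocount,
                        min_per_arm=thr.min_per_arm)
                sig_pairs[which_sex] = signatures.build_signatures(
                    de_tables[which_sex], which_sex, config.cancer_label,
                    size_cap=thr.signature_cap, alpha=thr.alpha_de)
            io.write_gmt(signatures.signatures_to_gmt(
                list(sig_pairs.values())), out / "signatures.gmt")
            return dict(sig_pairs)
        run_stage("signatures", _signatures)

    if config.stage_on("pathways"):
        def _pathways():
            if config.gene_sets_path:
                gene_sets = io.read_gmt(config.gene_sets_path)
            else:
                gene_sets = synth.generate_gene_sets(
                    dataset, seed=_derive_seed(config.seed, "gene_sets"))
                io.write_gmt(gene_sets, out / "gene_sets.gmt")
            sig_by_sex = {}
            for which_sex in ("male", "female"):
                if which_sex not in de_tables:
                    de_tables[which_sex] = diffexp.tumor_vs_normal_de(
                        dataset, which_sex, alpha=thr.alpha_de,
                        pseudocount=thr.pseudocount,
                        min_per_arm=thr.min_per_arm)
                t = de_tables[which_sex]
                sig_by_sex[which_sex] = list(t.index[t["significant"]])
            table, summary = pathways.analyze_pathways(
                gene_sets, sig_by_sex["male"], sig_by_sex["female"],
                dataset.gene_ids, alpha=thr.alpha_de)
            io.write_tsv(table, out / "pathways.tsv", "%.6g")
            summary_row = dict(summary)
            if summary_row["discordance_proportion"] == summary_row["discordance_proportion"]:
                summary_row["discordance_proportion"] = round(
                    summary_row["discordance_proportion"], 2)
            io.write_tsv(pd.DataFrame([{"cancer_label": config.cancer_label,
                                        **summary_row}]),
                         out / "pathway_summary.tsv", "%.2f", index=False)
            return {"table": table, "summary": summary}
        run_stage("pathways", _pathways)

    library: PerturbagenLibrary | None = None
    if config.stage_on("connectivity") or config.stage_on("permclass"):
        library = _build_library(config, sig_pairs, dataset.gene_ids)
        if config.library_gct is None:
            library.write(out / "library.gct", out / "library.manifest.tsv")
        results["library"] = library

    if config.stage_on("connectivity"):
        def _connectivity():
            per_sex = {}
            for which_sex in ("male", "female"):
                pair, _ = sig_pairs[which_sex].restrict_to(library.universe)
                scores = score_library(library, up_set=pair.sensitivity,
                                       down_set=pair.resistance)
                io.write_tsv(scores, out / f"connectivity_{which_sex}.tsv",
                             FLOAT_FMT)
                per_sex[which_sex] = scores
            scatter = pd.DataFrame({
                "reagent_class": per_sex["male"]["reagent_class"],
                "male_score": per_sex["male"]["score"],
                "female_score": per_sex["female"]["score"]})
            io.write_tsv(scatter, out / "connectivity_scatter.tsv", FLOAT_FMT)
            return per_sex
        run_stage("connectivity", _connectivity)

    if config.stage_on("permclass"):
        def _permclass():
            thr_run = permclass.Thresholds(
                **{**thr.__dict__,
                   "seed": _derive_seed(config.seed, "permclass")})
            dc = permclass.differential_connectivity(dataset, library, thr_run)
            io.write_tsv(dc.table, out / "differential_connectivity.tsv",
                         FLOAT_FMT)
            tally = dc.tally()
            io.write_tsv(pd.DataFrame([{"cancer_label": config.cancer_label,
                                        **tally}]),
                         out / "type_summary.tsv", None, index=False)
            return dc
        run_stage("permclass", _permclass)

    log = {"seed": config.seed, "cancer_label": config.cancer_label,
           "stages_run": sorted(timings), "timings_s":
               {k: round(v, 3) for k, v in timings.items()}}
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return results
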