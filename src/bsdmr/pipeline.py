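"""End-to-end orchestration: simulate -> summarize -> dmr -> annotate -> enrich -> qpcr.

Every stage writes a plain-text artifact re-loadable by its owning module,
and a JSON manifest records the parameter set, seed and per-stage record
counts so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .io import (read_cytosine_report, read_gene_annotation, write_dmr_bed,
                 write_dmg_table, read_term_annotation)
from .stats import global_summary, region_profile
from .dmr import DmrParams, call_dmrs, dmrs_to_frame
from .annotate import build_region_index, assign_dmgs, dmg_count_table
from .enrichment import enrich, results_to_frame
from .qpcr import QpcrPlate, ddct_fold_change
from .simulate import (SimulationConfig, simulate_annotation,
                       simulate_methylomes, simulate_terms,
                       simulate_qpcr_plate)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "bsdmr_run"
    seed: int = 42
    simulation: SimulationConfig | None = None   # None: load inputs from input_dir
    input_dir: str | None = None                 # pre-existing reports + annotation
    dmr_params: DmrParams = field(default_factory=DmrParams)
    promoter_bp: int = 2000
    enrichment_method: str = "bonferroni"
    enrichment_alpha: float = 0.05
    summary_min_depth: int = 4
    summary_error_rate: float = 0.005
    flank_bp: int = 2000
    bins_per_region: int = 20
    qpcr_true_fold: float = 3.0
    qpcr_n_per_group: int = 6
    qpcr_ct_noise_sd: float = 0.15


def _load_inputs(cfg: PipelineConfig):
    indir = cfg.input_dir
    genes = read_gene_annotation(os.path.join(indir, "genes.gff3"), "gff3")
    ref, trt = [], []
    for path in sorted(glob.glob(os.path.join(indir, "reference_*.cx.tsv"))):
        ref.append(read_cytosine_report(path, group="reference"))
    for path in sorted(glob.glob(os.path.join(indir, "treatment_*.cx.tsv"))):
        trt.append(read_cytosine_report(path, group="treatment"))
    if not ref or not trt:
        raise FileNotFoundError(
            f"{indir}: expected reference_*.cx.tsv and treatment_*.cx.tsv")
    return genes, ref, trt


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "counts": {},
                      "parameters": {
                          "dmr": dataclasses.asdict(cfg.dmr_params),
                          "promoter_bp": cfg.promoter_bp,
                          "enrichment_method": cfg.enrichment_method,
                          "enrichment_alpha": cfg.enrichment_alpha,
                          "summary_min_depth": cfg.summary_min_depth,
                          "summary_error_rate": cfg.summary_error_rate,
                          "flank_bp": cfg.flank_bp,
                          "bins_per_region": cfg.bins_per_region,
                      }}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("inputs")
        if cfg.simulation is not None:
            sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            manifest["parameters"]["simulation"] = _sim_dict(sim)
            _, genes = simulate_annotation(sim, os.path.join(cfg.outdir, "genes.gff3"))
            ref, trt, truth = simulate_methylomes(sim, genes, outdir=cfg.outdir)
            truth.to_json(os.path.join(cfg.outdir, "truth.json"))
            manifest["counts"]["planted_dmrs"] = len(truth.planted)
        elif cfg.input_dir is not None:
            genes, ref, trt = _load_inputs(cfg)
        else:
            raise ValueError("config needs either a simulation or an input_dir")
        manifest["counts"]["genes"] = len(genes)
        manifest["counts"]["replicates"] = [len(ref), len(trt)]

        stage("summarize")
        summ = global_summary(ref[0], cfg.summary_min_depth, cfg.summary_error_rate)
        summ.to_frame().to_csv(os.path.join(cfg.outdir, "global_summary.tsv"),
                               sep="\t", index=False, lineterminator="\n")
        prof = region_profile(ref[0], genes, cfg.flank_bp, cfg.bins_per_region)
        prof.to_frame().to_csv(os.path.join(cfg.outdir, "region_profile.tsv"),
                               sep="\t", index=False, lineterminator="\n")

        stage("dmr")
        dmrs = call_dmrs(ref, trt, cfg.dmr_params)
        write_dmr_bed(dmrs, os.path.join(cfg.outdir, "dmrs.bed"))
        for ctx in ("CG", "CHG", "CHH"):
            manifest["counts"][f"dmrs_{ctx}"] = sum(d.context == ctx for d in dmrs)
        manifest["counts"]["dmrs_total"] = len(dmrs)

        stage("annotate")
        index = build_region_index(genes, cfg.promoter_bp)
        dmgs = assign_dmgs(dmrs, index)
        write_dmg_table(dmgs, os.path.join(cfg.outdir, "dmgs.tsv"))
        dmg_count_table(dmgs).to_csv(os.path.join(cfg.outdir, "dmg_counts.tsv"),
                                     sep="\t", index=False, lineterminator="\n")
        manifest["counts"]["dmgs"] = len({d.gene_id for d in dmgs})

        stage("enrich")
        terms_path = os.path.join(cfg.outdir, "terms.tsv")
        selected = {d.gene_id for d in dmgs}
        if cfg.simulation is not None:
            simulate_terms(genes, enriched_term=("TERM:ENRICHED", selected, 0.9),
                           seed=cfg.seed, path=terms_path)
        if os.path.exists(terms_path):
            terms = read_term_annotation(terms_path)
            universe = set().union(*(t.annotated_genes for t in terms)) if terms else set()
            if universe:
                results = enrich(selected, terms, universe,
                                 method=cfg.enrichment_method,
                                 alpha=cfg.enrichment_alpha)
            else:
                results = []
        else:
            results = []
        results_to_frame(results).to_csv(os.path.join(cfg.outdir, "enrichment.tsv"),
                                         sep="\t", index=False, lineterminator="\n")
        manifest["counts"]["terms_tested"] = len(results)
        manifest["counts"]["terms_significant"] = sum(r.significant for r in results)

        stage("qpcr")
        plate_df = simulate_qpcr_plate(cfg.qpcr_n_per_group, cfg.qpcr_true_fold,
                                       cfg.qpcr_ct_noise_sd, seed=cfg.seed,
                                       path=os.path.join(cfg.outdir, "qpcr_plate.tsv"))
        res = ddct_fold_change(QpcrPlate(plate_df), target_gene="target")
        res.per_sample.to_csv(os.path.join(cfg.outdir, "qpcr_folds.tsv"),
                              sep="\t", index=False, lineterminator="\n",
                              float_format="%.6f")
        res.per_group.to_csv(os.path.join(cfg.outdir, "qpcr_group_summary.tsv"),
                             sep="\t", index=False, lineterminator="\n",
                             float_format="%.6f")
        manifest["counts"]["qpcr_treatment_fold"] = round(res.treatment_fold, 4)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _sim_dict(sim: SimulationConfig) -> dict:
    d = dataclasses.asdict(sim)
    d["planted_dmrs"] = [dataclasses.asdict(p) for p in sim.planted_dmrs]
    return d
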