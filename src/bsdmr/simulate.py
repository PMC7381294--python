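"""Seeded simulator for every input the pipeline consumes.

The generator emulates a two-group (reference vs treatment) WGBS design with
three replicate methylomes per group on a small toy genome: CG sites near
80% methylation, CHG/CHH near 1%, a dip of methylation around transcription
start sites, per-replicate coverage drawn from a Poisson, observed
methylated read counts from a binomial whose success probability folds in a
symmetric bisulfite-conversion/sequencing error, and differential regions of
at least five CpGs planted at configurable effect sizes and placements.
Every draw is fixed by the config seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS, GeneModel, MethylomeSample, RECORD_COLUMNS, \
    write_cytosine_report


@dataclass(frozen=True)
class PlantedDmr:
    """Specification of one differential region to plant."""

    context: str = "CG"
    n_sites: int = 8            # consecutive sites of the context (>= window size)
    level_ref: float = 0.8
    level_trt: float = 0.2
    placement: str = "gene_body"   # promoter | gene_body | intergenic


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 6)
    gene_length_bp: tuple[int, int] = (2_000, 8_000)
    # sites per kbp of chromosome, per context
    site_density_per_kbp: dict = field(default_factory=lambda: {
        "CG": 20.0, "CHG": 10.0, "CHH": 20.0})
    baseline_levels: dict = field(default_factory=lambda: {
        "CG": 0.80, "CHG": 0.01, "CHH": 0.01})
    tss_dip: tuple[int, float] = (200, 0.5)   # (half-width bp, level multiplier)
    depth_mean: float = 20.0
    conversion_error: float = 0.005
    replicates_per_group: int = 3
    promoter_bp: int = 2_000
    planted_dmrs: tuple[PlantedDmr, ...] = ()

    def __post_init__(self) -> None:
        for ctx, lv in self.baseline_levels.items():
            if not (0 <= lv <= 1):
                raise ValueError(f"baseline level for {ctx} outside [0,1]")
        if not (0 <= self.conversion_error < 1):
            raise ValueError("conversion_error must be in [0, 1)")
        if self.replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    planted: pd.DataFrame      # chrom, start, end, context, level_ref, level_trt, direction, n_sites
    site_levels: pd.DataFrame  # chrom, pos, strand, context, level_ref, level_trt

    def to_json(self, path) -> None:
        payload = {"planted": self.planted.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig,
                        path: str | os.PathLike | None = None
                        ) -> tuple[str, list[GeneModel]]:
    """Place non-overlapping multi-exon genes on the toy genome.

    Returns the GFF3 text (also written to ``path`` if given) and the gene
    models.  Raises when the requested genes cannot be placed.
    """
    rng = _rng(cfg.seed, 0)
    placed: dict[str, list[tuple[int, int]]] = {
        _chrom_name(i): [] for i in range(cfg.n_chroms)}
    genes: list[GeneModel] = []
    min_seg = 50   # bp floor for each exon/intron segment
    gap = 200      # bp between neighbouring genes
    for gi in range(cfg.n_genes):
        length = int(rng.integers(cfg.gene_length_bp[0], cfg.gene_length_bp[1] + 1))
        for _attempt in range(1000):
            chrom = _chrom_name(int(rng.integers(cfg.n_chroms)))
            if cfg.chrom_length_bp - length - 1 < 1:
                continue
            start = int(rng.integers(1, cfg.chrom_length_bp - length))
            end = start + length - 1
            if all(e < start - gap or s > end + gap for s, e in placed[chrom]):
                break
        else:
            raise RuntimeError(
                f"could not place gene {gi + 1}/{cfg.n_genes}; genome too dense")
        placed[chrom].append((start, end))
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_seg = 2 * n_exons - 1
        if length < n_seg * min_seg:
            n_exons, n_seg = 1, 1
        w = rng.dirichlet(np.ones(n_seg))
        seg = (w * (length - n_seg * min_seg)).astype(int) + min_seg
        seg[-1] += length - seg.sum()
        exons = []
        cursor = start
        for si, sl in enumerate(seg):
            if si % 2 == 0:
                exons.append((cursor, cursor + int(sl) - 1))
            cursor += int(sl)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"gene{gi + 1:03d}", chrom=chrom,
                               strand=strand, tx_start=start, tx_end=end,
                               exons=tuple(exons)))
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    gff = _to_gff3(genes)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(gff)
    return gff, genes


def _to_gff3(genes: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([g.chrom, "sim", "gene", str(g.tx_start),
                                str(g.tx_end), ".", g.strand, ".",
                                f"ID={g.gene_id}"]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join([g.chrom, "sim", "mRNA", str(g.tx_start),
                                str(g.tx_end), ".", g.strand, ".",
                                f"ID={mrna};Parent={g.gene_id}"]))
        for ei, (s, e) in enumerate(g.exons, start=1):
            lines.append("\t".join([g.chrom, "sim", "exon", str(s), str(e),
                                    ".", g.strand, ".",
                                    f"ID={mrna}.exon{ei};Parent={mrna}"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _site_positions(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Unique site positions per chromosome, assigned to contexts and strands."""
    frames = []
    for ci in range(cfg.n_chroms):
        chrom = _chrom_name(ci)
        counts = {c: int(round(cfg.site_density_per_kbp[c]
                               * cfg.chrom_length_bp / 1000)) for c in CONTEXTS}
        total = sum(counts.values())
        pos = rng.choice(cfg.chrom_length_bp, size=total, replace=False) + 1
        ctx = np.repeat(list(counts), list(counts.values()))
        strand = np.where(rng.random(total) < 0.5, "+", "-")
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "strand": strand, "context": ctx}))
    sites = pd.concat(frames, ignore_index=True)
    return sites.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _apply_tss_dip(sites: pd.DataFrame, genes: list[GeneModel],
                   cfg: SimulationConfig, level: np.ndarray) -> None:
    half, mult = cfg.tss_dip
    if half <= 0 or mult == 1.0:
        return
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    for g in genes:
        mask = (chrom == g.chrom) & (np.abs(pos - g.tss) <= half)
        level[mask] *= mult


def _plant_dmrs(sites: pd.DataFrame, genes: list[GeneModel],
                cfg: SimulationConfig, rng: np.random.Generator,
                level_ref: np.ndarray, level_trt: np.ndarray) -> pd.DataFrame:
    taken: list[tuple[str, int, int]] = []
    rows = []
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for pd_spec in cfg.planted_dmrs:
        candidates = _placement_intervals(pd_spec.placement, genes, cfg, rng)
        planted = False
        for chrom, lo, hi in candidates:
            in_reg = np.flatnonzero((chrom_arr == chrom) & (pos >= lo)
                                    & (pos <= hi) & (ctx_arr == pd_spec.context))
            if len(in_reg) < pd_spec.n_sites:
                continue
            offset = int(rng.integers(0, len(in_reg) - pd_spec.n_sites + 1))
            idx = in_reg[offset:offset + pd_spec.n_sites]
            start, end = int(pos[idx[0]]), int(pos[idx[-1]])
            if any(c == chrom and not (end < s or start > e)
                   for c, s, e in taken):
                continue
            level_ref[idx] = pd_spec.level_ref
            level_trt[idx] = pd_spec.level_trt
            taken.append((chrom, start, end))
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "context": pd_spec.context,
                         "level_ref": pd_spec.level_ref,
                         "level_trt": pd_spec.level_trt,
                         "direction": ("hyper" if pd_spec.level_trt > pd_spec.level_ref
                                       else "hypo"),
                         "n_sites": pd_spec.n_sites})
            planted = True
            break
        if not planted:
            raise RuntimeError(
                f"could not plant DMR {pd_spec}: not enough {pd_spec.context} "
                f"sites in any candidate {pd_spec.placement} region")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "level_ref", "level_trt", "direction",
                                       "n_sites"])


def _placement_intervals(placement: str, genes: list[GeneModel],
                         cfg: SimulationConfig, rng: np.random.Generator):
    order = rng.permutation(len(genes)) if genes else []
    if placement == "promoter":
        out = []
        for i in order:
            g = genes[i]
            if g.strand == "+":
                out.append((g.chrom, max(1, g.tx_start - cfg.promoter_bp),
                            g.tx_start - 1))
            else:
                out.append((g.chrom, g.tx_end + 1, g.tx_end + cfg.promoter_bp))
        return out
    if placement == "gene_body":
        return [(genes[i].chrom, genes[i].tx_start, genes[i].tx_end)
                for i in order]
    if placement == "intergenic":
        out = []
        for _ in range(200):
            chrom = _chrom_name(int(rng.integers(cfg.n_chroms)))
            width = 10_000
            lo = int(rng.integers(1, max(2, cfg.chrom_length_bp - width)))
            hi = lo + width - 1
            flank = cfg.promoter_bp
            if all(g.chrom != chrom or hi < g.tx_start - flank
                   or lo > g.tx_end + flank for g in genes):
                out.append((chrom, lo, hi))
        return out
    raise ValueError(f"unknown placement {placement!r}")


def simulate_methylomes(cfg: SimulationConfig, genes: list[GeneModel],
                        outdir: str | os.PathLike | None = None
                        ) -> tuple[list[MethylomeSample], list[MethylomeSample],
                                   SimulationTruth]:
    """Draw two groups of replicate methylomes plus ground truth.

    Per site, the true level is the context baseline, attenuated near TSSs,
    and overridden inside planted regions (group-specific).  Per replicate,
    coverage ~ Poisson(depth_mean) and the methylated count is binomial with
    success probability level*(1-e) + (1-level)*e, folding bisulfite
    conversion error ``e`` in symmetrically.  Zero-coverage sites are kept.
    """
    rng = _rng(cfg.seed, 1)
    sites = _site_positions(cfg, rng)
    base = sites["context"].map(cfg.baseline_levels).to_numpy(dtype=float)
    level_ref = base.copy()
    _apply_tss_dip(sites, genes, cfg, level_ref)
    level_trt = level_ref.copy()
    planted = _plant_dmrs(sites, genes, cfg, rng, level_ref, level_trt)

    truth = SimulationTruth(
        planted=planted,
        site_levels=sites.assign(level_ref=level_ref, level_trt=level_trt),
    )

    e = cfg.conversion_error
    samples: dict[str, list[MethylomeSample]] = {"reference": [], "treatment": []}
    for group, levels in (("reference", level_ref), ("treatment", level_trt)):
        p_obs = levels * (1 - e) + (1 - levels) * e
        for r in range(cfg.replicates_per_group):
            depth = rng.poisson(cfg.depth_mean, size=len(sites))
            n_meth = rng.binomial(depth, p_obs)
            df = pd.DataFrame({
                "chrom": sites["chrom"], "pos": sites["pos"],
                "strand": sites["strand"], "n_meth": n_meth,
                "n_unmeth": depth - n_meth, "context": sites["context"],
            })[RECORD_COLUMNS]
            sample = MethylomeSample(sample_id=f"{group}_{r + 1}", group=group,
                                     records=df)
            samples[group].append(sample)
            if outdir is not None:
                write_cytosine_report(
                    sample, os.path.join(outdir, f"{sample.sample_id}.cx.tsv"))
    return samples["reference"], samples["treatment"], truth


# ---------------------------------------------------------------------------
# term annotations and qPCR plates
# ---------------------------------------------------------------------------

def simulate_terms(genes: list[GeneModel] | list[str], n_terms: int = 20,
                   genes_per_term: tuple[int, int] = (5, 20),
                   enriched_term: tuple[str, set[str], float] | None = None,
                   seed: int = 0,
                   path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Random gene -> term table, optionally with one enriched term.

    ``enriched_term`` = (term_id, target gene ids, excess probability): each
    target gene is additionally annotated to the term with that probability,
    on top of a background draw.
    """
    rng = np.random.default_rng([seed, 2])
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    rows = []
    for t in range(n_terms):
        term_id = f"TERM:{t + 1:04d}"
        k = int(rng.integers(genes_per_term[0],
                             min(genes_per_term[1], len(gene_ids)) + 1))
        for gi in rng.choice(len(gene_ids), size=k, replace=False):
            rows.append((gene_ids[gi], term_id))
    if enriched_term is not None:
        term_id, targets, excess = enriched_term
        for gid in sorted(targets):
            if gid in gene_ids and rng.random() < excess:
                rows.append((gid, term_id))
    df = (pd.DataFrame(rows, columns=["gene_id", "term_id"])
            .drop_duplicates().sort_values(["term_id", "gene_id"])
            .reset_index(drop=True))
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")
    return df


def simulate_qpcr_plate(n_per_group: int = 6, true_fold: float = 3.0,
                        ct_noise_sd: float = 0.15, seed: int = 5,
                        target_gene: str = "target",
                        reference_gene: str = "ef1a",
                        path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Long-format qPCR plate with a planted expression fold change.

    Reference-gene Ct ~ N(20, sd) everywhere; target Ct ~ N(25, sd) in the
    reference group and shifted by -log2(true_fold) cycles in the treatment
    group (higher expression = earlier amplification).
    """
    rng = np.random.default_rng([seed, 3])
    rows = []
    for group, shift in (("reference", 0.0), ("treatment", -np.log2(true_fold))):
        for i in range(n_per_group):
            sid = f"{group[:3]}{i + 1}"
            rows.append((sid, group, reference_gene,
                         20.0 + ct_noise_sd * rng.standard_normal()))
            rows.append((sid, group, target_gene,
                         25.0 + shift + ct_noise_sd * rng.standard_normal()))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, lineterminator="\n",
                  float_format="%.6f")
    return df
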