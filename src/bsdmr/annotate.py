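"""Assignment of DMRs to gene promoters and gene bodies (DMG calling).

A gene whose promoter or gene body overlaps at least one DMR (by >= 1 bp) is
a differentially methylated gene (DMG).  The promoter is the strand-aware
window of ``promoter_bp`` immediately 5' of the TSS; the gene body is
TSS..TES including introns.  A DMR straddling the TSS contributes to both
region classes.  Per (gene, region class, context), the gene's direction is
that of the larger summed overlap length, with an explicit ``ambiguous``
state on an exact tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel
from .dmr import DMR

REGION_CLASSES = ("promoter", "gene_body")


@dataclass(frozen=True)
class DMG:
    gene_id: str
    region_class: str
    context: str
    direction: str        # hyper | hypo | ambiguous
    n_dmrs: int
    best_p: float
    total_overlap_bp: int


class GeneRegionIndex:
    """Promoter and gene-body intervals per gene, grouped by chromosome.

    Intervals are 1-based inclusive and clipped at position 1.
    """

    def __init__(self, entries: list[tuple[str, int, int, str, str]]):
        # entries: (chrom, start, end, gene_id, region_class)
        self.by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
        for chrom, start, end, gene_id, rc in entries:
            self.by_chrom.setdefault(chrom, []).append((start, end, gene_id, rc))
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort()

    def overlapping(self, chrom: str, start: int, end: int):
        """All (gene_id, region_class, ov_start, ov_end) regions intersecting [start, end]."""
        hits = []
        for s, e, gene_id, rc in self.by_chrom.get(chrom, ()):
            if s > end:
                break
            if e >= start:
                hits.append((gene_id, rc, max(s, start), min(e, end)))
        return hits


def build_region_index(genes: list[GeneModel], promoter_bp: int = 2000) -> GeneRegionIndex:
    """Strand-aware promoter (length ``promoter_bp`` ending at the TSS) + body index."""
    if promoter_bp < 1:
        raise ValueError("promoter_bp must be >= 1")
    entries = []
    for g in genes:
        if g.strand == "+":
            prom = (max(1, g.tx_start - promoter_bp), g.tx_start - 1)
        else:
            prom = (g.tx_end + 1, g.tx_end + promoter_bp)
        if prom[0] <= prom[1]:
            entries.append((g.chrom, prom[0], prom[1], g.gene_id, "promoter"))
        entries.append((g.chrom, g.tx_start, g.tx_end, g.gene_id, "gene_body"))
    return GeneRegionIndex(entries)


def assign_dmgs(dmrs: list[DMR], index: GeneRegionIndex) -> list[DMG]:
    """Intersect DMRs with the region index and call per-(gene, region, context) DMGs."""
    acc: dict[tuple[str, str, str], dict] = {}
    for d in dmrs:
        for gene_id, rc, ov_s, ov_e in index.overlapping(d.chrom, d.start, d.end):
            key = (gene_id, rc, d.context)
            rec = acc.setdefault(key, {"n": 0, "best_p": 1.0, "hyper_bp": 0,
                                       "hypo_bp": 0})
            ov = ov_e - ov_s + 1
            rec["n"] += 1
            rec["best_p"] = min(rec["best_p"], d.p_value)
            rec[f"{d.direction}_bp"] += ov
    out = []
    for (gene_id, rc, context), rec in sorted(acc.items()):
        if rec["hyper_bp"] > rec["hypo_bp"]:
            direction = "hyper"
        elif rec["hypo_bp"] > rec["hyper_bp"]:
            direction = "hypo"
        else:
            direction = "ambiguous"
        out.append(DMG(gene_id=gene_id, region_class=rc, context=context,
                       direction=direction, n_dmrs=rec["n"],
                       best_p=rec["best_p"],
                       total_overlap_bp=rec["hyper_bp"] + rec["hypo_bp"]))
    return out


def dmg_count_table(dmgs: list[DMG]) -> pd.DataFrame:
    """Cross-tabulate DMG counts per (region_class x direction x context).

    Genes are counted once per (region_class, context).  A deduplicated
    per-region total across contexts is appended as context 'any' (direction
    'all').
    """
    from .io import CONTEXTS

    rows = []
    for rc in REGION_CLASSES:
        for ctx in CONTEXTS:
            for direction in ("hyper", "hypo", "ambiguous"):
                n = len({d.gene_id for d in dmgs
                         if d.region_class == rc and d.context == ctx
                         and d.direction == direction})
                rows.append({"region_class": rc, "context": ctx,
                             "direction": direction, "n_genes": n})
        dedup = len({d.gene_id for d in dmgs if d.region_class == rc})
        rows.append({"region_class": rc, "context": "any", "direction": "all",
                     "n_genes": dedup})
    return pd.DataFrame(rows)
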