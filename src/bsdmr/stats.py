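"""Site, genome-wide and metagene methylation summaries.

A site's methylation level is Nm/(Nm+Nnm) — the fraction of reads reporting
methylation.  Two genome-wide statistics are reported side by side, because
"fraction of cytosines methylated" is ambiguous in common usage:

* the pooled *weighted level* per context, sum(Nm)/sum(Nm+Nnm); and
* the *site fraction methylated*: the fraction of covered sites at which a
  one-sided binomial test rejects the bisulfite-conversion error rate as the
  sole source of methylated reads.

The metagene profile averages levels over seven gene sub-regions (upstream
flank, first exon, first intron, internal exons, internal introns, last exon,
downstream flank), each scaled to a fixed number of bins in transcription
orientation, so the characteristic dip of CG methylation at the TSS is
visible regardless of gene length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CONTEXTS, GeneModel, MethylomeSample

REGION_ORDER = (
    "upstream", "first_exon", "first_intron", "internal_exon",
    "internal_intron", "last_exon", "downstream",
)


def site_level(n_meth: int, n_unmeth: int) -> float:
    """Methylation level Nm/(Nm+Nnm) of a single site; undefined at zero coverage."""
    total = n_meth + n_unmeth
    if total < 1:
        raise ValueError("site level undefined at zero coverage")
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("read counts must be non-negative")
    return n_meth / total


@dataclass
class GlobalSummary:
    per_context_weighted_level: dict[str, float]   # context -> sum(Nm)/sum(N), NaN if no sites
    per_context_site_fraction_methylated: dict[str, float]
    overall_site_fraction_methylated: float
    n_covered_sites: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "context": c,
                "weighted_level": self.per_context_weighted_level[c],
                "site_fraction": self.per_context_site_fraction_methylated[c],
                "n_sites": self.n_covered_sites[c],
            }
            for c in CONTEXTS
        ]
        return pd.DataFrame(rows)


def global_summary(sample: MethylomeSample, min_depth: int = 4,
                   error_rate: float = 0.005, call_alpha: float = 0.05) -> GlobalSummary:
    """Genome-wide methylation summary of one sample.

    Sites with total coverage below ``min_depth`` are ignored.  A covered
    site is *called methylated* when the one-sided binomial probability of
    observing at least its methylated read count under the conversion error
    rate alone falls below ``call_alpha``.  A context with no covered site is
    flagged missing (NaN), not zero.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    df = sample.records
    total = df["n_meth"] + df["n_unmeth"]
    covered = df[total >= min_depth].copy()
    covered["total"] = total[total >= min_depth]
    # P(X >= n_meth | total, error_rate), one-sided upper tail
    pvals = sps.binom.sf(covered["n_meth"].to_numpy() - 1,
                         covered["total"].to_numpy(), error_rate)
    covered["called"] = pvals < call_alpha

    weighted: dict[str, float] = {}
    fraction: dict[str, float] = {}
    n_sites: dict[str, int] = {}
    for c in CONTEXTS:
        sub = covered[covered["context"] == c]
        n_sites[c] = len(sub)
        if len(sub) == 0:
            weighted[c] = float("nan")
            fraction[c] = float("nan")
        else:
            weighted[c] = float(sub["n_meth"].sum() / sub["total"].sum())
            fraction[c] = float(sub["called"].mean())
    overall = float(covered["called"].mean()) if len(covered) else float("nan")
    return GlobalSummary(weighted, fraction, overall, n_sites)


@dataclass
class RegionProfile:
    """Mean methylation level per (region, bin, context) over genes."""

    region_order: tuple[str, ...]
    bins_per_region: int
    matrix: dict[str, np.ndarray]          # context -> 7 x bins array (NaN = missing)
    n_genes_contributing: dict[str, int]   # region -> genes possessing the region

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctx, mat in self.matrix.items():
            for ri, region in enumerate(self.region_order):
                for b in range(self.bins_per_region):
                    rows.append({
                        "region": region, "bin_index": b, "context": ctx,
                        "mean_level": mat[ri, b],
                        "n_genes": self.n_genes_contributing[region],
                    })
        return pd.DataFrame(rows)


def _gene_regions(g: GeneModel, flank_bp: int) -> dict[str, list[tuple[int, int]]]:
    """Intervals (1-based inclusive, in transcription order) of the seven regions."""
    exons = list(g.exons)
    tx_order = exons if g.strand == "+" else exons[::-1]
    introns = []
    for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
        if s2 - e1 > 1:
            introns.append((e1 + 1, s2 - 1))
    introns_tx = introns if g.strand == "+" else introns[::-1]

    regions: dict[str, list[tuple[int, int]]] = {}
    if g.strand == "+":
        up = (g.tx_start - flank_bp, g.tx_start - 1)
        down = (g.tx_end + 1, g.tx_end + flank_bp)
    else:
        up = (g.tx_end + 1, g.tx_end + flank_bp)
        down = (g.tx_start - flank_bp, g.tx_start - 1)
    up = (max(1, up[0]), up[1])
    down = (max(1, down[0]), down[1])
    if up[0] <= up[1]:
        regions["upstream"] = [up]
    if down[0] <= down[1]:
        regions["downstream"] = [down]
    regions["first_exon"] = [tx_order[0]]
    if len(tx_order) >= 2:
        regions["last_exon"] = [tx_order[-1]]
    if len(tx_order) > 2:
        regions["internal_exon"] = tx_order[1:-1]
    if introns_tx:
        regions["first_intron"] = [introns_tx[0]]
    if len(introns_tx) > 1:
        regions["internal_intron"] = introns_tx[1:]
    return regions


def region_profile(sample: MethylomeSample, genes: list[GeneModel],
                   flank_bp: int = 2000, bins_per_region: int = 20) -> RegionProfile:
    """Seven-region metagene methylation profile, strand-aware.

    Per gene and region, covered sites are pooled into ``bins_per_region``
    equal-length bins by relative position along the region in transcription
    orientation; the bin value is the pooled level per gene averaged over
    genes with data in that bin.  Genes lacking a region (single-exon genes
    have no introns or last exon) contribute nothing to it.
    """
    if not genes:
        raise ValueError("empty gene list")
    if flank_bp < bins_per_region:
        raise ValueError("flank_bp must be >= bins_per_region")

    df = sample.records
    total = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    df = df[total > 0]
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("pos") for c, sub in df.groupby("chrom")
    }

    nbins = bins_per_region
    # per context: sums of per-gene levels and gene counts, per (region, bin)
    level_sum = {c: np.zeros((len(REGION_ORDER), nbins)) for c in CONTEXTS}
    gene_cnt = {c: np.zeros((len(REGION_ORDER), nbins)) for c in CONTEXTS}
    n_genes_region = dict.fromkeys(REGION_ORDER, 0)

    for g in genes:
        regions = _gene_regions(g, flank_bp)
        chrom_sites = by_chrom.get(g.chrom)
        for region, ivals in regions.items():
            n_genes_region[region] += 1
            if chrom_sites is None:
                continue
            ri = REGION_ORDER.index(region)
            L = sum(e - s + 1 for s, e in ivals)
            # accumulate pooled counts per (context, bin) for this gene
            m_acc = {c: np.zeros(nbins) for c in CONTEXTS}
            t_acc = {c: np.zeros(nbins) for c in CONTEXTS}
            offset = 0
            pos_arr = chrom_sites["pos"].to_numpy()
            for s, e in ivals:
                lo = np.searchsorted(pos_arr, s, side="left")
                hi = np.searchsorted(pos_arr, e, side="right")
                if hi > lo:
                    sub = chrom_sites.iloc[lo:hi]
                    pos = sub["pos"].to_numpy()
                    if g.strand == "+":
                        off = offset + (pos - s)
                    else:
                        off = offset + (e - pos)
                    rel = (off + 0.5) / L
                    bins = np.minimum((rel * nbins).astype(int), nbins - 1)
                    for c in CONTEXTS:
                        mask = (sub["context"] == c).to_numpy()
                        if mask.any():
                            np.add.at(m_acc[c], bins[mask],
                                      sub["n_meth"].to_numpy()[mask])
                            np.add.at(t_acc[c], bins[mask],
                                      (sub["n_meth"] + sub["n_unmeth"]).to_numpy()[mask])
                offset += e - s + 1
            for c in CONTEXTS:
                has = t_acc[c] > 0
                level_sum[c][ri, has] += m_acc[c][has] / t_acc[c][has]
                gene_cnt[c][ri, has] += 1

    matrix = {}
    for c in CONTEXTS:
        with np.errstate(invalid="ignore"):
            matrix[c] = np.where(gene_cnt[c] > 0, level_sum[c] / gene_cnt[c], np.nan)
    return RegionProfile(REGION_ORDER, nbins, matrix, n_genes_region)
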