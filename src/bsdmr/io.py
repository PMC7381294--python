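"""Readers and writers for the pipeline's on-disk formats.

Formats handled here:

* per-cytosine count reports (Bismark cytosine/CX-report dialect: TSV with
  chrom, 1-based position, strand, methylated count, unmethylated count,
  context, optional trinucleotide column);
* gene annotations (GFF3 via :mod:`gffutils`, or BED12);
* two-column gene -> term annotation tables;
* DMR output as BED6+5 and DMG output as TSV.

Internal coordinates are 1-based inclusive throughout (the cytosine-report
convention); BED input/output is converted from/to 0-based half-open at the
boundary of this module and nowhere else.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
GROUPS = ("reference", "treatment")

#: dtypes of the canonical per-cytosine record table
RECORD_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]


class FormatError(ValueError):
    """A file violated the expected dialect."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine site: counts of methylated (Nm) and unmethylated (Nnm) reads."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    context: str  # CG | CHG | CHH
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class MethylomeSample:
    """A single replicate methylome as a sorted, de-duplicated site table.

    ``records`` is a DataFrame with columns chrom, pos, strand, n_meth,
    n_unmeth, context, sorted by (chrom, pos, strand) with no duplicate
    (chrom, pos, strand) keys.  Zero-coverage sites are retained; statistics
    downstream skip them.
    """

    sample_id: str
    group: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.records = _validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, RECORD_COLUMNS].copy()
    if len(df) == 0:
        return df.reset_index(drop=True)
    bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
    if bad_ctx:
        raise FormatError(f"unknown context token(s): {sorted(bad_ctx)}")
    bad_strand = set(df["strand"].unique()) - {"+", "-"}
    if bad_strand:
        raise FormatError(f"unknown strand token(s): {sorted(bad_strand)}")
    if (df["pos"] < 1).any():
        raise FormatError("positions must be 1-based (>= 1)")
    if (df[["n_meth", "n_unmeth"]] < 0).to_numpy().any():
        raise FormatError("negative read count")
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = df.loc[dup, ["chrom", "pos", "strand"]].iloc[0]
        raise FormatError(
            f"duplicate site key {first['chrom']}:{first['pos']}:{first['strand']}"
        )
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class GeneModel:
    """One gene represented by a single (longest) transcript.

    Coordinates are 1-based inclusive; ``exons`` is sorted by genomic
    position and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: a gene needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s < self.tx_start or e > self.tx_end:
                raise FormatError(f"{self.gene_id}: exon [{s},{e}] outside transcript bounds")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | os.PathLike, sample_id: str | None = None,
                         group: str = "reference") -> MethylomeSample:
    """Read a Bismark-style per-cytosine count report into a :class:`MethylomeSample`.

    Expected columns (TSV, no header): chrom, pos (1-based), strand, n_meth,
    n_unmeth, context; a 7th trinucleotide column, if present, is ignored.
    Zero-coverage sites are kept.  Raises :class:`FormatError` naming the line
    for malformed rows, unknown context tokens, or duplicate site keys.
    """
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed cytosine report: {exc}") from exc
    if len(df) and df.shape[1] < 6:
        raise FormatError(f"{path}: expected >= 6 tab-separated columns, got {df.shape[1]}")
    if len(df):
        df = df.iloc[:, :6]
        df.columns = RECORD_COLUMNS
    for col in ("pos", "n_meth", "n_unmeth"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad.index[bad.isna()][0]) + 1 if bad.isna().any() else "?"
            raise FormatError(f"{path}: non-integer {col} at line {line}") from exc
    try:
        df = _validate_records(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return MethylomeSample(sample_id=sample_id, group=group, records=df)


def write_cytosine_report(sample: MethylomeSample, path: str | os.PathLike) -> None:
    """Write ``sample`` as a 6-column cytosine report; round-trips with the reader."""
    sample.records.to_csv(path, sep="\t", header=False, index=False,
                          lineterminator="\n")


def classify_context(base_plus1: str, base_plus2: str) -> str:
    """Classify a cytosine's sequence context from the two 3' bases on its strand.

    CG if the next base is G; CHG if it is H (A/C/T) followed by G; CHH if
    both are H.  Ambiguity codes are rejected.
    """
    b1, b2 = base_plus1.upper(), base_plus2.upper()
    for b in (b1, b2):
        if b not in "ACGT":
            raise ValueError(f"invalid nucleotide {b!r} (ambiguity codes rejected)")
    if b1 == "G":
        return "CG"
    return "CHG" if b2 == "G" else "CHH"


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | os.PathLike, format: str = "gff3") -> list[GeneModel]:
    """Load gene models from GFF3 or BED12.

    For GFF3, a gene with several transcripts is represented by its longest
    one.  BED12 coordinates (0-based half-open) are converted to the internal
    1-based inclusive convention.
    """
    if format == "gff3":
        return _read_gff3(os.fspath(path))
    if format == "bed12":
        return _read_bed12(os.fspath(path))
    raise ValueError(f"unknown annotation format {format!r} (expected gff3 or bed12)")


def _read_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: tuple[int, gffutils.Feature] | None = None
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            span = tx.end - tx.start + 1
            if best is None or span > best[0]:
                best = (span, tx)
        if best is None:  # exons attached directly to the gene feature
            tx = gene
        else:
            tx = best[1]
        exons = sorted(
            (e.start, e.end) for e in db.children(tx, featuretype="exon")
        )
        if not exons:
            exons = [(tx.start, tx.end)]
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            tx_start=tx.start, tx_end=tx.end, exons=tuple(exons),
        ))
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 columns")
            chrom, start0, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: block count mismatch")
            tx_start, tx_end = start0 + 1, end
            exons = tuple(
                (start0 + bs + 1, start0 + bs + sz) for bs, sz in zip(starts, sizes)
            )
            genes.append(GeneModel(
                gene_id=name, chrom=chrom, strand=strand,
                tx_start=tx_start, tx_end=tx_end, exons=exons,
            ))
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# DMR / DMG / term tables
# ---------------------------------------------------------------------------

DMR_BED_EXTRA = ["level_reference", "level_treatment", "fold_change", "p_value",
                 "direction"]


def write_dmr_bed(dmrs: Iterable, path: str | os.PathLike) -> None:
    """Write DMRs as BED6+5 (0-based half-open; score = -10*log10(p), capped at 1000)."""
    rows = []
    for d in dmrs:
        score = 1000 if d.p_value <= 0 else min(1000, round(-10.0 * math.log10(d.p_value)))
        rows.append({
            "chrom": d.chrom, "start": d.start - 1, "end": d.end,
            "name": d.context, "score": int(score), "strand": ".",
            "level_reference": f"{d.level_ref:.6g}",
            "level_treatment": f"{d.level_trt:.6g}",
            "fold_change": f"{d.fold_change:.6g}",
            "p_value": f"{d.p_value:.6g}",
            "direction": d.direction,
        })
    cols = ["chrom", "start", "end", "name", "score", "strand"] + DMR_BED_EXTRA
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", header=False,
                                            index=False, lineterminator="\n")


def read_dmr_bed(path: str | os.PathLike):
    """Read BED6+5 DMRs written by :func:`write_dmr_bed` back into DMR objects."""
    from .dmr import DMR  # local import: avoids a module cycle

    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"]
                         + DMR_BED_EXTRA, dtype={0: str})
    except pd.errors.EmptyDataError:
        return []
    dmrs = []
    for row in df.itertuples(index=False):
        dmrs.append(DMR(
            chrom=row.chrom, context=row.name, start=int(row.start) + 1,
            end=int(row.end), level_ref=float(row.level_reference),
            level_trt=float(row.level_treatment),
            fold_change=float(row.fold_change), p_value=float(row.p_value),
            direction=row.direction, n_sites=0, merged_from=1,
        ))
    return dmrs


DMG_COLUMNS = ["gene_id", "region_class", "context", "direction", "n_dmrs",
               "best_p", "total_overlap_bp"]


def write_dmg_table(dmgs: Iterable, path: str | os.PathLike) -> None:
    """Write DMG hits as a headered TSV."""
    rows = [{c: getattr(d, c) for c in DMG_COLUMNS} for d in dmgs]
    pd.DataFrame(rows, columns=DMG_COLUMNS).to_csv(path, sep="\t", index=False,
                                                   lineterminator="\n")


def read_dmg_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_term_annotation(path: str | os.PathLike,
                         term_names: str | os.PathLike | None = None):
    """Read a two-column gene_id<TAB>term_id table into TermAnnotation objects."""
    from .enrichment import TermAnnotation

    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str, comment="#")
    names = {}
    if term_names is not None:
        ndf = pd.read_csv(term_names, sep="\t", header=None,
                          names=["term_id", "term_name"], dtype=str)
        names = dict(zip(ndf["term_id"], ndf["term_name"]))
    terms = []
    for term_id, sub in df.groupby("term_id", sort=True):
        terms.append(TermAnnotation(
            term_id=str(term_id), term_name=names.get(term_id, str(term_id)),
            annotated_genes=frozenset(sub["gene_id"]),
        ))
    return terms


def sample_from_records(records: Sequence[CytosineRecord], sample_id: str,
                        group: str) -> MethylomeSample:
    """Build a MethylomeSample from individual records (test/construction helper)."""
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context) for r in records],
        columns=RECORD_COLUMNS,
    )
    return MethylomeSample(sample_id=sample_id, group=group, records=df)
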