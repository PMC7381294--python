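# Methods

## Data model and conventions

Internal coordinates are 1-based inclusive everywhere; BED input/output is
converted at the I/O boundary (0-based half-open). A cytosine site is keyed
by (chromosome, position, strand); the + and − cytosines of a CpG dyad are
independent sites and are never collapsed. Contexts are CG, CHG, CHH
(H = A/C/T), read from the report's context column — the package does not
re-derive contexts from a reference genome (though `classify_context`
implements the definition for callers that have the flanking bases).
Zero-coverage sites are retained on input, because their positions matter
for window construction bookkeeping, but they enter no statistic: the site
level `Nm/(Nm+Nnm)` is undefined at zero coverage and asking for it raises.

Genes with several transcripts are represented by the longest one; a single
transcript model per gene is required by the seven-region metagene
partition and is the conventional reduction when no expression data guide
the choice.

## Genome-wide summaries

Because "percent of cytosines methylated" can mean either read-weighted or
site-counted methylation, `global_summary` reports both per context:

* **weighted level** — pooled `ΣNm / Σ(Nm+Nnm)` over covered sites;
* **site fraction methylated** — the fraction of covered sites at which a
  one-sided binomial test rejects the bisulfite-conversion error rate as
  the sole source of methylated reads (default `error_rate = 0.005`,
  matching a ~99.5 % conversion rate, at `call_alpha = 0.05`).

Sites need `min_depth = 4` pooled reads to count as covered (a common WGBS
floor; configurable). A context with no covered sites is flagged missing
(NaN) rather than zero. In high-methylation CG contexts the two statistics
nearly coincide; in CHG/CHH they diverge strongly (level ≈ 1–2 %, site
fraction ≈ 4 % at depth 20), which is why both are kept.

The metagene profile partitions each gene into upstream flank, first exon,
first intron, internal exons, internal introns, last exon, and downstream
flank — first/last in *transcription* order, so the first exon of a −
strand gene is its rightmost. Each region is rescaled to `bins_per_region`
(default 20) equal-length bins in transcription orientation
(`flank_bp = 2000`). A site's bin is determined by its mid-offset
`(offset + 0.5)/length`, which makes the profile exactly invariant under
mirroring the genome and flipping all strands (a property the tests
check). Bin values are per-gene pooled levels averaged over genes with
data; genes lacking a region (single-exon genes have no introns) contribute
nothing to it.

## DMR calling

Windows are consecutive, non-overlapping blocks of `window_sites = 5`
same-context sites per chromosome, tiled over *eligible* sites — pooled
depth ≥ `min_depth_per_group = 4` in both groups after summing replicates
within each group. Non-overlapping tiling (rather than sliding) avoids
dependent overlapping tests and makes "neighbouring DMRs" well defined; a
trailing remainder shorter than one window is discarded. Replicates are
pooled because a 2×2 Fisher table needs one count pair per group.

Each window's table `[[Nm_ref, Nnm_ref], [Nm_trt, Nnm_trt]]` gets a
two-sided Fisher exact p: the sum of hypergeometric probabilities of all
same-margin tables whose probability is ≤ the observed table's, with a
relative tolerance of 1e-7 on the comparison so floating-point noise cannot
exclude exact ties. The pmf is evaluated through log-gamma factorials; the
test suite checks the result against exact rational enumeration on every
table with total ≤ 40 (where the distinct-probability gap is always ≥ 1e-3,
so the tolerance is inert) and against an independent library
implementation on random larger tables. A zero row or column margin
returns p = 1 (no evidence) rather than erroring.

A window becomes a DMR iff its level fold change is ≥ `min_fold = 2` *and*
p ≤ `alpha = 0.05`, both inclusive. The fold uses pseudocounted levels
`(Nm + ½)/(Nm + Nnm + 1)` (Jeffreys), `fold = max(r, 1/r)`, so fully
unmethylated windows are finite; reported levels are the raw pooled ones.
Direction is hyper when the treatment level exceeds the reference level.
An optional Benjamini–Hochberg mode adjusts window p-values per context
before gating; it is off by default to match the raw-p rule.

**Merging.** Consecutive same-chromosome, same-context, same-direction
DMRs (no other DMR between them; gap unlimited by default, configurable via
`max_merge_gap`) are joined when the span from the upstream start to the
downstream end — re-pooled over *all* eligible sites of that context in the
span, not only the two DMRs' sites — still shows a twofold pseudocounted
change. Merging repeats left-to-right until a fixpoint and is idempotent.
Opposite-direction neighbours never merge, since a "twofold difference" of
a mixed-direction span is not meaningful. The merged DMR's p-value is
recomputed on the span for reporting, but the merge criterion is the fold
test only; in principle a merged span's p could exceed α, though in
practice two individually significant DMRs plus a passing span fold keep
it far below.

**Calibration and sensitivity.** Under a null simulation (both groups at
level 0.5, depth 20, 3 replicates, 2000 windows) no windows are emitted:
the p ≤ α gate bounds the rate at 5 % and the twofold gate removes
essentially everything else at that depth. In low-level contexts
(CHG/CHH ≈ 1 %), the twofold gate is weak — small-count fluctuations easily
double a near-zero level — so windows are admitted at a rate governed by
the (conservative, discrete) Fisher gate alone, ~1–3 % of windows in the
default simulation. These calls are an inherent property of the published
rule at low methylation, not an implementation artifact; recovery tests
therefore assess the planted CG design in the CG context. Planted CG
regions of 8 consecutive sites at 0.8 vs 0.2 with depth 20 × 3 replicates
are recovered essentially always: any 5-site tiling of an 8-site run
leaves at least one window with ≥ 4 differential sites, whose diluted fold
(≥ ~2.4) and p (≪ 0.05 at ~300 reads per group) both pass.

## DMG annotation

Promoter = `promoter_bp` (default 2000, never defined by convention-free
data, so configurable) immediately 5′ of the TSS, strand-aware and clipped
at position 1; gene body = TSS..TES including introns. Overlap threshold is
1 bp; a DMR straddling the TSS counts for both region classes. Per
(gene, region class, context), direction is decided by the larger summed
overlap length, with an explicit `ambiguous` state on exact ties instead of
a silent tie-break. The count table keeps contexts separate and adds a
deduplicated per-region total, since published per-context tallies and
deduplicated gene counts answer different questions.

## Enrichment

`p_raw = P(X ≥ m)` for `X ~ Hypergeom(N, M, n)` with N = genes having any
annotation (the universe), n = selected genes in N, M = genes annotated to
the term, m = selected genes in M — evaluated by log-gamma summation of the
upper tail (exact to ~1e-13 against integer enumeration for N ≤ 60).
Selected genes outside the universe are dropped with a warning; only terms
with M ≥ 1 in the universe are tested, and the Bonferroni factor T counts
exactly those (untestable terms should not consume correction budget).
Results sort by (p_raw, term_id), making output byte-stable. KEGG-style
pathway enrichment is the same computation on pathway gene sets. The
`rich factor` m/M is emitted as a column.

## qPCR

Per sample, technical replicates are averaged at the Ct level; then
`ΔCt = Ct(target) − Ct(reference gene)`, `ΔΔCt = ΔCt − mean ΔCt` over the
reference group, fold `= 2^(−ΔΔCt)` — the Livak convention with the
negative exponent, which the directionality of qPCR requires (higher
expression ⇒ earlier amplification ⇒ lower Ct). The group summary reports
both the mean ± s.e.m. of per-sample folds and the fold computed from the
group-mean ΔCt; the latter is exactly 1.0 for the reference group (anchor
normalization) and is the recommended point estimate, since the mean of
per-sample folds is biased upward by Jensen's inequality. Folds are
invariant under any global Ct shift.

## Simulator

The generator fixes every draw from one seed (two identical configs give
byte-identical files). Defaults emulate the study conditions: 3 replicates
per group; CG baseline 0.80 and CHG/CHH 0.01; a TSS dip (level × 0.5
within ±200 bp of each TSS); Poisson(20) per-replicate coverage; conversion
error 0.005 folded symmetrically into the binomial success probability
`level·(1−e) + (1−level)·e` — the minimal noise model under which the
Fisher test is well specified. Site placement is uniform per context
(20/10/20 sites per kbp for CG/CHG/CHH); CpG-island clustering is not
modelled because it does not affect the statistics under test. The toy
genome defaults to 2 × 1 Mb with 50 non-overlapping multi-exon genes; the
test and acceptance runs use 2 × 300 kb with 20 genes, which keeps the full
pipeline in seconds while leaving ≥ 2000 windows per context. Planted
regions override the group-specific true level on `n_sites ≥ 5` consecutive
same-context sites inside a chosen promoter, gene body, or intergenic
stretch, and the emitted truth table is asserted (in tests) to match the
generator's internal level arrays exactly.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate about real data: biological replicate variance beyond
binomial sampling (no overdispersion), non-uniform coverage and mapping
bias, context-dependent conversion efficiency, island/shore structure, and
correlated methylation between neighbouring sites. On real methylomes the
pooled Fisher test is anti-conservative under biological overdispersion;
the optional BH mode mitigates multiplicity but not overdispersion.

## Numerical and degenerate-input choices

* Fisher/hypergeometric tails: log-gamma pmf, clipped into [0, 1];
  zero margins → p = 1; m = 0 → tail exactly 1.0.
* Gates are inclusive (fold ≥ 2, p ≤ 0.05) as stated by the rule.
* Ties in DMG direction → `ambiguous`; ties in enrichment order → term id.
* Empty inputs: empty report parses to an empty sample; identical groups
  yield zero DMRs and empty-but-valid downstream outputs; an empty gene
  list or universe is an error (no meaningful statistic exists).
* The qPCR anchor uses the reference-group mean ΔCt, so a single-sample
  reference group is permitted but gives that sample fold 1 by
  construction.
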