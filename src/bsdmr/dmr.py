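"""Window-based differential-methylation-region (DMR) calling.

Two groups of replicate methylomes are compared per sequence context.
Eligible sites (pooled coverage in *both* groups at or above a floor) are
tiled, chromosome by chromosome, into consecutive non-overlapping windows of
five sites.  Each window is tested with a two-sided Fisher exact test on the
pooled 2x2 count table (methylated/unmethylated x group) and kept as a DMR
when the methylation level differs at least twofold and p <= 0.05.  Adjacent
same-direction DMRs are then joined whenever the pooled level of the full
span — re-pooled over every eligible site between the upstream DMR's start
and the downstream DMR's end — still differs twofold; otherwise they stay
independent.  Joining repeats to a fixpoint.

Fold changes are computed on pseudocounted levels
(level = (Nm + pc)/(Nm + Nnm + 2*pc), Jeffreys pc = 0.5 by default) so fully
unmethylated windows have a finite fold; the reported levels are the raw
pooled Nm/(Nm+Nnm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CONTEXTS, MethylomeSample

__all__ = [
    "DmrParams", "MethylWindow", "DMR", "SiteCountIndex",
    "fisher_exact_two_sided", "build_windows", "test_window",
    "merge_adjacent_dmrs", "call_dmrs",
]


@dataclass(frozen=True)
class DmrParams:
    """Tunable parameters of the DMR caller (defaults follow the published rule)."""

    window_sites: int = 5          # CpG sites per window
    min_fold: float = 2.0          # minimum level fold change
    alpha: float = 0.05            # Fisher p-value gate (inclusive)
    min_depth_per_group: int = 4   # pooled reads per site per group for eligibility
    pseudocount: float = 0.5       # added to Nm and Nnm for the fold ratio
    max_merge_gap: int | None = None  # bp between neighbours; None = unlimited
    fdr: bool = False              # optional Benjamini-Hochberg gate instead of raw p

    def __post_init__(self) -> None:
        if self.window_sites < 2:
            raise ValueError("window_sites must be >= 2")
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class MethylWindow:
    chrom: str
    context: str
    site_positions: tuple[int, ...]
    n_meth_ref: int
    n_unmeth_ref: int
    n_meth_trt: int
    n_unmeth_trt: int

    @property
    def span(self) -> tuple[int, int]:
        return self.site_positions[0], self.site_positions[-1]


@dataclass(frozen=True)
class DMR:
    chrom: str
    context: str
    start: int   # 1-based inclusive
    end: int
    level_ref: float
    level_trt: float
    fold_change: float
    p_value: float
    direction: str   # 'hyper' if treatment > reference else 'hypo'
    n_sites: int
    merged_from: int = 1


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_REL_TOL = 1e-7  # relative slack on the pmf <= pmf_observed comparison


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (with a
    1e-7 relative tolerance on the comparison).  A zero row or column margin
    carries no evidence and returns 1.0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (_log_comb(c1, k) + _log_comb(n - c1, r1 - k) - _log_comb(n, r1))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum()))


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

class SiteCountIndex:
    """Pooled per-group counts of all eligible sites, keyed by (chrom, context).

    Each entry is a DataFrame with columns pos (sorted), m_ref, u_ref, m_trt,
    u_trt.  Used both to tile windows and to re-pool counts over merged
    spans.
    """

    def __init__(self, tables: dict[tuple[str, str], pd.DataFrame]):
        self.tables = tables

    def span_counts(self, chrom: str, context: str, start: int,
                    end: int) -> tuple[int, int, int, int, int]:
        """(m_ref, u_ref, m_trt, u_trt, n_sites) pooled over eligible sites in [start, end]."""
        tab = self.tables.get((chrom, context))
        if tab is None:
            return 0, 0, 0, 0, 0
        pos = tab["pos"].to_numpy()
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        sub = tab.iloc[lo:hi]
        return (int(sub["m_ref"].sum()), int(sub["u_ref"].sum()),
                int(sub["m_trt"].sum()), int(sub["u_trt"].sum()), hi - lo)


def _pool_group(samples: list[MethylomeSample], context: str) -> pd.DataFrame:
    frames = [s.records[s.records["context"] == context] for s in samples]
    df = pd.concat(frames, ignore_index=True)
    pooled = (df.groupby(["chrom", "pos", "strand"], as_index=False)
                [["n_meth", "n_unmeth"]].sum())
    return pooled


def build_site_index(ref_samples: list[MethylomeSample],
                     trt_samples: list[MethylomeSample], context: str,
                     params: DmrParams) -> SiteCountIndex:
    """Pool replicates within each group and keep sites eligible in both groups."""
    if not ref_samples or not trt_samples:
        raise ValueError("each group needs at least one sample")
    ref = _pool_group(ref_samples, context)
    trt = _pool_group(trt_samples, context)
    merged = ref.merge(trt, on=["chrom", "pos", "strand"], how="inner",
                       suffixes=("_ref", "_trt"))
    depth_ref = merged["n_meth_ref"] + merged["n_unmeth_ref"]
    depth_trt = merged["n_meth_trt"] + merged["n_unmeth_trt"]
    eligible = merged[(depth_ref >= params.min_depth_per_group)
                      & (depth_trt >= params.min_depth_per_group)]
    eligible = eligible.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    tables = {}
    for chrom, sub in eligible.groupby("chrom", sort=True):
        tab = pd.DataFrame({
            "pos": sub["pos"].to_numpy(),
            "m_ref": sub["n_meth_ref"].to_numpy(),
            "u_ref": sub["n_unmeth_ref"].to_numpy(),
            "m_trt": sub["n_meth_trt"].to_numpy(),
            "u_trt": sub["n_unmeth_trt"].to_numpy(),
        })
        tables[(str(chrom), context)] = tab
    return SiteCountIndex(tables)


def build_windows(ref_samples: list[MethylomeSample],
                  trt_samples: list[MethylomeSample], context: str,
                  params: DmrParams | None = None,
                  site_index: SiteCountIndex | None = None) -> list[MethylWindow]:
    """Tile eligible sites of one context into consecutive non-overlapping windows.

    Within each chromosome, eligible sites are taken in coordinate order and
    partitioned into blocks of ``window_sites``; a trailing remainder is
    discarded.  Counts are pooled across replicates and across the window's
    sites.
    """
    params = params or DmrParams()
    if site_index is None:
        site_index = build_site_index(ref_samples, trt_samples, context, params)
    w = params.window_sites
    windows: list[MethylWindow] = []
    for (chrom, ctx), tab in sorted(site_index.tables.items()):
        n_full = len(tab) // w
        for i in range(n_full):
            block = tab.iloc[i * w:(i + 1) * w]
            windows.append(MethylWindow(
                chrom=chrom, context=ctx,
                site_positions=tuple(int(p) for p in block["pos"]),
                n_meth_ref=int(block["m_ref"].sum()),
                n_unmeth_ref=int(block["u_ref"].sum()),
                n_meth_trt=int(block["m_trt"].sum()),
                n_unmeth_trt=int(block["u_trt"].sum()),
            ))
    return windows


# ---------------------------------------------------------------------------
# window testing and merging
# ---------------------------------------------------------------------------

def _levels_and_fold(m_ref, u_ref, m_trt, u_trt, pc):
    tot_ref, tot_trt = m_ref + u_ref, m_trt + u_trt
    level_ref = m_ref / tot_ref if tot_ref else float("nan")
    level_trt = m_trt / tot_trt if tot_trt else float("nan")
    lr = (m_ref + pc) / (tot_ref + 2 * pc)
    lt = (m_trt + pc) / (tot_trt + 2 * pc)
    r = lt / lr
    fold = max(r, 1.0 / r)
    direction = "hyper" if lt > lr else "hypo"
    return level_ref, level_trt, fold, direction


def test_window(w: MethylWindow, params: DmrParams | None = None) -> DMR | None:
    """Fisher-test one window; return a DMR iff fold >= min_fold and p <= alpha."""
    params = params or DmrParams()
    level_ref, level_trt, fold, direction = _levels_and_fold(
        w.n_meth_ref, w.n_unmeth_ref, w.n_meth_trt, w.n_unmeth_trt,
        params.pseudocount)
    if fold < params.min_fold:
        return None
    p = fisher_exact_two_sided(w.n_meth_ref, w.n_unmeth_ref,
                               w.n_meth_trt, w.n_unmeth_trt)
    if p > params.alpha:
        return None
    return DMR(chrom=w.chrom, context=w.context, start=w.span[0], end=w.span[1],
               level_ref=level_ref, level_trt=level_trt, fold_change=fold,
               p_value=p, direction=direction, n_sites=len(w.site_positions))


def merge_adjacent_dmrs(dmrs: list[DMR], all_sites: SiteCountIndex,
                        params: DmrParams | None = None) -> list[DMR]:
    """Join neighbouring same-direction DMRs whose pooled span keeps a twofold change.

    Consecutive same-chromosome, same-context, same-direction DMRs (with no
    other DMR between them, gap <= ``max_merge_gap``) are joined when the
    region from the upstream DMR's start to the downstream DMR's end —
    re-pooled over ALL eligible sites of that context in the span — still
    shows at least ``min_fold`` level change; otherwise they stay separate.
    Scanning repeats until no pass makes a merge.  Idempotent.
    """
    params = params or DmrParams()
    out: list[DMR] = []
    keyfn = lambda d: (d.chrom, d.context)
    groups: dict[tuple[str, str], list[DMR]] = {}
    for d in dmrs:
        groups.setdefault(keyfn(d), []).append(d)
    for key, group in sorted(groups.items()):
        starts = [d.start for d in group]
        if starts != sorted(starts):
            raise ValueError("DMRs must be sorted by start within chromosome/context")
        merged = _merge_run(group, all_sites, params)
        out.extend(merged)
    out.sort(key=lambda d: (d.chrom, d.start, d.context))
    return out


def _merge_run(run: list[DMR], idx: SiteCountIndex, params: DmrParams) -> list[DMR]:
    changed = True
    while changed:
        changed = False
        new: list[DMR] = []
        i = 0
        while i < len(run):
            cur = run[i]
            if i + 1 < len(run):
                nxt = run[i + 1]
                gap = nxt.start - cur.end - 1
                gap_ok = params.max_merge_gap is None or gap <= params.max_merge_gap
                if cur.direction == nxt.direction and gap_ok:
                    m_ref, u_ref, m_trt, u_trt, n_sites = idx.span_counts(
                        cur.chrom, cur.context, cur.start, nxt.end)
                    lref, ltrt, fold, direction = _levels_and_fold(
                        m_ref, u_ref, m_trt, u_trt, params.pseudocount)
                    if fold >= params.min_fold:
                        p = fisher_exact_two_sided(m_ref, u_ref, m_trt, u_trt)
                        cur = DMR(chrom=cur.chrom, context=cur.context,
                                  start=cur.start, end=nxt.end,
                                  level_ref=lref, level_trt=ltrt,
                                  fold_change=fold, p_value=p,
                                  direction=direction, n_sites=n_sites,
                                  merged_from=cur.merged_from + nxt.merged_from)
                        new.append(cur)
                        i += 2
                        changed = True
                        continue
            new.append(cur)
            i += 1
        run = new
    return run


def call_dmrs(ref_samples: list[MethylomeSample],
              trt_samples: list[MethylomeSample],
              params: DmrParams | None = None,
              contexts: tuple[str, ...] = CONTEXTS) -> list[DMR]:
    """Full DMR calling over the requested contexts; deterministic for fixed inputs.

    Per context: pool replicates, tile eligible sites into windows, Fisher-test
    each window with the twofold gate, then apply the neighbour-joining rule.
    With ``params.fdr`` set, window p-values are Benjamini-Hochberg adjusted
    per context before gating (off by default).
    """
    params = params or DmrParams()
    out: list[DMR] = []
    for context in contexts:
        idx = build_site_index(ref_samples, trt_samples, context, params)
        windows = build_windows(ref_samples, trt_samples, context, params,
                                site_index=idx)
        if params.fdr:
            called = _test_windows_fdr(windows, params)
        else:
            called = [d for w in windows if (d := test_window(w, params))]
        out.extend(merge_adjacent_dmrs(called, idx, params))
    out.sort(key=lambda d: (d.chrom, d.start, d.context))
    return out


def _test_windows_fdr(windows: list[MethylWindow], params: DmrParams) -> list[DMR]:
    from statsmodels.stats.multitest import multipletests

    raw = DmrParams(window_sites=params.window_sites, min_fold=params.min_fold,
                    alpha=1.0, min_depth_per_group=params.min_depth_per_group,
                    pseudocount=params.pseudocount,
                    max_merge_gap=params.max_merge_gap)
    candidates = [(w, test_window(w, raw)) for w in windows]
    candidates = [(w, d) for w, d in candidates if d is not None]
    if not candidates:
        return []
    pvals = [d.p_value for _, d in candidates]
    reject, p_adj, _, _ = multipletests(pvals, alpha=params.alpha, method="fdr_bh")
    return [replace(d, p_value=float(q)) for (w, d), rej, q
            in zip(candidates, reject, p_adj) if rej]


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    cols = ["chrom", "context", "start", "end", "level_ref", "level_trt",
            "fold_change", "p_value", "direction", "n_sites", "merged_from"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dmrs],
                        columns=cols)
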