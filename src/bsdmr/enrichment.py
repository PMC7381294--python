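"""Gene-set over-representation analysis (GO/KEGG style).

For a universe of N annotated genes, a selection of n genes (the DMGs), and
a term annotating M genes of which m are selected, the enrichment p-value is
the hypergeometric upper tail

    p = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n) = P(X >= m),

computed through log-gamma factorials for numerical stability.  Raw p-values
are Bonferroni-corrected by the number of testable terms (M >= 1 in the
universe); terms with corrected p <= 0.05 are called significantly enriched.
A Benjamini-Hochberg mode is available for consumers preferring FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    annotated_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.annotated_genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    N: int        # genes with any annotation (universe)
    n: int        # selected genes within the universe
    M: int        # genes annotated to this term
    m: int        # selected genes annotated to this term
    p_raw: float
    p_adj: float
    significant: bool

    @property
    def rich_factor(self) -> float:
        return self.m / self.M if self.M else float("nan")


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), via log-gamma summation."""
    if not (0 <= M <= N):
        raise ValueError("require 0 <= M <= N")
    if not (0 <= n <= N):
        raise ValueError("require 0 <= n <= N")
    if not (0 <= m <= min(n, M)):
        raise ValueError("require 0 <= m <= min(n, M)")
    if m == 0:
        return 1.0
    hi = min(n, M)
    i = np.arange(m, hi + 1)
    logpmf = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logpmf).sum()))


def enrich(selected_genes: set[str], terms: list[TermAnnotation],
           universe: set[str], method: str = "bonferroni",
           alpha: float = 0.05) -> list[EnrichmentResult]:
    """Over-representation test of ``selected_genes`` against every term.

    Genes outside the universe are dropped (with a logged warning).  Only
    terms with at least one universe gene are tested; the correction budget
    T equals their number.  Results are sorted by raw p (ties by term id)
    and are byte-stable across reruns.
    """
    if not universe:
        raise ValueError("empty gene universe")
    dropped = selected_genes - universe
    if dropped:
        logger.warning("dropping %d selected gene(s) outside the universe", len(dropped))
    selected = selected_genes & universe
    N, n = len(universe), len(selected)

    testable = []
    for t in terms:
        genes = t.annotated_genes & universe
        if genes:
            testable.append((t, genes))
    T = len(testable)
    raw = []
    for t, genes in testable:
        M = len(genes)
        m = len(genes & selected)
        p = hypergeom_upper_tail(N, M, n, m)
        raw.append((t, M, m, p))

    if method == "bonferroni":
        adj = [min(1.0, p * T) for *_, p in raw]
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests
        if raw:
            _, adj, _, _ = multipletests([p for *_, p in raw], method="fdr_bh")
            adj = [float(q) for q in adj]
        else:
            adj = []
    else:
        raise ValueError(f"unknown correction method {method!r}")

    results = [
        EnrichmentResult(term_id=t.term_id, term_name=t.term_name, N=N, n=n,
                         M=M, m=m, p_raw=p, p_adj=q, significant=q <= alpha)
        for (t, M, m, p), q in zip(raw, adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "N", "n", "M", "m", "p_raw", "p_adj",
            "significant"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                      columns=cols)
    df["rich_factor"] = [r.rich_factor for r in results]
    return df
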