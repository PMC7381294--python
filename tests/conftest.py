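"""Shared fixtures and independent oracles for the test suite.

The oracles here (exact-rational Fisher enumeration, integer hypergeometric
tails, brute-force interval intersection) are deliberately written against
the definitions rather than the package code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from bsdmr.io import MethylomeSample, RECORD_COLUMNS
from bsdmr.simulate import (SimulationConfig, PlantedDmr, simulate_annotation,
                            simulate_methylomes)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer enumeration of all same-margin tables."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    nums = [comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = comb(n, r1)
    return float(Fraction(sum(x for x in nums if x <= obs), total))


def hypergeom_tail_oracle(N: int, M: int, n: int, m: int) -> float:
    """Exact P(X >= m) for X ~ Hypergeometric(N, M, n) by integer summation."""
    num = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, min(n, M) + 1))
    return float(Fraction(num, comb(N, n)))


def overlap_1based(s1: int, e1: int, s2: int, e2: int) -> int:
    """Length of the intersection of two 1-based inclusive intervals."""
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def make_sample(rows, sample_id="s", group="reference") -> MethylomeSample:
    """Sample from (chrom, pos, strand, n_meth, n_unmeth, context) tuples."""
    return MethylomeSample(sample_id=sample_id, group=group,
                           records=pd.DataFrame(rows, columns=RECORD_COLUMNS))


# ---------------------------------------------------------------------------
# simulated datasets (session-scoped: several modules reuse them)
# ---------------------------------------------------------------------------

SMALL_SIM = SimulationConfig(
    seed=42, n_chroms=2, chrom_length_bp=300_000, n_genes=20,
    planted_dmrs=tuple(PlantedDmr() for _ in range(10)),
)


@pytest.fixture(scope="session")
def small_dataset():
    """20 genes, 10 planted CG DMRs (0.8 vs 0.2), 3 replicates per group."""
    _, genes = simulate_annotation(SMALL_SIM)
    ref, trt, truth = simulate_methylomes(SMALL_SIM, genes)
    return {"cfg": SMALL_SIM, "genes": genes, "ref": ref, "trt": trt,
            "truth": truth}


@pytest.fixture(scope="session")
def called_dmrs(small_dataset):
    from bsdmr.dmr import DmrParams, call_dmrs
    return call_dmrs(small_dataset["ref"], small_dataset["trt"], DmrParams(),
                     contexts=("CG",))
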