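"""DMR caller: window tiling, Fisher exact test, fold gate, neighbour merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bsdmr.dmr import (DMR, DmrParams, MethylWindow, SiteCountIndex,
                       build_windows, call_dmrs, fisher_exact_two_sided,
                       merge_adjacent_dmrs)
from bsdmr.dmr import test_window as evaluate_window
from conftest import fisher_oracle, make_sample


def _samples_from_counts(chrom, positions, ref_counts, trt_counts, context="CG"):
    """One replicate per group built from per-site (n_meth, n_unmeth) pairs."""
    ref_rows = [(chrom, p, "+", m, u, context)
                for p, (m, u) in zip(positions, ref_counts)]
    trt_rows = [(chrom, p, "+", m, u, context)
                for p, (m, u) in zip(positions, trt_counts)]
    return ([make_sample(ref_rows, "r1", "reference")],
            [make_sample(trt_rows, "t1", "treatment")])


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((5, 5, 5, 5), 1.0),          # balanced
        ((0, 0, 3, 7), 1.0),          # zero row margin: no evidence
        ((2, 8, 8, 2), 0.0230),       # enumerated two-sided p
    ])
    def test_reference_tables(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, abs=1e-4)

    def test_matches_exact_enumeration_small_tables(self):
        for n in range(1, 16):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                    fisher_oracle(a, b, c, d), abs=1e-9)

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 60, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-6)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    @settings(max_examples=150, derandomize=True)
    def test_transposition_symmetry(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(fisher_exact_two_sided(a, c, b, d), abs=1e-12)
        assert p == pytest.approx(fisher_exact_two_sided(c, d, a, b), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestBuildWindows:
    def test_twelve_sites_give_two_windows_with_remainder_discarded(self):
        positions = list(range(100, 1300, 100))
        counts = [(10, 2)] * 12
        ref, trt = _samples_from_counts("chr1", positions, counts, counts)
        wins = build_windows(ref, trt, "CG", DmrParams())
        assert len(wins) == 2
        assert wins[0].site_positions == tuple(positions[:5])
        assert wins[1].site_positions == tuple(positions[5:10])
        assert wins[0].n_meth_ref == 50 and wins[0].n_unmeth_ref == 10

    def test_fewer_sites_than_window_gives_no_window(self):
        positions = [100, 200, 300, 400]
        counts = [(10, 2)] * 4
        ref, trt = _samples_from_counts("chr1", positions, counts, counts)
        assert build_windows(ref, trt, "CG", DmrParams()) == []

    def test_windows_never_span_chromosomes(self):
        counts = [(10, 2)] * 5
        r1, t1 = _samples_from_counts("chr1", range(100, 600, 100), counts, counts)
        r2, t2 = _samples_from_counts("chr2", range(100, 600, 100), counts, counts)
        ref = [make_sample(pd.concat([r1[0].records, r2[0].records]).values.tolist(),
                           "r", "reference")]
        trt = [make_sample(pd.concat([t1[0].records, t2[0].records]).values.tolist(),
                           "t", "treatment")]
        wins = build_windows(ref, trt, "CG", DmrParams())
        assert len(wins) == 2
        assert {w.chrom for w in wins} == {"chr1", "chr2"}

    def test_low_depth_sites_are_ineligible(self):
        positions = list(range(100, 1100, 100))
        ref_counts = [(10, 2)] * 10
        trt_counts = [(1, 1)] * 10   # pooled depth 2 < 4 in treatment
        ref, trt = _samples_from_counts("chr1", positions, ref_counts, trt_counts)
        assert build_windows(ref, trt, "CG", DmrParams()) == []

    def test_empty_group_rejected(self):
        ref, trt = _samples_from_counts("chr1", [100], [(5, 5)], [(5, 5)])
        with pytest.raises(ValueError):
            build_windows([], trt, "CG", DmrParams())


class TestTestWindow:
    def _window(self, mr, ur, mt, ut):
        return MethylWindow("chr1", "CG", (100, 200, 300, 400, 500),
                            mr, ur, mt, ut)

    def test_strong_hypo_window_is_called(self):
        d = evaluate_window(self._window(40, 10, 10, 40))
        assert d is not None
        assert d.direction == "hypo"
        # pseudocounted fold: (40.5/51)/(10.5/51) = 3.857
        assert d.fold_change == pytest.approx(40.5 / 10.5, rel=1e-12)
        assert d.p_value < 1e-6
        assert (d.start, d.end) == (100, 500)

    def test_identical_counts_give_null(self):
        assert evaluate_window(self._window(25, 25, 25, 25)) is None

    def test_fold_passes_but_fisher_fails(self):
        # table (3,2,1,4): pseudocounted fold 2.33 but two-sided p > 0.05
        assert fisher_oracle(3, 2, 1, 4) > 0.05
        assert evaluate_window(self._window(3, 2, 1, 4)) is None

    def test_fold_fails_but_fisher_passes(self):
        # large counts, small level shift: p tiny, fold < 2
        assert evaluate_window(self._window(500, 500, 600, 400)) is None

    def test_hyper_direction(self):
        d = evaluate_window(self._window(10, 40, 40, 10))
        assert d.direction == "hyper"


def _index_from_sites(chrom, context, rows):
    """rows: (pos, m_ref, u_ref, m_trt, u_trt)."""
    tab = pd.DataFrame(rows, columns=["pos", "m_ref", "u_ref", "m_trt", "u_trt"])
    return SiteCountIndex({(chrom, context): tab})


def _dmr(start, end, direction, chrom="chr1", context="CG", p=1e-4):
    lr, lt = (0.8, 0.2) if direction == "hypo" else (0.2, 0.8)
    return DMR(chrom=chrom, context=context, start=start, end=end,
               level_ref=lr, level_trt=lt, fold_change=3.9, p_value=p,
               direction=direction, n_sites=5)


class TestMerge:
    def test_adjacent_dmrs_merge_when_span_fold_holds(self):
        # 10 sites, uniformly ref 8/2 vs trt 2/8: span counts (80,20)/(20,80)
        rows = [(100 * (i + 1), 8, 2, 2, 8) for i in range(10)]
        idx = _index_from_sites("chr1", "CG", rows)
        dmrs = [_dmr(100, 500, "hypo"), _dmr(600, 1000, "hypo")]
        merged = merge_adjacent_dmrs(dmrs, idx, DmrParams())
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end, m.merged_from, m.n_sites) == (100, 1000, 2, 10)
        assert m.fold_change == pytest.approx(80.5 / 20.5, rel=1e-12)

    def test_diluting_span_keeps_dmrs_separate(self):
        # two differential 5-site runs separated by 10 neutral sites that
        # dilute the span fold below 2
        rows = ([(100 * (i + 1), 8, 2, 2, 8) for i in range(5)]
                + [(100 * (i + 6), 5, 5, 5, 5) for i in range(10)]
                + [(100 * (i + 16), 8, 2, 2, 8) for i in range(5)])
        idx = _index_from_sites("chr1", "CG", rows)
        dmrs = [_dmr(100, 500, "hypo"), _dmr(1600, 2000, "hypo")]
        # span counts by hand: ref (130,70) vs trt (70,130), fold 1.85 < 2
        merged = merge_adjacent_dmrs(dmrs, idx, DmrParams())
        assert len(merged) == 2

    def test_opposite_directions_never_merge(self):
        rows = [(100 * (i + 1), 8, 2, 2, 8) for i in range(10)]
        idx = _index_from_sites("chr1", "CG", rows)
        dmrs = [_dmr(100, 500, "hypo"), _dmr(600, 1000, "hyper")]
        assert len(merge_adjacent_dmrs(dmrs, idx, DmrParams())) == 2

    def test_max_merge_gap_blocks_distant_pairs(self):
        rows = [(100 * (i + 1), 8, 2, 2, 8) for i in range(5)] + \
               [(100_000 + 100 * i, 8, 2, 2, 8) for i in range(5)]
        idx = _index_from_sites("chr1", "CG", rows)
        dmrs = [_dmr(100, 500, "hypo"), _dmr(100_000, 100_400, "hypo")]
        assert len(merge_adjacent_dmrs(dmrs, idx,
                                       DmrParams(max_merge_gap=1000))) == 2
        assert len(merge_adjacent_dmrs(dmrs, idx, DmrParams())) == 1

    def test_cascade_merges_to_fixpoint(self):
        rows = [(100 * (i + 1), 8, 2, 2, 8) for i in range(15)]
        idx = _index_from_sites("chr1", "CG", rows)
        dmrs = [_dmr(100, 500, "hypo"), _dmr(600, 1000, "hypo"),
                _dmr(1100, 1500, "hypo")]
        merged = merge_adjacent_dmrs(dmrs, idx, DmrParams())
        assert len(merged) == 1
        assert merged[0].merged_from == 3

    def test_unsorted_input_rejected(self):
        rows = [(100 * (i + 1), 8, 2, 2, 8) for i in range(10)]
        idx = _index_from_sites("chr1", "CG", rows)
        with pytest.raises(ValueError):
            merge_adjacent_dmrs([_dmr(600, 1000, "hypo"),
                                 _dmr(100, 500, "hypo")], idx, DmrParams())

    def test_idempotent_on_random_dmr_lists(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n_sites = 40
            pos = np.sort(rng.choice(100_000, n_sites, replace=False)) + 1
            m_ref = rng.integers(0, 20, n_sites)
            m_trt = rng.integers(0, 20, n_sites)
            rows = [(int(p), int(a), int(20 - a), int(t), int(20 - t))
                    for p, a, t in zip(pos, m_ref, m_trt)]
            idx = _index_from_sites("chr1", "CG", rows)
            dmrs = []
            for i in range(0, n_sites - 4, 5):
                if rng.random() < 0.5:
                    continue
                direction = "hypo" if rng.random() < 0.5 else "hyper"
                dmrs.append(_dmr(int(pos[i]), int(pos[i + 4]), direction))
            once = merge_adjacent_dmrs(dmrs, idx, DmrParams())
            twice = merge_adjacent_dmrs(once, idx, DmrParams())
            assert once == twice


class TestCallDmrs:
    def test_identical_groups_give_no_dmrs(self):
        positions = list(range(100, 2100, 100))
        counts = [(10, 2)] * 20
        ref, trt = _samples_from_counts("chr1", positions, counts, counts)
        assert call_dmrs(ref, trt) == []

    def test_planted_regions_recovered(self, small_dataset, called_dmrs):
        truth = small_dataset["truth"].planted
        hits = sum(
            any(d.chrom == row.chrom and d.start <= row.end and d.end >= row.start
                for d in called_dmrs)
            for row in truth.itertuples())
        assert hits >= 9
        false_calls = sum(
            not any(r.chrom == d.chrom and d.start <= r.end and d.end >= r.start
                    for r in truth.itertuples())
            for d in called_dmrs)
        assert false_calls <= 0.1 * max(1, len(called_dmrs))

    def test_every_output_dmr_satisfies_the_gates(self, called_dmrs):
        params = DmrParams()
        assert called_dmrs  # the planted design must produce calls
        for d in called_dmrs:
            assert d.fold_change >= params.min_fold
            assert d.p_value <= params.alpha
            assert d.start <= d.end
            expected_dir = "hyper" if d.level_trt > d.level_ref else "hypo"
            assert d.direction == expected_dir

    def test_output_sorted_and_nonoverlapping_within_context(self, called_dmrs):
        by_key = {}
        for d in called_dmrs:
            by_key.setdefault((d.chrom, d.context), []).append(d)
        for group in by_key.values():
            for d1, d2 in zip(group[:-1], group[1:]):
                assert d1.start <= d2.start
                assert d1.end < d2.start

    def test_invariant_under_replicate_permutation(self, small_dataset):
        ref, trt = small_dataset["ref"], small_dataset["trt"]
        a = call_dmrs(ref, trt, contexts=("CG",))
        b = call_dmrs(ref[::-1], trt[::-1], contexts=("CG",))
        assert a == b

    def test_null_emission_rate_bounded_by_alpha(self):
        # both groups at level 0.5, depth 20, 3 reps, 2000+ windows
        rng = np.random.default_rng(13)
        n_sites = 10_000
        positions = np.arange(1, n_sites + 1) * 50
        ref, trt = [], []
        for group, lst in (("reference", ref), ("treatment", trt)):
            for r in range(3):
                depth = rng.poisson(20, n_sites)
                meth = rng.binomial(depth, 0.5)
                rows = pd.DataFrame({
                    "chrom": "chr1", "pos": positions, "strand": "+",
                    "n_meth": meth, "n_unmeth": depth - meth, "context": "CG"})
                lst.append(make_sample(rows.values.tolist(), f"{group}{r}", group))
        params = DmrParams()
        wins = build_windows(ref, trt, "CG", params)
        assert len(wins) >= 2000
        emitted = sum(evaluate_window(w, params) is not None for w in wins)
        assert emitted / len(wins) <= 0.05
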