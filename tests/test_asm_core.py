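"""ASM pair statistics, FDR adjustment, classification and chaining."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methhap.asm_core import (
    AsmBlock,
    AsmParams,
    CytosineSite,
    FragmentIndex,
    PairCounts,
    adjust_fdr,
    classify_pair,
    count_pair,
    extend_blocks,
    pair_pvalue,
    select_effective_sites,
    summarize_sites,
)
from methhap.io_bisulfite import MethFragment


def frag(calls, chrom="chr1", strand="+", fid=None, snps=()):
    return MethFragment(
        fragment_id=fid or f"f{id(calls)}",
        chrom=chrom, strand=strand,
        meth_calls=tuple(calls), snp_calls=tuple(snps),
    )


def table(a, b, c, d, p_adj=None):
    si = CytosineSite("chr1", 10, "+", "CpG", 0, 0)
    sj = CytosineSite("chr1", 20, "+", "CpG", 0, 0)
    return PairCounts(site_i=si, site_j=sj, n11=a, n12=b, n21=c, n22=d,
                      p_adj=p_adj)


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher: enumerate all tables at fixed margins
    and sum exact rational point probabilities <= the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def point(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if point(x) <= p_obs:
            total += point(x)
    return float(total)


def bh_oracle(pvals):
    """Naive BH step-up: q_(i) = min_{k>=i} p_(k) * m / k, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestSummarizeAndFilter:
    def test_tallies_and_levels(self):
        frags = [frag([(10, "M"), (20, "M")]), frag([(10, "M"), (20, "U")]),
                 frag([(10, "M")])]
        sites = summarize_sites(frags)
        by_pos = {s.pos: s for s in sites}
        assert by_pos[10].n_meth == 3 and by_pos[10].level == 1.0
        assert by_pos[20].level == 0.5
        assert set(by_pos) == {10, 20}  # uncovered positions absent

    def test_effective_site_rules(self):
        mk = lambda m, u: CytosineSite("chr1", 1, "+", "CpG", m, u)
        # level 0.95 -> totally methylated, removed; 0.05 -> removed;
        # level 0.5 at coverage 3 -> below the n=4 coverage gate
        assert select_effective_sites([mk(19, 1)]) == []
        assert select_effective_sites([mk(1, 19)]) == []
        assert select_effective_sites([mk(2, 1)], min_cov=4) == []
        kept = select_effective_sites([mk(5, 5)])
        assert len(kept) == 1

    def test_boundary_levels_inclusive(self):
        mk = lambda m, u: CytosineSite("chr1", 1, "+", "CpG", m, u)
        assert len(select_effective_sites([mk(9, 1)])) == 1   # level == 0.9
        assert len(select_effective_sites([mk(1, 9)])) == 1   # level == 0.1

    def test_bad_configuration_rejected(self):
        with pytest.raises(ValueError):
            select_effective_sites([], low=0.9, high=0.1)
        with pytest.raises(ValueError):
            select_effective_sites([], min_cov=0)


class TestCountPair:
    def test_direct_tally(self):
        frags = (
            [frag([(10, "M"), (20, "M")], fid=f"a{i}") for i in range(5)]
            + [frag([(10, "U"), (20, "U")], fid=f"b{i}") for i in range(5)]
        )
        pc = count_pair(frags, 10, 20)
        assert pc.counts == (5, 0, 0, 5)
        assert pc.total == 10

    def test_single_site_fragment_excluded(self):
        frags = [frag([(10, "M"), (20, "U")]), frag([(10, "M")])]
        assert count_pair(frags, 10, 20).counts == (0, 1, 0, 0)

    def test_position_order_enforced(self):
        with pytest.raises(ValueError):
            count_pair([], 20, 10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("MU_"), st.sampled_from("MU_")),
                    min_size=1, max_size=30))
    def test_matches_naive_per_fragment_tally(self, statuses):
        frags = []
        for i, (s1, s2) in enumerate(statuses):
            calls = [(10, s1)] if s1 != "_" else []
            calls += [(20, s2)] if s2 != "_" else []
            frags.append(frag(calls, fid=f"f{i}"))
        pc = count_pair(frags, 10, 20)
        expect = [0, 0, 0, 0]
        for s1, s2 in statuses:
            if s1 != "_" and s2 != "_":
                expect[(0 if s1 == "M" else 2) + (0 if s2 == "M" else 1)] += 1
        assert list(pc.counts) == expect
        # conservation: cells sum to fragments covering both sites
        assert pc.total == sum(1 for s1, s2 in statuses if "_" not in (s1, s2))
        # index-backed tally agrees with the naive scan
        idx = FragmentIndex(frags)
        assert idx.pair_table(pc.site_i, pc.site_j).counts == pc.counts


class TestPairPvalue:
    @pytest.mark.parametrize("cells,expected", [
        ((5, 0, 0, 5), 2 / 252),   # only the two extreme tables qualify
        ((2, 2, 2, 2), 1.0),       # observed table is the mode
        ((7, 0, 3, 0), 1.0),       # all-zero column: single possible table
        ((0, 0, 4, 9), 1.0),       # all-zero row
    ])
    def test_frozen_examples(self, cells, expected):
        assert pair_pvalue(table(*cells)) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pair_pvalue(table(0, 0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert pair_pvalue(table(a, b, c, d)) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_fisher(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            ours = pair_pvalue(table(int(a), int(b), int(c), int(d)))
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)


class TestAdjustFdr:
    def test_hand_worked_stepup(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert adjust_fdr([0.3]) == [pytest.approx(0.3)]

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            adjust_fdr([])
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80))
    def test_matches_naive_oracle_and_invariants(self, pvals):
        adj = adjust_fdr(pvals)
        assert adj == pytest.approx(bh_oracle(pvals), abs=1e-12)
        assert all(q >= p - 1e-12 for p, q in zip(pvals, adj))
        assert all(q <= 1.0 + 1e-12 for q in adj)

    def test_order_preserving_under_permutation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25).tolist()
        adj = adjust_fdr(p)
        perm = rng.permutation(25)
        adj_perm = adjust_fdr([p[i] for i in perm])
        assert [adj[i] for i in perm] == pytest.approx(adj_perm)


class TestClassifyPair:
    def test_balanced_diagonal_is_asm(self):
        assert classify_pair(table(10, 0, 0, 10, p_adj=1e-4)) is True

    def test_ratio_criterion_rejects(self):
        # 18/1 = 18 >= 2: the two patterns are not balanced
        assert classify_pair(table(18, 1, 1, 0, p_adj=0.01)) is False

    def test_top2_criterion_rejects(self):
        # top2 = 15/20 = 75% <= 90%
        assert classify_pair(table(9, 6, 3, 2, p_adj=0.01)) is False

    def test_pvalue_criterion_rejects(self):
        assert classify_pair(table(10, 0, 0, 10, p_adj=0.2)) is False

    def test_single_pattern_is_concordant_not_asm(self):
        # second max 0 -> ratio infinite: fully concordant, no ASM
        assert classify_pair(table(20, 0, 0, 0, p_adj=1e-6)) is False

    def test_threshold_ties_fail(self):
        # exactly 90% top-2 mass and exactly ratio 2 both fail (strict)
        assert classify_pair(table(9, 9, 1, 1, p_adj=1e-4)) is False
        assert classify_pair(table(12, 6, 1, 1, p_adj=1e-4),
                             top2_frac=0.8) is False

    def test_requires_adjusted_p(self):
        with pytest.raises(ValueError):
            classify_pair(table(5, 0, 0, 5))


class TestExtendBlocks:
    def _asm_frags(self, positions, n=10, fid_prefix="f"):
        """Fragments from two alleles: allele A all-M, allele B all-U."""
        out = []
        for i in range(n):
            out.append(frag([(p, "M") for p in positions], fid=f"{fid_prefix}A{i}"))
            out.append(frag([(p, "U") for p in positions], fid=f"{fid_prefix}B{i}"))
        return out

    def test_chain_breaks_at_rejected_pair(self):
        # s1..s3 allele-specific; s4..s5 allele-specific; but the s3-s4
        # link is concordant (everyone M at s4? no: make s3-s4 random)
        rng = np.random.default_rng(0)
        frags = []
        for i in range(12):
            # site 40's state is independent of the allele of origin
            coin = ["M" if rng.random() < 0.5 else "U" for _ in range(2)]
            frags.append(frag(
                [(10, "M"), (20, "M"), (30, "M"), (40, coin[0]),
                 (50, "M"), (60, "M")], fid=f"A{i}"))
            frags.append(frag(
                [(10, "U"), (20, "U"), (30, "U"), (40, coin[1]),
                 (50, "U"), (60, "U")], fid=f"B{i}"))
        sites = summarize_sites(frags)
        eff = select_effective_sites(sites)
        blocks = extend_blocks(eff, frags)
        spans = [(b.start, b.end) for b in blocks]
        # 40 joins neither side: its state is independent of allele
        assert (10, 30) in spans and (50, 60) in spans

    def test_no_accepted_pairs_no_blocks(self):
        frags = [frag([(10, "M"), (20, "M")], fid=f"x{i}") for i in range(10)]
        sites = summarize_sites(frags)
        blocks = extend_blocks(select_effective_sites(sites), frags)
        assert blocks == []

    def test_clean_asm_region_single_block(self):
        positions = list(range(100, 400, 20))
        frags = self._asm_frags(positions, n=10)
        sites = summarize_sites(frags)
        eff = select_effective_sites(sites)
        assert len(eff) == len(positions)
        blocks = extend_blocks(eff, frags)
        assert len(blocks) == 1
        assert blocks[0].sites == tuple(positions)
        assert blocks[0].n_cytosines == len(positions)

    def test_blocks_disjoint_and_pairs_accepted(self, noiseless_dataset):
        res = noiseless_dataset["results"]["asm"]
        by_group = {}
        for b in res.blocks:
            by_group.setdefault((b.chrom, b.strand), []).append(b)
        for blocks in by_group.values():
            blocks.sort(key=lambda b: b.start)
            for b1, b2 in zip(blocks, blocks[1:]):
                assert b1.end < b2.start  # non-overlapping
        for b in res.blocks:
            assert b.n_cytosines >= 2
            for pc in b.pairs:
                assert classify_pair(pc) is True
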