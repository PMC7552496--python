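"""HapScore consistency scoring and WGBS/Hi-C block merging."""

import pytest
from hypothesis import given, settings, strategies as st

from methhap.io_bisulfite import HetSNP
from methhap.hic_merge import hapscore, merge_blocks, score_overlap, site_scores
from methhap.snp_phase import PhaseVector


def pv(phases, start=100, step=100, source="WGBS", chrom="chr1"):
    entries = [
        (HetSNP(chrom, start + i * step, "A", "T"), p)
        for i, p in enumerate(phases)
    ]
    return PhaseVector(source=source, entries=entries)


class TestSiteScores:
    def test_identical_vectors(self):
        assert site_scores(pv([0, 1, 0, 1]), pv([0, 1, 0, 1])) == [1, 1, 1, 1]

    def test_globally_flipped_vectors(self):
        assert site_scores(pv([0, 1, 0, 1]), pv([1, 0, 1, 0])) == [-1, -1, -1, -1]

    def test_missing_scores_zero(self):
        assert site_scores(pv([0, 1, 0]), pv([0, None, 1])) == [1, 0, -1]

    def test_weight_k(self):
        assert site_scores(pv([0, 1]), pv([0, 0]), k=3) == [3, -3]

    def test_disjoint_vectors_empty(self):
        assert site_scores(pv([0, 1]), pv([0, 1], start=10_000)) == []

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            site_scores(pv([0]), pv([0]), k=0)


class TestHapScore:
    @pytest.mark.parametrize("scores,hs", [
        ([1, 1, 1, 1], 4),
        ([1, 1, -1, -1], 0),
        ([-1, -1, -1], 3),
        ([], 0),
    ])
    def test_absolute_sum(self, scores, hs):
        assert hapscore(scores) == hs

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from([0, 1, None]), min_size=1, max_size=20),
           st.lists(st.sampled_from([0, 1, None]), min_size=1, max_size=20))
    def test_flip_invariance_and_bounds(self, b_phases, h_phases):
        n = min(len(b_phases), len(h_phases))
        b, h = pv(b_phases[:n]), pv(h_phases[:n])
        hs = hapscore(site_scores(b, h))
        flipped_h = pv([None if p is None else 1 - p for p in h_phases[:n]])
        flipped_b = pv([None if p is None else 1 - p for p in b_phases[:n]])
        assert hapscore(site_scores(b, flipped_h)) == hs
        assert hapscore(site_scores(flipped_b, h)) == hs
        assert 0 <= hs <= n
        both_called = sum(
            1 for pb, ph in zip(b_phases[:n], h_phases[:n])
            if pb is not None and ph is not None
        )
        # hs attains k*n iff every co-called site agrees in one orientation
        if hs == n:
            assert both_called == n


class TestMergeBlocks:
    def test_hic_chains_two_wgbs_blocks(self):
        w1 = (None, pv([0, 1, 0], start=100, step=50))
        w2 = (None, pv([1, 1, 0], start=10_000, step=50))
        hic_phases = [0, 1, 0, 1, 1, 0]
        positions = [100, 150, 200, 10_000, 10_050, 10_100]
        h = (None, PhaseVector(source="HiC", entries=[
            (HetSNP("chr1", p, "A", "T"), ph)
            for p, ph in zip(positions, hic_phases)
        ]))
        merged = merge_blocks([w1, w2], [h])
        assert len(merged) == 1
        phases = {s.pos: p for s, p in merged[0][1].entries}
        assert phases == {100: 0, 150: 1, 200: 0,
                          10_000: 1, 10_050: 1, 10_100: 0}

    def test_flip_invariance_of_merge(self):
        w1 = (None, pv([0, 1, 0], start=100, step=50))
        w2 = (None, pv([1, 1, 0], start=10_000, step=50))
        positions = [100, 150, 200, 10_000, 10_050, 10_100]
        phases = [0, 1, 0, 1, 1, 0]
        mk = lambda ps: (None, PhaseVector(source="HiC", entries=[
            (HetSNP("chr1", p, "A", "T"), q) for p, q in zip(positions, ps)]))
        m1 = merge_blocks([w1, w2], [mk(phases)])
        m2 = merge_blocks([w1, w2], [mk([1 - p for p in phases])])
        assert [[(s.pos, p) for s, p in pvv.entries] for _b, pvv in m1] == \
               [[(s.pos, p) for s, p in pvv.entries] for _b, pvv in m2]

    def test_zero_hapscore_overlap_never_merges(self):
        w = (None, pv([0, 1], start=100, step=50))
        h = (None, PhaseVector(source="HiC", entries=[
            (HetSNP("chr1", 100, "A", "T"), 0),
            (HetSNP("chr1", 150, "A", "T"), 0),  # one agree, one disagree
        ]))
        assert score_overlap(w, h).hs == 0
        merged = merge_blocks([w], [h])
        assert len(merged) == 1
        assert merged[0][1].source == "WGBS"

    def test_below_min_shared_never_merges(self):
        w = (None, pv([0, 1], start=100, step=50))
        h = (None, PhaseVector(source="HiC", entries=[
            (HetSNP("chr1", 100, "A", "T"), 0),
            (HetSNP("chr1", 9_999, "A", "T"), 0),
        ]))
        merged = merge_blocks([w], [h], min_shared=2)
        assert all(m[1].source == "WGBS" for m in merged)

    def test_merge_order_independence(self):
        w1 = (None, pv([0, 1, 0], start=100, step=50))
        w2 = (None, pv([1, 1], start=10_000, step=50))
        w3 = (None, pv([0, 0], start=20_000, step=50))
        entries = []
        for blockpv in (w1[1], w2[1], w3[1]):
            entries.extend((s, p) for s, p in blockpv.entries)
        h = (None, PhaseVector(source="HiC", entries=entries))
        ref = merge_blocks([w1, w2, w3], [h])
        for perm in ([w3, w1, w2], [w2, w3, w1]):
            got = merge_blocks(perm, [h])
            assert [[(s.pos, p) for s, p in pvv.entries] for _b, pvv in got] \
                == [[(s.pos, p) for s, p in pvv.entries] for _b, pvv in ref]

    def test_orientation_conflict_aborts_component(self):
        w1 = (None, pv([0, 0], start=100, step=50))
        w2 = (None, pv([0, 0], start=10_000, step=50))
        agree = [0, 0, 0, 0]
        positions = [100, 150, 10_000, 10_050]
        mk = lambda ps, src: (None, PhaseVector(source=src, entries=[
            (HetSNP("chr1", p, "A", "T"), q) for p, q in zip(positions, ps)]))
        h1 = mk(agree, "HiC")              # consistent with both as-is
        h2 = mk([0, 0, 1, 1], "HiC")       # consistent only if w2 flips
        with pytest.warns(UserWarning, match="orientation conflict"):
            merged = merge_blocks([w1, w2], [h1, h2])
        assert sorted(pvv.source for _b, pvv in merged) == ["WGBS", "WGBS"]

    def test_merging_is_monotone_in_phased_snps_and_span(self, noiseless_dataset):
        res = noiseless_dataset["results"]["asm+snp"]
        from methhap.hic_merge import read_phased_blocks
        wgbs = [(b, b.phase) for b in res.blocks if b.phase and b.phase.phased]
        hic = read_phased_blocks(noiseless_dataset["paths"]["hic_blocks"])

        def n_phased(items):
            return sum(len(pvv.phased) for _b, pvv in items)

        def span(items):
            total = 0
            for _b, pvv in items:
                pos = [s.pos for s, p in pvv.entries if p is not None]
                if len(pos) > 1:
                    total += max(pos) - min(pos) + 1
            return total

        merged = merge_blocks(wgbs, hic)
        assert n_phased(merged) >= n_phased(wgbs)
        assert span(merged) >= span(wgbs)
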