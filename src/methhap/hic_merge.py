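"""Merging WGBS-phased blocks with Hi-C-phased blocks.

Hi-C read pairs link heterozygous SNPs over distances far beyond any
bisulfite fragment, so Hi-C-derived haplotype blocks (e.g. from HapCUT2)
can bridge WGBS methylation blocks into much longer haplotypes. Because
the haplotype-A labelling of each source is arbitrary, the two sets are
reconciled with a consistency score: over the SNPs shared by a WGBS
block B and a Hi-C block H, each site contributes

    S_i = +k  if B_i == H_i,   -k  if B_i == flipped H_i,   0 otherwise
          (either phase missing)

and the block-level HapScore is H_s = |sum_i S_i|, with 0 <= H_s <= k*n.
A pair of blocks merges only when H_s exceeds a threshold fraction of
its maximum (default 0.9 * k * n); the sign of the sum decides whether
the Hi-C phases must be flipped. One Hi-C block can chain several WGBS
blocks; chaining is resolved transitively with consistent orientation,
and orientation conflicts leave the blocks unmerged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from methhap.io_bisulfite import HetSNP
from methhap.snp_phase import PhaseVector

Key = tuple[str, int]  # (chrom, pos)


@dataclass
class ScoredOverlap:
    """Consistency scoring of one WGBS block against one Hi-C block."""

    wgbs_block: object
    hic_block: object
    shared_snps: list[Key]
    scores: list[int]
    k: int
    hs: int
    orientation: str  # 'same' | 'flipped' | 'undecided'


def read_phased_blocks(path) -> list[tuple[None, PhaseVector]]:
    """Parse a HapCUT2-style phased block file.

    Each block is a ``BLOCK:`` header followed by per-SNP lines
    ``index hap0 hap1 chrom pos ref alt [...]`` and a ``********``
    terminator. ``-`` in the haplotype columns means unphased and is
    preserved as a missing entry. Extra trailing columns (genotype,
    quality) are ignored.
    """
    blocks: list[tuple[None, PhaseVector]] = []
    entries: list[tuple[HetSNP, int | None]] = []
    in_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("BLOCK:"):
                if entries:
                    blocks.append((None, PhaseVector(source="HiC", entries=entries)))
                entries = []
                in_block = True
                continue
            if line.startswith("****"):
                if entries:
                    blocks.append((None, PhaseVector(source="HiC", entries=entries)))
                entries = []
                in_block = False
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
            _, h0, _h1, chrom, pos, ref, alt = fields[:7]
            if not in_block:
                raise ValueError(f"{path}:{lineno}: SNP line outside a BLOCK")
            snp = HetSNP(chrom=chrom, pos=int(pos), ref_allele=ref, alt_allele=alt)
            phase = None if h0 == "-" else int(h0)
            if phase not in (0, 1, None):
                raise ValueError(f"{path}:{lineno}: bad haplotype value {h0!r}")
            entries.append((snp, phase))
    if entries:
        blocks.append((None, PhaseVector(source="HiC", entries=entries)))
    return blocks


def _phase_map(pv: PhaseVector) -> dict[Key, int | None]:
    return {(s.chrom, s.pos): p for s, p in pv.entries}


def site_scores(b: PhaseVector, h: PhaseVector, k: int = 1) -> list[int]:
    """Per-shared-SNP consistency scores between two phase vectors.

    +k where the phases agree, -k where one equals the other flipped,
    0 where either is missing. Shared SNPs are those present in both
    vectors, in ascending position order.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    bm, hm = _phase_map(b), _phase_map(h)
    scores = []
    for key in sorted(set(bm) & set(hm)):
        pb, ph = bm[key], hm[key]
        if pb is None or ph is None:
            scores.append(0)
        elif pb == ph:
            scores.append(k)
        else:
            scores.append(-k)
    return scores


def hapscore(scores: Sequence[int]) -> int:
    """HapScore H_s: absolute value of the summed site scores."""
    return abs(sum(scores))


def score_overlap(wgbs, hic, k: int = 1) -> ScoredOverlap:
    """Score one (WGBS block, Hi-C block) pair and decide orientation."""
    wb, wpv = wgbs
    hb, hpv = hic
    bm, hm = _phase_map(wpv), _phase_map(hpv)
    shared = sorted(set(bm) & set(hm))
    scores = site_scores(wpv, hpv, k=k) if shared else []
    total = sum(scores)
    orientation = "same" if total > 0 else "flipped" if total < 0 else "undecided"
    return ScoredOverlap(
        wgbs_block=wb, hic_block=hb, shared_snps=shared, scores=scores,
        k=k, hs=abs(total), orientation=orientation,
    )


class _ParityUnionFind:
    """Union-find tracking relative orientation (flip parity) to the root."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.parity: dict[int, int] = {}

    def find(self, x: int) -> tuple[int, int]:
        self.parent.setdefault(x, x)
        self.parity.setdefault(x, 0)
        if self.parent[x] == x:
            return x, 0
        root, par = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= par
        return root, self.parity[x]

    def union(self, a: int, b: int, rel: int) -> bool:
        """Join a and b with relative parity ``rel``; False on conflict."""
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return (pa ^ pb) == rel
        self.parent[max(ra, rb)] = min(ra, rb)
        self.parity[max(ra, rb)] = pa ^ pb ^ rel
        return True


def _flip(pv_entries, flip: int):
    return [(s, p if p is None or not flip else 1 - p) for s, p in pv_entries]


def merge_blocks(
    wgbs: Sequence[tuple[object, PhaseVector]],
    hic: Sequence[tuple[object, PhaseVector]],
    k: int = 1,
    min_score_frac: float = 0.9,
    min_shared: int = 2,
    include_unmerged_hic: bool = False,
) -> list[tuple[object, PhaseVector]]:
    """Merge WGBS-phased blocks with Hi-C-phased blocks by HapScore.

    A (WGBS, Hi-C) pair qualifies when it shares at least ``min_shared``
    SNPs and its HapScore strictly exceeds ``min_score_frac * k * n``
    (n = shared SNPs). Qualified links orient the Hi-C phases (flipping
    when the score sum is negative) and merge the union of phased SNPs,
    with the WGBS assignment winning on shared sites. A Hi-C block
    chaining several WGBS blocks merges them transitively; an
    orientation-parity conflict leaves that component unmerged (with a
    warning). Undecided orientations never merge. Unmerged WGBS blocks
    pass through unchanged; unmerged Hi-C blocks are appended only when
    ``include_unmerged_hic`` is set.

    The result is sorted by (chrom, first phased position) and is
    independent of input order.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")

    def sort_key(item):
        _, pv = item
        if not pv.entries:
            return ("", 0)
        return (pv.entries[0][0].chrom, pv.entries[0][0].pos)

    wgbs = sorted(wgbs, key=sort_key)
    hic = sorted(hic, key=sort_key)

    # Qualified links: (wgbs idx, hic idx, flip-to-align-hic-to-wgbs).
    links: list[tuple[int, int, int]] = []
    for wi, w in enumerate(wgbs):
        for hi, h in enumerate(hic):
            ov = score_overlap(w, h, k=k)
            n = len(ov.shared_snps)
            if n < min_shared or ov.orientation == "undecided":
                continue
            if ov.hs > min_score_frac * k * n:
                links.append((wi, hi, 0 if ov.orientation == "same" else 1))

    # Transitive closure over WGBS blocks with orientation parity.
    uf = _ParityUnionFind()
    hic_anchor: dict[int, tuple[int, int]] = {}  # hic idx -> (wgbs idx, flip)
    conflict_nodes: set[int] = set()
    for wi, hi, flip in links:
        if hi not in hic_anchor:
            hic_anchor[hi] = (wi, flip)
            uf.find(wi)
        else:
            w0, f0 = hic_anchor[hi]
            # wi and w0 see the same hic block: relative parity f0 ^ flip
            if not uf.union(w0, wi, f0 ^ flip):
                conflict_nodes.add(wi)

    conflicted_roots = {uf.find(x)[0] for x in conflict_nodes}
    components: dict[int, list[int]] = {}
    for wi, _, _ in links:
        root, _ = uf.find(wi)
        components.setdefault(root, []).append(wi)

    merged_out: list[tuple[object, PhaseVector]] = []
    used_w: set[int] = set()
    used_h: set[int] = set()
    # every SNP a WGBS block carries, merged or not: Hi-C may not re-emit
    # one of these in another block (no SNP appears in two output blocks)
    wgbs_claimed: set[Key] = {
        (s.chrom, s.pos) for _b, pvv in wgbs for s, _p in pvv.entries
    }
    for root in sorted(components):
        members = sorted(set(components[root]))
        if root in conflicted_roots:
            warnings.warn(
                f"orientation conflict while chaining {len(members)} WGBS "
                "blocks via Hi-C; leaving them unmerged",
                stacklevel=2,
            )
            continue
        entries: dict[Key, tuple[HetSNP, int | None]] = {}
        for wi in members:
            _, par = uf.find(wi)
            for s, p in _flip(wgbs[wi][1].entries, par):
                entries[(s.chrom, s.pos)] = (s, p)  # WGBS wins by being first
            used_w.add(wi)
        hic_votes: dict[Key, list[tuple[HetSNP, int]]] = {}
        for wi, hi, flip in links:
            if wi not in members:
                continue
            _, par = uf.find(wi)
            for s, p in _flip(hic[hi][1].entries, flip ^ par):
                key = (s.chrom, s.pos)
                if p is not None and key not in entries and key not in wgbs_claimed:
                    hic_votes.setdefault(key, []).append((s, p))
            used_h.add(hi)
        for key, votes in hic_votes.items():
            phases = {p for _, p in votes}
            # conflicting Hi-C assignments from different blocks -> missing
            entries[key] = (votes[0][0], votes[0][1] if len(phases) == 1 else None)
        ordered = [entries[key] for key in sorted(entries)]
        merged_out.append((None, PhaseVector(source="merged", entries=ordered)))

    for wi, w in enumerate(wgbs):
        if wi not in used_w:
            merged_out.append(w)
    if include_unmerged_hic:
        for hi, h in enumerate(hic):
            if hi not in used_h:
                merged_out.append(h)
    merged_out.sort(key=sort_key)
    return merged_out
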