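"""Integrating heterozygous SNPs into methylation haplotype blocks.

A heterozygous SNP covered by the same fragments as an ASM cytosine
shows the same diagonal 2x2 structure — one allele travels with the
methylated pattern — so SNP sites enter the pair-testing and chaining
machinery exactly like cytosine sites. Within each block, haplotype A is
anchored at the block's first member site (methylated pattern M for a
cytosine, reference allele R for a SNP); phase 0 then means the
reference allele rides on haplotype A.

Blocks can be built from SNPs alone (read-backed SNP phasing, the
baseline), from cytosines alone, or from both. Adding methylation
evidence links SNPs that no read pair of SNPs could join, which is what
lengthens blocks and raises the phased fraction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from methhap.io_bisulfite import HetSNP, MethFragment
from methhap.asm_core import (
    AsmBlock,
    AsmParams,
    CytosineSite,
    FragmentIndex,
    PairCounts,
    apply_tests,
    candidate_pairs,
    chain_blocks,
    select_effective_sites,
    summarize_sites,
)

MODES = ("snp", "asm", "asm+snp")


@dataclass
class PhaseVector:
    """Per-SNP phase assignments for one block from one evidence source.

    ``entries`` pairs each HetSNP with a phase: 0 = reference allele on
    haplotype A, 1 = alternate allele on haplotype A, None = missing.
    ``source`` records the evidence ('WGBS' or 'HiC').
    """

    source: str
    entries: list[tuple[HetSNP, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [s.pos for s, _ in self.entries]
        if positions != sorted(positions):
            raise ValueError("phase entries must be sorted by position")
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate SNP in phase vector")

    @property
    def phased(self) -> list[tuple[HetSNP, int]]:
        return [(s, p) for s, p in self.entries if p is not None]

    def phase_of(self, chrom: str, pos: int) -> int | None:
        for s, p in self.entries:
            if s.chrom == chrom and s.pos == pos:
                return p
        return None


def count_meth_snp_pair(
    fragments: Sequence[MethFragment],
    cyt_pos: int,
    snp: HetSNP,
) -> PairCounts:
    """2x2 table crossing methylation at ``cyt_pos`` with the SNP allele.

    Cells are N(M,R), N(M,V), N(U,R), N(U,V) over fragments carrying
    both a methylation call at ``cyt_pos`` and an allele call at the
    SNP. A zero-total table signals that no fragment carried both calls
    — e.g. a conversion-confounded SNP whose allele calls were all
    suppressed.
    """
    cells = [0, 0, 0, 0]
    chrom = strand = None
    for frag in fragments:
        meth = dict(frag.meth_calls).get(cyt_pos)
        allele = dict(frag.snp_calls).get(snp.pos)
        if meth is None or allele is None:
            continue
        chrom, strand = frag.chrom, frag.strand
        cells[(0 if meth == "M" else 2) + (0 if allele == "R" else 1)] += 1
    cyt = CytosineSite(chrom or snp.chrom, cyt_pos, strand or "+", "CpG", 0, 0)
    if cyt_pos < snp.pos:
        return PairCounts(site_i=cyt, site_j=snp,
                          n11=cells[0], n12=cells[1], n21=cells[2], n22=cells[3])
    # keep site_i left of site_j: transpose the table
    return PairCounts(site_i=snp, site_j=cyt,
                      n11=cells[0], n12=cells[2], n21=cells[1], n22=cells[3])


def _propagate_phase(block: AsmBlock) -> dict[int, int | None]:
    """Haplotype-A status (0/1) per member position by BFS over pairs.

    The anchor is the block's first member site, assigned status 0
    (methylated pattern, or reference allele for a SNP). Each accepted
    pair with a decided relation propagates: 'same' preserves status,
    'cross' flips it. Pairs whose table ties between the two diagonals
    carry membership but no phase information.
    """
    edges: dict[int, list[tuple[int, int]]] = {p: [] for p in block.sites}
    for pc in block.pairs:
        rel = pc.relation
        if rel is None:
            continue
        flip = 0 if rel == "same" else 1
        edges[pc.site_i.pos].append((pc.site_j.pos, flip))
        edges[pc.site_j.pos].append((pc.site_i.pos, flip))
    status: dict[int, int | None] = {p: None for p in block.sites}
    anchor = block.sites[0]
    status[anchor] = 0
    queue = deque([anchor])
    while queue:
        u = queue.popleft()
        for v, flip in sorted(edges[u]):
            if status[v] is None:
                status[v] = status[u] ^ flip
                queue.append(v)
    return status


def phase_snps(
    block: AsmBlock,
    het_snps: Iterable[HetSNP],
    source: str = "WGBS",
) -> PhaseVector:
    """Assign each member SNP of a block to a methylation haplotype.

    The phase follows from haplotype-A status propagation along the
    block's accepted pairs; when a SNP is reached by several
    informative pairs (cycles in the evidence), each contributes a vote
    and conflicts resolve by majority, with ties left missing.
    """
    status = _propagate_phase(block)
    snp_lookup = {(s.chrom, s.pos): s for s in het_snps}
    entries: list[tuple[HetSNP, int | None]] = []
    for pos, kind in zip(block.sites, block.site_kinds):
        if kind != "snp":
            continue
        snp = snp_lookup.get((block.chrom, pos))
        if snp is None:
            continue
        votes: list[int] = []
        for pc in block.pairs:
            rel = pc.relation
            if rel is None:
                continue
            flip = 0 if rel == "same" else 1
            if pc.site_i.pos == pos:
                other = pc.site_j.pos
            elif pc.site_j.pos == pos:
                other = pc.site_i.pos
            else:
                continue
            if status[other] is not None:
                votes.append(status[other] ^ flip)
        ones = sum(votes)
        if not votes or ones * 2 == len(votes):  # no evidence, or tie
            phase: int | None = None
        else:
            phase = 1 if ones * 2 > len(votes) else 0
        entries.append((snp, phase))
    return PhaseVector(source=source, entries=entries)


def phased_fraction(
    phase_vectors: Iterable[PhaseVector],
    het_snps: Sequence[HetSNP],
) -> float:
    """Fraction of input heterozygous SNPs with a non-missing phase."""
    if not het_snps:
        raise ValueError("no heterozygous SNPs supplied")
    phased: set[tuple[str, int]] = set()
    for pv in phase_vectors:
        for snp, ph in pv.entries:
            if ph is not None:
                phased.add((snp.chrom, snp.pos))
    return len(phased) / len(het_snps)


@dataclass
class PipelineResult:
    """Outcome of one WGBS haplotype-calling run."""

    mode: str
    params: AsmParams
    blocks: list[AsmBlock]
    n_effective_sites: int
    n_tested_pairs: int
    n_asm_pairs: int
    het_snps: list[HetSNP]

    @property
    def phase_vectors(self) -> list[PhaseVector]:
        return [b.phase for b in self.blocks if b.phase is not None]

    @property
    def accepted_pairs(self) -> list[PairCounts]:
        return [pc for b in self.blocks for pc in b.pairs]

    @property
    def total_span(self) -> int:
        return sum(b.end - b.start + 1 for b in self.blocks)

    @property
    def n_phased_snps(self) -> int:
        phased = {
            (s.chrom, s.pos)
            for pv in self.phase_vectors
            for s, p in pv.entries
            if p is not None
        }
        return len(phased)

    def phased_fraction(self) -> float:
        if not self.het_snps:
            return 0.0
        return self.n_phased_snps / len(self.het_snps)

    def summary(self) -> dict[str, object]:
        return {
            "mode": self.mode,
            "n_effective_sites": self.n_effective_sites,
            "n_tested_pairs": self.n_tested_pairs,
            "n_asm_pairs": self.n_asm_pairs,
            "n_blocks": len(self.blocks),
            "total_span": self.total_span,
            "n_het_snps": len(self.het_snps),
            "n_phased_snps": self.n_phased_snps,
            "phased_fraction": round(self.phased_fraction(), 6),
        }


def _group_fragments(
    fragments: Iterable[MethFragment],
    by_strand: bool,
) -> dict[tuple[str, str], list[MethFragment]]:
    groups: dict[tuple[str, str], list[MethFragment]] = {}
    for frag in fragments:
        key = (frag.chrom, frag.strand if by_strand else ".")
        groups.setdefault(key, []).append(frag)
    return dict(sorted(groups.items()))


def run_pipeline(
    fragments: Iterable[MethFragment],
    het_snps: Sequence[HetSNP] = (),
    params: AsmParams | None = None,
    mode: str = "asm+snp",
) -> PipelineResult:
    """Full WGBS haplotype-block calling over all chromosomes.

    Fragments are grouped per chromosome and bisulfite strand (per
    chromosome only in SNP-only mode, where strand is irrelevant);
    effective sites are selected, consecutive site pairs tested, and
    the BH adjustment is applied over the union of all tested pairs in
    the run before classification and chaining. In 'asm+snp' mode,
    direct pairs of consecutive SNPs are kept in the tested family even
    when cytosines interleave, so methylation evidence can only add to
    what SNP-only phasing achieves.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    params = params or AsmParams()
    params.validate()
    fragments = list(fragments)
    het_snps = list(het_snps)

    snps_by_chrom: dict[str, list[HetSNP]] = {}
    for s in het_snps:
        snps_by_chrom.setdefault(s.chrom, []).append(s)

    groups = _group_fragments(fragments, by_strand=(mode != "snp"))

    per_group: list[tuple[tuple[str, str], list, list[PairCounts]]] = []
    all_pairs: list[PairCounts] = []
    n_effective = 0
    for (chrom, strand), frags in groups.items():
        index = FragmentIndex(frags)
        sites: list = []
        if mode in ("asm", "asm+snp"):
            cyt = summarize_sites(frags, context=params.context)
            sites.extend(
                select_effective_sites(
                    cyt, low=params.meth_low, high=params.meth_high,
                    min_cov=params.min_cov,
                )
            )
        if mode in ("snp", "asm+snp"):
            covered = [
                s for s in snps_by_chrom.get(chrom, [])
                if len(index.calls_at("snp", s.pos)) >= params.min_cov
            ]
            sites.extend(covered)
        sites.sort(key=lambda s: s.pos)
        n_effective += len(sites)
        extra: list[tuple[int, int]] = []
        if mode == "asm+snp":
            snp_idx = [i for i, s in enumerate(sites) if s.kind == "snp"]
            extra = [
                (i, j) for i, j in zip(snp_idx, snp_idx[1:]) if j - i > 1
            ]
        pairs = candidate_pairs(sites, index, min_cov=params.min_cov,
                                extra_pairs=extra)
        per_group.append(((chrom, strand), sites, pairs))
        all_pairs.extend(pairs)

    accepted = set(id(pc) for pc in apply_tests(all_pairs, params))

    blocks: list[AsmBlock] = []
    for (chrom, strand), sites, pairs in per_group:
        acc = [pc for pc in pairs if id(pc) in accepted]
        for block in chain_blocks(chrom, strand, acc):
            block.phase = phase_snps(block, snps_by_chrom.get(chrom, []))
            blocks.append(block)
    blocks.sort(key=lambda b: (b.chrom, b.start, b.strand))

    return PipelineResult(
        mode=mode,
        params=params,
        blocks=blocks,
        n_effective_sites=n_effective,
        n_tested_pairs=len(all_pairs),
        n_asm_pairs=len(accepted),
        het_snps=het_snps,
    )
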