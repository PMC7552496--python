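"""Allele-specific methylation calling and haplotype-block chaining.

The signal exploited here is per-read co-methylation: at a locus with
allele-specific methylation (ASM), reads sampled from one parental
allele carry methylated cytosines and reads from the other carry
unmethylated ones, so adjacent cytosine sites covered by the same reads
show a strongly diagonal 2x2 co-occurrence table. Each adjacent pair of
"effective" (partially methylated, sufficiently covered) sites is tested
with a two-sided Fisher exact test; p-values are adjusted genome-wide by
Benjamini-Hochberg, and a pair is called ASM when

1. the adjusted p-value falls below ``fdr`` (default 0.05),
2. the two largest cell counts together exceed ``top2_frac`` (default
   90%) of the reads covering both sites, and
3. the largest count is less than ``max_ratio`` (default 2) times the
   second largest — the two allelic patterns are roughly balanced.

Accepted pairs are chained left to right into haplotype blocks: an
accepted pair extends the open block, a rejected or uncovered pair
closes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

from methhap.io_bisulfite import MethFragment

@dataclass
class AsmParams:
    """Thresholds of the ASM caller, with the published defaults."""

    min_cov: int = 4          # reads required per site and per pair
    meth_low: float = 0.1     # below: totally unmethylated, removed
    meth_high: float = 0.9    # above: totally methylated, removed
    fdr: float = 0.05         # adjusted-p threshold (criterion 1)
    top2_frac: float = 0.9    # top-2 combination mass floor (criterion 2)
    max_ratio: float = 2.0    # max/second-max ceiling (criterion 3)
    context: str = "CpG"

    def validate(self) -> None:
        if not (0.0 <= self.meth_low < self.meth_high <= 1.0):
            raise ValueError(
                f"require 0 <= meth_low < meth_high <= 1, got "
                f"{self.meth_low}/{self.meth_high}"
            )
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.0 < self.fdr <= 1.0:
            raise ValueError("fdr must be in (0, 1]")
        if not 0.0 <= self.top2_frac <= 1.0:
            raise ValueError("top2_frac must be in [0, 1]")
        if self.max_ratio <= 1.0:
            raise ValueError("max_ratio must exceed 1")


@dataclass
class CytosineSite:
    """Per-position methylation tally on one strand."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    kind = "cyt"

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        """Methylation level n_meth / (n_meth + n_unmeth)."""
        cov = self.coverage
        if cov == 0:
            raise ValueError(f"site {self.chrom}:{self.pos} has no coverage")
        return self.n_meth / cov


@dataclass
class PairCounts:
    """2x2 read co-occurrence table for an adjacent site pair.

    For a meth-meth pair the cells are N(M_i,M_j), N(M_i,U_j),
    N(U_i,M_j), N(U_i,U_j); for meth-snp, methylation status crossed
    with reference/alternate allele; for snp-snp, allele crossed with
    allele. ``total`` equals the number of fragments with a call at both
    positions.
    """

    site_i: object  # CytosineSite or HetSNP; site_j.pos > site_i.pos
    site_j: object
    n11: int
    n12: int
    n21: int
    n22: int
    p_raw: float | None = None
    p_adj: float | None = None

    @property
    def kind(self) -> str:
        k = (self.site_i.kind, self.site_j.kind)
        if k == ("cyt", "cyt"):
            return "meth-meth"
        if k == ("snp", "snp"):
            return "snp-snp"
        return "meth-snp"

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def relation(self) -> str | None:
        """Haplotype pattern linking the two sites.

        'same' when the concordant diagonal (n11+n22) dominates: the
        index-0 statuses (M/R) travel together; 'cross' when the
        discordant diagonal dominates; None on a tie (no phase
        information).
        """
        diag, anti = self.n11 + self.n22, self.n12 + self.n21
        if diag > anti:
            return "same"
        if anti > diag:
            return "cross"
        return None


@dataclass
class AsmBlock:
    """A chained haplotype block of ASM site pairs.

    ``sites`` are the member positions (cytosines and SNPs) in
    ascending order, ``site_kinds`` the parallel 'cyt'/'snp' labels and
    ``pairs`` the accepted PairCounts linking them. ``phase`` is filled
    by the SNP-phasing stage.
    """

    chrom: str
    strand: str
    sites: tuple[int, ...]
    site_kinds: tuple[str, ...]
    pairs: list[PairCounts] = field(default_factory=list)
    phase: object | None = None  # PhaseVector, set by snp_phase

    @property
    def start(self) -> int:
        return self.sites[0]

    @property
    def end(self) -> int:
        return self.sites[-1]

    @property
    def n_cytosines(self) -> int:
        return sum(1 for k in self.site_kinds if k == "cyt")


class FragmentIndex:
    """Per-position lookup of fragment calls, built once per group.

    Maps ('cyt'|'snp', pos) to {fragment row: 0|1} where 0 encodes the
    index-0 status (M or R) and 1 the other (U or V).
    """

    def __init__(self, fragments: Sequence[MethFragment]):
        self.n_fragments = len(fragments)
        self._calls: dict[tuple[str, int], dict[int, int]] = {}
        for row, frag in enumerate(fragments):
            for pos, status in frag.meth_calls:
                self._calls.setdefault(("cyt", pos), {})[row] = 0 if status == "M" else 1
            for pos, status in frag.snp_calls:
                self._calls.setdefault(("snp", pos), {})[row] = 0 if status == "R" else 1

    def calls_at(self, kind: str, pos: int) -> dict[int, int]:
        return self._calls.get((kind, pos), {})

    def pair_table(self, site_i, site_j) -> PairCounts:
        """Tally the 2x2 table over fragments calling both sites."""
        if site_j.pos <= site_i.pos:
            raise ValueError("site_j must lie right of site_i")
        a = self.calls_at(site_i.kind, site_i.pos)
        b = self.calls_at(site_j.kind, site_j.pos)
        cells = [0, 0, 0, 0]
        if len(a) <= len(b):
            for row, s in a.items():
                t = b.get(row)
                if t is not None:
                    cells[s * 2 + t] += 1
        else:
            for row, t in b.items():
                s = a.get(row)
                if s is not None:
                    cells[s * 2 + t] += 1
        return PairCounts(site_i=site_i, site_j=site_j,
                          n11=cells[0], n12=cells[1], n21=cells[2], n22=cells[3])


def summarize_sites(
    fragments: Iterable[MethFragment],
    context: str = "CpG",
) -> list[CytosineSite]:
    """Tally M/U calls per cytosine position.

    Fragments must come from one chromosome and one bisulfite strand;
    positions never covered are absent from the output.
    """
    tallies: dict[int, list[int]] = {}
    chrom = strand = None
    for frag in fragments:
        if chrom is None:
            chrom, strand = frag.chrom, frag.strand
        elif (frag.chrom, frag.strand) != (chrom, strand):
            raise ValueError("summarize_sites expects one chromosome+strand group")
        for pos, status in frag.meth_calls:
            t = tallies.setdefault(pos, [0, 0])
            t[0 if status == "M" else 1] += 1
    return [
        CytosineSite(chrom=chrom, pos=pos, strand=strand, context=context,
                     n_meth=m, n_unmeth=u)
        for pos, (m, u) in sorted(tallies.items())
    ]


def select_effective_sites(
    sites: Iterable[CytosineSite],
    low: float = 0.1,
    high: float = 0.9,
    min_cov: int = 4,
) -> list[CytosineSite]:
    """Keep partially methylated, sufficiently covered sites.

    Totally methylated (level > ``high``) and totally unmethylated
    (level < ``low``) sites carry no allelic signal and are removed;
    the rest are the "effective" sites used for pairing.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return [
        s for s in sites
        if s.coverage >= min_cov and low <= s.level <= high
    ]


def count_pair(fragments: Sequence[MethFragment], pos_i: int, pos_j: int) -> PairCounts:
    """2x2 methylation co-occurrence table for cytosines at pos_i < pos_j.

    Counts only fragments carrying a methylation call at both positions;
    the cell sums therefore equal the number of such fragments.
    """
    if pos_i >= pos_j:
        raise ValueError(f"pos_i ({pos_i}) must be < pos_j ({pos_j})")
    cells = [0, 0, 0, 0]
    chrom = strand = None
    for frag in fragments:
        calls = dict(frag.meth_calls)
        si, sj = calls.get(pos_i), calls.get(pos_j)
        if si is None or sj is None:
            continue
        chrom, strand = frag.chrom, frag.strand
        cells[(0 if si == "M" else 2) + (0 if sj == "M" else 1)] += 1
    site_i = CytosineSite(chrom or "", pos_i, strand or "+", "CpG", 0, 0)
    site_j = CytosineSite(chrom or "", pos_j, strand or "+", "CpG", 0, 0)
    return PairCounts(site_i=site_i, site_j=site_j,
                      n11=cells[0], n12=cells[1], n21=cells[2], n22=cells[3])


def pair_pvalue(pc: PairCounts) -> float:
    """Two-sided Fisher exact p-value for the pair's 2x2 table.

    Computed by summing hypergeometric point probabilities no larger
    than that of the observed table at fixed margins (the
    minimum-likelihood rule). Inclusion is decided on exact integer
    weights C(r1,x)*C(r2,c1-x), so ties at equal point probability are
    handled without floating-point ambiguity. A table with an all-zero
    row or column admits a single outcome and yields p = 1.
    """
    n = pc.total
    if n == 0:
        raise ValueError("pair has no co-covering fragments; p-value undefined")
    a, b, c, d = pc.counts
    r1, r2, c1 = a + b, c + d, a + c
    obs_weight = comb(r1, a) * comb(r2, c1 - a)
    numerator = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= obs_weight:
            numerator += w
    return numerator / comb(n, c1)


def adjust_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{k >= i} p_(k) * m / k over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def classify_pair(
    pc: PairCounts,
    alpha: float = 0.05,
    top2_frac: float = 0.9,
    max_ratio: float = 2.0,
) -> bool:
    """Apply the three ASM-region criteria to an adjusted pair.

    True (ASM) iff p_adj < alpha, the two largest cells strictly exceed
    top2_frac of the total, and max/second-max is strictly below
    max_ratio. A zero second maximum means only one read pattern was
    observed — fully concordant, not allele-specific — and fails the
    ratio criterion (ratio treated as infinite).
    """
    if pc.p_adj is None:
        raise ValueError("pair has no adjusted p-value; run adjust_fdr first")
    if pc.p_adj >= alpha:
        return False
    c = sorted(pc.counts, reverse=True)
    mx, mx2 = c[0], c[1]
    if mx + mx2 <= top2_frac * pc.total:
        return False
    if mx2 == 0 or mx / mx2 >= max_ratio:
        return False
    return True


def candidate_pairs(
    sites: Sequence,
    index: FragmentIndex,
    min_cov: int = 4,
    extra_pairs: Iterable[tuple[int, int]] = (),
) -> list[PairCounts]:
    """Tables for consecutive site pairs with co-coverage >= min_cov.

    ``sites`` is the ascending list of effective sites (cytosines,
    optionally interleaved with SNP sites). ``extra_pairs`` adds
    non-consecutive (i, j) index pairs to the tested family — used to
    keep direct SNP-SNP links in play when cytosines interleave.
    Pairs below the coverage floor are dropped (uncovered), not tested.
    """
    for a, b in zip(sites, sites[1:]):
        if b.pos <= a.pos:
            raise ValueError("sites must be sorted by ascending position")
    wanted = list(zip(range(len(sites) - 1), range(1, len(sites)))) + [
        (i, j) for i, j in extra_pairs
    ]
    seen: set[tuple[int, int]] = set()
    out: list[PairCounts] = []
    for i, j in wanted:
        if (i, j) in seen:
            continue
        seen.add((i, j))
        pc = index.pair_table(sites[i], sites[j])
        if pc.total >= min_cov:
            out.append(pc)
    out.sort(key=lambda pc: (pc.site_i.pos, pc.site_j.pos))
    return out


def apply_tests(pairs: Sequence[PairCounts], params: AsmParams) -> list[PairCounts]:
    """Fisher-test every pair and BH-adjust across the whole family.

    The multiple-testing family is all pairs passed in — callers
    assemble the genome-wide collection before adjustment. Returns the
    accepted (ASM) pairs.
    """
    if not pairs:
        return []
    praw = [pair_pvalue(pc) for pc in pairs]
    padj = adjust_fdr(praw)
    accepted = []
    for pc, pr, pa in zip(pairs, praw, padj):
        pc.p_raw, pc.p_adj = pr, pa
        if classify_pair(pc, alpha=params.fdr, top2_frac=params.top2_frac,
                         max_ratio=params.max_ratio):
            accepted.append(pc)
    return accepted


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def chain_blocks(
    chrom: str,
    strand: str,
    accepted: Sequence[PairCounts],
) -> list[AsmBlock]:
    """Chain accepted ASM pairs into maximal haplotype blocks.

    Blocks are the connected components of sites linked by accepted
    pairs; for purely consecutive testing this reduces to the greedy
    left-to-right extension (an accepted pair extends the open block, a
    rejected or uncovered pair closes it). Emitted blocks have at least
    two member sites by construction.
    """
    uf = _UnionFind()
    meta: dict[int, str] = {}
    for pc in accepted:
        uf.union(pc.site_i.pos, pc.site_j.pos)
        meta[pc.site_i.pos] = pc.site_i.kind
        meta[pc.site_j.pos] = pc.site_j.kind
    groups: dict[int, list[int]] = {}
    for pos in meta:
        groups.setdefault(uf.find(pos), []).append(pos)
    blocks = []
    for root in sorted(groups):
        members = sorted(groups[root])
        pairs = [pc for pc in accepted if uf.find(pc.site_i.pos) == root]
        blocks.append(
            AsmBlock(
                chrom=chrom,
                strand=strand,
                sites=tuple(members),
                site_kinds=tuple(meta[p] for p in members),
                pairs=pairs,
            )
        )
    return blocks


def extend_blocks(
    effective_sites: Sequence,
    fragments: Sequence[MethFragment],
    params: AsmParams | None = None,
) -> list[AsmBlock]:
    """ASM blocks for one chromosome+strand group of effective sites.

    Convenience wrapper around the pipeline internals: tests consecutive
    pairs, BH-adjusts over this group's tests, classifies and chains.
    Genome-wide runs adjust across all groups jointly instead (see
    ``snp_phase.run_pipeline``).
    """
    params = params or AsmParams()
    params.validate()
    if not effective_sites:
        return []
    chrom = effective_sites[0].chrom
    strand = getattr(effective_sites[0], "strand", "+")
    index = FragmentIndex(list(fragments))
    pairs = candidate_pairs(effective_sites, index, min_cov=params.min_cov)
    accepted = apply_tests(pairs, params)
    return chain_blocks(chrom, strand, accepted)
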