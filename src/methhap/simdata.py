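"""Synthetic diploid bisulfite and Hi-C data with known haplotypes.

The generator emulates a diploid genome with planted heterozygous SNPs
and allele-specific methylation (ASM) regions: inside a region one
allele's CpGs are (almost all) methylated and the other's unmethylated,
while outside, both alleles share the same deterministic state per site
— the bimodal background typical of CpG methylomes, which the effective
-site filter removes. Bisulfite reads are drawn per allele as
already-aligned records (evenly tiled starts, so coverage is
deterministic), with configurable bisulfite-conversion failure and
sequencing-error rates; Hi-C evidence is emitted as phased SNP blocks
with configurable flip/missing noise.

All randomness flows from one integer seed through three named
``numpy`` generator streams: ``[seed, 0]`` for the truth set,
``[seed, 1]`` for bisulfite reads, ``[seed, 2]`` for Hi-C blocks, so
identical seed and parameters give byte-identical outputs.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from methhap.io_bisulfite import GenomeIndex, HetSNP, write_phased_blocks
from methhap.snp_phase import PhaseVector, PipelineResult

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Study conditions for one simulated dataset.

    Lengths are bp; ``depth`` is total haploid-summed coverage (each
    allele contributes depth/2); probabilities are per site or per
    base as noted.
    """

    genome_length: int = 100_000
    n_chroms: int = 1
    n_asm_regions: int = 10
    region_length: int = 2_000
    region_gap: int = 1_000           # minimum bp between planted regions
    cpg_spacing: tuple[int, int] = (8, 16)
    n_snps: int = 50
    snp_in_region_frac: float = 0.6   # SNPs planted inside ASM regions
    depth: int = 20
    fragment_length: int = 100
    paired: bool = False              # emit overlapping mate pairs
    p_hi: float = 0.95                # P(methylated-allele CpG state = M)
    p_lo: float = 0.05                # P(other-allele CpG state = M)
    background_meth_prob: float = 0.5  # shared background state
    conversion_failure: float = 0.0   # U read out as C
    seq_error: float = 0.0            # substitution at informative bases
    hic_blocks_per_chrom: int = 2
    hic_error: float = 0.0            # per-SNP phase flip in Hi-C blocks
    hic_missing: float = 0.0          # per-SNP missing rate in Hi-C blocks

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_asm_regions < 0:
            raise ValueError("n_asm_regions must be >= 0")
        if self.fragment_length < 2 * self.cpg_spacing[1]:
            raise ValueError("fragment_length too short to span adjacent CpGs")
        margin = 2 * self.fragment_length
        need = (self.n_asm_regions * self.region_length
                + max(0, self.n_asm_regions - 1) * self.region_gap
                + 2 * margin)
        if need > self.genome_length:
            raise ValueError(
                f"{self.n_asm_regions} regions of {self.region_length} bp do "
                f"not fit a {self.genome_length} bp chromosome"
            )


@dataclass
class SimTruth:
    """The planted ground truth behind one simulated dataset."""

    params: SimParams
    seed: int
    genome: GenomeIndex
    cpg_sites: dict[str, list[int]]                    # C of each CpG, 1-based
    site_states: dict[str, dict[int, tuple[str, str]]]  # pos -> (state A, state B)
    het_snps: list[HetSNP]
    snp_phase: dict[tuple[str, int], int]              # 0 = ref on haplotype A
    asm_regions: list[tuple[str, int, int, str]]       # (chrom, start, end, meth allele)

    def informative_cytosines(self, chrom: str) -> list[int]:
        """CpG positions whose two allele states differ (allelic signal)."""
        states = self.site_states[chrom]
        return [p for p in self.cpg_sites[chrom] if states[p][0] != states[p][1]]

    def expected_pairs(self, mode: str = "asm+snp", max_gap: int | None = None) -> set:
        """Site pairs a perfect caller should accept, as (chrom, i, j).

        Consecutive informative sites (allelic cytosines, plus het SNPs
        outside 'asm' mode) within ``max_gap`` bp (default half the
        fragment length, where tiled co-coverage is deep); in modes with
        SNPs, consecutive SNP pairs within the gap are included as well,
        mirroring the direct SNP-SNP links the pipeline keeps testing.
        """
        if max_gap is None:
            max_gap = self.params.fragment_length // 2
        expected: set[tuple[str, int, int]] = set()
        for chrom in self.genome.sequences:
            sites: list[int] = []
            if mode in ("asm", "asm+snp"):
                sites.extend(self.informative_cytosines(chrom))
            snps = sorted(s.pos for s in self.het_snps if s.chrom == chrom)
            if mode in ("snp", "asm+snp"):
                sites.extend(snps)
            sites.sort()
            for a, b in zip(sites, sites[1:]):
                if b - a <= max_gap:
                    expected.add((chrom, a, b))
            if mode == "asm+snp":
                for a, b in zip(snps, snps[1:]):
                    if b - a <= max_gap:
                        expected.add((chrom, a, b))
        return expected


def _place_regions(rng, params: SimParams, L: int) -> list[tuple[int, int]]:
    """Non-overlapping region intervals with jitter, away from the ends."""
    n, rl, gap = params.n_asm_regions, params.region_length, params.region_gap
    margin = 2 * params.fragment_length
    if n == 0:
        return []
    pitch = (L - 2 * margin - n * rl - (n - 1) * gap) // n
    out = []
    cursor = margin + 1
    for i in range(n):
        jitter = int(rng.integers(0, max(1, pitch)))
        start = cursor + jitter
        out.append((start, start + rl - 1))
        cursor = start + rl + gap
    return out


def make_truth(params: SimParams | None = None, seed: int = 0) -> SimTruth:
    """Draw a ground-truth diploid genome with planted ASM and SNPs.

    Chromosome sequences use A/T filler with CpG dinucleotides planted
    every ``cpg_spacing`` bp, so every cytosine is in CpG context and
    SNPs (A<->T) never create or destroy one. Within an ASM region the
    methylated allele's CpG states are M with probability ``p_hi`` and
    the other allele's with ``p_lo``; background CpGs share one state
    between alleles. SNPs inside regions are spaced >= 150 bp apart;
    background SNPs come as close pairs or singletons planted at least
    one fragment length away from regions and from each other's
    clusters.
    """
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng([seed, 0])
    L = params.genome_length
    flen = params.fragment_length

    sequences: dict[str, str] = {}
    cpg_sites: dict[str, list[int]] = {}
    site_states: dict[str, dict[int, tuple[str, str]]] = {}
    het_snps: list[HetSNP] = []
    snp_phase: dict[tuple[str, int], int] = {}
    asm_regions: list[tuple[str, int, int, str]] = []

    lo_sp, hi_sp = params.cpg_spacing
    n_in = round(params.n_snps * params.snp_in_region_frac)
    n_bg = params.n_snps - n_in

    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(np.array(list("AT")), size=L)
        cpgs: list[int] = []
        cursor = int(rng.integers(lo_sp, hi_sp + 1)) + 10
        while cursor + 1 <= L - 10:
            seq[cursor - 1] = "C"
            seq[cursor] = "G"
            cpgs.append(cursor)
            cursor += int(rng.integers(lo_sp, hi_sp + 1))
        regions = _place_regions(rng, params, L)
        for start, end in regions:
            meth_allele = "A" if rng.random() < 0.5 else "B"
            asm_regions.append((chrom, start, end, meth_allele))

        states: dict[int, tuple[str, str]] = {}
        for pos in cpgs:
            region = next(
                ((s, e, m) for (c, s, e, m) in asm_regions
                 if c == chrom and s <= pos <= e), None,
            )
            if region is None:
                shared = "M" if rng.random() < params.background_meth_prob else "U"
                states[pos] = (shared, shared)
            else:
                hi = "M" if rng.random() < params.p_hi else "U"
                lo = "M" if rng.random() < params.p_lo else "U"
                states[pos] = (hi, lo) if region[2] == "A" else (lo, hi)

        def _filler_positions(start: int, end: int) -> list[int]:
            return [p for p in range(start, end + 1) if seq[p - 1] in ("A", "T")]

        snp_positions: list[int] = []
        # in-region SNPs, round-robin over regions, spaced >= 150 bp
        chrom_regions = [(s, e) for (c, s, e, _m) in asm_regions if c == chrom]
        if chrom_regions and n_in:
            per_region = [n_in // len(chrom_regions)] * len(chrom_regions)
            for i in range(n_in % len(chrom_regions)):
                per_region[i] += 1
            for (s, e), want in zip(chrom_regions, per_region):
                placed: list[int] = []
                candidates = _filler_positions(s, e)
                attempts = 0
                while len(placed) < want and attempts < 200:
                    attempts += 1
                    p = int(rng.choice(candidates))
                    if all(abs(p - q) >= 150 for q in placed):
                        placed.append(p)
                snp_positions.extend(sorted(placed))
        # background SNP clusters: alternate close pairs and singletons
        margin_ints: list[tuple[int, int]] = []
        prev_end = flen
        for s, e in chrom_regions + [(L - flen + 1, L)]:
            if s - flen - 1 - prev_end >= 3 * flen:
                margin_ints.append((prev_end + 1, s - flen - 1))
            prev_end = e + flen
        placed_bg = 0
        want_pair = True
        anchors: list[int] = []
        attempts = 0
        while placed_bg < n_bg and attempts < 500 and margin_ints:
            attempts += 1
            lo_i, hi_i = margin_ints[int(rng.integers(len(margin_ints)))]
            if hi_i - lo_i < 60:
                continue
            p = int(rng.integers(lo_i, hi_i - 50))
            if any(abs(p - a) < 2 * flen for a in anchors):
                continue
            cand = _filler_positions(p, min(p + 45, hi_i))
            if not cand:
                continue
            anchors.append(p)
            first = cand[0]
            snp_positions.append(first)
            placed_bg += 1
            if want_pair and placed_bg < n_bg:
                far = [q for q in cand if 15 <= q - first <= 45]
                if far:
                    snp_positions.append(far[0])
                    placed_bg += 1
            want_pair = not want_pair

        for pos in sorted(set(snp_positions)):
            ref = str(seq[pos - 1])
            alt = "T" if ref == "A" else "A"
            het_snps.append(HetSNP(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt))
            snp_phase[(chrom, pos)] = int(rng.integers(0, 2))

        sequences[chrom] = "".join(seq)
        cpg_sites[chrom] = cpgs
        site_states[chrom] = states

    het_snps.sort(key=lambda s: (s.chrom, s.pos))
    return SimTruth(
        params=params, seed=seed, genome=GenomeIndex(sequences=sequences),
        cpg_sites=cpg_sites, site_states=site_states, het_snps=het_snps,
        snp_phase=snp_phase, asm_regions=asm_regions,
    )


def _haplotype_sequences(truth: SimTruth, chrom: str) -> tuple[list[str], list[str]]:
    base = list(truth.genome.sequences[chrom])
    hap_a, hap_b = base[:], base[:]
    for snp in truth.het_snps:
        if snp.chrom != chrom:
            continue
        phase = truth.snp_phase[(chrom, snp.pos)]
        # phase 0: ref on haplotype A, alt on B
        (hap_b if phase == 0 else hap_a)[snp.pos - 1] = snp.alt_allele
    return hap_a, hap_b


def simulate_bisulfite(
    truth: SimTruth,
    prefix: str | os.PathLike,
) -> dict[str, Path]:
    """Write FASTA, coordinate-sorted SAM and VCF for a truth set.

    Fragments tile each haplotype with evenly spaced starts (allele B
    offset by half a step), so per-site and pair co-coverage are
    deterministic at the nominal depth. On the original top strand an
    unmethylated CpG cytosine is emitted as T (as C with probability
    ``conversion_failure``); substitution errors at informative bases
    occur at ``seq_error``. Reads carry the XG:Z:CT bisulfite-strand
    tag. With ``paired`` set, each fragment is emitted as two
    overlapping mates sharing one molecule's states.
    """
    params = truth.params
    rng = np.random.default_rng([truth.seed, 1])
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta_path = prefix.with_suffix(".fa")
    sam_path = prefix.with_suffix(".sam")
    vcf_path = prefix.with_suffix(".vcf")

    with open(fasta_path, "w") as fh:
        for chrom, seq in truth.genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    fai = Path(str(fasta_path) + ".fai")
    if fai.exists():  # stale index from a previous run
        fai.unlink()

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in truth.genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim\n")
        for snp in truth.het_snps:
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\tPASS\t.\tGT\t0/1\n"
            )

    flen = params.fragment_length
    step = max(1, round(flen / max(1, params.depth / 2)))
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in truth.genome.lengths.items()],
    })

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for tid, chrom in enumerate(truth.genome.sequences):
            L = truth.genome.lengths[chrom]
            hap_a, hap_b = _haplotype_sequences(truth, chrom)
            haps = {"A": hap_a, "B": hap_b}
            cpgs = truth.cpg_sites[chrom]
            states = truth.site_states[chrom]
            snp_pos = [s.pos for s in truth.het_snps if s.chrom == chrom]
            starts: list[tuple[int, str]] = []
            for ai, allele in enumerate(("A", "B")):
                offset = 0 if allele == "A" else step // 2
                starts.extend(
                    (st, allele) for st in range(1 + offset, L - flen + 2, step)
                )
            starts.sort()
            records = []
            for start, allele in starts:
                end = start + flen - 1
                frag = haps[allele][start - 1:end]
                ai = 0 if allele == "A" else 1
                lo = bisect_left(cpgs, start)
                hi = bisect_right(cpgs, end)
                informative: list[int] = []
                for pos in cpgs[lo:hi]:
                    state = states[pos][ai]
                    if state == "M":
                        emitted = "C"
                    else:
                        emitted = "C" if rng.random() < params.conversion_failure else "T"
                    frag[pos - start] = emitted
                    informative.append(pos)
                for pos in snp_pos:
                    if start <= pos <= end:
                        informative.append(pos)
                if params.seq_error > 0:
                    for pos in informative:
                        if rng.random() < params.seq_error:
                            cur = frag[pos - start]
                            others = [b for b in "ACGT" if b != cur]
                            frag[pos - start] = others[int(rng.integers(3))]
                name = f"r_{chrom}_{allele}_{start}"
                seq_str = "".join(frag)
                if not params.paired:
                    records.append(_sam_record(header, name, tid, start - 1, seq_str, 0))
                else:
                    mlen = max(2 * flen // 3, 30)
                    r1 = _sam_record(header, name, tid, start - 1, seq_str[:mlen], 99)
                    r2_start0 = start - 1 + flen - mlen
                    r2 = _sam_record(header, name, tid, r2_start0, seq_str[flen - mlen:], 147)
                    r1.next_reference_id = r2.next_reference_id = tid
                    r1.next_reference_start = r2_start0
                    r2.next_reference_start = start - 1
                    r1.template_length = flen
                    r2.template_length = -flen
                    records.extend([r1, r2])
            records.sort(key=lambda r: r.reference_start)
            for rec in records:
                out.write(rec)

    return {"fasta": fasta_path, "sam": sam_path, "vcf": vcf_path}


def _sam_record(header, name: str, tid: int, start0: int, seq: str, flag: int):
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = tid
    a.reference_start = start0
    a.mapping_quality = 60
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.set_tag("XG", "CT")
    return a


def simulate_hic(
    truth: SimTruth,
    out_path: str | os.PathLike | None = None,
) -> list[tuple[None, PhaseVector]]:
    """Emit Hi-C-derived phased blocks for the planted SNPs.

    Long-range SNP links within one allele are summarised directly as
    HapCUT2-style blocks: each chromosome's SNPs are split into
    ``hic_blocks_per_chrom`` contiguous blocks whose phases equal the
    planted truth up to one random global flip per block, with each SNP
    independently flipped at ``hic_error`` and dropped at
    ``hic_missing``.
    """
    params = truth.params
    rng = np.random.default_rng([truth.seed, 2])
    blocks: list[tuple[None, PhaseVector]] = []
    for chrom in truth.genome.sequences:
        snps = [s for s in truth.het_snps if s.chrom == chrom]
        if not snps:
            continue
        for chunk in np.array_split(np.arange(len(snps)), params.hic_blocks_per_chrom):
            if len(chunk) == 0:
                continue
            flip = int(rng.integers(0, 2))
            entries: list[tuple[HetSNP, int | None]] = []
            for i in chunk:
                snp = snps[int(i)]
                if rng.random() < params.hic_missing:
                    entries.append((snp, None))
                    continue
                phase = truth.snp_phase[(chrom, snp.pos)] ^ flip
                if rng.random() < params.hic_error:
                    phase ^= 1
                entries.append((snp, phase))
            blocks.append((None, PhaseVector(source="HiC", entries=entries)))
    if out_path is not None:
        write_phased_blocks(blocks, out_path)
    return blocks


def write_truth_table(truth: SimTruth, out_path: str | os.PathLike) -> None:
    """Tab-separated ground truth: planted regions and SNP phases."""
    with open(out_path, "w") as fh:
        fh.write("#type\tchrom\tstart_or_pos\tend\tdetail\n")
        for chrom, start, end, allele in truth.asm_regions:
            fh.write(f"region\t{chrom}\t{start}\t{end}\tmethylated_allele={allele}\n")
        for snp in truth.het_snps:
            ph = truth.snp_phase[(snp.chrom, snp.pos)]
            fh.write(
                f"snp\t{snp.chrom}\t{snp.pos}\t{snp.pos}\t"
                f"{snp.ref_allele}>{snp.alt_allele};phase={ph}\n"
            )


def simulate_dataset(
    params: SimParams | None = None,
    seed: int = 0,
    outdir: str | os.PathLike = ".",
) -> tuple[SimTruth, dict[str, Path]]:
    """Convenience: truth + FASTA/SAM/VCF + Hi-C blocks + truth table."""
    truth = make_truth(params, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = simulate_bisulfite(truth, outdir / "sim")
    hic_path = outdir / "sim.hic_blocks.txt"
    simulate_hic(truth, out_path=hic_path)
    paths["hic_blocks"] = hic_path
    truth_path = outdir / "sim.truth.tsv"
    write_truth_table(truth, truth_path)
    paths["truth"] = truth_path
    return truth, paths


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

def pair_metrics(result: PipelineResult, truth: SimTruth) -> tuple[float, float]:
    """(recall, precision) of accepted site pairs against expected pairs."""
    expected = truth.expected_pairs(mode=result.mode)
    got = {(b.chrom, pc.site_i.pos, pc.site_j.pos)
           for b in result.blocks for pc in b.pairs}
    if not expected:
        return (1.0 if not got else 0.0), (1.0 if not got else 0.0)
    tp = len(expected & got)
    recall = tp / len(expected)
    precision = tp / len(got) if got else 1.0
    return recall, precision


def region_recovery(result: PipelineResult, truth: SimTruth) -> float:
    """Fraction of planted ASM regions recovered at effective-site resolution.

    A region counts as recovered when one called block's member
    cytosines are exactly the region's allelically informative CpGs.
    """
    if not truth.asm_regions:
        return 1.0
    block_cyts = [
        (b.chrom, frozenset(p for p, k in zip(b.sites, b.site_kinds) if k == "cyt"))
        for b in result.blocks
    ]
    hit = 0
    for chrom, start, end, _allele in truth.asm_regions:
        info = frozenset(
            p for p in truth.informative_cytosines(chrom) if start <= p <= end
        )
        if not info:
            hit += 1  # nothing recoverable was planted
            continue
        if any(c == chrom and cyts == info for c, cyts in block_cyts):
            hit += 1
    return hit / len(truth.asm_regions)


def switch_error_rate(
    phase_vectors,
    truth: SimTruth,
) -> tuple[int, int]:
    """(switch errors, comparisons) of phased SNPs against planted truth.

    For each phase vector, every consecutive pair of non-missing
    entries is compared on relative phase; a mismatch with the planted
    relative phase is one switch error. Global flips per block do not
    count, as the haplotype-A labelling is arbitrary.
    """
    errors = comparisons = 0
    for pv in phase_vectors:
        phased = [(s, p) for s, p in pv.entries if p is not None]
        for (s1, p1), (s2, p2) in zip(phased, phased[1:]):
            t1 = truth.snp_phase[(s1.chrom, s1.pos)]
            t2 = truth.snp_phase[(s2.chrom, s2.pos)]
            comparisons += 1
            if (p1 ^ p2) != (t1 ^ t2):
                errors += 1
    return errors, comparisons
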