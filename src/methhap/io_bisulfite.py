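"""Reading and writing for the methylation-haplotype pipeline.

Handles the reference FASTA, coordinate-sorted bisulfite SAM/BAM
alignments, heterozygous-SNP VCFs, the tab-separated ASM-region table and
HapCUT2-style phased-block files.

All genomic coordinates in the public data model are 1-based inclusive,
matching SAM/VCF conventions and the output formats.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam
from pyfaidx import Fasta

# Bases whose ref/alt pair cannot be distinguished after bisulfite
# conversion: C->T on original-top-strand fragments, G->A on
# original-bottom-strand fragments.
_CONFOUNDED = {"+": frozenset("CT"), "-": frozenset("GA")}

_CONTEXTS = ("CpG", "CHG", "CHH", "all")


@dataclass
class GenomeIndex:
    """Uppercased in-memory reference genome.

    ``sequences`` maps chromosome name to its nucleotide string;
    ``lengths`` maps chromosome name to its length in bp.
    """

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at 1-based ``pos``; 'N' outside the chromosome."""
        seq = self.sequences[chrom]
        if 1 <= pos <= len(seq):
            return seq[pos - 1]
        return "N"

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous SNV."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    id: str | None = None

    kind = "snp"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")


@dataclass
class MethFragment:
    """One sequencing fragment's ordered methylation and allele calls.

    A physical read pair contributes exactly one fragment: overlapping
    mate positions are deduplicated (first mate wins). ``meth_calls``
    holds (pos, 'M'|'U') at cytosine sites; ``snp_calls`` holds
    (pos, 'R'|'V') at heterozygous-SNP sites, where R matches the
    reference allele and V the alternate.
    """

    fragment_id: str
    chrom: str
    strand: str  # bisulfite strand of origin: '+' (OT) or '-' (OB)
    meth_calls: tuple[tuple[int, str], ...]
    snp_calls: tuple[tuple[int, str], ...] = ()


def load_genome(fasta_path: str | os.PathLike) -> GenomeIndex:
    """Load a FASTA reference into memory, uppercased.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    for duplicate chromosome names or an empty file.
    """
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(str(fasta_path))
    try:
        fa = Fasta(str(fasta_path), rebuild=True, build_index=True)
    except ValueError as exc:  # pyfaidx signals duplicates/empties this way
        raise ValueError(f"invalid FASTA {fasta_path}: {exc}") from exc
    sequences = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    if not sequences:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return GenomeIndex(sequences=sequences)


def load_het_snps(vcf_path: str | os.PathLike) -> list[HetSNP]:
    """Read heterozygous biallelic SNVs from a VCF.

    Multiallelic records, indels and non-het genotypes are dropped.
    Requires a GT field on the first sample.
    """
    snps: list[HetSNP] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if not list(vcf.header.samples):
            raise ValueError(f"VCF has no sample/GT column: {vcf_path}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            if set(gt) != {0, 1}:  # heterozygous only
                continue
            snps.append(
                HetSNP(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref.upper(),
                    alt_allele=alt.upper(),
                    id=rec.id,
                )
            )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


def _cytosine_context(genome: GenomeIndex, chrom: str, pos: int, strand: str) -> str | None:
    """Context (CpG/CHG/CHH) of the cytosine at 1-based ``pos``.

    On '+' the reference base must be C; on '-' it must be G (a cytosine
    on the minus strand, whose downstream neighbours lie at pos-1, pos-2
    on the plus strand, complemented).
    """
    if strand == "+":
        if genome.base(chrom, pos) != "C":
            return None
        nxt1, nxt2 = genome.base(chrom, pos + 1), genome.base(chrom, pos + 2)
        if nxt1 == "G":
            return "CpG"
        if nxt1 in "ACT" and nxt2 == "G":
            return "CHG"
        if nxt1 in "ACT" and nxt2 in "ACT":
            return "CHH"
        return None  # N in the window
    else:
        if genome.base(chrom, pos) != "G":
            return None
        nxt1, nxt2 = genome.base(chrom, pos - 1), genome.base(chrom, pos - 2)
        if nxt1 == "C":
            return "CpG"
        if nxt1 in "AGT" and nxt2 == "C":
            return "CHG"
        if nxt1 in "AGT" and nxt2 in "AGT":
            return "CHH"
        return None


def infer_bisulfite_strand(aln: pysam.AlignedSegment) -> str:
    """Bisulfite strand of origin for an alignment.

    Prefers aligner tags: Bismark-style ``XG`` ("CT" = original top
    strand, "GA" = original bottom strand), then BSMAP/bwa-meth-style
    ``YD`` ('f'/'r') or ``ZS``. Without tags, falls back to the FLAG
    orientation rule for directional libraries: the fragment's strand is
    that of read 1 (or of the read itself when single-end) — forward
    means original top ('+'), reverse means original bottom ('-').
    """
    if aln.has_tag("XG"):
        return "+" if aln.get_tag("XG") == "CT" else "-"
    if aln.has_tag("YD"):
        return "+" if str(aln.get_tag("YD")).startswith("f") else "-"
    if aln.has_tag("ZS"):
        return "+" if str(aln.get_tag("ZS")).startswith("+") else "-"
    if aln.is_paired:
        r1_reverse = aln.is_reverse if aln.is_read1 else aln.is_mate_reverse
        return "-" if r1_reverse else "+"
    return "-" if aln.is_reverse else "+"


def _call_alignment(
    aln: pysam.AlignedSegment,
    genome: GenomeIndex,
    strand: str,
    snp_at: dict[int, HetSNP],
    context_filter: str,
    meth: dict[int, str],
    snp: dict[int, str],
) -> None:
    """Accumulate per-position calls from one alignment into meth/snp maps.

    Positions already present are skipped (first mate wins on overlap).
    """
    chrom = aln.reference_name
    query = aln.query_sequence
    if query is None:
        return
    confounded = _CONFOUNDED[strand]
    for qpos, rpos0 in aln.get_aligned_pairs(matches_only=True):
        pos = rpos0 + 1
        read_base = query[qpos].upper()
        snprec = snp_at.get(pos)
        if snprec is not None:
            if pos not in snp and {snprec.ref_allele, snprec.alt_allele} != confounded:
                if read_base == snprec.ref_allele:
                    snp[pos] = "R"
                elif read_base == snprec.alt_allele:
                    snp[pos] = "V"
            continue
        if pos in meth:
            continue
        ref_base = genome.base(chrom, pos)
        if strand == "+":
            if ref_base != "C":
                continue
            status = "M" if read_base == "C" else "U" if read_base == "T" else None
        else:
            if ref_base != "G":
                continue
            status = "M" if read_base == "G" else "U" if read_base == "A" else None
        if status is None:
            continue
        if context_filter != "all":
            if _cytosine_context(genome, chrom, pos, strand) != context_filter:
                continue
        else:
            if _cytosine_context(genome, chrom, pos, strand) is None:
                continue
        meth[pos] = status


def extract_fragments(
    alignments: str | os.PathLike | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    genome: GenomeIndex,
    het_snps: Sequence[HetSNP] = (),
    context_filter: str = "CpG",
) -> Iterator[MethFragment]:
    """Convert bisulfite alignments into per-fragment M/U and R/V calls.

    On an original-top-strand fragment each reference cytosine passing
    ``context_filter`` yields M for a read C and U for a read T; on an
    original-bottom-strand fragment each reference G (a minus-strand
    cytosine) yields M for read G and U for read A. At heterozygous SNP
    positions the read base is matched against ref (R) and alt (V);
    calls are suppressed where conversion confounds the alleles (C/T
    pairs on '+' fragments, G/A on '-'). Mates of a pair are merged into
    one fragment; on overlap the first mate's call stands.

    Unmapped, secondary, supplementary and duplicate records are ignored.
    """
    if context_filter not in _CONTEXTS:
        raise ValueError(f"context_filter must be one of {_CONTEXTS}")

    own_file = False
    if isinstance(alignments, (str, os.PathLike)):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_file = True

    snp_index: dict[str, dict[int, HetSNP]] = {}
    for s in het_snps:
        snp_index.setdefault(s.chrom, {})[s.pos] = s

    # qname -> (strand, chrom, per-mate call maps); mates merge at flush
    # with read 1 winning on overlapping positions regardless of which
    # mate appeared first in coordinate order.
    pending: dict[str, tuple[str, str, dict, dict, dict, dict]] = {}
    last_pos: dict[str, int] = {}

    def _flush(qname: str) -> MethFragment:
        strand, chrom, m1, s1, m2, s2 = pending.pop(qname)
        meth = {**m2, **m1}
        snp = {**s2, **s1}
        return MethFragment(
            fragment_id=qname,
            chrom=chrom,
            strand=strand,
            meth_calls=tuple(sorted(meth.items())),
            snp_calls=tuple(sorted(snp.items())),
        )

    try:
        for aln in alignments:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            chrom = aln.reference_name
            if chrom not in genome:
                raise ValueError(f"alignment references unknown chromosome {chrom!r}")
            if last_pos.get(chrom, -1) > aln.reference_start:
                raise ValueError("alignments are not coordinate-sorted")
            last_pos[chrom] = aln.reference_start
            snps_here = snp_index.get(chrom, {})

            if not aln.is_paired:
                strand = infer_bisulfite_strand(aln)
                meth: dict[int, str] = {}
                snp: dict[int, str] = {}
                _call_alignment(aln, genome, strand, snps_here, context_filter, meth, snp)
                yield MethFragment(
                    fragment_id=aln.query_name,
                    chrom=chrom,
                    strand=strand,
                    meth_calls=tuple(sorted(meth.items())),
                    snp_calls=tuple(sorted(snp.items())),
                )
                continue

            qname = aln.query_name
            first_seen = qname not in pending
            if first_seen:
                strand = infer_bisulfite_strand(aln)
                pending[qname] = (strand, chrom, {}, {}, {}, {})
            entry = pending[qname]
            off = 2 if aln.is_read1 or not aln.is_read2 else 4
            _call_alignment(
                aln, genome, entry[0], snps_here, context_filter,
                entry[off], entry[off + 1],
            )
            if not first_seen:
                yield _flush(qname)
        for qname in list(pending):
            yield _flush(qname)
    finally:
        if own_file:
            alignments.close()


def write_asmr(blocks, out_path: str | os.PathLike, header: bool = True) -> None:
    """Write the ASM-region table: one line per block, five columns.

    Columns are ``chromosome start end LengthofBlock NumberofCytosines``
    with 1-based inclusive start/end at the first and last member
    cytosine; LengthofBlock = end - start + 1. Blocks without at least
    two member cytosines are skipped (nothing allele-specifically
    methylated to report).
    """
    with open(out_path, "w") as fh:
        if header:
            fh.write("chromosome\tstart\tend\tLengthofBlock\tNumberofCytosines\n")
        for b in blocks:
            cyt = [p for p, k in zip(b.sites, b.site_kinds) if k == "cyt"]
            if len(cyt) < 2:
                continue
            start, end = cyt[0], cyt[-1]
            fh.write(f"{b.chrom}\t{start}\t{end}\t{end - start + 1}\t{len(cyt)}\n")


def write_phased_blocks(blocks_with_phase, out_path: str | os.PathLike) -> None:
    """Write phased SNPs per block in a HapCUT2-style text format.

    Each block opens with a ``BLOCK:`` header and closes with a line of
    asterisks; each data line carries (index, hap0 allele, hap1 allele,
    chrom, pos, ref, alt) where hap0/hap1 are 0 (ref) / 1 (alt) or '-'
    for missing. Blocks with no phased SNPs are omitted.

    ``blocks_with_phase`` yields (block, PhaseVector) pairs; the block
    may be None for merged blocks that no longer map to one ASM block.
    """
    idx = 0
    with open(out_path, "w") as fh:
        for _block, pv in blocks_with_phase:
            entries = [(snp, ph) for snp, ph in pv.entries if ph is not None]
            if not entries:
                continue
            span = (entries[0][0].pos, entries[-1][0].pos)
            fh.write(
                f"BLOCK: offset: {idx + 1} len: {len(entries)} "
                f"phased: {len(entries)} span: {span[0]}-{span[1]}\n"
            )
            for snp, ph in entries:
                idx += 1
                h0, h1 = (0, 1) if ph == 0 else (1, 0)
                fh.write(
                    f"{idx}\t{h0}\t{h1}\t{snp.chrom}\t{snp.pos}\t"
                    f"{snp.ref_allele}\t{snp.alt_allele}\n"
                )
            fh.write("********\n")
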