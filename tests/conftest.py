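"""Shared fixtures: hand-built alignments and simulated datasets."""

from __future__ import annotations

import pysam
import pytest

from methhap.io_bisulfite import GenomeIndex, load_genome, load_het_snps, extract_fragments
from methhap.simdata import SimParams, simulate_dataset
from methhap.snp_phase import run_pipeline

NOISELESS = dict(p_hi=1.0, p_lo=0.0, conversion_failure=0.0, seq_error=0.0)


def make_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    })


def make_read(
    header: pysam.AlignmentHeader,
    name: str,
    start1: int,
    seq: str,
    flag: int = 0,
    tid: int = 0,
    xg: str | None = "CT",
    mate_start1: int | None = None,
) -> pysam.AlignedSegment:
    """A fully-matched aligned read at 1-based ``start1``."""
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = tid
    a.reference_start = start1 - 1
    a.mapping_quality = 60
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if xg is not None:
        a.set_tag("XG", xg)
    if mate_start1 is not None:
        a.next_reference_id = tid
        a.next_reference_start = mate_start1 - 1
    return a


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """Simulated noiseless diploid WGBS dataset + pipeline runs.

    Depth 20, 10 planted ASM regions, 50 het SNPs on a 100 kb
    chromosome, with deterministic allele states (p_hi=1, p_lo=0) and
    no conversion failures or sequencing errors.
    """
    outdir = tmp_path_factory.mktemp("noiseless")
    params = SimParams(**NOISELESS)
    truth, paths = simulate_dataset(params, seed=11, outdir=outdir)
    genome = load_genome(paths["fasta"])
    het_snps = load_het_snps(paths["vcf"])
    fragments = list(extract_fragments(str(paths["sam"]), genome, het_snps))
    results = {
        mode: run_pipeline(fragments, het_snps, mode=mode)
        for mode in ("snp", "asm", "asm+snp")
    }
    return {
        "truth": truth,
        "paths": paths,
        "genome": genome,
        "het_snps": het_snps,
        "fragments": fragments,
        "results": results,
    }
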