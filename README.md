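# methhap

Methylation-haplotype phasing from whole-genome bisulfite sequencing
(WGBS), with heterozygous-SNP integration and Hi-C block merging.

## The problem

The two parental alleles of a diploid genome can carry different DNA
methylation patterns (allele-specific methylation, ASM). Because a
bisulfite read reports the methylation state of every cytosine it
covers, reads sampled from opposite alleles at an ASM locus separate
into two coherent patterns — one mostly methylated, one mostly not.
That per-read co-methylation signal identifies ASM regions and, at the
same time, phases any heterozygous SNP the same reads cover, including
SNPs that no pair of reads could link on their own. Hi-C read pairs
then bridge these read-scale blocks over much larger distances.

`methhap` implements that pipeline for epigenomics analyses that need
ASM region calls or read-backed haplotypes from WGBS: ASM detection,
SNP phasing in three modes (SNP-only, methylation-only, combined), and
merging with externally phased Hi-C blocks (e.g. HapCUT2 output).

## The method

For each pair of adjacent *effective* cytosine sites *i*, *j* —
partially methylated (level within [0.1, 0.9]) and covered by at least
4 reads — reads covering both sites are tallied into a 2×2 table

    N_ij = N(M_i,M_j), N(M_i,U_j), N(U_i,M_j), N(U_i,U_j)

(and analogously methylation × SNP allele, N(M,R)…N(U,V), or allele ×
allele). The table is tested with a two-sided Fisher exact test
(minimum-likelihood hypergeometric enumeration, computed with exact
integer arithmetic), p-values are Benjamini–Hochberg-adjusted over all
pairs tested in the run, and a pair is called ASM when

1. adjusted p < 0.05,
2. the two largest cells together exceed 90 % of the covered reads, and
3. the largest cell is under 2× the second largest.

Accepted pairs chain left-to-right into haplotype blocks; each block's
SNPs are assigned to the methylation haplotypes (phase 0 = reference
allele with haplotype A, anchored at the block's first site). WGBS
blocks B and Hi-C blocks H are reconciled per shared SNP by

    S_i = +k if B_i == H_i,  -k if B_i == rev H_i,  0 otherwise,

and merged when the HapScore H_s = |Σ S_i| exceeds 0.9·k·n over n ≥ 2
shared SNPs, flipping H when the sum is negative; one Hi-C block can
chain several WGBS blocks into a single long haplotype.

A bundled simulator (`methhap simulate` / `methhap.simdata`) generates
diploid genomes with planted ASM regions, het SNPs, tiled bisulfite
reads and Hi-C blocks, together with truth tables, so the whole
pipeline is testable without external data.

## Worked example

```bash
methhap simulate --seed 3 --genome-length 30000 --n-asm-regions 3 --n-snps 12 -o demo
methhap asm --fasta demo/sim.fa --bam demo/sim.sam --vcf demo/sim.vcf -o demo/run
methhap merge --wgbs-blocks demo/run.blocks.txt --hic-blocks demo/sim.hic_blocks.txt -o demo/merged
```

prints

```
wrote 5 files under demo
463 ASM pairs in 5 blocks; 11/12 SNPs phased (91.7%)
5+2 blocks -> 2; 12 phased SNPs
```

and `demo/run.asmr.tsv` holds one line per ASM region:

```
chromosome	start	end	LengthofBlock	NumberofCytosines
chr1	2706	4695	1990	155
chr1	8412	10390	1979	155
chr1	18099	20087	1989	147
```

The three ~2 kb blocks are the three planted ASM regions, each chained
from ~150 cytosines. `demo/run.blocks.txt` lists the phased SNPs per
block in a HapCUT2-style format (columns: index, haplotype-A allele,
haplotype-B allele, chromosome, position, ref, alt); 11 of the 12
planted SNPs fall inside or between co-covered sites and get phased
from WGBS alone, and merging with the two simulated Hi-C blocks links
the per-region blocks into 2 chromosome-scale haplotypes carrying all
12 SNPs. Runs are deterministic: the same seed and inputs reproduce
every output byte for byte.

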