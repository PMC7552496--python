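# Methods

## Model and assumptions

A diploid sample contributes bisulfite fragments from two alleles. At a
locus with allele-specific methylation (ASM), the methylation calls of
a fragment are determined (up to noise) by its allele of origin, so two
nearby cytosine sites covered by the same fragments show a 2×2
co-occurrence table concentrated on one diagonal: N(M,M)/N(U,U) when
both sites are methylated on the same allele, N(M,U)/N(U,M) when on
opposite alleles. Heterozygous SNPs behave identically with
(reference, alternate) in place of (methylated, unmethylated), which
is what lets one machinery chain cytosines and SNPs into the same
haplotype blocks.

The method assumes fragments are independent draws from the two
alleles in roughly equal proportion, that methylation states are
stable per allele within a region, and that bisulfite conversion is
near-complete. It phases by physical linkage only — no population
panel, no transmission model.

### Site selection

Sites where both alleles agree carry no signal and dilute the tests:
a fully methylated or fully unmethylated site reads the same from
either allele. Per strand, cytosines are tallied to a methylation
level m/(m+u) and only *effective* sites are kept:

- `meth_low` ≤ level ≤ `meth_high` (defaults 0.1 and 0.9, i.e. the
  "totally" methylated/unmethylated sites are removed); boundary
  values are retained, the removal rules being strict inequalities;
- coverage ≥ `min_cov` (default 4 reads).

### The pair test

For each consecutive pair of effective sites, fragments with calls at
both positions form the 2×2 table. The two-sided Fisher exact test is
computed by hypergeometric enumeration at fixed margins, including
every table whose point probability does not exceed the observed
one. Inclusion is decided on integer weights C(r1,x)·C(r2,c1−x), so
ties at equal likelihood are exact rather than float-dependent; the
returned p is the weight ratio. A table with an empty row or column
admits a single outcome and yields p = 1. Benjamini–Hochberg
adjustment is applied across *all* pairs tested in a run (one
genome-wide multiple-testing family; per-group adjustment is available
through `extend_blocks` for single-region use).

A pair is ASM iff

1. p_adj < `fdr` (default 0.05),
2. (max + second max) cell count > `top2_frac` (default 0.9) × total —
   two patterns explain the reads, and
3. max / second max < `max_ratio` (default 2) — the two patterns are
   balanced, as expected from two alleles at similar dosage.

Criteria 2 and 3 are strict inequalities, so values exactly at the
thresholds fail. A second maximum of zero fails criterion 3 (the ratio
is treated as infinite): a single observed pattern is concordant
methylation, not ASM.

### Blocks and phase

Accepted pairs chain into blocks. The chain is implemented as
connected components over accepted links, which for consecutive-pair
testing is exactly the greedy left-to-right extension: an accepted
pair extends the open block, a rejected or co-coverage-starved pair
closes it. In `asm+snp` mode the tested family also keeps the direct
link between consecutive SNPs when cytosines interleave between them;
this guarantees that adding methylation evidence can only add to what
SNP-only phasing achieves, at the cost that a bridged block may
contain one interior site whose own consecutive test failed.

Within a block, haplotype A is anchored at the first member site
(status M, or R for a SNP) and propagated breadth-first along
accepted links: a diagonal-dominant table preserves status, an
anti-diagonal one flips it, and a tied table carries membership but no
phase information. Each SNP's phase is the majority vote over its
incident informative links; ties and unreachable sites are left
missing. Phase 0 means the reference allele rides on haplotype A.

The ASM-region table reports, per block with ≥ 2 member cytosines:
chromosome, 1-based inclusive start/end at the first and last member
cytosine, end − start + 1, and the cytosine count.

### Hi-C merging

Hi-C-phased blocks (HapCUT2-style files) are reconciled with WGBS
blocks by the consistency score S_i ∈ {+k, −k, 0} per shared SNP
(agree / disagree / either missing) and HapScore H_s = |Σ S_i|. Since
H_s is compared against `min_score_frac`·k·n, k cancels and is kept
only as an explicit weight (default 1). n counts SNPs present in both
vectors; missing phases score 0 and therefore weaken H_s, which is
the conservative direction. A pair of blocks with n ≥ `min_shared`
(default 2) and H_s strictly above the threshold (default fraction
0.9) merges, flipping the Hi-C phases when Σ S_i < 0. Chains through
multiple Hi-C blocks are resolved by union–find with orientation
parity; a parity conflict (a block that must both flip and not flip)
aborts that component's merge with a warning rather than guessing. On
shared SNPs the WGBS assignment wins (read-local evidence over
long-range inference); Hi-C-only SNPs are added in the component's
orientation, and a SNP carried by any WGBS block is never re-emitted
in another block. Merging is deterministic and independent of input
order.

## Input handling

Bisulfite strand comes from aligner tags when present — XG:Z:CT/GA
(Bismark), YD:f/r, ZS — otherwise from FLAG orientation for
directional libraries (read 1 forward = original top strand). On the
original top strand, reference-C positions read C→M, T→U; on the
bottom strand, reference-G positions read G→M, A→U; other read bases
give no call. Context is computed from the reference (CpG default;
CHG/CHH/all selectable). SNP calls match the read base against
ref/alt, and are suppressed entirely where conversion confounds the
alleles (C/T pairs on + fragments, G/A on −), avoiding reference
bias rather than guessing. Read pairs merge into one fragment with
read 1 winning on overlapping positions, whichever mate appears first
in coordinate order.

## The simulator

`simdata` plants the conditions the method is built for:

- **Genome**: A/T filler with CG dinucleotides every 8–16 bp, so every
  cytosine is CpG context and CpG spacing is bounded.
- **ASM regions** (default 10 × 2 kb on 100 kb, ≥ 1 kb apart): the
  methylated allele's CpG states are drawn M with probability `p_hi`
  (default 0.95), the other allele's with `p_lo` (0.05), fixed per
  site. Background CpGs share one state between alleles (methylated
  with probability 0.5) — the bimodal background of real CpG
  methylomes, which the effective-site filter removes.
- **SNPs** (default 50, 60 % inside regions): A↔T substitutions, so no
  CpG is created or destroyed and no allele pair is
  conversion-confounded. In-region SNPs are ≥ 150 bp apart; background
  SNPs form close pairs (≤ 45 bp) or singletons, clusters ≥ 2 fragment
  lengths apart and ≥ 1 fragment length from regions. This keeps every
  truth-expected pair (gap ≤ half a fragment length) strongly
  detectable and avoids gaps in the ambiguous detection zone.
- **Reads**: single-end 100 bp fragments (an overlapping paired-end
  mode exercises mate deduplication), tiling each allele with evenly
  spaced starts at depth/2 per allele — coverage is deterministic, so
  the noise-free limit recovers the plant exactly. Unmethylated
  cytosines are emitted as C (a false M) at the conversion-failure
  rate; substitution errors hit informative bases at the
  sequencing-error rate. Error draws at non-informative filler bases
  are skipped: they cannot change any call.
- **Hi-C**: per chromosome, SNPs are split into contiguous blocks
  (default 2) whose phases equal truth up to one random flip per
  block, with per-SNP error and missing rates.

Randomness derives from one seed through three named streams
(`[seed,0]` truth, `[seed,1]` reads, `[seed,2]` Hi-C); identical seed
and parameters give byte-identical files.

What passing tests on these data do **not** show: robustness to
mapping artefacts, PCR duplicates, coverage fluctuations, CNVs/allelic
imbalance, non-CpG methylation, or incomplete conversion beyond the
modelled uniform rate. The simulator's regularity (tiled coverage,
bounded gaps) is a design choice that makes recovery provable, not a
claim about real libraries.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere in the public model and
  the file formats (SAM/VCF convention).
- The exact test is computed in integer arithmetic; BH adjustment is
  delegated to `statsmodels` (`fdr_bh`) behind `adjust_fdr`.
- In `snp` mode fragments are grouped per chromosome (strand is
  irrelevant to allele calls); in methylation modes per chromosome and
  bisulfite strand, since the two strands' CpG states are assayed
  independently. A SNP can then, in principle, be phased once per
  strand group; the phased fraction counts unique SNPs.
- Degenerate inputs: empty p-value lists, zero-coverage sites and
  zero-total tables raise; an empty block list writes an empty (or
  header-only) table.
- Problem sizes in the validation runs — 100 kb genomes, depth 20–30,
  ten regions, fifty SNPs, five seeds for the noisy condition — were
  chosen so each full pipeline run takes a few seconds while every
  block, pair and phase decision is still exercised many hundreds of
  times per run.

## Known limitations

- Only consecutive effective-site pairs are tested (plus direct
  consecutive-SNP links in `asm+snp` mode), not all co-covered pairs
  within a fragment length.
- ASM calling requires balanced allelic dosage (criterion 3); strongly
  skewed mixtures will fail the ratio test by design.
- Blocks never span strands; symmetric CpG information is not pooled
  across strands.
- The Hi-C merge consumes already-phased blocks; it does not phase raw
  Hi-C read pairs.
- CRAM input and indel phasing are unsupported.
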