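# Methods

## The problem being modelled

A single outbred diploid individual carries two haplotypes that differ at
0.5–3% of bases, by small indels, and by occasional polynucleotide indels
of 100 bp and more. Short-read assembly of such a genome merges
homozygous-enough regions into one consensus and assembles divergent
regions twice, once per haplotype. This produces three linked signatures
that the package measures:

1. a bimodal k-mer multiplicity spectrum (heterozygous k-mers at half the
   homozygous multiplicity);
2. a bimodal contig/gene read-coverage distribution (split regions at 1×
   per-haplotype depth, merged regions at 2×);
3. pairs of near-identical "allelic" contigs that should be collapsed to
   one primary set before scaffolding.

All estimators are exercised against a synthetic diploid generator with
complete ground truth rather than against real sequencing data.

## Synthetic diploid generator (`hetkit.synth`)

Haplotype A is i.i.d. random sequence; repeat families (consensus length
`repeat_unit_len`, copies mutated to 3% divergence, placed at homologous
positions on both haplotypes) are written over it; gene models with
uniform exon (120–300 bp) and intron (60–400 bp) lengths are reserved
*before* repeat placement so that genes stay in unique sequence, as gene
bodies largely do in real repeat-rich genomes. Haplotype B is derived by
planting variants against A:

* **SNPs** at `snp_rate` (default 2.5% — the high end of the regime this
  generator emulates), modulated along each chromosome by mean-normalised
  lognormal factors (σ = 0.5 over 20 kb windows) so per-region
  heterozygosity spans a realistic 0.5–3% band while the genome-wide rate
  stays calibrated; a compensation factor keeps the realised rate at
  `snp_rate` despite exclusion zones around indels.
* **Small indels** at 0.002/base, truncated-geometric lengths 1–20 bp;
  **large indels** at 2×10⁻⁵/base with lengths ≥100 bp (geometric tail).
  The length law is a modelling choice; only the ≥100 bp class boundary is
  treated as meaningful downstream.
* Indels are left-normalised, and two constraints keep truth
  *alignment-identifiable*: indel events are at least 12 bp apart, and no
  SNP is planted within 8 bp of an indel. Without these, optimal
  alignments legitimately re-represent close variant clusters (gap runs
  merge, adjacent substitutions get absorbed into slid gaps) and planted
  counts could not be compared exactly against alignment-derived counts.

Reads are paired-end (150 bp, ~450 bp fragments), sampled independently
from each haplotype at `coverage_per_haplotype` (default 75×), with
substitution errors only. Read bases are stored genome-oriented;
placements are constructed through the planted-variant coordinate map
(an idealised mapper: reads go to their own haplotype's contig when it
exists, otherwise they are projected, CIGAR and soft-clips included, onto
the homologous contig). Transcripts are spliced single-haplotype products
with extra "population" alleles at 0.8% of transcribed bases, always
differing from both haplotype alleles. Read-level population alleles (off
by default) are planted at a random subset of SNP sites — third alleles
segregate at already-polymorphic sites, which is what makes them
observable as ">2 alleles at a site". BAC-like fragments tile the longest
chromosome with fixed ancestral overlaps; each is cut from one haplotype,
with fragment ends nudged outside indel footprints so that overlap truth
is unambiguous.

Two assembly emulations: `fragment_haplotypes` cuts both haplotypes
independently (input for collapse benchmarks); `paired_assembly` cuts
haplotype A with gene-aware breakpoints and keeps the B contig of a piece
exactly when its local variant density exceeds the chromosome mean — the
causal mechanism by which heterozygosity defeats haplotype merging, and
the reason the split-coverage gene group is the more heterozygous one.

Determinism: every stage draws from `numpy` generators seeded as
`[seed, stream]`; identical configs give byte-identical outputs.

## K-mer spectrum (`hetkit.kspec`)

Exact canonical k-mer counting: reads are 2-bit packed into one uint64
array in chunks (k ≤ 31 for packed counting; k must be odd), sorted in
place, and run-length encoded — no sketches, ~2 GB peak for a 100 Mb read
set. The error cutoff is the first non-decreasing bin of the raw
histogram (the error tail decays monotonically; smoothing is not used
here because the empty zero-bin distorts a smoothed minimum). Peaks are
local maxima of a 3-bin moving average above the cutoff; the two highest
maxima at least 1.5× apart in multiplicity are reported (hom = larger);
a candidate below 5% of the main peak's height is noise, yielding a
unimodal verdict rather than a fabricated het peak. Haploid genome size
is above-cutoff k-mer mass divided by the homozygous peak — heterozygous
k-mers sit at half multiplicity, so each het locus automatically
contributes one unit per haplotype. Branch classification samples solid
k-mers and rates each strand direction: exactly two above-cutoff
extensions, both ≤1.5× the het peak, is variant-like; ≥3 extensions or
any extension >1.75× the hom peak is repeat-like. The 1.5×/1.75×
thresholds are this package's concrete rendering of those categories and
are exposed as parameters.

## Allelic collapse (`hetkit.collapse`)

Candidate pairs share ≥10 canonical 21-mers; the diagonal offset is the
median over k-mers unique in both contigs; the implied overlap windows
are aligned with edlib (banded: pairs worse than 35% edit distance are
abandoned — this is what keeps repeat-sharing but non-allelic pairs
cheap). Identity defaults to matches over aligned base pairs with gap
columns excluded (`gap_policy="exclude"`); the alternative convention
(gaps as mismatches) is available but makes a single long indel mask an
otherwise near-identical allelic pair. Selection keeps pairs strictly
above 95% identity and 0.95 overlap fraction (of the shorter contig),
resolves connected components to the longest member (ties:
lexicographic), and collapse partitions the contig set exactly.
Reintegration rebuilds the three final record classes (scaffolds,
unplaced contigs, heterozygous contigs) with N90/N50/N10 summaries.

## Per-gene heterozygosity (`hetkit.hetcall`)

Transcript mapping is seed-and-chain: unique canonical 21-mers anchor
transcript/contig diagonals; anchors cluster into loci (genomic gap >
5 kb splits loci) and into exon-like blocks at diagonal jumps >40 bp.
Because exact seeds cannot start within k bases of an exon junction, a
variant cluster, or the transcript ends, block edges erode exactly where
variant sites concentrate; `_refine_blocks` extends outer edges to the
transcript ends and splits interior junction gaps at the
mismatch-minimising position (rejected above 35% mismatches). Transcript
orientation is chosen by chain coverage, not anchor count — canonical
k-mers match either strand. Filters follow the two-locus procedure:
alignments <30 bp dropped, transcripts with >5 loci dropped as
repeat/conserved-domain artefacts, loci sorted by mismatches and the top
two kept.

Coverage groups: mean depth over the top locus per gene; histogram modes
found with the same peak detector as the k-mer spectrum (adaptive bin
width); boundary = geometric mean of the modes (≈105 for 75/150), upper
bound = 5/3 × high mode; a gene exactly at the boundary is "merged"
(right-closed). Unimodal histograms fall back to a single group with a
flag.

Heterozygosity is measured over the **full transcribed span** (exons and
introns of the mapped locus): for merged genes from the pileup; for split
genes from the edlib alignment of the two locus spans, each substitution
column requiring its allele on ≥2 reads on its own contig and each gap
run counting one site when both flanks are covered. The span denominator
is a deliberate choice: exonic-blocks-only accounting inherits the seed
erosion bias (variant-rich edges drop out of the numerator more than the
denominator), while introns of the two haplotype loci are homologous and
carry the same regional variant rate, so the span estimate is unbiased.
The pileup het rule (depth ≥10, each allele on ≥2 reads, minor fraction
≥0.2) is shared package-wide and was chosen to suppress false sites at a
1% sequencing error rate; indel events count one site at their leftmost
position, with deletion and insertion evidence tracked in dedicated
pileup rows.

Population variance walks the transcript↔top-locus alignment over the
refined blocks: a transcript base matching neither the contig base, any
read-supported base (≥2 reads), nor the homologous second-locus base is a
population-variant site; the denominator is adequately covered aligned
transcript bases.

Synonymous/non-synonymous classification compares codons of aligned
in-frame sequences (standard table); gap runs count as indel events and
the codons they interrupt are skipped; a coding length not divisible by
three after gap removal is an error.

## Fragment overlaps (`hetkit.overlaps`)

Overlap regions (declared truth, or detected by seeding) are aligned
globally with affine gaps (match 2, mismatch −3, open 10, extend 1 — no
published scheme exists for this comparison, so the defaults favour long
clean gap runs). SNP columns are counted per aligned block; each is
read-supported when both alleles appear on ≥2 reads on either fragment's
pileup. Indel events are gap runs with positions and lengths (runs
interrupted by ≤2 match columns are deliberately not merged); the ≥100 bp
subset is tallied inclusively. Third-allele sites are aligned columns
where fragment bases plus read-supported bases (support floor: ≥2 reads
and ≥10% of depth, against sequencing error) exceed two distinct
alleles. Per-fragment heterozygosity uses the shared pileup rule over the
fragment length (SNP sites only by default; indel sites via a flag), and
per-fragment population variance counts >2-allele pileup sites.

## Exon-array combinatorics (`hetkit.combin`)

The isoform count of a locus with tandem arrays of mutually exclusive
exons is the product of array sizes (one exon per array; exon skipping is
out of scope). `enumerate_isoforms` is the brute-force oracle, capped.

## What the synthetic data does and does not show

The generator reproduces: diploid k-mer bimodality, coverage bimodality
driven by het-dependent assembly splitting, allelic-contig structure,
population alleles beyond the individual, and single-haplotype fragment
overlaps. It does not model: base-quality-dependent errors, sequencing
indel errors (flag exists but defaults off), chimeric or misassembled
contigs, repeat-induced misassembly, transcript splice variation, or
mapping ambiguity beyond exact multi-locus placement. Passing tests
therefore demonstrate correctness of the estimators under an idealised
mapper and clean assemblies, not robustness to real-world mapping or
assembly artefacts.

## Problem sizes

Benchmarks use desk-scale genomes: 1 Mb haploid at 50×/haplotype for
spectrum recovery (five/three seeds in tests/script), 200–300 kb for
collapse, het-calling (three SNP settings × ten seeds in tests) and
overlap accounting (ten seeds). These sizes leave hundreds to thousands
of planted events per measurement, so binomial tolerances (3 SDs) and
relative-error bounds (10–20%) are meaningful.

## Known limitations

* Identity/overlap statistics depend on the seed-estimated diagonal;
  highly repetitive contigs with no unique anchors fall back to all
  shared k-mers and can mis-estimate the window.
* The het caller's split arm requires both loci to be mapped by the same
  transcript; genes whose transcripts fail the multi-locus filters are
  absent from the gene table rather than imputed.
* Genome-size estimation assumes the homozygous peak is detected; very
  high repeat fractions with shallow coverage can leave the peak detector
  with a unimodal verdict.
* Exact-truth overlap accounting holds under the generator's variant
  spacing constraints; real data with dense variant clusters has
  genuinely ambiguous alignments, and counts there are
  convention-dependent.
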