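# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
limitations a user should keep in mind.

## The detection problem

A retrocopy is a reverse-transcribed mRNA reinserted into the genome by
LINE-1 machinery: intron-less, poly(A)-tailed, flanked by a target site
duplication (TSD), and nearly identical in sequence to its parent gene's
exons. When the insertion is absent from the reference assembly, reads
from the retrocopy mismap onto the parent gene's exons. This produces
three recoverable signatures: (i) read k-mers spanning exon–exon junctions
that exist in no genomic window; (ii) discordant pairs joining parent
exons to the insertion locus, with soft-clips at the breakpoints; and
(iii) excess exonic depth and carrier-restricted alt alleles at the parent
locus.

## k-mer inventories and the parent-gene call

For each gene the inventory is the set of spliced-transcript k-mers
(k = 30 by default, configurable down to desk scale) with **no** genomic
occurrence — exact or within Hamming distance ≤ 2 — on either strand.
The distance is substitution-only: the filter exists to stop sequencing
errors from turning a genomic k-mer into a false transcript-specific one,
and indel neighbors do not arise that way. k-mers are canonicalized
(lexicographic min of k-mer and reverse complement) in both inventory and
scan because reads are unstranded; k-mers containing N are skipped.
Multiple transcripts of a gene union under the gene id.

A gene is called in a sample when the number of *distinct* inventory
k-mers observed in the reads is strictly greater than `t_min = 5` **and**
at least `f_min = 10%` of the inventory. The 10% denominator is the
specific-k-mer inventory (not all transcript k-mers); both thresholds are
exposed. The implementation packs k-mers into 2-bit uint64 codes (hence
k ≤ 31) and checks Hamming neighborhoods against a sorted genome-k-mer
array, which keeps megabase-scale genomes interactive; tests verify it
against an exhaustive per-window Hamming scan.

## Insertion-site, junction and TSD resolution

Candidate reads overlap a parent exon by ≥1 bp and have a mate on another
chromosome or > `d_max` = 10 kb away; proper pairs and intron-only
overlaps are excluded (retrocopies carry no intron sequence, so
intron-only mates are uninformative). Mate positions are clustered by
single linkage with gap ≤ `cluster_window` = 500 bp; clusters with fewer
than `min_support` = 4 reads are dropped. These defaults were chosen to be
comfortably recoverable at 20× coverage and are all configurable.

Breakpoints come from soft-clips near the cluster: the left breakpoint is
the modal right edge of right-clipped alignments (reads anchored in the
left flank), the right breakpoint the modal left edge of left-clipped
alignments. Because LINE-1 integration duplicates the target site, the
left breakpoint falls *downstream* of the right one and the intervening
reference bases are the TSD; equal breakpoints are a blunt insertion
(TSD null). Modal ties break toward higher clip support, then the
leftmost coordinate. Junction sequences concatenate reference flank with
a per-column majority consensus of the clipped sequences (ties to the
alphabetically first base — deterministic). Clusters without clipped
support are emitted unresolved at cluster resolution with TSD null.
TSD lengths outside 5–50 bp only warn: the plausible range brackets the
empirically observed 10–31 bp without hard-rejecting unusual events.

Parents with k-mer evidence but no resolvable cluster are annotated two
ways: reads containing an exon–exon junction window (last j = 20 bases of
one exon + first j of the next, either orientation) confirm that *some*
retrocopy exists; evidence restricted to ≥ `m_min` = 2 males with zero
females flags a likely Y-linked insertion when the reference lacks a Y.
Reference-assembly retrocopies are classified present / het_absent /
hom_absent from the interval-to-genome depth ratio (< 0.15 hom_absent,
0.15–0.75 with ≥2 deletion-consistent straddling pairs het_absent) — a
deliberately simple read-pair + depth classifier, not a full SV caller.

## Variant attribution, consequences, fixed variants, masking

Pileup is exact counting over exon intervals from M-aligned bases (I/D
CIGAR ops are recorded left-aligned, anchored on the preceding base);
a sample is alt-positive at `r_min = 3` alt reads, guarding against
0.2%-error noise at ~20×. Attribution conditions on carrier status:
retrocopy iff present in ≥1 carrier and 0 non-carriers; parental iff
present in any non-carrier; cohorts without both classes yield only
ambiguous attributions (and a warning) — the reason carrier-only events
must be excluded from attribution studies.

Consequences use the standard genetic code on the annotated CDS:
substitutions mutate one codon (synonymous / missense / nonsense); indel
length mod 3 separates frameshift from in-frame.

"Fixed across all copies" is operationalized numerically: with CN
retrocopy haplotypes mismapping onto 2 parental alleles, a variant carried
by every copy has expected alt fraction CN/(CN+2) at the parent locus, so
a variant is fixed when every carrier's observed fraction reaches
`τ_fixed · CN/(CN+2)` with τ_fixed = 0.5. The half-threshold tolerates
depth noise while still rejecting variants on a minority of copies (a
variant on 5 of 25 copies shows ~0.19 ≪ 0.46). Fixed SNVs are N-masked in
the transcript; indel diagnostics are recorded but not masked (masking is
positional), and unmasking with the diagnostic table restores the input
exactly.

## Copy number, expression partition, TPM

Copy number is region mean depth (M ops only; duplicates assumed removed
upstream) divided by genome-wide mean depth supplied as a per-chromosome
summary — the summary should exclude the amplified region itself, which
at genome scale is negligible but matters on toy genomes. Regions under
1 kb warn. Allele-specific expression assigns each read pair by the
diagnostic alleles it covers: all-parent → parent, all-retro → retro,
conflict or none → unassigned; mates vote jointly because a pair is one
molecule. The reported retro fraction is retro/(retro+parent) — the
unassigned class is excluded from the denominator. TPM is the standard
length-normalized measure (rates normalized to 10⁶).

## Dating and clustering

Divergence is counted over ungapped columns of a pairwise alignment
(S substitutions in L columns, gap columns in neither); toy inputs are
aligned with Needleman–Wunsch (match 1 / mismatch −1 / gap −2), and
precomputed alignments are accepted for real sequences. The age is
`t = (S/L) / (k_lin · μ) · g` with defaults μ = 7.24×10⁻⁹
substitutions/site/generation and g = 8 years (the horse pedigree clock).
`k_lin` defaults to 1 — all divergence attributed to the retrocopy
lineage, matching the arithmetic this estimate is conventionally quoted
with; a two-lineage user can set k_lin = 2, which exactly halves ages.
Raw p-distance is used (no multiple-hit correction): at the divergences of
interest (~1.5%) the correction is below the sampling noise. The 95% CI
across haplotypes is Student-t, appropriate for the very small n involved.

Variant-presence profiles are clustered with Euclidean distance and
average linkage; node support is the fraction of ordinary bootstrap
(column-resampling) replicates containing the node's leaf set, ≥100
replicates, deterministic for a fixed seed. Rows are canonically sorted
before linkage so row order cannot change the result. Approximately
unbiased (multiscale) p-values are not implemented; ordinary bootstrap
support is reported instead.

## The synthetic-data generator

The generator emulates the features the pipeline keys on: multi-exon
genes (introns ≥ 200 bp) on gene-bearing chromosomes with a gene-free
insertion-target chromosome; retrocopies with optional internal exon
skipping (never the terminal exons), 5' truncation, configurable poly(A)
(default 30 bp), and TSDs drawn from the observed 10–31 bp range (default
17 bp, the observed median; an override admits values outside the range);
tandem segmental amplification with pre-duplication (shared) and
post-duplication (private, per-copy) substitutions — tandem by default
since dispersed copies change nothing the read-level evidence sees;
haplotype deletion for the reference-retrocopy check; and Poisson
molecular-clock divergence with a saturation guard at L/2 expected
substitutions.

Reads are 100 bp paired-end, insert 350 ± 35 bp, i.i.d. substitution
errors (default 0.2%), at 20× by default — the regime of the cohorts this
method targets. Alignments are emitted from simulation truth rather than
by a real aligner: every sample-genome base records its provenance, a read
is anchored on its longest single-provenance run (reference runs win
ties), and everything else is soft-clipped; reads inside a retrocopy are
placed on the parent's exons, reproducing the mismapping a mapper commits
against a reference lacking the insertion. Consequences of this
simplification: no mapping-quality model, no chimeric split alignments, no
alignment errors in repeats, single-haplotype samples (diploidy is
emulated where needed by merging two half-coverage haplotype simulations),
no indel sequencing errors, and no base-quality or duplicate modeling.
Passing tests therefore demonstrate the *logic* of each stage under
realistic coverage, error and event-size conditions — not robustness to
aligner artifacts or library-preparation pathologies in real data, where
an externally aligned SAM can be substituted at any stage boundary.

Determinism: one integer seed drives everything; identical configs and
seeds give byte-identical FASTQ/SAM/truth outputs.

## Problem sizes used in the checks

Parent-gene calling is exercised on 1 Mb two-chromosome genomes with 12
genes and 5 implanted retrocopies at 20× (20 seeds); insertion/TSD
resolution on 300 kb genomes with 5 events per seed (20 seeds);
attribution on 8-sample cohorts (3 carriers + 5 non-carriers, 20 seeds);
copy number at true N ∈ {1, 5, 15, 25, 35} (10 seeds each); expression
mixtures at 10,000 pairs; the clock loop at 18 MY with 200 replicates on
2 kb. The acceptance script runs reduced seed counts of the same
computations. These sizes were chosen so the full battery runs on a
single CPU in minutes while keeping binomial/Poisson sampling error well
inside the asserted tolerances.

## Known limitations

- Breakpoint resolution assumes soft-clip evidence survives near the
  insertion; heavily repetitive flanks (not simulated) would degrade it.
- Attribution is presence/absence-based; sites polymorphic in *both*
  parent and retrocopies resolve as parental (the conservative choice).
- The CN/(CN+2) expected fraction assumes one diploid parent locus and
  uniform mappability across copies.
- Dating ignores gene conversion between copies, which homogenizes
  within-species variation and can bias per-copy divergence; only
  single-haplotype (assembly-level) sequences should be dated.
- The VCF/BED emitters cover the minimal columns downstream consumers
  need, not the full specifications.
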