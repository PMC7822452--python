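# Methods

This note documents the models and procedures implemented in `mitovir`,
the parameters that matter, what the synthetic-data generators emulate
(and what they do not), and the numerical choices made where the design
was genuinely open. No empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Sequences, genetic codes and ORF discovery

Sequences are linear DNA/RNA strings over {A,C,G,T,N}; U is normalized
to T on ingest, and coordinates are 0-based half-open on the plus strand
everywhere (GenBank's 1-based inclusive convention is converted at the
I/O boundary by Biopython). Genetic codes are NCBI translation tables
restricted to the biologically relevant set: 1 (standard), 4
(mold/protozoan mitochondrial), 5 (invertebrate mitochondrial) and 16
(chlorophycean mitochondrial). Tables 4, 5 and 16 read TGA as
tryptophan; tables 4 and 5 share a stop set, so ORF *coordinates* are
identical under both and length-based conclusions do not depend on which
mitochondrial table is assumed. Table 5 is the default for viral ORFs
because the candidate hosts of interest are invertebrates.

`find_orfs` reports all maximal ORFs in the six frames: within each
stop-free segment, the ORF runs from the first permissible start codon
to the closing stop (inclusive). The default start policy is ATG-only;
`any_sense_codon` returns full stop-to-stop segments, which is the right
notion for ambigram scans, where a reverse-frame gene need not begin
with ATG. An ORF that runs off the sequence end is reported open
(`closed=False`); `aa_length` always counts coding codons only. Codons
containing N translate to 'X'; N is excluded from composition
denominators.

`ambigram_scan` addresses a narnavirus-specific question: some
capsidless RNA viruses maintain a second long ORF on the reverse
complement of the RdRp gene, which requires avoiding CUA, UUA and UCA
(the reverse complements of the stop codons) in the forward CDS. The
scan reports the longest reverse-strand stop-to-stop ORF overlapping the
forward gene and the observed/expected ratio of the three avoided
codons, with the expectation taken from the CDS mononucleotide
composition. On non-ambigrammatic genomes random reverse-frame segments
of a few hundred codons still occur; the meaningful signal is a reverse
ORF of length comparable to the forward gene.

## Compositional signatures

**Dinucleotide odds ratios.** ρ(xy) = f(xy)/(f(x)·f(y)) with overlapping
dinucleotide counts and mononucleotide frequencies measured on the same
single strand — the analysed genomes are ssRNA(+), so no
strand-symmetrization is applied. The mononucleotide-product expectation
is the default; a uniform (1/16) expectation is available behind a flag
for cross-checking against tools that use it. Ratios on an i.i.d.
sequence converge to 1; the bias classification flags a dinucleotide
when its ratio leaves the closed interval [0.78, 1.25] (values exactly
on a cutoff count as unbiased — the convention is documented because
the boundary itself is arbitrary).

**Codon usage.** Counts are pooled over all CDS of a set; all 64 codons
are reported including stops, as per-1000-*codon* frequencies (the
standard codon-usage-table semantics) summing to 1000 up to rounding,
plus each codon's fraction within its synonymous family under a stated
code. Correlation between usage vectors is computed on the full 64-dim
per-1000 vector: that keeps the comparison code-table-agnostic and
well-defined for pooled inputs.

**UGA(Trp) statistics.** For codes reading TGA as Trp, internal TGA and
all TGG are tallied and UGA(Trp)% = 100·UGA/(UGA+UGG). A TGA that is the
final codon of a CDS is curated as a stop, not a tryptophan, whatever
the table says — in annotated genomes a single trailing "UGA(Trp)" is
almost always the terminator. With zero observed Trp codons the
percentage is undefined and reported as missing.

**Correlation clustering.** Signature vectors are clustered by
average-linkage (UPGMA) hierarchical clustering on distance 1 − r
(Pearson), after which the tree is cut into maximal groups whose members
are *all mutually* correlated at r ≥ 0.8 (the threshold is a parameter).
Groups need at least two members; everything else stays an unassigned
singleton, and zero-variance vectors (undefined r) are excluded up
front. Labels are sorted before linkage so the result is invariant to
input order.

## Small-RNA analysis

**Filtering.** Reads shorter than 20 nt, or with fewer than 80% of bases
at Phred ≥ 20, are discarded (both thresholds configurable).

**Mapping.** Ungapped end-to-end placement on both strands with at most
`max_mm` substitutions (default 1) — the classic short-read-mapper
semantics for this analysis. The implementation uses pigeonhole k-mer
seeding (k = 7; a read split into max_mm+1 blocks has one exact block)
against an index of the reference, which is exhaustive for the genome
sizes this package targets (kilobases, not chromosomes). A
multi-mapping read is placed once, deterministically: fewest mismatches,
then lowest start coordinate, plus strand before minus. Users with their
own mapper can construct an `AlignmentSet` directly.

**Size profiles.** Read counts per (size, strand) over 15–35 nt — the
range covers every small-RNA class of interest — normalized jointly over
all 42 cells, with a Z-score over the same 42 cells for heatmaps and
clustering. A zero-variance spectrum has all Z-scores defined as 0.
Profile clustering reuses the UPGMA/threshold machinery on the Z-score
vectors.

**5′ base enrichment.** For each (size, strand) cell with ≥ 20 reads,
each base's 5′ count gets a two-sided exact binomial test against the
base composition of the read-bearing reference strand,
Bonferroni-corrected by 4 within the cell; a base is flagged when the
adjusted p < 0.05 *and* its observed fraction exceeds the expectation.
This per-cell binomial formulation is deliberately simple and
conservative; the measured false-flag rate under unbiased starts is
reported by the acceptance script (about 2% of tested cells).

**ECDF/KS comparison.** The Kolmogorov–Smirnov D statistic between two
read-size distributions is the maximum ECDF gap. Read sizes are small
integers, and the classical asymptotic null assumes continuity: with
this many ties it is badly conservative (measured type-I rate ~1% at
nominal 5%). The default p-value is therefore a permutation test —
sample-A counts are redrawn per size bin from the pooled counts
(multivariate hypergeometric, 999 permutations), which is exact up to
Monte-Carlo error under the null and measures at 5% rejection for 5%
nominal. The classical asymptotic p remains available via
`method="asymp"` for comparison with continuous-theory tools.

**Signature classification.** Rule-based, with all thresholds in
`ClassifyConfig`:

* *piRNA-like*: pooled modal size 24–30 with a clear peak (modal cell ≥
  10% of reads), 5′-U preference on the dominant strand, strand
  asymmetry (+/− ratio outside [1/3, 3]);
* *fungal siRNA-like*: modal size 20–22 on both strands, near-symmetric
  strands, 5′-U preference in a modal cell;
* *insect siRNA-like*: modal size 19–23 on both strands, near-symmetric
  strands, no 5′ preference;
* otherwise *none*.

A "5′-U preference" requires both the binomial flag and an observed U
fraction ≥ 0.5: the biological signature is a strong majority
preference, and demanding it keeps a marginally significant tilt in an
unbiased library from misclassifying an insect-siRNA profile. With
these defaults each preset at 10,000 reads is recovered in 100/100
seeded replicates (recomputed by the acceptance script).

## Seed-driven progressive assembly

A deliberately small seed-and-extend assembler for desk-scale targeted
reconstruction, not a production assembler. Each round: recruit reads
with an ungapped overlap of ≥ `min_overlap` (default 20 nt) and ≤
`max_mm` substitutions (default 1) against the current contig, either
strand; then extend each end one column at a time by majority vote of
the overhanging bases, requiring `min_depth` support (default 2; use 3
for noisy reads). Ties break toward the lexicographically smallest
base, making the whole procedure deterministic. Iteration stops when
neither end grows or after `max_rounds`. Overlaps are
substitution-only (no indels), consistent with the error model of the
synthetic read generator; contig length is non-decreasing by
construction, and on error-free tiling reads the reconstruction is exact
up to end effects smaller than a read length.

## Abundance, EVE screening and evidence integration

Abundance is reads-per-million: RPM = mapped·10⁶/total. The
exogenous-vs-EVE decision from a DNA library is three-valued:
*exogenous* when the positive control (host mitochondrial RPM ≥ 10)
works, the virus is essentially absent from DNA (RPM ≤ 0.1) and present
in RNA; *candidate_EVE* when viral DNA reads clearly exceed that
ceiling; *indeterminate* otherwise. The defaults are declared, not
derived — "complete absence" has no universal quantitative boundary
against index-hopping and cross-mapping background, so both thresholds
are configurable and logged.

The evidence report evaluates eight criteria: (1) phylogenetic
placement — outside this package, always `not_evaluated`; (2) AT-content
closeness to each candidate host mitochondrion; (3) codon-usage cluster
co-membership at r ≥ 0.8; (4) UGA(Trp)% concordance; (5) dinucleotide
profile correlation; (6) small-RNA signature class; (7) prevalence
across RNA libraries of the sampled organism; (8) RNA abundance combined
with the EVE status. Closeness criteria return *neutral* inside a margin
(2 points AT, 5 points UGA%, 0.05 in r) so coin-flip differences never
count as support; criteria with missing inputs are `not_evaluated`. The
overall call names a host group only when ≥ 4 evaluated criteria support
it and none supports the alternative — a deliberately conservative
operationalization of a narrative argument, with every raw number
carried in the report so users can re-weigh the evidence. The voting
rule is monotone: removing a supporting criterion can only weaken the
call.

Criteria 7 and 8 support the *sampled* organism's host group
(`EvidenceConfig.sampled_group`): prevalence in many libraries of one
organism is evidence about that organism, which the configuration makes
explicit rather than implicit.

## Synthetic data: what it emulates, and what it does not

**Viral genomes.** `gen_viral_genome` emits one long ORF (ATG…TAA) under
a chosen code with untranslated flanks, a requested AT content, and a
requested fraction of Trp codons encoded as TGA. Amino acids are drawn
from an average globular-protein composition (Trp 1.3%, so an
804-codon ORF carries ~8–17 Trp codons); AT is tuned only at free flank
positions and synonymous wobble positions (same first two bases), so the
protein and the UGA/UGG split are never perturbed, and the residual
tolerance is ±2 percentage points. The requested UGA fraction is
realized at the nearest achievable value given the drawn Trp count
(e.g. 12/17 = 70.6% for a 73.3% request) and recounted into the emitted
truth. Infeasible requests — a UGA fraction under the standard code, an
AT target outside the reachable range — raise an explicit error rather
than drifting. The `MITOVIRUS_PRESET` (2697 nt, 804 codons, table 5,
69.74% AT, 73.3% UGA(Trp)) is the package's reference genome for an
insect-mitovirus-like sequence.

**Codon-usage families.** A family is one skewed base table (wobble
positions AT-rich with probability `at3_bias`) with members drawn as
high-concentration Dirichlet jitter around it. At the two default
settings (0.9 vs 0.6) within-family codon-usage vectors stay at Pearson
r ≥ 0.95 while between-family pairs sit near 0, so threshold clustering
at 0.8 has a comfortable margin. An optional parameter pins the TGA
share of the Trp mass for building hosts and viruses with prescribed
UGA(Trp) usage.

**Small-RNA reads.** Sizes follow a discretized Gaussian truncated to
15–35 nt (matching the unimodal peaks of real virus-derived small-RNA
spectra without inventing a new distribution); strands are Bernoulli;
the 5′-base bias is implemented by partitioning start positions by their
5′ base and sampling the matching class with exactly the requested
probability, so every read remains an exact substring of the reference.
Presets: insect siRNA (21 ± 1.6 nt, symmetric, no bias), fungal siRNA
(21 ± 1.2 nt, symmetric, 5′-U at 0.85), piRNA (27 ± 1.8 nt, 85% plus
strand, 5′-U at 0.9). The siRNA strand ratio of 0.5 reflects symmetric
dicing of dsRNA replication intermediates; it is a modeling choice, as
is the piRNA asymmetry level.

**Long reads and DNA libraries.** Tiling reads at a requested coverage
with i.i.d. substitution errors; DNA libraries draw a
Binomial(n, viral_fraction) share of reads from the viral genome when an
integration is simulated, and zero otherwise.

**What passing tests do not show.** The generators produce no sequencing
adapters, PCR duplicates, indels, quality-score structure, chimeras, or
contaminating taxa; real libraries have all of these. Mapping and
assembly results on synthetic data therefore bound the method's
behaviour under its own error model, not under real instrument error.
The host-assignment scenarios use two cleanly separated candidate
families; real candidate panels can be compositionally intermediate, in
which case the margins push criteria to *neutral* and the overall call
to *indeterminate* — the designed failure mode.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen
to exercise every code path with stable statistics: 10,000-read
small-RNA libraries (100 replicates per preset), 500 KS replicate pairs
at n = 2000, 200 enrichment replicates at n = 1000, 2000–4000-codon CDS
sets, 3-kb genomes at 30× for assembly, and 20 clustering replicates.
These are the package's own defaults for validation, and all scale
linearly if larger runs are wanted.
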