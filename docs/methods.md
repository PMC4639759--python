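# Methods

axokit characterizes very large genomes — the giant, repeat-rich genomes of
salamanders being the motivating case — from shotgun read sets and
single-chromosome capture libraries, without requiring a genome assembly.
This note records the models behind each module, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## K-mer spectrum model

For reads of length `L`, every read contributes `L − k + 1` k-mers, each
counted in canonical form (the lexicographic minimum of the k-mer and its
reverse complement; `k` is restricted to odd values so that no k-mer can
equal its own reverse complement and canonicalization is unambiguous).
The multiplicity spectrum `f(m)` — distinct canonical k-mers seen exactly
`m` times — decomposes additively by origin:

- **error**: k-mers created by sequencing error, piled at low `m`;
- **2N (diploid single copy)**: a hump at the k-mer coverage `C_k`,
  because a homozygous single-copy k-mer is sampled from both haplotypes;
- **1N (allelic)**: a secondary hump near `C_k/2` from heterozygous sites,
  each haplotype-private k-mer being sampled from one haplotype only;
- **repeat**: a long right tail, with a family at copy number `c` peaking
  near `c·C_k`.

From the fitted single-copy peak follow:

- base coverage via the read-end undersampling correction
  `C_base = C_k · L/(L − k + 1)` (a base near a read end sits in fewer
  than `k` windows, so k-mers undersample bases by exactly this factor);
- genome size `G = Σ_{m>m_err} m·f(m) / C_k` (every genomic base
  contributes ~`C_k` k-mer observations regardless of copy number, so the
  genomic k-mer mass divided by `C_k` is the haploid length);
- the single-copy fraction: the share of genomic k-mer mass with
  `m ∈ [max(m_err+1, mean − 3σ), mean + 3σ]`. Mass-based (not
  distinct-k-mer-based) because mass is directly in genome-length units; a
  distinct-k-mer variant is available behind the `distinct=True` flag.

### Numerical decisions

- **Error cutoff** `m_err`: the first local minimum of `f(m)` scanning up
  from `m = 1` (`f(m) ≤ f(m−1)` and `f(m) < f(m+1)`). A histogram with no
  valley (no error/signal separation) is an error, not a silent guess.
- **Peak statistics.** The mode is the argmax of `f(m)` above the cutoff,
  ties broken toward the lower multiplicity for determinism. A provisional
  width `σ₀` is the standard deviation of the peak's left half reflected
  about the mode — the right flank is contaminated by low-copy repeats,
  the reflected left half is not. The **mean** is then the centroid of
  `f(m)` over `[m_err+1, mode + 3σ₀]`, clipped to within ±1 of the mode.
  This choice matters: the sampling distribution of single-copy k-mer
  multiplicity is right-skewed (Poisson-like), so the sub-bin peak
  *location* (e.g. a parabolic vertex) sits below the component *mean*
  that the genome-size identity requires; on simulations the centroid
  removes a ~4% systematic overestimate of `G`. Two near-tied modal bins
  yield the half-integer between them, and an exactly symmetric peak
  yields its centre, as a symmetric-sampling assumption demands. `σ` is
  finally recomputed by left-half reflection about the fitted mean.
- **Decomposition.** The 1N component is estimated by mirror subtraction:
  below the mode the 2N peak should be symmetric, so the excess of `f(m)`
  over its mirror image `f(2·mode − m)` on `(m_err, mode)` is attributed
  to the 1N hump; the 2N component is the remainder below the mode plus
  its truncated reflection above; the repeat component is whatever is
  left above the cutoff. Components re-sum to the observed spectrum
  exactly at every multiplicity, by construction. When the expected 1N
  centre `C_k/2` lies at or below the error cutoff the 1N component is
  zeroed with a warning — heterozygous signal is then indistinguishable
  from error.
- **Copy-number spectrum.** `cn(m) = m / C_k`, carrying genome fraction
  `m·f(m)` over the genomic mass. The per-chromosome band flags
  `cn ∈ (hi/C_k, n_chrom · hi/C_k]` (default 14 chromosome pairs):
  sequence that could still be single copy with respect to one
  chromosome.
- **Histogram bounds.** Default `k = 21` (the mathematics is identical at
  any odd `k`; 21 keeps desk-scale memory) and cap 100 000 with
  multiplicities at or beyond the cap pooled — the pooled bin keeps its
  exact k-mer mass so conservation `Σ m·f(m) = k-mers counted` holds on
  every input.

## Depth profiling

Per-base depth over reference intervals counts aligned read bases (CIGAR
`M/=/X`) from primary, non-duplicate records at or above a MAPQ threshold;
deletions advance the reference without depth. Duplicates are excluded by
default because amplified (WGA) libraries are duplicate-heavy. Bases with
depth in a single-copy range (default `[1, 40]`, configurable) define an
alignment-based single-copy fraction, extrapolated to genome scale by
multiplying by `G`. A three-column depth TSV is accepted in place of SAM
so external depth tools can be used directly.

`exact_map_sam` places error-free reads by exact substring search, first
verifying occurrence wins. Reads drawn from every copy of a repeat
therefore pile onto its first occurrence in the reference — the behaviour
that makes depth proportional to genome-wide copy number when the
reference interval holds one copy, as with BAC-sized references inside a
much larger genome. It is a deliberate idealization for simulated,
substitution-only reads, not a general-purpose aligner.

## Capture-library validation

Reads are credited to mapped markers by shared canonical 31-mer seeds
(default `min_seeds = 2`); the marker sharing the most seeds wins and ties
are discarded as paralog-ambiguous, so every credited read maps to exactly
one marker. Marker recovery is presence/absence (≥ 1 hit read) rather than
read counts because amplification bias makes per-marker counts unreliable.
Per linkage group, enrichment requires *both* a one-sided binomial test of
recovered markers at the pooled off-target background rate
(`alpha = 10⁻³`) *and* a recovery fold ≥ 5 — the conjunction guards
against significant-but-tiny effects and against tiny-background false
calls; a zero background with any recovery is enriched by convention.
Linkage groups co-enriched in the same library in ≥ 2 independent
libraries are joined; connected components become chromosomes, and an
unjoined LG with ≥ 2 supporting libraries becomes a single-LG chromosome.
Two libraries of independent support mirror the replication logic that
justifies merging linkage groups at all.

## Synteny

Chromosome-level enrichment is the observed ortholog count over the
chromosome's annotated gene total, with a one-sided hypergeometric
p-value (draws = total orthologs, from a universe partitioned by the
annotation) as a principled null for an observed/annotated ratio. Block
segmentation sorts ortholog positions and splits where a
consecutive-gene gap exceeds a threshold (chromosome length / 10 when the
length is known, else 10 Mb), discarding blocks of fewer than 5 genes so
that single strays do not masquerade as conserved segments; discarded
gene counts are recorded so totals stay conserved. The module reports
block structure only — it does not infer fusion, inversion or duplication
mechanisms.

## Assembly statistics

Contigs are maximal runs free of `N`-gaps (gap = run of ≥ `gap_min` Ns,
default 1, matching assemblers that emit `N`-filled gaps). N50 is the
largest piece length such that pieces at least that long cover half the
total. A singleton is a scaffold that is a single gapless contig;
"proportion scaffolded" is the count-based share of non-singleton
scaffolds, with a length-based variant and an
unscaffolded-contig singleton variant behind flags, since both readings
of the standard report columns are defensible. Improvement percentages
between assembly versions are rounded to the nearest integer, halves away
from zero. One property worth noting: N50 is *not* monotone under growing
a single piece (growing a small piece can shift the half-total past the
largest piece and lower the N50); the suite asserts the invariants that
do hold — permutation invariance, scale equivariance and the half-total
coverage guarantee.

## Synthetic data: what it emulates, and what it does not

`build_genome` draws a uniform-random single-copy background, inserts
each repeat family's copies (a master unit independently mutated per copy
at the family divergence) at uniform positions — insertion, never
overwriting, so truth fractions are exact — and derives the second
haplotype by per-site substitution at the heterozygosity rate. Every
position carries a truth label. `simulate_reads` samples read (or
fragment) starts uniformly, or window-wise with gamma-distributed weights
(mean 1, variance = dispersion) under capture bias, emulating the over-
and under-amplification of whole-genome-amplified single-chromosome
libraries; errors are substitution-only; FASTQ qualities are constant
because nothing downstream uses them.

Deliberately not modelled: indels and structural variants, quality-score
profiles, GC bias, PCR chimeras, transposition dynamics, and nested or
tandem-structured repeat placement. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
robustness to every artefact of real libraries.

### Test and validation problem sizes

Simulated validations run at desk scale, chosen to exercise every code
path while keeping the default suite fast: the parameter-recovery study
uses a 2 Mb diploid genome (1.4 Mb single copy plus satellite-like,
LTR-like and LINE-like families totalling 30% repeat bases at divergences
0.002–0.01), heterozygosity 5×10⁻⁴ (inbred laboratory-strain scale), 15×
coverage, 0.5% error, `k = 21`, three seeded replicates; capture-library
validation uses 12 linkage groups × 10 markers with libraries of 500
reads at ≤ 10% off-target content (2% cross-LG marker carryover plus 8%
anonymous genomic background), twenty seeded replicates; counter/oracle
equivalence runs on inputs up to 1 Mb. Identical seeds give byte-identical
genomes, read sets and results throughout.

## Known limitations

- K-mer counting holds all packed k-mers in memory (`k ≤ 31`); it is
  meant for desk-scale validation and histogram production, not for
  counting hundreds of gigabases (use a dedicated counter and load its
  two-column histogram instead).
- The spectrum model is moment-based, not a full mixture likelihood;
  heterozygosity close to the error band, or coverage low enough that the
  1N and error components merge, degrades the decomposition first.
- The exact mapper requires substitution-free agreement with the
  reference and is unsuitable for real error profiles.
- Enrichment thresholds (`alpha`, fold, support) are operating points
  chosen for well-separated capture libraries, not universal constants.
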