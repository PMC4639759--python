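# axokit

Characterization of very large genomes from shotgun and single-chromosome
capture sequencing — without a genome assembly.

Some of the most informative model organisms have genomes too large and
repeat-rich to assemble outright; the Mexican axolotl's ~32 Gb genome is
the canonical example. axokit implements the analytics that make such
genomes tractable before (and alongside) assembly:

- **k-mer spectrum modelling** (`axokit.spectrum`): count canonical
  k-mers, locate the error/signal valley, fit the single-copy coverage
  peak, and estimate base coverage, genome size, the single-copy fraction,
  the 1N/2N/repeat decomposition and the repeat copy-number spectrum;
- **alignment-depth profiling** (`axokit.depth`): per-base depth over
  reference intervals with MAPQ filtering, single-copy/repeat
  classification by depth, and genome-scale extrapolation;
- **capture-library validation** (`axokit.assign`): match reads from
  laser-captured, amplified single-chromosome libraries to genetically
  mapped markers, call per-linkage-group enrichment, and coalesce linkage
  groups into chromosomes from replicated co-enrichment;
- **conserved synteny** (`axokit.synteny`): ortholog enrichment per
  reference chromosome with hypergeometric p-values, and gap-based
  synteny-block segmentation;
- **assembly statistics** (`axokit.asmstats`): contig/scaffold N50,
  singleton counts, scaffolding proportions, improvement percentages;
- **synthetic data with ground truth** (`axokit.simulate`): diploid
  genomes with specified repeat families, heterozygosity, and shotgun or
  capture-biased read sampling, so every estimator can be validated
  against known truth.

## The core model

For reads of length `L`, the multiplicity spectrum `f(m)` of canonical
k-mers separates sequencing error (low `m`), heterozygous single-copy
sequence (a 1N hump near `C_k/2`), homozygous single-copy sequence (the
2N peak at the k-mer coverage `C_k`) and repeats (a tail at `c·C_k` for
copy number `c`). With `m_err` the error cutoff and `C_k` the fitted peak
mean:

```
C_base = C_k · L / (L − k + 1)            # read-end undersampling correction
G      = Σ_{m > m_err} m · f(m) / C_k     # haploid genome size
single-copy fraction = mass with m in [max(m_err+1, C_k − 3σ), C_k + 3σ]
                       over the genomic mass
```

See `docs/methods.md` for estimator details and design rationale.

## Worked example

```python
import axokit as ak

spec = ak.GenomeSpec(
    single_copy_length=700_000,
    repeat_families=(
        ak.RepeatFamilySpec("ltr", unit_length=2000, copy_number=100, divergence=0.005),
        ak.RepeatFamilySpec("satellite", unit_length=200, copy_number=500, divergence=0.002),
    ),
    heterozygosity=0.001,
    seed=42,
)
genome = ak.build_genome(spec)
reads = ak.simulate_reads(
    genome, ak.ReadSimSpec(coverage=18, read_length=100, error_rate=0.005, seed=43)
)
hist = ak.count_kmers(reads, k=21)
model = ak.fit_coverage_model(hist, read_length=100)
```

Printing the fitted model gives:

```
true genome size     : 1,000,000 bp (70.0% single copy)
error cutoff         : m <= 5
k-mer coverage C_k   : 12.70 (mode 12, sigma 3.34)
base coverage C_base : 15.87x
genome size estimate : 1,027,733 bp
single-copy window   : [6.00, 22.71]
single-copy fraction : 71.8% (737,694 bp)
```

The 1 Mb truth (700 kb single copy + 300 kb of repeats) is recovered to
within 3%, and the single-copy fraction to within 2 points. `C_k` sits
below the nominal 18× because a read of length 100 yields only 80
21-mers and 0.5% per-base error voids ~10% of k-mer windows; the
`C_base` correction restores the base-level scale.

The same analyses are available from the shell:

```
axokit simulate-genome --config genome.yaml --seed 42 --out g
axokit simulate-reads --genome g.fasta --coverage 18 --error 0.005 --seed 43 --out r
axokit kspec count -k 21 --out hist.tsv r.fastq
axokit kspec fit --hist hist.tsv --read-length 100 -k 21 --out model.json
axokit kspec report --hist hist.tsv --model model.json --out report
axokit depth profile --sam r.sam --min-mapq 0 --out track.tsv
axokit assign match --markers markers.fa --map map.tsv --reads lib.fastq \
    --library-id lib3 --out hits.tsv
axokit synteny blocks --orthologs orthologs.tsv --chrom GG5 --out blocks.bed
axokit asmstats --fasta assembly.fa --out stats.tsv
```

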