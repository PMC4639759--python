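"""Synthetic diploid genomes with known repeat structure, and read simulation.

The simulator builds a diploid genome from a single-copy background plus
repeat families of specified unit length, copy number and per-copy
divergence, applies heterozygosity between the two haplotypes, and samples
shotgun reads — optionally with the window-level amplification bias that
characterizes whole-genome-amplified single-chromosome capture libraries.
Every position of the genome carries a ground-truth class label
(``single_copy`` or a repeat-family label), so downstream estimators of
genome size, single-copy fraction and repeat copy number can be tested
against exact truth.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._encode import canonical_str, decode, encode

SINGLE_COPY = "single_copy"


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family: a master unit copied ``copy_number`` times.

    Each copy is mutated independently at ``divergence`` substitutions per
    base before insertion, so families model anything from young
    high-identity satellites (divergence ~0) to decayed transposon
    relics (divergence up to 0.5).
    """

    label: str
    unit_length: int
    copy_number: int
    divergence: float

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError("unit_length must be positive")
        if self.copy_number < 2:
            raise ValueError("copy_number must be >= 2 (a repeat repeats)")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must lie in [0, 0.5]")

    @property
    def total_bases(self) -> int:
        return self.unit_length * self.copy_number


@dataclass(frozen=True)
class GenomeSpec:
    single_copy_length: int
    repeat_families: tuple[RepeatFamilySpec, ...] = ()
    heterozygosity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.single_copy_length < 1:
            raise ValueError("single_copy_length must be positive")
        if not 0.0 <= self.heterozygosity <= 0.05:
            raise ValueError("heterozygosity must lie in [0, 0.05]")
        object.__setattr__(self, "repeat_families", tuple(self.repeat_families))
        labels = [f.label for f in self.repeat_families]
        if len(set(labels)) != len(labels):
            raise ValueError("repeat family labels must be unique")

    @property
    def total_length(self) -> int:
        return self.single_copy_length + sum(f.total_bases for f in self.repeat_families)


@dataclass
class SimulatedGenome:
    """Two equal-length haplotypes plus a per-position truth mask.

    ``mask`` holds small integer codes; ``mask_labels[code]`` gives the class
    label (``single_copy`` or a family label).  Haplotypes are stored as
    uint8 code arrays; the ``haplotypes`` property decodes to strings.
    """

    hap_codes: tuple[np.ndarray, np.ndarray]
    mask: np.ndarray
    mask_labels: tuple[str, ...]
    spec: GenomeSpec | None = None

    @property
    def total_length(self) -> int:
        return int(self.hap_codes[0].size)

    @property
    def haplotypes(self) -> tuple[str, str]:
        return decode(self.hap_codes[0]), decode(self.hap_codes[1])

    def class_fractions(self) -> dict[str, float]:
        """Fraction of haploid genome length in each truth class."""
        counts = np.bincount(self.mask, minlength=len(self.mask_labels))
        return {lab: counts[i] / self.total_length for i, lab in enumerate(self.mask_labels)}

    def single_copy_fraction(self) -> float:
        return self.class_fractions().get(SINGLE_COPY, 0.0)

    def to_fasta(self, path: str | Path, name: str = "genome") -> None:
        with open(path, "w") as fh:
            for i, hap in enumerate(self.haplotypes, start=1):
                fh.write(f">{name}_hap{i}\n")
                for j in range(0, len(hap), 80):
                    fh.write(hap[j : j + 80] + "\n")

    def truth_table(self, path: str | Path) -> None:
        """Write the per-position class table as TSV (1-based, run-length)."""
        with open(path, "w") as fh:
            fh.write("start\tend\tclass\n")
            mask = self.mask
            boundaries = np.flatnonzero(np.diff(mask)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [mask.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{s + 1}\t{e}\t{self.mask_labels[mask[s]]}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SimulatedGenome":
        """Load a two-record FASTA as a genome (truth mask all single-copy)."""
        haps: list[np.ndarray] = []
        with open(path) as fh:
            from Bio.SeqIO.FastaIO import SimpleFastaParser

            for _title, seq in SimpleFastaParser(fh):
                haps.append(encode(seq))
        if len(haps) == 1:
            haps.append(haps[0].copy())
        if len(haps) != 2 or haps[0].size != haps[1].size:
            raise ValueError("expected one or two equal-length FASTA records")
        mask = np.zeros(haps[0].size, dtype=np.int16)
        return cls(hap_codes=(haps[0], haps[1]), mask=mask, mask_labels=(SINGLE_COPY,))


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (never to itself)."""
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def build_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Construct a diploid genome per the spec; deterministic under its seed.

    Repeat copies are *inserted* into the single-copy background (never
    overwritten), so the truth mask accounts for every base exactly and the
    single-copy fraction equals ``single_copy_length / total_length``.
    """
    rng = np.random.default_rng(spec.seed)
    repeat_bases = sum(f.total_bases for f in spec.repeat_families)
    if repeat_bases > 10 * spec.single_copy_length:
        warnings.warn(
            "repeat bases exceed 10x the single-copy background; "
            "the genome will be dominated by repeats",
            stacklevel=2,
        )

    background = rng.integers(0, 4, size=spec.single_copy_length, dtype=np.uint8)
    labels = (SINGLE_COPY,) + tuple(f.label for f in spec.repeat_families)

    # One (insertion point, family code, copy codes) triple per copy.
    copies: list[tuple[int, int, np.ndarray]] = []
    for fam_code, fam in enumerate(spec.repeat_families, start=1):
        unit = rng.integers(0, 4, size=fam.unit_length, dtype=np.uint8)
        for _ in range(fam.copy_number):
            insert_at = int(rng.integers(0, spec.single_copy_length + 1))
            copies.append((insert_at, fam_code, _mutate(unit, fam.divergence, rng)))
    copies.sort(key=lambda t: t[0])

    seq_parts: list[np.ndarray] = []
    mask_parts: list[np.ndarray] = []
    prev = 0
    for insert_at, fam_code, copy_codes in copies:
        seq_parts.append(background[prev:insert_at])
        mask_parts.append(np.zeros(insert_at - prev, dtype=np.int16))
        seq_parts.append(copy_codes)
        mask_parts.append(np.full(copy_codes.size, fam_code, dtype=np.int16))
        prev = insert_at
    seq_parts.append(background[prev:])
    mask_parts.append(np.zeros(spec.single_copy_length - prev, dtype=np.int16))

    hap1 = np.concatenate(seq_parts)
    mask = np.concatenate(mask_parts)
    hap2 = _mutate(hap1, spec.heterozygosity, rng)
    return SimulatedGenome(hap_codes=(hap1, hap2), mask=mask, mask_labels=labels, spec=spec)


@dataclass(frozen=True)
class ReadSimSpec:
    coverage: float
    read_length: int = 100
    paired: bool = False
    insert_size: int = 300
    error_rate: float = 0.0
    bias: str = "none"  # "none" | "capture"
    bias_window: int = 10_000
    bias_dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.bias not in ("none", "capture"):
            raise ValueError("bias must be 'none' or 'capture'")
        if self.bias == "capture" and self.bias_dispersion < 0:
            raise ValueError("bias dispersion must be >= 0")
        if self.paired and self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length for paired reads")


@dataclass
class ReadSet:
    """Simulated reads plus their ground-truth origins.

    ``codes`` is an (n_reads, read_length) uint8 matrix of read sequences
    (already reverse-complemented for minus-strand reads and with errors
    applied).  Truth arrays record the source haplotype (0/1), the 0-based
    reference start of the read on the genome, and the strand (+1/-1).
    """

    codes: np.ndarray
    hap: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    mate: np.ndarray | None = None  # 0 = unpaired/first, 1 = second in pair
    reference_length: int = 0
    reference_name: str = "genome"

    @property
    def n_reads(self) -> int:
        return int(self.codes.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.codes.shape[1])

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def to_fastq(self, path: str | Path, quality: str = "I") -> None:
        """Interleaved FASTQ with constant quality symbols."""
        qual = quality * self.read_length
        with open(path, "w") as fh:
            for i, row in enumerate(self.codes):
                suffix = "" if self.mate is None else f"/{self.mate[i] + 1}"
                fh.write(f"@read{i}{suffix}\n{decode(row)}\n+\n{qual}\n")

    def to_sam(self, path: str | Path) -> None:
        """Truth alignments as single-end SAM against haplotype-1 coordinates.

        Positions are exact by construction (substitution-only errors), so
        this stands in for an external aligner on error-free or low-error
        simulations.
        """
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            fh.write(f"@SQ\tSN:{self.reference_name}\tLN:{self.reference_length}\n")
            cigar = f"{self.read_length}M"
            for i, row in enumerate(self.codes):
                flag = 16 if self.strand[i] < 0 else 0
                seq = decode(row)
                fh.write(
                    f"read{i}\t{flag}\t{self.reference_name}\t{self.start[i] + 1}\t"
                    f"60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                )


def simulate_reads(genome: SimulatedGenome, spec: ReadSimSpec) -> ReadSet:
    """Sample shotgun reads from a diploid genome.

    Expected total bases = ``coverage x haploid genome length``; reads are
    drawn from the two haplotypes with equal probability.  Under
    ``bias="capture"`` fragment starts are drawn window-wise with
    gamma-distributed sampling weights (mean 1, variance = dispersion),
    emulating the over/under-amplification of whole-genome-amplified
    single-chromosome libraries; ``bias="none"`` gives uniform starts.
    """
    rng = np.random.default_rng(spec.seed)
    glen = genome.total_length
    rl = spec.read_length
    frag = spec.insert_size if spec.paired else rl
    if frag > glen:
        raise ValueError(f"fragment length {frag} exceeds genome length {glen}")

    if spec.paired:
        n_frags = max(1, round(spec.coverage * glen / (2 * rl)))
    else:
        n_frags = max(1, round(spec.coverage * glen / rl))
    max_start = glen - frag  # inclusive

    if spec.bias == "capture" and spec.bias_dispersion > 0:
        n_win = max(1, -(-glen // spec.bias_window))
        # Gamma with mean 1, variance = dispersion.
        shape = 1.0 / spec.bias_dispersion
        weights = rng.gamma(shape, scale=spec.bias_dispersion, size=n_win)
        win_starts = np.arange(n_win) * spec.bias_window
        win_sizes = np.minimum(spec.bias_window, glen - win_starts)
        p = weights * win_sizes
        p /= p.sum()
        windows = rng.choice(n_win, size=n_frags, p=p)
        offs = rng.random(n_frags)
        starts = (win_starts[windows] + offs * win_sizes[windows]).astype(np.int64)
        starts = np.minimum(starts, max_start)
    else:
        starts = rng.integers(0, max_start + 1, size=n_frags)

    haps = rng.integers(0, 2, size=n_frags)
    flip = rng.random(n_frags) < 0.5  # fragment orientation

    offsets = np.arange(rl)
    if spec.paired:
        r1 = starts[:, None] + offsets  # left read, forward
        r2 = (starts + frag - rl)[:, None] + offsets  # right read, reverse
        read_starts = np.concatenate([starts, starts + frag - rl])
        read_hap = np.concatenate([haps, haps])
        # First mate forward / second reverse, swapped when the fragment flips.
        strand = np.concatenate(
            [np.where(flip, -1, 1), np.where(flip, 1, -1)]
        ).astype(np.int8)
        mate = np.concatenate(
            [np.zeros(n_frags, dtype=np.int8), np.ones(n_frags, dtype=np.int8)]
        )
        idx = np.concatenate([r1, r2], axis=0)
    else:
        idx = starts[:, None] + offsets
        read_starts = starts
        read_hap = haps
        strand = np.where(flip, -1, 1).astype(np.int8)
        mate = None

    hap_stack = np.stack(genome.hap_codes)  # (2, glen)
    codes = hap_stack[read_hap[:, None], idx].astype(np.uint8)

    rev = strand < 0
    if rev.any():
        codes[rev] = 3 - codes[rev, ::-1]

    if spec.error_rate > 0:
        err = rng.random(codes.shape) < spec.error_rate
        codes[err] = (codes[err] + rng.integers(1, 4, size=int(err.sum()))) % 4

    return ReadSet(
        codes=codes,
        hap=read_hap.astype(np.int8),
        start=read_starts.astype(np.int64),
        strand=strand,
        mate=mate,
        reference_length=glen,
    )


def truth_kmer_counts(genome: SimulatedGenome, k: int) -> Counter:
    """Exact canonical k-mer multiset over both haplotypes, by direct
    string enumeration.  Deliberately brute force: this is the independent
    oracle against which the packed counter is validated."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for hap in genome.haplotypes:
        if k > len(hap):
            raise ValueError("k exceeds haplotype length")
        for i in range(len(hap) - k + 1):
            counts[canonical_str(hap[i : i + k])] += 1
    return counts


def truth_spectrum(genome: SimulatedGenome, k: int):
    """Exact multiplicity histogram of canonical k-mers over both haplotypes."""
    from .spectrum import SpectrumHistogram

    per_kmer = truth_kmer_counts(genome, k)
    hist: Counter = Counter(per_kmer.values())
    return SpectrumHistogram(k=k, counts=dict(hist))
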