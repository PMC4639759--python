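"""K-mer spectrum modelling: coverage, genome size and repeat structure.

Given shotgun reads, the multiplicity spectrum f(m) — the number of distinct
canonical k-mers seen exactly m times — decomposes the genome by copy
number.  Erroneous k-mers pile up at low multiplicity; single-copy diploid
sequence forms a hump at the k-mer coverage C_k; heterozygous (allelic, 1N)
sequence forms a secondary hump near C_k/2; repeats extend a long right
tail.  From the fitted single-copy peak follow the base-level coverage
C_base = C_k * L/(L-k+1) (a read of length L yields only L-k+1 k-mers, so
k-mers undersample bases near read ends), the genome size
G = sum_{m > m_err} m*f(m) / C_k, and the single-copy fraction of the
genome (mass within the peak mean +/- 3 sigma).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from ._encode import canonical_kmers, canonical_kmers_matrix, encode

DEFAULT_CAP = 100_000


@dataclass
class SpectrumHistogram:
    """Distinct-canonical-k-mer counts per multiplicity.

    ``counts[m]`` = number of distinct canonical k-mers observed exactly m
    times.  Multiplicities >= ``cap`` are pooled into the ``cap`` bin (the
    distinct count), with their exact k-mer mass kept in ``overflow_mass``
    so that conservation — sum(m * f(m)) == total k-mers counted — holds on
    every input.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)
    cap: int = DEFAULT_CAP
    read_length: int | None = None
    overflow_mass: int = 0

    def __post_init__(self) -> None:
        if any(m < 1 or c < 0 for m, c in self.counts.items()):
            raise ValueError("multiplicities must be >= 1 and counts >= 0")

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts, default=0)

    def total_mass(self) -> int:
        """Total k-mers counted: sum of m*f(m), exact even past the cap."""
        inner = sum(m * c for m, c in self.counts.items() if m < self.cap)
        return inner + self.overflow_mass

    def genomic_mass(self, error_cutoff: int) -> int:
        """k-mer mass above the error cutoff."""
        inner = sum(m * c for m, c in self.counts.items() if error_cutoff < m < self.cap)
        return inner + self.overflow_mass

    def n_distinct(self) -> int:
        return sum(self.counts.values())

    def dense(self, upto: int | None = None) -> np.ndarray:
        """f as a dense array indexed by multiplicity (index 0 unused)."""
        hi = self.max_multiplicity if upto is None else upto
        f = np.zeros(hi + 2, dtype=np.int64)
        for m, c in self.counts.items():
            if m <= hi:
                f[m] = c
        return f

    def write(self, path: str | Path) -> None:
        """Two-column ``multiplicity count`` table, ascending (histo dialect)."""
        with open(path, "w") as fh:
            if self.overflow_mass:
                fh.write(f"#overflow_mass\t{self.overflow_mass}\n")
            for m in sorted(self.counts):
                fh.write(f"{m} {self.counts[m]}\n")

    @classmethod
    def read(
        cls,
        path: str | Path,
        k: int,
        cap: int = DEFAULT_CAP,
        read_length: int | None = None,
    ) -> "SpectrumHistogram":
        counts: dict[int, int] = {}
        overflow = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    fields = line.lstrip("#").split()
                    if fields and fields[0] == "overflow_mass":
                        overflow = int(fields[1])
                    continue
                m_s, c_s = line.split()
                counts[int(m_s)] = int(c_s)
        return cls(k=k, counts=counts, cap=cap, read_length=read_length, overflow_mass=overflow)


def _iter_sequences(reads) -> Iterable[str]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(reads)
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            for _t, seq in SimpleFastaParser(fh):
                yield seq
        elif first == "@":
            for _t, seq, _q in FastqGeneralIterator(fh):
                yield seq
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ")


def count_kmers(
    reads,
    k: int,
    cap: int = DEFAULT_CAP,
    read_length: int | None = None,
) -> SpectrumHistogram:
    """Count canonical k-mers and return the multiplicity spectrum.

    ``reads`` may be a FASTA/FASTQ path, an iterable of sequence strings, or
    a :class:`~axokit.simulate.ReadSet`.  k must be odd (an even k admits
    reverse-complement palindromes, which make canonicalization ambiguous).
    k-mers spanning a non-ACGT symbol are skipped; conservation
    sum(m*f(m)) == number of retained k-mers holds exactly.
    """
    if k % 2 == 0:
        raise ValueError(
            "k must be odd: an even-length k-mer can equal its own reverse "
            "complement, which makes canonical counting ambiguous"
        )
    from .simulate import ReadSet

    if isinstance(reads, ReadSet):
        kmers = canonical_kmers_matrix(reads.codes, k)
        if read_length is None:
            read_length = reads.read_length
    else:
        if isinstance(reads, (str, Path)):
            seqs: Iterable[str] = _iter_sequences(reads)
        else:
            seqs = reads
        parts = []
        lengths = set()
        for seq in seqs:
            lengths.add(len(seq))
            if len(seq) >= k:
                parts.append(canonical_kmers(encode(seq), k))
        if read_length is None and len(lengths) == 1:
            read_length = lengths.pop()
        kmers = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
        )

    if kmers.size == 0:
        return SpectrumHistogram(k=k, counts={}, cap=cap, read_length=read_length)

    _, per_kmer = np.unique(kmers, return_counts=True)
    mult, n_at_mult = np.unique(per_kmer, return_counts=True)

    counts: dict[int, int] = {}
    overflow_distinct = 0
    overflow_mass = 0
    for m, c in zip(mult.tolist(), n_at_mult.tolist()):
        if m >= cap:
            overflow_distinct += c
            overflow_mass += m * c
        else:
            counts[m] = c
    if overflow_distinct:
        counts[cap] = overflow_distinct
    return SpectrumHistogram(
        k=k, counts=counts, cap=cap, read_length=read_length, overflow_mass=overflow_mass
    )


def kmer_counts(reads, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct canonical k-mers (packed uint64) and their multiplicities."""
    from .simulate import ReadSet

    if isinstance(reads, ReadSet):
        kmers = canonical_kmers_matrix(reads.codes, k)
    else:
        parts = [canonical_kmers(encode(s), k) for s in reads if len(s) >= k]
        kmers = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return np.unique(kmers, return_counts=True)


def find_error_cutoff(hist: SpectrumHistogram) -> int:
    """First local minimum of f(m) scanning upward from m=1.

    k-mers with multiplicity <= the returned value are classed presumptively
    erroneous.  Raises if the histogram never rises again (no error/signal
    valley).
    """
    if sum(1 for c in hist.counts.values() if c > 0) < 3:
        raise ValueError("histogram needs >= 3 non-zero bins to locate a valley")
    f = hist.dense()
    for m in range(2, f.size - 1):
        if f[m] <= f[m - 1] and f[m] < f[m + 1]:
            return m
    raise ValueError("no error/signal separation: histogram has no valley")


@dataclass(frozen=True)
class PeakFit:
    mode: int
    mean: float
    sigma: float


def fit_single_copy_peak(hist: SpectrumHistogram, error_cutoff: int) -> PeakFit:
    """Fit the single-copy (2N) peak above the error cutoff.

    mode: argmax of f(m) for m > error_cutoff, ties broken toward the lower
    multiplicity.  A provisional width sigma_0 is taken from the peak's
    left half reflected about the mode (the right flank is contaminated by
    low-copy repeats, the reflected left half is not).  mean: centroid of
    f(m) over the peak support [error_cutoff + 1, mode + 3*sigma_0] —
    this recovers the fractional mean of a right-skewed sampling
    distribution (two near-tied modal bins yield the half-integer between
    them; a symmetric peak yields its centre exactly) and is clipped to
    within +/- 1 of the mode.  sigma: left-half reflection recomputed
    about the fitted mean.
    """
    f = hist.dense().astype(float)
    max_m = hist.max_multiplicity
    if error_cutoff >= max_m:
        raise ValueError("no histogram mass above the error cutoff")
    above = f[error_cutoff + 1 : max_m + 1]
    if above.max() <= 0 or above.min() == above.max():
        raise ValueError("histogram is flat above the error cutoff")
    mode = int(np.argmax(above)) + error_cutoff + 1

    ds = np.arange(1, mode - error_cutoff)
    left = f[mode - ds] if ds.size else np.empty(0)
    wsum = f[mode] + 2.0 * left.sum()
    if wsum <= 0:
        raise ValueError("empty single-copy peak")
    sigma0 = float(np.sqrt((2.0 * left * ds.astype(float) ** 2).sum() / wsum))

    hi = int(np.floor(mode + 3.0 * max(sigma0, 1.0)))
    ms = np.arange(error_cutoff + 1, min(hi, max_m) + 1)
    wts = f[ms]
    mean = float(np.clip((wts * ms).sum() / wts.sum(), mode - 1, mode + 1))

    # Reflected distribution about the mean: centre bin (if the mean is
    # integral) once, left flank doubled; its variance equals that of the
    # full symmetric peak.
    if abs(mean - round(mean)) < 1e-9:
        centre = int(round(mean))
        ds2 = np.arange(1, centre - error_cutoff)
        left2 = f[centre - ds2] if ds2.size else np.empty(0)
        denom = f[centre] + 2.0 * left2.sum()
        var = float((2.0 * left2 * ds2.astype(float) ** 2).sum() / denom) if denom > 0 else 0.0
    else:
        msl = np.arange(error_cutoff + 1, int(np.floor(mean)) + 1)
        wl = f[msl]
        var = float((wl * (mean - msl) ** 2).sum() / wl.sum()) if wl.sum() > 0 else 0.0
    return PeakFit(mode=mode, mean=mean, sigma=float(np.sqrt(var)))


def kmer_to_base_coverage(c_k: float, read_length: int, k: int) -> float:
    """Correct k-mer coverage for undersampling at read ends:
    C_base = C_k * L / (L - k + 1)."""
    if read_length <= k:
        raise ValueError("read_length must exceed k")
    return c_k * read_length / (read_length - k + 1)


def base_to_kmer_coverage(c_base: float, read_length: int, k: int) -> float:
    """Exact inverse of :func:`kmer_to_base_coverage`."""
    if read_length <= k:
        raise ValueError("read_length must exceed k")
    return c_base * (read_length - k + 1) / read_length


@dataclass
class CoverageModel:
    """Fitted spectrum model: coverage, genome size and single-copy window."""

    k: int
    read_length: int
    error_cutoff: int
    mode: int
    mean_kmer_coverage: float
    sigma: float
    base_coverage: float
    genome_size: float
    single_copy_window: tuple[float, float]
    single_copy_fraction: float
    single_copy_bp: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["single_copy_window"] = list(self.single_copy_window)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoverageModel":
        d = json.loads(Path(path).read_text())
        d["single_copy_window"] = tuple(d["single_copy_window"])
        return cls(**d)


def estimate_genome_size(
    hist: SpectrumHistogram, mean_kmer_coverage: float, error_cutoff: int
) -> float:
    """G = sum_{m > m_err} m*f(m) / C_k (haploid genome length in bp)."""
    if mean_kmer_coverage <= 0:
        raise ValueError("mean k-mer coverage must be positive")
    return hist.genomic_mass(error_cutoff) / mean_kmer_coverage


def single_copy_window(fit: PeakFit, error_cutoff: int) -> tuple[float, float]:
    """Multiplicity window [lo, hi] = [max(m_err+1, mean-3s), mean+3s]."""
    lo = max(error_cutoff + 1.0, fit.mean - 3.0 * fit.sigma)
    hi = fit.mean + 3.0 * fit.sigma
    return lo, hi


def single_copy_mass_fraction(
    hist: SpectrumHistogram,
    window: tuple[float, float],
    error_cutoff: int,
    distinct: bool = False,
) -> float:
    """Fraction of genomic k-mer mass inside the single-copy window.

    With ``distinct=True`` the fraction is over distinct k-mers instead of
    k-mer mass (occurrences); the mass-based form is the default because it
    is directly in genome-length units.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty single-copy window")
    weight = (lambda m, c: c) if distinct else (lambda m, c: m * c)
    total = sum(weight(m, c) for m, c in hist.counts.items() if m > error_cutoff and m < hist.cap)
    if not distinct:
        total += hist.overflow_mass
    if total == 0:
        raise ValueError("no genomic mass above the error cutoff")
    inside = sum(weight(m, c) for m, c in hist.counts.items() if lo <= m <= hi and m > error_cutoff)
    return inside / total


def fit_coverage_model(
    hist: SpectrumHistogram,
    read_length: int | None = None,
    error_cutoff: int | None = None,
) -> CoverageModel:
    """Full pipeline: error cutoff, peak fit, coverage, size, window, fraction."""
    if read_length is None:
        read_length = hist.read_length
    if read_length is None:
        raise ValueError("read_length required (not recorded in histogram)")
    m_err = find_error_cutoff(hist) if error_cutoff is None else error_cutoff
    fit = fit_single_copy_peak(hist, m_err)
    c_base = kmer_to_base_coverage(fit.mean, read_length, hist.k)
    g = estimate_genome_size(hist, fit.mean, m_err)
    window = single_copy_window(fit, m_err)
    frac = single_copy_mass_fraction(hist, window, m_err)
    return CoverageModel(
        k=hist.k,
        read_length=read_length,
        error_cutoff=m_err,
        mode=fit.mode,
        mean_kmer_coverage=fit.mean,
        sigma=fit.sigma,
        base_coverage=c_base,
        genome_size=g,
        single_copy_window=window,
        single_copy_fraction=frac,
        single_copy_bp=frac * g,
    )


@dataclass
class SpectrumDecomposition:
    """Per-multiplicity masses of the error / 1N / 2N / repeat components.

    Arrays are indexed by multiplicity (index 0 unused) and re-sum to the
    observed f(m) exactly at every m; ``residual`` records any remainder
    (zero by construction).
    """

    multiplicity: np.ndarray
    observed: np.ndarray
    error: np.ndarray
    allelic_1n: np.ndarray
    diploid_2n: np.ndarray
    repeat: np.ndarray
    residual: np.ndarray
    center_1n: float | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "multiplicity": self.multiplicity,
                "observed": self.observed,
                "error": self.error,
                "allelic_1N": self.allelic_1n,
                "diploid_2N": self.diploid_2n,
                "repeat": self.repeat,
                "residual": self.residual,
            }
        )


def decompose_spectrum(hist: SpectrumHistogram, model: CoverageModel) -> SpectrumDecomposition:
    """Split f(m) into error, allelic (1N), diploid single-copy (2N) and
    repeat components.

    The 1N component is estimated by mirror subtraction: below the mode the
    2N peak should be symmetric, so the excess of f(m) over its mirror image
    f(2*mode - m) on (m_err, mode) is attributed to the heterozygous 1N hump
    (expected near C_k/2).  The 2N component is the remainder below the mode
    and the truncated reflection of that remainder above it; everything else
    above the cutoff is repeat.  Components re-sum to the observed spectrum
    exactly.
    """
    f = hist.dense().astype(np.int64)
    m_err = model.error_cutoff
    mode = model.mode
    size = f.size
    mult = np.arange(size)

    error = np.zeros(size, dtype=np.int64)
    error[: m_err + 1] = f[: m_err + 1]

    n1 = np.zeros(size, dtype=np.int64)
    c1 = model.mean_kmer_coverage / 2.0
    center_1n: float | None
    if c1 <= m_err:
        warnings.warn(
            "expected 1N centre lies at or below the error cutoff; "
            "heterozygous signal is indistinguishable from error",
            stacklevel=2,
        )
        center_1n = None
    else:
        for m in range(m_err + 1, mode):
            mirror = 2 * mode - m
            fm_mirror = f[mirror] if mirror < size else 0
            n1[m] = max(int(f[m]) - int(fm_mirror), 0)
        w = n1[m_err + 1 : mode].astype(float)
        center_1n = (
            float((w * np.arange(m_err + 1, mode)).sum() / w.sum()) if w.sum() > 0 else None
        )

    n2 = np.zeros(size, dtype=np.int64)
    for m in range(m_err + 1, mode + 1):
        n2[m] = f[m] - n1[m]
    for m in range(mode + 1, size):
        mirror = 2 * mode - m
        n2[m] = min(int(f[m]), int(n2[mirror])) if mirror > m_err else 0

    repeat = f - error - n1 - n2
    np.maximum(repeat, 0, out=repeat)
    residual = f - error - n1 - n2 - repeat
    return SpectrumDecomposition(
        multiplicity=mult,
        observed=f,
        error=error,
        allelic_1n=n1,
        diploid_2n=n2,
        repeat=repeat,
        residual=residual,
        center_1n=center_1n,
    )


@dataclass
class CopyNumberSpectrum:
    """Genome fraction as a function of estimated copy number cn = m / C_k."""

    copy_number: np.ndarray
    fraction: np.ndarray
    per_chromosome_band: tuple[float, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"copy_number": self.copy_number, "fraction": self.fraction})

    def mass_in(self, cn_lo: float, cn_hi: float) -> float:
        sel = (self.copy_number >= cn_lo) & (self.copy_number <= cn_hi)
        return float(self.fraction[sel].sum())


def copy_number_spectrum(
    hist: SpectrumHistogram, model: CoverageModel, chromosomes: int = 14
) -> CopyNumberSpectrum:
    """Copy-number view of the spectrum.

    Each multiplicity m above the error cutoff maps to an estimated copy
    number m / C_k carrying genome fraction m*f(m) / (genomic mass);
    fractions sum to 1.  The per-chromosome band flags copy numbers between
    the single-copy window's upper edge and ``chromosomes`` times it —
    sequence that could still be single copy with respect to an individual
    chromosome (~1 copy per chromosome).
    """
    if chromosomes < 1:
        raise ValueError("chromosomes must be >= 1")
    m_err = model.error_cutoff
    c_k = model.mean_kmer_coverage
    total = hist.genomic_mass(m_err)
    if total == 0:
        raise ValueError("no genomic mass above the error cutoff")
    ms = np.array(sorted(m for m in hist.counts if m > m_err), dtype=float)
    mass = np.array([hist.counts[int(m)] * m for m in ms], dtype=float)
    # Pooled bin at the cap carries its exact overflow mass.
    if hist.cap in hist.counts and hist.overflow_mass:
        mass[ms == hist.cap] = hist.overflow_mass
    cn = ms / c_k
    frac = mass / total
    hi_single = model.single_copy_window[1] / c_k
    band = (hi_single, chromosomes * hi_single)
    return CopyNumberSpectrum(copy_number=cn, fraction=frac, per_chromosome_band=band)
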