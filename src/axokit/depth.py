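"""Alignment-depth profiling of reference intervals.

Per-base read depth over assembled reference intervals (BAC-style clones or
chromosome contigs) gives an alignment-based view of the single-copy /
repeat partition that complements the k-mer spectrum: bases covered at
roughly the genome-wide sequencing depth are effectively single copy, while
depth scales with copy number for repeats.  Depths are computed from SAM
records with a mapping-quality filter, or loaded from a plain per-base
depth table to accommodate external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam


@dataclass
class DepthTrack:
    """Per-base depth arrays per reference interval, after MAPQ filtering."""

    depths: dict[str, np.ndarray]
    mapq_threshold: int = 0

    @property
    def total_bases(self) -> int:
        return sum(int(a.size) for a in self.depths.values())

    def histogram(self) -> dict[int, int]:
        """depth -> number of bases at that depth, over all intervals."""
        if not self.depths:
            return {}
        allv = np.concatenate([a for a in self.depths.values()])
        counts = np.bincount(allv)
        return {int(d): int(c) for d, c in enumerate(counts) if c > 0}

    def write_tsv(self, path: str | Path) -> None:
        """Three-column TSV: interval, 1-based position, depth."""
        with open(path, "w") as fh:
            fh.write("interval\tposition\tdepth\n")
            for name, arr in self.depths.items():
                for i, d in enumerate(arr, start=1):
                    fh.write(f"{name}\t{i}\t{d}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, mapq_threshold: int = 0) -> "DepthTrack":
        """Read an interval/position/depth table (positions 1-based)."""
        per: dict[str, dict[int, int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("interval\t"):
                    continue
                name, pos_s, d_s = line.split("\t")
                per.setdefault(name, {})[int(pos_s)] = int(d_s)
        depths = {}
        for name, d in per.items():
            arr = np.zeros(max(d), dtype=np.int64)
            for pos, v in d.items():
                arr[pos - 1] = v
            depths[name] = arr
        return cls(depths=depths, mapq_threshold=mapq_threshold)


def _check_references(sam_path: str) -> None:
    """Fail loudly on RNAMEs missing from the header (pysam silently
    demotes such records to unmapped)."""
    names: set[str] = set()
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for fieldv in line.rstrip("\n").split("\t")[1:]:
                        if fieldv.startswith("SN:"):
                            names.add(fieldv[3:])
                continue
            rname = line.split("\t", 3)[2]
            if rname != "*" and rname not in names:
                raise ValueError(
                    f"alignment references {rname!r}, absent from the SAM header"
                )


def depth_from_alignments(
    sam_path: str | Path,
    mapq_min: int = 0,
    include_duplicates: bool = False,
) -> DepthTrack:
    """Per-base depth from a SAM file.

    Counts aligned read bases (CIGAR M/=/X) from primary mapped records
    with MAPQ >= ``mapq_min``; unmapped, secondary and supplementary
    records are always excluded, duplicate-flagged records by default
    (whole-genome-amplified libraries are duplicate-heavy).  Deletions and
    reference skips advance the reference without adding depth.
    """
    sam_path = str(sam_path)
    _check_references(sam_path)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if sam.nreferences == 0:
            raise ValueError(f"{sam_path}: SAM header has no reference (@SQ) lines")
        depths = {
            name: np.zeros(length, dtype=np.int64)
            for name, length in zip(sam.references, sam.lengths)
        }
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate and not include_duplicates:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            name = rec.reference_name
            if name not in depths:
                raise ValueError(f"alignment references {name!r}, absent from the header")
            arr = depths[name]
            pos = rec.reference_start
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X consume both read and reference
                    arr[pos : pos + length] += 1
                    pos += length
                elif op in (2, 3):  # D, N consume reference only
                    pos += length
                # I, S, H, P consume no reference
    return DepthTrack(depths=depths, mapq_threshold=mapq_min)


def exact_map_sam(
    reads,
    reference: str,
    path: str | Path,
    name: str = "ref",
    seed_k: int = 31,
) -> int:
    """Map reads to a reference by exact substring search and write SAM.

    Each read (or its reverse complement) must match the reference exactly
    to be placed; the first verifying position wins, so reads from every
    copy of a repeat pile onto its first occurrence — the behaviour that
    lets depth reflect genome-wide copy number on a single-copy reference
    interval.  Intended for error-free or near-error-free simulated reads;
    returns the number of reads placed.

    ``reads`` may be a :class:`~axokit.simulate.ReadSet` or an iterable of
    sequence strings.
    """
    from ._encode import encode, forward_kmers, revcomp
    from .simulate import ReadSet

    seqs = reads.sequences() if isinstance(reads, ReadSet) else list(reads)
    ref_codes = encode(reference)
    if (ref_codes > 3).any():
        raise ValueError("reference must be ACGT-only for exact mapping")
    index: dict[int, list[int]] = {}
    for pos, km in enumerate(forward_kmers(ref_codes, seed_k).tolist()):
        index.setdefault(km, []).append(pos)

    n_mapped = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{name}\tLN:{len(reference)}\n")
        for i, seq in enumerate(seqs):
            if len(seq) < seed_k:
                continue
            placed = None
            for flag, oriented in ((0, seq), (16, revcomp(seq))):
                key = int(forward_kmers(encode(oriented[:seed_k]), seed_k)[0])
                for pos in index.get(key, ()):
                    if reference[pos : pos + len(oriented)] == oriented:
                        placed = (flag, pos, oriented)
                        break
                if placed:
                    break
            if placed is None:
                continue
            flag, pos, oriented = placed
            fh.write(
                f"read{i}\t{flag}\t{name}\t{pos + 1}\t60\t{len(oriented)}M\t*\t0\t0\t"
                f"{oriented}\t*\n"
            )
            n_mapped += 1
    return n_mapped


@dataclass
class RepeatProfile:
    """Depth-based single-copy/repeat summary with genome-scale extrapolation."""

    depth_histogram: dict[int, int]
    single_copy_range: tuple[int, int]
    single_copy_fraction: float
    extrapolated_single_copy: float
    extrapolated_repeat: float
    modal_depth: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("depth\tbases\n")
            for d in sorted(self.depth_histogram):
                fh.write(f"{d}\t{self.depth_histogram[d]}\n")


def repeat_profile(
    track: DepthTrack,
    depth_range: tuple[int, int] = (1, 40),
    genome_size: float = 0.0,
) -> RepeatProfile:
    """Classify bases as ~single copy by depth and extrapolate to the genome.

    ``single_copy_fraction`` is the proportion of profiled bases whose depth
    lies in ``depth_range`` (inclusive); applied to ``genome_size`` this
    splits the genome into single-copy and repetitive extrapolations that
    sum to G exactly.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if track.total_bases == 0:
        raise ValueError("empty depth track")
    d_lo, d_hi = depth_range
    hist = track.histogram()
    total = sum(hist.values())
    inside = sum(c for d, c in hist.items() if d_lo <= d <= d_hi)
    frac = inside / total
    positive = {d: c for d, c in hist.items() if d > 0}
    modal = max(positive, key=positive.get) if positive else 0
    return RepeatProfile(
        depth_histogram=hist,
        single_copy_range=(d_lo, d_hi),
        single_copy_fraction=frac,
        extrapolated_single_copy=frac * genome_size,
        extrapolated_repeat=(1.0 - frac) * genome_size,
        modal_depth=modal,
    )


def copy_number_from_depth(track: DepthTrack, base_coverage: float):
    """Per-base estimated copy number cn = depth / C_base, summarized as a
    (copy_number, base fraction) table over all profiled intervals."""
    import pandas as pd

    if base_coverage <= 0:
        raise ValueError("base_coverage must be positive")
    hist = track.histogram()
    total = sum(hist.values())
    if total == 0:
        raise ValueError("empty depth track")
    rows = [
        {"depth": d, "copy_number": d / base_coverage, "fraction": c / total}
        for d, c in sorted(hist.items())
    ]
    return pd.DataFrame(rows)


def per_base_copy_number(track: DepthTrack, base_coverage: float) -> dict[str, np.ndarray]:
    """Raw per-base copy-number arrays (depth / C_base) per interval."""
    if base_coverage <= 0:
        raise ValueError("base_coverage must be positive")
    return {name: arr / base_coverage for name, arr in track.depths.items()}
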