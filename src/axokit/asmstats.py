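"""Assembly summary statistics: contig/scaffold N50, singletons, scaffolding.

Scaffolds are FASTA records possibly containing N-filled gaps; contigs are
the maximal N-free runs within them.  Statistics mirror the standard
de novo assembly report: total length, scaffold count, singleton count
(scaffolds that are a single gapless contig), contig and scaffold N50,
proportion of scaffolds that actually scaffold (join >= 2 contigs), and
the number of scaffolds longer than the scaffold N50.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

_VALID = set("ACGTN")


def split_contigs(sequence: str, gap_min: int = 1, min_contig_len: int = 1) -> list[str]:
    """Maximal N-free runs of a scaffold, split at runs of >= ``gap_min`` Ns.

    Runs shorter than ``gap_min`` are kept inside a contig (some assemblers
    emit single ambiguous bases that are not gaps).  Contigs shorter than
    ``min_contig_len`` are dropped.  Raises on symbols outside {A,C,G,T,N}.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    if gap_min < 1:
        raise ValueError("gap_min must be >= 1")
    pieces = re.split("N{%d,}" % gap_min, seq)
    return [p for p in pieces if len(p.replace("N", "")) and len(p) >= min_contig_len]


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that pieces of length >= L together cover >= half the
    total length.  Computed by descending accumulation."""
    if not len(lengths):
        raise ValueError("N50 of an empty length list is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return int(length)
    raise AssertionError("unreachable")


@dataclass
class AssemblyStats:
    name: str
    total_length: int
    n_scaffolds: int
    n_singletons: int
    n_contigs: int
    contig_n50: int
    scaffold_n50: int
    proportion_scaffolded: float
    n_gt_n50: int

    @property
    def total_length_mb(self) -> float:
        return self.total_length / 1e6


def _iter_fasta(source) -> Iterable[tuple[str, str]]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from SimpleFastaParser(fh)
    else:
        yield from source  # (name, sequence) pairs


def summarize(
    assembly,
    name: str = "assembly",
    gap_min: int = 1,
    min_contig_len: int = 1,
    length_based_scaffolding: bool = False,
    count_unscaffolded_contigs: bool = False,
) -> AssemblyStats:
    """Full assembly report from a FASTA path or (name, sequence) pairs.

    A singleton is a scaffold consisting of exactly one contig and no gap;
    ``proportion_scaffolded`` is the count-based proportion of non-singleton
    scaffolds, or the proportion of total length in non-singleton scaffolds
    with ``length_based_scaffolding=True``.  With
    ``count_unscaffolded_contigs=True`` the singleton column counts
    unscaffolded contigs instead of single-contig scaffolds (an alternative
    reading of the same report column).
    """
    scaffold_lengths: list[int] = []
    contig_lengths: list[int] = []
    n_singletons = 0
    n_single_contig = 0
    singleton_length = 0
    for rec_name, seq in _iter_fasta(assembly):
        contigs = split_contigs(seq, gap_min=gap_min, min_contig_len=min_contig_len)
        scaffold_lengths.append(len(seq))
        contig_lengths.extend(len(c) for c in contigs)
        has_gap = re.search("N{%d,}" % gap_min, seq.upper()) is not None
        if len(contigs) == 1:
            n_single_contig += 1
            if not has_gap:
                n_singletons += 1
                singleton_length += len(seq)
    if not scaffold_lengths:
        raise ValueError("empty assembly")
    n_scaffolds = len(scaffold_lengths)
    # Alternative reading of the singleton column: contigs that ended up in
    # no multi-contig scaffold, regardless of residual gap characters.
    n_singletons_out = n_single_contig if count_unscaffolded_contigs else n_singletons
    scf_n50 = n50(scaffold_lengths)
    total = sum(scaffold_lengths)
    if length_based_scaffolding:
        prop = (total - singleton_length) / total if total else 0.0
    else:
        prop = (n_scaffolds - n_singletons) / n_scaffolds
    return AssemblyStats(
        name=name,
        total_length=total,
        n_scaffolds=n_scaffolds,
        n_singletons=n_singletons_out,
        n_contigs=len(contig_lengths),
        contig_n50=n50(contig_lengths) if contig_lengths else 0,
        scaffold_n50=scf_n50,
        proportion_scaffolded=prop,
        n_gt_n50=sum(1 for length in scaffold_lengths if length > scf_n50),
    )


def percent_improvement(raw_n50: float, ec_n50: float) -> int:
    """Percent N50 change from a raw to an error-corrected assembly,
    rounded to the nearest integer, halves away from zero."""
    if raw_n50 <= 0:
        raise ValueError("raw N50 must be positive")
    pct = 100.0 * (ec_n50 - raw_n50) / raw_n50
    return int(pct + 0.5) if pct >= 0 else -int(-pct + 0.5)


def write_stats_tsv(stats_list: Sequence[AssemblyStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "assembly\tlength_mb\tn_scaffolds\tn_singletons\tcontig_n50\t"
            "proportion_scaffolded\tscaffold_n50\tn_gt_n50\n"
        )
        for s in stats_list:
            fh.write(
                f"{s.name}\t{s.total_length_mb:.1f}\t{s.n_scaffolds}\t{s.n_singletons}\t"
                f"{s.contig_n50}\t{s.proportion_scaffolded:.3f}\t{s.scaffold_n50}\t{s.n_gt_n50}\n"
            )
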