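"""Validation of single-chromosome capture libraries against a genetic map.

A laser-captured, amplified chromosome library should be heavily enriched
for reads matching markers from the linkage group(s) carried by that
chromosome.  Reads are matched to mapped marker sequences by shared
canonical k-mer seeds (an aligner-free stand-in for near-exact alignment),
marker recovery is summarized per linkage group, enrichment is called with
a one-sided binomial test plus a fold threshold, and linkage groups that
are repeatedly co-enriched across independent libraries are coalesced into
chromosomes.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._encode import canonical_kmers, encode


@dataclass
class MarkerSet:
    """Mapped marker sequences: id -> (sequence, linkage group, cM position)."""

    sequences: dict[str, str]
    linkage_group: dict[str, str]
    position_cm: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.sequences) - set(self.linkage_group)
        if missing:
            raise ValueError(f"markers without a linkage group: {sorted(missing)[:5]}")

    @property
    def n_markers(self) -> int:
        return len(self.sequences)

    def groups(self) -> dict[str, list[str]]:
        by_lg: dict[str, list[str]] = defaultdict(list)
        for mid, lg in self.linkage_group.items():
            by_lg[lg].append(mid)
        return dict(by_lg)

    @classmethod
    def from_files(cls, fasta: str | Path, map_tsv: str | Path) -> "MarkerSet":
        """Marker FASTA plus a ``marker_id  LG  cM`` map table."""
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        seqs: dict[str, str] = {}
        with open(fasta) as fh:
            for title, seq in SimpleFastaParser(fh):
                seqs[title.split()[0]] = seq.upper()
        lg: dict[str, str] = {}
        cm: dict[str, float] = {}
        with open(map_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("marker"):
                    continue
                mid, group, pos = line.split("\t")[:3]
                lg[mid] = group
                cm[mid] = float(pos)
        seqs = {m: s for m, s in seqs.items() if m in lg}
        return cls(sequences=seqs, linkage_group=lg, position_cm=cm)


def _seed_index(markers: MarkerSet, seed_k: int) -> dict[int, list[int]]:
    """Canonical seed k-mer -> marker indices containing it."""
    index: dict[int, list[int]] = defaultdict(list)
    for idx, (mid, seq) in enumerate(markers.sequences.items()):
        if len(seq) < seed_k:
            continue
        for km in np.unique(canonical_kmers(encode(seq), seed_k)).tolist():
            index[km].append(idx)
    return index


def match_reads_to_markers(
    reads,
    markers: MarkerSet,
    seed_k: int = 31,
    min_seeds: int = 2,
) -> dict[str, int]:
    """Credit each read to at most one marker by shared canonical seeds.

    A read hits a marker when they share >= ``min_seeds`` distinct canonical
    ``seed_k``-mers; the marker sharing the most seeds wins, and a tie for
    the top count discards the read (paralog ambiguity).  Returns hit read
    counts per marker id.

    ``reads`` may be an iterable of sequence strings, a FASTQ/FASTA path,
    or a :class:`~axokit.simulate.ReadSet`.
    """
    if not markers.sequences:
        raise ValueError("empty marker set")
    from .simulate import ReadSet
    from .spectrum import _iter_sequences

    if isinstance(reads, ReadSet):
        seqs = reads.sequences()
    elif isinstance(reads, (str, Path)):
        seqs = _iter_sequences(reads)
    else:
        seqs = reads

    index = _seed_index(markers, seed_k)
    marker_ids = list(markers.sequences)
    hits: dict[str, int] = defaultdict(int)
    for seq in seqs:
        if len(seq) < seed_k:
            continue
        shared: dict[int, int] = defaultdict(int)
        for km in np.unique(canonical_kmers(encode(seq), seed_k)).tolist():
            for midx in index.get(km, ()):
                shared[midx] += 1
        if not shared:
            continue
        best = max(shared.values())
        if best < min_seeds:
            continue
        top = [midx for midx, c in shared.items() if c == best]
        if len(top) != 1:
            continue  # ambiguous between paralogous markers
        hits[marker_ids[top[0]]] += 1
    return dict(hits)


def recovery_proportions(
    hits: dict[str, dict[str, int]], markers: MarkerSet
) -> pd.DataFrame:
    """Per-(library, linkage group) marker recovery report.

    Recovery is presence/absence (a marker counts as recovered with >= 1
    hit read).  For each LG the background b pools recovery over all other
    LGs' markers.  Returns a frame with columns: library, lg, markers_total,
    markers_recovered, p, background, fold.
    """
    by_lg = markers.groups()
    empty = [lg for lg, ms in by_lg.items() if not ms]
    if empty:
        warnings.warn(f"linkage groups without markers excluded: {empty}", stacklevel=2)
        by_lg = {lg: ms for lg, ms in by_lg.items() if ms}
    rows = []
    for lib, lib_hits in hits.items():
        recovered = {m for m, c in lib_hits.items() if c > 0}
        rec_by_lg = {lg: sum(1 for m in ms if m in recovered) for lg, ms in by_lg.items()}
        tot_by_lg = {lg: len(ms) for lg, ms in by_lg.items()}
        all_rec = sum(rec_by_lg.values())
        all_tot = sum(tot_by_lg.values())
        for lg in sorted(by_lg):
            n, k = tot_by_lg[lg], rec_by_lg[lg]
            p = k / n
            off_tot = all_tot - n
            b = (all_rec - k) / off_tot if off_tot else 0.0
            if b > 0:
                fold = p / b
            else:
                fold = np.inf if p > 0 else np.nan
            rows.append(
                {
                    "library": lib,
                    "lg": lg,
                    "markers_total": n,
                    "markers_recovered": k,
                    "p": p,
                    "background": b,
                    "fold": fold,
                }
            )
    return pd.DataFrame(rows)


def call_enrichment(
    report: pd.DataFrame, alpha: float = 1e-3, min_fold: float = 5.0
) -> pd.DataFrame:
    """Flag (library, LG) pairs as enriched.

    Enriched iff the one-sided binomial test of markers_recovered out of
    markers_total at the background rate gives p-value < ``alpha`` AND the
    recovery fold is >= ``min_fold``.  A zero background with any recovery
    is enriched by convention (p-value reported as 0).
    """
    report = report.copy()
    pvals = []
    for _, row in report.iterrows():
        k, n, b = int(row.markers_recovered), int(row.markers_total), float(row.background)
        if b <= 0:
            pvals.append(0.0 if k > 0 else 1.0)
        elif b >= 1:
            pvals.append(1.0)
        else:
            pvals.append(stats.binomtest(k, n, b, alternative="greater").pvalue)
    report["pvalue"] = pvals
    fold_ok = (report["fold"] >= min_fold) | np.isinf(report["fold"])
    report["enriched"] = (report["pvalue"] < alpha) & fold_ok & (report["p"] > report["background"])
    return report


@dataclass
class ChromosomeModel:
    """Chromosome label -> linkage groups it comprises, with library support."""

    chromosomes: dict[str, frozenset[str]]
    support: dict[str, tuple[str, ...]]

    @property
    def partition(self) -> set[frozenset[str]]:
        return set(self.chromosomes.values())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tlinkage_groups\tsupporting_libraries\n")
            for label in sorted(self.chromosomes):
                lgs = ",".join(sorted(self.chromosomes[label]))
                libs = ",".join(self.support[label])
                fh.write(f"{label}\t{lgs}\t{libs}\n")


def coalesce_linkage_groups(report: pd.DataFrame, min_support: int = 2) -> ChromosomeModel:
    """Merge linkage groups repeatedly co-enriched across libraries.

    Two LGs are connected when co-enriched in the same library in at least
    ``min_support`` independent libraries; connected components become
    chromosomes.  An unconnected LG becomes a single-LG chromosome when it
    is enriched in >= ``min_support`` libraries.  With no enriched calls
    the model is empty (not an error).
    """
    enriched = report[report["enriched"]] if "enriched" in report else report.iloc[0:0]
    lib_sets: dict[str, set[str]] = defaultdict(set)
    for _, row in enriched.iterrows():
        lib_sets[row["library"]].add(row["lg"])

    edge_support: dict[tuple[str, str], set[str]] = defaultdict(set)
    node_support: dict[str, set[str]] = defaultdict(set)
    for lib, lgs in lib_sets.items():
        for lg in lgs:
            node_support[lg].add(lib)
        for a in lgs:
            for b in lgs:
                if a < b:
                    edge_support[(a, b)].add(lib)

    graph = nx.Graph()
    for lg, libs in node_support.items():
        if len(libs) >= min_support:
            graph.add_node(lg)
    for (a, b), libs in edge_support.items():
        if len(libs) >= min_support:
            graph.add_edge(a, b)

    chromosomes: dict[str, frozenset[str]] = {}
    support: dict[str, tuple[str, ...]] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components, start=1):
        label = f"chr{i}"
        chromosomes[label] = frozenset(comp)
        libs = set()
        for lg in comp:
            libs |= node_support[lg]
        support[label] = tuple(sorted(libs))
    return ChromosomeModel(chromosomes=chromosomes, support=support)


def write_hits_tsv(hits: dict[str, dict[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library\tmarker\tcount\n")
        for lib in sorted(hits):
            for marker in sorted(hits[lib]):
                fh.write(f"{lib}\t{marker}\t{hits[lib][marker]}\n")


def read_hits_tsv(paths) -> dict[str, dict[str, int]]:
    hits: dict[str, dict[str, int]] = defaultdict(dict)
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for path in paths:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("library\t"):
                    continue
                lib, marker, count = line.split("\t")
                hits[lib][marker] = hits[lib].get(marker, 0) + int(count)
    return dict(hits)
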