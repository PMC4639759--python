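"""Conserved-synteny scoring between an assigned chromosome and a reference
genome.

Given a best-hit ortholog table (query gene -> reference chromosome and
position) and per-chromosome annotated gene totals, the enrichment of a
reference chromosome is the observed ortholog count divided by its total
annotated genes, with a one-sided hypergeometric p-value against uniform
placement.  Ortholog positions along one chromosome are segmented into
synteny blocks at large positional gaps, exposing discontinuous
distributions such as those produced by ancestral fusion/inversion events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """``gene  chrom  pos`` TSV -> DataFrame (one best target per gene)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["gene", "chrom", "pos"], dtype={"chrom": str}
    )
    if df["gene"].duplicated().any():
        raise ValueError("ortholog table must have one best target per query gene")
    if (df["pos"] < 0).any():
        raise ValueError("ortholog positions must be >= 0")
    return df


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """``chrom  n_genes  [length_bp]`` TSV -> DataFrame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "n_genes": int(parts[1]),
                    "length_bp": float(parts[2]) if len(parts) > 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def enrichment_scores(
    orthologs: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome ortholog enrichment E_c = n_c / N_c with p-values.

    n_c = orthologs observed on chromosome c, N_c = genes annotated to c.
    The one-sided p-value is hypergeometric: drawing the total number of
    orthologs from the annotated gene universe, the probability of >= n_c
    landing on c.  Raises if an ortholog names a chromosome missing from
    the annotation.
    """
    ann = annotation.set_index("chrom")
    if (ann["n_genes"] < 1).any():
        raise ValueError("annotated gene counts must be >= 1")
    missing = set(orthologs["chrom"]) - set(ann.index)
    if missing:
        raise ValueError(f"orthologs on chromosomes missing from annotation: {sorted(missing)}")
    n_by_chrom = orthologs["chrom"].value_counts()
    universe = int(ann["n_genes"].sum())
    draws = int(len(orthologs))
    rows = []
    for chrom in ann.index:
        n_c = int(n_by_chrom.get(chrom, 0))
        big_n = int(ann.loc[chrom, "n_genes"])
        pval = float(stats.hypergeom.sf(n_c - 1, universe, big_n, draws)) if n_c else 1.0
        rows.append(
            {
                "chrom": chrom,
                "n_orthologs": n_c,
                "n_annotated": big_n,
                "enrichment": n_c / big_n,
                "pvalue": pval,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Block:
    start: float  # bp, inclusive of the first gene
    end: float  # bp, position of the last gene
    n_genes: int


@dataclass
class SyntenyBlocks:
    """Gap-segmented ortholog clusters along one reference chromosome."""

    chrom: str
    blocks: tuple[Block, ...]
    n_genes_total: int  # before discarding small blocks
    n_genes_discarded: int
    gap_threshold: float
    min_genes: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def write_bed(self, path: str | Path) -> None:
        """Blocks as BED (0-based half-open; end = last gene position + 1)."""
        with open(path, "w") as fh:
            for i, b in enumerate(self.blocks, start=1):
                fh.write(
                    f"{self.chrom}\t{int(b.start)}\t{int(b.end) + 1}\t"
                    f"block{i}\t{b.n_genes}\n"
                )


def segment_blocks(
    orthologs: pd.DataFrame,
    chrom: str,
    gap_threshold: float | None = None,
    min_genes: int = 5,
    chrom_length: float | None = None,
) -> SyntenyBlocks:
    """Segment ortholog positions on ``chrom`` into synteny blocks.

    Positions are sorted and split wherever the gap between consecutive
    genes exceeds ``gap_threshold`` (default: chromosome length / 10 when
    known, else 10 Mb); blocks with fewer than ``min_genes`` genes are
    discarded (single strays are noise, dense clusters are signal), with
    the discarded gene count recorded so totals stay conserved.
    """
    on_chrom = orthologs[orthologs["chrom"] == chrom]
    if on_chrom.empty:
        raise ValueError(f"no orthologs on chromosome {chrom!r}")
    if gap_threshold is None:
        gap_threshold = chrom_length / 10.0 if chrom_length else 10e6
    pos = np.sort(on_chrom["pos"].to_numpy(dtype=float))
    breaks = np.flatnonzero(np.diff(pos) > gap_threshold) + 1
    raw = [
        Block(start=float(seg[0]), end=float(seg[-1]), n_genes=int(seg.size))
        for seg in np.split(pos, breaks)
    ]
    kept = tuple(b for b in raw if b.n_genes >= min_genes)
    discarded = sum(b.n_genes for b in raw) - sum(b.n_genes for b in kept)
    return SyntenyBlocks(
        chrom=chrom,
        blocks=kept,
        n_genes_total=int(pos.size),
        n_genes_discarded=int(discarded),
        gap_threshold=float(gap_threshold),
        min_genes=min_genes,
    )
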