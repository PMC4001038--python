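"""Insertion-density gene fitness for liquid-enrichment transposon sequencing.

A dense random-insertion pool is grown under selection and the surviving
unique insertion sites are compared gene by gene against the genome-wide
site density. A gene's fitness is

    fitness = log2[ (n_window / win_len) / (N / Lambda) ]

where n_window counts unique insertion sites in the gene's 5-85% coding
window, win_len is that window's length, and N / Lambda are the same sums
over all genes. Genes whose insertion density matches the genome-wide
density score 0; a gene whose mutants overgrow the pool accumulates a read-
and site-excess and scores positive. Fitness depends only on unique sites,
never on read depth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome_annotation import GenomeAnnotation, coding_window

INSERTION_COLUMNS = ["chrom", "position", "strand", "reads"]


@dataclass
class InsertionTable:
    """Unique transposon insertion sites with read counts for one grown pool."""

    records: pd.DataFrame  # columns chrom, position, strand, reads
    condition: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = set(INSERTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"insertion table missing columns {sorted(missing)}")
        if df.duplicated(subset=["chrom", "position", "strand"]).any():
            raise ValueError("duplicate (chrom, position, strand) insertion sites")
        if (df["reads"] < 1).any():
            raise ValueError("read counts must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    def unique_sites(self) -> pd.DataFrame:
        """Distinct (chrom, position) sites; strand is ignored for gene
        assignment because a transposon on either strand disrupts the gene."""
        return self.records.drop_duplicates(subset=["chrom", "position"])[
            ["chrom", "position"]
        ]


@dataclass(frozen=True)
class DoublingEstimate:
    final_cells: float
    start_pool: int
    doublings: float
    n_positive_genes: Optional[int] = None


def count_in_window(
    insertions: InsertionTable,
    annotation: GenomeAnnotation,
    f_lo: float = 0.05,
    f_hi: float = 0.85,
) -> pd.DataFrame:
    """Per-gene unique-site counts inside the coding window.

    Returns a frame indexed like the annotation with columns gene_id,
    n_window, win_len. Sites outside every window contribute to no gene;
    a site inside two overlapping genes' windows counts for both.
    """
    sites = insertions.unique_sites()
    pos_by_chrom = {
        chrom: np.sort(grp["position"].to_numpy())
        for chrom, grp in sites.groupby("chrom")
    }
    rows = []
    for gene in annotation:
        win = coding_window(gene, f_lo, f_hi)
        pos = pos_by_chrom.get(gene.chrom)
        if pos is None or win.win_len == 0:
            n = 0
        else:
            n = int(
                np.searchsorted(pos, win.win_end, side="right")
                - np.searchsorted(pos, win.win_start, side="left")
            )
        rows.append({"gene_id": gene.gene_id, "n_window": n, "win_len": win.win_len})
    return pd.DataFrame(rows, columns=["gene_id", "n_window", "win_len"])


def tnle_gene_fitness(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Log2 insertion-density ratio per gene.

    Genes with no in-window site would score -inf; they instead receive the
    pseudocount and are flagged (``flagged_zero``) so downstream positive-
    fitness logic can exclude non-measurements.
    """
    n = counts["n_window"].to_numpy(dtype=float)
    win_len = counts["win_len"].to_numpy(dtype=float)
    N = n.sum()
    if N == 0:
        raise ValueError("no in-window insertions: cannot form the global density")
    lam = win_len.sum()
    global_density = N / lam
    flagged = n == 0
    numer = np.where(flagged, pseudocount, n)
    with np.errstate(divide="ignore"):
        fitness = np.log2((numer / win_len) / global_density)
    out = counts.copy()
    out["fitness"] = fitness
    out["flagged_zero"] = flagged
    return out


def fold_change(f: float) -> float:
    """Fold change in relative abundance for a log2 fitness value."""
    return float(2.0 ** f)


def log2_fold(fold: float) -> float:
    """Inverse of :func:`fold_change`."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return float(math.log2(fold))


def positive_fitness_set(records: pd.DataFrame) -> tuple[list[str], int]:
    """Genes with strictly positive fitness, and their summed in-window sites.

    The summed site count is the effective starting pool for the doublings
    estimate: under strong selection only these genes' mutants contribute
    appreciably to the final population. Pseudocount-flagged genes never
    qualify (their fitness is an artifact of the zero-count fill).
    """
    mask = (records["fitness"] > 0) & (~records["flagged_zero"])
    sel = records.loc[mask]
    return sel["gene_id"].tolist(), int(sel["n_window"].sum())


def estimate_doublings(
    final_cells: float, start_pool: int, n_positive_genes: Optional[int] = None
) -> DoublingEstimate:
    """Population doublings = log2(final cell count / effective starting pool)."""
    if start_pool < 1:
        raise ValueError("start_pool must be >= 1")
    if final_cells < start_pool:
        raise ValueError("final_cells must be >= start_pool")
    return DoublingEstimate(
        final_cells=float(final_cells),
        start_pool=int(start_pool),
        doublings=float(math.log2(final_cells / start_pool)),
        n_positive_genes=n_positive_genes,
    )


def run_tnle(
    insertions: InsertionTable,
    annotation: GenomeAnnotation,
    pseudocount: float = 1.0,
    final_cells: Optional[float] = None,
) -> tuple[pd.DataFrame, Optional[DoublingEstimate]]:
    """Full pipeline: window counts -> fitness -> optional doublings estimate."""
    counts = count_in_window(insertions, annotation)
    records = tnle_gene_fitness(counts, pseudocount=pseudocount)
    estimate = None
    if final_cells is not None:
        genes, pool = positive_fitness_set(records)
        if pool >= 1:
            estimate = estimate_doublings(final_cells, pool, n_positive_genes=len(genes))
    return records, estimate


def read_insertions_tsv(path: str | os.PathLike, condition: str = "") -> InsertionTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "position": int, "strand": str, "reads": int}
    )
    return InsertionTable(df, condition=condition)


def write_insertions_tsv(table: InsertionTable, path: str | os.PathLike) -> None:
    table.records.to_csv(path, sep="\t", index=False)
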