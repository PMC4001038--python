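"""Gene/operon coordinate model shared by both fitness pipelines.

Coordinates in files (GFF3 and the 7-column TSV dialect) are 1-based
inclusive. Internal window arithmetic uses 0-based half-open offsets;
conversion happens only at the I/O boundary of each function.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "operon_id", "is_pseudo"]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Gene:
    """One gene: 1-based inclusive span on a chromosome strand.

    ``operon_id`` groups consecutive same-strand genes predicted to be
    co-transcribed; ``is_pseudo`` marks pseudogenes, which are retained and
    scored like ordinary genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    operon_id: Optional[str] = None
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CodingWindow:
    """The insertion-scoring window of a gene (1-based inclusive span).

    Only insertions between fractions ``f_lo`` and ``f_hi`` of the coding
    sequence, measured 5'->3' on the coding strand, count toward fitness;
    insertions near either terminus often leave a functional product.
    """

    gene_id: str
    win_start: int
    win_end: int
    win_len: int


@dataclass(frozen=True)
class MappedPosition:
    """Result of locating a genomic position against the annotation.

    ``gene_ids`` lists every containing gene (>=1 for genic hits, usually
    exactly one since synthetic genomes are non-overlapping). For intergenic
    positions it is empty and ``label`` carries the nearest strand-aware
    downstream gene and the distance to its 5' end, e.g.
    ``"intergenic:327bp_upstream_of:DVU0590"``.
    """

    gene_ids: tuple[str, ...]
    label: str
    nearest_gene: Optional[str] = None
    distance: Optional[int] = None

    @property
    def is_intergenic(self) -> bool:
        return not self.gene_ids


@dataclass
class GenomeAnnotation:
    """Ordered gene records plus chromosome bounds and operon membership."""

    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self.validate()

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome "
                    f"{g.chrom} length {self.chrom_lengths[g.chrom]}"
                )
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise AnnotationError("duplicate gene_id in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[Gene]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except AttributeError:
            self._by_id = {g.gene_id: g for g in self.genes}
            return self._by_id[gene_id]

    @property
    def operons(self) -> dict[str, str]:
        """Mapping gene_id -> operon_id for genes with a prediction."""
        return {g.gene_id: g.operon_id for g in self.genes if g.operon_id}

    def adjacent_operon_pairs(self) -> list[tuple[str, str]]:
        """Pairs of adjacent genes predicted to share an operon.

        Operon members are consecutive same-strand genes, so adjacency in
        chromosome order within an operon id is the pairing used by the
        operon-correlation quality metric.
        """
        pairs = []
        for a, b in zip(self.genes, self.genes[1:]):
            if (
                a.chrom == b.chrom
                and a.operon_id is not None
                and a.operon_id == b.operon_id
                and a.strand == b.strand
            ):
                pairs.append((a.gene_id, b.gene_id))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "operon_id": g.operon_id if g.operon_id is not None else "",
                    "is_pseudo": g.is_pseudo,
                }
                for g in self.genes
            ],
            columns=TSV_COLUMNS,
        )


def coding_window(gene: Gene, f_lo: float = 0.05, f_hi: float = 0.85) -> CodingWindow:
    """Scoring window of a gene: offsets o with floor(f_lo*L) <= o < floor(f_hi*L).

    Offsets are 0-based from the 5' end of the coding strand: from ``start``
    on '+' genes, from ``end`` on '-' genes. Returned coordinates are 1-based
    inclusive genome positions; ``win_len = floor(f_hi*L) - floor(f_lo*L)``.
    """
    if not (0.0 <= f_lo < f_hi <= 1.0):
        raise ValueError(f"require 0 <= f_lo < f_hi <= 1, got ({f_lo}, {f_hi})")
    L = gene.length
    lo = math.floor(f_lo * L)
    hi = math.floor(f_hi * L)
    if gene.strand == "+":
        win_start, win_end = gene.start + lo, gene.start + hi - 1
    else:
        win_start, win_end = gene.end - hi + 1, gene.end - lo
    return CodingWindow(gene.gene_id, win_start, win_end, hi - lo)


def in_window(window: CodingWindow, position: int) -> bool:
    return window.win_start <= position <= window.win_end


def map_position(annotation: GenomeAnnotation, chrom: str, position: int) -> MappedPosition:
    """Locate a 1-based position: containing gene(s), else an intergenic label.

    Intergenic positions are labelled by the nearest gene they lie upstream
    of (strand-aware 5' distance), following the convention of labels like
    "intergenic region 327 bp upstream of <gene>"; if the position is not
    upstream of any gene, the nearest gene by absolute distance is used with
    a ``near`` label.
    """
    if chrom not in annotation.chrom_lengths:
        raise AnnotationError(f"unknown chromosome {chrom}")
    if not (1 <= position <= annotation.chrom_lengths[chrom]):
        raise AnnotationError(
            f"position {position} outside chromosome {chrom} "
            f"[1, {annotation.chrom_lengths[chrom]}]"
        )
    hits = tuple(
        g.gene_id
        for g in annotation.genes
        if g.chrom == chrom and g.start <= position <= g.end
    )
    if hits:
        return MappedPosition(hits, hits[0] if len(hits) == 1 else "|".join(hits))

    upstream_of: list[tuple[int, str]] = []
    nearest: list[tuple[int, str]] = []
    for g in annotation.genes:
        if g.chrom != chrom:
            continue
        if g.strand == "+" and position < g.start:
            upstream_of.append((g.start - position, g.gene_id))
        elif g.strand == "-" and position > g.end:
            upstream_of.append((position - g.end, g.gene_id))
        nearest.append((min(abs(position - g.start), abs(position - g.end)), g.gene_id))
    if upstream_of:
        dist, gid = min(upstream_of)
        return MappedPosition((), f"intergenic:{dist}bp_upstream_of:{gid}", gid, dist)
    if nearest:
        dist, gid = min(nearest)
        return MappedPosition((), f"intergenic:{dist}bp_near:{gid}", gid, dist)
    return MappedPosition((), "intergenic:no_genes_on_chrom")


def read_annotation(path: str | os.PathLike, format: Optional[str] = None) -> GenomeAnnotation:
    """Load a GenomeAnnotation from GFF3 or the 7-column TSV dialect.

    ``format`` is inferred from the extension when omitted. Both dialects are
    1-based inclusive. The TSV header is gene_id/chrom/start/end/strand/
    operon_id/is_pseudo; GFF3 carries operon_id and is_pseudo as attributes
    and chromosome lengths as ``##sequence-region`` pragmas.
    """
    path = os.fspath(path)
    if format is None:
        format = "gff3" if path.endswith((".gff", ".gff3")) else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_tsv(path: str) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for i, row in df.iterrows():
        try:
            genes.append(
                Gene(
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    operon_id=row["operon_id"] if pd.notna(row["operon_id"]) and row["operon_id"] != "" else None,
                    is_pseudo=str(row["is_pseudo"]).lower() in ("true", "1", "yes"),
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path} line {i + 2}: {exc}") from exc
    chrom_lengths = _infer_chrom_lengths(path, genes)
    return GenomeAnnotation(chrom_lengths, genes)


def _infer_chrom_lengths(path: str, genes: list[Gene]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region") or line.startswith("#chrom_length"):
                parts = line.split()
                lengths[parts[1]] = int(parts[-1])
    for g in genes:
        if g.chrom not in lengths:
            lengths[g.chrom] = max(
                lengths.get(g.chrom, 0), max(x.end for x in genes if x.chrom == g.chrom)
            )
    return lengths


def _read_gff3(path: str) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        operon = attrs.get("operon_id", [None])[0] or None
        pseudo = (attrs.get("is_pseudo", ["false"])[0]).lower() in ("true", "1", "yes")
        gene_id = attrs.get("ID", [feat.id])[0]
        try:
            genes.append(
                Gene(gene_id, feat.seqid, feat.start, feat.end, feat.strand, operon, pseudo)
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path} feature {gene_id}: {exc}") from exc
    chrom_lengths = _infer_chrom_lengths(path, genes)
    return GenomeAnnotation(chrom_lengths, genes)


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    with open(path, "w") as fh:
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"#chrom_length\t{chrom}\t{length}\n")
        annotation.to_frame().to_csv(fh, sep="\t", index=False)


def write_annotation_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.operon_id:
                attrs.append(f"operon_id={g.operon_id}")
            if g.is_pseudo:
                attrs.append("is_pseudo=true")
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "tnfit",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
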