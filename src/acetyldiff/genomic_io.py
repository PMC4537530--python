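"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open (BED-native). The only
place a different convention appears is the variant table, whose
positions are 1-based in the file and converted on read. Chromosome
names are matched by exact string equality; an optional normalisation
helper can strip or add a ``chr`` prefix, but nothing happens silently.

Malformed lines are fatal and reported with their line number: a
deterministic pipeline beats a permissive parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "VariantRecord",
    "TermAnnotation",
    "BedRecord",
    "BedTable",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_term_table",
    "write_term_table",
    "read_variant_table",
    "write_variant_table",
    "normalize_chrom",
]


class FormatError(ValueError):
    """Raised for any malformed input file; carries the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its stranded transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS {self.tss}")


@dataclass(frozen=True)
class VariantRecord:
    """A catalog SNP-trait association. ``position`` is 0-based internally."""

    snp_id: str
    chrom: str
    position: int
    trait: str
    p_value: float
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(
                f"variant {self.snp_id}: p-value {self.p_value} outside (0, 1]"
            )
        if self.position < 0:
            raise ValueError(f"variant {self.snp_id}: negative position")


@dataclass(frozen=True)
class TermAnnotation:
    gene_id: str
    ontology: str
    term_id: str
    term_name: str


class BedRecord(NamedTuple):
    interval: GenomicInterval
    name: Optional[str] = None
    score: Optional[float] = None


@dataclass
class BedTable:
    """Parsed BED content: records in file order plus a sortedness flag."""

    records: list[BedRecord]
    is_sorted: bool = True

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.records]


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalise a chromosome name to ``chr``-prefixed or bare style.

    Explicit opt-in only; no reader applies this by itself.
    """
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "bare":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome style {style!r}")


def _coordinate_sorted(records: Sequence[BedRecord]) -> bool:
    prev = None
    for r in records:
        key = (r.interval.chrom, r.interval.start, r.interval.end)
        if prev is not None and key < prev:
            return False
        prev = key
    return True


def read_bed(path: Union[str, Path], expected_columns: int = 3) -> BedTable:
    """Read a BED3/BED6 file into validated intervals.

    Every line must carry at least ``expected_columns`` (>= 3) tab-separated
    fields. Input order is preserved; ``is_sorted`` reports whether the file
    was coordinate-sorted. Malformed lines raise :class:`FormatError` with
    the line number.
    """
    if expected_columns < 3:
        raise ValueError("BED requires at least 3 columns")
    path = Path(path)
    records: list[BedRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < expected_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {expected_columns} columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            name = fields[3] if len(fields) > 3 else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append(BedRecord(iv, name, score))
    return BedTable(records=records, is_sorted=_coordinate_sorted(records))


def write_bed(
    records: Iterable[Union[BedRecord, GenomicInterval]],
    path: Union[str, Path],
    columns: int = 3,
    sort: bool = False,
) -> None:
    """Write intervals as BED (0-based half-open, tab-separated, no header).

    ``columns`` is 3 or 6; with 6, missing names become ``.`` and missing
    scores ``0``. ``sort=True`` writes coordinate-sorted output.
    """
    recs = [r if isinstance(r, BedRecord) else BedRecord(r) for r in records]
    if sort:
        recs = sorted(recs, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in recs:
            iv = r.interval
            if columns == 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = r.name if r.name is not None else "."
                score = r.score if r.score is not None else 0
                if isinstance(score, float) and score == int(score):
                    score = int(score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def _read_table(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_gene_table(path: Union[str, Path]) -> list[GeneRecord]:
    """Read a gene TSV (columns: gene_id, chrom, strand, tss_position)."""
    df = _read_table(path, ["gene_id", "chrom", "strand", "tss_position"])
    genes = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(
                GeneRecord(row.gene_id, row.chrom, row.strand, int(row.tss_position))
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{idx}: {exc}") from None
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise FormatError(f"{path}: duplicate gene_id(s): {', '.join(sorted(dups)[:5])}")
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss_position"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_term_table(path: Union[str, Path]) -> list[TermAnnotation]:
    """Read gene→term annotations; duplicate (gene, ontology, term) rows collapse."""
    df = _read_table(path, ["gene_id", "ontology", "term_id", "term_name"])
    seen = set()
    out = []
    for row in df.itertuples(index=False):
        key = (row.gene_id, row.ontology, row.term_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(TermAnnotation(row.gene_id, row.ontology, row.term_id, row.term_name))
    return out


def write_term_table(terms: Iterable[TermAnnotation], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [(t.gene_id, t.ontology, t.term_id, t.term_name) for t in terms],
        columns=["gene_id", "ontology", "term_id", "term_name"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_variant_table(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a GWAS-catalog-style variant TSV.

    File positions are 1-based and converted to the internal 0-based
    convention. Duplicate (snp_id, trait) rows collapse to the smallest
    p-value.
    """
    df = _read_table(
        path, ["snp_id", "chrom", "position_1based", "trait", "p_value"]
    )
    best: dict[tuple[str, str], VariantRecord] = {}
    order: list[tuple[str, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            p = float(row.p_value)
        except ValueError:
            raise FormatError(
                f"{path}:{idx}: unparseable p-value {row.p_value!r}"
            ) from None
        try:
            pos1 = int(row.position_1based)
            rec = VariantRecord(
                snp_id=row.snp_id,
                chrom=row.chrom,
                position=pos1 - 1,
                trait=row.trait,
                p_value=p,
                source_ref=getattr(row, "pubmed_id", ""),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{idx}: {exc}") from None
        key = (rec.snp_id, rec.trait)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.p_value < best[key].p_value:
            best[key] = rec
    return [best[k] for k in order]


def write_variant_table(variants: Iterable[VariantRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            (v.snp_id, v.chrom, v.position + 1, v.trait, repr(v.p_value), v.source_ref)
            for v in variants
        ],
        columns=["snp_id", "chrom", "position_1based", "trait", "p_value", "pubmed_id"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
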