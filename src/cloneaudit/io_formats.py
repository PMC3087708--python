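"""Readers and writers for the external representations the pipeline touches.

Coordinate conventions are strict: everything in memory is 0-based
half-open; the 1-based inclusive convention of GFF3 (and of the TSV gene
dialect, which mirrors it) exists only at the file boundary. Plate
locations follow the arrayed-library literal form ``<chrom>-<plate><row><col>``
(e.g. ``IV-2B04``) on a 384-well geometry, 16 rows A-P by 24 columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_DNA_GENOME = set("ACGTN")
_DNA_PRIMER = set("ACGT")

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24

_LOCATION_RE = re.compile(r"^([A-Za-z0-9]+)-(\d+)([A-Z])(\d{1,2})$")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class GeneStatus(str, Enum):
    ALIVE = "ALIVE"
    RETIRED = "RETIRED"


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: an uppercase DNA string over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise FormatError("empty chromosome id")
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.chrom_id!r}")
        bad = set(self.sequence) - _DNA_GENOME
        if bad:
            raise FormatError(
                f"sequence {self.chrom_id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus with strand and alive/retired annotation status.

    ``start``/``end`` are 0-based half-open on the forward strand of
    ``chrom_id``.
    """

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    status: GeneStatus = GeneStatus.ALIVE

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")


@dataclass(frozen=True, order=True)
class PlateLocation:
    """A well on an arrayed 384-well plate, e.g. ``IV-2B04``."""

    chrom_label: str
    plate_no: int
    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise FormatError(f"plate row {self.row!r} outside A-{PLATE_ROWS[-1]}")
        if not (1 <= self.col <= PLATE_COLS):
            raise FormatError(f"plate column {self.col} outside 1-{PLATE_COLS}")
        if self.plate_no < 1:
            raise FormatError(f"plate number {self.plate_no} must be positive")

    @property
    def row_index(self) -> int:
        """1-based row number (A=1 ... P=16)."""
        return PLATE_ROWS.index(self.row) + 1

    @classmethod
    def from_text(cls, text: str) -> "PlateLocation":
        m = _LOCATION_RE.match(text.strip())
        if m is None:
            raise FormatError(f"malformed plate location {text!r}")
        chrom, plate, row, col = m.groups()
        return cls(chrom_label=chrom, plate_no=int(plate), row=row, col=int(col))

    def __str__(self) -> str:
        return f"{self.chrom_label}-{self.plate_no}{self.row}{self.col:02d}"

    @property
    def plate_key(self) -> tuple[str, int]:
        return (self.chrom_label, self.plate_no)


@dataclass(frozen=True)
class CloneRecord:
    """One library well: a named clone, its primer pair, its annotated
    target gene and its plate location."""

    clone_name: str
    fwd_primer: str
    rev_primer: str
    annotated_gene: str
    location: PlateLocation

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.fwd_primer), ("reverse", self.rev_primer)):
            if len(primer) < 10:
                raise FormatError(
                    f"clone {self.clone_name!r}: {label} primer shorter than 10 nt"
                )
            bad = set(primer) - _DNA_PRIMER
            if bad:
                raise FormatError(
                    f"clone {self.clone_name!r}: {label} primer has non-ACGT characters "
                    f"{sorted(bad)}"
                )


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a genome FASTA into :class:`GenomeSequence` records.

    Sequences are uppercased; record order is preserved. An empty file,
    an empty record, or a duplicated id raises :class:`FormatError`.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate chromosome id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def _parse_status(raw: str | None, where: str) -> GeneStatus:
    if raw is None or raw == "":
        return GeneStatus.ALIVE
    try:
        return GeneStatus(raw.upper())
    except ValueError:
        raise FormatError(f"{where}: unknown gene status {raw!r}") from None


def _gene_from_1based(gene_id: str, chrom: str, start1: int, end1: int, strand: str,
                      status: GeneStatus, where: str) -> GeneRecord:
    if start1 > end1:
        raise FormatError(f"{where}: start {start1} > end {end1}")
    try:
        return GeneRecord(gene_id, chrom, start1 - 1, end1, strand, status)
    except FormatError as exc:
        raise FormatError(f"{where}: {exc}") from None


def read_gene_table(path: str | Path, dialect: str = "gff3") -> list[GeneRecord]:
    """Read a gene annotation table.

    ``dialect='gff3'`` expects 9-column GFF3 ``gene`` features with ``ID=``
    and an optional ``status=`` attribute; ``dialect='tsv'`` expects columns
    ``gene_id  chrom  start  end  strand  [status]``. Both file dialects use
    1-based inclusive coordinates; returned records are 0-based half-open.
    """
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            where = f"{path}:{lineno}"
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) != 9:
                    raise FormatError(f"{where}: expected 9 GFF3 columns, got {len(fields)}")
                chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = fields
                if ftype != "gene":
                    continue
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gene_id = attr_map.get("ID")
                if not gene_id:
                    raise FormatError(f"{where}: gene feature without ID attribute")
                status = _parse_status(attr_map.get("status"), where)
            else:
                if fields and fields[0].lower() == "gene_id":  # header row
                    continue
                if len(fields) not in (5, 6):
                    raise FormatError(f"{where}: expected 5 or 6 TSV columns, got {len(fields)}")
                gene_id, chrom, start1, end1, strand = fields[:5]
                status = _parse_status(fields[5] if len(fields) == 6 else None, where)
            if gene_id in seen:
                raise FormatError(f"{where}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                _gene_from_1based(gene_id, chrom, int(start1), int(end1), strand, status, where)
            )
    return genes


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """Read a clone/primer TSV with header
    ``clone_name  fwd  rev  annotated_gene  location``."""
    clones: list[CloneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["clone_name", "fwd", "rev", "annotated_gene", "location"]
        if [h.strip().lower() for h in header] != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            name, fwd, rev, gene, loc = (f.strip() for f in fields)
            try:
                location = PlateLocation.from_text(loc)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            clones.append(CloneRecord(name, fwd.upper(), rev.upper(), gene, location))
    return clones


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path,
                     dialect: str = "gff3") -> None:
    """Write genes back out in the requested dialect (inverse of
    :func:`read_gene_table`)."""
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id};status={g.status.value}"
                fh.write(
                    f"{g.chrom_id}\tcloneaudit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
        elif dialect == "tsv":
            fh.write("gene_id\tchrom\tstart\tend\tstrand\tstatus\n")
            for g in genes:
                fh.write(
                    f"{g.gene_id}\t{g.chrom_id}\t{g.start + 1}\t{g.end}\t{g.strand}\t"
                    f"{g.status.value}\n"
                )
        else:
            raise ValueError(f"unknown gene-table dialect {dialect!r}")


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.chrom_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_clone_table(clones: Iterable[CloneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_name\tfwd\trev\tannotated_gene\tlocation\n")
        for c in clones:
            fh.write(
                f"{c.clone_name}\t{c.fwd_primer}\t{c.rev_primer}\t{c.annotated_gene}\t"
                f"{c.location}\n"
            )


def write_evaluation_table(evaluations: Sequence, path: str | Path) -> None:
    """Write one TSV row per evaluated clone.

    Rows are ordered by plate then well so repeated runs produce
    byte-identical output.
    """
    rows = sorted(
        evaluations,
        key=lambda e: (e.location.chrom_label, e.location.plate_no,
                       e.location.row, e.location.col),
    )
    with open(path, "w") as fh:
        fh.write(
            "clone_name\tlocation\tscore\tcategory\tflags\tpredicted_targets\tn_amplicons\n"
        )
        for e in rows:
            flags = ",".join(sorted(e.flags))
            targets = ",".join(
                f"{t.gene_id}:{t.identity:.3f}:{t.aligned_length}" for t in e.predicted_targets
            )
            fh.write(
                f"{e.clone_name}\t{e.location}\t{e.score}\t{e.category.name}\t"
                f"{flags}\t{targets}\t{len(e.amplicons)}\n"
            )
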