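"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: FASTA (sequences), BED3/BED4 (0-based half-open
intervals), JASPAR PFM text (motif count matrices) and TSV tables with a
header row.  Coordinates are never converted between 0- and 1-based: BED
input is retained verbatim and all internal intervals are 0-based
half-open.  All writers emit UTF-8 with LF line endings, and every writer's
output is accepted by its paired parser.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as _bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input stream violates its declared format."""


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, with an identifier.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is '+', '-' or '.'.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start {self.start} in region {self.id!r}")
        if self.end <= self.start:
            raise FormatError(
                f"end {self.end} <= start {self.start} in region {self.id!r}"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PWM:
    """A position frequency/weight matrix over the ACGT alphabet.

    ``matrix`` holds one row per base in A, C, G, T order and one column per
    motif position; entries may be counts or probabilities, all
    non-negative, with no column entirely zero.
    """

    id: str
    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise FormatError(f"PWM {self.id!r}: matrix must be 4 x width")
        if self.matrix.shape[1] < 1:
            raise FormatError(f"PWM {self.id!r}: zero width")
        if (self.matrix < 0).any():
            raise FormatError(f"PWM {self.id!r}: negative entries")
        if (self.matrix.sum(axis=0) == 0).any():
            raise FormatError(f"PWM {self.id!r}: column with all-zero counts")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Column-normalized matrix (each column sums to 1)."""
        return self.matrix / self.matrix.sum(axis=0, keepdims=True)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits relative to uniform background."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return 2.0 + h


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(stream: IO[str] | str) -> list[tuple[str, str]]:
    """Parse FASTA records into ``(id, sequence)`` pairs, order preserved.

    Sequences are upper-cased; the alphabet is ACGTN (case-insensitive).
    """
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    text = handle.read()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError("sequence data before first FASTA header")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], stream: IO[str]) -> None:
    seqrecs = (SeqRecord(Seq(s), id=i, description="") for i, s in records)
    SeqIO.write(seqrecs, stream, "fasta")


def read_fasta_file(path) -> list[tuple[str, str]]:
    with open(path, encoding="utf-8") as fh:
        return parse_fasta(fh)


def write_fasta_file(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        write_fasta(records, fh)


def sequences_from_genome(genome_fasta_path, regions: Sequence[Region]) -> list[tuple[str, str]]:
    """Extract region sequences from an indexed genome FASTA (via pyfaidx)."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta_path))
    out = []
    for r in regions:
        if r.chrom not in genome:
            raise KeyError(f"chromosome {r.chrom!r} not in genome FASTA")
        out.append((r.id, str(genome[r.chrom][r.start : r.end]).upper()))
    return out


# ---------------------------------------------------------------------------
# BED


def parse_bed(stream: IO[str] | str) -> list[Region]:
    """Parse BED3/BED4(+) lines into :class:`Region` objects.

    Coordinates are kept verbatim (0-based half-open).  Column 4, when
    present, is the region id; otherwise ``chrom:start-end`` is generated.
    Column 6, when present, is the strand.
    """
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    regions: list[Region] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"line {lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric coordinates") from exc
        if end <= start:
            raise FormatError(f"line {lineno}: end {end} <= start {start}")
        name = cols[3] if len(cols) >= 4 and cols[3] not in ("", ".") else ""
        strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
        regions.append(Region(cols[0], start, end, name, strand))
    return regions


def write_bed(regions: Iterable[Region], stream: IO[str]) -> None:
    for r in regions:
        stream.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def read_bed_file(path) -> list[Region]:
    with open(path, encoding="utf-8") as fh:
        return parse_bed(fh)


def write_bed_file(regions: Iterable[Region], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        write_bed(regions, fh)


# ---------------------------------------------------------------------------
# JASPAR PFM


def parse_jaspar_pfm(stream: IO[str] | str) -> list[PWM]:
    """Parse JASPAR text PFMs (``>ID name`` header, labelled A/C/G/T rows).

    Row order in the file is irrelevant: rows are matched by their base
    label and normalized to A, C, G, T order.  Counts are preserved as
    given.
    """
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    text = handle.read()
    if not text.strip():
        return []
    # Pre-validate per record: exactly the four base rows, equal widths.
    for block in text.split(">")[1:]:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header, rows = lines[0], lines[1:]
        labels = []
        widths = []
        for row in rows:
            label = row.strip()[:1].upper()
            labels.append(label)
            widths.append(len(row.replace("[", " ").replace("]", " ").split()) - 1)
        missing = set("ACGT") - set(labels)
        if missing:
            raise FormatError(
                f"motif {header.split()[0]!r}: missing base row(s) {sorted(missing)}"
            )
        if len(set(widths)) > 1:
            raise FormatError(f"motif {header.split()[0]!r}: rows of unequal width")
    try:
        bio = _bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # malformed numbers etc.
        raise FormatError(f"malformed JASPAR PFM stream: {exc}") from exc
    pwms = []
    for m in bio:
        mat = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
        pwms.append(PWM(id=m.matrix_id or m.name, matrix=mat, name=m.name or ""))
    ids = [p.id for p in pwms]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate motif ids in PFM stream")
    return pwms


def write_jaspar_pfm(pwms: Iterable[PWM], stream: IO[str]) -> None:
    for p in pwms:
        stream.write(f">{p.id} {p.name or p.id}\n")
        for b, row in zip(ALPHABET, p.matrix):
            vals = " ".join(f"{v:g}" for v in row)
            stream.write(f"{b} [ {vals} ]\n")


def read_jaspar_file(path) -> list[PWM]:
    with open(path, encoding="utf-8") as fh:
        return parse_jaspar_pfm(fh)


def write_jaspar_file(pwms: Iterable[PWM], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        write_jaspar_pfm(pwms, fh)


# ---------------------------------------------------------------------------
# TSV tables


@dataclass
class TableSchema:
    """Column contract for :func:`parse_table`.

    ``columns`` maps column name -> dtype; ``index`` names the unique row-id
    column; ``optional`` lists columns tolerated when absent.
    """

    columns: dict[str, type]
    index: str | None = None
    optional: tuple[str, ...] = ()
    allow_extra: bool = True


COUNTS_SCHEMA = TableSchema(columns={}, index="acs_id")
TSS_SCHEMA = TableSchema(
    columns={"gene_id": str, "chrom": str, "strand": str, "tss": int},
    index="gene_id",
)
GENE_FC_SCHEMA = TableSchema(
    columns={"gene_id": str, "log2fc": float, "fdr": float},
    index="gene_id",
    optional=("fdr",),
)


def parse_table(stream: IO[str] | str, schema: TableSchema) -> pd.DataFrame:
    """Parse a TSV with header into a typed DataFrame, validating the schema."""
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    try:
        df = pd.read_csv(handle, sep="\t", header=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"unparseable TSV: {exc}") from exc
    for name, typ in schema.columns.items():
        if name not in df.columns:
            if name in schema.optional:
                continue
            raise FormatError(f"missing required column {name!r}")
        if typ in (int, float):
            try:
                df[name] = pd.to_numeric(df[name])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric value in column {name!r}") from exc
            if typ is int:
                df[name] = df[name].astype(int)
    if schema.index is not None:
        if schema.index not in df.columns:
            raise FormatError(f"missing row-id column {schema.index!r}")
        dup = df[schema.index][df[schema.index].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate row id {dup.iloc[0]!r}")
        df = df.set_index(schema.index)
    return df


def read_counts_table(path) -> pd.DataFrame:
    """Read a counts TSV (rows = ACS, columns = samples) as an integer frame."""
    with open(path, encoding="utf-8") as fh:
        df = parse_table(fh, COUNTS_SCHEMA)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError("non-numeric count value") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError("negative count value")
    return df


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
              lineterminator="\n")
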