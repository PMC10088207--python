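"""Reading and writing the formats the benchmark touches.

FASTA/FASTQ parsing goes through Biopython; SAM through pysam; PAF (a plain
tab-separated format pysam does not read) is parsed here. All coordinates are
normalized to 0-based half-open at this boundary — SAM's 1-based POS never
leaks past the parser.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "ReferenceSequence",
    "RawAlignmentRecord",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "parse_alignments",
    "write_report",
]

PHRED_OFFSET = 33
MAX_PHRED = 93

_DNA_RE = re.compile(r"^[ACGTN]*$")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass
class Read:
    """A basecalled read: sequence plus per-base Phred quality scores."""

    read_id: str
    sequence: str
    qualities: list[int]
    species_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        for q in self.qualities:
            if not 0 <= q <= MAX_PHRED:
                raise FormatError(
                    f"read {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSequence:
    """A reference sequence (chromosome, genome, or resquiggled chunk)."""

    ref_id: str
    sequence: str
    species_label: str = ""
    chromosome_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.ref_id!r}: empty sequence")
        if not _DNA_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(
                f"reference {self.ref_id!r}: non-ACGTN characters {bad}"
            )
        if not self.species_label:
            self.species_label = self.ref_id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RawAlignmentRecord:
    """One read-to-reference alignment as reported by an external aligner.

    Coordinates are 0-based half-open. ``aligned`` is False for records the
    aligner emitted as unmapped; those carry no coordinates or CIGAR but are
    kept so failure rates can be computed.
    """

    read_id: str
    ref_id: str | None = None
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    cigar: str = ""
    md_tag: str | None = None
    aligned: bool = True
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not self.aligned:
            return
        if self.ref_end <= self.ref_start:
            raise FormatError(
                f"alignment of {self.read_id!r}: ref_end {self.ref_end} "
                f"<= ref_start {self.ref_start}"
            )
        consumed = cigar_reference_length(self.cigar)
        if consumed != self.ref_end - self.ref_start:
            raise FormatError(
                f"alignment of {self.read_id!r}: CIGAR consumes {consumed} "
                f"reference bases but span is {self.ref_end - self.ref_start}"
            )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) tuples."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MDN=X")


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MIS=X")


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (possibly gzipped) FASTA file into ReferenceSequence records.

    Sequences are upper-cased; record order is preserved. The species label
    defaults to the record id; a second whitespace-separated header token of
    the form ``species=X chromosome=Y`` overrides labels.
    """
    records: list[ReferenceSequence] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header, got {first!r}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            species = rec.id
            chromosome = None
            for token in rec.description.split()[1:]:
                if token.startswith("species="):
                    species = token[len("species=") :]
                elif token.startswith("chromosome="):
                    chromosome = token[len("chromosome=") :]
            records.append(
                ReferenceSequence(
                    ref_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    species_label=species,
                    chromosome_label=chromosome,
                )
            )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: str | Path) -> list[Read]:
    """Read a (possibly gzipped) 4-line FASTQ file (Phred+33)."""
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0]
                if len(seq) != len(qual):
                    raise FormatError(
                        f"read {read_id!r}: sequence length {len(seq)} "
                        f"!= quality length {len(qual)}"
                    )
                reads.append(
                    Read(
                        read_id=read_id,
                        sequence=seq.upper(),
                        qualities=[ord(c) - PHRED_OFFSET for c in qual],
                    )
                )
        except ValueError as exc:  # Biopython signals malformed records this way
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.ref_id} species={rec.species_label}"
            if rec.chromosome_label is not None:
                header += f" chromosome={rec.chromosome_label}"
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def _sam_record_to_raw(aln: pysam.AlignedSegment) -> RawAlignmentRecord:
    if aln.is_unmapped:
        return RawAlignmentRecord(read_id=aln.query_name, aligned=False)
    cigar = aln.cigarstring or ""
    md = aln.get_tag("MD") if aln.has_tag("MD") else None
    if "M" in cigar and md is None and not aln.has_tag("cs"):
        raise FormatError(
            f"read {aln.query_name!r}: CIGAR uses plain M with no MD or cs tag; "
            "unresolvable mismatches"
        )
    return RawAlignmentRecord(
        read_id=aln.query_name,
        ref_id=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        cigar=cigar,
        md_tag=str(md) if md is not None else None,
        is_primary=not (aln.is_secondary or aln.is_supplementary),
    )


_CS_OP_RE = re.compile(r"(:\d+|\*[a-z]{2}|\+[a-z]+|-[a-z]+|=[A-Za-z]+|~[a-z]{2}\d+[a-z]{2})")


def cs_to_cigar(cs: str) -> str:
    """Convert a minimap2 short-form cs tag into an =/X/I/D CIGAR."""
    parts = _CS_OP_RE.findall(cs)
    if "".join(parts) != cs:
        raise FormatError(f"malformed cs tag {cs!r}")
    out: list[str] = []

    def emit(n: int, op: str) -> None:
        if out and out[-1][-1] == op:
            prev = int(out[-1][:-1])
            out[-1] = f"{prev + n}{op}"
        else:
            out.append(f"{n}{op}")

    for part in parts:
        head, body = part[0], part[1:]
        if head == ":":
            emit(int(body), "=")
        elif head == "=":
            emit(len(body), "=")
        elif head == "*":
            emit(1, "X")
        elif head == "+":
            emit(len(body), "I")
        elif head == "-":
            emit(len(body), "D")
        else:
            raise FormatError(f"unsupported cs op {part!r} (spliced alignment)")
    return "".join(out)


def _parse_paf_line(line: str, lineno: int) -> RawAlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise FormatError(f"PAF line {lineno}: expected >= 12 columns, got {len(fields)}")
    read_id, strand = fields[0], fields[4]
    ref_id = fields[5]
    if ref_id == "*":
        return RawAlignmentRecord(read_id=read_id, aligned=False)
    ref_start, ref_end = int(fields[7]), int(fields[8])
    tags = {f.split(":", 1)[0]: f.split(":", 2)[2] for f in fields[12:] if f.count(":") >= 2}
    if "cs" in tags:
        cigar = cs_to_cigar(tags["cs"])
    elif "cg" in tags:
        cigar = tags["cg"]
        if "M" in cigar:
            raise FormatError(
                f"read {read_id!r}: PAF cg CIGAR uses plain M with no cs tag; "
                "unresolvable mismatches"
            )
    else:
        raise FormatError(f"read {read_id!r}: PAF record without cs or cg tag")
    primary = tags.get("tp", "P") == "P"
    return RawAlignmentRecord(
        read_id=read_id,
        ref_id=ref_id,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        cigar=cigar,
        is_primary=primary,
    )


def parse_alignments(
    path: str | Path, format: str = "sam", primary_only: bool = True
) -> list[RawAlignmentRecord]:
    """Parse SAM or PAF alignments into RawAlignmentRecords.

    Unmapped records are returned flagged ``aligned=False`` rather than
    dropped, so the caller can compute failure rates. With ``primary_only``
    (the default) secondary and supplementary records are discarded.
    """
    records: list[RawAlignmentRecord] = []
    if format == "sam":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                rec = _sam_record_to_raw(aln)
                if primary_only and not rec.is_primary:
                    continue
                records.append(rec)
    elif format == "paf":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = _parse_paf_line(line, lineno)
                if primary_only and not rec.is_primary:
                    continue
                records.append(rec)
    else:
        raise ValueError(f"unknown alignment format {format!r} (expected 'sam' or 'paf')")
    return records


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(rows: Sequence[dict], path: str | Path, format: str = "tsv") -> None:
    """Write keyed records as a TSV or JSON report.

    Columns are emitted in sorted-key order and floats with six significant
    digits, so reports are byte-stable across runs.
    """
    rows = list(rows)
    if rows:
        keys = sorted(rows[0].keys())
        for i, row in enumerate(rows):
            if sorted(row.keys()) != keys:
                raise ValueError(
                    f"row {i} has keys {sorted(row.keys())}, expected {keys}"
                )
    else:
        keys = []
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in rows:
                fh.write("\t".join(_format_value(row[k]) for k in keys) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(
                [{k: row[k] for k in keys} for row in rows],
                fh,
                indent=1,
                default=_format_value,
            )
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
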