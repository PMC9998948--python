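"""Readers, writers, and the shared domain types.

Every other module consumes only the types defined here.  Internal
conventions: coordinates are 0-based half-open; sequences use the DNA
alphabet with U normalized to T on ingest (the original RNA alphabet is
remembered per record); minus-strand hits store coordinates on the forward
strand of the target with an orientation flag.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AnnotationLabel",
    "AlignmentHit",
    "ExpressionTable",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_repeatmasker_table",
    "write_repeatmasker_out",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "load_config",
    "get_logger",
    "revcomp",
]

_VALID = set("ACGTUN")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_RC)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally with Sanger qualities.

    ``seq`` is always over {A,C,G,T,N}; if the source contained U it is
    mapped to T and ``was_rna`` set so writers can restore it.
    """

    id: str
    seq: str
    desc: str = ""
    qual: str | None = None
    was_rna: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: sequence/quality length mismatch "
                f"({len(self.seq)} vs {len(self.qual)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


# Controlled vocabulary: Wicker-style orders and the derivative categories.
ORDERS = {
    "LTR", "DIRS", "PLE", "LINE", "SINE", "TIR", "Maverick", "Helitron",
    "TRIM", "LARD", "MITE", "unknown",
}


@dataclass(frozen=True)
class AnnotationLabel:
    """Class/order/superfamily label in the hierarchical TE classification."""

    te_class: str = "unknown"   # {"I", "II", "unknown"}
    order: str = "unknown"
    superfamily: str = "unknown"

    def __post_init__(self):
        if self.te_class not in {"I", "II", "unknown"}:
            raise ValueError(f"bad TE class {self.te_class!r}")
        if self.superfamily != "unknown" and self.order == "unknown":
            raise ValueError(
                f"superfamily {self.superfamily!r} requires a known order"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """A read-to-consensus alignment segment.

    Coordinates are 0-based half-open on both the read and the consensus,
    always on the forward strand; ``strand`` records orientation.
    ``pct_div`` is percent divergence over the aligned segment.
    """

    read_id: str
    consensus_id: str
    read_start: int
    read_end: int
    cons_start: int
    cons_end: int
    strand: str = "+"
    pct_div: float = 0.0
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.read_start < self.read_end):
            raise ValueError(f"bad read interval [{self.read_start},{self.read_end})")
        if not (0.0 <= self.pct_div <= 100.0):
            raise ValueError(f"pct_div {self.pct_div} outside [0,100]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def read_len(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ExpressionTable:
    """A (row id x sample id) matrix of non-negative values with a unit tag."""

    values: pd.DataFrame
    unit: str = "count"  # {"count", "TPM", "RPM"}

    def __post_init__(self):
        if self.unit not in {"count", "TPM", "RPM"}:
            raise ValueError(f"bad unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column ids must be unique")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _normalize(rec_id: str, seq: str, idx: int) -> tuple[str, bool]:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ParseError(
            f"record {idx} ({rec_id!r}): invalid symbols {sorted(bad)}"
        )
    was_rna = "U" in seq
    if was_rna:
        seq = seq.replace("U", "T")
    return seq, was_rna


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"record {i} ({rec.id!r}): empty sequence")
        seq, was_rna = _normalize(rec.id, seq, i)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, seq, desc, was_rna=was_rna))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            seq = r.seq.replace("T", "U") if r.was_rna else r.seq
            header = f">{r.id}" + (f" {r.desc}" if r.desc else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line FASTQ records (Sanger qualities), validating lengths."""
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = str(rec.seq)
            if not seq:
                raise ParseError(f"record {i} ({rec.id!r}): empty sequence")
            seq, was_rna = _normalize(rec.id, seq, i)
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(SequenceRecord(rec.id, seq, qual=qual, was_rna=was_rna))
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise ParseError(str(exc)) from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            seq = r.seq.replace("T", "U") if r.was_rna else r.seq
            fh.write(f"@{r.id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# RepeatMasker tables

_OUT_HEADER_TOKENS = {"SW", "score", "bit"}


def _parse_rm_fields(fields: list[str]) -> AlignmentHit | None:
    # .out layout: score div del ins query qbeg qend (qleft) strand/C
    #              repeat class/family rbeg rend (rleft) id
    # .align block headers share the leading 9 columns; repeat coords for a
    # "C" hit arrive as (left) rend rbeg.
    score = float(fields[0])
    pct_div = float(fields[1])
    query = fields[4]
    qbeg, qend = int(fields[5]), int(fields[6])
    if fields[8] in {"C", "-"}:
        strand = "-"
        rest = fields[9:]
    elif fields[8] == "+":
        strand = "+"
        rest = fields[9:]
    else:
        strand = "+"
        rest = fields[8:]
    repeat = rest[0]
    # consensus coordinates are the first two bare (non-parenthesized)
    # numbers after the repeat name; "(left)" values and an optional
    # class/family column are skipped
    nums = [int(f) for f in rest[1:5] if f.isdigit()][:2]
    if strand == "+":
        rbeg, rend = nums[0], nums[1]   # printed as: rbeg rend (left)
    else:
        rend, rbeg = nums[0], nums[1]   # printed as: (left) rend rbeg
    if rbeg > rend:
        rbeg, rend = rend, rbeg
    # 1-based inclusive -> 0-based half-open
    return AlignmentHit(
        read_id=query,
        consensus_id=repeat,
        read_start=qbeg - 1,
        read_end=qend,
        cons_start=rbeg - 1,
        cons_end=rend,
        strand=strand,
        pct_div=pct_div,
        score=score,
    )


def parse_repeatmasker_table(path: str | Path, dialect: str = "out") -> list[AlignmentHit]:
    """Parse a RepeatMasker ``.out`` or ``.align`` table into alignment hits.

    Unrecognized lines (headers, alignment text, asterisk continuation
    markers) are skipped and counted; a file yielding no hits despite
    non-blank content raises :class:`ParseError`.
    """
    if dialect not in {"out", "align"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    skipped = 0
    n_content = 0
    log = get_logger()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_content += 1
            fields = line.split()
            if fields[0] in _OUT_HEADER_TOKENS:
                skipped += 1
                continue
            try:
                float(fields[0])
            except ValueError:
                skipped += 1
                continue
            if len(fields) < 11:
                skipped += 1
                continue
            try:
                hit = _parse_rm_fields(fields)
            except (ValueError, IndexError):
                skipped += 1
                continue
            if hit is not None:
                hits.append(hit)
    if skipped:
        log.warning("parse_repeatmasker_table: skipped %d unparseable lines", skipped)
    if not hits and n_content:
        raise ParseError(f"{path}: no parseable alignment lines")
    return hits


def write_repeatmasker_out(
    hits: Sequence[AlignmentHit],
    path: str | Path,
    read_lengths: dict[str, int] | None = None,
    cons_lengths: dict[str, int] | None = None,
) -> None:
    """Write hits in the 15-column ``.out`` layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "SW perc perc perc query position in query matching repeat position in repeat\n"
            "score div. del. ins. sequence begin end (left) repeat class/family begin end (left) ID\n\n"
        )
        for i, h in enumerate(hits, 1):
            qleft = (read_lengths or {}).get(h.read_id, h.read_end) - h.read_end
            rleft = (cons_lengths or {}).get(h.consensus_id, h.cons_end) - h.cons_end
            if h.strand == "+":
                rcols = f"{h.cons_start + 1} {h.cons_end} ({rleft})"
                strand = "+"
            else:
                rcols = f"({rleft}) {h.cons_end} {h.cons_start + 1}"
                strand = "C"
            fh.write(
                f"{h.score:.0f} {h.pct_div:.2f} 0.00 0.00 {h.read_id} "
                f"{h.read_start + 1} {h.read_end} ({qleft}) {strand} "
                f"{h.consensus_id} Unspecified {rcols} {i}\n"
            )


# ---------------------------------------------------------------------------
# TSV matrices, config, logging

def read_matrix_tsv(path: str | Path, unit: str = "count") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, unit=unit)


def write_matrix_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


_logger: logging.Logger | None = None


def get_logger(verbosity: int = 0) -> logging.Logger:
    """Package logger writing to stderr; verbosity 0=WARNING, 1=INFO, 2=DEBUG."""
    global _logger
    if _logger is None:
        _logger = logging.getLogger("tescope")
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
        _logger.addHandler(handler)
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    _logger.setLevel(level)
    return _logger
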