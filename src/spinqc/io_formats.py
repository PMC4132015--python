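"""Readers, writers and core record types for the pipeline's external formats.

This module is the single source of truth for parsing dialects and
coordinate conventions:

* FASTQ is Phred+33 only (Illumina 1.8+); offset-64 input is out of scope.
* BLAST tabular rows keep their native 1-based inclusive coordinates.
  Any internal interval arithmetic converts to 0-based half-open at the
  boundary of the consuming function, never here.
* The 12-column BLAST dialect carries no query/subject lengths; those are
  supplied separately through a reference sidecar table (see
  :mod:`spinqc.orthology`).

Parsing is order-preserving and filter-free: no record is dropped except
the ``*`` unmapped-pool row of an idxstats-style counts table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class Read:
    """A single sequencing read.

    ``id`` is the mate-agnostic stem (trailing ``/1`` / ``/2`` and any
    whitespace-delimited description removed); ``mate`` is 1, 2 or ``None``
    when the pairing convention could not be inferred.
    """

    id: str
    seq: str
    quals: list[int]
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Transcript:
    """An assembled sequence, optionally carrying locus/isoform structure."""

    id: str
    seq: str
    locus_id: Optional[str] = None
    isoform_index: Optional[int] = None
    isoform_total: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ParseError(f"transcript {self.id!r}: empty sequence")
        if self.isoform_index is not None and self.isoform_total is not None:
            if self.isoform_index > self.isoform_total:
                raise ParseError(
                    f"transcript {self.id!r}: isoform index "
                    f"{self.isoform_index} > total {self.isoform_total}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular BLAST output.

    Coordinates are 1-based inclusive as in the format. On the subject a
    reversed interval (``sstart > send``, minus-strand TBLASTN hits) is
    permitted; consumers normalize with :meth:`subject_span`.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def subject_span(self) -> int:
        """Number of subject positions covered by this HSP."""
        return abs(self.send - self.sstart) + 1


@dataclass(frozen=True)
class CountRecord:
    """Per-transcript mapped-read count (idxstats semantics)."""

    transcript_id: str
    length: int
    mapped: int
    unmapped: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParseError(
                f"count record {self.transcript_id!r}: length must be >= 1"
            )
        if self.mapped < 0 or self.unmapped < 0:
            raise ParseError(
                f"count record {self.transcript_id!r}: negative count"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _split_mate(title: str) -> tuple[str, Optional[int]]:
    """Infer the mate number from a FASTQ title line.

    Handles the classic ``name/1`` suffix and the Casava 1.8+ style where
    the mate is the first character of the second whitespace field
    (``name 1:N:0:ACGT``). Anything else is treated as unpaired.
    """
    fields = title.split()
    name = fields[0]
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    if len(fields) > 1 and fields[1][:1] in ("1", "2") and ":" in fields[1]:
        return name, int(fields[1][0])
    return name, None


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records as :class:`Read` objects, in file order."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            stem, mate = _split_mate(rec.description or rec.id)
            yield Read(
                id=stem,
                seq=str(rec.seq),
                quals=list(rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
    except ValueError as exc:  # Biopython names the offending record
        raise ParseError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], handle_or_path: Union[TextIO, PathLike]) -> int:
    """Write reads as 4-line FASTQ with Unix line endings; returns count."""
    own = isinstance(handle_or_path, (str, Path))
    fh = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for r in reads:
            name = f"{r.id}/{r.mate}" if r.mate in (1, 2) else r.id
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{name}\n{r.seq}\n+\n{qual}\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> Iterator[tuple[str, str]]:
    """Stream ``(id, sequence)`` pairs; ids are cut at the first whitespace.

    Wrapped sequence lines are concatenated. A header with no sequence is a
    parse error, as is sequence text before any header.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        yield rec.id, seq


def write_fasta(
    seqs: Iterable[tuple[str, str]],
    handle_or_path: Union[TextIO, PathLike],
    wrap: Optional[int] = None,
) -> int:
    """Write ``(id, seq)`` pairs as FASTA; ``wrap=None`` keeps one line per record."""
    own = isinstance(handle_or_path, (str, Path))
    fh = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n


def read_transcripts(path: PathLike) -> Iterator[Transcript]:
    """Read a FASTA of assembled transcripts, decoding locus-style ids."""
    from .assembly_merge import parse_locus_id  # local import: avoid cycle

    for name, seq in read_fasta(path):
        parsed = parse_locus_id(name)
        if parsed is None:
            yield Transcript(id=name, seq=seq)
        else:
            locus, idx, total = parsed
            yield Transcript(
                id=name,
                seq=seq,
                locus_id=str(locus),
                isoform_index=idx,
                isoform_total=total,
            )


# ---------------------------------------------------------------------------
# 12-column tabular BLAST
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = 12


def read_blast_tab(path: PathLike) -> Iterator[BlastHit]:
    """Stream rows of a 12-column tab-separated BLAST table.

    Parsing is filter-free: e-value cutoffs are applied downstream
    (:func:`spinqc.orthology.best_hits`), never here. Extra columns beyond
    the canonical 12 are ignored with a logged warning; fewer than 12 is a
    parse error carrying the line number.
    """
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _BLAST_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_BLAST_COLUMNS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            if len(cols) > _BLAST_COLUMNS and not warned:
                logger.warning(
                    "%s: rows have more than %d columns; extras ignored",
                    path,
                    _BLAST_COLUMNS,
                )
                warned = True
            try:
                yield BlastHit(
                    qseqid=cols[0],
                    sseqid=cols[1],
                    pident=float(cols[2]),
                    length=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def write_blast_tab(
    hits: Iterable[BlastHit], handle_or_path: Union[TextIO, PathLike]
) -> int:
    own = isinstance(handle_or_path, (str, Path))
    fh = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.qseqid,
                        h.sseqid,
                        f"{h.pident:.2f}",
                        h.length,
                        h.mismatch,
                        h.gapopen,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )
            n += 1
    finally:
        if own:
            fh.close()
    return n


# ---------------------------------------------------------------------------
# idxstats-style counts
# ---------------------------------------------------------------------------


def read_counts_tsv(path: PathLike) -> Iterator[CountRecord]:
    """Stream an idxstats-like counts table (name, length, mapped[, unmapped]).

    A terminal ``*`` row (the unmapped pool samtools idxstats appends) is
    silently dropped; the optional fourth column defaults to 0.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "*":
                continue
            if len(cols) not in (3, 4):
                raise ParseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(cols)}"
                )
            try:
                length = int(cols[1])
                mapped = int(cols[2])
                unmapped = int(cols[3]) if len(cols) == 4 else 0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if mapped < 0 or unmapped < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            yield CountRecord(cols[0], length, mapped, unmapped)


def write_counts_tsv(
    records: Iterable[CountRecord], handle_or_path: Union[TextIO, PathLike]
) -> int:
    own = isinstance(handle_or_path, (str, Path))
    fh = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.length}\t{r.mapped}\t{r.unmapped}\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())
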