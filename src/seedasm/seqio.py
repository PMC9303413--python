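"""FASTA/FASTQ input and output and the indexed read store.

Sequences are normalised on ingest: uppercased, ``U`` mapped to ``T`` and
IUPAC ambiguity codes other than ``N`` replaced by ``N`` (nucleotide data
only; protein sequences are uppercased and left alone).  Every record id is
the first whitespace-delimited token of its header and must be unique within
a store.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("seedasm")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*BZJUO")
_AMBIGUITY = frozenset("RYSWKMBDHV")

_MATE_SUFFIXES = ("/1", "/2", ".1", ".2", "_1", "_2")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input; message names the offending line."""


@dataclass
class SeqRecord:
    """A stored sequencing read or query sequence.

    qualities, when present, are Phred scores (one per base).  mate_of links
    the two reads of a pair by id.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    mate_of: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def looks_nucleotide(seq: str, threshold: float = 0.95) -> bool:
    """Heuristic alphabet call: mostly ACGTUN means nucleotide."""
    if not seq:
        return True
    probe = seq[:1000].upper()
    hits = sum(c in "ACGTUN" for c in probe)
    return hits / len(probe) >= threshold


def normalize_sequence(seq: str, alphabet: str = "auto") -> str:
    """Uppercase; for nucleotide data map U->T and ambiguity codes to N."""
    seq = seq.upper()
    if alphabet == "auto":
        alphabet = "nucleotide" if looks_nucleotide(seq) else "protein"
    if alphabet == "protein":
        return seq
    seq = seq.replace("U", "T")
    if any(c in _AMBIGUITY for c in seq):
        logger.warning("ambiguity codes replaced by N")
        seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
    return seq


def _strip_mate_suffix(name: str) -> tuple[str, Optional[int]]:
    for suf in ("/1", "/2"):
        if name.endswith(suf):
            return name[:-2], int(suf[1])
    return name, None


def _header_line_number(path: str | os.PathLike, record_index: int) -> int:
    """Line number (1-based) of the record_index-th FASTA header."""
    seen = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                seen += 1
                if seen == record_index:
                    return lineno
    return 0


def read_fasta(path: str | os.PathLike, alphabet: str = "auto") -> list[SeqRecord]:
    """Parse a FASTA file into records.

    The id is the first whitespace token of the header; sequences are
    normalised (see module docstring).  Malformed headers and empty
    sequences raise :class:`ParseError` naming the line.
    """
    records: list[SeqRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: line 1: expected '>' to start FASTA")
        fh.seek(0)
        try:
            entries = list(SimpleFastaParser(fh))
        except ValueError as exc:  # pragma: no cover - biopython wording
            raise ParseError(f"{path}: {exc}") from exc
    for i, (title, seq) in enumerate(entries):
        tokens = title.split()
        if not tokens:
            raise ParseError(
                f"{path}: line {_header_line_number(path, i)}: empty FASTA header"
            )
        seq = "".join(seq.split())
        if not seq:
            raise ParseError(
                f"{path}: line {_header_line_number(path, i)}: record "
                f"{tokens[0]!r} has an empty sequence"
            )
        records.append(SeqRecord(id=tokens[0], sequence=normalize_sequence(seq, alphabet)))
    return records


def read_fastq(
    path: str | os.PathLike,
    offset: int = 33,
    alphabet: str = "nucleotide",
    link_interleaved_mates: bool = False,
) -> list[SeqRecord]:
    """Parse a 4-line-per-record FASTQ file.

    Qualities are decoded as ``ord(char) - offset`` (Phred+33 by default,
    Phred+64 selectable).  With ``link_interleaved_mates`` consecutive
    records whose names differ only by a ``/1``/``/2`` suffix (or are equal)
    are cross-linked as mates.
    """
    records: list[SeqRecord] = []
    with open(path) as fh:
        try:
            entries = list(FastqGeneralIterator(fh))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    for title, seq, qual in entries:
        name = title.split()[0]
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: record {name!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        quals = [ord(c) - offset for c in qual]
        if quals and min(quals) < 0:
            raise ParseError(
                f"{path}: record {name!r}: negative quality; wrong offset {offset}?"
            )
        records.append(
            SeqRecord(id=name, sequence=normalize_sequence(seq, alphabet), qualities=quals)
        )
    if link_interleaved_mates:
        for a, b in zip(records[::2], records[1::2]):
            base_a, _ = _strip_mate_suffix(a.id)
            base_b, _ = _strip_mate_suffix(b.id)
            if base_a == base_b:
                a.mate_of, b.mate_of = b.id, a.id
    return records


def read_fastq_paired(
    path1: str | os.PathLike, path2: str | os.PathLike, offset: int = 33
) -> list[SeqRecord]:
    """Parse a two-file read pair; mates are linked by shared base name.

    Names are matched after stripping a trailing ``/1``/``/2`` (Illumina
    mate-number comments vanish with the header's first-token rule).  If the
    two names collide exactly, ``/1``/``/2`` suffixes are appended to keep
    ids unique.
    """
    r1 = read_fastq(path1, offset=offset)
    r2 = read_fastq(path2, offset=offset)
    if len(r1) != len(r2):
        raise ParseError(f"paired files differ in record count: {len(r1)} vs {len(r2)}")
    for a, b in zip(r1, r2):
        base_a, _ = _strip_mate_suffix(a.id)
        base_b, _ = _strip_mate_suffix(b.id)
        if base_a != base_b:
            raise ParseError(f"mate name mismatch: {a.id!r} vs {b.id!r}")
        if a.id == b.id:
            a.id, b.id = a.id + "/1", b.id + "/2"
        a.mate_of, b.mate_of = b.id, a.id
    return [rec for pair in zip(r1, r2) for rec in pair]


def write_fasta(
    records: Iterable[SeqRecord | tuple[str, str]],
    path: str | os.PathLike,
    line_width: int = 60,
) -> None:
    """Write records as multi-line FASTA (60 columns by default)."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, SeqRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | os.PathLike, offset: int = 33) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities or [30] * len(rec.sequence)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + offset) for q in quals)
                + "\n"
            )


@dataclass
class ReadStore:
    """Insertion-ordered collection of reads with retrieval by id.

    Plays the role of a blastable read database plus id-based retrieval:
    search scans it, recruitment pulls selected reads back out by id.
    Duplicate ids are rejected.
    """

    _records: dict[str, SeqRecord] = field(default_factory=dict)

    def add(self, record: SeqRecord) -> None:
        if record.id in self._records:
            raise ValueError(f"duplicate read id {record.id!r}")
        self._records[record.id] = record

    def add_all(self, records: Iterable[SeqRecord]) -> None:
        for rec in records:
            self.add(rec)

    def __getitem__(self, read_id: str) -> SeqRecord:
        return self._records[read_id]

    def get(self, read_id: str) -> Optional[SeqRecord]:
        return self._records.get(read_id)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._records

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self._records.values())

    @classmethod
    def from_files(cls, paths: Sequence[str | os.PathLike], offset: int = 33) -> "ReadStore":
        """Build a store from FASTA/FASTQ files (format sniffed per file)."""
        store = cls()
        for path in paths:
            with open(path) as fh:
                first = fh.read(1)
            if first == "@":
                store.add_all(read_fastq(path, offset=offset))
            else:
                store.add_all(read_fasta(path))
        return store

    def save(self, directory: str | os.PathLike) -> None:
        """Persist to a directory as FASTA plus a pyfaidx ``.fai`` index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / "reads.fasta"
        write_fasta(self, fasta)
        try:
            import pyfaidx

            pyfaidx.Faidx(str(fasta))
        except Exception:  # pyfaidx optional; the FASTA alone suffices
            pass
        mates = [(r.id, r.mate_of) for r in self if r.mate_of]
        if mates:
            with open(directory / "mates.tsv", "w") as fh:
                for rid, mate in mates:
                    fh.write(f"{rid}\t{mate}\n")

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ReadStore":
        directory = Path(directory)
        store = cls()
        store.add_all(read_fasta(directory / "reads.fasta"))
        mates_path = directory / "mates.tsv"
        if mates_path.exists():
            with open(mates_path) as fh:
                for line in fh:
                    rid, mate = line.rstrip("\n").split("\t")
                    if rid in store:
                        store[rid].mate_of = mate
        return store
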