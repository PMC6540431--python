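"""Readers and writers for the external formats the pipeline touches.

All parsers validate strictly and reject malformed input instead of
coercing it; round-trips through the writers are lossless up to line
wrapping. Nucleotide sequences are upper-cased on read and restricted to
``{A, C, G, T, N}``; FASTQ qualities are fixed to Phred+33.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "TranscriptRecord",
    "ReadPair",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_genes_trans_map",
    "write_genes_trans_map",
    "phred_scores",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled nucleotide sequence, optionally tied to a gene cluster."""

    transcript_id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise FormatError("transcript_id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.transcript_id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.transcript_id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """A synchronized pair of mates with Phred+33 quality strings."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


def phred_scores(qual: str) -> list[int]:
    """Decode a Phred+33 quality string to integer scores ('I' -> 40)."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def _iter_fasta_chunks(path: str | Path) -> Iterator[tuple[str, str]]:
    header: str | None = None
    parts: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(parts)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                parts.append(line.strip())
    if header is not None:
        yield header, "".join(parts)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a nucleotide FASTA file into :class:`TranscriptRecord` objects.

    Headers are truncated at the first whitespace; sequences are
    upper-cased and validated against ``{A, C, G, T, N}``.
    """
    seen: set[str] = set()
    records: list[TranscriptRecord] = []
    for name, seq in _iter_fasta_chunks(path):
        if name in seen:
            raise FormatError(f"duplicate FASTA id {name!r}")
        seen.add(name)
        records.append(TranscriptRecord(name, seq.upper()))
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered ``{id: peptide}`` mapping."""
    out: dict[str, str] = {}
    for name, seq in _iter_fasta_chunks(path):
        if name in out:
            raise FormatError(f"duplicate FASTA id {name!r}")
        if not seq:
            raise FormatError(f"record {name!r}: empty sequence")
        out[name] = seq.upper()
    return out


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_protein_fasta(peptides: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in peptides.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        while True:
            block = list(itertools.islice(fh, 4))
            if not block:
                return
            if len(block) < 4:
                raise FormatError(f"{path}: truncated FASTQ record at end of file")
            head, seq, plus, qual = (line.rstrip("\n") for line in block)
            if not head.startswith("@"):
                raise FormatError(f"{path}: expected '@' header, got {head!r}")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: expected '+' separator, got {plus!r}")
            name = head[1:].split()[0]
            if len(seq) != len(qual):
                raise FormatError(f"{path}: read {name!r} sequence/quality length mismatch")
            yield name, seq.upper(), qual


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mate files as :class:`ReadPair` objects."""
    it1, it2 = _iter_fastq(path1), _iter_fastq(path2)
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise FormatError("mate files are not synchronized (unequal record counts)")
        name1, seq1, qual1 = rec1
        name2, seq2, qual2 = rec2
        # mate ids may carry /1,/2 suffixes; the stem must agree
        stem1 = name1.rsplit("/", 1)[0]
        stem2 = name2.rsplit("/", 1)[0]
        if stem1 != stem2:
            raise FormatError(f"mate id mismatch: {name1!r} vs {name2!r}")
        yield ReadPair(stem1, seq1, qual1, seq2, qual2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_genes_trans_map(path: str | Path) -> dict[str, str]:
    """Read a headerless two-column (gene, transcript) map.

    Returns ``{transcript_id: gene_id}``. Duplicate rows for the same
    (gene, transcript) pair are deduplicated silently; a transcript listed
    under two distinct genes is rejected.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            gene, transcript = fields
            if transcript in mapping and mapping[transcript] != gene:
                raise FormatError(
                    f"transcript {transcript!r} listed under two genes "
                    f"({mapping[transcript]!r} and {gene!r})"
                )
            mapping[transcript] = gene
    return mapping


def write_genes_trans_map(mapping: dict[str, str], path: str | Path) -> None:
    """Write ``{transcript_id: gene_id}`` as two-column (gene, transcript) text."""
    with open(path, "w") as fh:
        for transcript, gene in mapping.items():
            fh.write(f"{gene}\t{transcript}\n")
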