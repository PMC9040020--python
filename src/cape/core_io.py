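"""Genomic interval / sequence primitives and standard-format readers.

Coordinates are 0-based half-open (BED convention) everywhere, including
FASTA extraction.  Sequences are uppercase over the alphabet {A,C,G,T,N};
any other IUPAC letter is mapped to N on read.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_NON_ALPHABET = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, uppercase over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT letter to N."""
    return _NON_ALPHABET.sub("N", seq.upper())


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, order preserved.

    Raises ``ValueError`` naming the record if one has no sequence.
    """
    records = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else header
            if not seq:
                raise ValueError(f"record {rec_id!r} has an empty sequence")
            records.append(SequenceRecord(rec_id, normalize_sequence(seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open) into intervals, file order.

    Invalid lines (fewer than 3 columns, non-integer or inverted
    coordinates) raise ``ValueError`` reporting the 1-based line number.
    """
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                iv = GenomicInterval(chrom, start, end, name=name, strand=strand)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED (BED6 when name/strand are set, else BED3)."""
    with open(path, "w") as out:
        for iv in intervals:
            if iv.name is not None or iv.strand is not None:
                out.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                    f"{iv.strand or '.'}\n"
                )
            else:
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


class Genome:
    """Random-access genome: a mapping chrom -> normalized sequence string.

    Built either from an in-memory dict or from a FASTA file (via
    :func:`read_fasta`; for large genomes prefer ``Genome.from_faidx``).
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {c: normalize_sequence(s) for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        return cls({r.id: r.seq for r in read_fasta(path)})

    @classmethod
    def from_faidx(cls, path: str | os.PathLike) -> "Genome":
        """Load through pyfaidx (builds/uses a .fai sidecar)."""
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def keys(self):
        return self._seqs.keys()


def extract_sequence(genome: Genome | dict[str, str], iv: GenomicInterval) -> SequenceRecord:
    """Extract the forward-strand sequence of ``iv`` (strand is ignored)."""
    seqs = genome if isinstance(genome, Genome) else Genome(genome)
    if iv.chrom not in seqs:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    chrom_seq = seqs[iv.chrom]
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {len(chrom_seq)}"
        )
    name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
    return SequenceRecord(name, chrom_seq[iv.start:iv.end])


def one_hot_encode(rec: SequenceRecord | str) -> np.ndarray:
    """One-hot encode a sequence as an L×4 matrix, columns A,C,G,T.

    N rows are uniform 0.25, keeping every row stochastic.
    """
    seq = rec.seq if isinstance(rec, SequenceRecord) else rec
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for base, col in _BASE_INDEX.items():
        out[idx == ord(base), col] = 1.0
    out[idx == ord("N")] = 0.25
    bad = ~np.isin(idx, [ord(b) for b in "ACGTN"])
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return out


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for N-free inputs (N rows -> 'N')."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError("expected an L×4 matrix")
    chars = []
    for row in matrix:
        if np.allclose(row, 0.25):
            chars.append("N")
        else:
            chars.append(ALPHABET[int(np.argmax(row))])
    return "".join(chars)


def gc_content(rec: SequenceRecord | str) -> float:
    """(G+C) / length; N counts in the denominator only."""
    seq = rec.seq if isinstance(rec, SequenceRecord) else rec
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return sizes
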