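"""Sequence I/O, coordinate conventions and ORF finding.

All internal coordinates are 0-based half-open.  Positions inside an
siRNA that are exposed to users (e.g. "10th nucleotide") are 1-based;
conversion happens only at I/O boundaries.

Transcripts are stored DNA-alphabet uppercase (U -> T on input) and are
assumed to be in sense orientation, so only the three forward frames are
searched for open reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "Transcript",
    "read_fasta",
    "write_fasta",
    "find_longest_orf",
    "revcomp",
    "to_rna",
    "to_dna",
]

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet (T becomes U)."""
    return seq.replace("T", "U")


def to_dna(seq: str) -> str:
    """RNA -> DNA alphabet (U becomes T)."""
    return seq.replace("U", "T")


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Transcript:
    """A sense-orientation transcript sequence with an optional ORF."""

    id: str
    seq: str
    orf: Optional[Interval] = field(default=None)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        seq = self.seq.upper().replace("U", "T")
        for i, ch in enumerate(seq):
            if ch not in _IUPAC_DNA:
                raise ValueError(
                    f"transcript {self.id!r}: non-IUPAC character {ch!r} at position {i + 1}"
                )
        self.seq = seq
        if self.orf is not None and self.orf.end > len(seq):
            raise ValueError(f"transcript {self.id!r}: ORF outside sequence")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[Transcript]:
    """Read a multi-FASTA file into Transcripts.

    U is stored as T, lowercase is uppercased, and the id is the token
    before the first whitespace.  Raises ``ValueError`` on an empty
    file, a duplicate id, or a non-IUPAC character.
    """
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(Transcript(id=rec.id, seq=str(rec.seq)))
    return out


def write_fasta(transcripts: Iterable[Transcript], path) -> None:
    """Write Transcripts as 60-column wrapped FASTA."""
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def find_longest_orf(t: Transcript, min_len: int = 90) -> Optional[Interval]:
    """Longest ATG..stop ORF (stop included) over the three forward frames.

    Returns ``None`` when no ORF of at least ``min_len`` nt exists.
    Ties in length are broken by leftmost start for determinism.
    """
    if len(t.seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = t.seq
    best: Optional[Interval] = None
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOP_CODONS:
                length = pos + 3 - start
                if length >= min_len and (
                    best is None
                    or length > len(best)
                    or (length == len(best) and start < best.start)
                ):
                    best = Interval(start, pos + 3)
                start = None
    return best
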