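"""Candidate siRNA enumeration and the per-siRNA feature vector.

A candidate is a k-mer target site on the sense transcript together
with its antisense (guide) strand, the reverse complement in RNA
alphabet.  The duplex model is a blunt k-bp duplex (sense equals the
reverse complement of the antisense); the 2-nt 3' overhangs of natural
siRNAs are outside the paired region by construction, so terminal
tetramers are always taken inside it.  Positions quoted in feature
names ("10th nt") are 1-based along the antisense strand 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .energetics import (
    StackTable,
    default_stack_table,
    fold_mfe,
    nn_duplex_energy,
    site_accessibility,
)
from .seqio import Interval, Transcript, revcomp, to_rna

__all__ = [
    "SirnaCandidate",
    "FeatureVector",
    "enumerate_sirnas",
    "thermo_asymmetry",
    "sequence_features",
    "antisense_binding_energy",
    "compute_feature_table",
]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SirnaCandidate:
    """One prospective siRNA: target site (sense) plus guide strand."""

    index: int  # 0-based start of the target site on the transcript
    site: str  # sense target-site sequence, DNA alphabet
    antisense: str  # guide strand 5'->3', RNA alphabet
    region: str = "UTR"  # "ORF" or "UTR"

    @classmethod
    def from_site(cls, index: int, site: str, region: str = "UTR") -> "SirnaCandidate":
        return cls(index=index, site=site, antisense=to_rna(revcomp(site)), region=region)

    @property
    def k(self) -> int:
        return len(self.site)


@dataclass
class FeatureVector:
    """The per-siRNA features considered by the efficacy model."""

    thermo_asymmetry: float  # kcal/mol; positive favors antisense loading
    self_fold_mfe: float  # kcal/mol; <= 0
    accessibility: Optional[float]  # fraction in [0, 1]
    gc_full: float  # percent
    gc_9_14: float  # percent
    a10: bool
    region: str  # "ORF" or "UTR"
    binding_energy: float  # kcal/mol
    extra: Optional[float] = field(default=None)  # pluggable ninth feature slot


def enumerate_sirnas(t: Transcript, k: int = 21) -> tuple[list[SirnaCandidate], int]:
    """All k-mer candidates in transcript order.

    Candidates whose site contains a non-ACGT character are excluded;
    the second return value is the number excluded.
    """
    if len(t.seq) < k:
        raise ValueError(f"transcript {t.id!r} shorter than k={k}")
    out: list[SirnaCandidate] = []
    excluded = 0
    for i in range(len(t.seq) - k + 1):
        site = t.seq[i : i + k]
        if set(site) - _ACGT:
            excluded += 1
            continue
        region = "ORF" if t.orf is not None and t.orf.contains(Interval(i, i + k)) else "UTR"
        out.append(SirnaCandidate.from_site(i, site, region))
    return out, excluded


def thermo_asymmetry(c: SirnaCandidate, table: Optional[StackTable] = None) -> float:
    """Pairing-energy difference between the antisense 5'-terminal
    tetramer and the sense 5'-terminal tetramer (both as duplexes with
    their complements).  Positive values mean the antisense 5' end is
    the weaker-paired end, favoring its selection as guide strand.
    """
    if c.k < 8:
        raise ValueError("siRNA too short for terminal tetramers")
    if table is None:
        table = default_stack_table()
    anti5 = c.antisense[:4]
    # sense 5' tetramer == revcomp of the antisense 3' tetramer
    sense5 = to_rna(c.site[:4])
    return nn_duplex_energy(anti5, table) - nn_duplex_energy(sense5, table)


def sequence_features(antisense: str) -> tuple[float, float, bool]:
    """(gc_full %, gc over 1-based positions 9-14 %, adenine at 10th)."""
    if len(antisense) < 14:
        raise ValueError("antisense shorter than 14 nt")
    s = antisense.upper()
    gc_full = 100.0 * sum(ch in "GC" for ch in s) / len(s)
    window = s[8:14]
    gc_9_14 = 100.0 * sum(ch in "GC" for ch in window) / len(window)
    a10 = s[9] == "A"
    return gc_full, gc_9_14, a10


def antisense_binding_energy(c: SirnaCandidate, table: Optional[StackTable] = None) -> float:
    """Hybridization energy of the full antisense strand to its perfect
    complement (k-1 nearest-neighbor stacks)."""
    return nn_duplex_energy(c.antisense, table or default_stack_table())


def compute_feature_table(
    t: Transcript,
    k: int = 21,
    table: Optional[StackTable] = None,
    flank: int = 80,
    with_accessibility: bool = True,
) -> list[tuple[SirnaCandidate, FeatureVector]]:
    """One (candidate, features) row per enumerable siRNA.

    A site counts as ORF only when it lies entirely inside the
    transcript's ORF.  ``with_accessibility=False`` skips the partition
    function (the slowest feature) and stores ``None``.
    """
    if table is None:
        table = default_stack_table()
    candidates, _ = enumerate_sirnas(t, k)
    rows: list[tuple[SirnaCandidate, FeatureVector]] = []
    for c in candidates:
        gc_full, gc_9_14, a10 = sequence_features(c.antisense)
        acc = (
            site_accessibility(t, Interval(c.index, c.index + k), flank=flank)
            if with_accessibility
            else None
        )
        fv = FeatureVector(
            thermo_asymmetry=thermo_asymmetry(c, table),
            self_fold_mfe=fold_mfe(c.antisense, table),
            accessibility=acc,
            gc_full=gc_full,
            gc_9_14=gc_9_14,
            a10=a10,
            region=c.region,
            binding_energy=antisense_binding_energy(c, table),
        )
        rows.append((c, fv))
    return rows
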