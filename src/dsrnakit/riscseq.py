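"""Strand-specific exact-match mapping of small-RNA reads onto a dsRNA
template, and profile statistics.

A read maps sense when it occurs verbatim in the template and antisense
when its reverse complement does; all occurrences count (the original
pipeline reported all valid zero-mismatch alignments in both
orientations, for which exact substring search is equivalent).  The
positional depth profile is restricted to 21-nt reads; the length
histogram covers mapped reads of 16-30 nt.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .seqio import Transcript, revcomp, to_dna

__all__ = [
    "StrandDepthProfile",
    "map_reads",
    "read_fastq",
    "antisense_fraction",
    "abundance_extremes",
    "position_composition_test",
    "CompositionTestResult",
]

PROFILE_READ_LENGTH = 21
HIST_RANGE = range(16, 31)


@dataclass
class StrandDepthProfile:
    template_id: str
    template_seq: str
    sense: Counter  # 0-based alignment start -> 21-nt read count
    antisense: Counter
    length_histogram: Counter  # mapped read length (16-30) -> count
    mapped_21nt: int = 0
    discarded: int = 0

    @property
    def sense_total(self) -> int:
        return sum(self.sense.values())

    @property
    def antisense_total(self) -> int:
        return sum(self.antisense.values())

    def antisense_site_counts(self) -> dict[int, int]:
        """Per template start position: antisense 21-nt read count."""
        return dict(self.antisense)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def read_fastq(path) -> list[str]:
    """Read sequences from a (plain or gzip) FASTQ file."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: list[str] = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip().upper())
    return seqs


def map_reads(
    reads: Iterable[str],
    template: Transcript,
    min_len: int = 16,
    max_len: int = 30,
) -> StrandDepthProfile:
    """Map reads by exact substring search in both orientations.

    Reads outside [min_len, max_len] are discarded by the pass-through
    length filter; reads matching neither strand are discarded.
    """
    if not template.seq:
        raise ValueError("empty template")
    tpl = template.seq
    profile = StrandDepthProfile(
        template_id=template.id,
        template_seq=tpl,
        sense=Counter(),
        antisense=Counter(),
        length_histogram=Counter(),
    )
    for read in reads:
        seq = to_dna(read.strip().upper())
        if not (min_len <= len(seq) <= max_len):
            profile.discarded += 1
            continue
        sense_pos = _find_all(tpl, seq)
        anti_pos = _find_all(tpl, revcomp(seq))
        if not sense_pos and not anti_pos:
            profile.discarded += 1
            continue
        profile.length_histogram[len(seq)] += 1
        if len(seq) == PROFILE_READ_LENGTH:
            for p in sense_pos:
                profile.sense[p] += 1
                profile.mapped_21nt += 1
            for p in anti_pos:
                profile.antisense[p] += 1
                profile.mapped_21nt += 1
    return profile


def antisense_fraction(p: StrandDepthProfile) -> float:
    """Percent of mapped 21-nt reads in antisense orientation."""
    total = p.sense_total + p.antisense_total
    if total == 0:
        raise ValueError("no mapped 21-nt reads")
    return 100.0 * p.antisense_total / total


def antisense_sequence(p: StrandDepthProfile, position: int) -> str:
    """Antisense 21-mer (5'->3', RNA) whose alignment starts at
    ``position`` on the template."""
    site = p.template_seq[position : position + PROFILE_READ_LENGTH]
    return revcomp(site).replace("T", "U")


def abundance_extremes(
    profiles: Sequence[StrandDepthProfile], fraction: float = 0.15
) -> tuple[list[str], list[str]]:
    """(top, bottom) antisense 21-mer sets by mapped-count rank.

    Candidate antisense species (one per template start position with at
    least the full 21-mer inside the template) are pooled across
    profiles and ranked by count; ties at the percentile boundary are
    broken by (template order, position) for determinism.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    entries: list[tuple[int, int, int, str]] = []  # (count, tpl_idx, pos, seq)
    for ti, p in enumerate(profiles):
        counts = p.antisense_site_counts()
        for pos in range(len(p.template_seq) - PROFILE_READ_LENGTH + 1):
            entries.append((counts.get(pos, 0), ti, pos, antisense_sequence(p, pos)))
    if not entries:
        raise ValueError("no candidate antisense positions")
    n_tail = max(1, int(round(fraction * len(entries))))
    by_count = sorted(entries, key=lambda e: (-e[0], e[1], e[2]))
    top = [e[3] for e in by_count[:n_tail]]
    by_count_asc = sorted(entries, key=lambda e: (e[0], e[1], e[2]))
    bottom = [e[3] for e in by_count_asc[:n_tail]]
    return top, bottom


@dataclass(frozen=True)
class CompositionTestResult:
    position: int  # 1-based along the antisense strand
    base: str
    top_count: int
    bottom_count: int
    chi_square: float
    p_value: float
    p_adjusted: float


def _pearson_chi2(a: int, n_a: int, b: int, n_b: int) -> tuple[float, float]:
    """2x2 Pearson chi-square (no continuity correction), 1 df."""
    table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    if (expected == 0).any():
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(_stats.chi2.sf(chi2, df=1))


def position_composition_test(
    top: Sequence[str],
    bottom: Sequence[str],
    bases: str = "ACGU",
    family_size: Optional[int] = None,
) -> list[CompositionTestResult]:
    """Per (position, base) 2x2 chi-square between the top and bottom
    abundance sets, Bonferroni-adjusted over 21 positions x 4 bases.
    """
    if not top or not bottom:
        raise ValueError("both sets must be non-empty")
    top = [s.upper().replace("T", "U") for s in top]
    bottom = [s.upper().replace("T", "U") for s in bottom]
    length = len(top[0])
    if any(len(s) != length for s in top) or any(len(s) != length for s in bottom):
        raise ValueError("sequences of unequal length within a set")
    if family_size is None:
        family_size = length * len(bases)
    results: list[CompositionTestResult] = []
    for pos in range(length):
        top_col = [s[pos] for s in top]
        bot_col = [s[pos] for s in bottom]
        for base in bases:
            a = sum(ch == base for ch in top_col)
            b = sum(ch == base for ch in bot_col)
            chi2, p = _pearson_chi2(a, len(top), b, len(bottom))
            results.append(
                CompositionTestResult(
                    position=pos + 1,
                    base=base,
                    top_count=a,
                    bottom_count=b,
                    chi_square=chi2,
                    p_value=p,
                    p_adjusted=min(1.0, p * family_size),
                )
            )
    return results


def profile_from_sam(path, template: Transcript) -> StrandDepthProfile:
    """Adapter: build a profile from a SAM file of alignments to the
    template (zero-mismatch alignments assumed, flag 16 = antisense)."""
    profile = StrandDepthProfile(
        template_id=template.id,
        template_seq=template.seq,
        sense=Counter(),
        antisense=Counter(),
        length_histogram=Counter(),
    )
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            flag, pos, seq = int(fields[1]), int(fields[3]) - 1, fields[9]
            if flag & 4:
                profile.discarded += 1
                continue
            if not (16 <= len(seq) <= 30):
                profile.discarded += 1
                continue
            profile.length_histogram[len(seq)] += 1
            if len(seq) == PROFILE_READ_LENGTH:
                strand = profile.antisense if flag & 16 else profile.sense
                strand[pos] += 1
                profile.mapped_21nt += 1
    return profile
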