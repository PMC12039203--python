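"""Mismatch-tolerant siRNA vs transcriptome matching and safety scores.

The matcher is a pigeonhole seed search: a k-mer within Hamming
distance m of a transcript window must match at least one of m+1
disjoint seed chunks exactly, so candidate loci are found through an
exact-substring index of the transcriptome and verified by Hamming
count.  Both orientations are searched (a hit on the reverse strand
means the reverse complement of the query occurs in the transcript).
Indels are not considered.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
import warnings

from .seqio import Transcript, revcomp

__all__ = [
    "Hit",
    "OfftargetHitTable",
    "EssentialSet",
    "TranscriptomeIndex",
    "mismatch_hits",
    "collect_hits",
    "safety_scores",
]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class Hit:
    transcript_id: str
    position: int  # 0-based start on the transcript's sense strand
    strand: str  # "+" query found verbatim, "-" reverse complement found
    mismatches: int


@dataclass
class EssentialSet:
    """Transcript ids flagged essential for one species."""

    species: str
    ids: frozenset[str]

    @classmethod
    def from_file(cls, species: str, path) -> "EssentialSet":
        with open(path) as fh:
            ids = frozenset(line.strip() for line in fh if line.strip())
        return cls(species=species, ids=ids)


@dataclass
class SpeciesHits:
    """Per-candidate hit summary against one species' transcriptome."""

    total_transcripts_hit: int
    essential_transcripts_hit: int
    hits: list[Hit] = field(default_factory=list)


@dataclass
class OfftargetHitTable:
    """hits[candidate_index][species] -> SpeciesHits"""

    hits: dict[int, dict[str, SpeciesHits]]

    def weighted_counts(self, essential_weight: float = 20.0) -> dict[int, float]:
        if essential_weight < 0:
            raise ValueError("essential weight must be non-negative")
        out: dict[int, float] = {}
        for idx, per_species in self.hits.items():
            w = 0.0
            for sh in per_species.values():
                other = sh.total_transcripts_hit - sh.essential_transcripts_hit
                w += essential_weight * sh.essential_transcripts_hit + other
            out[idx] = w
        return out


def _seed_chunks(k: int, m: int) -> list[tuple[int, int]]:
    """m+1 near-equal disjoint chunks covering [0, k)."""
    n_chunks = m + 1
    base, rem = divmod(k, n_chunks)
    bounds, pos = [], 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


class TranscriptomeIndex:
    """Exact-substring index over fixed-length chunks of a transcriptome."""

    def __init__(self, transcriptome: Sequence[Transcript]):
        self.transcripts = list(transcriptome)
        self._chunk_index: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_for(self, length: int) -> dict[str, list[tuple[int, int]]]:
        if length not in self._chunk_index:
            idx: dict[str, list[tuple[int, int]]] = defaultdict(list)
            for ti, t in enumerate(self.transcripts):
                seq = t.seq
                for p in range(len(seq) - length + 1):
                    idx[seq[p : p + length]].append((ti, p))
            self._chunk_index[length] = dict(idx)
        return self._chunk_index[length]

    def _hamming_verify(self, ti: int, pos: int, query: str, m: int) -> Optional[int]:
        seq = self.transcripts[ti].seq
        if pos < 0 or pos + len(query) > len(seq):
            return None
        mm = 0
        window = seq[pos : pos + len(query)]
        for a, b in zip(query, window):
            if a != b:
                mm += 1
                if mm > m:
                    return None
        return mm

    def find(self, query: str, m: int) -> list[tuple[int, int, int]]:
        """(transcript_index, position, mismatches) of every occurrence
        of ``query`` at Hamming distance <= m on the given strand."""
        k = len(query)
        chunks = _seed_chunks(k, m)
        found: dict[tuple[int, int], int] = {}
        for s, e in chunks:
            seed = query[s:e]
            index = self._index_for(e - s)
            for ti, p in index.get(seed, ()):
                start = p - s
                key = (ti, start)
                if key in found:
                    continue
                mm = self._hamming_verify(ti, start, query, m)
                if mm is not None:
                    found[key] = mm
        return sorted((ti, pos, mm) for (ti, pos), mm in found.items())


def mismatch_hits(
    sirna_site: str,
    transcriptome: Sequence[Transcript] | TranscriptomeIndex,
    m: int = 1,
) -> list[Hit]:
    """Every occurrence of the site k-mer or its reverse complement in
    any transcript at Hamming distance <= m, regardless of strand."""
    if m not in (0, 1, 2):
        raise ValueError("m must be 0, 1 or 2")
    site = sirna_site.upper()
    if set(site) - _ACGT:
        raise ValueError("ambiguous base in siRNA site")
    index = (
        transcriptome
        if isinstance(transcriptome, TranscriptomeIndex)
        else TranscriptomeIndex(transcriptome)
    )
    hits: list[Hit] = []
    for strand, query in (("+", site), ("-", revcomp(site))):
        for ti, pos, mm in index.find(query, m):
            hits.append(Hit(index.transcripts[ti].id, pos, strand, mm))
    hits.sort(key=lambda h: (h.transcript_id, h.position, h.strand))
    return hits


def collect_hits(
    candidates: Iterable[tuple[int, str]],
    transcriptomes: dict[str, Sequence[Transcript]],
    m: int = 1,
    essential: Optional[dict[str, EssentialSet]] = None,
) -> OfftargetHitTable:
    """Run ``mismatch_hits`` for every (candidate_index, site) against
    every species and summarize per-transcript (deduplicated) counts."""
    essential = essential or {}
    indexes = {sp: TranscriptomeIndex(tr) for sp, tr in transcriptomes.items()}
    for sp, ess in essential.items():
        if sp in indexes:
            known = {t.id for t in indexes[sp].transcripts}
            orphans = ess.ids - known
            if orphans:
                warnings.warn(
                    f"{sp}: {len(orphans)} essential id(s) absent from transcriptome",
                    stacklevel=2,
                )
    table: dict[int, dict[str, SpeciesHits]] = {}
    for idx, site in candidates:
        per_species: dict[str, SpeciesHits] = {}
        for sp, index in indexes.items():
            hits = mismatch_hits(site, index, m)
            tids = {h.transcript_id for h in hits}
            ess_ids = essential[sp].ids if sp in essential else frozenset()
            per_species[sp] = SpeciesHits(
                total_transcripts_hit=len(tids),
                essential_transcripts_hit=len(tids & ess_ids),
                hits=hits,
            )
        table[idx] = per_species
    return OfftargetHitTable(hits=table)


def safety_scores(
    hits: OfftargetHitTable, essential_weight: float = 20.0
) -> dict[int, float]:
    """Percent-normalized safety: least-off-target candidate scores 100,
    most scores 0; all tied -> all 100.

    The counting unit is transcripts hit (deduplicated); essential-gene
    transcripts count ``essential_weight`` times (default 20:1).
    """
    if not hits.hits:
        raise ValueError("no candidates")
    w = hits.weighted_counts(essential_weight)
    w_min = min(w.values())
    w_max = max(w.values())
    if w_max == w_min:
        return {idx: 100.0 for idx in w}
    return {idx: 100.0 * (w_max - v) / (w_max - w_min) for idx, v in w.items()}
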