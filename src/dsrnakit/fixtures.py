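"""Deterministic synthetic-data generators.

Every generator is a pure function of its parameters and seed (one
numpy ``default_rng`` per call), so identical calls produce
byte-identical outputs.  The generators emit the same formats the
analysis modules consume.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .biostats import SurvivalRecord
from .seqio import Transcript, revcomp

__all__ = [
    "gen_transcriptome",
    "plant_site",
    "gen_reads",
    "gen_survival",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


def gen_transcriptome(
    n: int, length: int, gc: float = 0.5, seed: int = 0, prefix: str = "tx"
) -> list[Transcript]:
    """n i.i.d. random transcripts at the requested GC content."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        out.append(Transcript(id=f"{prefix}{i + 1}", seq=seq))
    return out


def plant_site(
    t: Transcript,
    site: str,
    mismatches: int = 0,
    position: int = 0,
    seed: int = 0,
) -> Transcript:
    """Copy of ``t`` with ``site`` written at ``position``, carrying
    exactly ``mismatches`` substitutions at distinct random offsets."""
    site = site.upper()
    if position < 0 or position + len(site) > len(t.seq):
        raise ValueError("position out of range")
    if not 0 <= mismatches <= len(site):
        raise ValueError("invalid mismatch count")
    rng = np.random.default_rng(seed)
    planted = list(site)
    offsets = rng.choice(len(site), size=mismatches, replace=False)
    for off in offsets:
        planted[off] = rng.choice([b for b in "ACGT" if b != planted[off]])
    new_seq = t.seq[:position] + "".join(planted) + t.seq[position + len(site) :]
    return Transcript(id=t.id, seq=new_seq, orf=t.orf)


def gen_reads(
    template: Transcript,
    antisense_fraction: float = 50.0,
    positional_weights: Optional[Sequence[float]] = None,
    n: int = 1000,
    seed: int = 0,
    read_length: int = 21,
) -> list[tuple[str, str]]:
    """n read records (id, sequence) drawn from template positions.

    Start positions follow ``positional_weights`` (uniform by default,
    one weight per possible start); strand is antisense with the given
    percent probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= antisense_fraction <= 100:
        raise ValueError("antisense_fraction is a percent")
    n_starts = len(template.seq) - read_length + 1
    if n_starts < 1:
        raise ValueError("template shorter than the read length")
    if positional_weights is None:
        w = np.full(n_starts, 1.0 / n_starts)
    else:
        w = np.asarray(positional_weights, dtype=float)
        if len(w) != n_starts:
            raise ValueError(f"need {n_starts} positional weights, got {len(w)}")
        w = w / w.sum()
    rng = np.random.default_rng(seed)
    starts = rng.choice(n_starts, size=n, p=w)
    anti = rng.random(n) < antisense_fraction / 100.0
    reads = []
    for i, (s, is_anti) in enumerate(zip(starts, anti)):
        frag = template.seq[s : s + read_length]
        seq = revcomp(frag) if is_anti else frag
        reads.append((f"read{i + 1}", seq))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write (id, seq) records as plain FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def gen_survival(
    n_per_group: int,
    groups: dict[str, float],
    max_day: int = 8,
    control_hazard: float = 0.15,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Discrete daily-death survival fixture.

    ``groups`` maps group label -> hazard ratio vs control; the control
    daily hazard is ``control_hazard`` and a group with ratio HR dies
    each day with probability 1 - (1 - h)^HR.  Survivors at ``max_day``
    are censored there.
    """
    if max_day < 2:
        raise ValueError("max_day must be >= 2")
    if not 0 < control_hazard < 1:
        raise ValueError("control_hazard must be in (0, 1)")
    if any(hr <= 0 for hr in groups.values()):
        raise ValueError("hazard ratios must be positive")
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for group, hr in groups.items():
        daily = 1.0 - (1.0 - control_hazard) ** hr
        for i in range(n_per_group):
            day, event = max_day, 0
            for d in range(1, max_day + 1):
                if rng.random() < daily:
                    day, event = d, 1
                    break
            records.append(
                SurvivalRecord(subject=f"{group}_{i + 1}", group=group, time=day, event=event)
            )
    return records
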