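"""Efficacy/combined scoring, sliding-window region selection, and
siRNA-insertion construct building.

Quantitative features are percent normalized so that higher always
means predicted better: asymmetry up, self-folding MFE toward zero up,
GC 9-14 up, adenine at position 10 true -> 100.  Asymmetry uses
theoretical bounds derived from the stack-table extremes over all
tetramers; GC percentages are natively on [0, 100]; self-folding and
accessibility fall back to the empirical min/max over the transcript's
candidate set.  The default efficacy score is the equally weighted mean
of the four features found predictive of insecticidal efficacy
(asymmetry, self-folding, GC 9-14, A10); the remaining features are
computed and reported but excluded from the default score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .energetics import StackTable, default_stack_table
from .seqio import Interval, Transcript
from .sirna_features import FeatureVector, SirnaCandidate

__all__ = [
    "ScoreProfile",
    "WindowResult",
    "DsConstruct",
    "DEFAULT_WEIGHTS",
    "normalize_features",
    "efficacy_scores",
    "combined_scores",
    "select_window",
    "build_insertion_construct",
]

#: Features significantly associated with efficacy, equally weighted.
DEFAULT_WEIGHTS: dict[str, float] = {
    "thermo_asymmetry": 1.0,
    "self_fold": 1.0,
    "gc_9_14": 1.0,
    "a10": 1.0,
}

_KNOWN_FEATURES = (
    "thermo_asymmetry",
    "self_fold",
    "gc_9_14",
    "a10",
    "gc_full",
    "accessibility",
    "binding_energy",
)


@dataclass
class ScoreProfile:
    """Per-candidate normalized features plus efficacy/safety/combined."""

    positions: list[int]  # candidate 0-based site starts
    k: int
    normalized: dict[str, np.ndarray]  # feature -> percent values
    efficacy: np.ndarray
    safety: Optional[np.ndarray] = None
    combined: Optional[np.ndarray] = None

    @property
    def window_scores(self) -> np.ndarray:
        """Scores the window mean uses: combined when safety known."""
        return self.combined if self.combined is not None else self.efficacy


@dataclass
class WindowResult:
    window: Interval
    mean_score: float
    site_positions: list[int]
    site_scores: np.ndarray
    restricted_to_orf: bool
    truncated: bool = False  # allowed region shorter than requested W


@dataclass
class DsConstruct:
    backbone: str
    insert: str
    insertion_offset: int
    template: str


def _asymmetry_bounds(table: StackTable) -> tuple[float, float]:
    """Theoretical (min, max) of the asymmetry over all tetramer pairs:
    the difference of two 3-stack sums is bounded by the stack extremes."""
    lo = 3 * table.min_stack - 3 * table.max_stack
    return lo, -lo


def _minmax_percent(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.full_like(x, 100.0, dtype=float)
    return np.clip(100.0 * (x - lo) / (hi - lo), 0.0, 100.0)


def normalize_features(
    features: Sequence[FeatureVector], table: Optional[StackTable] = None
) -> dict[str, np.ndarray]:
    """Percent-normalize each quantitative feature, oriented so that
    higher = predicted better."""
    if table is None:
        table = default_stack_table()
    asym = np.array([f.thermo_asymmetry for f in features], dtype=float)
    fold = np.array([f.self_fold_mfe for f in features], dtype=float)
    gc914 = np.array([f.gc_9_14 for f in features], dtype=float)
    gcfull = np.array([f.gc_full for f in features], dtype=float)
    a10 = np.array([100.0 if f.a10 else 0.0 for f in features])
    bind = np.array([f.binding_energy for f in features], dtype=float)
    lo, hi = _asymmetry_bounds(table)
    out: dict[str, np.ndarray] = {
        "thermo_asymmetry": _minmax_percent(asym, lo, hi),
        # MFE toward 0 is better; empirical bounds over this candidate set
        "self_fold": _minmax_percent(fold, fold.min(), fold.max()),
        "gc_9_14": gc914.copy(),
        "gc_full": gcfull.copy(),
        "a10": a10,
        "binding_energy": _minmax_percent(bind, bind.min(), bind.max()),
    }
    acc = [f.accessibility for f in features]
    if all(a is not None for a in acc):
        accv = np.array(acc, dtype=float)
        out["accessibility"] = _minmax_percent(accv, accv.min(), accv.max())
    return out


def efficacy_scores(
    features: Sequence[FeatureVector],
    weights: Optional[dict[str, float]] = None,
    table: Optional[StackTable] = None,
) -> np.ndarray:
    """Weighted mean of normalized features, percent per candidate."""
    weights = dict(DEFAULT_WEIGHTS) if weights is None else dict(weights)
    unknown = set(weights) - set(_KNOWN_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature weight(s): {sorted(unknown)}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    norm = normalize_features(features, table)
    acc = np.zeros(len(features))
    for name, w in weights.items():
        if w == 0:
            continue
        if name not in norm:
            raise ValueError(f"feature {name!r} unavailable (accessibility skipped?)")
        acc = acc + w * norm[name]
    return acc / total


def combined_scores(
    efficacy: Sequence[float], safety: Sequence[float], priority: float = 50.0
) -> np.ndarray:
    """Priority-slider blend: combined = (p*E + (100-p)*S)/100.

    At 50 the average; at 80 efficacy counts 4x the safety score.
    """
    E = np.asarray(efficacy, dtype=float)
    S = np.asarray(safety, dtype=float)
    if E.shape != S.shape:
        raise ValueError("efficacy and safety lists differ in length")
    if not 0 <= priority <= 100:
        raise ValueError("priority must be in [0, 100]")
    return (priority * E + (100.0 - priority) * S) / 100.0


def make_profile(
    candidates: Sequence[SirnaCandidate],
    features: Sequence[FeatureVector],
    weights: Optional[dict[str, float]] = None,
    safety: Optional[dict[int, float]] = None,
    priority: float = 50.0,
    table: Optional[StackTable] = None,
) -> ScoreProfile:
    """Assemble a ScoreProfile from feature vectors and optional safety."""
    eff = efficacy_scores(features, weights, table)
    profile = ScoreProfile(
        positions=[c.index for c in candidates],
        k=candidates[0].k if candidates else 21,
        normalized=normalize_features(features, table),
        efficacy=eff,
    )
    if safety is not None:
        s = np.array([safety[c.index] for c in candidates])
        profile.safety = s
        profile.combined = combined_scores(eff, s, priority)
    return profile


def select_window(
    profile: ScoreProfile,
    transcript: Transcript,
    W: int = 300,
    restrict_to_orf: bool = False,
    objective: str = "max",
) -> WindowResult:
    """Best-mean-score window of width ``W``, scanned 1 nt at a time.

    The window mean is taken over the W-k+1 siRNA sites lying fully
    inside the window.  Leftmost window wins ties.  When the allowed
    region is shorter than W the whole region is returned, flagged.
    """
    if objective not in ("max", "min"):
        raise ValueError("objective must be 'max' or 'min'")
    allowed = (
        transcript.orf
        if restrict_to_orf and transcript.orf is not None
        else Interval(0, len(transcript.seq))
    )
    k = profile.k
    if len(allowed) < k:
        raise ValueError("allowed region shorter than the siRNA length")
    scores = np.asarray(profile.window_scores, dtype=float)
    pos = np.asarray(profile.positions)
    truncated = len(allowed) < W
    width = min(W, len(allowed))

    starts = np.arange(allowed.start, allowed.end - width + 1)
    # candidates fully inside window [s, s+width): pos >= s and pos <= s+width-k
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + width - k, side="right")
    counts = hi - lo
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    with np.errstate(invalid="ignore"):
        means = (csum[hi] - csum[lo]) / np.where(counts > 0, counts, 1)
    if not (counts > 0).any():
        raise ValueError("no candidate sites inside the allowed region")
    sign = 1.0 if objective == "max" else -1.0
    keyed = np.where(counts > 0, sign * means, -np.inf)
    best_idx = int(np.argmax(keyed))  # argmax takes the first (leftmost) tie
    start = int(starts[best_idx])
    mean = float(means[best_idx])
    window = Interval(start, start + width)
    inside = (pos >= window.start) & (pos + k <= window.end)
    return WindowResult(
        window=window,
        mean_score=mean,
        site_positions=[int(p) for p in pos[inside]],
        site_scores=scores[inside],
        restricted_to_orf=restrict_to_orf,
        truncated=truncated,
    )


def build_insertion_construct(backbone: Transcript | str, site: str) -> DsConstruct:
    """Insert the target site at the backbone midpoint.

    The template length is len(backbone) + len(site); the insert is
    present verbatim at offset floor(len(backbone)/2).
    """
    seq = backbone.seq if isinstance(backbone, Transcript) else backbone.upper()
    site = site.upper()
    if len(seq) < 2:
        raise ValueError("backbone too short")
    if set(site) - set("ACGT"):
        raise ValueError("ambiguous base in insert site")
    offset = len(seq) // 2
    template = seq[:offset] + site + seq[offset:]
    return DsConstruct(backbone=seq, insert=site, insertion_offset=offset, template=template)
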