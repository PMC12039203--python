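"""Thermodynamic backends: nearest-neighbor duplex energies, single-strand
folding MFE, and target-site accessibility.

Duplex energies use the Watson-Crick nearest-neighbor stack set at 37 C
determined by optical melting (shipped as ``data/nn_stacks.tsv``).
Initiation, symmetry and terminal-AU penalty terms are deliberately
excluded: the asymmetry feature downstream is a difference of two 4-bp
energies, so shared constants cancel.

Folding and accessibility use a reduced internal model (no external
folding engine is required):

* ``fold_mfe`` - a stacking-energy dynamic program over nested
  structures (Watson-Crick + GU wobble pairs, minimum hairpin loop of
  3 unpaired bases, loops otherwise unpenalized, lone pairs contribute
  zero energy).  The result is never positive.
* ``site_accessibility`` - a McCaskill-style equilibrium partition
  function over the same structure space with per-pair Boltzmann
  weights, evaluated on the site plus a local flank.  Per-base unpaired
  probabilities are obtained exactly by re-evaluating the partition
  function with the base excluded from pairing.

Temperature is fixed at 37 C.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .seqio import Interval, Transcript, revcomp, to_dna, to_rna

__all__ = [
    "StackTable",
    "load_stack_table",
    "nn_duplex_energy",
    "fold_mfe",
    "site_accessibility",
    "RT37",
]

#: Gas constant times 310.15 K, kcal/mol.
RT37 = 0.0019872 * 310.15

_RNA = set("ACGU")

#: Allowed pairs in the folding model and their reduced per-pair
#: energies (kcal/mol) for the partition function.
_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -1.1,
    ("U", "A"): -1.1,
    ("G", "U"): -0.9,
    ("U", "G"): -0.9,
}

_MIN_HAIRPIN = 3  # unpaired bases enclosed by any pair


class StackTable:
    """The 16 nearest-neighbor dinucleotide stack energies (kcal/mol).

    Keys are the 5'->3' top-strand dinucleotide; the partner strand is
    the Watson-Crick complement.  Validates completeness, negativity
    and rotation symmetry on construction.
    """

    def __init__(self, values: Mapping[str, float]):
        vals = {k.upper().replace("T", "U"): float(v) for k, v in values.items()}
        expected = {a + b for a in "ACGU" for b in "ACGU"}
        if set(vals) != expected:
            missing = sorted(expected - set(vals))
            raise ValueError(f"stack table incomplete; missing {missing}")
        for k, v in vals.items():
            if v >= 0:
                raise ValueError(f"stack {k}: energy must be negative, got {v}")
            rot = to_rna(revcomp(to_dna(k)))
            if abs(vals[rot] - v) > 1e-9:
                raise ValueError(f"stack table not rotation-symmetric at {k}/{rot}")
        self._values = vals

    def __getitem__(self, stack: str) -> float:
        return self._values[stack]

    def items(self):
        return self._values.items()

    @property
    def min_stack(self) -> float:
        return min(self._values.values())

    @property
    def max_stack(self) -> float:
        return max(self._values.values())


def load_stack_table(path: Optional[str] = None) -> StackTable:
    """Load a stack table from a TSV (columns ``stack``, ``dg37``).

    Without ``path`` the packaged default parameter set is used.
    """
    if path is None:
        source = resources.files("dsrnakit.data").joinpath("nn_stacks.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    reader = csv.DictReader(rows, delimiter="\t")
    values = {row["stack"]: float(row["dg37"]) for row in reader}
    return StackTable(values)


_DEFAULT_TABLE: Optional[StackTable] = None


def default_stack_table() -> StackTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_stack_table()
    return _DEFAULT_TABLE


def _check_rna(strand: str) -> str:
    s = strand.upper()
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"non-ACGU character(s) {sorted(bad)} in strand")
    return s


def nn_duplex_energy(strand: str, table: Optional[StackTable] = None) -> float:
    """Free energy of ``strand`` hybridized to its full Watson-Crick
    complement: the sum of its len-1 nearest-neighbor stacks.

    No initiation or terminal-AU terms are added (they cancel in every
    downstream difference).
    """
    s = _check_rna(strand)
    if len(s) < 2:
        raise ValueError("duplex needs at least 2 bases")
    if table is None:
        table = default_stack_table()
    return sum(table[s[i : i + 2]] for i in range(len(s) - 1))


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIR_ENERGY


def fold_mfe(strand: str, table: Optional[StackTable] = None) -> float:
    """Minimum free energy of the single strand's secondary structure.

    Stacking-only nested-structure dynamic program; 0 when no stable
    structure exists; never positive.
    """
    s = _check_rna(strand)
    if table is None:
        table = default_stack_table()
    n = len(s)
    if n < _MIN_HAIRPIN + 2:
        return 0.0
    NEG = float("inf")
    # V[i][j]: best energy on [i..j] with (i,j) paired; W[i][j]: best on [i..j]
    V = [[NEG] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]

    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            if _pairable(s[i], s[j]):
                inner = W[i + 1][j - 1] if j - 1 > i + 1 else 0.0
                best = inner  # (i,j) closes whatever is inside, no stack bonus
                if (
                    j - 1 - (i + 1) > _MIN_HAIRPIN
                    and _pairable(s[i + 1], s[j - 1])
                    and V[i + 1][j - 1] < NEG
                ):
                    stacked = table[s[i : i + 2]] + V[i + 1][j - 1]
                    if stacked < best:
                        best = stacked
                V[i][j] = best
            # W recursion
            w = W[i + 1][j]
            for k in range(i + _MIN_HAIRPIN + 1, j + 1):
                if V[i][k] < NEG:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    cand = V[i][k] + rest
                    if cand < w:
                        w = cand
            W[i][j] = w
    return min(0.0, W[0][n - 1])


def _partition_function(s: str, forbidden: Optional[int] = None) -> float:
    """Boltzmann partition function over nested structures of ``s``.

    ``forbidden`` excludes one position from pairing, which restricts
    the sum to structures where that base is unpaired.
    """
    n = len(s)
    w = np.zeros((n, n))
    for k in range(n):
        for j in range(k + _MIN_HAIRPIN + 1, n):
            if (s[k], s[j]) in _PAIR_ENERGY and k != forbidden and j != forbidden:
                w[k, j] = np.exp(-_PAIR_ENERGY[(s[k], s[j])] / RT37)
    # Q[i][j] on [i..j]; padded so Q[i, i-1] == 1 (empty segment)
    Q = np.ones((n + 1, n + 1))
    for j in range(n):
        col = Q[: j + 1, j].copy()  # Q[i][j-1] for i <= j (Q[j, j-1] = 1 via pad)
        # add structures where j pairs with some k >= i
        ks = np.nonzero(w[:, j])[0]
        if ks.size:
            inner = np.array([Q[k + 1, j - 1 + 1] for k in ks])  # Q[k+1][j-1]
            contrib = w[ks, j] * inner
            # Q[i][k-1] for each i<=k: rows i, column k-1 (padded index k)
            left = Q[: j + 1, ks]  # left[i, m] = Q[i][ks[m]-1]
            mask = ks[None, :] >= np.arange(j + 1)[:, None]
            col = col + (left * contrib[None, :] * mask).sum(axis=1)
        Q[: j + 1, j + 1] = col
    return float(Q[0, n])


def unpaired_probabilities(strand: str, positions: Optional[list[int]] = None) -> np.ndarray:
    """Equilibrium probability that each requested position is unpaired."""
    s = _check_rna(strand)
    n = len(s)
    if positions is None:
        positions = list(range(n))
    q_all = _partition_function(s)
    out = np.empty(len(positions))
    for idx, h in enumerate(positions):
        out[idx] = _partition_function(s, forbidden=h) / q_all
    return out


def site_accessibility(t: Transcript, site: Interval, flank: int = 80) -> float:
    """Mean per-base unpaired probability of ``site`` under the
    partition function computed on the subsequence site +/- ``flank``
    (clipped at transcript ends).  Returns a fraction in [0, 1].
    """
    if site.end > len(t.seq) or site.start < 0:
        raise ValueError("site outside transcript")
    lo = max(0, site.start - flank)
    hi = min(len(t.seq), site.end + flank)
    sub = to_rna(t.seq[lo:hi])
    positions = list(range(site.start - lo, site.end - lo))
    probs = unpaired_probabilities(sub, positions)
    return float(np.clip(probs.mean(), 0.0, 1.0))
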