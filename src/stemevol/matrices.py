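"""Substitution counts within variable stems and their log-odds transforms.

Two comparison modes are tallied over the columns of variable stems:

* **extant/extant** — every unordered pair of sequences within a variable
  clade, stored fold-symmetric (lower triangle), matching the conventional
  presentation of symmetric substitution tables;
* **ancestral/extant** — the reconstructed clade-node sequence against each
  member, stored directional (ancestor row -> extant column).

The unit of counting is one tally per (sequence pair, column) for the
single-nucleotide matrices and per (sequence pair, column pair) for the
base-pair matrices. States are {A, C, G, U, -} for singles and the ordered
5'->3' duplets over those symbols, excluding the all-gap duplet, for pairs.
Columns holding ``~``, IUPAC ambiguity, or an unresolved ancestral ``?`` are
skipped. Log-odds cells are log2(observed / expected) in bits, with expected
frequencies taken from the matrix's own marginals; zero-observation cells
are undefined (NA), not minus infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .alphabet import BASES, GAP, STATES
from .ancestral import AncestralSequences
from .errors import EmptyMatrixError
from .stems import Stem
from .tree import Node

EXTANT_EXTANT = "extant_extant"
ANCESTRAL_EXTANT = "ancestral_extant"

_USABLE = frozenset(BASES) | {GAP}


def pair_states() -> tuple[str, ...]:
    """The 24 ordered duplets over {A,C,G,U,-}, '--' excluded."""
    return tuple(
        a + b for a, b in product(STATES, repeat=2) if not (a == GAP and b == GAP)
    )


@dataclass
class SubstitutionCounts:
    """Raw change counts over single-nucleotide or base-pair states."""

    mode: str  # "single" | "pair"
    comparison: str  # EXTANT_EXTANT | ANCESTRAL_EXTANT
    states: tuple[str, ...]
    counts: np.ndarray  # int64, square; lower-triangular for extant/extant

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    @property
    def symmetric(self) -> bool:
        return self.comparison == EXTANT_EXTANT

    def manifest(self) -> dict:
        return {
            "mode": self.mode,
            "comparison": self.comparison,
            "n_states": len(self.states),
            "total_events": self.total_events,
            "counting_unit": (
                "sequence-pair x column"
                if self.mode == "single"
                else "sequence-pair x column-pair"
            ),
            "skip_rules": "~, IUPAC ambiguity, ancestral '?', all-gap duplets",
            "storage": "fold-symmetric lower triangle"
            if self.symmetric
            else "directional ancestor-row x extant-column",
        }


@dataclass
class LogOddsMatrix:
    """log2(observed/expected) in bits; NaN marks undefined (unobserved) cells."""

    mode: str
    comparison: str
    states: tuple[str, ...]
    values: np.ndarray  # float; NaN undefined
    total_events: int = 0

    @property
    def symmetric(self) -> bool:
        return self.comparison == EXTANT_EXTANT


def _usable(ch: str) -> bool:
    return ch in _USABLE


def _clade_rows(alignment, clade: Node) -> dict[str, str]:
    rows = dict(zip(alignment.ids, alignment.rows))
    return {
        leaf.name: rows[leaf.name] for leaf in clade.leaves() if leaf.name in rows
    }


def count_single_changes(
    alignment,
    stem_clades,
    mode: str = EXTANT_EXTANT,
    anc: AncestralSequences | None = None,
) -> SubstitutionCounts:
    """Tally single-nucleotide juxtapositions over variable-stem columns.

    ``stem_clades`` is a sequence of (Stem, clade Node) pairs as produced by
    variable-stem detection. In extant/extant mode every unordered pair of
    clade members contributes one tally per usable column; in
    ancestral/extant mode (``anc`` required) the clade-node reconstruction is
    compared against each member, tallied ancestor -> extant.
    """
    idx = {s: k for k, s in enumerate(STATES)}
    counts = np.zeros((len(STATES), len(STATES)), dtype=np.int64)

    for stem, clade in stem_clades:
        rows = _clade_rows(alignment, clade)
        cols = stem.columns
        if mode == EXTANT_EXTANT:
            for r1, r2 in combinations(sorted(rows), 2):
                for c in cols:
                    a, b = rows[r1][c], rows[r2][c]
                    if _usable(a) and _usable(b):
                        hi, lo = max(idx[a], idx[b]), min(idx[a], idx[b])
                        counts[hi, lo] += 1
        elif mode == ANCESTRAL_EXTANT:
            if anc is None:
                raise ValueError("ancestral/extant mode requires reconstructions")
            anc_seq = anc.sequences[clade.id]
            for name in sorted(rows):
                for c in cols:
                    a, b = anc_seq[c], rows[name][c]
                    if _usable(a) and _usable(b):
                        counts[idx[a], idx[b]] += 1
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")

    return SubstitutionCounts(
        mode="single", comparison=mode, states=STATES, counts=counts
    )


def count_pair_changes(
    alignment,
    stem_clades,
    mode: str = EXTANT_EXTANT,
    anc: AncestralSequences | None = None,
) -> SubstitutionCounts:
    """Tally base-pair (duplet) changes over variable-stem column pairs.

    The state of a sequence at a stem column pair (i, j) is the ordered
    duplet (char_i, char_j); all-gap duplets are excluded from tallies, so a
    compensatory double change G:C -> A:U counts once as a duplet change.
    """
    states = pair_states()
    idx = {s: k for k, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=np.int64)

    def duplet(seq: str, i: int, j: int) -> str | None:
        a, b = seq[i], seq[j]
        if not (_usable(a) and _usable(b)):
            return None
        d = a + b
        return None if d == GAP + GAP else d

    for stem, clade in stem_clades:
        rows = _clade_rows(alignment, clade)
        if mode == EXTANT_EXTANT:
            for r1, r2 in combinations(sorted(rows), 2):
                for i, j in stem.pairs:
                    d1, d2 = duplet(rows[r1], i, j), duplet(rows[r2], i, j)
                    if d1 is None or d2 is None:
                        continue
                    hi, lo = max(idx[d1], idx[d2]), min(idx[d1], idx[d2])
                    counts[hi, lo] += 1
        elif mode == ANCESTRAL_EXTANT:
            if anc is None:
                raise ValueError("ancestral/extant mode requires reconstructions")
            anc_seq = anc.sequences[clade.id]
            for name in sorted(rows):
                for i, j in stem.pairs:
                    da, de = duplet(anc_seq, i, j), duplet(rows[name], i, j)
                    if da is None or de is None:
                        continue
                    counts[idx[da], idx[de]] += 1
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")

    return SubstitutionCounts(
        mode="pair", comparison=mode, states=states, counts=counts
    )


def log_odds_transform(
    counts: SubstitutionCounts, pseudocount: float = 0.0
) -> LogOddsMatrix:
    """Transform counts into a log2(observed/expected) matrix.

    Observed frequencies are counts normalized by the total; expected
    frequencies are products of the matrix's own marginals. For
    fold-symmetric counts the marginal of state i is f_ii plus half the
    off-diagonal mass involving i, and off-diagonal expectations use both
    orderings (2 f_i f_j); for directional counts, row and column marginals
    are used as-is. Cells with zero observations stay undefined (NaN).
    """
    n = len(counts.states)
    raw = counts.counts.astype(float)
    if counts.symmetric:
        mask = np.tril(np.ones((n, n), dtype=bool))
    else:
        mask = np.ones((n, n), dtype=bool)
    if pseudocount:
        raw = raw + pseudocount * mask
    total = raw.sum()
    if total <= 0:
        raise EmptyMatrixError("cannot transform a matrix with zero total events")
    f = raw / total

    values = np.full((n, n), np.nan)
    if counts.symmetric:
        p = np.array(
            [
                f[i, i]
                + 0.5 * (f[i, :i].sum() + f[i + 1 :, i].sum())
                for i in range(n)
            ]
        )
        for i in range(n):
            for j in range(i + 1):
                obs = f[i, j]
                exp = p[i] * p[j] * (1.0 if i == j else 2.0)
                if obs > 0 and exp > 0:
                    values[i, j] = np.log2(obs / exp)
    else:
        prow = f.sum(axis=1)
        pcol = f.sum(axis=0)
        for i in range(n):
            for j in range(n):
                obs = f[i, j]
                exp = prow[i] * pcol[j]
                if obs > 0 and exp > 0:
                    values[i, j] = np.log2(obs / exp)

    return LogOddsMatrix(
        mode=counts.mode,
        comparison=counts.comparison,
        states=counts.states,
        values=values,
        total_events=int(counts.counts.sum()),
    )
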