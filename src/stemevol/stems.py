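"""Stem, loop and pseudoknot annotation from a consensus secondary structure.

A consensus structure string assigns every alignment column either to a base
pair (matched bracket or letter symbols) or to an unpaired region. Matched
pairs are grouped into *stems* — maximal runs of nested, contiguous pairs —
and two stems form a *pseudoknot* when their arcs cross: pairs (i, j) and
(k, l) cross iff i < k < j < l. Per-sequence *realized* stem length is the
number of a stem's column pairs actually forming a canonical pair
(Watson-Crick or G-U wobble) in that sequence, which is the quantity whose
variation across a phylogeny the rest of the package analyses.

Column indices are 0-based half-open internally; every report and error
message uses 1-based columns, matching how alignment columns are cited.
"""

from __future__ import annotations

import json
import string
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .alphabet import UNKNOWN, is_base, is_canonical
from .errors import StructureError, ValidationError

OPENERS = "([{<"
CLOSERS = ")]}>"
#: structure-line characters treated as "unpaired"
UNPAIRED_CHARS = set(".,:_-~")

#: modal-length share thresholds for the three variability categories:
#: conserved 71-100%, intermediate 41-70%, variable 1-40% of species
CATEGORY_BINS = ((0.70, "conserved"), (0.40, "intermediate"), (0.0, "variable"))


def parse_structure_pairs(structure: str) -> list[tuple[int, int]]:
    """Match a structure string into a list of (i, j) column pairs, i < j.

    Round/square/curly/angle brackets each nest independently; uppercase
    letters open and the corresponding lowercase letters close pseudoknotted
    helices (WUSS convention). Raises :class:`StructureError` with a 1-based
    column on the first unmatched symbol.
    """
    stacks: dict[str, list[int]] = defaultdict(list)
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch in UNPAIRED_CHARS:
            continue
        if ch in OPENERS:
            stacks[ch].append(i)
        elif ch in CLOSERS:
            opener = OPENERS[CLOSERS.index(ch)]
            if not stacks[opener]:
                raise StructureError(
                    f"unmatched '{ch}' at column {i + 1}", column=i + 1
                )
            pairs.append((stacks[opener].pop(), i))
        elif ch.isalpha() and ch.isupper():
            stacks[ch].append(i)
        elif ch.isalpha() and ch.islower():
            opener = ch.upper()
            if not stacks[opener]:
                raise StructureError(
                    f"unmatched '{ch}' at column {i + 1}", column=i + 1
                )
            pairs.append((stacks[opener].pop(), i))
        else:
            raise StructureError(
                f"unrecognized structure symbol {ch!r} at column {i + 1}",
                column=i + 1,
            )
    for opener, stack in stacks.items():
        if stack:
            col = stack[-1] + 1
            raise StructureError(f"unmatched '{opener}' at column {col}", column=col)
    return sorted(pairs)


def arcs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True iff arcs p=(i,j) and q=(k,l) cross: i<k<j<l or k<i<l<j."""
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


@dataclass
class Stem:
    """One helix: an ordered (outermost-first) list of paired columns."""

    label: str
    pairs: tuple[tuple[int, int], ...]
    bulge_columns: tuple[int, ...] = ()
    pseudoknot: bool = False
    crossing_partners: tuple[str, ...] = ()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def columns(self) -> tuple[int, ...]:
        """All paired columns of the stem, ascending."""
        return tuple(sorted(c for p in self.pairs for c in p))

    @property
    def span(self) -> tuple[int, int]:
        """(first, last+1) half-open column span of the outermost pair."""
        return (self.pairs[0][0], self.pairs[0][1] + 1)


@dataclass
class StemSet:
    """All stems of a consensus structure plus the leftover loop intervals."""

    stems: list[Stem]
    loops: list[tuple[int, int]]  # half-open unpaired intervals, bulges excluded
    length: int

    def __iter__(self):
        return iter(self.stems)

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stems]

    def by_label(self, label: str) -> Stem:
        for s in self.stems:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_json(self, path) -> None:
        """Dump stems with 1-based columns."""
        payload = {
            "length": self.length,
            "stems": [
                {
                    "label": s.label,
                    "pairs": [[i + 1, j + 1] for i, j in s.pairs],
                    "bulge_columns": [c + 1 for c in s.bulge_columns],
                    "pseudoknot": s.pseudoknot,
                    "crossing_partners": list(s.crossing_partners),
                }
                for s in self.stems
            ],
            "loops": [[a + 1, b] for a, b in self.loops],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _stem_label(index: int) -> str:
    letters = string.ascii_uppercase
    if index < len(letters):
        return letters[index]
    return f"S{index + 1}"


def extract_stems(structure: str) -> StemSet:
    """Group the matched pairs of a structure string into stems.

    A helix is extended pair by pair while nesting is direct and contiguous:
    a single-strand bulge (gap on one side only) keeps the stem together,
    while an internal loop (>=1 unpaired column on both strands) or an
    intervening paired column from another helix starts a new stem. Crossing
    is then tested between every pair of stems to set pseudoknot flags.
    """
    pairs = parse_structure_pairs(structure)
    paired_cols = {c for p in pairs for c in p}

    groups: list[list[tuple[int, int]]] = []
    for pair in pairs:
        if groups:
            pi, pj = groups[-1][-1]
            qi, qj = pair
            nested = pi < qi and qj < pj
            if nested:
                gap_left = qi - pi - 1
                gap_right = pj - qj - 1
                interrupted = any(
                    c in paired_cols
                    for c in list(range(pi + 1, qi)) + list(range(qj + 1, pj))
                )
                if not interrupted and (gap_left == 0 or gap_right == 0):
                    groups[-1].append(pair)
                    continue
        groups.append([pair])

    groups.sort(key=lambda g: g[0][0])
    stems: list[Stem] = []
    for idx, grp in enumerate(groups):
        bulges: list[int] = []
        for (pi, pj), (qi, qj) in zip(grp, grp[1:]):
            bulges.extend(range(pi + 1, qi))
            bulges.extend(range(qj + 1, pj))
        stems.append(
            Stem(label=_stem_label(idx), pairs=tuple(grp), bulge_columns=tuple(bulges))
        )

    for a in range(len(stems)):
        for b in range(a + 1, len(stems)):
            if any(arcs_cross(p, q) for p in stems[a].pairs for q in stems[b].pairs):
                stems[a].pseudoknot = True
                stems[b].pseudoknot = True
                stems[a].crossing_partners += (stems[b].label,)
                stems[b].crossing_partners += (stems[a].label,)

    claimed = paired_cols | {c for s in stems for c in s.bulge_columns}
    loops: list[tuple[int, int]] = []
    start = None
    for c in range(len(structure)):
        if c not in claimed:
            if start is None:
                start = c
        elif start is not None:
            loops.append((start, c))
            start = None
    if start is not None:
        loops.append((start, len(structure)))

    return StemSet(stems=stems, loops=loops, length=len(structure))


def realized_stem_length(
    row: str, stem: Stem, count_bulges: bool = False
) -> int | None:
    """Count the stem's column pairs forming a canonical pair in ``row``.

    Returns ``None`` (the *unknown* flag) when any stem column holds ``~``,
    i.e. the region was not sequenced. IUPAC-ambiguous characters make a pair
    non-countable (skipped, neither paired nor broken). With ``count_bulges``,
    stem-internal bulge columns holding an unambiguous base add one each.
    """
    cols = stem.columns + (stem.bulge_columns if count_bulges else ())
    for c in cols:
        if c >= len(row):
            raise ValidationError(
                f"stem {stem.label} column {c + 1} outside row of length {len(row)}"
            )
        if row[c] == UNKNOWN:
            return None
    n = 0
    for i, j in stem.pairs:
        a, b = row[i], row[j]
        if is_base(a) and is_base(b) and is_canonical(a, b):
            n += 1
    if count_bulges:
        n += sum(1 for c in stem.bulge_columns if is_base(row[c]))
    return n


@dataclass
class StemLengthTable:
    """Species x stem realized lengths with unknown-region and partial flags."""

    lengths: pd.DataFrame  # float; NaN where unknown
    unknown: pd.DataFrame  # bool; True where the stem region overlaps '~'
    partial: pd.Series = field(default=None)  # bool per species: row contains '~'

    def __post_init__(self):
        if self.partial is None:
            self.partial = pd.Series(False, index=self.lengths.index)

    @property
    def species(self) -> list[str]:
        return list(self.lengths.index)

    @property
    def stem_labels(self) -> list[str]:
        return list(self.lengths.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence calls (realized length > 0); unknown cells False."""
        return (self.lengths > 0).fillna(False)

    def known_values(self, stem: str) -> pd.Series:
        col = self.lengths[stem]
        return col[~self.unknown[stem]].dropna()

    def modal_length(self, stem: str) -> int | None:
        """Most common known length; ties broken toward the larger length."""
        vals = self.known_values(stem)
        if vals.empty:
            return None
        counts = vals.value_counts()
        top = counts[counts == counts.max()]
        return int(max(top.index))

    def modal_share(self, stem: str) -> float | None:
        vals = self.known_values(stem)
        if vals.empty:
            return None
        modal = self.modal_length(stem)
        return float((vals == modal).sum() / len(vals))

    def category(self, stem: str) -> str | None:
        """Variability category from the share of species at the modal length."""
        share = self.modal_share(stem)
        if share is None:
            return None
        for threshold, name in CATEGORY_BINS:
            if share > threshold:
                return name
        return "variable"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.stem_labels) + "\n")
            for sp in self.species:
                cells = []
                for st in self.stem_labels:
                    if self.unknown.loc[sp, st]:
                        cells.append("NA")
                    else:
                        cells.append(str(int(self.lengths.loc[sp, st])))
                fh.write(sp + "\t" + "\t".join(cells) + "\n")
            cats = [str(self.category(st)) for st in self.stem_labels]
            fh.write("#category\t" + "\t".join(cats) + "\n")


def build_stem_length_table(
    alignment, stems: StemSet, count_bulges: bool = False
) -> StemLengthTable:
    """Realized length of every stem in every sequence of the alignment."""
    data = np.full((len(alignment.ids), len(stems)), np.nan)
    unknown = np.zeros_like(data, dtype=bool)
    partial = []
    for r, (sid, row) in enumerate(zip(alignment.ids, alignment.rows)):
        partial.append(UNKNOWN in row)
        for c, stem in enumerate(stems):
            length = realized_stem_length(row, stem, count_bulges=count_bulges)
            if length is None:
                unknown[r, c] = True
            else:
                data[r, c] = length
    labels = stems.labels
    return StemLengthTable(
        lengths=pd.DataFrame(data, index=list(alignment.ids), columns=labels),
        unknown=pd.DataFrame(unknown, index=list(alignment.ids), columns=labels),
        partial=pd.Series(partial, index=list(alignment.ids)),
    )


def arc_diagram_data(
    stems: StemSet, annotations: Mapping[str, str] | None = None
) -> list[dict]:
    """Drawing-neutral arc list: one (x1, x2, label, color_class) span per stem.

    ``annotations`` maps stem labels to a category or ancestral-state class,
    which becomes the arc's color class. Coordinates are 1-based outermost
    pair positions; crossing (pseudoknot) arcs are flagged.
    """
    annotations = dict(annotations or {})
    known = set(stems.labels)
    bad = set(annotations) - known
    if bad:
        raise ValidationError(f"annotation keys not among stems: {sorted(bad)}")
    arcs = []
    for s in stems:
        i, j = s.pairs[0]
        arcs.append(
            {
                "x1": i + 1,
                "x2": j + 1,
                "label": s.label,
                "color_class": annotations.get(s.label),
                "crossing": s.pseudoknot,
            }
        )
    return arcs
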