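"""Detection and classification of stem gain/loss events on a phylogeny.

Two processes change a stem's realized length across a tree:

* **whole-stem insertion/deletion** — the stem appears or disappears as a
  sequence block, diagnosed by the absence or presence of sequence at the
  reconstructed ancestral node of the variable clade;
* **pairing change by substitutions/indels** — the nucleotides remain but
  point mutations or single-base indels create or disrupt base pairs.

"No sequence present" is operationalized as a gap fraction of at least
``theta_gap`` (default 0.9) over the stem's paired columns; species whose
stem region overlaps ``~`` (not sequenced) are excluded from the call, since
presence or absence of structure cannot be asserted there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import GAP, UNKNOWN
from .ancestral import AncestralSequences
from .errors import DegenerateTableError, NoCallError
from .stems import Stem, StemLengthTable, StemSet, realized_stem_length
from .tree import Node, PhyloTree

WHOLE_STEM_INSERTION = "whole_stem_insertion"
WHOLE_STEM_DELETION = "whole_stem_deletion"
PAIRING_CHANGE = "pairing_change_substitution_indel"

#: the two top-level classes of Table-3-style frequency summaries
WHOLE_STEM_CLASSES = frozenset({WHOLE_STEM_INSERTION, WHOLE_STEM_DELETION})

DEFAULT_THETA_GAP = 0.9


@dataclass
class EventRecord:
    """One classified stem change with the evidence needed to re-derive it."""

    stem: str
    clade: int  # post-order node id of the variable clade
    event_class: str
    direction: str  # "gain" or "loss"
    evidence: dict = field(default_factory=dict)

    @property
    def is_whole_stem(self) -> bool:
        return self.event_class in WHOLE_STEM_CLASSES

    def to_dict(self) -> dict:
        return asdict(self)


def find_variable_stems(
    table: StemLengthTable, tree: PhyloTree
) -> list[tuple[str, int]]:
    """Smallest clades across which each stem's realized length varies.

    A change on some branch makes the subtree below it internally uniform
    yet different from its sister lineages, so a clade is reported when one
    of its branches carries a single length and another branch carries a
    different length, provided that *pair* of lengths has not already been
    explained by a reported descendant clade — the same contrast is never
    echoed at every ancestor on the way to the root, while fresh contrasts
    (new length pairs) still surface. Unknown cells are ignored; the root is
    reported as a last resort when an unexplained contrast survives to the
    top without any uniform branch to witness it. Returns (stem label,
    clade node id) pairs.
    """
    out: list[tuple[str, int]] = []
    for stem in table.stem_labels:
        values = dict(table.known_values(stem).items())
        seen: dict[int, set] = {}  # node id -> lengths observed in subtree
        explained: set[frozenset] = set()  # length pairs already reported
        for node in tree.root.postorder():
            if node.is_leaf:
                seen[node.id] = (
                    {values[node.name]} if node.name in values else set()
                )
                continue
            child_sets = [seen[c.id] for c in node.children]
            union = set().union(*child_sets)
            report = False
            for k, cs in enumerate(child_sets):
                if len(cs) != 1:
                    continue
                x = next(iter(cs))
                rest = set().union(
                    *(s for i, s in enumerate(child_sets) if i != k)
                )
                if any(
                    y != x and frozenset((x, y)) not in explained for y in rest
                ):
                    report = True
                    break
            if not report and node is tree.root:
                report = any(
                    frozenset((a, b)) not in explained
                    for a in union
                    for b in union
                    if a != b
                )
            if report:
                out.append((stem, node.id))
                explained |= {
                    frozenset((a, b)) for a in union for b in union if a != b
                }
            seen[node.id] = union
    return out


def _gap_fraction(chars: str) -> float | None:
    informative = [c for c in chars if c != "?"]
    if not informative:
        return None
    return sum(1 for c in informative if c == GAP) / len(informative)


def classify_stem_event(
    stem: Stem,
    clade: Node,
    alignment,
    anc: AncestralSequences,
    theta_gap: float = DEFAULT_THETA_GAP,
    count_bulges: bool = False,
) -> EventRecord:
    """Classify the stem change within ``clade`` using the ancestral sequence.

    Let g_anc be the gap fraction of the clade-node ancestral sequence over
    the stem's paired columns, and g_ext the same per extant member. The call
    is whole-stem insertion when g_anc >= theta_gap and some descendant
    realizes the stem; whole-stem deletion when the ancestor carries a
    realized stem and some descendant's region is (near-)all-gap; otherwise
    a pairing change by substitutions/indels. Members with ``~`` in the
    region are excluded; if none remain, a :class:`NoCallError` is raised.

    Parsimony cannot always polarize the clade node itself (losses on most
    branches cost the same as ancestral absence plus gains, leaving ``?``);
    when more than half of the stem's columns are unresolved there, the
    nearest ancestor whose region is resolved is consulted instead — the
    reconstructed common node at which sequence presence can actually be
    read. If no ancestor resolves (an innovation at the root bifurcation),
    ancestral presence falls back to the majority state over all sequenced
    rows of the alignment; the evidence records which route was taken.
    """
    rows = dict(zip(alignment.ids, alignment.rows))
    cols = stem.columns

    members, excluded = [], []
    for leaf in clade.leaves():
        row = rows[leaf.name]
        if any(row[c] == UNKNOWN for c in cols):
            excluded.append(leaf.name)
        else:
            members.append(leaf.name)
    if not members:
        raise NoCallError(
            f"stem {stem.label}: every descendant of clade {clade.id} is unsequenced"
        )

    def unresolved_fraction(node_id: int) -> float:
        seq = anc.sequences[node_id]
        return sum(1 for c in cols if seq[c] == "?") / len(cols)

    anc_node = clade
    while unresolved_fraction(anc_node.id) > 0.5 and anc_node.parent is not None:
        anc_node = anc_node.parent

    polarity = "reconstruction"
    if unresolved_fraction(anc_node.id) > 0.5:
        # no resolvable ancestor anywhere above: majority over sequenced rows
        polarity = "majority_fallback"
        fracs = [
            _gap_fraction("".join(row[c] for c in cols))
            for row in rows.values()
            if not any(row[c] == UNKNOWN for c in cols)
        ]
        absent = sum(1 for g in fracs if g >= theta_gap)
        if absent > len(fracs) - absent:
            g_anc, anc_len = 1.0, 0
        else:
            g_anc = 0.0
            carrier_lengths = [
                realized_stem_length(row, stem, count_bulges=count_bulges)
                for row in rows.values()
                if not any(row[c] == UNKNOWN for c in cols)
                and _gap_fraction("".join(row[c] for c in cols)) < theta_gap
            ]
            anc_len = max((v for v in carrier_lengths if v is not None), default=0)
    else:
        anc_seq = anc.sequences[anc_node.id]
        g_anc = _gap_fraction("".join(anc_seq[c] for c in cols))
        # '?' positions in the ancestor behave like ambiguity: non-countable
        anc_len = realized_stem_length(
            anc_seq.replace("?", "N"), stem, count_bulges=count_bulges
        )

    desc_lengths = {}
    desc_gap = {}
    for name in members:
        row = rows[name]
        desc_lengths[name] = realized_stem_length(
            row, stem, count_bulges=count_bulges
        )
        desc_gap[name] = _gap_fraction("".join(row[c] for c in cols))

    evidence = {
        "ancestral_node": anc_node.id,
        "polarity": polarity,
        "ancestral_gap_fraction": g_anc,
        "ancestral_realized_length": anc_len,
        "descendant_lengths": desc_lengths,
        "descendant_gap_fractions": desc_gap,
        "species": members,
        "excluded_unknown": excluded,
        "theta_gap": theta_gap,
    }

    if g_anc >= theta_gap and any(v > 0 for v in desc_lengths.values()):
        cls, direction = WHOLE_STEM_INSERTION, "gain"
    elif (
        g_anc < theta_gap
        and (anc_len or 0) > 0
        and any(g >= theta_gap for g in desc_gap.values())
    ):
        cls, direction = WHOLE_STEM_DELETION, "loss"
    else:
        cls = PAIRING_CHANGE
        median_desc = float(np.median(list(desc_lengths.values())))
        direction = "gain" if median_desc > (anc_len or 0) else "loss"

    return EventRecord(
        stem=stem.label,
        clade=clade.id,
        event_class=cls,
        direction=direction,
        evidence=evidence,
    )


def tabulate_event_frequencies(
    events_by_family: Mapping[str, Sequence[EventRecord]]
) -> pd.DataFrame:
    """Per-family percentages of whole-stem vs substitution/indel events.

    Returns a DataFrame indexed by family with raw counts and percentages;
    families with no events are excluded with a warning.
    """
    rows = {}
    for family, events in events_by_family.items():
        if not events:
            warnings.warn(f"family {family!r} has no events; excluded")
            continue
        n_whole = sum(1 for e in events if e.is_whole_stem)
        n_sub = len(events) - n_whole
        rows[family] = {
            "whole_stem_indel": n_whole,
            "substitution_indel": n_sub,
            "whole_stem_indel_pct": 100.0 * n_whole / len(events),
            "substitution_indel_pct": 100.0 * n_sub / len(events),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def chi_square_event_rates(counts) -> tuple[float, int, float]:
    """Pearson chi-square on an r x 2 family-by-class count table.

    Returns (statistic, df, p) with df = (r - 1); no continuity correction.
    Raises :class:`DegenerateTableError` if any expected count is zero.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise DegenerateTableError("need an r x 2 table with r >= 2")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        raise DegenerateTableError("empty table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected cell")
    stat = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[0] - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def write_event_log(events: Sequence[EventRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=1)
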