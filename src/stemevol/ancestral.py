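"""Parsimony ancestral-state reconstruction on a fixed rooted tree.

Three reconstructions are provided, all deterministic and all tolerant of
polytomies:

* **squared-change parsimony** for continuous characters (stem lengths):
  internal values minimize the sum over branches of (parent - child)^2,
  which is obtained exactly by solving the linear system in which every
  internal node equals the mean of its neighbors. Branch lengths are
  ignored (unweighted form).
* **sequence parsimony**: per alignment column, a unit-cost Sankoff dynamic
  program over the five states {A, C, G, U, -}. The gap is a full character
  state, so an ancestor can be reconstructed as having *no sequence* in a
  region; ``~`` (not sequenced) and IUPAC ambiguity at a leaf constrain the
  leaf to the compatible state set at zero cost. A node whose minimal-cost
  state set is not a singleton is written ``?`` and the full set is kept.
* **presence parsimony**: the same machinery over {present, absent}, with
  ties reported as ``unresolved``.

Sankoff's recursion on a binary tree with unit costs reduces to the classic
Fitch count, which the tests exploit as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import BASES, GAP, IUPAC_AMBIGUITY, STATES, UNKNOWN
from .errors import MappingError, MissingDataError
from .tree import PhyloTree

# ---------------------------------------------------------------------------
# continuous characters


@dataclass
class ContinuousReconstruction:
    """Squared-change parsimony estimates, keyed by post-order node id."""

    values: dict[int, float]
    cost: float


def squared_change_parsimony(
    tree: PhyloTree, leaf_values: Mapping[str, float]
) -> ContinuousReconstruction:
    """Minimize sum over edges of (parent - child)^2 over internal values.

    Every leaf must have a value; species with unknown cells should be pruned
    from the tree beforehand. The optimum satisfies, at each internal node,
    value = mean of neighbor values, a sparse linear system solved directly.
    """
    for leaf in tree.leaves:
        if leaf.name not in leaf_values:
            raise MissingDataError(f"no value for leaf {leaf.name!r}")

    internals = [n for n in tree.nodes if not n.is_leaf]
    values: dict[int, float] = {
        leaf.id: float(leaf_values[leaf.name]) for leaf in tree.leaves
    }
    if internals:
        index = {n.id: k for k, n in enumerate(internals)}
        A = np.zeros((len(internals), len(internals)))
        b = np.zeros(len(internals))
        for n in internals:
            k = index[n.id]
            neighbors = list(n.children) + ([n.parent] if n.parent else [])
            A[k, k] = len(neighbors)
            for m in neighbors:
                if m.is_leaf:
                    b[k] += values[m.id]
                else:
                    A[k, index[m.id]] -= 1.0
        x = np.linalg.solve(A, b)
        for n in internals:
            values[n.id] = float(x[index[n.id]])

    cost = 0.0
    for n in tree.nodes:
        if n.parent is not None:
            cost += (values[n.parent.id] - values[n.id]) ** 2
    return ContinuousReconstruction(values=values, cost=cost)


# ---------------------------------------------------------------------------
# discrete characters: generic unit-cost Sankoff with optimal-state sets


def sankoff_optimal_sets(
    tree: PhyloTree,
    leaf_state_sets: Mapping[str, frozenset],
    states: Sequence,
) -> tuple[float, dict[int, frozenset]]:
    """Unit-cost Sankoff over arbitrary states, polytomies included.

    ``leaf_state_sets`` gives, per leaf name, the set of states compatible
    with the observation (all states for missing data) at zero cost. Returns
    the minimal total number of changes and, for every node, the set of
    states that occur in at least one globally minimal labeling (computed by
    an up pass followed by a down pass over conditional costs).
    """
    n_states = len(states)
    inf = float("inf")
    up: dict[int, np.ndarray] = {}

    for node in tree.root.postorder():
        if node.is_leaf:
            try:
                allowed = leaf_state_sets[node.name]
            except KeyError:
                raise MappingError(f"leaf {node.name!r} has no observation")
            cost = np.array(
                [0.0 if s in allowed else inf for s in states]
            )
        else:
            cost = np.zeros(n_states)
            for child in node.children:
                c = up[child.id]
                best = c.min()
                # min over t of c[t] + 1[s != t]  ==  min(c[s], best + 1)
                cost += np.minimum(c, best + 1.0)
        up[node.id] = cost

    total = float(up[tree.root.id].min())

    # down pass: down[v][s] = minimal cost of the rest of the tree given v=s
    down: dict[int, np.ndarray] = {tree.root.id: np.zeros(n_states)}
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        base = up[node.id] + down[node.id]
        for child in node.children:
            c = up[child.id]
            contrib = np.minimum(c, c.min() + 1.0)
            rest = base - contrib  # cost with child's subtree removed
            best_rest = rest.min()
            # min over parent state s of rest[s] + 1[s != t]
            down[child.id] = np.minimum(rest, best_rest + 1.0)

    optimal: dict[int, frozenset] = {}
    for node in tree.nodes:
        combined = up[node.id] + down[node.id]
        optimal[node.id] = frozenset(
            s for s, v in zip(states, combined) if v <= total + 1e-9
        )
    return total, optimal


# ---------------------------------------------------------------------------
# ancestral sequences


@dataclass
class AncestralSequences:
    """Parsimony ancestral sequences keyed by post-order node id.

    ``sequences`` covers every node (leaves echo their observed rows);
    ``ambiguous`` maps node id -> {0-based column -> sorted optimal states}
    wherever the reconstruction wrote ``?``. ``column_scores`` holds the
    per-column minimal change counts summing to ``score``.
    """

    sequences: dict[int, str]
    score: float
    column_scores: list[float]
    ambiguous: dict[int, dict[int, list[str]]] = field(default_factory=dict)

    def to_fasta(self, path, tree: PhyloTree, internal_only: bool = True) -> None:
        with open(path, "w") as fh:
            for node in tree.nodes:
                if internal_only and node.is_leaf:
                    continue
                fh.write(f">{node.name}\n{self.sequences[node.id]}\n")


def _leaf_state_set(ch: str, gaps_as_missing: bool) -> frozenset:
    if ch in BASES:
        return frozenset({ch})
    if ch == GAP:
        return frozenset(STATES) if gaps_as_missing else frozenset({GAP})
    if ch == UNKNOWN:
        return frozenset(STATES)
    if ch in IUPAC_AMBIGUITY:
        return IUPAC_AMBIGUITY[ch]
    raise ValueError(f"unexpected sequence character {ch!r}")


def parsimony_ancestral_sequences(
    tree: PhyloTree, alignment, gaps_as_missing: bool = False
) -> AncestralSequences:
    """Column-independent 5-state parsimony sequences for every tree node.

    Every tree leaf must appear in the alignment. By default the gap is a
    fifth state with unit cost; ``gaps_as_missing`` instead treats leaf gaps
    as missing data (no constraint, no cost).
    """
    rows = dict(zip(alignment.ids, alignment.rows))
    missing = [lf.name for lf in tree.leaves if lf.name not in rows]
    if missing:
        raise MappingError(f"tree leaves absent from alignment: {missing}")

    L = alignment.n_columns
    node_chars: dict[int, list[str]] = {n.id: [] for n in tree.nodes}
    ambiguous: dict[int, dict[int, list[str]]] = {}
    column_scores: list[float] = []
    for col in range(L):
        leaf_sets = {
            lf.name: _leaf_state_set(rows[lf.name][col], gaps_as_missing)
            for lf in tree.leaves
        }
        score, optimal = sankoff_optimal_sets(tree, leaf_sets, STATES)
        column_scores.append(score)
        for node in tree.nodes:
            if node.is_leaf:
                node_chars[node.id].append(rows[node.name][col])
                continue
            opt = optimal[node.id]
            if len(opt) == 1:
                node_chars[node.id].append(next(iter(opt)))
            else:
                node_chars[node.id].append("?")
                ambiguous.setdefault(node.id, {})[col] = sorted(opt)

    return AncestralSequences(
        sequences={nid: "".join(chars) for nid, chars in node_chars.items()},
        score=float(sum(column_scores)),
        column_scores=column_scores,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# presence / absence

PRESENT, ABSENT, UNRESOLVED = "present", "absent", "unresolved"
_PRESENCE_STATES = (PRESENT, ABSENT)


@dataclass
class PresenceReconstruction:
    """Per-node stem presence call, keyed by post-order node id."""

    states: dict[int, str]
    cost: float


def presence_reconstruction(
    tree: PhyloTree, presence: Mapping[str, str]
) -> PresenceReconstruction:
    """Two-state unit-cost parsimony; ties are reported as ``unresolved``.

    Leaf observations are ``present``, ``absent`` or ``unknown`` (the last
    contributes no cost and no constraint).
    """
    leaf_sets = {}
    for leaf in tree.leaves:
        try:
            obs = presence[leaf.name]
        except KeyError:
            raise MappingError(f"leaf {leaf.name!r} has no presence observation")
        if obs == "unknown":
            leaf_sets[leaf.name] = frozenset(_PRESENCE_STATES)
        elif obs in _PRESENCE_STATES:
            leaf_sets[leaf.name] = frozenset({obs})
        else:
            raise ValueError(f"bad presence observation {obs!r} for {leaf.name!r}")
    cost, optimal = sankoff_optimal_sets(tree, leaf_sets, _PRESENCE_STATES)
    states = {}
    for node in tree.nodes:
        opt = optimal[node.id]
        states[node.id] = next(iter(opt)) if len(opt) == 1 else UNRESOLVED
    return PresenceReconstruction(states=states, cost=cost)
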