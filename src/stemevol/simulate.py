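"""Simulation of structured-RNA evolution along a tree, with logged truth.

The generator emulates the processes that reshape stems in real families:
whole-stem insertions (a new hairpin appears in a lineage, opening fresh
alignment columns that are gap-filled elsewhere), whole-stem deletions
(a lineage's stem block is gapped out), base-pair substitutions that are
compensated with a configurable probability (covariation), single-base
indels inside stems, and loop substitutions. Because insertions create
their own columns, the emitted alignment is a true multiple alignment and
no aligner is involved. Event counts per branch are Poisson with rate x
branch length; at most one whole-stem event touches a given stem on a given
branch, so the truth log is uniquely interpretable.

Everything — the alignment with consensus structure, the tree, the true
ancestral sequence at every node, and the event log — is returned for
end-to-end testing of the inference pipeline, and the whole simulation is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import BASES, GAP, UNKNOWN
from .errors import GenerationError
from .io import StructuralAlignment
from .stems import StemSet, extract_stems
from .tree import Node, PhyloTree

#: Watson-Crick partner used when a substitution is compensated
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: the six canonical pairs the root generator draws stems from
_CANONICAL = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


@dataclass
class EvolutionConfig:
    """Per-branch rates and root geometry for the simulator.

    Rates are expected event counts per unit branch length. Defaults give a
    family in which a handful of whole-stem gains/losses coexist with an
    order of magnitude more pairing changes, the regime reported for real
    stem-loop evolution (whole-stem events the rarer class).
    """

    seed: int = 0
    whole_stem_insertion_rate: float = 0.05
    whole_stem_deletion_rate: float = 0.05
    pair_substitution_rate: float = 0.5
    compensation_probability: float = 0.5
    in_stem_indel_rate: float = 0.2
    loop_substitution_rate: float = 0.5
    n_stems: int = 4
    stem_length_range: tuple[int, int] = (4, 8)
    loop_length_range: tuple[int, int] = (3, 6)
    pseudoknot: bool = False
    #: fraction of leaves whose terminal region is censored with '~'
    tilde_mask_fraction: float = 0.0

    def __post_init__(self):
        for name in (
            "whole_stem_insertion_rate",
            "whole_stem_deletion_rate",
            "pair_substitution_rate",
            "in_stem_indel_rate",
            "loop_substitution_rate",
        ):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        if not 0.0 <= self.compensation_probability <= 1.0:
            raise GenerationError("compensation_probability must be in [0, 1]")
        if self.n_stems < 1 or self.stem_length_range[0] < 1:
            raise GenerationError("need at least one stem of length >= 1")


@dataclass
class SimStem:
    """A simulated stem over global column ids."""

    label: str
    pair_cols: list[tuple[int, int]]  # (left col id, right col id), outermost first
    loop_cols: list[int]
    born_at: str  # "root" or the name of the node below the insertion branch
    is_pseudoknot: bool = False

    @property
    def all_cols(self) -> list[int]:
        return [c for p in self.pair_cols for c in p] + list(self.loop_cols)


@dataclass
class RootTemplate:
    """The ancestral molecule the simulation starts from."""

    sequence: str
    structure: str
    stemset: StemSet = None

    def __post_init__(self):
        if self.stemset is None:
            self.stemset = extract_stems(self.structure)


@dataclass
class SimulatedFamily:
    """A simulated alignment, its tree, and the complete generating truth."""

    alignment: StructuralAlignment
    tree: PhyloTree
    ancestral: dict[int, str]  # node id -> true sequence (gapped, full length)
    events: list[dict]
    stems_truth: list[dict]  # label, pairs (final column indices), born_at


def random_tree(
    n_leaves: int, seed: int = 0, branch_length: float = 1.0, rng=None
) -> PhyloTree:
    """Random rooted binary topology by sequential joining, unit branches."""
    rng = np.random.default_rng(seed) if rng is None else rng
    pool = [Node(name=f"t{i + 1}", length=branch_length) for i in range(n_leaves)]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = Node(length=branch_length)
        parent.add(pool[i])
        parent.add(pool[j])
        pool = [n for k, n in enumerate(pool) if k not in (i, j)] + [parent]
    pool[0].length = None
    return PhyloTree(pool[0])


def generate_root(config: EvolutionConfig, rng=None) -> RootTemplate:
    """A hairpin-series root molecule with all stems canonically paired.

    Hairpins are separated by linker loops; with ``pseudoknot`` enabled, a
    3-bp helix pairs the first hairpin's loop with the following linker,
    producing crossing arcs.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo_s, hi_s = config.stem_length_range
    lo_l, hi_l = config.loop_length_range
    if config.pseudoknot and (hi_l < 5 or config.n_stems < 1):
        raise GenerationError("pseudoknot needs loops of length >= 5")

    seq: list[str] = []
    struct: list[str] = []

    def random_base() -> str:
        return BASES[rng.integers(len(BASES))]

    pk_left: list[int] = []
    for k in range(config.n_stems):
        stem_len = int(rng.integers(lo_s, hi_s + 1))
        loop_len = int(rng.integers(lo_l, hi_l + 1))
        if config.pseudoknot and k == 0:
            loop_len = max(loop_len, 5)
        left = [random_base() for _ in range(stem_len)]
        right = []
        for b in reversed(left):
            pair = [p for p in _CANONICAL if p[0] == b]
            right.append(pair[rng.integers(len(pair))][1])
        start = len(seq)
        seq.extend(left)
        struct.extend("(" * stem_len)
        loop_start = len(seq)
        for i in range(loop_len):
            seq.append(random_base())
            struct.append(".")
        if config.pseudoknot and k == 0:
            pk_left = list(range(loop_start, loop_start + 3))
            for i, c in enumerate(pk_left):
                struct[c] = "A"
        seq.extend(right)
        struct.extend(")" * stem_len)
        if k < config.n_stems - 1 or (config.pseudoknot and k == 0):
            linker_len = int(rng.integers(lo_l, hi_l + 1))
            if config.pseudoknot and k == 0:
                linker_len = max(linker_len, 4)
            linker_start = len(seq)
            for _ in range(linker_len):
                seq.append(random_base())
                struct.append(".")
            if config.pseudoknot and k == 0:
                pk_right = list(range(linker_start, linker_start + 3))
                for c_left, c_right in zip(pk_left, reversed(pk_right)):
                    struct[c_right] = "a"
                    seq[c_right] = _WC[seq[c_left]]

    return RootTemplate(sequence="".join(seq), structure="".join(struct))


# ---------------------------------------------------------------------------


def _poisson(rng, rate: float, bl: float) -> int:
    return int(rng.poisson(rate * bl)) if rate > 0 else 0


def evolve(
    tree: PhyloTree, root: RootTemplate, config: EvolutionConfig
) -> SimulatedFamily:
    """Run the simulation along ``tree`` starting from ``root``.

    Branch lengths default to 1 where absent. Returns the leaf alignment
    (with a consensus structure covering every column ever created), the
    true sequence at every internal node, and the event log.
    """
    rng = np.random.default_rng(config.seed)

    L0 = len(root.sequence)
    order: list[int] = list(range(L0))
    next_col = L0

    stems: list[SimStem] = []
    pk_cols: set[int] = set()
    for s in root.stemset.stems:
        sim = SimStem(
            label=s.label,
            pair_cols=[tuple(p) for p in s.pairs],
            loop_cols=[],
            born_at="root",
            is_pseudoknot=s.pseudoknot,
        )
        stems.append(sim)
        if s.pseudoknot:
            pk_cols.update(c for p in s.pairs for c in p)
    paired0 = {c for s in stems for p in s.pair_cols for c in p}
    loop_cols: set[int] = {c for c in range(L0) if c not in paired0}
    # hairpin loops own their unpaired columns except those claimed by a pk helix
    for s in stems:
        if s.is_pseudoknot:
            continue
        i0, j0 = s.pair_cols[0]
        s.loop_cols = [
            c for c in range(i0 + 1, j0) if c in loop_cols and c not in pk_cols
        ]

    root_seq: dict[int, str] = {
        c: ch for c, ch in enumerate(root.sequence) if ch != GAP
    }
    events: list[dict] = []
    node_seqs: dict[int, dict[int, str]] = {}
    n_inserted = 0

    def anchor_positions() -> list[int | None]:
        """Insertion anchors: the start, or just after any stem's last column."""
        return [None] + [max(c for p in s.pair_cols for c in p) for s in stems]

    def mutate_branch(parent_seq: dict[int, str], node: Node) -> dict[int, str]:
        nonlocal next_col, n_inserted
        seq = dict(parent_seq)
        bl = node.length if node.length is not None else 1.0
        touched: set[str] = set()

        # whole-stem insertions
        for _ in range(_poisson(rng, config.whole_stem_insertion_rate, bl)):
            stem_len = int(
                rng.integers(config.stem_length_range[0], config.stem_length_range[1] + 1)
            )
            loop_len = int(
                rng.integers(config.loop_length_range[0], config.loop_length_range[1] + 1)
            )
            anchors = anchor_positions()
            anchor = anchors[rng.integers(len(anchors))]
            at = 0 if anchor is None else order.index(anchor) + 1
            n_cols = 2 * stem_len + loop_len
            new_ids = list(range(next_col, next_col + n_cols))
            next_col += n_cols
            order[at:at] = new_ids
            left = new_ids[:stem_len]
            loop = new_ids[stem_len : stem_len + loop_len]
            right = new_ids[stem_len + loop_len :]
            label = f"INS{n_inserted}"
            n_inserted += 1
            pairs = list(zip(left, reversed(right)))
            for lc, rc in pairs:
                a, b = _CANONICAL[rng.integers(len(_CANONICAL))]
                seq[lc], seq[rc] = a, b
            for c in loop:
                seq[c] = BASES[rng.integers(len(BASES))]
            stems.append(
                SimStem(
                    label=label,
                    pair_cols=pairs,
                    loop_cols=list(loop),
                    born_at=node.name,
                )
            )
            loop_cols.update(loop)
            touched.add(label)
            events.append(
                {
                    "event_class": "whole_stem_insertion",
                    "stem": label,
                    "node": node.name,
                    "direction": "gain",
                }
            )

        # whole-stem deletions (at most one whole-stem event per stem per branch)
        for _ in range(_poisson(rng, config.whole_stem_deletion_rate, bl)):
            eligible = [
                s
                for s in stems
                if s.label not in touched
                and any(seq.get(c, GAP) != GAP for p in s.pair_cols for c in p)
            ]
            if not eligible:
                continue
            victim = eligible[rng.integers(len(eligible))]
            for c in victim.all_cols:
                seq.pop(c, None)
            touched.add(victim.label)
            events.append(
                {
                    "event_class": "whole_stem_deletion",
                    "stem": victim.label,
                    "node": node.name,
                    "direction": "loss",
                }
            )

        # base-pair substitutions, compensated with probability p_comp
        for _ in range(_poisson(rng, config.pair_substitution_rate, bl)):
            candidates = [
                (s, p)
                for s in stems
                for p in s.pair_cols
                if seq.get(p[0], GAP) in BASES and seq.get(p[1], GAP) in BASES
            ]
            if not candidates:
                continue
            stem_obj, (lc, rc) = candidates[rng.integers(len(candidates))]
            side, other = (lc, rc) if rng.random() < 0.5 else (rc, lc)
            old = seq[side]
            new = [b for b in BASES if b != old][rng.integers(3)]
            seq[side] = new
            compensated = rng.random() < config.compensation_probability
            if compensated:
                seq[other] = _WC[new]
            events.append(
                {
                    "event_class": "pair_substitution",
                    "stem": stem_obj.label,
                    "node": node.name,
                    "compensated": compensated,
                }
            )

        # single-base indels inside stems
        for _ in range(_poisson(rng, config.in_stem_indel_rate, bl)):
            present = [
                (s, c)
                for s in stems
                for p in s.pair_cols
                for c in p
                if seq.get(c, GAP) in BASES
            ]
            partially = [
                (s, c)
                for s in stems
                for p in s.pair_cols
                for c in p
                if seq.get(c, GAP) == GAP
                and any(seq.get(cc, GAP) in BASES for pp in s.pair_cols for cc in pp)
            ]
            do_insert = bool(partially) and rng.random() < 0.5
            pool = partially if do_insert else present
            if not pool:
                continue
            stem_obj, col = pool[rng.integers(len(pool))]
            if do_insert:
                seq[col] = BASES[rng.integers(len(BASES))]
            else:
                seq.pop(col, None)
            events.append(
                {
                    "event_class": "in_stem_indel",
                    "stem": stem_obj.label,
                    "node": node.name,
                    "direction": "gain" if do_insert else "loss",
                }
            )

        # loop substitutions
        for _ in range(_poisson(rng, config.loop_substitution_rate, bl)):
            pool = [c for c in loop_cols if seq.get(c, GAP) in BASES]
            if not pool:
                continue
            col = pool[rng.integers(len(pool))]
            old = seq[col]
            seq[col] = [b for b in BASES if b != old][rng.integers(3)]
            events.append(
                {"event_class": "loop_substitution", "node": node.name}
            )

        return seq

    def descend(node: Node, seq: dict[int, str]) -> None:
        node_seqs[node.id] = seq
        for child in node.children:
            descend(child, mutate_branch(seq, child))

    descend(tree.root, root_seq)

    if not any(node_seqs[lf.id] for lf in tree.leaves):
        raise GenerationError("rates deleted every base from every leaf")

    # linearize over the final global column order
    final_index = {cid: k for k, cid in enumerate(order)}
    L = len(order)

    def linearize(seq: dict[int, str]) -> str:
        chars = [GAP] * L
        for cid, ch in seq.items():
            chars[final_index[cid]] = ch
        return "".join(chars)

    struct_chars = ["."] * L
    for s in stems:
        op, cl = ("A", "a") if s.is_pseudoknot else ("(", ")")
        for lc, rc in s.pair_cols:
            struct_chars[final_index[lc]] = op
            struct_chars[final_index[rc]] = cl
    structure = "".join(struct_chars)

    leaf_rows = {lf.name: linearize(node_seqs[lf.id]) for lf in tree.leaves}

    # optional censoring of terminal regions with '~'
    if config.tilde_mask_fraction > 0:
        names = sorted(leaf_rows)
        n_mask = int(round(config.tilde_mask_fraction * len(names)))
        chosen = rng.choice(len(names), size=n_mask, replace=False) if n_mask else []
        for k in chosen:
            name = names[int(k)]
            m = int(rng.integers(1, max(2, L // 5)))
            row = leaf_rows[name]
            if rng.random() < 0.5:
                leaf_rows[name] = UNKNOWN * m + row[m:]
            else:
                leaf_rows[name] = row[: L - m] + UNKNOWN * m

    ids = [lf.name for lf in tree.leaves]
    alignment = StructuralAlignment(
        ids=ids,
        rows=[leaf_rows[i] for i in ids],
        consensus_structure=structure,
        family_label="simulated",
    )
    ancestral = {
        n.id: linearize(node_seqs[n.id]) for n in tree.nodes if not n.is_leaf
    }
    stems_truth = [
        {
            "label": s.label,
            "pairs": [
                (final_index[lc], final_index[rc]) for lc, rc in s.pair_cols
            ],
            "born_at": s.born_at,
            "is_pseudoknot": s.is_pseudoknot,
        }
        for s in stems
    ]
    return SimulatedFamily(
        alignment=alignment,
        tree=tree,
        ancestral=ancestral,
        events=events,
        stems_truth=stems_truth,
    )


def simulate_family(
    config: EvolutionConfig, n_leaves: int = 12
) -> SimulatedFamily:
    """Convenience wrapper: random tree + random root + evolve, one seed."""
    tree = random_tree(n_leaves, seed=config.seed)
    root = generate_root(config, rng=np.random.default_rng(config.seed + 1))
    return evolve(tree, root, config)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_report(
    sim: SimulatedFamily,
    inferred_stems: StemSet,
    inferred_events,
    inferred_anc,
) -> dict:
    """Score an inference run against the simulation's truth.

    Whole-stem recall: planted whole-stem events whose stem (matched by
    paired-column overlap) was called with the same class. Class precision:
    inferred events whose top-level class (whole-stem vs pairing change)
    agrees with the classes of truth events on that stem. Ancestral accuracy:
    fraction of non-'?' reconstructed positions matching the true internal
    sequences. Counts are returned so batches can be pooled.
    """
    truth_cols = {
        t["label"]: frozenset(c for p in t["pairs"] for c in p)
        for t in sim.stems_truth
    }
    inferred_cols = {s.label: frozenset(s.columns) for s in inferred_stems}

    def truth_label_for(inferred_label: str) -> str | None:
        cols = inferred_cols[inferred_label]
        best, best_ov = None, 0
        for lab, tcols in truth_cols.items():
            ov = len(cols & tcols)
            if ov > best_ov:
                best, best_ov = lab, ov
        return best

    whole_truth = [
        e for e in sim.events if e["event_class"].startswith("whole_stem")
    ]
    sub_truth_stems = {
        e["stem"]
        for e in sim.events
        if e["event_class"] in ("pair_substitution", "in_stem_indel")
    }
    whole_truth_stems = {(e["stem"], e["event_class"]) for e in whole_truth}

    inferred_by_stem: dict[str, list] = {}
    for ev in inferred_events:
        lab = truth_label_for(ev.stem)
        inferred_by_stem.setdefault(lab, []).append(ev)

    n_detected = 0
    for e in whole_truth:
        hits = inferred_by_stem.get(e["stem"], [])
        if any(h.event_class == e["event_class"] for h in hits):
            n_detected += 1

    n_correct = 0
    for ev in inferred_events:
        lab = truth_label_for(ev.stem)
        if ev.is_whole_stem:
            ok = any(stem == lab for stem, _ in whole_truth_stems) and any(
                cls == ev.event_class for stem, cls in whole_truth_stems if stem == lab
            )
        else:
            ok = lab in sub_truth_stems
        n_correct += bool(ok)

    anc_total = anc_match = 0
    for nid, true_seq in sim.ancestral.items():
        inf_seq = inferred_anc.sequences.get(nid)
        if inf_seq is None:
            continue
        for a, b in zip(inf_seq, true_seq):
            if a != "?":
                anc_total += 1
                anc_match += a == b
    return {
        "n_planted_whole_stem": len(whole_truth),
        "n_detected_whole_stem": n_detected,
        "whole_stem_recall": (
            n_detected / len(whole_truth) if whole_truth else None
        ),
        "n_inferred_events": len(inferred_events),
        "n_class_correct": n_correct,
        "class_precision": (
            n_correct / len(inferred_events) if inferred_events else None
        ),
        "ancestral_positions": anc_total,
        "ancestral_matches": anc_match,
        "ancestral_accuracy": anc_match / anc_total if anc_total else 1.0,
    }
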