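"""Substitution counting and log-odds identities against hand arithmetic."""

import numpy as np
import pytest

import stemevol as se
from stemevol.alphabet import STATES
from stemevol.errors import EmptyMatrixError
from stemevol.matrices import (
    ANCESTRAL_EXTANT,
    EXTANT_EXTANT,
    SubstitutionCounts,
    pair_states,
)
from stemevol.stems import Stem, extract_stems


def _setup(rows, structure="((....))"):
    """Alignment + one stem treated as variable over the whole (cherry) tree."""
    ids = [f"s{i}" for i in range(len(rows))]
    aln = se.StructuralAlignment(ids=ids, rows=rows, consensus_structure=structure)
    newick = "(" + ",".join(ids) + ");"
    tree = se.PhyloTree.from_newick(newick)
    stems = extract_stems(structure)
    return aln, tree, [(stems.stems[0], tree.root)]


def _idx(state):
    return STATES.index(state)


class TestSingleCounts:
    def test_identical_sequences_diagonal_only(self):
        aln, tree, sc = _setup(["GCAAAAGC", "GCAAAAGC"])
        counts = se.count_single_changes(aln, sc, EXTANT_EXTANT)
        c = counts.counts
        assert counts.total_events == 4  # 4 paired columns
        assert c[_idx("G"), _idx("G")] == 2 and c[_idx("C"), _idx("C")] == 2

    def test_unordered_tally_off_diagonal(self):
        # stem columns 0,1,6,7; rows differ at column 1 (C vs U)
        aln, tree, sc = _setup(["GCAAAAGC", "GUAAAAGC"])
        counts = se.count_single_changes(aln, sc, EXTANT_EXTANT)
        c = counts.counts
        assert c[_idx("U"), _idx("C")] == 1  # stored in the lower triangle
        assert c[_idx("C"), _idx("U")] == 0

    def test_ancestral_mode_is_directional(self):
        aln, tree, sc = _setup(["AGAAAACU", "AGAAAACU"])
        anc = se.parsimony_ancestral_sequences(tree, aln)
        # force a distinct ancestral state at one stem column
        anc.sequences[tree.root.id] = "A-AAAACU"
        counts = se.count_single_changes(aln, sc, ANCESTRAL_EXTANT, anc=anc)
        c = counts.counts
        assert c[_idx("A"), _idx("A")] == 2  # A->A for both members
        assert c[_idx("-"), _idx("G")] == 2  # '-'->G
        assert c[_idx("G"), _idx("-")] == 0

    def test_skip_rules(self):
        # '~' and IUPAC ambiguity columns are skipped, gaps are counted
        aln, tree, sc = _setup(["GNAAAA~C", "GCAAAA-C"])
        counts = se.count_single_changes(aln, sc, EXTANT_EXTANT)
        assert counts.total_events == 2  # cols 1 (N) and 6 (~) skipped
        assert counts.counts[_idx("G"), _idx("G")] == 1
        assert counts.counts[_idx("C"), _idx("C")] == 1

    def test_ancestral_question_marks_skipped(self):
        aln, tree, sc = _setup(["GCAAAAGC", "GCAAAAGC"])
        anc = se.parsimony_ancestral_sequences(tree, aln)
        anc.sequences[tree.root.id] = "?CAAAAG?"
        counts = se.count_single_changes(aln, sc, ANCESTRAL_EXTANT, anc=anc)
        assert counts.total_events == 4  # 2 members x 2 usable columns


class TestPairCounts:
    def test_identical_rows_diagonal(self):
        aln, tree, sc = _setup(["GCAAAAGC", "GCAAAAGC"])
        counts = se.count_pair_changes(aln, sc, EXTANT_EXTANT)
        ps = pair_states()
        # pair (0,7) reads 5'->3' as G:C, pair (1,6) as C:G
        assert counts.counts[ps.index("GC"), ps.index("GC")] == 1
        assert counts.counts[ps.index("CG"), ps.index("CG")] == 1
        assert counts.total_events == 2

    def test_compensatory_double_change_single_tally(self):
        aln, tree, sc = _setup(["GAAAAAUC", "AAAAAAUU"], structure="(......)")
        counts = se.count_pair_changes(aln, sc, EXTANT_EXTANT)
        ps = pair_states()
        hi, lo = sorted((ps.index("GC"), ps.index("AU")), reverse=True)
        assert counts.counts[hi, lo] == 1
        assert counts.total_events == 1

    def test_single_side_change(self):
        aln, tree, sc = _setup(["GAAAAAUC", "GAAAAAUU"], structure="(......)")
        counts = se.count_pair_changes(aln, sc, EXTANT_EXTANT)
        ps = pair_states()
        hi, lo = sorted((ps.index("GC"), ps.index("GU")), reverse=True)
        assert counts.counts[hi, lo] == 1

    def test_all_gap_duplet_excluded(self):
        aln, tree, sc = _setup(["GAAAAAUC", "-AAAAAU-"], structure="(......)")
        counts = se.count_pair_changes(aln, sc, EXTANT_EXTANT)
        assert counts.total_events == 0


class TestLogOdds:
    def _sym_counts(self, grid):
        c = np.zeros((5, 5), dtype=np.int64)
        for (a, b), v in grid.items():
            hi, lo = sorted((_idx(a), _idx(b)), reverse=True)
            c[hi, lo] = v
        return SubstitutionCounts("single", EXTANT_EXTANT, STATES, c)

    def test_hand_computed_example(self):
        # {A:A}=8, {A,C}=2, {C:C}=0  ->  p_A=0.9, p_C=0.1
        lo = se.log_odds_transform(self._sym_counts({("A", "A"): 8, ("A", "C"): 2}))
        assert lo.values[_idx("A"), _idx("A")] == pytest.approx(np.log2(0.8 / 0.81))
        assert lo.values[_idx("C"), _idx("A")] == pytest.approx(
            np.log2(0.2 / (2 * 0.9 * 0.1))
        )
        assert np.isnan(lo.values[_idx("C"), _idx("C")])

    def test_single_cell_matrix_is_zero(self):
        lo = se.log_odds_transform(self._sym_counts({("A", "A"): 10}))
        assert lo.values[_idx("A"), _idx("A")] == pytest.approx(0.0)

    def test_independence_gives_all_zero_cells(self):
        # counts proportional to marginal products: c_ii = a_i^2, c_ij = 2 a_i a_j
        a = np.array([1, 2, 3, 4, 10])
        c = np.zeros((5, 5), dtype=np.int64)
        for i in range(5):
            for j in range(i + 1):
                c[i, j] = a[i] * a[j] * (1 if i == j else 2)
        lo = se.log_odds_transform(
            SubstitutionCounts("single", EXTANT_EXTANT, STATES, c)
        )
        tril = np.tril_indices(5)
        assert np.allclose(lo.values[tril], 0.0, atol=1e-12)

    def test_directional_independence(self):
        r = np.array([1, 2, 3, 4, 5])
        c = np.outer(r, r)
        lo = se.log_odds_transform(
            SubstitutionCounts("single", ANCESTRAL_EXTANT, STATES, c)
        )
        assert np.allclose(lo.values, 0.0, atol=1e-12)

    def test_scale_invariance(self):
        base = self._sym_counts({("A", "A"): 8, ("A", "C"): 2, ("G", "U"): 5})
        scaled = SubstitutionCounts(
            "single", EXTANT_EXTANT, STATES, base.counts * 17
        )
        v1, v2 = se.log_odds_transform(base).values, se.log_odds_transform(scaled).values
        assert np.allclose(np.nan_to_num(v1), np.nan_to_num(v2))

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = rng.integers(0, 50, size=(5, 5))
            counts = SubstitutionCounts("single", ANCESTRAL_EXTANT, STATES, c)
            if counts.total_events == 0:
                continue
            f = counts.counts / counts.total_events
            assert f.sum() == pytest.approx(1.0)

    def test_transpose_swaps_ancestor_and_extant(self):
        rng = np.random.default_rng(6)
        c = rng.integers(1, 20, size=(5, 5))
        lo = se.log_odds_transform(
            SubstitutionCounts("single", ANCESTRAL_EXTANT, STATES, c)
        )
        lo_t = se.log_odds_transform(
            SubstitutionCounts("single", ANCESTRAL_EXTANT, STATES, c.T)
        )
        assert np.allclose(lo_t.values, lo.values.T)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyMatrixError):
            se.log_odds_transform(
                SubstitutionCounts(
                    "single", EXTANT_EXTANT, STATES, np.zeros((5, 5), dtype=np.int64)
                )
            )

    def test_pseudocount_defines_all_cells(self):
        lo = se.log_odds_transform(
            self._sym_counts({("A", "A"): 8, ("A", "C"): 2}), pseudocount=0.5
        )
        tril = np.tril_indices(5)
        assert not np.isnan(lo.values[tril]).any()


def test_swapping_sequences_leaves_extant_counts_unchanged():
    rows = ["GCAAAAGC", "GUAAAAAC"]
    a1, t1, sc1 = _setup(rows)
    a2, t2, sc2 = _setup(rows[::-1])
    c1 = se.count_single_changes(a1, sc1, EXTANT_EXTANT).counts
    c2 = se.count_single_changes(a2, sc2, EXTANT_EXTANT).counts
    assert (c1 == c2).all()


def test_planted_compensatory_changes_stay_canonical():
    """On simulated data the compensatory duplet pairs appear among the
    defined positive off-diagonal cells of the extant/extant pair matrix."""
    cfg = se.EvolutionConfig(
        seed=2, compensation_probability=1.0, in_stem_indel_rate=0.0,
        whole_stem_insertion_rate=0.0, whole_stem_deletion_rate=0.0,
        pair_substitution_rate=2.0,
    )
    sim = se.simulate_family(cfg, n_leaves=10)
    stems = extract_stems(sim.alignment.consensus_structure)
    # with full compensation every stem stays canonical: all observed
    # off-diagonal duplet changes are canonical <-> canonical
    sc = [(s, sim.tree.root) for s in stems]
    counts = se.count_pair_changes(sim.alignment, sc, EXTANT_EXTANT)
    ps = pair_states()
    canonical = {"AU", "UA", "GC", "CG", "GU", "UG"}
    observed = np.argwhere(counts.counts > 0)
    for i, j in observed:
        assert ps[i] in canonical and ps[j] in canonical
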