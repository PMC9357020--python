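"""Parsimony: lengths, indices, ancestral states, search, consensus, Bremer."""
from itertools import product

import numpy as np
import pytest

from conglobe.errors import InsufficientDataError, MappingError
from conglobe.morpho_io import CharacterMatrix
from conglobe.parsimony import (
    bremer_supports,
    exhaustive_search,
    fitch_asr,
    fitch_length,
    heuristic_search,
    strict_consensus,
    tree_score,
)
from conglobe.phylogeny import Phylogeny, tree_from_splits


def brute_force_length(tree, char):
    """Oracle: minimize changes over all internal-node state assignments."""
    states = sorted({s for s in char.values() if s not in "?-"})
    internals = tree.internal_nodes()
    tips = tree.tips()
    best = None
    tip_choices = {
        t: [char[tree.taxon(t)]] if char[tree.taxon(t)] not in "?-" else states
        for t in tips
    }
    for internal_assign in product(states, repeat=len(internals)):
        assign = dict(zip(internals, internal_assign))
        for tip_assign in product(*(tip_choices[t] for t in tips)):
            assign.update(zip(tips, tip_assign))
            changes = sum(
                1
                for n in tree.nodes
                if tree.parent(n) is not None and assign[n] != assign[tree.parent(n)]
            )
            best = changes if best is None else min(best, changes)
    return best


# ---------------------------------------------------------------------------
# Fitch length
# ---------------------------------------------------------------------------


def test_fitch_length_hand_examples():
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    assert fitch_length(tree, {"A": "0", "B": "0", "C": "1", "D": "1"}) == 1
    assert fitch_length(tree, {"A": "0", "B": "1", "C": "0", "D": "1"}) == 2
    assert fitch_length(tree, {"A": "0", "B": "0", "C": "0", "D": "0"}) == 0
    # missing data never adds steps
    assert fitch_length(tree, {"A": "0", "B": "?", "C": "1", "D": "1"}) == 1
    assert fitch_length(tree, {"A": "0", "B": "-", "C": "1", "D": "1"}) == 1


def test_fitch_length_multistate_on_polytomy():
    # star tree: every tip differing from the root's state costs one change,
    # so length = n_tips - max state frequency (here 5 - 2 = 3)
    tree = Phylogeny.from_nested(("A", "B", "C", "D", "E"))
    char = {"A": "0", "B": "1", "C": "2", "D": "2", "E": "1"}
    assert fitch_length(tree, char) == 3


def test_fitch_length_matches_brute_force_small_random():
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        # random rooted binary tree by sequential pairing
        groups = list(taxa)
        while len(groups) > 1:
            i, j = sorted(rng.choice(len(groups), 2, replace=False))
            groups[i] = (groups[i], groups.pop(j))
        tree = Phylogeny.from_nested(groups[0])
        char = {
            t: str(rng.integers(3)) if rng.random() > 0.15 else "?" for t in taxa
        }
        if all(v == "?" for v in char.values()):
            char[taxa[0]] = "0"
        assert fitch_length(tree, char) == brute_force_length(tree, char)


def test_fitch_length_taxon_mismatch():
    tree = Phylogeny.from_nested((("A", "B"), "C"))
    with pytest.raises(MappingError):
        fitch_length(tree, {"A": "0", "B": "1"})


# ---------------------------------------------------------------------------
# tree score (CI / RI)
# ---------------------------------------------------------------------------


def test_tree_score_hand_example():
    # ((A,B),(C,D)): char1 0011 fits (1 step), char2 0101 is homoplastic (2)
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    mat = CharacterMatrix(
        ["A", "B", "C", "D"],
        np.array([list("00"), list("01"), list("10"), list("11")]),
    )
    score = tree_score(tree, mat)
    assert score.length == 3  # 1 + 2
    assert score.min_steps == 2  # each char: 2 states - 1
    # g per char: n_applicable - max state frequency = 4 - 2 = 2
    assert score.max_steps == 4
    assert score.ci == pytest.approx(2 / 3)
    assert score.ri == pytest.approx((4 - 3) / (4 - 2))
    assert score.rounded() == (0.67, 0.5)


def test_tree_score_perfect_fit_ci_one():
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    mat = CharacterMatrix(["A", "B", "C", "D"], np.array([["0"], ["0"], ["1"], ["1"]]))
    score = tree_score(tree, mat)
    assert score.ci == 1.0 and score.ri == 1.0


def test_tree_score_ignores_missing_in_m_and_g():
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    mat = CharacterMatrix(["A", "B", "C", "D"], np.array([["?"], ["0"], ["1"], ["1"]]))
    score = tree_score(tree, mat)
    assert score.min_steps == 1
    assert score.max_steps == 1  # 3 applicable - freq(1)=2
    assert score.length == 1


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def test_fitch_asr_mpr_sets_hand_example():
    # classic: ((A:0,B:1),(C:0,D:1)) -> root MPR set is {0,1}
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    asr = fitch_asr(tree, {"A": "0", "B": "1", "C": "0", "D": "1"})
    assert asr.length == 2
    assert asr.states[tree.root] == frozenset("01")
    # tips keep their observed state
    assert asr.states[tree.tip_of("A")] == frozenset("0")


def test_fitch_asr_resolution_attains_minimum_length():
    rng = np.random.default_rng(18)
    for _ in range(10):
        tree = Phylogeny.from_nested(
            ((("A", "B"), "C"), (("D", "E"), "F"))
        )
        char = {t: str(rng.integers(3)) for t in "ABCDEF"}
        asr = fitch_asr(tree, char)
        changes = sum(
            1
            for n in tree.nodes
            if tree.parent(n) is not None
            and asr.resolution[n] != asr.resolution[tree.parent(n)]
        )
        assert changes == asr.length == fitch_length(tree, char)


def test_fitch_asr_unambiguous_change_flagged():
    # (A,B,(C,D)): the root is pinned to {0} by two 0-tips, the CD node to
    # {1} by two 1-tips, so the change on the CD stem is forced and unambiguous
    tree = Phylogeny.from_nested(("A", "B", ("C", "D")))
    asr = fitch_asr(tree, {"A": "0", "B": "0", "C": "1", "D": "1"})
    assert asr.length == 1
    assert len(asr.changes) == 1
    change = asr.changes[0]
    assert change.parent_states == frozenset("0")
    assert change.child_states == frozenset("1")
    assert change.unambiguous
    assert asr.unambiguous_changes() == [change]


def test_fitch_asr_sliding_change_not_flagged():
    # a single change whose position slides along a path: endpoint MPR sets
    # overlap everywhere, so no branch is annotated as a forced change
    tree = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    asr = fitch_asr(tree, {"A": "0", "B": "0", "C": "1", "D": "1"})
    assert asr.length == 1
    assert asr.states[tree.root] == frozenset("01")
    assert asr.changes == []


def test_fitch_asr_state_origins_single_nested_gain():
    # pectinate (A,(B,(C,(D,E)))) with 0,0,1,1,1: one origin of state 1
    tree = Phylogeny.from_nested(("A", ("B", ("C", ("D", "E")))))
    asr = fitch_asr(tree, {"A": "0", "B": "0", "C": "1", "D": "1", "E": "1"})
    assert len(asr.state_origins("1")) == 1
    assert asr.state_origins("0") == []


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _random_matrix(rng, n_taxa, n_chars, n_states=2):
    taxa = [f"t{i}" for i in range(n_taxa)]
    cells = rng.integers(n_states, size=(n_taxa, n_chars)).astype("<U1")
    return CharacterMatrix(taxa, cells)


def test_exhaustive_counts_topologies_via_uninformative_matrix():
    # all 15 unrooted 5-taxon topologies tie on an uninformative matrix
    mat = CharacterMatrix(
        [f"t{i}" for i in range(5)], np.array([["0"], ["0"], ["0"], ["0"], ["1"]])
    )
    res = exhaustive_search(mat)
    assert res.best_length == 1
    assert len(res.trees) == 15


def test_exhaustive_recovers_generating_topology():
    # characters exactly mark the clades of ((A,B),(C,D),E)
    mat = CharacterMatrix(
        ["A", "B", "C", "D", "E"],
        np.array([list("10"), list("10"), list("01"), list("01"), list("00")]),
    )
    res = exhaustive_search(mat)
    assert res.best_length == 2
    truth = Phylogeny.from_nested((("A", "B"), ("C", "D"), "E"))
    assert len(res.trees) == 1
    assert res.trees[0].bipartitions() == truth.bipartitions()


def test_exhaustive_limits():
    with pytest.raises(InsufficientDataError):
        exhaustive_search(_random_matrix(np.random.default_rng(0), 10, 3))


def test_heuristic_matches_exhaustive_on_random_matrices():
    rng = np.random.default_rng(19)
    for i in range(10):
        mat = _random_matrix(rng, 7, 12, n_states=3)
        h = heuristic_search(mat, n_replicates=8, seed=i)
        e = exhaustive_search(mat)
        assert h.best_length == e.best_length


def test_heuristic_deterministic_given_seed():
    mat = _random_matrix(np.random.default_rng(20), 8, 10)
    a = heuristic_search(mat, n_replicates=5, seed=42)
    b = heuristic_search(mat, n_replicates=5, seed=42)
    assert a.best_length == b.best_length
    assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]


def test_heuristic_needs_four_taxa():
    with pytest.raises(InsufficientDataError):
        heuristic_search(_random_matrix(np.random.default_rng(0), 3, 4))


def test_search_scores_consistent_with_tree_score():
    rng = np.random.default_rng(21)
    mat = _random_matrix(rng, 7, 15, n_states=3)
    res = exhaustive_search(mat)
    for t in res.trees[:5]:
        assert tree_score(t, mat).length == res.best_length


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def test_strict_consensus_identical_trees():
    t = Phylogeny.from_nested(((("A", "B"), "C"), ("D", "E")))
    cons = strict_consensus([t, t.copy()])
    assert cons.bipartitions() == t.bipartitions()


def test_strict_consensus_conflicting_trees_collapse():
    t1 = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    t2 = Phylogeny.from_nested((("A", "C"), ("B", "D")))
    cons = strict_consensus([t1, t2])
    assert cons.bipartitions() == set()  # star tree


def test_strict_consensus_keeps_shared_clade():
    t1 = Phylogeny.from_nested(((("A", "B"), "C"), ("D", "E")))
    t2 = Phylogeny.from_nested(((("A", "B"), "D"), ("C", "E")))
    cons = strict_consensus([t1, t2])
    ab = frozenset([frozenset("AB"), frozenset("CDE")])
    assert cons.bipartitions() == {ab}


def test_strict_consensus_tip_set_mismatch():
    t1 = Phylogeny.from_nested((("A", "B"), "C"))
    t2 = Phylogeny.from_nested((("A", "B"), "D"))
    with pytest.raises(MappingError):
        strict_consensus([t1, t2])


def test_tree_from_splits_round_trip():
    t = Phylogeny.from_nested(((("A", "B"), ("C", "D")), ("E", "F")))
    rebuilt = tree_from_splits(sorted(t.taxa()), t.bipartitions())
    assert rebuilt.bipartitions() == t.bipartitions()


# ---------------------------------------------------------------------------
# Bremer support
# ---------------------------------------------------------------------------


def test_bremer_support_equals_character_redundancy():
    """A clade marked by j identical binary characters decays at exactly j."""
    taxa = ["A", "B", "C", "D", "E", "F"]
    # {A,B} supported by 3 characters, {A,B,C} by 1
    cols = ["110000"] * 3 + ["111000"]
    cells = np.array([[c[i] for c in cols] for i in range(6)])
    mat = CharacterMatrix(taxa, cells)
    search = heuristic_search(mat, n_replicates=10, seed=0)
    supports = {
        tuple(sorted(min(s.split, key=lambda side: (len(side), sorted(side))))): s
        for s in bremer_supports(mat, search, seed=0)
    }
    ab = supports[("A", "B")]
    abc = supports[("A", "B", "C")]
    assert ab.support == 3 and not ab.capped
    assert abc.support == 1 and not abc.capped


def test_bremer_capped_when_uncontradicted():
    taxa = ["A", "B", "C", "D", "E", "F"]
    cols = ["110000"] * 12  # support far above the default cap
    cells = np.array([[c[i] for c in cols] for i in range(6)])
    mat = CharacterMatrix(taxa, cells)
    search = heuristic_search(mat, n_replicates=5, seed=1)
    sup = bremer_supports(mat, search, max_subopt=5, seed=1)
    ab = [s for s in sup if frozenset("AB") in s.split][0]
    assert ab.capped and ab.support == 5
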