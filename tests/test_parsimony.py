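import itertools

import pandas as pd
import pytest

from cretrace.parsimony import (
    CharacterMatrix,
    LineagePartition,
    TreeError,
    default_lineage_partition,
    derive_network_character,
    dollo_losses,
    fitch_changes,
    gains_only_count,
    lineage_gains,
    load_packaged_matrix,
    load_packaged_tree,
    parse_newick,
    write_newick,
)

# ---------------------------------------------------------------------------
# Brute-force oracles on explicitly enumerated small trees.  A tree is a
# nested tuple of tip names; edges are enumerated to place events on.


def _subtree_tips(node):
    if isinstance(node, str):
        return [node]
    return [t for child in node for t in _subtree_tips(child)]


def _all_nodes(node):
    yield node
    if not isinstance(node, str):
        for child in node:
            yield from _all_nodes(child)


def brute_min_changes(topology, states):
    """Fitch oracle: minimise changes over all internal 0/1 labelings."""
    internals = [n for n in _all_nodes(topology) if not isinstance(n, str)]

    def cost(assignment):
        total = 0

        def node_state(n):
            if isinstance(n, str):
                return states[n]
            return assignment[id(n)]

        for n in internals:
            for child in n:
                if node_state(child) != assignment[id(n)]:
                    total += 1
        return total

    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assignment = {id(n): s for n, s in zip(internals, combo)}
        c = cost(assignment)
        best = c if best is None else min(best, c)
    return best


def brute_min_gains(topology, states):
    """Gains-only oracle: minimal set of subtrees covering all present tips
    and no absent tip."""
    nodes = list(_all_nodes(topology))
    present = {t for t, s in states.items() if s == 1}
    candidates = [
        n for n in nodes if all(states[t] == 1 for t in _subtree_tips(n))
    ]
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            covered = set()
            for n in combo:
                covered |= set(_subtree_tips(n))
            if covered == present:
                return r
    return 0


def brute_min_losses(topology, states, gain_subtree):
    """Dollo oracle: minimal loss-edge set under a single fixed gain."""
    nodes = [n for n in _all_nodes(gain_subtree)]
    present = {t for t in _subtree_tips(gain_subtree) if states[t] == 1}
    if {t for t, s in states.items() if s == 1} - set(_subtree_tips(gain_subtree)):
        raise ValueError("infeasible")
    for r in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            lost = set()
            for n in combo:
                lost |= set(_subtree_tips(n))
            states_ok = all(
                (t in present) == (t not in lost)
                for t in _subtree_tips(gain_subtree)
                if states[t] in (0, 1)
            )
            if states_ok:
                return r
    raise AssertionError("no loss placement found")


def _to_newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(_to_newick(c) for c in node) + ")"


SMALL_TREES = [
    ("A", "B"),
    (("A", "B"), ("C", "D")),
    (("A", ("B", "C")), ("D", "E")),
    ((("A", "B"), ("C", "D")), (("E", "F"), ("G", "H"))),
    (("A", "B", "C"), ("D", "E")),  # multifurcation
]


class TestNewick:
    def test_minimal_tree(self):
        t = parse_newick("(A,B);")
        assert set(t.tips) == {"A", "B"}

    def test_internal_labels_preserved_and_round_trip(self):
        t = parse_newick("((A,B)X,(C,D)Y)R;")
        assert t.node("X") is not None and t.node("Y") is not None
        assert write_newick(t).replace(" ", "") == "((A,B)X,(C,D)Y)R;"

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),(A,C));")

    def test_missing_semicolon_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("(A,B)")


class TestNetworkCharacter:
    def _matrix(self, rows):
        return CharacterMatrix(
            pd.DataFrame(rows, columns=["svPAX2", "dacDACH1", "invEN2"],
                         index=[f"sp{i}" for i in range(len(rows))])
        )

    def test_default_two_of_three(self):
        m = derive_network_character(
            self._matrix([["1", "1", "1"], ["0", "1", "1"], ["0", "0", "0"], ["1", "?", "?"]])
        )
        assert list(m.df["network"]) == ["1", "1", "0", "0"]

    def test_min_present_configurable(self):
        m = self._matrix([["1", "0", "0"]])
        assert derive_network_character(m, 1).df["network"].iloc[0] == "1"
        assert derive_network_character(m, 3).df["network"].iloc[0] == "0"
        with pytest.raises(ValueError):
            derive_network_character(m, 4)


class TestEventCounts:
    def test_dollo_examples(self):
        t = parse_newick("((A,B),(C,D))R;")
        assert dollo_losses(t, {"A": 1, "B": 1, "C": 1, "D": 1}, "R") == 0
        assert dollo_losses(t, {"A": 1, "B": 0, "C": 1, "D": 1}, "R") == 1

    def test_dollo_infeasible_gain_node_raises(self):
        t = parse_newick("((A,B)X,(C,D)Y)R;")
        with pytest.raises(TreeError):
            dollo_losses(t, {"A": 1, "B": 0, "C": 1, "D": 0}, "X")

    def test_gains_only_examples(self):
        t = parse_newick("((A,B),(C,D))R;")
        assert gains_only_count(t, {"A": 1, "B": 1, "C": 1, "D": 1}) == 1
        assert gains_only_count(t, {"A": 1, "B": 0, "C": 1, "D": 1}) == 2
        assert gains_only_count(t, {"A": 0, "B": 0, "C": 0, "D": 0}) == 0

    def test_fitch_examples(self):
        t = parse_newick("((A,B),(C,D))R;")
        assert fitch_changes(t, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0
        assert fitch_changes(t, {"A": 1, "B": 0, "C": 1, "D": 1}) == 1
        t2 = parse_newick("((A,C),(B,D))R;")
        assert fitch_changes(t2, {"A": 1, "B": 0, "C": 0, "D": 1}) == 2

    @pytest.mark.parametrize("topology", SMALL_TREES)
    def test_all_counts_match_brute_force(self, topology):
        tips = _subtree_tips(topology)
        tree = parse_newick(_to_newick(topology) + "R;")
        for bits in itertools.product((0, 1), repeat=len(tips)):
            states = dict(zip(tips, bits))
            assert fitch_changes(tree, states) == brute_min_changes(topology, states)
            assert gains_only_count(tree, states) == brute_min_gains(topology, states)
            if any(bits):
                assert dollo_losses(tree, states, "R") == brute_min_losses(
                    topology, states, topology
                )

    @pytest.mark.parametrize("topology", SMALL_TREES[:4])
    def test_parsimony_inequalities(self, topology):
        tips = _subtree_tips(topology)
        tree = parse_newick(_to_newick(topology) + "R;")
        for bits in itertools.product((0, 1), repeat=len(tips)):
            if not any(bits):
                continue
            states = dict(zip(tips, bits))
            fitch = fitch_changes(tree, states)
            assert fitch <= gains_only_count(tree, states)
            present = [t for t, s in states.items() if s == 1]
            mrca = tree.mrca(present)
            assert fitch <= 1 + dollo_losses(tree, states, mrca)

    def test_dollo_at_mrca_is_minimal_over_feasible_gains(self):
        tree = parse_newick("(((A,B)X,(C,D)Y)Z,(E,F)W)R;")
        states = {"A": 1, "B": 1, "C": 0, "D": 1, "E": 0, "F": 0}
        mrca = tree.mrca(["A", "B", "D"])
        at_mrca = dollo_losses(tree, states, mrca)
        for gain in ("Z", "R"):
            assert dollo_losses(tree, states, gain) >= at_mrca

    def test_counts_invariant_under_child_order(self):
        states = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 1}
        t1 = parse_newick("((A,B)X,((C,D)Y,E)Z)R;")
        t2 = parse_newick("((E,(D,C)Y)Z,(B,A)X)R;")
        for fn in (fitch_changes, gains_only_count):
            assert fn(t1, states) == fn(t2, states)
        assert dollo_losses(t1, states, "R") == dollo_losses(t2, states, "R")

    def test_missing_states_constrain_nothing(self):
        t = parse_newick("((A,B),(C,D))R;")
        full = {"A": 1, "B": 1, "C": 1, "D": 1}
        partial = {"A": 1, "B": 1, "C": 1}  # D unknown
        assert dollo_losses(t, partial, "R") == dollo_losses(t, full, "R") == 0
        assert fitch_changes(t, partial) == 0


class TestStudyFixture:
    def test_single_origin_at_pda_implies_two_losses(self):
        tree = load_packaged_tree()
        matrix = derive_network_character(load_packaged_matrix())
        states = matrix.states("network")
        assert dollo_losses(tree, states, "PDA") == 2

    def test_convergence_implies_six_lineage_gains(self):
        tree = load_packaged_tree()
        matrix = derive_network_character(load_packaged_matrix())
        states = matrix.states("network")
        assert lineage_gains(tree, states, default_lineage_partition()) >= 6

    def test_losses_are_hemichordate_and_priapulid(self):
        tree = load_packaged_tree()
        matrix = derive_network_character(load_packaged_matrix())
        states = matrix.states("network")
        absent_eubilaterians = [
            sp for sp, s in states.items()
            if s == 0 and sp in {t for t in tree.tip_labels(tree.node("PDA"))}
        ]
        assert sorted(absent_eubilaterians) == ["P_caudatus", "S_kowalevskii"]

    def test_lineage_partition_tips_on_tree(self):
        default_lineage_partition().validate_on(load_packaged_tree())

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError):
            LineagePartition.from_dict({"a": ["X", "Y"], "b": ["Y"]})
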