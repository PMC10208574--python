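"""Gain/loss counting of binary presence/absence characters on a rooted tree.

Encodes the species x CRE presence/absence matrix on a rooted species tree
and counts the evolutionary events implied by competing scenarios:

* ``dollo_losses`` — a single gain on a specified ancestral branch
  (typically the last common ancestor of Protostomia and Deuterostomia,
  PDA) and the minimal number of subsequent losses;
* ``gains_only_count`` — Camin-Sokal style counting with no reversals, the
  minimal number of independent gains;
* ``fitch_changes`` — the unordered-parsimony change count, as a baseline;
* ``lineage_gains`` — gains required under the convergent-origins reading,
  one per named lineage that contains at least one presence.

``?`` states (genome not accessible, or no gene homolog) are treated as
missing data and constrain nothing.

Newick parsing and writing are delegated to dendropy; internal node labels
(clade names such as PDA and LCBA) are preserved.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "PhyloTree",
    "CharacterMatrix",
    "LineagePartition",
    "EventCount",
    "TreeError",
    "parse_newick",
    "write_newick",
    "derive_network_character",
    "dollo_losses",
    "gains_only_count",
    "fitch_changes",
    "lineage_gains",
    "load_packaged_tree",
    "load_packaged_matrix",
    "default_lineage_partition",
]

CHARACTERS = ("svPAX2", "dacDACH1", "invEN2")
MISSING = "?"


class TreeError(ValueError):
    """Malformed Newick, unknown node label, or an infeasible scenario."""


class PhyloTree:
    """A rooted tree with unique tip labels and named internal clades."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels {dupes}")
        self.tips = tuple(tips)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def node(self, label: str) -> dendropy.Node:
        """Find a node by tip or internal label."""
        for nd in self._tree.preorder_node_iter():
            if (nd.taxon and nd.taxon.label == label) or nd.label == label:
                return nd
        raise TreeError(f"no node labelled {label!r}")

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of the named nodes."""
        nodes = [self.node(l) for l in labels]
        if not nodes:
            raise TreeError("mrca of an empty label set")
        ancestor_sets = []
        for nd in nodes:
            anc, cur = [], nd
            while cur is not None:
                anc.append(id(cur))
                cur = cur.parent_node
            ancestor_sets.append(anc)
        common = set(ancestor_sets[0]).intersection(*map(set, ancestor_sets[1:]))
        for node_id in ancestor_sets[0]:  # deepest-first along the first path
            if node_id in common:
                cur = nodes[0]
                while id(cur) != node_id:
                    cur = cur.parent_node
                return cur
        raise TreeError("nodes share no common ancestor")  # pragma: no cover

    @staticmethod
    def tip_labels(node: dendropy.Node) -> list[str]:
        return [leaf.taxon.label for leaf in node.leaf_iter()]


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string, preserving internal node labels."""
    if not text.strip().endswith(";"):
        raise TreeError("Newick must end with a semicolon")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    tree.suppress_unifurcations()
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    out = tree._tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    return out


@dataclass
class CharacterMatrix:
    """Species x character states, each in {"0", "1", "?"}."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.astype(str)
        bad = set(self.df.values.ravel()) - {"0", "1", MISSING}
        if bad:
            raise ValueError(f"illegal states {sorted(bad)}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    def states(self, character: str) -> dict[str, int]:
        """Tip -> 0/1 map for one character; ``?`` entries are dropped."""
        col = self.df[character]
        return {sp: int(v) for sp, v in col.items() if v != MISSING}

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="species", dtype=str))


def derive_network_character(
    matrix: CharacterMatrix, min_present: int = 2
) -> CharacterMatrix:
    """Add the aggregate ``network`` character: >= ``min_present`` CREs present.

    ``?`` states count as not-present for this aggregation (a network call
    is only made from positive evidence).
    """
    if not 1 <= min_present <= 3:
        raise ValueError("min_present must lie in 1..3")
    df = matrix.df.copy()
    present = (df[list(CHARACTERS)] == "1").sum(axis=1)
    df["network"] = (present >= min_present).astype(int).astype(str)
    return CharacterMatrix(df)


def _has_present(node, states: Mapping[str, int]) -> bool:
    return any(states.get(t) == 1 for t in PhyloTree.tip_labels(node))


def _has_absent(node, states: Mapping[str, int]) -> bool:
    return any(states.get(t) == 0 for t in PhyloTree.tip_labels(node))


def dollo_losses(
    tree: PhyloTree, states: Mapping[str, int], gain_node: str | dendropy.Node
) -> int:
    """Minimal losses given a single gain on the branch to ``gain_node``.

    Counts the maximal subtrees below the gain node that contain at least
    one absent tip and no present tip; one loss on the stem of each such
    subtree suffices and is necessary.  Missing tips constrain nothing.
    ``gain_node`` may be a label or a node of the tree.
    """
    gain = gain_node if isinstance(gain_node, dendropy.Node) else tree.node(gain_node)
    clade_tips = set(PhyloTree.tip_labels(gain))
    outside_present = [
        t for t, s in states.items() if s == 1 and t not in clade_tips
    ]
    if outside_present:
        raise TreeError(
            f"present tips outside the gain clade: {sorted(outside_present)}; "
            "a single gain at this node cannot explain them"
        )
    losses = 0
    stack = [gain]
    while stack:
        nd = stack.pop()
        if _has_present(nd, states):
            stack.extend(nd.child_nodes())
        elif _has_absent(nd, states):
            losses += 1
        # subtrees with only missing tips: no event required
    return losses


def gains_only_count(tree: PhyloTree, states: Mapping[str, int]) -> int:
    """Minimal independent gains with reversals forbidden (Camin-Sokal).

    A gain branch may be placed wherever its subtree contains no absent
    tip; the count is the number of maximal such subtrees that contain at
    least one present tip.
    """
    count = 0
    stack = [(tree.root, False)]
    while stack:
        nd, ancestor_pure = stack.pop()
        pure = not _has_absent(nd, states)
        if pure:
            if not ancestor_pure and _has_present(nd, states):
                count += 1
            continue
        for child in nd.child_nodes():
            stack.append((child, False))
    return count


def fitch_changes(tree: PhyloTree, states: Mapping[str, int]) -> int:
    """Minimal state changes under unordered (Fitch) parsimony.

    Missing tips carry the full state set {0, 1} and never force a change.
    """
    changes = 0

    def down(nd) -> frozenset:
        nonlocal changes
        if nd.is_leaf():
            s = states.get(nd.taxon.label)
            return frozenset({0, 1}) if s is None else frozenset({s})
        child_sets = [down(c) for c in nd.child_nodes()]
        inter = frozenset.intersection(*child_sets)
        if inter:
            return inter
        # binary-character Fitch on a multifurcation: count the minimal
        # number of children disagreeing with the majority state
        union = frozenset.union(*child_sets)
        votes = {s: sum(1 for cs in child_sets if cs == frozenset({s})) for s in (0, 1)}
        changes += min(votes[0], votes[1])
        if votes[0] == votes[1]:
            return union
        return frozenset({0 if votes[0] > votes[1] else 1})

    down(tree.root)
    return changes


@dataclass(frozen=True)
class LineagePartition:
    """Named clades -> disjoint tip sets (the convergent-origin lineages)."""

    clades: tuple[tuple[str, frozenset], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "LineagePartition":
        items = tuple((name, frozenset(tips)) for name, tips in d.items())
        seen: set[str] = set()
        for name, tips in items:
            if seen & tips:
                raise ValueError(f"lineage {name!r} overlaps another lineage")
            seen |= tips
        return cls(items)

    def validate_on(self, tree: PhyloTree) -> None:
        tipset = set(tree.tips)
        for name, tips in self.clades:
            missing = tips - tipset
            if missing:
                raise TreeError(f"lineage {name!r}: tips not on tree {sorted(missing)}")


def lineage_gains(
    tree: PhyloTree, states: Mapping[str, int], partition: LineagePartition
) -> int:
    """Independent gains implied by convergence: one per lineage with a presence."""
    partition.validate_on(tree)
    return sum(
        1
        for _name, tips in partition.clades
        if any(states.get(t) == 1 for t in tips)
    )


@dataclass(frozen=True)
class EventCount:
    scenario: str
    gains: int
    losses: int

    def __post_init__(self) -> None:
        if self.gains < 0 or self.losses < 0:
            raise ValueError("counts must be >= 0")


# ---------------------------------------------------------------------------
# Packaged study fixture: the metazoan species tree used for the published
# presence/absence matrix, with the PDA and LCBA ancestors labelled, and the
# matrix states themselves.

def _data_text(name: str) -> str:
    return (
        importlib.resources.files("cretrace").joinpath("data", name).read_text()
    )


def load_packaged_tree() -> PhyloTree:
    """The metazoan species tree with PDA/LCBA internal labels."""
    return parse_newick(_data_text("metazoa_tree.nwk"))


def load_packaged_matrix() -> CharacterMatrix:
    """Published per-species CRE presence/absence states (0/1/?)."""
    return CharacterMatrix.from_tsv(
        StringIO(_data_text("metazoa_cre_matrix.tsv"))
    )


def default_lineage_partition() -> LineagePartition:
    """The six lineages of the convergent-origins scenario."""
    return LineagePartition.from_dict(
        {
            "chordates": ["B_lanceolatum", "C_intestinalis", "M_musculus", "H_sapiens"],
            "brachiopods": ["L_anatina"],
            "annelids": ["C_teleta"],
            "molluscs": ["O_bimaculoides"],
            "panarthropods": ["H_exemplaris", "D_melanogaster"],
            "nematodes": ["C_elegans"],
        }
    )
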