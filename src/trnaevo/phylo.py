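"""Presence/absence histories of tRNA types on a species tree.

Given a rooted species tree and the repertoire matrix, each anticodon type's
0/1 presence pattern is summarised three ways:

* small-parsimony change counts (:func:`fitch_min_changes`, exact also on
  polytomies via unit-cost dynamic programming);
* a Dollo reconstruction (:func:`dollo_events`): at most one gain, placed on
  the edge above the MRCA of the present tips, plus the minimal set of
  losses (maximal all-absent subtrees within the gain clade);
* a deterministic history category (:func:`classify_type_history`):
  ancestral absence, recent gain, clade-specific loss, sparse loss, or
  ubiquitous presence.

The category rules formalise the phylogenetic reasoning used to argue that
A-starting anticodons were never present in the archaeal common ancestor
while C-starting anticodons were lost convergently in specific clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

_INF = float("inf")


@dataclass(frozen=True)
class HistoryParams:
    """Thresholds for :func:`classify_type_history`.

    ``gain_max``: a type present in at most this many tips is a recent gain
    (reported gains in Archaea were seen in 1-2 genomes).  ``background_frac``:
    minimum presence fraction outside a clade for its total absence inside to
    count as clade-specific loss.
    """

    gain_max: int = 2
    background_frac: float = 0.75


@dataclass(frozen=True)
class Category:
    """History classification of one tRNA type."""

    name: str  # ancestral_absence | recent_gain | clade_specific_loss | sparse_loss | ubiquitous
    clades: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.clades:
            return f"{self.name}({','.join(self.clades)})"
        return self.name


@dataclass
class Event:
    """One gain or loss on a branch (the edge above ``branch_id``'s node)."""

    trna_type: str
    event: str  # "gain" | "loss"
    branch_id: str
    note: str = ""
    node: object = field(default=None, repr=False, compare=False)


def load_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    s = str(source)
    if "(" in s and ";" in s:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(
            path=s, schema="newick", preserve_underscores=True
        )
    tree.is_rooted = True
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("tree tip labels are not unique")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _leaf_sets(tree: dendropy.Tree) -> dict:
    """Map each node to the frozenset of its descendant tip labels."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = s
    return out


def branch_id(node, leaf_sets=None) -> str:
    """Stable human-readable id for the edge above ``node``.

    Internal nodes without a label are identified by first/last tip and tip
    count, which is unique within a tree (nested clades differ in size,
    disjoint clades in their first tip).
    """
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    tips = sorted(leaf_sets[node]) if leaf_sets else sorted(
        l.taxon.label for l in node.leaf_iter()
    )
    return f"mrca({tips[0]},{tips[-1]},{len(tips)})"


def resolve_clades(
    tree: dendropy.Tree, clades: Mapping[str, Sequence[str] | str]
) -> dict[str, frozenset[str]]:
    """Resolve clade definitions to tip sets and check monophyly.

    A clade may be given as a list of tip labels or as the label of an
    internal node.  Every clade must be monophyletic in the tree.
    """
    leaf_sets = _leaf_sets(tree)
    by_label = {node.label: node for node in tree.preorder_internal_node_iter() if node.label}
    tips_all = set(tip_labels(tree))
    out = {}
    for label, spec in clades.items():
        if isinstance(spec, str):
            if spec not in by_label:
                raise ValueError(f"clade {label!r}: no internal node named {spec!r}")
            tipset = leaf_sets[by_label[spec]]
        else:
            tipset = frozenset(spec)
            missing = tipset - tips_all
            if missing:
                raise ValueError(f"clade {label!r}: unknown tips {sorted(missing)}")
            mrca = tree.mrca(taxon_labels=sorted(tipset))
            if leaf_sets[mrca] != tipset:
                raise ValueError(
                    f"clade {label!r} is not monophyletic: MRCA spans "
                    f"{sorted(leaf_sets[mrca] - tipset)} extra tip(s)"
                )
        out[label] = tipset
    return out


def read_clades(path, tree: dendropy.Tree) -> dict[str, frozenset[str]]:
    """Clade definitions YAML: ``label: [tip, ...]`` or ``label: node_name``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return resolve_clades(tree, doc or {})


def _check_presence(tree: dendropy.Tree, presence: Mapping[str, int]) -> None:
    missing = set(tip_labels(tree)) - set(presence)
    if missing:
        raise ValueError(f"presence map missing tip(s): {sorted(missing)}")


def fitch_min_changes(
    tree: dendropy.Tree, presence: Mapping[str, int]
) -> tuple[int, dict[str, int]]:
    """Minimum number of 0/1 state changes explaining the tip states.

    Unit-cost small parsimony solved by dynamic programming over node state
    costs, which stays exact on polytomies.  Returns the minimum change
    count and one optimal ancestral labeling (branch id -> state); ties are
    broken toward the parent's state, and toward absence at the root.
    """
    _check_presence(tree, presence)
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = 1 if presence[node.taxon.label] >= 1 else 0
            cost[node] = (0 if s == 0 else _INF, 0 if s == 1 else _INF)
        else:
            c0 = c1 = 0.0
            for ch in node.child_nodes():
                c0 += min(cost[ch][0], cost[ch][1] + 1)
                c1 += min(cost[ch][1], cost[ch][0] + 1)
            cost[node] = (c0, c1)
    root = tree.seed_node
    total = min(cost[root])
    leaf_sets = _leaf_sets(tree)
    labeling: dict[str, int] = {}
    state: dict = {root: 0 if cost[root][0] <= cost[root][1] else 1}
    for node in tree.preorder_node_iter():
        if node is not root:
            ps = state[node.parent_node]
            keep = cost[node][ps]
            flip = cost[node][1 - ps] + 1
            state[node] = ps if keep <= flip else 1 - ps
        labeling[branch_id(node, leaf_sets)] = state[node]
    return int(total), labeling


def dollo_events(
    tree: dendropy.Tree, presence: Mapping[str, int], trna_type: str = ""
) -> list[Event]:
    """Dollo reconstruction: one gain, minimal losses, for one type.

    If no tip carries the type the history is empty (absent at the root, a
    type that never evolved).  Otherwise the single gain sits on the edge
    above the MRCA of the present tips and each maximal all-absent subtree
    inside the gain clade receives one loss.
    """
    _check_presence(tree, presence)
    present = sorted(t for t, v in presence.items() if v >= 1)
    if not present:
        return []
    leaf_sets = _leaf_sets(tree)
    if len(present) == 1:
        gain_node = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == present[0]
        )
    else:
        gain_node = tree.mrca(taxon_labels=present)
    events = [
        Event(trna_type, "gain", branch_id(gain_node, leaf_sets), node=gain_node)
    ]

    def absent(node) -> bool:
        return all(presence[t] == 0 for t in leaf_sets[node])

    stack = list(gain_node.child_nodes())
    while stack:
        node = stack.pop()
        if absent(node):
            events.append(
                Event(trna_type, "loss", branch_id(node, leaf_sets), node=node)
            )
        else:
            stack.extend(node.child_nodes())
    return events


def replay_events(
    tree: dendropy.Tree, events: Iterable[Event], root_present: bool = False
) -> dict[str, int]:
    """Replay gain/loss events from the root down; returns tip 0/1 states.

    Events must reference nodes of ``tree`` (as produced by
    :func:`dollo_events` or the synthetic generator's truth log).
    """
    by_node: dict = {}
    for ev in events:
        by_node.setdefault(ev.node, []).append(ev.event)
    state: dict = {}
    tips: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        s = (
            (1 if root_present else 0)
            if node.parent_node is None
            else state[node.parent_node]
        )
        for kind in by_node.get(node, []):
            s = 1 if kind == "gain" else 0
        state[node] = s
        if node.is_leaf():
            tips[node.taxon.label] = s
    return tips


def classify_type_history(
    tree: dendropy.Tree,
    presence: Mapping[str, int],
    named_clades: Mapping[str, frozenset[str]] | None = None,
    params: HistoryParams = HistoryParams(),
) -> Category:
    """Deterministic history category for one type's presence pattern.

    Rule priority: (1) present in no tip -> ancestral_absence; (2) present
    in at most ``gain_max`` tips -> recent_gain; (3) no absences ->
    ubiquitous; (4) absent from every member of one or more named clades
    while present in at least ``background_frac`` of the remaining genomes
    -> clade_specific_loss(those clades); (5) otherwise sparse_loss.
    """
    _check_presence(tree, presence)
    tips = set(tip_labels(tree))
    n_present = sum(1 for t in tips if presence[t] >= 1)
    if n_present == 0:
        return Category("ancestral_absence")
    if n_present <= params.gain_max:
        return Category("recent_gain")
    if n_present == len(tips):
        return Category("ubiquitous")
    lost = []
    for label, ctips in (named_clades or {}).items():
        if any(presence[t] >= 1 for t in ctips):
            continue
        outside = tips - ctips
        if not outside:
            continue
        frac = sum(1 for t in outside if presence[t] >= 1) / len(outside)
        if frac >= params.background_frac:
            lost.append(label)
    if lost:
        return Category("clade_specific_loss", tuple(sorted(lost)))
    return Category("sparse_loss")


def map_matrix_events(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    named_clades: Mapping[str, frozenset[str]] | None = None,
    params: HistoryParams = HistoryParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify and Dollo-reconstruct every column of a repertoire matrix.

    Returns ``(events, categories)`` DataFrames.  The matrix index must
    match the tree tips exactly.
    """
    tips = set(tip_labels(tree))
    genomes = set(matrix.index)
    if tips != genomes:
        raise ValueError(
            "tree/matrix mismatch: "
            f"only in tree {sorted(tips - genomes)}, only in matrix {sorted(genomes - tips)}"
        )
    ev_rows = []
    cat_rows = []
    for col in sorted(matrix.columns):
        presence = {g: int(matrix.loc[g, col]) for g in matrix.index}
        cat = classify_type_history(tree, presence, named_clades, params)
        n_present = sum(1 for v in presence.values() if v >= 1)
        cat_rows.append(
            {
                "trna_type": col,
                "category": cat.name,
                "clades": ",".join(cat.clades),
                "n_present": n_present,
            }
        )
        if cat.name == "ubiquitous":
            continue  # no absences: nothing to reconstruct
        for ev in dollo_events(tree, presence, col):
            ev_rows.append(
                {
                    "trna_type": ev.trna_type,
                    "event": ev.event,
                    "branch_id": ev.branch_id,
                    "note": ev.note,
                }
            )
    events = pd.DataFrame(ev_rows, columns=["trna_type", "event", "branch_id", "note"])
    categories = pd.DataFrame(
        cat_rows, columns=["trna_type", "category", "clades", "n_present"]
    ).set_index("trna_type")
    return events, categories


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def write_categories(categories: pd.DataFrame, path) -> None:
    categories.to_csv(path, sep="\t", index_label="trna_type")
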