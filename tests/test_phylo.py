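"""Parsimony reconstruction and history classification on species trees."""

import itertools

import pandas as pd
import pytest

from trnaevo.phylo import (
    Category,
    HistoryParams,
    classify_type_history,
    dollo_events,
    fitch_min_changes,
    load_tree,
    map_matrix_events,
    replay_events,
    resolve_clades,
)

BALANCED4 = "((A,B),(C,D));"


def brute_force_min_changes(tree, presence):
    """Exhaustive minimum over all internal 0/1 labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for states in itertools.product([0, 1], repeat=len(internals)):
        lab = dict(zip(internals, states))
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = lab[node] if node in lab else presence[node.taxon.label]
            ps = lab[node.parent_node]
            changes += int((1 if s >= 1 else 0) != ps)
        best = changes if best is None else min(best, changes)
    return best


def random_tree(rng, n_tips):
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [
            f"({nodes[i]},{nodes[j]})"
        ]
    return load_tree(nodes[0] + ";"), labels


class TestFitch:
    def test_one_change_for_clean_split(self):
        tree = load_tree(BALANCED4)
        n, _ = fitch_min_changes(tree, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert n == 1

    def test_all_present_needs_no_change(self):
        tree = load_tree(BALANCED4)
        assert fitch_min_changes(tree, {t: 1 for t in "ABCD"})[0] == 0

    def test_alternating_pattern_needs_two(self):
        tree = load_tree(BALANCED4)
        assert fitch_min_changes(tree, {"A": 0, "B": 1, "C": 0, "D": 1})[0] == 2

    def test_missing_tip_rejected(self):
        tree = load_tree(BALANCED4)
        with pytest.raises(ValueError, match="missing tip"):
            fitch_min_changes(tree, {"A": 0, "B": 0, "C": 1})

    def test_matches_exhaustive_oracle_on_random_trees(self, rng):
        for _ in range(200):
            n_tips = int(rng.integers(2, 7))
            tree, labels = random_tree(rng, n_tips)
            presence = {t: int(rng.integers(0, 2)) for t in labels}
            got, labeling = fitch_min_changes(tree, presence)
            assert got == brute_force_min_changes(tree, presence)
            # returned labeling must realize exactly that many changes
            changes = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                from trnaevo.phylo import branch_id, _leaf_sets

                ls = _leaf_sets(tree)
                changes += int(
                    labeling[branch_id(node, ls)] != labeling[branch_id(node.parent_node, ls)]
                )
            assert changes == got

    def test_polytomy_handled_exactly(self, rng):
        tree = load_tree("(A,B,C,(D,E));")
        presence = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 0}
        assert fitch_min_changes(tree, presence)[0] == brute_force_min_changes(
            tree, presence
        )


class TestDollo:
    def test_all_absent_gives_empty_history(self):
        tree = load_tree(BALANCED4)
        assert dollo_events(tree, {t: 0 for t in "ABCD"}) == []

    def test_gain_above_mrca_of_present_clade(self):
        tree = load_tree(BALANCED4)
        events = dollo_events(tree, {"A": 0, "B": 0, "C": 1, "D": 1}, "x")
        assert len(events) == 1
        assert events[0].event == "gain"
        assert events[0].branch_id == "mrca(C,D,2)"

    def test_single_loss_for_absent_cherry(self):
        # all present except the (A,B) clade: gain at root, one loss above it
        tree = load_tree("(((A,B),C),(D,E));")
        events = dollo_events(tree, {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1})
        kinds = sorted(e.event for e in events)
        assert kinds == ["gain", "loss"]
        gain = next(e for e in events if e.event == "gain")
        loss = next(e for e in events if e.event == "loss")
        assert gain.branch_id == "mrca(A,E,5)"  # the root
        assert loss.branch_id == "mrca(A,B,2)"

    def test_single_present_tip(self):
        tree = load_tree(BALANCED4)
        events = dollo_events(tree, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert [e.event for e in events] == ["gain"]
        assert events[0].branch_id == "A"

    def test_replay_reproduces_tip_states(self, rng):
        for _ in range(50):
            tree, labels = random_tree(rng, int(rng.integers(2, 8)))
            presence = {t: int(rng.integers(0, 2)) for t in labels}
            events = dollo_events(tree, presence)
            tips = replay_events(tree, events, root_present=False)
            assert tips == {t: (1 if presence[t] else 0) for t in labels}

    def test_loss_count_at_least_fitch_minus_one(self, rng):
        for _ in range(50):
            tree, labels = random_tree(rng, int(rng.integers(2, 8)))
            presence = {t: int(rng.integers(0, 2)) for t in labels}
            events = dollo_events(tree, presence)
            fitch, _ = fitch_min_changes(tree, presence)
            assert len(events) >= fitch - 1


class TestClassification:
    tree6 = "(((A,B)cladeX,(C,D)),(E,F));"

    def test_absent_everywhere_is_ancestral_absence(self):
        tree = load_tree(self.tree6)
        cat = classify_type_history(tree, {t: 0 for t in "ABCDEF"})
        assert cat == Category("ancestral_absence")

    def test_one_or_two_tips_is_recent_gain(self):
        tree = load_tree(self.tree6)
        p = {t: 0 for t in "ABCDEF"}
        p["A"] = 1
        assert classify_type_history(tree, p).name == "recent_gain"
        p["E"] = 1
        assert classify_type_history(tree, p).name == "recent_gain"

    def test_clade_specific_loss_requires_background_presence(self):
        tree = load_tree(self.tree6)
        clades = resolve_clades(tree, {"X": ["A", "B"]})
        p = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 1}
        cat = classify_type_history(tree, p, clades)
        assert cat == Category("clade_specific_loss", ("X",))
        # background presence below threshold -> sparse loss
        p2 = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0, "F": 1}
        strict = HistoryParams(background_frac=0.9)
        assert classify_type_history(tree, p2, clades, strict).name == "sparse_loss"

    def test_no_absence_is_ubiquitous(self):
        tree = load_tree(self.tree6)
        assert classify_type_history(tree, {t: 1 for t in "ABCDEF"}).name == "ubiquitous"

    def test_invariant_to_tip_order_permutation(self, rng):
        tree = load_tree(self.tree6)
        clades = resolve_clades(tree, {"X": ["A", "B"]})
        p = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 0}
        items = list(p.items())
        for _ in range(5):
            rng.shuffle(items)
            assert classify_type_history(tree, dict(items), clades) == \
                classify_type_history(tree, p, clades)


class TestCladeValidation:
    def test_non_monophyletic_clade_rejected(self):
        tree = load_tree(self.__class__.tree6) if hasattr(self, "tree6") else load_tree(TestClassification.tree6)
        with pytest.raises(ValueError, match="not monophyletic"):
            resolve_clades(tree, {"bad": ["A", "C"]})

    def test_internal_node_name_resolves(self):
        tree = load_tree(TestClassification.tree6)
        clades = resolve_clades(tree, {"X": "cladeX"})
        assert clades["X"] == frozenset({"A", "B"})


class TestMapMatrixEvents:
    def test_all_ones_matrix_all_ubiquitous_no_events(self):
        tree = load_tree(TestClassification.tree6)
        mat = pd.DataFrame(1, index=list("ABCDEF"), columns=["Leu-GAG", "Met-CAU"])
        events, cats = map_matrix_events(tree, mat)
        assert len(events) == 0
        assert (cats["category"] == "ubiquitous").all()

    def test_identical_columns_get_identical_categories(self):
        tree = load_tree(TestClassification.tree6)
        col = [1, 1, 0, 1, 1, 0]
        mat = pd.DataFrame({"Leu-GAG": col, "Met-CAU": col}, index=list("ABCDEF"))
        _, cats = map_matrix_events(tree, mat)
        assert cats.loc["Leu-GAG", "category"] == cats.loc["Met-CAU", "category"]

    def test_genome_mismatch_reported(self):
        tree = load_tree(TestClassification.tree6)
        mat = pd.DataFrame(1, index=list("ABCDE"), columns=["Leu-GAG"])
        with pytest.raises(ValueError, match="only in tree"):
            map_matrix_events(tree, mat)
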