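"""CHAID tree: chi-square engine, merging, growth, prediction, evaluation."""

import numpy as np
import pandas as pd
import pytest

from htarisk import datasets
from htarisk.chaid import (
    ChaidNode,
    ChaidParams,
    ConfusionMatrix,
    ContingencyTable,
    build_tree,
    chi_square,
    evaluate,
    merge_categories,
    node_report,
)


def hand_chi_square(counts):
    """Independent textbook oracle: sum over cells of (O-E)^2/E."""
    counts = np.asarray(counts, dtype=float)
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    total = counts.sum()
    expected = np.outer(rows, cols) / total
    return float(((counts - expected) ** 2 / expected).sum())


class TestChiSquare:
    def test_perfect_independence(self):
        stat, dof, p = chi_square(np.array([[10, 10], [10, 10]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_arithmetic(self):
        stat, dof, _ = chi_square(np.array([[20, 0], [0, 20]]))
        assert stat == pytest.approx(40.0)
        assert dof == 1

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            table = rng.integers(1, 40, size=(3, 4))
            stat, dof, _ = chi_square(table)
            assert stat == pytest.approx(hand_chi_square(table), abs=1e-10)
            assert dof == 6

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square(np.array([[3, 4]]))
        with pytest.raises(ValueError, match="degenerate"):
            chi_square(np.array([[3, 0], [4, 0]]))


class TestMergeCategories:
    def test_binary_predictor_with_signal_unchanged(self):
        pred = ["a"] * 40 + ["b"] * 40
        target = ["II"] * 38 + ["V"] * 2 + ["V"] * 38 + ["II"] * 2
        assert sorted(merge_categories(pred, target)) == [("a",), ("b",)]

    def test_identical_distributions_merge(self):
        # categories a and b share a target distribution; c differs strongly
        pred = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        target = (["II"] * 28 + ["III"] * 2) + (["II"] * 27 + ["III"] * 3) + (["III"] * 28 + ["II"] * 2)
        groups = merge_categories(pred, target)
        assert ("a", "b") in groups or ("b", "a") in groups
        assert len(groups) == 2

    def test_no_signal_merges_to_one_group(self):
        pred = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        target = ["II", "III"] * 30
        assert len(merge_categories(pred, target)) == 1

    def test_ordinal_merges_only_adjacent(self):
        # periods 1 and 3 share a distribution but cannot merge across 2
        pred = [1] * 30 + [2] * 30 + [3] * 30
        target = (["II"] * 28 + ["III"] * 2) + (["III"] * 28 + ["II"] * 2) + (["II"] * 28 + ["III"] * 2)
        groups = merge_categories(pred, target, ordinal=True)
        assert (1, 3) not in groups


def planted_frame(n=400, seed=0, strength=1.0):
    """Cases where cause 3 forces Level IV with probability `strength`."""
    rng = np.random.default_rng(seed)
    cause = rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.15, 0.2, 0.5])
    road = rng.choice([1, 2, 3], size=n, p=[0.8, 0.1, 0.1])
    level = np.where(
        (cause == 3) & (rng.random(n) < strength),
        "IV",
        rng.choice(["II", "III"], size=n, p=[0.8, 0.2]),
    )
    return pd.DataFrame({"cause_factor": cause, "road_level": road, "severity_level": level})


class TestBuildTree:
    def test_perfectly_predictive_cause_at_root(self):
        frame = planted_frame(strength=1.0)
        tree = build_tree(frame, predictors=("cause_factor", "road_level"))
        assert tree.root.split_var == "cause_factor"
        pure_child = next(c for grp, c in zip(tree.root.groups, tree.root.children) if 3 in grp)
        assert pure_child.class_counts["IV"] == pure_child.size

    def test_root_distribution_equals_input_distribution(self):
        counts = {"II": 408, "III": 104, "IV": 32, "V": 25}
        frame = pd.DataFrame(
            {
                "severity_level": [lvl for lvl, n in counts.items() for _ in range(n)],
                "road_level": [1] * 569,
            }
        )
        tree = build_tree(frame, predictors=("road_level",))
        assert tree.root.class_counts == counts
        assert tree.root.size == 569

    def test_children_sum_to_parent_everywhere(self):
        tree = build_tree(planted_frame(strength=0.9), predictors=("cause_factor", "road_level"))

        def check(node):
            if node.children:
                assert sum(c.size for c in node.children) == node.size
                for c in node.children:
                    check(c)

        check(tree.root)

    def test_deterministic(self):
        frame = planted_frame(strength=0.9, seed=4)
        t1 = build_tree(frame, predictors=("cause_factor", "road_level"))
        t2 = build_tree(frame, predictors=("cause_factor", "road_level"))
        assert t1.to_json() == t2.to_json()

    def test_pruning_monotone_in_min_child_and_alpha(self):
        frame = planted_frame(n=600, strength=0.7, seed=2)
        preds = ("cause_factor", "road_level")
        base = build_tree(frame, predictors=preds, params=ChaidParams()).n_nodes()
        stricter_child = build_tree(frame, predictors=preds, params=ChaidParams(min_parent=80, min_child=80)).n_nodes()
        stricter_alpha = build_tree(
            frame, predictors=preds, params=ChaidParams(alpha_split=1e-6)
        ).n_nodes()
        assert stricter_child <= base
        assert stricter_alpha <= base

    def test_empty_predictors_rejected(self):
        with pytest.raises(ValueError):
            build_tree(planted_frame(), predictors=("not_a_column",))


class TestPredict:
    def test_routes_to_pure_leaf(self):
        frame = planted_frame(strength=1.0)
        tree = build_tree(frame, predictors=("cause_factor", "road_level"))
        assert tree.predict({"cause_factor": 3, "road_level": 1}) == "IV"

    def test_modal_class_with_severity_tie_break(self):
        node = ChaidNode(node_id=1, depth=0, class_counts={"II": 28, "III": 3, "IV": 1})
        assert node.modal_class() == "II"
        tied = ChaidNode(node_id=2, depth=0, class_counts={"II": 5, "IV": 5})
        assert tied.modal_class() == "IV"

    def test_root_only_tree_predicts_global_mode(self):
        frame = planted_frame(strength=0.0)
        tree = build_tree(frame, predictors=("road_level",))
        assert tree.predict({"road_level": 2}) == "II"

    def test_unseen_category_routes_to_largest_child(self):
        frame = planted_frame(strength=1.0)
        tree = build_tree(frame, predictors=("cause_factor", "road_level"))
        assert tree.predict({"cause_factor": 99, "road_level": 1}) in {"II", "III", "IV"}


class TestConfusionMatrix:
    def test_published_matrix_arithmetic(self):
        counts = datasets.confusion_counts_china()
        cm = ConfusionMatrix(counts)
        assert cm.overall_accuracy * 100 == pytest.approx(75.2, abs=0.05)
        rows = cm.row_percent()
        assert rows["II"] == pytest.approx(97.8, abs=0.05)
        assert rows["III"] == pytest.approx(8.7, abs=0.05)
        assert rows["IV"] == pytest.approx(0.0, abs=1e-12)
        assert rows["V"] == pytest.approx(80.0, abs=0.05)

    def test_self_prediction_is_diagonal(self):
        labels = ["II", "III", "II", "V", "IV", "II"]
        cm = evaluate(labels, labels)
        mat = cm.counts.to_numpy()
        assert np.trace(mat) == len(labels)
        assert mat.sum() == len(labels)
        assert cm.overall_accuracy == 1.0

    def test_label_outside_level_set(self):
        with pytest.raises(ValueError):
            evaluate(["II", "VI"], ["II", "II"], labels=["II", "III"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(["II"], ["II", "III"])


class TestNodeReport:
    def test_share_and_class_percentages(self):
        node = ChaidNode(node_id=7, depth=2, class_counts={"II": 28, "III": 3, "IV": 1})
        rep = node_report(node, total_cases=569)
        assert rep["share_percent"] == 5.6
        assert rep["class_percent"] == {"II": 87.5, "III": 9.4, "IV": 3.1}

    def test_empty_class_present(self):
        node = ChaidNode(node_id=8, depth=1, class_counts={"II": 10, "V": 0})
        rep = node_report(node, total_cases=100)
        assert rep["class_percent"]["V"] == 0.0
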