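"""Fuzzy tree induction and forest classification.

The crisp-limit checks compare the package's induction against an
independent brute-force implementation of classical ambiguity-greedy tree
building (pure Python, enumerating every attribute at every node).
"""

import json
import math

import numpy as np
import pytest

from drscreen import (
    FRFParams,
    classification_ambiguity,
    classify,
    classify_cohort,
    fuzzy_subsethood,
    induce_tree,
    load_model,
    make_fixture,
    save_model,
    train_forest,
)
from drscreen.forest import (
    ModelFormatError,
    UndefinedEvidenceError,
    _tree_rng,
    classify_evidence,
    possibility_ambiguity,
    select_attribute,
    tree_depth,
)
from drscreen.fuzzy import CLASS_LABELS, FuzzyEvidence, FuzzyPartition, FuzzySet


# ---------------------------------------------------------------------------
# independent brute-force oracle for the crisp limit


def oracle_tree(rows, attrs, tau):
    """Classical ambiguity-greedy decision tree on crisp binary data.

    ``rows`` is a list of (attribute-value dict with values in {0, 1},
    label in {0, 1}).  At every node all remaining attributes are scored by
    the partition-weighted nonspecificity of the class possibility
    distribution; the minimiser (lexicographic ties) is split on.
    """

    def g_of(counts):
        n = sum(counts)
        props = [c / n for c in counts]
        top = max(props)
        pi = sorted((p / top for p in props), reverse=True) + [0.0]
        return sum((pi[i] - pi[i + 1]) * math.log(i + 1) for i in range(len(pi) - 1))

    def grow(subset, remaining):
        n = len(subset)
        n1 = sum(y for _, y in subset)
        props = [(n - n1) / n, n1 / n]
        best = 1 if props[1] >= props[0] else 0
        if props[best] >= tau or not remaining:
            return ("leaf", best, props[best])
        scores = {}
        for a in sorted(remaining):
            parts = {0: [], 1: []}
            for r, y in subset:
                parts[r[a]].append(y)
            total, acc = 0, 0.0
            for lv in (0, 1):
                ys = parts[lv]
                if not ys:
                    continue
                total += len(ys)
                acc += len(ys) * g_of([len(ys) - sum(ys), sum(ys)])
            scores[a] = acc / total
        attr, low = None, float("inf")
        for a in sorted(scores):
            if scores[a] < low - 1e-12:  # rounding-noise ties stay lexicographic
                attr, low = a, scores[a]
        children = {}
        for lv in (0, 1):
            sub = [(r, y) for r, y in subset if r[attr] == lv]
            if not sub:
                children[lv] = ("leaf", best, props[best])
            else:
                children[lv] = grow(sub, [a for a in remaining if a != attr])
        return ("node", attr, children)

    return grow(rows, sorted(attrs))


def oracle_route(tree, record):
    while tree[0] == "node":
        tree = tree[2][record[tree[1]]]
    return tree[1]  # class index


def crisp_evidence(rows, attrs):
    """Package-side evidence for the same data: one-hot over levels (0, 1)."""
    parts = {
        a: FuzzyPartition(a, [FuzzySet("no", level="0"), FuzzySet("yes", level="1")])
        for a in attrs
    }
    mats = {
        a: np.column_stack(
            [[1.0 - r[a] for r, _ in rows], [float(r[a]) for r, _ in rows]]
        )
        for a in attrs
    }
    y = np.array([y for _, y in rows], dtype=float)
    classes = np.column_stack([1.0 - y, y])
    return FuzzyEvidence(mats, parts, classes)


def assert_same_tree(node, oracle):
    if oracle[0] == "leaf":
        assert node["leaf"], f"expected leaf, got split on {node.get('attribute')}"
        assert node["class"] == CLASS_LABELS[oracle[1]]
        assert node["truth"] == pytest.approx(oracle[2], abs=1e-12)
    else:
        assert not node["leaf"]
        assert node["attribute"] == oracle[1]
        for j, lv in enumerate((0, 1)):
            assert_same_tree(node["children"][j], oracle[2][lv])


def random_crisp_rows(rng, n, n_attrs):
    attrs = [f"x{i}" for i in range(n_attrs)]
    while True:
        rows = [
            ({a: int(rng.integers(2)) for a in attrs}, int(rng.integers(2)))
            for _ in range(n)
        ]
        labels = {y for _, y in rows}
        if len(labels) == 2:
            return rows, attrs


# ---------------------------------------------------------------------------


class TestSubsethood:
    def test_reflexive(self):
        e = np.array([0.3, 0.9, 0.1])
        assert fuzzy_subsethood(e, e) == 1.0

    def test_hand_evaluated_half(self):
        assert fuzzy_subsethood([1, 1], [1, 0]) == 0.5

    def test_disjoint_is_zero(self):
        assert fuzzy_subsethood([0.5, 0.5], [0, 0]) == 0.0

    def test_zero_evidence_is_an_error(self):
        with pytest.raises(UndefinedEvidenceError):
            fuzzy_subsethood([0, 0], [1, 1])


class TestAmbiguity:
    @pytest.mark.parametrize(
        "pi, expected",
        [((1, 0), 0.0), ((1, 1), 0.6931), ((1, 0.5), 0.3466)],
    )
    def test_possibility_nonspecificity(self, pi, expected):
        assert possibility_ambiguity(pi) == pytest.approx(expected, abs=5e-5)

    def test_from_evidence_equals_ln2_for_balanced_classes(self):
        w = np.ones(4)
        classes = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        amb = classification_ambiguity(w, [classes[:, 0], classes[:, 1]])
        assert amb == pytest.approx(math.log(2))

    def test_single_possible_class_is_zero(self):
        w = np.ones(3)
        classes = np.array([[1, 0]] * 3, dtype=float)
        assert classification_ambiguity(w, [classes[:, 0], classes[:, 1]]) == 0.0


class TestSelectAttribute:
    def test_perfect_separator_beats_noise(self):
        rng = np.random.default_rng(0)
        rows = [({"sep": y, "noise": int(rng.integers(2))}, y)
                for y in [0, 1] * 6]
        ev = crisp_evidence(rows, ["noise", "sep"])
        got = select_attribute(["noise", "sep"], ev, np.ones(12))
        assert got == "sep"

    def test_tie_goes_to_lexicographically_first(self):
        rows = [({"a": v, "b": v}, y) for v, y in [(0, 0), (0, 1), (1, 0), (1, 1)]]
        ev = crisp_evidence(rows, ["a", "b"])
        assert select_attribute(["b", "a"], ev, np.ones(4)) == "a"

    def test_matches_brute_force_scores_on_small_crisp_data(self):
        rng = np.random.default_rng(7)
        rows, attrs = random_crisp_rows(rng, 12, 2)
        ev = crisp_evidence(rows, attrs)
        oracle = oracle_tree(rows, attrs, tau=1.1)  # force a split at the root
        got = select_attribute(attrs, ev, np.ones(12))
        assert got == oracle[1]


class TestInduceTree:
    def _params(self, tau, n_attrs):
        return FRFParams(n_trees=1, attributes_per_node=n_attrs,
                         leaf_threshold=tau, bootstrap=False)

    def test_zero_threshold_gives_immediate_majority_leaf(self):
        rng = np.random.default_rng(1)
        rows, attrs = random_crisp_rows(rng, 15, 2)
        ev = crisp_evidence(rows, attrs)
        tree = induce_tree(ev, self._params(0.0, 2), _tree_rng(0, 0))
        assert tree["leaf"]
        majority = int(sum(y for _, y in rows) >= len(rows) / 2)
        assert tree["class"] == CLASS_LABELS[majority]

    def test_perfect_single_attribute_split_is_depth_one(self):
        rows = [({"x0": v}, v) for v in [0, 1] * 5]
        ev = crisp_evidence(rows, ["x0"])
        tree = induce_tree(ev, self._params(1.0, 1), _tree_rng(0, 0))
        assert tree_depth(tree) == 1
        assert tree["children"][0]["class"] == "without_risk"
        assert tree["children"][1]["class"] == "with_risk"

    @pytest.mark.parametrize("seed", range(8))
    def test_crisp_limit_matches_brute_force_tree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        n_attrs = int(rng.integers(2, 4))
        rows, attrs = random_crisp_rows(rng, n, n_attrs)
        ev = crisp_evidence(rows, attrs)
        tree = induce_tree(ev, self._params(1.0, n_attrs), _tree_rng(seed, 0))
        assert_same_tree(tree, oracle_tree(rows, attrs, 1.0))

    def test_increasing_threshold_never_shrinks_depth(self):
        rng = np.random.default_rng(3)
        rows, attrs = random_crisp_rows(rng, 18, 3)
        ev = crisp_evidence(rows, attrs)
        depths = [
            tree_depth(induce_tree(ev, self._params(tau, 3), _tree_rng(0, 0)))
            for tau in (0.0, 0.5, 0.8, 1.0)
        ]
        assert depths == sorted(depths)

    def test_row_permutation_leaves_tree_unchanged(self):
        rng = np.random.default_rng(5)
        rows, attrs = random_crisp_rows(rng, 16, 3)
        perm = list(rng.permutation(16))
        t1 = induce_tree(crisp_evidence(rows, attrs),
                         self._params(1.0, 3), _tree_rng(2, 0))
        t2 = induce_tree(crisp_evidence([rows[i] for i in perm], attrs),
                         self._params(1.0, 3), _tree_rng(2, 0))
        assert t1 == t2


class TestForest:
    def test_training_is_bit_reproducible(self, small_evidence):
        p = FRFParams(n_trees=4, seed=42)
        f1 = train_forest(small_evidence, p)
        f2 = train_forest(small_evidence, p)
        assert json.dumps(f1.trees) == json.dumps(f2.trees)

    def test_single_class_evidence_rejected(self, small_evidence):
        ev = small_evidence
        pos = np.flatnonzero(ev.classes[:, 1] > 0)
        with pytest.raises(ValueError, match="both classes"):
            train_forest(ev.subset(pos), FRFParams(n_trees=1))

    def test_single_tree_forest_equals_its_tree(self, small_cohort, small_evidence):
        p = FRFParams(n_trees=1, bootstrap=False, seed=9)
        forest = train_forest(small_evidence, p)
        votes = classify_evidence(forest, small_evidence)
        support = np.zeros((small_evidence.n, 2))
        from drscreen.forest import _tree_support

        _tree_support(forest.trees[0], np.ones(small_evidence.n),
                      small_evidence.attr_memberships, support, "min", 0.0)
        expected = support / support.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(votes, expected)

    def test_votes_normalised_and_certainty_at_least_half(self, small_cohort, small_forest):
        preds = classify_cohort(small_forest, small_cohort)
        for p in preds:
            assert p.votes[0] + p.votes[1] == pytest.approx(1.0)
            assert 0.5 <= p.certainty <= 1.0
            assert p.certainty == pytest.approx(max(p.votes))

    def test_crisp_forest_routes_records_like_hard_lookup(self):
        rng = np.random.default_rng(11)
        rows, attrs = random_crisp_rows(rng, 14, 3)
        ev = crisp_evidence(rows, attrs)
        tree = induce_tree(ev, FRFParams(n_trees=1, attributes_per_node=3,
                                         leaf_threshold=1.0, bootstrap=False),
                           _tree_rng(4, 0))
        oracle = oracle_tree(rows, attrs, 1.0)
        from drscreen.forest import _tree_support

        for r, _ in rows:
            m = {a: np.array([[1.0 - r[a], float(r[a])]]) for a in attrs}
            support = np.zeros((1, 2))
            _tree_support(tree, np.ones(1), m, support, "min", 0.0)
            assert support[0].argmax() == oracle_route(oracle, r)

    def test_classify_rejects_incomplete_record(self, small_forest):
        with pytest.raises(ValueError, match="missing predictor"):
            classify(small_forest, {"age": 60, "sex": "male"})

    def test_classify_single_record_matches_batch(self, small_cohort, small_forest):
        rec = small_cohort.records.iloc[3].to_dict()
        single = classify(small_forest, rec)
        batch = classify_cohort(small_forest, small_cohort)[3]
        assert single.label == batch.label
        assert single.certainty == pytest.approx(batch.certainty)


class TestModelIO:
    def test_round_trip_preserves_predictions(self, tmp_path, small_forest):
        gen = make_fixture("separable", n=100, seed=5)
        path = tmp_path / "model.json"
        save_model(small_forest, path)
        loaded = load_model(path)
        p1 = classify_cohort(small_forest, gen.cohort)
        p2 = classify_cohort(loaded, gen.cohort)
        assert [p.label for p in p1] == [p.label for p in p2]
        np.testing.assert_allclose([p.certainty for p in p1],
                                   [p.certainty for p in p2])

    def test_two_saves_are_byte_identical(self, tmp_path, small_forest):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        save_model(small_forest, a)
        save_model(small_forest, b)
        assert a.read_bytes() == b.read_bytes()

    def test_truncated_file_is_a_load_error(self, tmp_path, small_forest):
        path = tmp_path / "model.json"
        save_model(small_forest, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_wrong_format_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ModelFormatError, match="format"):
            load_model(path)
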