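"""Logic regression: tree algebra, scoring, annealing, model selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from poolgen import logicreg as lr


def _truth_table(tree, p):
    rows = np.array(list(itertools.product([0, 1], repeat=p)), dtype=np.uint8)
    return lr.evaluate_tree(tree, rows)


@st.composite
def random_trees(draw, p=4, max_depth=3):
    def build(depth):
        if depth >= max_depth or draw(st.booleans()):
            return lr.leaf(draw(st.integers(0, p - 1)), draw(st.booleans()))
        op = "and" if draw(st.booleans()) else "or"
        return (op, build(depth + 1), build(depth + 1))
    return build(0)


class TestTrees:
    def test_figure_style_tree_evaluates_true(self):
        # naevi>50 OR [skin IV AND (R151C OR brown hair)] on the row
        # (naevi>50=0, skinIV=1, R151C=1, brown=0)
        tree = lr.node("or", lr.leaf(0),
                       lr.node("and", lr.leaf(1),
                               lr.node("or", lr.leaf(2), lr.leaf(3))))
        row = np.array([[0, 1, 1, 0]], dtype=np.uint8)
        assert lr.evaluate_tree(tree, row)[0]

    def test_single_leaf_is_identity(self):
        X = np.array([[0], [1]], dtype=np.uint8)
        assert lr.evaluate_tree(lr.leaf(0), X).tolist() == [False, True]
        assert lr.evaluate_tree(lr.leaf(0, comp=True), X).tolist() == [True, False]

    @given(random_trees())
    @settings(max_examples=60, deadline=None)
    def test_evaluation_matches_bruteforce_truth_table(self, tree):
        # independent recursive evaluator over all 2^4 inputs
        def brute(t, row):
            if t[0] == "leaf":
                v = bool(row[t[1]])
                return (not v) if t[2] else v
            a, b = brute(t[1], row), brute(t[2], row)
            return (a and b) if t[0] == "and" else (a or b)

        rows = list(itertools.product([0, 1], repeat=4))
        expected = [brute(tree, r) for r in rows]
        got = _truth_table(tree, 4)
        assert got.tolist() == expected

    @given(random_trees())
    @settings(max_examples=30, deadline=None)
    def test_complement_involution(self, tree):
        def complement_leaf(t):
            if t[0] == "leaf":
                return lr.leaf(t[1], not t[2])
            return (t[0], complement_leaf(t[1]), t[2])

        twice = complement_leaf(complement_leaf(tree))
        assert (_truth_table(twice, 4) == _truth_table(tree, 4)).all()

    def test_serialization_uses_field_notation(self):
        tree = lr.node("and", lr.leaf(3, comp=True),
                       lr.node("or", lr.leaf(4), lr.leaf(0)))
        assert lr.tree_to_string(tree) == "X4^C ∧ (X5 ∨ X1)"


class TestDichotomize:
    def test_nevi_threshold_dummy(self):
        df = pd.DataFrame({"nevi_count": [60, 12, np.nan]})
        out = lr.dichotomize(df, [{"name": "naevi_gt50", "source": "nevi_count",
                                   "gt": 50}])
        assert out["naevi_gt50"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(out["naevi_gt50"].iloc[2])

    def test_intermediate_class_scores_zero_on_both_extremes(self):
        df = pd.DataFrame({"skin_type": [2, 1, 4]})
        spec = [{"name": "skin_I", "source": "skin_type", "classes": {1}},
                {"name": "skin_IV", "source": "skin_type", "classes": {4}}]
        out = lr.dichotomize(df, spec)
        assert out.iloc[0].tolist() == [0.0, 0.0]

    def test_constant_dummy_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            lr.dichotomize(df, [{"name": "never", "source": "x", "gt": 10}])


class TestScoring:
    def test_perfect_predictor_drives_deviance_to_zero(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        X = y[:, None].astype(np.uint8)
        m = lr.score_model([lr.leaf(0)], X, y)
        assert m.deviance < 1e-6
        assert "coefficient_capped" in m.flags

    def test_2x2_closed_form_deviance(self):
        # single binary predictor: saturated 2-cell logistic; deviance equals
        # -2 * sum of cell binomial log-likelihoods at observed rates
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        X = np.r_[np.ones(100), np.zeros(100)][:, None].astype(np.uint8)
        m = lr.score_model([lr.leaf(0)], X, y)
        def cell(s, n):
            p = s / n
            return s * math.log(p) + (n - s) * math.log(1 - p)
        expected = -2 * (cell(30, 100) + cell(10, 100))
        assert m.deviance == pytest.approx(expected, rel=1e-8)
        assert m.coefficients[0] == pytest.approx(
            math.log(30 * 90 / (70 * 10)), abs=1e-6)

    def test_constant_tree_collapses_to_null_deviance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(float)
        X = rng.integers(0, 2, (200, 2)).astype(np.uint8)
        # X1 OR X1^C is always true -> constant column -> intercept-only
        tree = lr.node("or", lr.leaf(0), lr.leaf(0, comp=True))
        m = lr.score_model([tree], X, y)
        p = y.mean()
        null_dev = -2 * (y.sum() * math.log(p) + (200 - y.sum()) * math.log(1 - p))
        assert m.deviance == pytest.approx(null_dev, rel=1e-10)
        assert any("collinear" in f for f in m.flags)


class TestMoves:
    def test_prune_on_single_leaf_resampled_to_legal_move(self):
        rng = np.random.default_rng(0)
        sched = lr.AnnealSchedule(move_probs={"prune_branch": 1.0})
        trees, move = lr.propose_move([lr.leaf(0)], rng, sched, p=5,
                                      max_leaves=4)
        assert move == "alternate_leaf"
        assert lr.tree_size(trees[0]) == 1

    def test_grow_adds_exactly_one_leaf(self):
        rng = np.random.default_rng(1)
        sched = lr.AnnealSchedule(move_probs={"grow_branch": 1.0})
        start = lr.node("and", lr.leaf(0), lr.leaf(1))
        trees, move = lr.propose_move([start], rng, sched, p=5, max_leaves=8)
        assert move == "grow_branch"
        assert lr.tree_size(trees[0]) == 3

    def test_empirical_move_mix_matches_probabilities(self):
        rng = np.random.default_rng(2)
        sched = lr.AnnealSchedule()
        start = [lr.node("or", lr.node("and", lr.leaf(0), lr.leaf(1)),
                         lr.leaf(2))]
        counts = {}
        n = 20_000
        for _ in range(n):
            _, move = lr.propose_move(start, rng, sched, p=6, max_leaves=8)
            counts[move] = counts.get(move, 0) + 1
        for name, prob in sched.move_probs.items():
            assert counts.get(name, 0) / n == pytest.approx(prob, abs=0.02)


def _planted_data(rng, n=2000, p=8, log_or=np.log(3), baseline=0.2,
                  rule=None):
    X = rng.integers(0, 2, size=(n, p)).astype(np.uint8)
    if rule is None:
        rule = lr.node("or", lr.leaf(0), lr.leaf(1))
    active = lr.evaluate_tree(rule, X)
    y = (rng.random(n) < expit(logit(baseline) + log_or * active)).astype(float)
    return X, y, rule


class TestAnneal:
    def test_recovers_planted_rule(self):
        recovered = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            X, y, rule = _planted_data(rng, n=4000)
            m = lr.anneal_search(
                X, y, lr.AnnealSchedule(iterations=3000, seed=seed),
                max_trees=1, max_leaves=2)
            if lr.trees_equivalent(m.trees[0], rule, X):
                recovered += 1
        assert recovered >= 0.9 * runs

    def test_never_beats_exhaustive_oracle(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X, y, _ = _planted_data(rng, n=400, p=4)
            oracle = lr.exhaustive_search(X, y, max_leaves=3)
            m = lr.anneal_search(
                X, y, lr.AnnealSchedule(iterations=2000, seed=seed),
                max_trees=1, max_leaves=3)
            assert m.deviance >= oracle.deviance - 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X, y, _ = _planted_data(rng, n=600, p=6)
        sched = lr.AnnealSchedule(iterations=800, seed=99)
        m1 = lr.anneal_search(X, y, sched, max_trees=1, max_leaves=4)
        m2 = lr.anneal_search(X, y, sched, max_trees=1, max_leaves=4)
        assert m1.deviance == m2.deviance
        assert [lr.canonical_string(t) for t in m1.trees] == \
               [lr.canonical_string(t) for t in m2.trees]

    def test_all_constant_predictors_error(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        X = np.ones((60, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="constant"):
            lr.anneal_search(X, y)


class TestExhaustive:
    def test_p1_leaf_and_complement_are_equivalent_minimizers(self):
        import math
        # X predicts y imperfectly: 30/40 cases and 10/60 controls have X=1
        y = np.r_[np.ones(40), np.zeros(60)]
        X = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(50)]
        X = X[:, None].astype(np.uint8)
        m = lr.exhaustive_search(X, y, max_leaves=1)
        # X1 and X1^C give the same saturated 2-cell fit (sign flips), so
        # the minimizer must be equivalent to the single leaf, at the
        # closed-form 2-cell deviance
        assert lr.trees_equivalent(m.trees[0], lr.leaf(0), X)
        def cell(s, n):
            p = s / n
            return s * math.log(p) + (n - s) * math.log(1 - p)
        expected = -2 * (cell(30, 40) + cell(10, 60))
        assert m.deviance == pytest.approx(expected, rel=1e-8)

    def test_noiseless_or_rule_recovered_exactly(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (300, 3)).astype(np.uint8)
        y = (X[:, 0] | X[:, 1]).astype(float)
        m = lr.exhaustive_search(X, y, max_leaves=3)
        truth = (X[:, 0] | X[:, 1]).astype(bool)
        assert (lr.evaluate_tree(m.trees[0], X) == truth).all()

    def test_agrees_with_independent_candidate_loop(self):
        # independent scoring loop over the same candidate set
        rng = np.random.default_rng(11)
        X, y, _ = _planted_data(rng, n=250, p=3)
        m = lr.exhaustive_search(X, y, max_leaves=2)
        best = np.inf
        for t in lr._enumerate_trees(3, 2):
            d = lr.score_model([t], X, y).deviance
            best = min(best, d)
        assert m.deviance == pytest.approx(best, rel=1e-10)

    def test_enumeration_guard(self):
        X = np.zeros((100, 40), dtype=np.uint8)
        X[::2] = 1
        with pytest.raises(ValueError, match="guard"):
            lr.exhaustive_search(X, np.r_[np.ones(50), np.zeros(50)],
                                 max_leaves=3)


class TestSelection:
    def test_strong_signal_attains_permutation_floor(self):
        rng = np.random.default_rng(21)
        X, y, _ = _planted_data(rng, n=1500, p=6, log_or=np.log(6))
        rep = lr.select_model(
            X, y, grid=((1, 1), (1, 2)), folds=3, permutations=20,
            schedule=lr.AnnealSchedule(iterations=500), seed=2)
        assert rep.p_value == pytest.approx(1 / 21)

    def test_pure_noise_rarely_significant(self):
        flagged = 0
        reps = 8
        for i in range(reps):
            rng = np.random.default_rng(300 + i)
            X = rng.integers(0, 2, (400, 5)).astype(np.uint8)
            y = rng.integers(0, 2, 400).astype(float)
            rep = lr.select_model(
                X, y, grid=((1, 2),), folds=3, permutations=24,
                schedule=lr.AnnealSchedule(iterations=300), seed=i)
            if rep.p_value <= 0.05:
                flagged += 1
        assert flagged <= 2

    def test_selection_deterministic_given_seed(self):
        rng = np.random.default_rng(31)
        X, y, _ = _planted_data(rng, n=500, p=5)
        kw = dict(grid=((1, 1), (1, 2)), folds=3, permutations=20,
                  schedule=lr.AnnealSchedule(iterations=300), seed=7)
        r1 = lr.select_model(X, y, **kw)
        r2 = lr.select_model(X, y, **kw)
        assert r1.p_value == r2.p_value
        assert r1.chosen == r2.chosen
        assert (r1.cv_deviance == r2.cv_deviance).all()
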