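"""Logic regression: Boolean-tree predictors inside a logistic model.

Logic regression searches for Boolean combinations (AND/OR trees over
possibly complemented binary predictors) that, entered as covariates of a
logistic model

    logit P(Y=1) = alpha + sum_j beta_j L_j,

minimize the binomial deviance.  It is aimed at finding subpopulations at
high or low risk characterized by high-order interactions — e.g. a
combined genotype-phenotype rule such as

    "more than 50 common naevi" OR [ "skin type IV" AND ( R151C OR brown hair ) ]

The tree space is explored by simulated annealing over the usual move set
(alternate a leaf, alternate an operator, grow/prune a branch, split or
delete a leaf); model size is selected by cross-validation with a one
standard-error rule, and overall signal is assessed by a randomization
(permutation) test.  A brute-force enumerator over small trees serves as
an exact optimizer for low-dimensional problems.

Trees are immutable nested tuples: a leaf is ``("leaf", index, comp)`` and
an internal node ``("and"|"or", left, right)``.  The human-readable
serialization uses the conventional symbols (AND = ``∧``, OR = ``∨``,
complement = ``^C``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

__all__ = [
    "leaf",
    "node",
    "tree_size",
    "evaluate_tree",
    "tree_to_string",
    "canonical_string",
    "LogicModel",
    "AnnealSchedule",
    "SelectionReport",
    "dichotomize",
    "score_model",
    "propose_move",
    "anneal_search",
    "exhaustive_search",
    "select_model",
    "trees_equivalent",
]

AND, OR, LEAF = "and", "or", "leaf"
_OP_SYMBOL = {AND: "∧", OR: "∨"}


# --------------------------------------------------------------------------
# trees


def leaf(index: int, comp: bool = False):
    """A leaf referencing predictor ``index``, optionally complemented."""
    return (LEAF, int(index), bool(comp))


def node(op: str, left, right):
    if op not in (AND, OR):
        raise ValueError(f"operator must be 'and' or 'or', got {op!r}")
    return (op, left, right)


def is_leaf(tree) -> bool:
    return tree[0] == LEAF


def tree_size(tree) -> int:
    """Number of leaves."""
    if is_leaf(tree):
        return 1
    return tree_size(tree[1]) + tree_size(tree[2])


def tree_predictors(tree) -> set:
    if is_leaf(tree):
        return {tree[1]}
    return tree_predictors(tree[1]) | tree_predictors(tree[2])


def evaluate_tree(tree, X) -> np.ndarray:
    """Evaluate a Boolean tree on a binary predictor matrix, vectorized.

    ``X`` is (n, p) with entries 0/1; returns a boolean vector of length n.
    Complements are applied at the leaves (the only place the search moves
    put them).
    """
    X = np.asarray(X)
    if is_leaf(tree):
        col = X[:, tree[1]].astype(bool)
        return ~col if tree[2] else col
    left = evaluate_tree(tree[1], X)
    right = evaluate_tree(tree[2], X)
    return (left & right) if tree[0] == AND else (left | right)


def tree_to_string(tree, names=None) -> str:
    """Parenthesized Boolean string, e.g. ``X4^C ∧ (X5 ∨ X1)``."""
    def name(i):
        return names[i] if names is not None else f"X{i + 1}"

    def rec(t, top=False):
        if is_leaf(t):
            return name(t[1]) + ("^C" if t[2] else "")
        s = f"{rec(t[1])} {_OP_SYMBOL[t[0]]} {rec(t[2])}"
        return s if top else f"({s})"

    return rec(tree, top=True)


def canonical_string(tree) -> str:
    """Order-normalized serialization used for deterministic tie-breaks."""
    if is_leaf(tree):
        return f"x{tree[1]:04d}" + ("c" if tree[2] else "")
    a, b = canonical_string(tree[1]), canonical_string(tree[2])
    if a > b:
        a, b = b, a
    return f"({a} {tree[0]} {b})"


def _paths(tree, path=()):
    """All node positions as root-to-node paths of 0 (left) / 1 (right)."""
    yield path, tree
    if not is_leaf(tree):
        yield from _paths(tree[1], path + (0,))
        yield from _paths(tree[2], path + (1,))


def _replace_at(tree, path, subtree):
    if not path:
        return subtree
    head, *rest = path
    left, right = tree[1], tree[2]
    if head == 0:
        return (tree[0], _replace_at(left, tuple(rest), subtree), right)
    return (tree[0], left, _replace_at(right, tuple(rest), subtree))


def _random_leaf(rng, p: int):
    return leaf(int(rng.integers(p)), bool(rng.integers(2)))


# --------------------------------------------------------------------------
# model containers


@dataclass
class LogicModel:
    """A fitted logic-regression model.

    ``trees`` are the Boolean expressions L_j, ``coefficients`` their
    log-odds coefficients beta_j, ``intercept`` alpha, and ``deviance`` the
    training binomial deviance (-2 log-likelihood).
    """

    intercept: float
    coefficients: list
    trees: list
    deviance: float
    names: list | None = None
    flags: tuple = ()

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def total_leaves(self) -> int:
        return sum(tree_size(t) for t in self.trees)

    def describe(self) -> str:
        parts = [f"logit = {self.intercept:+.3f}"]
        for b, t in zip(self.coefficients, self.trees):
            parts.append(f"{b:+.3f} * [{tree_to_string(t, self.names)}]")
        return " ".join(parts)

    def predict_logit(self, X):
        eta = np.full(np.asarray(X).shape[0], self.intercept, dtype=float)
        for b, t in zip(self.coefficients, self.trees):
            eta += b * evaluate_tree(t, X)
        return eta

    def deviance_on(self, X, y) -> float:
        """Binomial deviance of this model evaluated on new data."""
        eta = self.predict_logit(X)
        y = np.asarray(y, dtype=float)
        return float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class AnnealSchedule:
    """Simulated-annealing control parameters.

    ``t0=None`` auto-tunes the initial temperature so that roughly 90% of
    early uphill moves are accepted; cooling is geometric with ratio
    ``rho``.  Move probabilities must sum to one.
    """

    t0: float | None = None
    rho: float = 0.999
    iterations: int = 50_000
    move_probs: dict = field(default_factory=lambda: {
        "alternate_leaf": 0.30,
        "alternate_operator": 0.15,
        "grow_branch": 0.15,
        "prune_branch": 0.15,
        "split_leaf": 0.125,
        "delete_leaf": 0.125,
    })
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("cooling ratio rho must be in (0, 1)")
        tot = sum(self.move_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"move probabilities sum to {tot}, not 1")


# --------------------------------------------------------------------------
# fitting


def dichotomize(df, spec):
    """Build named binary predictors from a harmonized table.

    ``spec`` is a list of dicts with keys ``name``, ``source`` and one of:

    - ``gt`` / ``ge`` / ``lt`` / ``le``: numeric threshold;
    - ``classes``: a set of class values mapped to 1.

    Extreme-class dummies (e.g. skin type I vs skin type IV) should be
    created as separate entries so intermediate classes score zero on
    both — misclassification concentrates in intermediate classes, so the
    extremes carry the cleanest signal.  Missing source values propagate
    to NaN; a dummy that comes out constant raises an error.
    """
    import pandas as pd

    out = {}
    for item in spec:
        src = df[item["source"]]
        x = src.astype(float) if "classes" not in item else src
        if "gt" in item:
            col = (x > item["gt"]).astype(float)
        elif "ge" in item:
            col = (x >= item["ge"]).astype(float)
        elif "lt" in item:
            col = (x < item["lt"]).astype(float)
        elif "le" in item:
            col = (x <= item["le"]).astype(float)
        elif "classes" in item:
            col = src.isin(item["classes"]).astype(float)
        else:
            raise ValueError(f"{item['name']}: no threshold or class set given")
        col = col.where(~src.isna(), np.nan)
        observed = col.dropna()
        if observed.nunique() < 2:
            raise ValueError(
                f"dummy {item['name']!r} is constant after dichotomization"
            )
        out[item["name"]] = col
    return pd.DataFrame(out, index=df.index)


def _fit_logistic_counts(design, successes, totals, max_iter=50, tol=1e-10):
    """Newton fit of a binomial GLM on aggregated pattern counts.

    Returns (coef, deviance, capped).  Fitted linear predictors are capped
    at +-30, which handles perfectly predictive trees gracefully (deviance
    then effectively 0 for those rows, and ``capped`` is flagged).
    """
    n_pat, p = design.shape
    coef = np.zeros(p)
    capped = False
    dev_old = np.inf
    for _ in range(max_iter):
        eta = design @ coef
        if np.any(np.abs(eta) > 30):
            capped = True
            eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = totals * mu * (1 - mu)
        z = eta + (successes - totals * mu) / np.maximum(w, 1e-12)
        WX = design * w[:, None]
        try:
            coef = np.linalg.solve(design.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(WX, w * z, rcond=None)
        eta = np.clip(design @ coef, -30, 30)
        ll = float(np.sum(successes * eta - totals * np.logaddexp(0.0, eta)))
        dev = -2.0 * ll
        if abs(dev_old - dev) < tol:
            break
        dev_old = dev
    return coef, max(dev, 0.0), capped


def score_model(trees, X, y):
    """Fit alpha and beta_j for fixed trees; return the binomial deviance.

    The logistic fit runs on aggregated data: n subjects collapse onto at
    most 2^k distinct tree-evaluation patterns, which makes scoring cheap
    inside the annealing loop.  Collinear tree columns (identical truth
    columns) are collapsed to one with a flag; the deviance is computed on
    the reduced design.

    Returns a :class:`LogicModel` (without names).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    cols = [evaluate_tree(t, X) for t in trees]
    flags = []

    # drop duplicate truth columns (collinear in the design)
    keep = []
    seen = {}
    for j, c in enumerate(cols):
        key = c.tobytes()
        if key in seen or (~c).tobytes() in seen or c.all() or (~c).all():
            flags.append(f"tree{j}_collinear")
            continue
        seen[key] = j
        keep.append(j)

    if not keep:
        # intercept-only model
        p = y.mean()
        p = min(max(p, 1e-12), 1 - 1e-12)
        dev = -2.0 * (y.sum() * math.log(p) + (len(y) - y.sum()) * math.log(1 - p))
        alpha = math.log(p / (1 - p))
        return LogicModel(alpha, [0.0] * len(trees), list(trees), float(dev),
                          flags=tuple(flags))

    mat = np.column_stack([cols[j] for j in keep]).astype(np.uint8)
    # pattern code per subject -> aggregated successes/totals
    code = mat @ (1 << np.arange(mat.shape[1], dtype=np.uint64))
    order = np.argsort(code, kind="stable")
    code_s = code[order]
    y_s = y[order]
    cut = np.flatnonzero(np.r_[True, code_s[1:] != code_s[:-1]])
    totals = np.diff(np.r_[cut, code_s.size]).astype(float)
    successes = np.add.reduceat(y_s, cut)
    pat_codes = code_s[cut]
    pat = ((pat_codes[:, None] >> np.arange(mat.shape[1], dtype=np.uint64)) & 1).astype(float)
    design = np.column_stack([np.ones(len(pat_codes)), pat])

    coef, dev, capped = _fit_logistic_counts(design, successes, totals)
    if capped or np.abs(design @ coef).max() > 25:
        flags.append("coefficient_capped")
    betas = [0.0] * len(trees)
    for slot, j in enumerate(keep):
        betas[j] = float(coef[1 + slot])
    return LogicModel(float(coef[0]), betas, list(trees), float(dev),
                      flags=tuple(flags))


# --------------------------------------------------------------------------
# moves


def _apply_move(trees, which, move, rng, p, max_leaves):
    """Try one move on tree ``which``; return new tree list or None if illegal."""
    t = trees[which]
    total = sum(tree_size(tr) for tr in trees)
    positions = list(_paths(t))
    leaves = [(pa, nd) for pa, nd in positions if is_leaf(nd)]
    internals = [(pa, nd) for pa, nd in positions if not is_leaf(nd)]

    if move == "alternate_leaf":
        pa, nd = leaves[rng.integers(len(leaves))]
        for _ in range(10):
            new = _random_leaf(rng, p)
            if new != nd:
                break
        else:  # pragma: no cover - p==1 single-state corner
            new = leaf(nd[1], not nd[2])
        new_t = _replace_at(t, pa, new)
    elif move == "alternate_operator":
        if not internals:
            return None
        pa, nd = internals[rng.integers(len(internals))]
        flipped = (OR if nd[0] == AND else AND, nd[1], nd[2])
        new_t = _replace_at(t, pa, flipped)
    elif move in ("grow_branch", "split_leaf"):
        if total >= max_leaves:
            return None
        if move == "grow_branch":
            pa, nd = positions[rng.integers(len(positions))]
        else:
            pa, nd = leaves[rng.integers(len(leaves))]
        op = AND if rng.integers(2) else OR
        new_t = _replace_at(t, pa, (op, nd, _random_leaf(rng, p)))
    elif move == "prune_branch":
        if not internals:
            return None
        pa, nd = internals[rng.integers(len(internals))]
        child = nd[1] if rng.integers(2) else nd[2]
        new_t = _replace_at(t, pa, child)
    elif move == "delete_leaf":
        if is_leaf(t):
            return None
        pa, nd = leaves[rng.integers(len(leaves))]
        parent_path = pa[:-1]
        parent = t
        for step in parent_path:
            parent = parent[1 + step]
        sibling = parent[2] if pa[-1] == 0 else parent[1]
        new_t = _replace_at(t, parent_path, sibling)
    else:
        raise ValueError(f"unknown move {move!r}")

    out = list(trees)
    out[which] = new_t
    return out


def propose_move(trees, rng, schedule: AnnealSchedule, p: int, max_leaves: int):
    """Draw one legal move: tree chosen uniformly, move type by schedule.

    Illegal draws (pruning a single leaf, growing at the size bound) are
    resampled up to a bounded number of times, after which an
    alternate-leaf move — always legal — is applied.

    Returns ``(new_trees, move_name)``.
    """
    names = list(schedule.move_probs)
    probs = np.array([schedule.move_probs[m] for m in names])
    for _ in range(20):
        which = int(rng.integers(len(trees)))
        move = names[rng.choice(len(names), p=probs)]
        out = _apply_move(trees, which, move, rng, p, max_leaves)
        if out is not None:
            return out, move
    which = int(rng.integers(len(trees)))
    out = _apply_move(trees, which, "alternate_leaf", rng, p, max_leaves)
    return out, "alternate_leaf"


# --------------------------------------------------------------------------
# search


def _check_predictors(X):
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("predictor matrix must be 2-D")
    if X.dtype.kind == "f" and np.isnan(X).any():
        raise ValueError("missing predictor values: drop incomplete rows first")
    vals = np.unique(X)
    if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        raise ValueError("predictors must be binary 0/1")
    const = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if len(const) == X.shape[1]:
        raise ValueError("all predictors are constant")
    return X.astype(np.uint8)


def anneal_search(X, y, schedule: AnnealSchedule | None = None,
                  max_trees: int = 1, max_leaves: int = 8,
                  names=None) -> LogicModel:
    """Search tree space by simulated annealing; return the best model seen.

    Metropolis acceptance on the binomial deviance: downhill moves are
    always accepted, an uphill move of size ``delta`` with probability
    exp(-delta / T); T cools geometrically.  When the schedule's ``t0`` is
    None it is tuned from a pre-pass of random moves so the initial uphill
    acceptance rate is about 0.9.  The best-ever model (not the final
    state) is returned.  Fully deterministic given the schedule seed.
    """
    X = _check_predictors(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 observations")
    if schedule is None:
        schedule = AnnealSchedule()
    rng = np.random.default_rng(schedule.seed)
    p = X.shape[1]
    max_leaves_total = max_leaves * max_trees

    trees = [leaf(int(rng.integers(p)), bool(rng.integers(2)))
             for _ in range(max_trees)]
    current = score_model(trees, X, y)
    best = current

    t0 = schedule.t0
    if t0 is None:
        ups = []
        probe_trees, probe_score = trees, current.deviance
        for _ in range(60):
            cand, _mv = propose_move(probe_trees, rng, schedule, p, max_leaves_total)
            d = score_model(cand, X, y).deviance
            if d > probe_score:
                ups.append(d - probe_score)
            probe_trees, probe_score = cand, d
        t0 = (np.mean(ups) if ups else 1.0) / (-math.log(0.9))
        trees = probe_trees
        current = score_model(trees, X, y)
        if current.deviance < best.deviance:
            best = current

    T = max(t0, 1e-9)
    for _ in range(schedule.iterations):
        cand_trees, _mv = propose_move(trees, rng, schedule, p, max_leaves_total)
        cand = score_model(cand_trees, X, y)
        delta = cand.deviance - current.deviance
        if delta <= 0 or rng.random() < math.exp(-delta / T):
            trees, current = cand_trees, cand
            if (current.deviance < best.deviance - 1e-12 or
                (abs(current.deviance - best.deviance) <= 1e-12 and
                 _model_key(current) < _model_key(best))):
                best = current
        T *= schedule.rho

    best.names = list(names) if names is not None else None
    return best


def trees_equivalent(t1, t2, X) -> bool:
    """Whether two trees define the same logistic covariate on these rows.

    True when the evaluation columns are identical or exact complements:
    (L, beta) and (not-L, -beta) are the same fitted model, so De Morgan
    rewritings count as the same rule.
    """
    a = evaluate_tree(t1, X)
    b = evaluate_tree(t2, X)
    return bool((a == b).all() or (a == ~b).all())


def _model_key(model: LogicModel):
    return (model.total_leaves, tuple(sorted(canonical_string(t) for t in model.trees)))


def _enumerate_trees(p: int, max_leaves: int):
    """All tree shapes up to ``max_leaves`` leaves over p predictors."""
    leaves1 = [leaf(i, c) for i in range(p) for c in (False, True)]
    yield from leaves1
    if max_leaves >= 2:
        for l1, l2 in itertools.combinations(leaves1, 2):
            for op in (AND, OR):
                yield (op, l1, l2)
    if max_leaves >= 3:
        for l1 in leaves1:
            for l2, l3 in itertools.combinations(leaves1, 2):
                for op_in in (AND, OR):
                    inner = (op_in, l2, l3)
                    for op_out in (AND, OR):
                        yield (op_out, l1, inner)


def exhaustive_search(X, y, max_leaves: int = 3, guard: int = 10_000,
                      names=None) -> LogicModel:
    """Exact single-tree optimizer by enumeration (an oracle for annealing).

    Enumerates every Boolean expression with at most ``max_leaves`` leaves
    (3 at most), deduplicated by truth table over the observed rows, and
    returns the global deviance minimizer.  Ties break toward the smaller
    tree, then the lexicographically smallest canonical serialization.
    Raises if the candidate count exceeds ``guard``.
    """
    if max_leaves > 3:
        raise ValueError("exhaustive search supports at most 3 leaves")
    X = _check_predictors(X)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    n_cand = 2 * p + 2 * math.comb(2 * p, 2) + 2 * p * 2 * math.comb(2 * p, 2) * 2
    if n_cand > guard:
        raise ValueError(
            f"~{n_cand} candidate expressions exceed the enumeration guard "
            f"({guard}); reduce p or max_leaves"
        )

    best = None
    best_key = None
    seen = set()
    for t in _enumerate_trees(p, max_leaves):
        col = evaluate_tree(t, X)
        key = col.tobytes()
        if key in seen:
            continue
        seen.add(key)
        m = score_model([t], X, y)
        k = (round(m.deviance, 10), tree_size(t), canonical_string(t))
        if best is None or k < best_key:
            best, best_key = m, k
    best.names = list(names) if names is not None else None
    return best


# --------------------------------------------------------------------------
# model selection


@dataclass
class SelectionReport:
    """Cross-validation and randomization-test model selection output."""

    grid: list                 # (max_trees, max_leaves) points
    cv_deviance: np.ndarray    # mean test deviance per grid point
    cv_se: np.ndarray          # SE over folds
    chosen: tuple              # grid point selected by the 1-SE rule
    final_model: LogicModel
    observed_deviance: float
    permuted_deviances: np.ndarray
    p_value: float
    seed: int


def _stratified_folds(y, folds, rng):
    y = np.asarray(y)
    idx0 = rng.permutation(np.flatnonzero(y == 0))
    idx1 = rng.permutation(np.flatnonzero(y == 1))
    assignment = np.empty(len(y), dtype=int)
    assignment[idx0] = np.arange(len(idx0)) % folds
    assignment[idx1] = np.arange(len(idx1)) % folds
    # guard: every fold needs both classes
    for f in range(folds):
        yy = y[assignment == f]
        if len(set(yy)) < 2:
            warnings.warn("fold with a single class; refolding without stratification",
                          stacklevel=3)
            assignment = rng.permutation(np.arange(len(y)) % folds)
            break
    return assignment


def select_model(X, y, grid=((1, 1), (1, 2), (1, 3)), folds: int = 5,
                 permutations: int = 20, schedule: AnnealSchedule | None = None,
                 seed: int = 0, names=None) -> SelectionReport:
    """Choose model size by cross-validation; test signal by randomization.

    For each grid point (number of trees, leaves per tree), the annealing
    search runs on each training fold and the fitted model is scored on
    the held-out fold; the selected size is the smallest (by total leaf
    budget) whose mean CV deviance is within one standard error of the
    minimizer.  The randomization test re-runs the search on
    permuted outcomes: p = (1 + #{permuted best deviance <= observed}) /
    (permutations + 1), so a strong planted signal attains the
    1/(permutations+1) floor.  Deterministic given ``seed``.
    """
    X = _check_predictors(X)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("need at least two folds")
    if permutations < 20:
        raise ValueError("need at least 20 permutations")
    if schedule is None:
        schedule = AnnealSchedule(iterations=3000)
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, folds, rng)

    cv_mean, cv_se = [], []
    for (k_trees, k_leaves) in grid:
        fold_devs = []
        for f in range(folds):
            tr, te = assignment != f, assignment == f
            sub_seed = int(rng.integers(2**31 - 1))
            m = anneal_search(X[tr], y[tr],
                              dc_replace(schedule, seed=sub_seed),
                              max_trees=k_trees, max_leaves=k_leaves)
            fold_devs.append(m.deviance_on(X[te], y[te]) / te.sum())
        fold_devs = np.array(fold_devs)
        cv_mean.append(fold_devs.mean())
        cv_se.append(fold_devs.std(ddof=1) / np.sqrt(folds))
    cv_mean, cv_se = np.array(cv_mean), np.array(cv_se)

    i_min = int(np.argmin(cv_mean))
    budget = [g[0] * g[1] for g in grid]
    within = [i for i in range(len(grid))
              if cv_mean[i] <= cv_mean[i_min] + cv_se[i_min]]
    chosen_i = min(within, key=lambda i: (budget[i], i))
    chosen = tuple(grid[chosen_i])

    final_seed = int(rng.integers(2**31 - 1))
    final = anneal_search(X, y, dc_replace(schedule, seed=final_seed),
                          max_trees=chosen[0], max_leaves=chosen[1], names=names)

    perm_devs = []
    for _ in range(permutations):
        yp = rng.permutation(y)
        ps = int(rng.integers(2**31 - 1))
        mp = anneal_search(X, yp, dc_replace(schedule, seed=ps),
                           max_trees=chosen[0], max_leaves=chosen[1])
        perm_devs.append(mp.deviance)
    perm_devs = np.array(perm_devs)
    p_value = (1 + np.sum(perm_devs <= final.deviance)) / (permutations + 1)

    return SelectionReport(list(grid), cv_mean, cv_se, chosen, final,
                           final.deviance, perm_devs, float(p_value), seed)
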