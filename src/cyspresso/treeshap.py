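"""Exact Shapley attributions for decision-tree ensembles.

For a single tree, the value function of the Shapley game is the
path-dependent expectation: conditioning on a feature subset S, the tree
is walked from the root, following the split whenever the split feature
is in S and otherwise averaging both children weighted by their training
cover.  Shapley values of this game are computed exactly in polynomial
time by propagating, along each root-leaf path, the weighted proportions
of feature subsets that let the sample reach the leaf ("one" fractions
for features followed, cover-ratio "zero" fractions for features averaged
over), together with the combinatorial Shapley weights per subset size.

The implementation keeps, per path, arrays of unique split features with
their one/zero fractions and an array ``pw`` where ``pw[j]`` is the sum
over subsets of size j of the product of fractions times
j!(D-j)!/(D+1)!.  Extending and unwinding these arrays follows the
recurrence

    w'_j = z * w_j * (D+1-j)/(D+2) + o * w_{j-1} * j/(D+2)

which is inverted exactly when a feature is removed.  Correctness is
checked in the test suite against a brute-force enumeration of all
feature subsets on small random trees.

Forest attributions are the across-tree average (matching the forest
probability, which averages tree probabilities), so local accuracy holds:
base value + sum of contributions = predicted probability of the positive
class, to floating-point precision.

A Monte-Carlo permutation-sampling estimator of the same game is provided
as a fallback for structures the exact path algorithm does not cover; it
is quadratic-cost and intended for small models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class TreeArrays:
    """Flat arrays of one fitted decision tree (positive-class output)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    cover: np.ndarray        # weighted training samples per node
    value: np.ndarray        # per-node positive-class probability
    max_depth: int


def tree_arrays_from_sklearn(tree, positive_class_index: int) -> TreeArrays:
    """Extract :class:`TreeArrays` from a fitted sklearn tree estimator."""
    t = tree.tree_
    raw = t.value[:, 0, :]
    totals = raw.sum(axis=1)
    value = raw[:, positive_class_index] / np.where(totals > 0, totals, 1.0)
    return TreeArrays(
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(np.float64),
        cover=t.weighted_n_node_samples.astype(np.float64),
        value=np.ascontiguousarray(value, dtype=np.float64),
        max_depth=int(t.max_depth),
    )


def tree_expected_value(tree: TreeArrays) -> float:
    """Cover-weighted expectation of the tree output (the base value)."""
    leaves = tree.children_left == -1
    return float(
        np.sum(tree.cover[leaves] * tree.value[leaves]) / tree.cover[0]
    )


@njit(cache=False)
def _unwound_sum(PW, PZ, PO, row, nf, i):  # pragma: no cover - numba
    D = nf
    z = PZ[row, i]
    o = PO[row, i]
    next_one = PW[row, D]
    total = 0.0
    for j in range(D - 1, -1, -1):
        if o != 0.0:
            u = next_one * (D + 1) / ((j + 1) * o)
            total += u
            next_one = PW[row, j] - u * z * (D - j) / (D + 1)
        else:
            total += PW[row, j] * (D + 1) / (z * (D - j))
    return total


@njit(cache=False)
def _tree_shap_sample(
    children_left,
    children_right,
    feature,
    threshold,
    cover,
    value,
    x,
    phi,
    PD,
    PZ,
    PO,
    PW,
    st_node,
    st_depth,
    st_nf,
    st_z,
    st_o,
    st_f,
):  # pragma: no cover - numba
    # row 0: empty path
    PW[0, 0] = 1.0
    sp = 0
    st_node[sp] = 0
    st_depth[sp] = 1
    st_nf[sp] = 0
    st_z[sp] = 1.0
    st_o[sp] = 1.0
    st_f[sp] = -1
    sp += 1
    while sp > 0:
        sp -= 1
        node = st_node[sp]
        depth = st_depth[sp]
        nf = st_nf[sp]
        z = st_z[sp]
        o = st_o[sp]
        f = st_f[sp]

        # copy parent path (row depth-1) into this frame's row
        for j in range(nf + 1):
            PW[depth, j] = PW[depth - 1, j]
        for i in range(1, nf + 1):
            PD[depth, i] = PD[depth - 1, i]
            PZ[depth, i] = PZ[depth - 1, i]
            PO[depth, i] = PO[depth - 1, i]

        if f >= 0:
            # extend with (z, o, f): D -> D+1 features
            nf1 = nf + 1
            PD[depth, nf1] = f
            PZ[depth, nf1] = z
            PO[depth, nf1] = o
            PW[depth, nf1] = 0.0
            for j in range(nf1, 0, -1):
                PW[depth, j] = (
                    o * PW[depth, j - 1] * j / (nf1 + 1)
                    + z * PW[depth, j] * (nf1 - j) / (nf1 + 1)
                )
            PW[depth, 0] = z * PW[depth, 0] * nf1 / (nf1 + 1)
            nf = nf1

        if children_left[node] == -1:  # leaf
            v = value[node]
            for i in range(1, nf + 1):
                total = _unwound_sum(PW, PZ, PO, depth, nf, i)
                phi[PD[depth, i]] += total * (PO[depth, i] - PZ[depth, i]) * v
        else:
            fsplit = feature[node]
            left = children_left[node]
            right = children_right[node]
            if x[fsplit] <= threshold[node]:
                hot, cold = left, right
            else:
                hot, cold = right, left
            hz = cover[hot] / cover[node]
            cz = cover[cold] / cover[node]
            iz = 1.0
            io = 1.0
            k = 0
            for i in range(1, nf + 1):
                if PD[depth, i] == fsplit:
                    k = i
                    break
            if k > 0:
                iz = PZ[depth, k]
                io = PO[depth, k]
                # destructive unwind of slot k on this row
                D = nf
                zz = PZ[depth, k]
                oo = PO[depth, k]
                next_one = PW[depth, D]
                for j in range(D - 1, -1, -1):
                    if oo != 0.0:
                        u = next_one * (D + 1) / ((j + 1) * oo)
                        next_one = PW[depth, j] - u * zz * (D - j) / (D + 1)
                        PW[depth, j] = u
                    else:
                        PW[depth, j] = PW[depth, j] * (D + 1) / (zz * (D - j))
                for i in range(k, D):
                    PD[depth, i] = PD[depth, i + 1]
                    PZ[depth, i] = PZ[depth, i + 1]
                    PO[depth, i] = PO[depth, i + 1]
                nf = D - 1

            st_node[sp] = cold
            st_depth[sp] = depth + 1
            st_nf[sp] = nf
            st_z[sp] = iz * cz
            st_o[sp] = 0.0
            st_f[sp] = fsplit
            sp += 1
            st_node[sp] = hot
            st_depth[sp] = depth + 1
            st_nf[sp] = nf
            st_z[sp] = iz * hz
            st_o[sp] = io
            st_f[sp] = fsplit
            sp += 1


@njit(cache=False)
def _tree_shap_matrix(
    children_left, children_right, feature, threshold, cover, value, X, phi, max_depth
):  # pragma: no cover - numba
    n = X.shape[0]
    size = max_depth + 3
    stack_size = 2 * size + 2
    PD = np.zeros((size, size), dtype=np.int64)
    PZ = np.zeros((size, size), dtype=np.float64)
    PO = np.zeros((size, size), dtype=np.float64)
    PW = np.zeros((size, size), dtype=np.float64)
    st_node = np.zeros(stack_size, dtype=np.int64)
    st_depth = np.zeros(stack_size, dtype=np.int64)
    st_nf = np.zeros(stack_size, dtype=np.int64)
    st_z = np.zeros(stack_size, dtype=np.float64)
    st_o = np.zeros(stack_size, dtype=np.float64)
    st_f = np.zeros(stack_size, dtype=np.int64)
    for s in range(n):
        _tree_shap_sample(
            children_left,
            children_right,
            feature,
            threshold,
            cover,
            value,
            X[s],
            phi[s],
            PD,
            PZ,
            PO,
            PW,
            st_node,
            st_depth,
            st_nf,
            st_z,
            st_o,
            st_f,
        )


def tree_shap(tree: TreeArrays, X: np.ndarray) -> np.ndarray:
    """Exact Shapley contributions of one tree for each row of X.

    Returns an (n_samples, n_features) matrix; row sums equal
    tree_output(x) - tree_expected_value(tree).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    _tree_shap_matrix(
        tree.children_left,
        tree.children_right,
        tree.feature,
        tree.threshold,
        tree.cover,
        tree.value,
        X,
        phi,
        tree.max_depth,
    )
    return phi


def forest_shap(forest, X: np.ndarray, positive_class_index: int = 1) -> tuple[np.ndarray, float]:
    """Average per-tree Shapley contributions over a fitted forest.

    Returns (phi, base_value); phi[s].sum() + base_value equals the
    forest's predicted positive-class probability for sample s.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    base = 0.0
    estimators = forest.estimators_
    for est in estimators:
        arrays = tree_arrays_from_sklearn(est, positive_class_index)
        phi += tree_shap(arrays, X)
        base += tree_expected_value(arrays)
    phi /= len(estimators)
    base /= len(estimators)
    return phi, base


# ---------------------------------------------------------------------------
# reference expectation and Monte-Carlo fallback
# ---------------------------------------------------------------------------


def expected_value_given(tree: TreeArrays, x: np.ndarray, known: np.ndarray) -> float:
    """Path-dependent expectation of the tree conditioned on a feature set.

    Splits on features in ``known`` (boolean mask) follow ``x``; all other
    splits average both children weighted by training cover.  This is the
    value function of the Shapley game the exact algorithm solves; it is
    also the brute-force oracle used in tests.
    """

    def walk(node: int) -> float:
        if tree.children_left[node] == -1:
            return float(tree.value[node])
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if known[f]:
            child = left if x[f] <= tree.threshold[node] else right
            return walk(child)
        wl = tree.cover[left] / tree.cover[node]
        wr = tree.cover[right] / tree.cover[node]
        return wl * walk(left) + wr * walk(right)

    return walk(0)


def sampling_shap(
    forest,
    X: np.ndarray,
    n_draws: int = 2000,
    seed: int = 0,
    positive_class_index: int = 1,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo permutation-sampling Shapley estimate of the same game.

    For each draw a random permutation of the features used by the forest
    is walked; each feature's marginal effect on the path-dependent
    expectation is accumulated.  Cost grows with (features used) x
    (nodes) x n_draws, so this is a fallback for small models; the seed
    and draw count are recorded by the caller.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    trees = [tree_arrays_from_sklearn(est, positive_class_index) for est in forest.estimators_]
    used = sorted(set(np.concatenate([t.feature[t.feature >= 0] for t in trees]).tolist()))
    used = np.asarray(used, dtype=np.int64)
    n, F = X.shape
    phi = np.zeros((n, F), dtype=np.float64)
    base = float(np.mean([tree_expected_value(t) for t in trees]))

    def value(x: np.ndarray, known: np.ndarray) -> float:
        return float(np.mean([expected_value_given(t, x, known) for t in trees]))

    for s in range(n):
        for _ in range(n_draws):
            order = rng.permutation(used)
            known = np.zeros(F, dtype=bool)
            prev = base
            for f in order:
                known[f] = True
                cur = value(X[s], known)
                phi[s, f] += cur - prev
                prev = cur
        phi[s] /= n_draws
    return phi, base
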