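"""Path-dependent Shapley attribution for scikit-learn tree ensembles.

For a single decision tree, define the value of a feature coalition S at
input x as the expected leaf output under the *path-dependent* traversal:
at a node splitting on a feature in S the branch is chosen by x; at any
other node both branches are taken, weighted by their training cover
fractions.  The attribution of feature f is the Shapley value of f under
this coalition game; a forest averages the per-tree attributions.  By
construction the attributions satisfy local accuracy: they sum, together
with the tree's base (all-features-absent) value, to the predicted
positive-class probability at x.

The fast kernel here exploits the per-leaf factorization of that game:
the coalition value decomposes over leaves, and for one leaf it is a
product over the distinct features on the leaf's root path of either an
indicator (feature present: does x satisfy every threshold for it on the
path?) or the product of the path's cover fractions for that feature
(feature absent).  The Shapley sum for one leaf then reduces to an
elementary-symmetric-polynomial recurrence over at most nine features,
evaluated in a numba kernel.  :func:`exact_shapley` is the independent
brute-force oracle (explicit subset enumeration with recursive tree
traversal) used to verify the kernel on small models.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numba import njit

__all__ = ["forest_shap_values", "exact_shapley"]

_MAX_PATH_FEATURES = 32


def _tree_leaf_tables(tree, feature_count: int):
    """Flatten one fitted sklearn tree into per-leaf path tables.

    Per leaf: distinct path features with their admissible (lo, hi]
    interval for x, the product of cover fractions over that feature's
    edges, and the leaf's positive-class probability.
    """
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    value = tree.value  # (n_nodes, 1, n_classes) normalized by sklearn >= 1.3

    feats, los, his, qs, vals, starts = [], [], [], [], [], [0]

    def walk(node, path):
        if left[node] == -1:  # leaf
            v = value[node][0]
            vals.append(v[1] / v.sum() if v.sum() else 0.0)
            for f, (lo, hi, q) in sorted(path.items()):
                feats.append(f)
                los.append(lo)
                his.append(hi)
                qs.append(q)
            starts.append(len(feats))
            return
        f, thr = feature[node], threshold[node]
        seen = f in path
        lo, hi, q = path[f] if seen else (-np.inf, np.inf, 1.0)
        frac_l = cover[left[node]] / cover[node]
        path[f] = (lo, min(hi, thr), q * frac_l)
        walk(left[node], path)
        path[f] = (max(lo, thr), hi, q * (1.0 - frac_l))
        walk(right[node], path)
        if seen:
            path[f] = (lo, hi, q)
        else:
            del path[f]

    walk(0, {})
    return (np.asarray(feats, dtype=np.int64), np.asarray(los), np.asarray(his),
            np.asarray(qs), np.asarray(vals), np.asarray(starts, dtype=np.int64))


def _shapley_weights(max_players: int) -> np.ndarray:
    """W[t, d] = t! (d-1-t)! / d! for a game with d players."""
    W = np.zeros((max_players + 1, max_players + 1))
    for d in range(1, max_players + 1):
        for t in range(d):
            W[t, d] = math.factorial(t) * math.factorial(d - 1 - t) / math.factorial(d)
    return W


@njit(cache=True)
def _kernel(X, starts, feats, los, his, qs, vals, leaf_w, W, n_features):
    n = X.shape[0]
    phi = np.zeros((n, n_features))
    n_leaves = starts.shape[0] - 1
    p = np.empty(_MAX_PATH_FEATURES)
    c = np.empty(_MAX_PATH_FEATURES + 1)
    for i in range(n):
        for L in range(n_leaves):
            s, e = starts[L], starts[L + 1]
            d = e - s
            if d == 0:
                continue
            for k in range(d):
                j = s + k
                x = X[i, feats[j]]
                p[k] = 1.0 if (x > los[j]) and (x <= his[j]) else 0.0
            for k in range(d):
                qk = qs[s + k]
                pk = p[k]
                if pk == 1.0 and qk == 1.0:
                    continue
                QB = 1.0
                deg = 0
                c[0] = 1.0
                for m in range(d):
                    if m == k:
                        continue
                    qm = qs[s + m]
                    if p[m] == 1.0:
                        c[deg + 1] = 0.0
                        for t in range(deg + 1, 0, -1):
                            c[t] = c[t - 1] + qm * c[t]
                        c[0] = qm * c[0]
                        deg += 1
                    else:
                        QB *= qm
                acc = 0.0
                for t in range(deg + 1):
                    acc += W[t, d] * c[t]
                phi[i, feats[s + k]] += leaf_w[L] * (pk - qk) * QB * acc * vals[L]
    return phi


def forest_shap_values(model, X) -> tuple[np.ndarray, float]:
    """Per-sample path-dependent Shapley values for a fitted forest.

    Parameters
    ----------
    model
        Fitted ``RandomForestClassifier`` (or any sklearn ensemble exposing
        ``estimators_`` with ``tree_``).
    X
        (n, n_features) array of inputs.

    Returns
    -------
    (phi, base)
        ``phi[i, j]`` attributes the positive-class probability of sample
        ``i`` to feature ``j``; ``base`` is the coalition-empty expected
        probability.  ``phi.sum(axis=1) + base`` equals
        ``model.predict_proba(X)[:, 1]`` up to floating error.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n_features = int(model.n_features_in_)
    trees = [est.tree_ for est in model.estimators_]
    tree_w = 1.0 / len(trees)

    all_feats, all_los, all_his, all_qs, all_vals = [], [], [], [], []
    all_starts = [np.asarray([0], dtype=np.int64)]
    leaf_w = []
    base = 0.0
    offset = 0
    for tree in trees:
        feats, los, his, qs, vals, starts = _tree_leaf_tables(tree, n_features)
        all_feats.append(feats)
        all_los.append(los)
        all_his.append(his)
        all_qs.append(qs)
        all_vals.append(vals)
        all_starts.append(starts[1:] + offset)
        offset += len(feats)
        leaf_w.extend([tree_w] * (len(starts) - 1))
        # empty-coalition value: cover-weighted mean over leaves
        for L in range(len(starts) - 1):
            base += tree_w * vals[L] * np.prod(qs[starts[L]:starts[L + 1]])

    phi = _kernel(
        X,
        np.concatenate(all_starts),
        np.concatenate(all_feats) if offset else np.zeros(0, dtype=np.int64),
        np.concatenate(all_los) if offset else np.zeros(0),
        np.concatenate(all_his) if offset else np.zeros(0),
        np.concatenate(all_qs) if offset else np.zeros(0),
        np.concatenate(all_vals),
        np.asarray(leaf_w),
        _shapley_weights(_MAX_PATH_FEATURES - 1),
        n_features,
    )
    return phi, float(base)


# ---------------------------------------------------------------------------
# brute-force oracle


def _coalition_value(tree, x, S) -> float:
    """Path-dependent expected positive-class probability given coalition S."""
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    value = tree.value

    def rec(node) -> float:
        if left[node] == -1:
            v = value[node][0]
            return v[1] / v.sum() if v.sum() else 0.0
        f = feature[node]
        if f in S:
            nxt = left[node] if x[f] <= threshold[node] else right[node]
            return rec(nxt)
        wl = cover[left[node]] / cover[node]
        return wl * rec(left[node]) + (1.0 - wl) * rec(right[node])

    return rec(0)


def exact_shapley(model, x) -> tuple[np.ndarray, float]:
    """Brute-force Shapley attribution by explicit subset enumeration.

    Exponential in the feature count — intended as a correctness oracle for
    models with at most four features, and refused beyond six.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = int(model.n_features_in_)
    if M > 6:
        raise ValueError("exact Shapley enumeration is limited to <= 6 features")
    trees = [est.tree_ for est in model.estimators_]

    def v(S: frozenset) -> float:
        return float(np.mean([_coalition_value(t, x, S) for t in trees]))

    cache = {S: v(frozenset(S))
             for r in range(M + 1)
             for S in itertools.combinations(range(M), r)}
    phi = np.zeros(M)
    for f in range(M):
        others = [g for g in range(M) if g != f]
        for r in range(M):
            w = math.factorial(r) * math.factorial(M - r - 1) / math.factorial(M)
            for S in itertools.combinations(others, r):
                phi[f] += w * (cache[tuple(sorted(S + (f,)))] - cache[S])
    return phi, cache[()]
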