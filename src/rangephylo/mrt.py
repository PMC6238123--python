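"""Multivariate regression trees for habitat delimitation.

A multivariate regression tree (MRT) is CART with the whole
plot-by-species abundance matrix as the response: node impurity is the
sum of squared deviations of each plot's species vector from the node's
multivariate mean, and a split on an environmental predictor is chosen
to maximise the impurity reduction.  A maximal tree is grown, the nested
cost-complexity (weakest-link) pruning sequence is derived, and the tree
size is selected by minimising the cross-validated relative error

    CVRE = (cross-validated prediction sum of squares)
           / (total sum of squares about the grand multivariate mean),

averaged over repeated k-fold cross-validation.  Leaves of the selected
tree are the habitat types, labelled H1..Hk in order of increasing leaf
mean elevation (ties broken by latitude).  The resubstitution R^2 of the
tree is 1 minus its relative error.

Only numeric predictors are supported (elevation, latitude, optionally
longitude); there are no surrogate splits and no missing-value handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MRTNode", "MRTModel", "node_impurity", "best_split", "grow_and_select"]

_EPS = 1e-12


def node_impurity(rows: np.ndarray) -> float:
    """Sum of squared deviations about the multivariate (species) mean.

    ``rows`` is the abundance sub-matrix of the plots in the node
    (plots x species); a single plot, or identical plots, give 0.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[0] == 0:
        raise ValueError("empty node has no impurity")
    return float(((rows - rows.mean(axis=0)) ** 2).sum())


def best_split(
    Y: np.ndarray,
    X: np.ndarray,
    predictors: list[str] | None = None,
    min_leaf: int = 5,
) -> tuple[str | int, float, float] | None:
    """Exhaustive best binary split of one node.

    Scans every predictor (in the given column order) and every midpoint
    between consecutive distinct sorted values, subject to ``min_leaf``
    plots on each side, and returns ``(variable, threshold, gain)`` for
    the split maximising the impurity reduction.  Ties are broken by
    predictor order, then by the smaller threshold.  Returns ``None``
    when no admissible split exists (too few plots, or all predictor
    values tied).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = Y.shape[0]
    if n < 2 * min_leaf:
        return None
    parent = node_impurity(Y)
    names = predictors if predictors is not None else list(range(X.shape[1]))

    best: tuple[float, int, float] | None = None  # (gain, pred_idx, threshold)
    row_sq = (Y**2).sum(axis=1)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = Y[order]
        cum = np.cumsum(ys, axis=0)
        cum_sq = np.cumsum(row_sq[order])
        tot, tot_sq = cum[-1], cum_sq[-1]
        k = np.arange(1, n)  # size of left child
        sse_left = cum_sq[:-1] - (cum[:-1] ** 2).sum(axis=1) / k
        sse_right = (tot_sq - cum_sq[:-1]) - ((tot - cum[:-1]) ** 2).sum(axis=1) / (
            n - k
        )
        valid = (k >= min_leaf) & (k <= n - min_leaf) & (xs[1:] > xs[:-1])
        if not valid.any():
            continue
        gains = np.where(valid, parent - (sse_left + sse_right), -np.inf)
        i = int(np.argmax(gains))  # argmax takes the first max: smallest threshold
        if gains[i] > -np.inf and (best is None or gains[i] > best[0] + _EPS):
            best = (float(gains[i]), j, float((xs[i] + xs[i + 1]) / 2.0))
    if best is None or best[0] <= _EPS:
        return None
    gain, j, thr = best
    return names[j], thr, gain


@dataclass
class MRTNode:
    """One node of the fitted tree (internal if ``var`` is not None)."""

    idx: np.ndarray                      # training plot indices in this node
    impurity: float
    var: str | None = None
    threshold: float | None = None
    left: "MRTNode | None" = None
    right: "MRTNode | None" = None
    prune_alpha: float = np.inf          # complexity at which this split dies
    leaf_label: str | None = None
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def leaves(self, alpha: float = -1.0) -> list["MRTNode"]:
        """Leaves of the subtree pruned at complexity ``alpha``.

        A split is collapsed once ``alpha`` reaches its ``prune_alpha``;
        the default returns the leaves of the unpruned (maximal) tree.
        """
        if self.is_leaf or self.prune_alpha <= alpha:
            return [self]
        return self.left.leaves(alpha) + self.right.leaves(alpha)


def _grow(Y, X, idx, predictors, min_leaf) -> MRTNode:
    node = MRTNode(idx=idx, impurity=node_impurity(Y[idx]))
    found = best_split(Y[idx], X[idx], predictors, min_leaf)
    if found is None:
        return node
    var, thr, _gain = found
    j = predictors.index(var)
    mask = X[idx, j] <= thr
    node.var, node.threshold = var, thr
    node.left = _grow(Y, X, idx[mask], predictors, min_leaf)
    node.right = _grow(Y, X, idx[~mask], predictors, min_leaf)
    return node


def _prune_sequence(root: MRTNode) -> list[tuple[float, int]]:
    """Weakest-link pruning; stamps ``prune_alpha`` on every internal node.

    Returns the nested cost-complexity sequence ``[(alpha, n_leaves),
    ...]`` with alpha strictly increasing from 0 (maximal tree) to the
    value collapsing the tree to its root.
    """
    for node in _iter_nodes(root):
        if not node.is_leaf:
            node.prune_alpha = np.inf

    def stats(node) -> tuple[float, int]:
        # (sum of leaf impurities, n leaves), treating stamped nodes as leaves
        if node.is_leaf or node.prune_alpha < np.inf:
            return node.impurity, 1
        r1, k1 = stats(node.left)
        r2, k2 = stats(node.right)
        return r1 + r2, k1 + k2

    def alive(node, out):
        if node.is_leaf or node.prune_alpha < np.inf:
            return out
        out.append(node)
        alive(node.left, out)
        alive(node.right, out)
        return out

    seq: list[tuple[float, int]] = [(0.0, stats(root)[1])]
    while True:
        live = alive(root, [])
        if not live:
            break
        g = {}
        for node in live:
            r_sub, k = stats(node)
            g[id(node)] = (node.impurity - r_sub) / max(k - 1, 1)
        g_min = max(min(g.values()), 0.0)
        for node in live:
            if g[id(node)] <= g_min + _EPS:
                node.prune_alpha = g_min
        size = stats(root)[1]
        if g_min <= seq[-1][0] + _EPS:
            seq[-1] = (seq[-1][0], size)  # collapses at the same alpha
        else:
            seq.append((g_min, size))
    return seq


def _iter_nodes(root: MRTNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        if not n.is_leaf:
            stack.extend((n.left, n.right))


def _predict_leaf(root: MRTNode, x_row: np.ndarray, pred_index: dict, alpha: float):
    node = root
    while not node.is_leaf and node.prune_alpha > alpha:
        j = pred_index[node.var]
        node = node.left if x_row[j] <= node.threshold else node.right
    return node


@dataclass
class MRTModel:
    """Fitted, CVRE-selected multivariate regression tree."""

    root: MRTNode
    predictors: list[str]
    cvre: float
    r_squared: float
    leaf_assignment: pd.Series          # plot_id -> habitat label H1..Hk
    size_path: pd.DataFrame             # size, alpha, rel_error, cvre, cvre_se
    selected_size: int
    _alpha: float = field(default=np.inf, repr=False)
    _leaf_means: dict = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return self.selected_size

    def predict_habitat(self, env: pd.DataFrame) -> pd.Series:
        X = env[self.predictors].to_numpy(dtype=float)
        pidx = {p: j for j, p in enumerate(self.predictors)}
        labels = [
            _predict_leaf(self.root, X[i], pidx, self._alpha).leaf_label
            for i in range(len(env))
        ]
        return pd.Series(labels, index=env.index, name="habitat")

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(node, depth):
            pad = "  " * depth
            if node.is_leaf or node.prune_alpha <= self._alpha:
                lines.append(
                    f"{pad}leaf {node.leaf_label}: n={len(node.idx)} "
                    f"impurity={node.impurity:.4f}"
                )
                return
            lines.append(
                f"{pad}{node.var} <= {node.threshold:.4f} "
                f"(n={len(node.idx)}, impurity={node.impurity:.4f})"
            )
            rec(node.left, depth + 1)
            rec(node.right, depth + 1)

        rec(self.root, 0)
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        rows = []

        def rec(node, nid):
            is_leaf = node.is_leaf or node.prune_alpha <= self._alpha
            rows.append(
                {
                    "node_id": nid,
                    "variable": "" if is_leaf else node.var,
                    "threshold": np.nan if is_leaf else node.threshold,
                    "n_plots": len(node.idx),
                    "impurity": node.impurity,
                    "leaf_label": node.leaf_label or "",
                }
            )
            if not is_leaf:
                rec(node.left, 2 * nid)
                rec(node.right, 2 * nid + 1)

        rec(self.root, 1)
        return pd.DataFrame(rows)


def grow_and_select(
    comm: pd.DataFrame,
    env: pd.DataFrame,
    predictors: list[str] | None = None,
    min_leaf: int = 5,
    cv_folds: int = 10,
    n_cv_reps: int = 50,
    seed: int = 0,
    hellinger: bool = False,
) -> MRTModel:
    """Grow a maximal MRT and prune to the minimum-CVRE size.

    ``comm`` is the plot-by-species abundance matrix (raw abundances by
    default; ``hellinger=True`` square-root-transforms row proportions
    first), ``env`` the plot environment table; ``predictors`` defaults
    to elevation and latitude, plus longitude when present.
    Cross-validation folds are assigned from ``seed``, so the fit is
    deterministic.
    """
    if predictors is None:
        predictors = [c for c in ("elevation", "latitude", "longitude") if c in env]
    if not set(predictors) <= set(env.columns):
        raise ValueError(f"predictors {predictors} not all in environment table")
    comm = comm.loc[env.index]
    Y = comm.to_numpy(dtype=float)
    if hellinger:
        totals = Y.sum(axis=1, keepdims=True)
        Y = np.sqrt(np.divide(Y, totals, out=np.zeros_like(Y), where=totals > 0))
    X = env[predictors].to_numpy(dtype=float)
    n = Y.shape[0]
    if n < 2 * min_leaf:
        raise ValueError(f"{n} plots is fewer than 2*min_leaf = {2 * min_leaf}")

    root = _grow(Y, X, np.arange(n), predictors, min_leaf)
    seq = _prune_sequence(root)  # [(alpha, size)] alphas increasing, sizes decreasing
    alphas = np.array([a for a, _ in seq])
    sizes = np.array([k for _, k in seq])
    tss = node_impurity(Y)
    if tss <= 0:
        raise ValueError("community matrix has zero total variance")

    # representative complexity for each candidate size: geometric mean of
    # consecutive pruning alphas (infinite for the root-only tree)
    betas = np.empty(len(seq))
    for i in range(len(seq)):
        if sizes[i] == 1:
            betas[i] = np.inf
        elif i + 1 < len(seq):
            betas[i] = float(np.sqrt(max(alphas[i], 0.0) * max(alphas[i + 1], _EPS)))
        else:
            betas[i] = alphas[i]

    resub = np.array(
        [sum(l.impurity for l in root.leaves(b)) / tss for b in betas]
    )

    pidx = {p: j for j, p in enumerate(predictors)}
    rng = np.random.default_rng([int(seed) % (2**31), 37])
    cv_folds = min(cv_folds, n)
    cvre_reps = np.zeros((n_cv_reps, len(betas)))
    for rep in range(n_cv_reps):
        fold = rng.permutation(n) % cv_folds
        press = np.zeros(len(betas))
        for f in range(cv_folds):
            test = np.where(fold == f)[0]
            train = np.where(fold != f)[0]
            if len(train) < 2 * min_leaf or len(test) == 0:
                continue
            sub_root = _grow(Y, X, train, predictors, min_leaf)
            _prune_sequence(sub_root)
            for bi, b in enumerate(betas):
                for t in test:
                    leaf = _predict_leaf(sub_root, X[t], pidx, b)
                    mu = Y[leaf.idx].mean(axis=0)
                    press[bi] += float(((Y[t] - mu) ** 2).sum())
        cvre_reps[rep] = press / tss
    cvre_mean = cvre_reps.mean(axis=0)
    cvre_se = cvre_reps.std(axis=0, ddof=1) / np.sqrt(n_cv_reps) if n_cv_reps > 1 else np.zeros_like(cvre_mean)

    # minimum CVRE; ties go to the smaller tree (sizes decrease along seq)
    best_i = int(len(cvre_mean) - 1 - np.argmin(cvre_mean[::-1]))
    alpha_sel = betas[best_i]

    leaves = root.leaves(alpha_sel)
    elev = env["elevation"].to_numpy(dtype=float) if "elevation" in env else X[:, 0]
    lat = env["latitude"].to_numpy(dtype=float) if "latitude" in env else X[:, -1]
    keyed = sorted(
        leaves, key=lambda l: (elev[l.idx].mean(), lat[l.idx].mean())
    )
    assignment = pd.Series(index=comm.index, dtype=object, name="habitat")
    for li, leaf in enumerate(keyed):
        leaf.leaf_label = f"H{li + 1}"
        assignment.iloc[leaf.idx] = leaf.leaf_label

    path = pd.DataFrame(
        {
            "size": sizes,
            "alpha": alphas,
            "rel_error": resub,
            "cvre": cvre_mean,
            "cvre_se": cvre_se,
        }
    )
    return MRTModel(
        root=root,
        predictors=predictors,
        cvre=float(cvre_mean[best_i]),
        r_squared=float(1.0 - resub[best_i]),
        leaf_assignment=assignment,
        size_path=path,
        selected_size=int(sizes[best_i]),
        _alpha=float(alpha_sel),
    )
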