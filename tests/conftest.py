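"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (explicit loops over
pairs, paths and candidate thresholds) so they share no code path with
the package implementation they check.
"""

from __future__ import annotations

import io

import numpy as np
import pytest

import rangephylo as rp


@pytest.fixture(scope="session")
def toy_tree():
    return rp.tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def toy_D(toy_tree):
    return rp.patristic_distances(toy_tree)


def random_tree(n_tips: int, seed: int):
    return rp.simulate_phylogeny(n_tips, seed=seed)


# ---------------------------------------------------------------------------
# Brute-force oracles


def biopython_distances(tree) -> tuple[list[str], np.ndarray]:
    """Patristic matrix via Bio.Phylo path summation (independent library)."""
    from Bio import Phylo

    bt = Phylo.read(io.StringIO(tree.as_string(schema="newick")), "newick")
    tips = bt.get_terminals()
    labels = [t.name for t in tips]
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bt.distance(tips[i], tips[j])
    return labels, d


def brute_mpd(species, D, abund=None):
    species = list(species)
    total, wsum = 0.0, 0.0
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            w = 1.0 if abund is None else abund[a] * abund[b]
            total += w * D.to_dataframe().loc[a, b]
            wsum += w
    return total / wsum


def brute_mntd(species, D, abund=None):
    species = list(species)
    df = D.to_dataframe()
    total, wsum = 0.0, 0.0
    for a in species:
        near = min(df.loc[a, b] for b in species if b != a)
        w = 1.0 if abund is None else abund[a]
        total += w * near
        wsum += w
    return total / wsum


def brute_dpw(c1, c2, D):
    df = D.to_dataframe()
    vals = [df.loc[a, b] for a in c1 for b in c2]
    return sum(vals) / len(vals)


def brute_dnn(c1, c2, D):
    df = D.to_dataframe()
    m1 = np.mean([min(df.loc[a, b] for b in c2) for a in c1])
    m2 = np.mean([min(df.loc[a, b] for a in c1) for b in c2])
    return (m1 + m2) / 2.0


def brute_impurity(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    mean = rows.mean(axis=0)
    return sum((rows[i, s] - mean[s]) ** 2
               for i in range(rows.shape[0]) for s in range(rows.shape[1]))


def brute_best_split(Y, X, min_leaf):
    """Exhaustive split search by direct partition evaluation."""
    n, p = X.shape
    best = None
    for j in range(p):
        for thr in sorted(set((a + b) / 2.0
                              for a, b in zip(sorted(X[:, j])[:-1],
                                              sorted(X[:, j])[1:])
                              if a < b)):
            left = Y[X[:, j] <= thr]
            right = Y[X[:, j] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = brute_impurity(Y) - brute_impurity(left) - brute_impurity(right)
            if best is None or gain > best[0] + 1e-9:
                best = (gain, j, thr)
    if best is None or best[0] <= 1e-9:
        return None
    return best[1], best[2], best[0]


def random_community(rng, labels, k_min=2, k_max=None):
    k_max = k_max or len(labels)
    k = int(rng.integers(k_min, k_max + 1))
    chosen = rng.choice(len(labels), size=k, replace=False)
    return [labels[i] for i in chosen]
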