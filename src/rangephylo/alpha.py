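"""Phylogenetic community structure: MPD, MNTD and null-model SES.

MPD (mean pairwise phylogenetic distance) summarises tree-wide, "basal"
relatedness of the species co-occurring in a plot; MNTD (mean nearest
taxon distance) summarises "terminal" relatedness near the tips.  Each
observed value is standardised against a null model that keeps every
plot's species richness and its multiset of abundance values but redraws
the species identities uniformly (without replacement) from the full
species pool:

    SES = (observed - mean_null) / sd_null

Negative SES means co-occurring species are more closely related than
expected (phylogenetic clustering, the signature of environmental
filtering on a conserved trait); positive SES means overdispersion.
The same machinery applies to habitat-scale assemblages obtained by
pooling member plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PatristicMatrix

__all__ = [
    "mpd",
    "mntd",
    "null_communities",
    "ses",
    "habitat_assemblage",
    "GradientRegression",
    "regress_ses",
]

Metric = Literal["mpd", "mntd"]


def _as_vector(community, D: PatristicMatrix) -> np.ndarray:
    """Community -> abundance vector aligned with ``D.labels``.

    Accepts a mapping/Series keyed by species, a sequence of species
    names (presence only), or an array already aligned with the matrix.
    """
    if isinstance(community, pd.Series):
        v = np.zeros(len(D.labels))
        v[D.indices(community.index)] = community.to_numpy(dtype=float)
        return v
    if isinstance(community, dict):
        return _as_vector(pd.Series(community), D)
    arr = np.asarray(community)
    if arr.dtype.kind in "UOS":  # species names: presence/absence
        v = np.zeros(len(D.labels))
        v[D.indices(arr)] = 1.0
        return v
    if arr.shape != (len(D.labels),):
        raise ValueError("abundance vector length does not match distance matrix")
    return arr.astype(float)


def mpd(community, D: PatristicMatrix, weighted: bool = False) -> float:
    """Mean pairwise distance among the species present.

    Unweighted: plain mean over unordered distinct pairs.  Weighted:
    abundance-product weights on the distinct pairs.  Returns NaN for
    communities with fewer than two species.
    """
    v = _as_vector(community, D)
    idx = np.flatnonzero(v > 0)
    if len(idx) < 2:
        return float("nan")
    sub = D.values[np.ix_(idx, idx)]
    if not weighted:
        k = len(idx)
        return float(sub.sum() / (k * (k - 1)))
    w = v[idx]
    ww = np.outer(w, w)
    np.fill_diagonal(ww, 0.0)
    return float((sub * ww).sum() / ww.sum())


def mntd(community, D: PatristicMatrix, weighted: bool = False) -> float:
    """Mean distance from each present species to its nearest co-occurring
    relative (abundance-weighted mean if ``weighted``).  NaN below two
    species."""
    v = _as_vector(community, D)
    idx = np.flatnonzero(v > 0)
    if len(idx) < 2:
        return float("nan")
    sub = D.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if not weighted:
        return float(nearest.mean())
    w = v[idx]
    return float((nearest * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Null model


def _pool_indices(pool, D: PatristicMatrix) -> np.ndarray:
    return D.indices(pool) if pool is not None else np.arange(len(D.labels))


def null_communities(
    comm: pd.DataFrame,
    pool: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> Iterator[pd.DataFrame]:
    """Stream of richness-preserving pool-randomised community matrices.

    Each replicate keeps, for every plot, its species richness and its
    multiset of abundance values, but the identities holding those
    abundances are drawn uniformly without replacement from the full
    species pool (default: all columns of ``comm``).  Plots are
    randomised independently.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    pool = list(pool) if pool is not None else list(comm.columns)
    if not set(comm.columns[(comm > 0).any()]) <= set(pool):
        raise ValueError("pool must contain every observed species")
    npool = len(pool)
    rich = (comm > 0).sum(axis=1)
    if (rich > npool).any():
        raise ValueError("a plot is richer than the species pool")
    rng = np.random.default_rng([int(seed) % (2**31), 43])
    values = [row[row > 0] for row in comm.to_numpy()]
    for _ in range(n_null):
        out = np.zeros((len(comm), npool), dtype=comm.to_numpy().dtype)
        for i, vals in enumerate(values):
            k = len(vals)
            if k == 0:
                continue
            chosen = rng.choice(npool, size=k, replace=False, shuffle=False)
            out[i, chosen] = rng.permutation(vals)
        yield pd.DataFrame(out, index=comm.index, columns=pool)


def _null_subsets(
    rng: np.random.Generator, npool: int, k: int, n_null: int
) -> np.ndarray:
    """(n_null, k) matrix of uniform k-subsets of range(npool)."""
    keys = rng.random((n_null, npool))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _null_metrics(
    Dsub: np.ndarray,
    idx_sets: np.ndarray,
    metric: Metric,
    weights: np.ndarray | None,
) -> np.ndarray:
    """Metric value for each null identity set (optionally weighted)."""
    sub = Dsub[idx_sets[:, :, None], idx_sets[:, None, :]]
    k = idx_sets.shape[1]
    if metric == "mpd":
        if weights is None:
            return sub.sum(axis=(1, 2)) / (k * (k - 1))
        ww = weights[:, :, None] * weights[:, None, :]
        ww[:, np.arange(k), np.arange(k)] = 0.0
        return (sub * ww).sum(axis=(1, 2)) / ww.sum(axis=(1, 2))
    sub = sub.copy()
    sub[:, np.arange(k), np.arange(k)] = np.inf
    nearest = sub.min(axis=2)
    if weights is None:
        return nearest.mean(axis=1)
    return (nearest * weights).sum(axis=1) / weights.sum(axis=1)


def _rank_p(obs: float, nulls: np.ndarray) -> float:
    """Two-sided permutation p with the +1 correction."""
    n = len(nulls)
    lo = int((nulls <= obs + 1e-12).sum())
    hi = int((nulls >= obs - 1e-12).sum())
    return min(1.0, 2.0 * min(lo + 1, hi + 1) / (n + 1))


def ses(
    metric: Metric,
    comm: pd.DataFrame,
    D: PatristicMatrix,
    pool: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = False,
    null_model: Literal["pool", "shuffle"] = "pool",
) -> pd.DataFrame:
    """Standardised effect size of ``metric`` for every plot.

    Returns one row per plot: observed, null_mean, null_sd, ses, rank_p,
    n_null.  Plots with fewer than two species, or with a degenerate
    null (sd = 0), get NaN SES.  ``null_model='shuffle'`` replaces the
    per-plot pool draw with a single relabelling of the pool per
    replicate (tip-label shuffle), an alternative null that preserves
    co-occurrence structure.
    """
    if metric not in ("mpd", "mntd"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pool = list(pool) if pool is not None else list(comm.columns)
    pool_idx = _pool_indices(pool, D)
    Dsub = D.values[np.ix_(pool_idx, pool_idx)]
    npool = len(pool)
    col_in_pool = {s: i for i, s in enumerate(pool)}
    missing = set(comm.columns[(comm > 0).any()]) - set(pool)
    if missing:
        raise ValueError(f"observed species not in pool: {sorted(missing)}")

    fn = mpd if metric == "mpd" else mntd
    Dpool = PatristicMatrix(pool, Dsub)
    rng = np.random.default_rng([int(seed) % (2**31), 47])
    rows = []
    Y = np.zeros((len(comm), npool))
    for j, s in enumerate(comm.columns):
        Y[:, col_in_pool[s]] = comm[s].to_numpy(dtype=float)

    if null_model == "shuffle":
        perms = np.stack([rng.permutation(npool) for _ in range(n_null)])

    for i, plot in enumerate(comm.index):
        v = Y[i]
        obs = fn(v, Dpool, weighted=weighted)
        k = int((v > 0).sum())
        if k < 2 or not np.isfinite(obs):
            rows.append((plot, metric, obs, np.nan, np.nan, np.nan, np.nan, n_null))
            continue
        present = np.flatnonzero(v > 0)
        if null_model == "pool":
            idx_sets = _null_subsets(rng, npool, k, n_null)
            if weighted:
                vals = v[present]
                w = np.stack([rng.permutation(vals) for _ in range(n_null)])
            else:
                w = None
        else:  # tip-label shuffle: identities mapped through the permutation
            idx_sets = perms[:, present]
            w = np.broadcast_to(v[present], (n_null, k)) if weighted else None
        nulls = _null_metrics(Dsub, idx_sets, metric, w)
        sd = float(nulls.std(ddof=1))
        mean = float(nulls.mean())
        if sd <= 0:
            rows.append((plot, metric, obs, mean, sd, np.nan, np.nan, n_null))
            continue
        rows.append(
            (plot, metric, obs, mean, sd, (obs - mean) / sd, _rank_p(obs, nulls), n_null)
        )
    return pd.DataFrame(
        rows,
        columns=["unit", "metric", "observed", "null_mean", "null_sd", "ses",
                 "rank_p", "n_null"],
    ).set_index("unit")


def habitat_assemblage(comm: pd.DataFrame, habitats: pd.Series) -> pd.DataFrame:
    """Pool plots into habitat-scale assemblages (element-wise row sums)."""
    habitats = habitats.loc[comm.index]
    return comm.groupby(habitats).sum().sort_index()


# ---------------------------------------------------------------------------
# SES along gradients


@dataclass
class GradientRegression:
    """OLS of a per-plot SES on a single environmental predictor."""

    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def to_row(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def regress_ses(
    ses_table: pd.DataFrame, env: pd.DataFrame, predictor: str
) -> GradientRegression:
    """Ordinary least squares of SES against one predictor (e.g. elevation)."""
    if predictor not in env.columns:
        raise ValueError(f"predictor {predictor!r} not in environment table")
    merged = ses_table.join(env[predictor], how="inner").dropna(
        subset=["ses", predictor]
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 non-missing points for regression")
    x = merged[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    fit = stats.linregress(x, merged["ses"].to_numpy(dtype=float))
    metric = ses_table["metric"].iloc[0] if "metric" in ses_table else "ses"
    return GradientRegression(
        response=f"ses_{metric}",
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(merged),
    )
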