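"""Phylogenetic beta diversity: Dpw, Dnn, SES, Mantel partitioning.

Dpw is the mean patristic distance over all cross pairs of species from
two assemblages (shared species contribute their zero self-distance,
the "comdist" convention); Dnn averages, in both directions, each
species' distance to its nearest relative in the other assemblage.  Dpw
captures deep ("basal") turnover, Dnn shallow ("terminal") turnover.
Both are standardised against the same richness-preserving pool
randomisation used for the within-plot metrics, applied jointly to all
units of each null replicate; positive SES means assemblages are more
phylogenetically distinct than expected.

The association of phylogenetic dissimilarity with elevation distance
and geographic (great-circle) distance is quantified by Mantel and
partial Mantel permutation tests on the unfolded distance matrices —
the classic device for separating environmental filtering (beta ~
environment | space) from dispersal limitation (beta ~ space |
environment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core_io import PatristicMatrix

__all__ = [
    "dpw",
    "dnn",
    "BetaMatrices",
    "ses_beta",
    "SpatialDistances",
    "spatial_distances",
    "MantelResult",
    "mantel",
    "partial_mantel",
]

_EARTH_RADIUS_KM = 6371.0


def _present(community, D: PatristicMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Indices into D plus abundances for the species present."""
    if isinstance(community, pd.Series):
        comm = community[community > 0]
        return D.indices(comm.index), comm.to_numpy(dtype=float)
    if isinstance(community, dict):
        return _present(pd.Series(community), D)
    arr = np.asarray(community)
    if arr.dtype.kind in "UOS":
        return D.indices(arr), np.ones(len(arr))
    idx = np.flatnonzero(arr > 0)
    return idx, arr[idx].astype(float)


def dpw(c1, c2, D: PatristicMatrix, weighted: bool = False) -> float:
    """Mean pairwise patristic distance across two assemblages.

    Mean of D over all ordered cross pairs (s in c1, t in c2), including
    the zero self-distances of shared species; the weighted variant uses
    relative-abundance-product weights.  NaN if either side is empty.
    """
    i1, w1 = _present(c1, D)
    i2, w2 = _present(c2, D)
    if len(i1) == 0 or len(i2) == 0:
        return float("nan")
    sub = D.values[np.ix_(i1, i2)]
    if not weighted:
        return float(sub.mean())
    ww = np.outer(w1 / w1.sum(), w2 / w2.sum())
    return float((sub * ww).sum())


def dnn(c1, c2, D: PatristicMatrix, weighted: bool = False) -> float:
    """Mean nearest-neighbour distance between two assemblages.

    Symmetrised: the mean over c1's species of the minimum distance into
    c2 is averaged with the reverse direction (abundance-weighted means
    if ``weighted``).  Zero when the assemblages share all species.
    """
    i1, w1 = _present(c1, D)
    i2, w2 = _present(c2, D)
    if len(i1) == 0 or len(i2) == 0:
        return float("nan")
    sub = D.values[np.ix_(i1, i2)]
    near1 = sub.min(axis=1)
    near2 = sub.min(axis=0)
    if not weighted:
        return float((near1.mean() + near2.mean()) / 2.0)
    m1 = (near1 * w1).sum() / w1.sum()
    m2 = (near2 * w2).sum() / w2.sum()
    return float((m1 + m2) / 2.0)


# ---------------------------------------------------------------------------
# SES of beta metrics


@dataclass
class BetaMatrices:
    """Observed and standardised pairwise beta-diversity matrices."""

    unit_ids: list[str]
    metric: str
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    ses: np.ndarray
    n_null: int

    def frame(self, which: str = "ses") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.unit_ids, columns=self.unit_ids)


def ses_beta(
    comm: pd.DataFrame,
    D: PatristicMatrix,
    metric: Literal["dpw", "dnn"] = "dpw",
    pool: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = False,
) -> BetaMatrices:
    """SES of Dpw or Dnn for every pair of rows of ``comm``.

    Each null replicate redraws every unit's identities (richness and
    abundance multiset preserved, uniform pool draws) jointly, then the
    pairwise metric is recomputed; SES is per unit pair.  Degenerate
    null sd yields a NaN entry.
    """
    if metric not in ("dpw", "dnn"):
        raise ValueError(f"unknown beta metric {metric!r}")
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pool = list(pool) if pool is not None else list(comm.columns)
    missing = set(comm.columns[(comm > 0).any()]) - set(pool)
    if missing:
        raise ValueError(f"observed species not in pool: {sorted(missing)}")
    Dpool = D.reorder(pool)
    Dsub = Dpool.values
    npool = len(pool)
    n = len(comm)

    Y = np.zeros((n, npool))
    for j, s in enumerate(comm.columns):
        Y[:, Dpool.indices([s])[0]] = comm[s].to_numpy(dtype=float)

    rng = np.random.default_rng([int(seed) % (2**31), 53])
    rich = (Y > 0).sum(axis=1).astype(int)
    if (rich > npool).any():
        raise ValueError("a unit is richer than the species pool")
    # per-unit null identity sets (n_null, k_i), plus permuted abundances
    idx_sets: list[np.ndarray | None] = []
    w_sets: list[np.ndarray | None] = []
    for i in range(n):
        k = rich[i]
        if k == 0:
            idx_sets.append(None)
            w_sets.append(None)
            continue
        keys = rng.random((n_null, npool))
        idx_sets.append(np.argpartition(keys, k - 1, axis=1)[:, :k])
        if weighted:
            vals = Y[i, Y[i] > 0]
            w_sets.append(np.stack([rng.permutation(vals) for _ in range(n_null)]))
        else:
            w_sets.append(None)

    obs = np.zeros((n, n))
    mean = np.zeros((n, n))
    sd = np.zeros((n, n))
    z = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            if a == b:
                # self-comparison: Dnn is 0 by definition; Dpw is the
                # within-unit cross-pair mean including self pairs
                obs[a, b] = _pair_obs(Y[a], Y[a], Dsub, metric, weighted)
                mean[a, b] = sd[a, b] = z[a, b] = np.nan
                continue
            o = _pair_obs(Y[a], Y[b], Dsub, metric, weighted)
            obs[a, b] = obs[b, a] = o
            if idx_sets[a] is None or idx_sets[b] is None or not np.isfinite(o):
                mean[a, b] = mean[b, a] = np.nan
                sd[a, b] = sd[b, a] = np.nan
                z[a, b] = z[b, a] = np.nan
                continue
            nulls = _pair_nulls(
                Dsub, idx_sets[a], idx_sets[b], metric, w_sets[a], w_sets[b]
            )
            m = float(nulls.mean())
            s = float(nulls.std(ddof=1))
            mean[a, b] = mean[b, a] = m
            sd[a, b] = sd[b, a] = s
            z[a, b] = z[b, a] = (o - m) / s if s > 0 else np.nan
    return BetaMatrices(
        unit_ids=list(comm.index),
        metric=metric,
        observed=obs,
        null_mean=mean,
        null_sd=sd,
        ses=z,
        n_null=n_null,
    )


def _pair_obs(v1, v2, Dsub, metric, weighted):
    i1 = np.flatnonzero(v1 > 0)
    i2 = np.flatnonzero(v2 > 0)
    if len(i1) == 0 or len(i2) == 0:
        return float("nan")
    sub = Dsub[np.ix_(i1, i2)]
    if metric == "dpw":
        if not weighted:
            return float(sub.mean())
        ww = np.outer(v1[i1] / v1[i1].sum(), v2[i2] / v2[i2].sum())
        return float((sub * ww).sum())
    near1, near2 = sub.min(axis=1), sub.min(axis=0)
    if not weighted:
        return float((near1.mean() + near2.mean()) / 2.0)
    m1 = (near1 * v1[i1]).sum() / v1[i1].sum()
    m2 = (near2 * v2[i2]).sum() / v2[i2].sum()
    return float((m1 + m2) / 2.0)


def _pair_nulls(Dsub, idx1, idx2, metric, w1, w2):
    """Null metric values for one unit pair, vectorised over replicates."""
    sub = Dsub[idx1[:, :, None], idx2[:, None, :]]  # (n_null, k1, k2)
    if metric == "dpw":
        if w1 is None:
            return sub.mean(axis=(1, 2))
        ww = (w1 / w1.sum(axis=1, keepdims=True))[:, :, None] * (
            w2 / w2.sum(axis=1, keepdims=True)
        )[:, None, :]
        return (sub * ww).sum(axis=(1, 2))
    near1 = sub.min(axis=2)
    near2 = sub.min(axis=1)
    if w1 is None:
        return (near1.mean(axis=1) + near2.mean(axis=1)) / 2.0
    m1 = (near1 * w1).sum(axis=1) / w1.sum(axis=1)
    m2 = (near2 * w2).sum(axis=1) / w2.sum(axis=1)
    return (m1 + m2) / 2.0


# ---------------------------------------------------------------------------
# Spatial distances


@dataclass
class SpatialDistances:
    """Geographic (km) and elevation (m) distance matrices over units."""

    unit_ids: list[str]
    geographic: np.ndarray
    elevation: np.ndarray

    def frame(self, which: str = "geographic") -> pd.DataFrame:
        return pd.DataFrame(
            getattr(self, which), index=self.unit_ids, columns=self.unit_ids
        )


def spatial_distances(env: pd.DataFrame) -> SpatialDistances:
    """Great-circle and elevation-difference distances between plots.

    Geographic distance is haversine on latitude/longitude (Earth radius
    6,371 km); with latitude only, the meridian arc is used.  Elevation
    distance is the absolute difference in metres.
    """
    if "latitude" not in env.columns:
        raise ValueError("environment table lacks latitude")
    lat = np.deg2rad(env["latitude"].to_numpy(dtype=float))
    bad = env.index[~np.isfinite(lat)]
    if len(bad):
        raise ValueError(f"plots with missing coordinates: {list(bad)}")
    if "longitude" in env.columns and env["longitude"].notna().all():
        lon = np.deg2rad(env["longitude"].to_numpy(dtype=float))
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        )
        geo = 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    else:
        geo = _EARTH_RADIUS_KM * np.abs(lat[:, None] - lat[None, :])
    elev = env["elevation"].to_numpy(dtype=float)
    if not np.isfinite(elev).all():
        raise ValueError("plots with missing elevation")
    return SpatialDistances(
        unit_ids=list(env.index),
        geographic=geo,
        elevation=np.abs(elev[:, None] - elev[None, :]),
    )


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass
class MantelResult:
    """Matrix-correlation statistic with its permutation p-value."""

    kind: Literal["simple", "partial"]
    r: float
    p_value: float
    n_perm: int
    n_units: int
    alternative: str
    matrices: tuple[str, ...] = ("X", "Y")
    conditioned_on: str | None = None

    def to_row(self) -> dict:
        return {
            "kind": self.kind,
            "matrix_x": self.matrices[0],
            "matrix_y": self.matrices[1],
            "conditioned_on": self.conditioned_on or "",
            "r": self.r,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n_units": self.n_units,
            "alternative": self.alternative,
        }


def _check_square(M, name) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} is not a square matrix")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError(f"{name} is not symmetric")
    return M


def _triangle(M: np.ndarray, iu) -> np.ndarray:
    return M[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def _perm_triangles(Y: np.ndarray, iu, rng, n_perm: int):
    for _ in range(n_perm):
        p = rng.permutation(Y.shape[0])
        yield Y[p[iu[0]], p[iu[1]]]


def _perm_p(r_obs: float, r_perm: np.ndarray, alternative: str) -> float:
    n = len(r_perm)
    if alternative == "greater":
        cnt = (r_perm >= r_obs - 1e-12).sum()
    elif alternative == "less":
        cnt = (r_perm <= r_obs + 1e-12).sum()
    elif alternative == "two-sided":
        cnt = (np.abs(r_perm) >= abs(r_obs) - 1e-12).sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + cnt) / (n + 1))


def mantel(
    X,
    Y,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    names: tuple[str, str] = ("X", "Y"),
) -> MantelResult:
    """Mantel test: Pearson correlation of unfolded distance matrices.

    ``r`` correlates the upper off-diagonal triangles; significance is
    obtained by simultaneously permuting rows and columns of ``Y``.
    One-sided ("greater", the usual distance-decay alternative) by
    default.
    """
    X = _check_square(X, "X")
    Y = _check_square(Y, "Y")
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y have different sizes")
    if n < 4:
        raise ValueError("need at least 4 units for a Mantel test")
    iu = np.triu_indices(n, k=1)
    x = _triangle(X, iu)
    y = _triangle(Y, iu)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a distance matrix triangle")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng([int(seed) % (2**31), 59])
    r_perm = np.array([_pearson(x, yt) for yt in _perm_triangles(Y, iu, rng, n_perm)])
    return MantelResult(
        kind="simple",
        r=r_obs,
        p_value=_perm_p(r_obs, r_perm, alternative),
        n_perm=n_perm,
        n_units=n,
        alternative=alternative,
        matrices=names,
    )


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    den = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
    if den == 0:
        raise ValueError("conditioning matrix is collinear with X or Y")
    return float((rxy - rxz * ryz) / den)


def partial_mantel(
    X,
    Y,
    Z,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    names: tuple[str, str, str] = ("X", "Y", "Z"),
) -> MantelResult:
    """Partial Mantel test of X ~ Y holding Z constant.

    The statistic is the first-order partial correlation of the unfolded
    triangles; the null distribution permutes rows/columns of ``X`` and
    recomputes the partial statistic (r_YZ stays fixed).
    """
    X = _check_square(X, "X")
    Y = _check_square(Y, "Y")
    Z = _check_square(Z, "Z")
    n = X.shape[0]
    if Y.shape[0] != n or Z.shape[0] != n:
        raise ValueError("matrices have different sizes")
    if n < 4:
        raise ValueError("need at least 4 units for a partial Mantel test")
    iu = np.triu_indices(n, k=1)
    x, y, z = X[iu], Y[iu], Z[iu]
    for v, nm in ((x, "X"), (y, "Y"), (z, "Z")):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {nm} triangle")
    ryz = _pearson(y, z)
    r_obs = _partial_r(_pearson(x, y), _pearson(x, z), ryz)
    rng = np.random.default_rng([int(seed) % (2**31), 61])
    r_perm = np.empty(n_perm)
    for i, xt in enumerate(_perm_triangles(X, iu, rng, n_perm)):
        r_perm[i] = _partial_r(_pearson(xt, y), _pearson(xt, z), ryz)
    return MantelResult(
        kind="partial",
        r=r_obs,
        p_value=_perm_p(r_obs, r_perm, alternative),
        n_perm=n_perm,
        n_units=n,
        alternative=alternative,
        matrices=names[:2],
        conditioned_on=names[2],
    )
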