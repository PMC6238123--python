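"""Dufrene-Legendre indicator species analysis (IndVal).

For species *s* and habitat *j*, specificity ``A`` is the mean abundance
of *s* in the plots of *j* divided by the sum of its mean abundances
across all habitats, and fidelity ``B`` is the fraction of the plots of
*j* that contain *s*.  Their product ``IndVal = A * B`` lies in [0, 1]:
it equals 1 exactly when the species occurs in every plot of one habitat
and nowhere else.  A species' indicator value is the maximum over
habitats; its significance is assessed by permuting the plot-to-habitat
labels (group sizes preserved) and comparing the observed maximum to the
permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndValTable", "indval", "indval_test"]


@dataclass
class IndValTable:
    """Per species x habitat components plus per-species summary.

    ``components`` is a long table (species, habitat, A, B, indval);
    ``summary`` has one row per species: best_habitat, indval, and, after
    a permutation test, p_value and n_perm.  Species with zero total
    abundance have undefined specificity and are excluded from testing.
    """

    components: pd.DataFrame
    summary: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if "p_value" not in self.summary:
            raise ValueError("run indval_test to obtain p-values")
        s = self.summary.dropna(subset=["p_value"])
        return s[s["p_value"] <= alpha]

    def to_frame(self) -> pd.DataFrame:
        """Flat output table: one row per species x habitat."""
        out = self.components.merge(
            self.summary.reset_index(), on="species", how="left", suffixes=("", "_best")
        )
        out["is_best"] = out["habitat"] == out["best_habitat"]
        return out


def _group_matrix(habitats: pd.Series) -> tuple[np.ndarray, list[str]]:
    labels = sorted(habitats.unique())
    member = np.stack([(habitats == h).to_numpy() for h in labels])
    return member.astype(float), labels


def _indval_components(Y: np.ndarray, member: np.ndarray):
    """A, B, indval arrays of shape (n_habitats, n_species)."""
    sizes = member.sum(axis=1)[:, None]
    mean_ab = (member @ Y) / sizes
    denom = mean_ab.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, mean_ab / denom, np.nan)
    B = (member @ (Y > 0)) / sizes
    return A, B, A * B


def indval(comm: pd.DataFrame, habitats: pd.Series) -> IndValTable:
    """IndVal statistics (no significance test).

    ``habitats`` maps each plot of ``comm`` to a habitat label; at least
    two habitats, each with at least one plot, are required.
    """
    habitats = habitats.loc[comm.index]
    member, labels = _group_matrix(habitats)
    if len(labels) < 2:
        raise ValueError("need at least 2 habitats for indicator analysis")
    Y = comm.to_numpy(dtype=float)
    A, B, iv = _indval_components(Y, member)

    comp = pd.DataFrame(
        {
            "species": np.repeat(comm.columns, len(labels)),
            "habitat": np.tile(labels, len(comm.columns)),
            "A": A.T.ravel(),
            "B": B.T.ravel(),
            "indval": iv.T.ravel(),
        }
    )
    with np.errstate(invalid="ignore"):
        best = np.nanargmax(np.where(np.isnan(iv), -1.0, iv), axis=0)
    stat = iv[best, np.arange(iv.shape[1])]
    summary = pd.DataFrame(
        {
            "best_habitat": [labels[b] if np.isfinite(stat[i]) else None
                             for i, b in enumerate(best)],
            "indval": stat,
        },
        index=pd.Index(comm.columns, name="species"),
    )
    return IndValTable(components=comp, summary=summary)


def indval_test(
    comm: pd.DataFrame,
    habitats: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> IndValTable:
    """IndVal with a permutation test of each species' maximum statistic.

    Habitat labels are permuted across plots ``n_perm`` times (group
    sizes preserved); ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful test")
    table = indval(comm, habitats)
    habitats = habitats.loc[comm.index]
    member, _labels = _group_matrix(habitats)
    Y = comm.to_numpy(dtype=float)
    obs = table.summary["indval"].to_numpy()

    rng = np.random.default_rng([int(seed) % (2**31), 41])
    n = Y.shape[0]
    exceed = np.zeros(Y.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _A, _B, iv = _indval_components(Y[perm], member)
        exceed += np.where(np.isnan(iv), -1.0, iv).max(axis=0) >= obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[~np.isfinite(obs)] = np.nan

    table.summary["p_value"] = p
    table.summary["n_perm"] = n_perm
    return table
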