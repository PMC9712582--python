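"""Dufrene-Legendre indicator value (IndVal) analysis with a Monte Carlo null.

For taxon *i* and sample group *j* (here: SOM subclusters),

    IndVal_ij = A_ij * F_ij * 100

where specificity ``A_ij`` is the mean abundance of taxon *i* in group *j*
divided by the sum of its mean abundances over all groups, and fidelity
``F_ij`` is the fraction of group-*j* samples in which the taxon occurs.
IndVal reaches 100 exactly when the taxon occurs in every sample of one
group and nowhere else.  The analysis runs on *untransformed* counts.

Significance of each taxon's maximum IndVal is assessed by shuffling group
labels across samples (group sizes preserved); the p-value is
``(1 + #{permuted max >= observed max}) / (1 + n_permutations)`` so it can
never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorValueAnalysis",
    "IndValResults",
    "specificity_fidelity",
    "indval_scores",
    "indval_significance",
]


def _group_matrix(groups: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """(n_groups, n_samples) row-stochastic membership matrix (rows sum to 1)."""
    G = (groups[None, :] == levels[:, None]).astype(float)
    return G / G.sum(axis=1, keepdims=True)


def _a_f(X: np.ndarray, Gm: np.ndarray):
    means = Gm @ X                       # per-group mean abundance
    colsum = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(colsum > 0, means / colsum, 0.0)
    F = Gm @ (X > 0)
    return A, F


def specificity_fidelity(matrix: pd.DataFrame, groups: pd.Series):
    """Per taxon x group specificity A and fidelity F (both in [0, 1]).

    ``groups`` maps every sample code of ``matrix`` to its subcluster.
    Taxa with zero total abundance get an all-zero A row (they carry no
    indicator information).  A uses within-group *means*, so unequal group
    sizes do not bias specificity.
    """
    groups = groups.reindex(matrix.index)
    if groups.isna().any():
        bad = list(matrix.index[groups.isna()])
        raise ValueError(f"unlabelled samples: {bad}")
    levels = np.array(sorted(pd.unique(groups)))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for indicator analysis")
    Gm = _group_matrix(groups.to_numpy(), levels)
    A, F = _a_f(matrix.to_numpy(dtype=float), Gm)
    idx = pd.Index(levels, name="group")
    return (pd.DataFrame(A, index=idx, columns=matrix.columns),
            pd.DataFrame(F, index=idx, columns=matrix.columns))


def indval_scores(A: pd.DataFrame, F: pd.DataFrame):
    """IndVal = A * F * 100 plus each taxon's argmax group (ties -> first)."""
    for name, M in (("A", A), ("F", F)):
        v = M.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError(f"{name} entries must lie in [0, 1]")
    iv = A * F * 100.0
    best = iv.idxmax(axis=0)     # first occurrence on ties
    return iv, best, iv.max(axis=0)


def indval_significance(matrix: pd.DataFrame, groups: pd.Series,
                        n_permutations: int = 4999, seed: int = 0) -> pd.Series:
    """Permutation p-value of each taxon's maximum IndVal."""
    if n_permutations < 99:
        raise ValueError("need n_permutations >= 99")
    groups = groups.reindex(matrix.index)
    levels = np.array(sorted(pd.unique(groups)))
    g = groups.to_numpy()
    X = matrix.to_numpy(dtype=float)
    P = (X > 0).astype(float)
    Gm = _group_matrix(g, levels)
    A, F = _a_f(X, Gm)
    observed = (A * F * 100.0).max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_permutations):
        Gp = Gm[:, rng.permutation(len(g))]
        Ap, Fp = _a_f(X, Gp)
        exceed += (Ap * Fp * 100.0).max(axis=0) >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return pd.Series(p, index=matrix.columns, name="pvalue")


@dataclass
class IndValResults:
    """Fitted indicator analysis: A, F, IndVal tables and per-taxon tests."""

    A: pd.DataFrame
    F: pd.DataFrame
    indval: pd.DataFrame
    best_group: pd.Series
    max_indval: pd.Series
    pvalues: pd.Series
    n_permutations: int
    seed: int

    def summary(self, tiers=(0.001, 0.01, 0.05), alpha: float = 0.05) -> dict:
        """Counts of significant indicators per group, tier bands, fraction.

        Tier bands are disjoint: p <= tiers[0], (tiers[0], tiers[1]], ...
        A taxon counts for its argmax group when p <= alpha.
        """
        sig = self.pvalues <= alpha
        per_group = {g: int(((self.best_group == g) & sig).sum())
                     for g in self.indval.index}
        bands, lo = {}, 0.0
        for t in tiers:
            bands[t] = int(((self.pvalues > lo) & (self.pvalues <= t)).sum())
            lo = t
        return {
            "per_group": per_group,
            "tier_counts": bands,
            "n_significant": int(sig.sum()),
            "indicative_fraction": float(sig.mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        """Long table: taxon, group, A, F, IndVal, p (argmax row starred)."""
        rows = []
        for taxon in self.indval.columns:
            for g in self.indval.index:
                p = self.pvalues[taxon]
                star = ""
                if g == self.best_group[taxon]:
                    star = ("***" if p <= 0.001 else "**" if p <= 0.01
                            else "*" if p <= 0.05 else "")
                rows.append((taxon, g, self.A.loc[g, taxon],
                             self.F.loc[g, taxon], self.indval.loc[g, taxon],
                             p if g == self.best_group[taxon] else np.nan, star))
        return pd.DataFrame(rows, columns=["taxon", "group", "A", "F",
                                           "IndVal", "pvalue", "signif"])


class IndicatorValueAnalysis:
    """Model object: untransformed counts plus a sample-group labelling.

    Parameters
    ----------
    matrix : DataFrame
        Non-empty samples x taxa integer counts (untransformed).
    groups : Series
        Subcluster label per sample code.
    """

    def __init__(self, matrix: pd.DataFrame, groups: pd.Series):
        self.matrix = matrix
        self.groups = groups.reindex(matrix.index)
        if self.groups.isna().any():
            bad = list(matrix.index[self.groups.isna()])
            raise ValueError(f"unlabelled samples: {bad}")

    def fit(self, n_permutations: int = 4999, seed: int = 0) -> IndValResults:
        A, F = specificity_fidelity(self.matrix, self.groups)
        iv, best, mx = indval_scores(A, F)
        p = indval_significance(self.matrix, self.groups, n_permutations, seed)
        return IndValResults(A, F, iv, best, mx, p, n_permutations, seed)
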