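"""Canonical correspondence analysis (CCA) of assemblages vs geochemistry.

CCA is correspondence analysis constrained so that ordination axes are
linear combinations of environmental variables.  The species table is
chi-square standardised (``Qbar = (P - r c') / sqrt(r c')`` with ``P`` the
proportion table and ``r, c`` its margins), row-weighted-regressed onto the
standardised environmental variables, and the fitted part eigen-decomposed
by SVD.  The sum of squares of ``Qbar`` is the total inertia; the fitted
sum of squares the constrained inertia.  Per-axis percentages are reported
both against total inertia (species-data variance) and constrained inertia
(species-environment relation).

Species preparation follows the classic CANOCO choices: square-root
transform and optional downweighting of rare taxa (taxa rarer than a fifth
of the commonest taxon's frequency are shrunk proportionally).
Significance of environmental variables uses Monte Carlo permutation of
the residuals under the fitted model (or free row permutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CanonicalCorrespondenceAnalysis",
    "CCAResults",
    "prepare_species",
    "screen_collinear",
]


def prepare_species(matrix: pd.DataFrame, downweight: bool = True) -> pd.DataFrame:
    """Square-root transform, optionally downweighting rare taxa.

    A taxon occurring in ``f`` samples with ``f < f_max / 5`` is multiplied
    by ``f / (f_max / 5)``; commoner taxa are untouched.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty species matrix")
    Y = np.sqrt(matrix.to_numpy(dtype=float))
    if downweight:
        freq = (matrix.to_numpy() > 0).sum(axis=0).astype(float)
        threshold = freq.max() / 5.0
        w = np.where(freq < threshold, freq / threshold, 1.0)
        Y = Y * w[None, :]
    return pd.DataFrame(Y, index=matrix.index, columns=matrix.columns)


def screen_collinear(env: pd.DataFrame, r_threshold: float = 0.9):
    """Greedy collinearity screen on absolute pairwise correlations.

    While any |r| exceeds the threshold, the member of the worst pair with
    the larger mean absolute correlation to everything else is dropped.
    Constant columns are excluded up front.  Returns
    ``(retained_env, report)`` where the report maps dropped column ->
    reason.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables to screen")
    report: dict[str, str] = {}
    keep = list(env.columns)
    for col in list(keep):
        if env[col].nunique() <= 1:
            keep.remove(col)
            report[col] = "constant column"
    while len(keep) >= 2:
        corr = env[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] <= r_threshold:
            break
        a, b = worst
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        drop = a if (mean_a, a) >= (mean_b, b) else b
        other = b if drop == a else a
        keep.remove(drop)
        report[drop] = (f"|r|={corr.loc[worst]:.3f} with {other} "
                        f"> threshold {r_threshold}")
    return env[keep], report


def _chi_square_standardise(Y: np.ndarray):
    if (Y < 0).any():
        raise ValueError("species matrix must be non-negative")
    row_tot = Y.sum(axis=1)
    if (row_tot <= 0).any():
        raise ValueError("species matrix has all-zero samples; drop them first")
    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0
    Qbar = (P[:, keep] - np.outer(r, c[keep])) / np.sqrt(np.outer(r, c[keep]))
    return Qbar, r, c[keep], keep


def _weighted_standardise(X: np.ndarray, r: np.ndarray):
    mean = r @ X
    Xc = X - mean
    sd = np.sqrt(r @ (Xc ** 2))
    sd = np.where(sd > 0, sd, 1.0)
    return Xc / sd


def _fit_projection(Qbar, r, Xstd):
    """Row-weighted projection of Qbar onto the env space; returns fitted part."""
    Xw = np.sqrt(r)[:, None] * Xstd
    B, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    return Xw @ B


def _dependent_columns(Xw: np.ndarray, names) -> list:
    rank, bad = 0, []
    for j in range(Xw.shape[1]):
        new = np.linalg.matrix_rank(Xw[:, : j + 1])
        if new == rank:
            bad.append(names[j])
        rank = new
    return bad


@dataclass
class CCAResults:
    """Constrained-ordination fit: eigenvalues, inertias and scores."""

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    species_scores: pd.DataFrame
    site_scores: pd.DataFrame       # linear-combination (constrained) scores
    biplot_scores: pd.DataFrame     # per environmental variable
    scaling: int
    dropped_samples: list = field(default_factory=list)
    dropped_taxa: list = field(default_factory=list)

    @property
    def prop_species_variance(self) -> np.ndarray:
        """Per-axis % of species-data variance (eigenvalue / total inertia)."""
        return self.eigenvalues / self.total_inertia * 100.0

    @property
    def prop_species_env(self) -> np.ndarray:
        """Per-axis % of the species-environment relation."""
        return self.eigenvalues / self.constrained_inertia * 100.0

    def summary(self) -> pd.DataFrame:
        axes = [f"CCA{i + 1}" for i in range(len(self.eigenvalues))]
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "species_variance_pct": self.prop_species_variance,
            "species_env_pct": self.prop_species_env,
        }, index=axes)


class CanonicalCorrespondenceAnalysis:
    """Model object: a prepared species matrix and environmental variables.

    Samples with missing environmental values are dropped from this
    analysis only (recorded on the results); taxa absent from every
    retained sample are dropped likewise.

    Parameters
    ----------
    species : DataFrame
        Samples x taxa, non-negative reals (see :func:`prepare_species`).
    env : DataFrame
        Samples x variables; standardised internally with CA row weights.
    scaling : int
        1 focuses on inter-sample distances (site scores scaled by the
        square-root eigenvalues), 2 on inter-taxon chi-square distances.
    """

    def __init__(self, species: pd.DataFrame, env: pd.DataFrame, scaling: int = 1):
        env = env.reindex(species.index)
        complete = env.notna().all(axis=1) & (species.sum(axis=1) > 0)
        self.dropped_samples = list(species.index[~complete])
        self.species = species.loc[complete]
        self.env = env.loc[complete]
        if self.species.shape[0] < 2:
            raise ValueError("need >= 2 samples with complete environment rows")
        self.scaling = scaling

    def fit(self) -> CCAResults:
        Y = self.species.to_numpy(dtype=float)
        Qbar, r, c, keep = _chi_square_standardise(Y)
        taxa = list(self.species.columns[keep])
        dropped_taxa = list(self.species.columns[~keep])
        total = float((Qbar ** 2).sum())

        Xstd = _weighted_standardise(self.env.to_numpy(dtype=float), r)
        Xw = np.sqrt(r)[:, None] * Xstd
        if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
            bad = _dependent_columns(Xw, list(self.env.columns))
            raise ValueError(f"environment matrix is rank-deficient; "
                             f"dependent columns: {bad}")
        fitted = _fit_projection(Qbar, r, Xstd)
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        rank = min(Xw.shape[1], Qbar.shape[1], Qbar.shape[0] - 1)
        nz = s[:rank] > 1e-12 * max(s[0], 1.0) if len(s) else np.array([], bool)
        U, s, Vt = U[:, :rank][:, nz], s[:rank][nz], Vt[:rank][nz]
        eig = s ** 2
        constrained = float((fitted ** 2).sum())

        axes = [f"CCA{i + 1}" for i in range(len(eig))]
        u = U / np.sqrt(r)[:, None]           # unit-variance site scores
        v = Vt.T / np.sqrt(c)[:, None]        # unit-variance species scores
        if self.scaling == 1:
            site, spec = u * s[None, :], v
        else:
            site, spec = u, v * s[None, :]
        # biplot arrows: weighted correlation of env with unit site scores
        bip = (np.sqrt(r)[:, None] * Xstd).T @ U
        bipnorm = np.linalg.norm(Xw, axis=0)
        bip = bip / bipnorm[:, None]

        return CCAResults(
            eigenvalues=eig,
            total_inertia=total,
            constrained_inertia=constrained,
            species_scores=pd.DataFrame(spec, index=taxa, columns=axes),
            site_scores=pd.DataFrame(site, index=self.species.index, columns=axes),
            biplot_scores=pd.DataFrame(bip, index=self.env.columns, columns=axes),
            scaling=self.scaling,
            dropped_samples=self.dropped_samples,
            dropped_taxa=dropped_taxa,
        )

    def variance_by_variable(self) -> pd.DataFrame:
        """Marginal % of total inertia explained by each variable alone."""
        Y = self.species.to_numpy(dtype=float)
        Qbar, r, _c, _keep = _chi_square_standardise(Y)
        total = float((Qbar ** 2).sum())
        rows = []
        for col in self.env.columns:
            Xstd = _weighted_standardise(self.env[[col]].to_numpy(float), r)
            fitted = _fit_projection(Qbar, r, Xstd)
            rows.append(float((fitted ** 2).sum()) / total * 100.0)
        return pd.DataFrame({"marginal_pct": rows}, index=self.env.columns)

    def permutation_test(self, variable: str, n_permutations: int = 999,
                         seed: int = 0, method: str = "full") -> dict:
        """Monte Carlo significance of one variable's constraint.

        ``method="full"`` permutes the residuals of the fitted
        single-constraint model (permutation under the full model);
        ``"free"`` permutes the variable's rows freely.  The p-value is
        ``(1 + #{F* >= F}) / (1 + n_permutations)``.
        """
        if n_permutations < 99:
            raise ValueError("need n_permutations >= 99")
        if variable not in self.env.columns:
            raise KeyError(f"unknown variable {variable!r}")
        Y = self.species.to_numpy(dtype=float)
        Qbar, r, _c, _keep = _chi_square_standardise(Y)
        total = float((Qbar ** 2).sum())
        n = Qbar.shape[0]
        x = self.env[[variable]].to_numpy(dtype=float)

        def pseudo_f(Q, xcol):
            Xstd = _weighted_standardise(xcol, r)
            fitted = _fit_projection(Q, r, Xstd)
            ca = float((fitted ** 2).sum())
            resid = float((Q ** 2).sum()) - ca
            return ca / (resid / (n - 2))

        f_obs = pseudo_f(Qbar, x)
        rng = np.random.default_rng(seed)
        exceed = 0
        if method == "full":
            # ter Braak-style: permute the residuals of the fitted (full)
            # model, rebuild the response on the reduced (empty) model
            Xstd = _weighted_standardise(x, r)
            fitted = _fit_projection(Qbar, r, Xstd)
            resid = Qbar - fitted
            for _ in range(n_permutations):
                Qp = resid[rng.permutation(n)]
                exceed += pseudo_f(Qp, x) >= f_obs
        elif method == "free":
            for _ in range(n_permutations):
                exceed += pseudo_f(Qbar, x[rng.permutation(n)]) >= f_obs
        else:
            raise ValueError("method must be 'full' or 'free'")
        p = (1.0 + exceed) / (1.0 + n_permutations)
        return {"variable": variable, "pseudo_F": f_obs, "pvalue": p,
                "n_permutations": n_permutations, "method": method}
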