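"""Among-core differences in relative taxon abundance via Poisson GLMs.

The question: can one sediment core represent the whole site?  Counts of
every taxon in every sample are modelled with a Poisson family and log
link, with ``ln(sample volume)`` entered as an offset so that effects act
on counts per unit sediment volume.  Sample age is converted to a factor
(default 6 levels, quantile-binned within the cores' age-overlap window)
and entered as a fixed main effect.  A core x taxon interaction captures
among-core differences in *relative* abundance; candidate fixed-effect
structures are compared by small-sample AICc, and post-hoc Wald contrasts
on the interaction identify the taxa driving the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "build_count_table",
    "CoreAbundanceGLM",
    "PoissonGLMResults",
    "aicc_selection",
    "interaction_contrasts",
]

_TERM_FORMULAS = {
    "core": "C(core)",
    "taxon": "C(taxon)",
    "age": "C(age_category)",
    "core:taxon": "C(core):C(taxon)",
    "core:age": "C(core):C(age_category)",
    "age:taxon": "C(age_category):C(taxon)",
}


def build_count_table(matrix: pd.DataFrame, meta: pd.DataFrame,
                      cores: list[str] | None = None, n_age_levels: int = 6,
                      aggregate: bool = False) -> pd.DataFrame:
    """Zero-filled long count table over the core x age x taxon grid.

    Samples outside ``cores``, without an age estimate, or outside the
    cores' common age-overlap window are excluded.  Ages are binned into
    ``n_age_levels`` quantile categories of the retained samples; every
    category must be represented in every core.  By default one row per
    sample x taxon is kept (offset = ln(sample volume)); with
    ``aggregate=True`` counts are summed within (core, age category,
    taxon) and offsets combine as ln(summed volume).
    """
    meta = meta.loc[matrix.index]
    keep = meta["age_mean_AD"].notna()
    if cores is not None:
        keep &= meta["core_id"].isin(cores)
    meta = meta.loc[keep]
    if meta["core_id"].nunique() < 2:
        raise ValueError("need at least 2 cores with aged samples")
    lo = meta.groupby("core_id")["age_mean_AD"].min().max()
    hi = meta.groupby("core_id")["age_mean_AD"].max().min()
    if lo >= hi:
        raise ValueError("cores have no overlapping age window")
    meta = meta.loc[(meta["age_mean_AD"] >= lo) & (meta["age_mean_AD"] <= hi)]

    cat = pd.qcut(meta["age_mean_AD"], q=n_age_levels,
                  labels=range(1, n_age_levels + 1), duplicates="raise")
    counts_per_cell = pd.crosstab(meta["core_id"], cat)
    if (counts_per_cell == 0).any().any() or \
            counts_per_cell.shape[1] < n_age_levels:
        raise ValueError(f"an age category is empty for some core; "
                         f"reduce n_age_levels below {n_age_levels}")

    sub = matrix.loc[meta.index]
    long = sub.stack().rename("count").reset_index()
    long.columns = ["sample_code", "taxon", "count"]
    long["core"] = meta.loc[long["sample_code"], "core_id"].to_numpy()
    long["age_category"] = cat.loc[long["sample_code"]].to_numpy()
    long["offset"] = np.log(meta.loc[long["sample_code"], "volume_cm3"].to_numpy())
    if aggregate:
        vol = np.exp(long["offset"])
        long = (long.assign(volume=vol)
                .groupby(["core", "age_category", "taxon"], observed=True)
                .agg(count=("count", "sum"), volume=("volume", "sum"))
                .reset_index())
        long["offset"] = np.log(long.pop("volume"))
    return long


@dataclass
class PoissonGLMResults:
    """Fitted Poisson GLM: coefficients, likelihood and diagnostics."""

    params: pd.Series
    llf: float
    df_model: int
    df_resid: int
    deviance: float
    fitted: np.ndarray
    converged: bool
    terms: tuple
    _sm_results: object = None

    @property
    def k_params(self) -> int:
        return len(self.params)

    def summary(self):
        return self._sm_results.summary()


class CoreAbundanceGLM:
    """Model object: a long count table plus a fixed-effect structure.

    ``terms`` is a subset of ``{"core", "taxon", "age", "core:taxon",
    "core:age", "age:taxon"}``; the offset always enters with coefficient 1.
    """

    def __init__(self, data: pd.DataFrame, terms=("core", "taxon",
                                                  "core:taxon", "age")):
        unknown = [t for t in terms if t not in _TERM_FORMULAS]
        if unknown:
            raise ValueError(f"unknown terms {unknown}")
        self.data = data.reset_index(drop=True)
        self.terms = tuple(terms)

    @property
    def formula(self) -> str:
        rhs = " + ".join(_TERM_FORMULAS[t] for t in self.terms) or "1"
        return f"count ~ {rhs}"

    def fit(self) -> PoissonGLMResults:
        """Maximum likelihood via iteratively reweighted least squares."""
        if "core:taxon" in self.terms:
            cell = self.data.groupby(["core", "taxon"], observed=True)["count"].sum()
            dead = cell[cell == 0]
            if len(dead):
                warnings.warn(f"{len(dead)} all-zero core x taxon strata; "
                              "their interaction effects are weakly identified",
                              stacklevel=2)
        model = smf.glm(self.formula, data=self.data,
                        family=sm.families.Poisson(),
                        offset=self.data["offset"].to_numpy())
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise ValueError("design matrix is rank-deficient after dummy coding")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(maxiter=100, tol=1e-10)
        return PoissonGLMResults(
            params=res.params, llf=float(res.llf),
            df_model=int(res.df_model), df_resid=int(res.df_resid),
            deviance=float(res.deviance), fitted=np.asarray(res.fittedvalues),
            converged=bool(res.converged), terms=self.terms, _sm_results=res)


def _aicc(llf: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_selection(data: pd.DataFrame, candidates: dict) -> pd.DataFrame:
    """Fit candidate fixed-effect structures and rank them by AICc.

    ``candidates`` maps model name -> term tuple.  Returns a table with
    log-likelihood, parameter count, AICc, delta-AICc and Akaike weights,
    sorted best first; failed fits are dropped with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    n = len(data)
    rows = {}
    for name, terms in candidates.items():
        try:
            fit = CoreAbundanceGLM(data, terms).fit()
        except Exception as exc:  # noqa: BLE001 - candidate failure is survivable
            warnings.warn(f"candidate {name!r} failed: {exc}", stacklevel=2)
            continue
        rows[name] = (fit.llf, fit.k_params, _aicc(fit.llf, fit.k_params, n))
    table = pd.DataFrame(rows, index=["loglik", "k", "AICc"]).T
    table["k"] = table["k"].astype(int)
    table = table.sort_values("AICc")
    table["delta_AICc"] = table["AICc"] - table["AICc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_AICc"])
    table["weight"] = rel / rel.sum()
    return table


def interaction_contrasts(fit: PoissonGLMResults, pairs=None,
                          adjust: str = "holm") -> pd.DataFrame:
    """Per-taxon Wald contrasts of among-core log relative abundance.

    For each core pair and taxon the contrast is the core difference in
    linear predictor for that taxon minus the across-taxa mean core
    difference, i.e. the interaction part only (a core's overall abundance
    level cancels).  Chi-square p-values are Holm-adjusted; rows are
    ranked by absolute contrast size.
    """
    res = fit._sm_results
    if "core:taxon" not in fit.terms:
        raise ValueError("fit does not include a core:taxon interaction")
    data = res.model.data.frame
    cores = sorted(data["core"].unique())
    taxa = sorted(data["taxon"].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cores) for b in cores[i + 1:]]
    for a, b in pairs:
        if a not in cores or b not in cores:
            raise KeyError(f"core pair ({a}, {b}) absent from design")

    # design rows for one reference cell grid (age fixed, offset irrelevant)
    grid = pd.DataFrame([(c, t) for c in cores for t in taxa],
                        columns=["core", "taxon"])
    grid["age_category"] = data["age_category"].iloc[0]
    import patsy
    X = np.asarray(patsy.dmatrix(res.model.data.design_info, grid))
    X = X.reshape(len(cores), len(taxa), -1)
    beta = res.params.to_numpy()
    cov = res.cov_params().to_numpy()

    rows = []
    for a, b in pairs:
        ia, ib = cores.index(a), cores.index(b)
        D = X[ia] - X[ib]                 # (n_taxa, p) per-taxon core difference
        D = D - D.mean(axis=0, keepdims=True)
        est = D @ beta
        var = np.einsum("ip,pq,iq->i", D, cov, D)
        stat = np.where(var > 0, est ** 2 / var, 0.0)
        pvals = scipy.stats.chi2.sf(stat, df=1)
        # all-zero strata inflate both estimate and variance; flag, rank last
        ok = var < 1e4
        for t, e, s, p, i in zip(taxa, est, stat, pvals, ok):
            rows.append((a, b, t, e, s, p, bool(i)))
    out = pd.DataFrame(rows, columns=["core_a", "core_b", "taxon",
                                      "estimate", "wald_chi2", "pvalue",
                                      "identified"])
    if adjust == "holm":
        out["pvalue_adj"] = _holm(out["pvalue"].to_numpy())
    elif adjust == "none":
        out["pvalue_adj"] = out["pvalue"]
    else:
        raise ValueError("adjust must be 'holm' or 'none'")
    out["_rank"] = np.where(out["identified"], np.abs(out["estimate"]), -np.inf)
    return (out.sort_values("_rank", ascending=False)
            .drop(columns="_rank").reset_index(drop=True))


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    stepped = (m - np.arange(m)) * p[order]
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
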