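import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from palaeosom import abundance
from palaeosom.abundance import (CoreAbundanceGLM, _aicc, _holm,
                                 aicc_selection, build_count_table,
                                 interaction_contrasts)


@pytest.fixture(scope="module")
def long_counts(study_scenario):
    matrix = study_scenario["matrix"].iloc[:, :12]
    return build_count_table(matrix, study_scenario["sample"],
                             cores=["W1", "W2", "W4"], n_age_levels=6)


def test_build_count_table_grid(long_counts, study_scenario):
    # grid complete: every (core, age, taxon) combination has rows
    grid = long_counts.groupby(["core", "age_category", "taxon"],
                               observed=True).size()
    assert (grid > 0).all()
    assert len(grid) == 3 * 6 * 12
    # zero-filled: taxa absent from a sample appear with count 0
    assert (long_counts["count"] == 0).any()
    assert set(long_counts["core"]) == {"W1", "W2", "W4"}


def test_age_binning_is_monotone(long_counts, study_scenario):
    meta = study_scenario["sample"]
    per_sample = long_counts.drop_duplicates("sample_code")
    ages = meta.loc[per_sample["sample_code"], "age_mean_AD"].to_numpy()
    cats = per_sample["age_category"].astype(int).to_numpy()
    order = np.argsort(ages)
    assert (np.diff(cats[order]) >= 0).all()


def test_build_count_table_errors(study_scenario):
    matrix = study_scenario["matrix"].iloc[:, :5]
    meta = study_scenario["sample"]
    with pytest.raises(ValueError, match="reduce n_age_levels"):
        build_count_table(matrix, meta, cores=["W1", "W2", "W4"],
                          n_age_levels=25)
    with pytest.raises(ValueError, match="2 cores"):
        build_count_table(matrix, meta, cores=["W1"])


def test_aggregated_table(study_scenario):
    matrix = study_scenario["matrix"].iloc[:, :5]
    agg = build_count_table(matrix, study_scenario["sample"],
                            cores=["W1", "W2", "W4"], n_age_levels=4,
                            aggregate=True)
    assert len(agg) == 3 * 4 * 5
    per = build_count_table(matrix, study_scenario["sample"],
                            cores=["W1", "W2", "W4"], n_age_levels=4)
    assert agg["count"].sum() == per["count"].sum()


def test_intercept_only_closed_form(long_counts):
    fit = CoreAbundanceGLM(long_counts, ()).fit()
    expected = np.log(long_counts["count"].sum()
                      / np.exp(long_counts["offset"]).sum())
    assert fit.params.iloc[0] == pytest.approx(expected, abs=1e-10)


def test_saturated_model_zero_deviance(study_scenario):
    matrix = study_scenario["matrix"].iloc[:, :4]
    agg = build_count_table(matrix, study_scenario["sample"],
                            cores=["W2", "W4"], n_age_levels=2,
                            aggregate=True)
    # core x taxon x age saturates the aggregated grid
    fit = CoreAbundanceGLM(
        agg, ("core", "taxon", "age", "core:taxon", "core:age",
              "age:taxon")).fit()
    if fit.k_params == len(agg):  # fully saturated
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(fit.fitted.sum(), agg["count"].sum(),
                               rtol=1e-8)


def test_glm_matches_direct_likelihood_oracle():
    """IRLS coefficients equal a direct optimisation of the Poisson
    log-likelihood on a small fixture."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "core": np.repeat(["A", "B"], 12),
        "taxon": list(np.tile(["t1", "t2", "t3"], 8)),
        "age_category": list(np.tile([1, 2], 12)),
        "offset": np.log(rng.uniform(5, 70, 24)),
    })
    eta = 0.3 + (data["core"] == "B") * 0.5 + (data["taxon"] == "t2") * 0.8
    data["count"] = rng.poisson(np.exp(eta + data["offset"] - 3.0))
    fit = CoreAbundanceGLM(data, ("core", "taxon", "age")).fit()

    X = fit._sm_results.model.exog
    y = data["count"].to_numpy()
    off = data["offset"].to_numpy()

    def nll(beta):
        mu = np.exp(X @ beta + off)
        return mu.sum() - y @ (X @ beta + off)

    res = scipy.optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                                  options={"gtol": 1e-12, "maxiter": 500})
    np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-6)


def test_offset_shift_exactness(long_counts):
    """Doubling all volumes shifts only the intercept, by -ln 2."""
    fit1 = CoreAbundanceGLM(long_counts, ("core", "taxon", "age")).fit()
    doubled = long_counts.copy()
    doubled["offset"] = doubled["offset"] + np.log(2.0)
    fit2 = CoreAbundanceGLM(doubled, ("core", "taxon", "age")).fit()
    p1, p2 = fit1.params, fit2.params
    assert p2["Intercept"] - p1["Intercept"] == pytest.approx(-np.log(2),
                                                              abs=1e-8)
    rest = p1.index.drop("Intercept")
    np.testing.assert_allclose(p1[rest], p2[rest], atol=1e-8)


def test_score_equation_and_irls_deviance(long_counts):
    fit = CoreAbundanceGLM(long_counts, ("core", "taxon", "age")).fit()
    assert fit.converged
    np.testing.assert_allclose(fit.fitted.sum(), long_counts["count"].sum(),
                               rtol=1e-8)
    # first entries are initialisation artifacts of the IRLS history
    dev = np.asarray(fit._sm_results.fit_history["deviance"])
    assert (np.diff(dev)[2:] <= 1e-8).all()


def test_aicc_formula_and_large_n_limit():
    ll, k = -1234.5, 20
    assert _aicc(ll, k, 100) == pytest.approx(
        -2 * ll + 2 * k + 2 * k * (k + 1) / (100 - k - 1))
    assert _aicc(ll, k, 10 ** 6) == pytest.approx(-2 * ll + 2 * k, abs=1e-2)
    assert _aicc(ll, k, k + 1) == np.inf


def test_aicc_selection_table(long_counts):
    table = aicc_selection(long_counts, {
        "full": ("core", "taxon", "core:taxon", "age"),
        "main": ("core", "taxon", "age"),
        "main2": ("core", "taxon", "age"),
    })
    assert table["weight"].sum() == pytest.approx(1.0)
    assert table["AICc"].is_monotonic_increasing
    # duplicate candidates share identical AICc and split their weight
    assert table.loc["main", "AICc"] == pytest.approx(table.loc["main2", "AICc"])
    assert table.loc["main", "weight"] == pytest.approx(
        table.loc["main2", "weight"])
    with pytest.raises(ValueError):
        aicc_selection(long_counts, {"only": ("core",)})


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    p = rng.uniform(size=25)
    np.testing.assert_allclose(_holm(p), multipletests(p, method="holm")[1])


def _two_core_data(seed, shift_taxon=None, shift=np.log(4.0), n_taxa=6,
                   n_samples=12):
    rng = np.random.default_rng(seed)
    taxa = [f"t{j}" for j in range(n_taxa)]
    rows = []
    for core in ("A", "B"):
        for i in range(n_samples):
            vol = rng.uniform(5, 70)
            age = 1 + (i * 2) // n_samples
            base = rng.uniform(0.5, 2.0)
            for j, t in enumerate(taxa):
                eta = np.log(vol) + np.log(base) + 0.3 * j - 2.0
                if core == "B" and t == shift_taxon:
                    eta += shift
                rows.append((core, age, t, rng.poisson(np.exp(eta)),
                             np.log(vol)))
    return pd.DataFrame(rows, columns=["core", "age_category", "taxon",
                                       "count", "offset"])


def test_planted_shift_ranks_first():
    data = _two_core_data(3, shift_taxon="t2")
    fit = CoreAbundanceGLM(data, ("core", "taxon", "core:taxon", "age")).fit()
    contr = interaction_contrasts(fit)
    assert contr.iloc[0]["taxon"] == "t2"
    assert contr.iloc[0]["pvalue_adj"] < 0.05


def test_contrast_of_core_with_itself_is_zero():
    data = _two_core_data(4)
    fit = CoreAbundanceGLM(data, ("core", "taxon", "core:taxon", "age")).fit()
    contr = interaction_contrasts(fit, pairs=[("A", "A")])
    np.testing.assert_allclose(contr["estimate"], 0.0, atol=1e-10)
    with pytest.raises(KeyError):
        interaction_contrasts(fit, pairs=[("A", "Z")])


def test_contrasts_calibrated_under_null():
    """Identically generated cores: familywise error after Holm stays near
    the nominal 5% level (120 null datasets)."""
    any_sig = 0
    n_sets = 120
    for seed in range(n_sets):
        data = _two_core_data(1000 + seed)
        fit = CoreAbundanceGLM(data,
                               ("core", "taxon", "core:taxon", "age")).fit()
        contr = interaction_contrasts(fit)
        any_sig += int((contr["pvalue_adj"] <= 0.05).any())
    # binomial(120, 0.05) 99.9% upper tail is ~14
    assert any_sig <= 14


def test_requires_interaction_term(long_counts):
    fit = CoreAbundanceGLM(long_counts, ("core", "taxon", "age")).fit()
    with pytest.raises(ValueError, match="interaction"):
        interaction_contrasts(fit)
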