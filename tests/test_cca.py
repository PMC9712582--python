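import numpy as np
import pandas as pd
import pytest
import scipy.stats

from palaeosom.ordination import (CanonicalCorrespondenceAnalysis,
                                  prepare_species, screen_collinear)


def _random_species(seed, n=10, m=6):
    rng = np.random.default_rng(seed)
    Y = rng.poisson(3.0, size=(n, m)) + 1  # strictly positive, no zero margins
    return pd.DataFrame(Y, index=[f"s{i}" for i in range(n)],
                        columns=[f"t{j}" for j in range(m)])


def _ca_eigenvalues(Y):
    """Oracle: plain correspondence analysis via SVD of the chi-square
    standardised matrix."""
    Y = np.asarray(Y, dtype=float)
    P = Y / Y.sum()
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    s = np.linalg.svd(Q, compute_uv=False)
    return (s ** 2)[s ** 2 > 1e-12]


def test_prepare_species_transform_and_downweight():
    m = pd.DataFrame({"common": [1, 4, 9, 16, 0],
                      "rare": [4, 0, 0, 0, 0]}, index=list("abcde"))
    plain = prepare_species(m, downweight=False)
    np.testing.assert_allclose(plain["common"], [1, 2, 3, 4, 0])
    down = prepare_species(m, downweight=True)
    # f_max = 4, threshold 0.8, rare taxon has f = 1 -> weight 1/0.8 capped? no:
    # f < threshold is false (1 >= 0.8 fails -> 1 > 0.8), weight 1 stays.
    np.testing.assert_allclose(down["common"], plain["common"])


def test_downweight_half_weight():
    """A taxon occurring in f_max/10 samples gets weight 0.5."""
    n = 20
    m = pd.DataFrame(0, index=range(n), columns=["common", "rare"])
    m["common"] = 1          # present in all 20 samples
    m.iloc[:2, 1] = 9        # rare: present in 2 = f_max/10 samples
    out = prepare_species(m, downweight=True)
    assert out.iloc[0]["rare"] == pytest.approx(0.5 * 3.0)


def test_screen_collinear():
    rng = np.random.default_rng(0)
    n = 400
    K = rng.normal(1.0, 0.3, n)
    C = rng.normal(size=n)
    env = pd.DataFrame({
        "K": K, "Na": K + 0.05 * C + rng.normal(0, 0.01, n),
        "Ca": rng.normal(10, 2, n), "C": C, "const": 1.0})
    env["Mg"] = 0.35 * env["Ca"] + rng.normal(0, 0.1, n)
    kept, report = screen_collinear(env, r_threshold=0.9)
    assert "const" in report and "constant" in report["const"]
    assert ("Na" in report) != ("K" in report)      # one of the pair dropped
    assert "Na" in report                           # Na leans on C too
    assert ("Mg" in report) != ("Ca" in report)
    kept_all, report2 = screen_collinear(env.drop(columns="const"),
                                         r_threshold=1.0)
    assert report2 == {}


def test_screen_identical_columns():
    env = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                        "c": [4.0, 1, 3, 2]})
    kept, report = screen_collinear(env)
    assert len(kept.columns) == 2 and len(report) == 1


def test_cca_matches_skbio_oracle():
    """Eigenvalues agree with an independent CCA implementation."""
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    Y = _random_species(1)
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(10, 3)), index=Y.index,
                     columns=list("abc"))
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()
    sk = skbio_ord.cca(Y, X)
    np.testing.assert_allclose(res.eigenvalues,
                               np.asarray(sk.eigvals)[:len(res.eigenvalues)],
                               atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_cca_matches_generalized_eigen_oracle(seed):
    """Constrained eigenvalues equal the eigenvalues of Q' H Q where H is
    the row-weighted projection onto the environment space."""
    Y = _random_species(seed)
    rng = np.random.default_rng(100 + seed)
    X = pd.DataFrame(rng.normal(size=(10, 3)), index=Y.index,
                     columns=list("abc"))
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()

    A = Y.to_numpy(dtype=float)
    P = A / A.sum()
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X.to_numpy() - r @ X.to_numpy()
    Xw = np.sqrt(r)[:, None] * (Xc / np.sqrt(r @ (Xc ** 2)))
    H = Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T
    lam = np.linalg.eigvalsh(Q.T @ H @ Q)[::-1]
    np.testing.assert_allclose(res.eigenvalues, lam[:len(res.eigenvalues)],
                               atol=1e-8)


def test_cca_saturated_constraints_equal_ca():
    Y = _random_species(3)
    dummies = pd.get_dummies(pd.Series(Y.index, index=Y.index)).astype(float)
    X = dummies.iloc[:, :-1]  # n-1 dummies span the centred sample space
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()
    assert res.constrained_inertia == pytest.approx(res.total_inertia, abs=1e-10)
    ca = _ca_eigenvalues(Y)
    np.testing.assert_allclose(res.eigenvalues[:len(ca)], ca, atol=1e-8)


def test_total_inertia_is_scaled_chi_square():
    Y = _random_species(4)
    chi2 = scipy.stats.chi2_contingency(Y.to_numpy())[0]
    assert _ca_eigenvalues(Y).sum() == pytest.approx(chi2 / Y.to_numpy().sum())
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(10, 2)), index=Y.index, columns=["a", "b"])
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()
    assert res.total_inertia == pytest.approx(chi2 / Y.to_numpy().sum())
    assert res.constrained_inertia <= res.total_inertia + 1e-12
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_single_binary_variable_one_axis():
    Y = _random_species(6, n=6, m=4)
    X = pd.DataFrame({"grp": [0, 0, 0, 1.0, 1, 1]}, index=Y.index)
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()
    assert len(res.eigenvalues) == 1
    # equals between-group CA of the group-collapsed two-way table
    collapsed = np.vstack([Y.iloc[:3].sum(0), Y.iloc[3:].sum(0)])
    lam = _ca_eigenvalues(collapsed)
    np.testing.assert_allclose(res.eigenvalues, lam, atol=1e-8)


def test_axis_percentages_and_summary():
    Y = _random_species(7)
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(10, 2)), index=Y.index, columns=["a", "b"])
    res = CanonicalCorrespondenceAnalysis(Y, X).fit()
    np.testing.assert_allclose(res.prop_species_env.sum(), 100.0)
    s = res.summary()
    assert list(s.index) == [f"CCA{i+1}" for i in range(len(res.eigenvalues))]
    np.testing.assert_allclose(
        s["species_variance_pct"],
        res.eigenvalues / res.total_inertia * 100.0)


def test_variance_by_variable_duplicate_and_driver(study_scenario):
    from palaeosom import drop_empty_samples
    kept, _ = drop_empty_samples(study_scenario["matrix"])
    species = prepare_species(kept)
    geo = study_scenario["geochem"].loc[kept.index]
    rng = np.random.default_rng(0)
    env = pd.DataFrame({
        "pH": geo["pH"], "pH_copy": geo["pH"],
        "noise1": rng.normal(size=len(geo)),
        "noise2": rng.normal(size=len(geo))}, index=geo.index)
    model = CanonicalCorrespondenceAnalysis(species, env)
    marg = model.variance_by_variable()["marginal_pct"]
    assert marg["pH"] == pytest.approx(marg["pH_copy"], abs=1e-10)
    assert marg["pH"] > marg["noise1"] and marg["pH"] > marg["noise2"]


def test_permutation_test_driver_and_determinism(study_scenario):
    from palaeosom import drop_empty_samples
    kept, _ = drop_empty_samples(study_scenario["matrix"])
    species = prepare_species(kept)
    geo = study_scenario["geochem"].loc[kept.index]
    rng = np.random.default_rng(1)
    env = pd.DataFrame({"pH": geo["pH"],
                        "noise": rng.normal(size=len(geo))}, index=geo.index)
    model = CanonicalCorrespondenceAnalysis(species, env)
    t1 = model.permutation_test("pH", n_permutations=999, seed=3)
    assert t1["pvalue"] <= 0.01
    t2 = model.permutation_test("pH", n_permutations=999, seed=3)
    assert t1["pvalue"] == t2["pvalue"]
    t3 = model.permutation_test("noise", n_permutations=199, seed=3,
                                method="free")
    assert t3["pvalue"] > 0.01
    with pytest.raises(KeyError):
        model.permutation_test("missing")
    with pytest.raises(ValueError):
        model.permutation_test("pH", n_permutations=10)


def test_rank_deficient_env_names_columns():
    Y = _random_species(9)
    x = np.arange(10.0)
    X = pd.DataFrame({"a": x, "b": 2 * x}, index=Y.index)
    with pytest.raises(ValueError, match="b"):
        CanonicalCorrespondenceAnalysis(Y, X).fit()


def test_missing_environment_rows_dropped():
    Y = _random_species(10)
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.normal(size=(10, 2)), index=Y.index, columns=["a", "b"])
    X.iloc[0, 0] = np.nan
    model = CanonicalCorrespondenceAnalysis(Y, X)
    assert model.dropped_samples == ["s0"]
    res = model.fit()
    assert len(res.site_scores) == 9
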