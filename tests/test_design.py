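"""Face-centred CCD generation, quadratic fitting, ANOVA, optimisation."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ringforce.design import (
    CCDDesign,
    DesignError,
    FactorSpec,
    decode,
    encode,
    fit_quadratic,
    generate_ccd,
    predict_optimum,
    quadratic_design_matrix,
    quadratic_term_names,
)
from ringforce.synthetic import default_ccd_factors, make_ccd_responses


def factors_k(k):
    return [FactorSpec(f"x{i}", -1.0, 0.0, 1.0) for i in range(k)]


@pytest.mark.parametrize(
    "k,r_f,r_a,r_c,expected",
    [
        (3, 4, 4, 8, 64),  # the replicated three-factor formulation design
        (2, 1, 1, 1, 9),  # minimal three-level design
        (3, 1, 1, 1, 15),  # the fifteen distinct seeding conditions
    ],
)
def test_run_counts(k, r_f, r_a, r_c, expected):
    design = generate_ccd(factors_k(k), r_f=r_f, r_a=r_a, r_c=r_c)
    assert design.n_runs == expected == 2**k * r_f + 2 * k * r_a + r_c


def test_point_type_partition():
    d = generate_ccd(factors_k(3), r_f=4, r_a=4, r_c=8)
    counts = {t: d.point_type.count(t) for t in ("factorial", "axial", "center")}
    assert counts == {"factorial": 32, "axial": 24, "center": 8}
    coded = d.coded
    assert set(np.unique(coded)) <= {-1.0, 0.0, 1.0}  # face-centred: alpha = 1
    axial = coded[[t == "axial" for t in d.point_type]]
    assert np.all(np.sum(np.abs(axial), axis=1) == 1)


def test_invalid_designs_rejected():
    with pytest.raises(DesignError):
        generate_ccd(factors_k(1))
    with pytest.raises(DesignError):
        generate_ccd(factors_k(2), r_f=0)


@given(
    k=st.integers(2, 4),
    r_f=st.integers(1, 3),
    r_a=st.integers(1, 3),
    r_c=st.integers(1, 6),
)
def test_run_count_formula_and_sign_symmetry(k, r_f, r_a, r_c):
    d = generate_ccd(factors_k(k), r_f=r_f, r_a=r_a, r_c=r_c)
    assert d.n_runs == 2**k * r_f + 2 * k * r_a + r_c
    for j in range(k):
        flipped = d.coded.copy()
        flipped[:, j] *= -1
        orig = {tuple(r) for r in d.coded}
        assert {tuple(r) for r in flipped} == orig  # sign flip permutes the runs


# ---------------------------------------------------------------------------
# coded-unit transform


def test_encode_examples():
    collagen = FactorSpec("collagen_mg_ml", 1.8, 2.0, 2.2)
    cells = FactorSpec("total_cells", 40_000, 70_000, 100_000)
    assert encode(2.0, collagen) == pytest.approx(0.0)
    assert encode(collagen.high, collagen) == pytest.approx(1.0)
    assert encode(75_000, cells) == pytest.approx(5_000 / 30_000)


@given(x=st.floats(1.0, 3.0))
def test_decode_inverts_encode(x):
    f = FactorSpec("c", 1.8, 2.0, 2.2)
    assert decode(encode(x, f), f) == pytest.approx(x, rel=1e-12, abs=1e-12)


def test_factor_midpoint_enforced():
    with pytest.raises(ValueError):
        FactorSpec("bad", 0.0, 0.9, 1.0)
    with pytest.raises(ValueError):
        FactorSpec("bad", 1.0, 0.5, 0.0)


# ---------------------------------------------------------------------------
# quadratic fit + ANOVA


def test_noiseless_surface_recovered_exactly():
    d = generate_ccd(default_ccd_factors(), r_f=1, r_a=1, r_c=2)
    y, truth = make_ccd_responses(d, noise_sd=0.0)
    fit = fit_quadratic(d, y)
    assert np.max(np.abs(fit.coefficients.to_numpy() - truth["beta"])) < 1e-8


def test_ols_matches_normal_equations(rng):
    for _ in range(10):
        k = int(rng.integers(2, 4))
        d = generate_ccd(factors_k(k), r_f=2, r_a=2, r_c=4)
        y = rng.normal(0, 1, d.n_runs)
        fit = fit_quadratic(d, y)
        X = quadratic_design_matrix(d.coded)
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent normal equations
        assert np.max(np.abs(fit.coefficients.to_numpy() - beta)) < 1e-10


def test_anova_sums_of_squares_partition(rng):
    d = generate_ccd(factors_k(3), r_f=2, r_a=2, r_c=6)
    y = rng.normal(5, 2, d.n_runs)
    fit = fit_quadratic(d, y)
    X = quadratic_design_matrix(d.coded)
    fitted = X @ fit.coefficients.to_numpy()
    ess = np.sum((fitted - y.mean()) ** 2)
    ssr = fit.anova.loc["Residual", "sum_sq"]
    tss = np.sum((y - y.mean()) ** 2)
    assert ess + ssr == pytest.approx(tss, rel=1e-9)
    pvals = fit.anova.drop(index="Residual")["p"]
    assert ((pvals >= 0) & (pvals <= 1)).all()


def test_constant_responses_convention():
    d = generate_ccd(factors_k(2), r_f=2, r_a=2, r_c=4)
    fit = fit_quadratic(d, np.full(d.n_runs, 3.5))
    coefs = fit.coefficients
    assert coefs["intercept"] == pytest.approx(3.5)
    assert np.allclose(coefs.drop("intercept").to_numpy(), 0.0, atol=1e-10)
    assert fit.r_squared == 0.0


def test_rank_deficiency_names_aliased_terms():
    # factorial-only runs alias every pure quadratic with the intercept
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=2)))
    coded = np.repeat(corners, 3, axis=0)
    d = CCDDesign(factors=factors_k(2), coded=coded,
                  point_type=["factorial"] * len(coded), replicates=(3, 0, 0))
    with pytest.raises(DesignError, match="aliased"):
        fit_quadratic(d, np.zeros(len(coded)))


def test_wrong_response_length_rejected():
    d = generate_ccd(factors_k(2))
    with pytest.raises(ValueError):
        fit_quadratic(d, np.zeros(d.n_runs + 1))


# ---------------------------------------------------------------------------
# optimum prediction


def _fit_from_beta(factors, beta_map):
    d = generate_ccd(factors, r_f=2, r_a=2, r_c=4)
    names = quadratic_term_names(factors)
    beta = np.array([beta_map.get(n, 0.0) for n in names])
    y = quadratic_design_matrix(d.coded) @ beta
    return fit_quadratic(d, y)


def test_concave_surface_interior_optimum():
    f = factors_k(2)
    # y = 5 - (x0 - 0.2)^2 - x1^2
    fit = _fit_from_beta(
        f, {"intercept": 5 - 0.04, "x0": 0.4, "x0^2": -1.0, "x1^2": -1.0}
    )
    opt = predict_optimum(fit, f)
    assert opt.coded_settings["x0"] == pytest.approx(0.2, abs=1e-6)
    assert opt.coded_settings["x1"] == pytest.approx(0.0, abs=1e-6)
    assert opt.predicted_response == pytest.approx(5.0, abs=1e-9)


def test_monotone_surface_boundary_optimum():
    f = factors_k(2)
    fit = _fit_from_beta(f, {"intercept": 1.0, "x0": 2.0})
    opt = predict_optimum(fit, f)
    assert opt.coded_settings["x0"] == pytest.approx(1.0, abs=1e-9)
    fit_min = predict_optimum(fit, f, objective="minimize")
    assert fit_min.coded_settings["x0"] == pytest.approx(-1.0, abs=1e-9)


def test_optimum_beats_brute_force_grid(rng):
    f = factors_k(3)
    names = quadratic_term_names(f)
    axes = [np.linspace(-1, 1, 51)] * 3
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    Xg = quadratic_design_matrix(grid)
    for _ in range(20):
        beta = rng.normal(0, 1, len(names))
        fit = _fit_from_beta(f, dict(zip(names, beta)))
        opt = predict_optimum(fit, f)
        assert opt.predicted_response >= (Xg @ beta).max() - 1e-6


def test_settings_stay_inside_coded_box(rng):
    f = factors_k(3)
    names = quadratic_term_names(f)
    for _ in range(5):
        beta = rng.normal(0, 2, len(names))
        opt = predict_optimum(_fit_from_beta(f, dict(zip(names, beta))), f)
        for v in opt.coded_settings.values():
            assert -1.0 <= v <= 1.0
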