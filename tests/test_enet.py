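"""Elastic-net logistic solver: oracle agreement, KKT optimality, CV, stability."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rpindex.datatypes import ValidationError
from rpindex.enet import (
    cv_lambda,
    fit_enet,
    kkt_residual,
    lambda_grid,
    lambda_max,
    penalized_objective,
    stability_select,
)


def lbfgs_oracle(X, y, pf, alpha, lam):
    """Independent convex solver: split beta = b+ - b- and run L-BFGS-B."""
    n, p = X.shape

    def unpack(z):
        return z[0], z[1 : p + 1] - z[p + 1 :]

    def f(z):
        b0, beta = unpack(z)
        eta = b0 + X @ beta
        nll = np.mean(np.logaddexp(0, eta) - y * eta)
        bp, bm = z[1 : p + 1], z[p + 1 :]
        return nll + lam * np.sum(pf * (alpha * (bp + bm) + 0.5 * (1 - alpha) * (bp - bm) ** 2))

    def g(z):
        b0, beta = unpack(z)
        ph = 1 / (1 + np.exp(-(b0 + X @ beta)))
        gl = X.T @ (ph - y) / n
        return np.concatenate(
            [
                [np.mean(ph - y)],
                gl + lam * pf * (alpha + (1 - alpha) * beta),
                -gl + lam * pf * (alpha - (1 - alpha) * beta),
            ]
        )

    res = minimize(
        f, np.zeros(2 * p + 1), jac=g, method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * p),
        options=dict(maxiter=50000, ftol=1e-16, gtol=1e-12),
    )
    b0, beta = unpack(res.x)
    return b0, beta, res.fun


def _binary_design(seed, n, p, standardize=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if standardize:
        X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[: min(3, p)] = [1.5, -1.0, 0.8][: min(3, p)]
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    return X, y


def test_lambda_above_lambda_max_gives_null_model():
    X, y = _binary_design(0, 60, 8)
    pf = np.ones(8)
    lmax = lambda_max(X, y, 0.5, pf)
    fit = fit_enet(X, y, alpha=0.5, lambda_=lmax * 1.001, penalty_factors=pf)
    assert (fit.coefficients == 0).all()
    ybar = y.mean()
    assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)
    # just below lambda_max at least one coefficient enters
    fit2 = fit_enet(X, y, alpha=0.5, lambda_=lmax * 0.95, penalty_factors=pf)
    assert (fit2.coefficients != 0).any()


def test_unpenalized_fit_matches_statsmodels_logit():
    import statsmodels.api as sm

    X, y = _binary_design(1, 120, 4, standardize=False)
    fit = fit_enet(X, y, alpha=0.5, lambda_=0.0, tol=1e-12)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
    assert fit.intercept == pytest.approx(sm_fit.params[0], abs=1e-5)
    np.testing.assert_allclose(fit.coefficients, sm_fit.params[1:], rtol=1e-5, atol=1e-6)


@pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
@pytest.mark.parametrize("lam", [0.01, 0.05, 0.2])
def test_solver_matches_convex_oracle(alpha, lam):
    X, y = _binary_design(2, 50, 8)
    pf = np.ones(8)
    pf[0] = 0.0  # one exempt covariate column
    fit = fit_enet(X, y, alpha=alpha, lambda_=lam, penalty_factors=pf, tol=1e-10)
    assert fit.converged
    b0o, betao, f_oracle = lbfgs_oracle(X, y, pf, alpha, lam)
    f_mine = penalized_objective(X, y, pf, alpha, lam, fit.intercept, fit.coefficients)
    assert f_mine <= f_oracle + 1e-8 * max(1.0, abs(f_oracle))
    np.testing.assert_allclose(fit.coefficients, betao, atol=2e-5)
    assert kkt_residual(X, y, pf, alpha, lam, fit.intercept, fit.coefficients) < 1e-6


def test_exempt_covariate_is_never_shrunk_to_zero():
    X, y = _binary_design(3, 80, 6)
    pf = np.ones(6)
    pf[2] = 0.0
    lmax = lambda_max(X, y, 0.5, pf)
    fit = fit_enet(X, y, alpha=0.5, lambda_=lmax * 2, penalty_factors=pf)
    assert (np.delete(fit.coefficients, 2) == 0).all()
    assert fit.coefficients[2] != 0.0


def test_nonzero_count_mostly_monotone_along_path():
    X, y = _binary_design(4, 100, 20)
    grid = lambda_grid(X, y, 0.5, np.ones(20), n_lambda=30)
    from rpindex.enet import fit_path

    fits = fit_path(X, y, 0.5, grid, dev_stop=False)
    nz = [(f.coefficients != 0).sum() for f in fits]
    # lambda decreases along the grid, so the active set should only grow;
    # tolerate occasional local swaps in correlated designs
    violations = sum(a < b for a, b in zip(nz[1:], nz[:-1]))
    assert violations <= 2
    assert nz[-1] >= nz[0]


def test_constant_column_is_dropped_not_fatal():
    X, y = _binary_design(5, 60, 5)
    X[:, 3] = 2.0
    fit = fit_enet(X, y, alpha=0.5, lambda_=0.02)
    assert fit.coefficients[3] == 0.0


def test_fit_rejects_single_class_and_misaligned_inputs():
    X, _ = _binary_design(6, 30, 4)
    with pytest.raises(ValidationError):
        fit_enet(X, np.ones(30), lambda_=0.1)
    with pytest.raises(ValidationError):
        fit_enet(X, np.r_[np.zeros(10), np.ones(19)], lambda_=0.1)


def test_cv_is_deterministic_under_seed():
    X, y = _binary_design(7, 90, 15)
    cv1 = cv_lambda(X, y, alpha=0.5, seed=42)
    cv2 = cv_lambda(X, y, alpha=0.5, seed=42)
    assert cv1.lambda_min == cv2.lambda_min
    assert cv1.lambda_1se == cv2.lambda_1se
    np.testing.assert_array_equal(cv1.mean_deviance, cv2.mean_deviance)
    assert cv1.lambda_1se >= cv1.lambda_min
    assert (np.diff(cv1.lambdas) < 0).all()


def test_strong_predictor_always_enters_cv_model():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n, p = 300, 20
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * X[:, 0]))).astype(float)
        cv = cv_lambda(X, y, alpha=0.5, seed=seed)
        fit = fit_enet(X, y, alpha=0.5, lambda_=cv.lambda_1se)
        assert fit.coefficients[0] != 0.0, seed


def test_single_bootstrap_frequencies_are_binary():
    X, y = _binary_design(8, 80, 10)
    st = stability_select(X, y, n_bootstraps=1, seed=0, lambda_mode="fixed", fixed_lambda=0.05)
    assert set(np.unique(st.frequencies)) <= {0.0, 1.0}


def test_stability_is_deterministic_under_seed():
    X, y = _binary_design(9, 80, 10)
    kw = dict(n_bootstraps=10, seed=3, lambda_mode="fixed", fixed_lambda=0.03)
    st1 = stability_select(X, y, **kw)
    st2 = stability_select(X, y, **kw)
    np.testing.assert_array_equal(st1.inclusion_counts, st2.inclusion_counts)


def test_stability_separates_planted_from_null_markers(clean_cohort):
    from rpindex.genotype_io import encode_cohort

    _, cohort, phen, truth = clean_cohort
    enc = encode_cohort(cohort)
    X, y = enc.values, phen["endpoint"].to_numpy(float)
    cv = cv_lambda(X, y, alpha=0.5, seed=0)
    st = stability_select(X, y, alpha=0.5, n_bootstraps=60, seed=0,
                          lambda_mode="fixed", fixed_lambda=cv.lambda_1se)
    causal = np.array([enc.site_ids.index(s) for s in truth.causal_site_ids])
    is_causal = np.isin(st.penalized_columns, causal)
    freq = st.frequencies
    assert freq[is_causal].mean() > freq[~is_causal].mean()
    assert set(causal) <= set(st.selected)
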