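"""Elastic-net penalized logistic regression with per-feature penalty factors.

This is the modelling core: a glmnet-style cyclic coordinate-descent solver for

    min over (b0, beta) of
        -(1/n) sum_i [ y_i eta_i - log(1 + exp(eta_i)) ]
        + lambda * sum_j pf_j * ( alpha*|beta_j| + (1-alpha)/2 * beta_j^2 )

with eta = b0 + X beta.  ``pf_j`` is the per-column penalty factor: 1 for SNP
dosage columns, 0 for clinical covariates that are exempt from shrinkage; the
intercept is never penalized.  The solver works on internally standardized
columns (mean 0, variance 1 with 1/n normalisation) and returns coefficients on
the input scale.  Around it sit the cross-validation lambda search (binomial
deviance over stratified folds) and bootstrap stability selection (markers kept
when their coefficient is nonzero in more than half of the resamples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetFit",
    "CVResult",
    "StabilityResult",
    "fit_enet",
    "fit_path",
    "lambda_grid",
    "cv_lambda",
    "stability_select",
    "penalized_objective",
    "kkt_residual",
]

_PMIN = 1e-5  # probability clip, as in the reference coordinate-descent algorithm


# ---------------------------------------------------------------------------
# Numba kernel: IRLS + cyclic coordinate descent on standardized columns
# ---------------------------------------------------------------------------

@njit(cache=False)
def _update_col(X, w, r, wx2, beta, j, lam, alpha, pf, n):
    """Soft-threshold update of one column against the working residual."""
    bj = beta[j]
    g = 0.0
    for i in range(n):
        g += w[i] * X[i, j] * r[i]
    g = g / n + wx2[j] * bj
    thr = lam * alpha * pf[j]
    if g > thr:
        num = g - thr
    elif g < -thr:
        num = g + thr
    else:
        num = 0.0
    denom = wx2[j] + lam * (1.0 - alpha) * pf[j]
    bnew = num / denom if denom > 0.0 else 0.0
    if bnew != bj:
        d = bnew - bj
        for i in range(n):
            r[i] -= X[i, j] * d
        beta[j] = bnew
        return abs(d)
    return 0.0


@njit(cache=False)
def _update_intercept(w, r, wsum, n):
    g0 = 0.0
    for i in range(n):
        g0 += w[i] * r[i]
    d0 = g0 / wsum
    if d0 != 0.0:
        for i in range(n):
            r[i] -= d0
    return d0


@njit(cache=False)
def _cd_logistic(X, y, pf, alpha, lam, beta, b0, max_outer, max_inner, tol):
    """In-place coordinate descent; X standardized, returns (b0, outer_iters, converged).

    Inner solver uses the active-set strategy: after a full sweep, iterate on
    the nonzero set until converged, then re-run a full sweep to admit new
    columns.
    """
    n, p = X.shape
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    wx2 = np.empty(p)
    active = np.empty(p, dtype=np.int64)
    for outer in range(max_outer):
        # quadratic approximation at the current linear predictor
        for i in range(n):
            v = b0
            for j in range(p):
                if beta[j] != 0.0:
                    v += X[i, j] * beta[j]
            eta[i] = v
        for i in range(n):
            pr = 1.0 / (1.0 + np.exp(-eta[i]))
            if pr < _PMIN:
                pr = _PMIN
            elif pr > 1.0 - _PMIN:
                pr = 1.0 - _PMIN
            wi = pr * (1.0 - pr)
            w[i] = wi
            r[i] = (y[i] - pr) / wi  # z - eta
        wsum = w.sum()
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wx2[j] = s / n
        delta_outer = 0.0
        inner_used = 0
        while inner_used < max_inner:
            # full sweep over all columns
            delta = 0.0
            for j in range(p):
                d = _update_col(X, w, r, wx2, beta, j, lam, alpha, pf, n)
                if d > delta:
                    delta = d
            d0 = _update_intercept(w, r, wsum, n)
            b0 += d0
            if abs(d0) > delta:
                delta = abs(d0)
            inner_used += 1
            if delta > delta_outer:
                delta_outer = delta
            if delta < tol:
                break
            # iterate on the active set until it converges
            n_active = 0
            for j in range(p):
                if beta[j] != 0.0:
                    active[n_active] = j
                    n_active += 1
            while inner_used < max_inner:
                delta = 0.0
                for k in range(n_active):
                    d = _update_col(X, w, r, wx2, beta, active[k], lam, alpha, pf, n)
                    if d > delta:
                        delta = d
                d0 = _update_intercept(w, r, wsum, n)
                b0 += d0
                if abs(d0) > delta:
                    delta = abs(d0)
                inner_used += 1
                if delta > delta_outer:
                    delta_outer = delta
                if delta < tol:
                    break
        if delta_outer < tol:
            return b0, outer + 1, True
    return b0, max_outer, False


# ---------------------------------------------------------------------------
# Python surface
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetFit:
    intercept: float
    coefficients: np.ndarray
    alpha: float
    lambda_: float
    n_iterations: int
    converged: bool
    objective: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/n variance, reference-algorithm convention
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d constant column(s) from the fit", int((~keep).sum()))
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return np.ascontiguousarray(Xs), mu, sd, keep


def penalized_objective(X, y, pf, alpha, lam, intercept, beta) -> float:
    """Penalized negative mean log-likelihood on the given (already scaled) design."""
    eta = intercept + X @ beta
    # log(1+e^eta) computed stably
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = float(lam * np.sum(pf * (alpha * np.abs(beta) + 0.5 * (1 - alpha) * beta**2)))
    return nll + pen


def kkt_residual(X, y, pf, alpha, lam, intercept, beta) -> float:
    """Max violation of the subgradient optimality conditions (standardized scale)."""
    n = X.shape[0]
    p_hat = 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))
    grad = X.T @ (p_hat - y) / n
    viol = abs(float(np.mean(p_hat - y)))
    for j in range(X.shape[1]):
        g = grad[j] + lam * (1 - alpha) * pf[j] * beta[j]
        if beta[j] != 0.0:
            viol = max(viol, abs(g + lam * alpha * pf[j] * np.sign(beta[j])))
        else:
            viol = max(viol, max(0.0, abs(g) - lam * alpha * pf[j]))
    return viol


def _validate_fit_inputs(X, y, alpha, lam):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y are not aligned")
    if np.isnan(X).any():
        raise ValidationError("design matrix contains missing values; impute first")
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha outside [0,1]: {alpha}")
    if lam < 0:
        raise ValidationError(f"negative lambda: {lam}")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    return X, y


def fit_enet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_: float = 0.01,
    penalty_factors: np.ndarray | None = None,
    tol: float = 1e-8,
    max_outer: int = 200,
    max_inner: int = 2000,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> ElasticNetFit:
    """Fit penalized logistic regression at one (alpha, lambda) point.

    ``penalty_factors`` defaults to all-ones; pass 0 for covariate columns
    exempt from penalization.  Coefficients are returned on the input scale.
    """
    X, y = _validate_fit_inputs(X, y, alpha, lambda_)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, dtype=float)
    if pf.shape != (p,) or (pf < 0).any():
        raise ValidationError("penalty_factors must be nonnegative, one per column")
    if lambda_ == 0.0 and p >= n:
        raise ValidationError("lambda=0 with p >= n: unpenalized logistic fit is not identified")

    Xs, mu, sd, keep = _standardize(X)
    pf_s = np.ascontiguousarray(pf[keep])
    if warm_start is not None:
        b0w, bw = warm_start
        beta_s = np.ascontiguousarray(bw[keep] * sd[keep])
        b0_init = b0w + float(bw[keep] @ mu[keep])
    else:
        ybar = y.mean()
        b0_init = float(np.log(ybar / (1 - ybar)))
        beta_s = np.zeros(int(keep.sum()))

    b0_s, iters, converged = _cd_logistic(
        Xs, y, pf_s, float(alpha), float(lambda_), beta_s, b0_init,
        max_outer, max_inner, tol,
    )
    if not converged:
        logger.warning("coordinate descent did not converge (lambda=%g)", lambda_)

    beta = np.zeros(p)
    beta[keep] = beta_s / sd[keep]
    intercept = b0_s - float(beta[keep] @ mu[keep])
    obj = penalized_objective(Xs, y, pf_s, alpha, lambda_, b0_s, beta_s)
    return ElasticNetFit(intercept, beta, alpha, lambda_, iters, converged, obj)


def lambda_max(X, y, alpha, penalty_factors) -> float:
    """Smallest lambda zeroing all penalized columns, from the null-fit gradient."""
    X, y = _validate_fit_inputs(X, y, alpha, 0.0)
    pf = np.asarray(penalty_factors, dtype=float)
    free = pf == 0
    if free.any():
        # fit intercept + exempt covariates first; their residual sets the entry point
        null = fit_enet(X[:, free], y, alpha=alpha, lambda_=0.0,
                        penalty_factors=np.zeros(int(free.sum())))
        p_hat = null.predict_proba(X[:, free])
    else:
        p_hat = np.full(X.shape[0], y.mean())
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    grad = np.abs(Xs.T @ (y - p_hat)) / X.shape[0]
    alpha_eff = max(alpha, 1e-3)
    pen = pf > 0
    if not pen.any():
        return 0.0
    return float(np.max(grad[pen] / (alpha_eff * pf[pen])))


def lambda_grid(X, y, alpha, penalty_factors, n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(X, y, alpha, penalty_factors)
    if lmax == 0.0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def fit_path(
    X,
    y,
    alpha,
    lambdas,
    penalty_factors=None,
    tol: float = 1e-7,
    dev_stop: bool = True,
) -> list[ElasticNetFit]:
    """Warm-started fits along a descending lambda sequence.

    With ``dev_stop`` the path stops early, reference-algorithm style, once the
    fraction of null deviance explained exceeds 0.999 or stops improving (the
    remaining lambdas would only refit noise); the returned list may then be
    shorter than ``lambdas``.
    """
    y_arr = np.asarray(y, dtype=float)
    ybar = y_arr.mean()
    null_dev = binomial_deviance(y_arr, np.full(len(y_arr), ybar))
    fits = []
    warm = None
    prev_ratio = 0.0
    for lam in lambdas:
        fit = fit_enet(X, y, alpha=alpha, lambda_=float(lam),
                       penalty_factors=penalty_factors, tol=tol, warm_start=warm)
        warm = (fit.intercept, fit.coefficients)
        fits.append(fit)
        if dev_stop:
            dev = binomial_deviance(y_arr, fit.predict_proba(X))
            ratio = 1.0 - dev / null_dev
            if ratio > 0.999 or (len(fits) > 1 and ratio - prev_ratio < 1e-5):
                break
            prev_ratio = ratio
    return fits


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    lambdas: np.ndarray          # descending grid
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float            # minimum mean validation deviance
    lambda_1se: float            # largest lambda within one SE of the minimum
    n_folds: int
    seed: int

    def chosen(self, rule: str = "1se") -> float:
        if rule == "1se":
            return self.lambda_1se
        if rule == "min":
            return self.lambda_min
        raise ValidationError(f"unknown lambda rule {rule!r}")


def _stratified_folds(
    y: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Fold labels balancing both outcome classes across folds.

    ``groups`` forces rows sharing a label into the same fold — used when
    cross-validating inside a bootstrap resample, where duplicated draws of one
    original sample must not straddle the train/validation boundary.
    """
    if groups is None:
        folds = np.empty(len(y), dtype=np.int64)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        return folds
    uniq, first = np.unique(groups, return_index=True)
    group_fold = _stratified_folds(y[first], n_folds, rng)
    lookup = dict(zip(uniq.tolist(), group_fold.tolist()))
    return np.array([lookup[g] for g in groups.tolist()], dtype=np.int64)


def binomial_deviance(y, p_hat) -> float:
    p_hat = np.clip(p_hat, _PMIN, 1 - _PMIN)
    return float(-2.0 * np.mean(y * np.log(p_hat) + (1 - y) * np.log(1 - p_hat)))


def cv_lambda(
    X,
    y,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    penalty_factors=None,
    n_lambda: int = 100,
    lambda_ratio: float = 1e-3,
    lambdas: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    fold_tol: float = 1e-5,
) -> CVResult:
    """Choose lambda by stratified k-fold cross-validated binomial deviance.

    The grid is first truncated by an early-stopping full-data path (the
    reference algorithm's convention), so fold fits do not chase the dense,
    noise-only tail of the path.
    """
    X, y = _validate_fit_inputs(X, y, alpha, 0.0)
    n = len(y)
    if n < n_folds:
        raise ValidationError(f"n_samples={n} < n_folds={n_folds}")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 2:
        raise ValidationError("need at least 2 samples of each class for stratified CV")
    eff_folds = min(n_folds, n_pos, n_neg)
    if eff_folds < n_folds:
        logger.info("reducing folds from %d to %d to keep both classes per training fold",
                    n_folds, eff_folds)
    pf = np.ones(X.shape[1]) if penalty_factors is None else np.asarray(penalty_factors, float)
    if lambdas is None:
        lambdas = lambda_grid(X, y, alpha, pf, n_lambda=n_lambda, ratio=lambda_ratio)
        full_fits = fit_path(X, y, alpha, lambdas, penalty_factors=pf, tol=fold_tol)
        lambdas = lambdas[: len(full_fits)]
    lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, eff_folds, rng, groups=groups)
    dev = np.empty((eff_folds, len(lambdas)))
    for k in range(eff_folds):
        tr, va = folds != k, folds == k
        fits = fit_path(X[tr], y[tr], alpha, lambdas, penalty_factors=pf,
                        tol=fold_tol, dev_stop=False)
        for li, fit in enumerate(fits):
            dev[k, li] = binomial_deviance(y[va], fit.predict_proba(X[va]))
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(eff_folds)
    best = int(np.argmin(mean))
    within = np.flatnonzero(mean <= mean[best] + se[best])
    # grid is descending, so the first index within one SE is the largest lambda
    return CVResult(lambdas, mean, se, float(lambdas[best]), float(lambdas[within[0]]),
                    eff_folds, seed)


# ---------------------------------------------------------------------------
# Bootstrap stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    n_bootstraps: int
    inclusion_counts: np.ndarray      # per penalized-column nonzero count
    penalized_columns: np.ndarray     # indices into the design's columns
    seed: int
    rule_threshold: float = 0.5
    n_redrawn: int = 0
    bootstrap_lambdas: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def frequencies(self) -> np.ndarray:
        return self.inclusion_counts / self.n_bootstraps

    @property
    def selected(self) -> np.ndarray:
        """Design-column indices of markers present in more than half the bootstraps."""
        return self.penalized_columns[self.frequencies > self.rule_threshold]


def stability_select(
    X,
    y,
    alpha: float = 0.5,
    n_bootstraps: int = 500,
    seed: int = 0,
    penalty_factors=None,
    lambda_mode: str = "cv",
    fixed_lambda: float | None = None,
    lambda_rule: str = "1se",
    n_folds: int = 10,
    n_lambda: int = 100,
    lambda_ratio: float = 1e-3,
    rule_threshold: float = 0.5,
    max_redraws: int = 100,
) -> StabilityResult:
    """Bootstrap stability selection for the penalized markers.

    Resamples the cohort with replacement ``n_bootstraps`` times; within each
    resample, lambda is chosen by cross-validation (``lambda_mode="cv"``, the
    default) or fixed to ``fixed_lambda`` (``lambda_mode="fixed"``, the fast
    variant using a full-data CV lambda).  A marker counts as present in a
    bootstrap when its coefficient is nonzero at that bootstrap's lambda.
    Covariates with penalty factor 0 take no part in the rule: they are always
    retained downstream.
    """
    X, y = _validate_fit_inputs(X, y, alpha, 0.0)
    if n_bootstraps < 1:
        raise ValidationError("n_bootstraps must be >= 1")
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    pen_cols = np.flatnonzero(pf > 0)
    if lambda_mode == "fixed" and fixed_lambda is None:
        raise ValidationError("lambda_mode='fixed' requires fixed_lambda")
    if lambda_mode not in ("cv", "fixed"):
        raise ValidationError(f"unknown lambda_mode {lambda_mode!r}")

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(pen_cols), dtype=np.int64)
    lambdas_used = np.empty(n_bootstraps)
    n_redrawn = 0
    warm = None
    if lambda_mode == "fixed":
        full = fit_enet(X, y, alpha=alpha, lambda_=float(fixed_lambda), penalty_factors=pf)
        warm = (full.intercept, full.coefficients)
    for b in range(n_bootstraps):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 1 < yb.sum() < n - 1:
                break
            n_redrawn += 1
            logger.info("bootstrap %d degenerate (one class); redrawn", b)
        else:
            raise ValidationError("could not draw a two-class bootstrap resample")
        Xb = X[idx]
        if lambda_mode == "cv":
            # grouped folds: all copies of one original sample share a fold
            cv = cv_lambda(Xb, yb, alpha=alpha, n_folds=n_folds,
                           seed=int(rng.integers(0, 2**31 - 1)), penalty_factors=pf,
                           n_lambda=n_lambda, lambda_ratio=lambda_ratio, groups=idx)
            lam = cv.chosen(lambda_rule)
        else:
            lam = float(fixed_lambda)
        fit = fit_enet(Xb, yb, alpha=alpha, lambda_=lam, penalty_factors=pf,
                       warm_start=warm, tol=1e-6)
        counts += fit.coefficients[pen_cols] != 0.0
        lambdas_used[b] = lam
    return StabilityResult(n_bootstraps, counts, pen_cols, seed,
                           rule_threshold, n_redrawn, lambdas_used)
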