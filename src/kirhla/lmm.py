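"""Random-intercept linear mixed model via profiled (RE)ML.

The analysis needs exactly one flavour of mixed model: a Gaussian linear
model with a single random intercept per mother,

    y = X beta + Z u + e,   u ~ N(0, tau^2 I),   e ~ N(0, sigma^2 I),

where Z indicates the mother of each child. For this structure the
marginal covariance is block diagonal, V_j = sigma^2 (I + lambda J_{n_j})
with lambda = tau^2 / sigma^2, and both beta and sigma^2 profile out in
closed form for fixed lambda (Sherman-Morrison on each block). Estimation
therefore reduces to a bounded one-dimensional optimisation of the profiled
REML (or ML) criterion in lambda, which is orders of magnitude faster than
a generic mixed-model optimiser and exact at the lambda = 0 boundary. When
every mother has a single child the criterion is flat in lambda and the
fixed-effect estimates and standard errors coincide with OLS identically.

Wald inference on the fixed effects uses the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, optimize
from scipy.stats import norm

from .errors import FitError

__all__ = ["RandomInterceptFit", "fit_random_intercept"]

_Z95 = norm.ppf(0.975)


@dataclass
class RandomInterceptFit:
    """Estimates from a single-random-intercept LMM."""

    params: np.ndarray          # fixed-effect estimates
    bse: np.ndarray             # Wald standard errors
    cov_params: np.ndarray
    sigma2: float               # residual variance
    tau2: float                 # mother-level (random-intercept) variance
    nobs: int
    n_groups: int
    reml: bool
    neg2loglik: float           # -2 x profiled (RE)ML criterion at the optimum

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def conf_int(self) -> np.ndarray:
        half = _Z95 * self.bse
        return np.column_stack([self.params - half, self.params + half])


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    codes, inverse = np.unique(groups, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    Xs, ys, gs = X[order], y[order], inverse[order]
    starts = np.flatnonzero(np.r_[True, np.diff(gs) > 0])
    sizes = np.diff(np.r_[starts, len(gs)])
    S = np.add.reduceat(Xs, starts, axis=0)     # per-group column sums of X
    t = np.add.reduceat(ys, starts)             # per-group sums of y
    return S, t, sizes.astype(float), len(codes)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: Optional[np.ndarray] = None,
    reml: bool = True,
) -> RandomInterceptFit:
    """Fit ``y = X beta + u[group] + e`` by profiled (RE)ML.

    ``groups`` may be any label array (one label per row); ``None`` fits
    plain OLS. The variance ratio is optimised on a log grid bracket with a
    golden-section refinement; the boundary tau^2 = 0 is admissible and
    returned rather than raised.
    """
    y = np.asarray(y, dtype=float)
    X_raw = np.asarray(X, dtype=float)
    n, p = X_raw.shape
    if n <= p:
        raise FitError(f"n={n} rows cannot identify p={p} fixed effects")

    # standardise internally: centring/scaling conditions the normal
    # equations and makes the fit invariant (to fp noise) under recentring
    # of covariates; estimates are mapped back afterwards
    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)
    varying = sd > 0
    if not varying.any():
        raise FitError("design has no varying column")
    const_idx = np.flatnonzero(~varying)
    X = X_raw.copy()
    X[:, varying] = (X_raw[:, varying] - mu[varying]) / sd[varying]
    my, sy = float(y.mean()), float(y.std())
    if sy == 0:
        raise FitError("response is constant")
    y = (y - my) / sy

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    if groups is None:
        groups = np.arange(n)
    S, t, sizes, n_groups = _group_stats(X, y, np.asarray(groups))
    dof = n - p if reml else n

    def profile(lam: float):
        c = lam / (1.0 + lam * sizes)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:
            raise FitError(f"singular fixed-effect covariance (X'V^-1 X): {exc}") from exc
        beta = linalg.cho_solve(cf, b)
        ywy = yty - float((c * t) @ t)
        rss = ywy - float(beta @ b)
        if rss <= 0:
            raise FitError("non-positive residual sum of squares")
        sigma2 = rss / dof
        crit = dof * np.log(sigma2) + float(np.sum(np.log1p(lam * sizes)))
        if reml:
            crit += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return crit, beta, sigma2, A

    def dprofile(lam: float) -> float:
        """Analytic d(criterion)/d(lambda); used to polish the optimum."""
        c = lam / (1.0 + lam * sizes)
        dc = 1.0 / (1.0 + lam * sizes) ** 2
        A = XtX - (S * c[:, None]).T @ S
        dA = -(S * dc[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        db = -S.T @ (dc * t)
        cf = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cf, b)
        ywy = yty - float((c * t) @ t)
        rss = ywy - float(beta @ b)
        drss = -float((dc * t) @ t) - 2.0 * float(beta @ db) - float(beta @ (dA @ beta))
        d = dof * drss / rss + float(np.sum(sizes / (1.0 + lam * sizes)))
        if reml:
            d += float(np.trace(linalg.cho_solve(cf, dA)))
        return d

    # lambda = 0 boundary plus a bounded search in log-lambda
    best_lam, best = 0.0, profile(0.0)
    if (sizes > 1).any():
        res = optimize.minimize_scalar(
            lambda u: profile(np.exp(u))[0], bounds=(-10.0, 6.0), method="bounded",
            options={"xatol": 1e-8, "maxiter": 200},
        )
        if not res.success:
            raise FitError("variance-ratio optimisation did not converge "
                           "(mother-level variance component)")
        if res.fun < best[0] - 1e-10:
            lam = float(np.exp(res.x))
            # polish: root of the analytic derivative around the optimum
            lo, hi = lam / 1.5, lam * 1.5
            dlo, dhi = dprofile(lo), dprofile(hi)
            if dlo < 0.0 < dhi:
                lam = float(optimize.brentq(dprofile, lo, hi,
                                            xtol=1e-14, rtol=1e-14))
            best_lam = lam
            best = profile(best_lam)

    crit, beta, sigma2, A = best

    # map the standardised-scale estimates back to the original scale:
    # beta_orig = T gamma + t with T upper-left diagonal sy/sd_j and, for the
    # intercept-like constant column, the centring offsets folded in
    T = np.zeros((p, p))
    t_shift = np.zeros(p)
    vidx = np.flatnonzero(varying)
    for j in vidx:
        T[j, j] = sy / sd[j]
    if const_idx.size:
        c0 = const_idx[0]
        k = X_raw[0, c0]  # constant column value (1 for an intercept)
        T[c0, c0] = sy / k
        for j in vidx:
            T[c0, j] = -sy * mu[j] / (sd[j] * k)
        t_shift[c0] = my / k
        for c in const_idx[1:]:
            T[c, c] = sy
    cov_s = sigma2 * linalg.inv(A)
    beta = T @ beta + t_shift
    cov = T @ cov_s @ T.T
    sigma2 = sy**2 * sigma2
    bse = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(bse)) or np.any(bse <= 0):
        raise FitError("non-positive or non-finite standard errors (singular covariance)")
    return RandomInterceptFit(
        params=beta, bse=bse, cov_params=cov,
        sigma2=float(sigma2), tau2=float(best_lam * sigma2),
        nobs=n, n_groups=n_groups, reml=reml, neg2loglik=float(crit),
    )
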