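"""Mixed-model fitting for the paired population design.

Two model families share one random-effects structure -- a random intercept
per species and a random intercept per population nested within species --
reflecting the sampling design: populations of the two congeneric species
are the paired observational units, and each population contributes one
observation per marker type.

* :func:`fit_linear_mixed` -- Gaussian responses with known case weights
  ``w`` entering the residual variance as ``sigma_e^2 / w_i``.  The
  likelihood is profiled analytically over the fixed effects and the
  residual scale, leaving a 2-D optimization over the two variance ratios.
  Supports ML (for likelihood-ratio tests) and REML (for marginal means and
  intervals).

* :func:`fit_binomial_mixed` -- binomial counts with logit link, fitted by
  the Laplace approximation to the marginal likelihood: a penalized Newton
  solve for the joint mode of the random effects inside a quasi-Newton
  outer optimization over fixed effects and variance parameters.  This is
  the same approximation lme4's ``glmer`` uses by default.

Nothing here knows about diversity indices; callers supply a response, a
design matrix and the two grouping factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

__all__ = ["MixedFit", "fit_linear_mixed", "fit_binomial_mixed"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixedFit:
    """A fitted mixed model (either family)."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    loglik: float
    sigma_species: float
    sigma_population: float
    sigma_resid: float | None  # None for binomial
    method: str  # "ML" or "REML" (binomial: "Laplace-ML")
    converged: bool
    n_obs: int
    family: str = "gaussian"
    messages: list[str] = field(default_factory=list)


def _group_codes(labels: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(labels, return_inverse=True)
    return codes, int(codes.max()) + 1


# ---------------------------------------------------------------------------
# Gaussian family
# ---------------------------------------------------------------------------


def _lmm_profile(
    gamma: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    sp: np.ndarray,
    pop: np.ndarray,
    w: np.ndarray,
    reml: bool,
) -> tuple[float, dict]:
    """Negative profiled log-likelihood at variance ratios ``gamma >= 0``.

    ``V = sigma_e^2 * V0`` with ``V0 = g_s A + g_p B + diag(1/w)``; beta and
    sigma_e^2 are profiled out in closed form.
    """
    gs, gp = np.maximum(np.asarray(gamma, dtype=float), 0.0)
    n, p = X.shape
    if sp.ndim == 2:  # precomputed boolean masks
        A, B = sp, pop
    else:
        A = sp[:, None] == sp[None, :]
        B = pop[:, None] == pop[None, :]
    V0 = np.diag(1.0 / w) + gs * A + gp * B
    try:
        L = linalg.cholesky(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e300, {}
    logdet_V0 = 2.0 * np.log(np.diag(L)).sum()
    Xs = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    ys = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    XtX = Xs.T @ Xs
    try:
        beta = np.linalg.solve(XtX, Xs.T @ ys)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    quad = float(r @ r)
    dof = n - p if reml else n
    if quad <= 0:
        quad = 1e-12
    sigma2 = quad / dof
    ll = -0.5 * (dof * (_LOG2PI + np.log(sigma2)) + logdet_V0 + dof)
    if reml:
        sign, logdet_XtX = np.linalg.slogdet(XtX)
        if sign <= 0:
            return 1e300, {}
        ll -= 0.5 * logdet_XtX
        # constant term log|X'X|^{1/2} omitted consistently across fits
    aux = {
        "beta": beta,
        "sigma2_e": sigma2,
        "vcov_beta": sigma2 * np.linalg.inv(XtX),
        "gs": gs,
        "gp": gp,
    }
    return -ll, aux


def fit_linear_mixed(
    y: np.ndarray,
    X: np.ndarray,
    species: np.ndarray,
    population: np.ndarray,
    weights: np.ndarray | None = None,
    reml: bool = False,
) -> MixedFit:
    """Fit the weighted nested linear mixed model.

    ``weights`` are precision weights (observation i has residual variance
    ``sigma_e^2 / w_i``); they are normalized to mean 1 so fixed-effect
    estimates are invariant to their overall scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    sp, _ = _group_codes(np.asarray(species))
    pop, _ = _group_codes(np.asarray(population))

    # degenerate response: no residual information, return a flat fit
    if np.ptp(y) == 0.0:
        beta = np.zeros(p)
        beta[0] = y[0] if p else 0.0
        return MixedFit(
            beta=beta,
            vcov_beta=np.zeros((p, p)),
            loglik=0.0,
            sigma_species=0.0,
            sigma_population=0.0,
            sigma_resid=0.0,
            method="REML" if reml else "ML",
            converged=True,
            n_obs=n,
            messages=["constant response; degenerate fit"],
        )

    A = sp[:, None] == sp[None, :]
    B = pop[:, None] == pop[None, :]
    best = None
    for start in ([1.0, 1.0], [0.05, 0.05]):
        res = optimize.minimize(
            lambda g: _lmm_profile(g, y, X, A, B, w, reml)[0],
            x0=np.asarray(start),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * 2,
            options={"ftol": 1e-14, "gtol": 1e-10, "eps": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, aux = _lmm_profile(best.x, y, X, A, B, w, reml)
    sigma2_e = aux["sigma2_e"]
    return MixedFit(
        beta=aux["beta"],
        vcov_beta=aux["vcov_beta"],
        loglik=-nll,
        sigma_species=float(np.sqrt(aux["gs"] * sigma2_e)),
        sigma_population=float(np.sqrt(aux["gp"] * sigma2_e)),
        sigma_resid=float(np.sqrt(sigma2_e)),
        method="REML" if reml else "ML",
        converged=bool(best.success),
        n_obs=n,
        messages=[] if best.success else [best.message],
    )


# ---------------------------------------------------------------------------
# Binomial family (logit link, Laplace approximation)
# ---------------------------------------------------------------------------


def _laplace_profiled(
    lg: np.ndarray,
    yy: np.ndarray,
    nn: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    n_sp: int,
    n_pop: int,
    lnconst: float,
    v_cache: np.ndarray,
) -> tuple[float, dict]:
    """Laplace log-likelihood at log-sd pair ``lg``, beta profiled out.

    The inner penalized Newton maximizes the joint criterion over fixed
    effects and random effects together (the same profiling ``glmer`` uses
    at its default Laplace approximation); the outer optimizer then only
    searches the two variance parameters.
    """
    n, p = X.shape
    q = n_sp + n_pop
    if not np.all(np.isfinite(lg)):
        return -1e300, {}
    penalty = 1e4 * (max(0.0, abs(lg[0]) - 8.0) + max(0.0, abs(lg[1]) - 8.0))
    ls = float(np.clip(lg[0], -8.0, 8.0))
    lp = float(np.clip(lg[1], -8.0, 8.0))
    s2 = np.empty(q)
    s2[:n_sp] = np.exp(2.0 * ls)
    s2[n_sp:] = np.exp(2.0 * lp)
    dinv = 1.0 / s2
    A = np.hstack([X, Z])  # design for v = (beta, u)
    pen = np.concatenate([np.zeros(p), dinv])
    v = v_cache.copy()

    def joint(v):
        eta = A @ v
        u = v[p:]
        ll = float(yy @ eta - nn @ np.logaddexp(0.0, eta))
        ll -= 0.5 * float((u * dinv) @ u)
        ll -= 0.5 * float(np.log(s2).sum()) + 0.5 * q * _LOG2PI
        return ll, eta

    g_prev, eta = joint(v)
    if not np.isfinite(g_prev):
        v[:] = 0.0
        g_prev, eta = joint(v)
        if not np.isfinite(g_prev):
            return -1e300, {}
    H = None
    for _ in range(60):
        mu = special.expit(eta)
        grad = A.T @ (yy - nn * mu) - pen * v
        W = nn * mu * (1.0 - mu)
        H = (A.T * W) @ A
        H[np.diag_indices(p + q)] += pen
        # tiny ridge on the beta block guards rank-deficient designs
        H[np.diag_indices(p)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -1e300, {}
        t = 1.0
        g_new, eta_new, v_new = g_prev, eta, v
        for _ in range(20):
            v_try = v + t * step
            g_try, eta_try = joint(v_try)
            if np.isfinite(g_try) and g_try >= g_prev - 1e-12:
                g_new, eta_new, v_new = g_try, eta_try, v_try
                break
            t *= 0.5
        moved = abs(g_new - g_prev)
        v, g_prev, eta = v_new, g_new, eta_new
        if moved < 1e-11:
            break
    v_cache[:] = v
    mu = special.expit(eta)
    W = nn * mu * (1.0 - mu)
    Hu = (Z.T * W) @ Z
    Hu[np.diag_indices(q)] += dinv
    sign, logdet = np.linalg.slogdet(Hu)
    if sign <= 0 or not np.isfinite(logdet):
        return -1e300, {}
    ll = g_prev + 0.5 * q * _LOG2PI - 0.5 * logdet + lnconst - penalty
    if not np.isfinite(ll):
        return -1e300, {}
    # conditional vcov of beta: Schur complement of the u block
    Hxx = (X.T * W) @ X
    Hxz = (X.T * W) @ Z
    try:
        vcov_beta = np.linalg.inv(Hxx - Hxz @ np.linalg.solve(Hu, Hxz.T))
    except np.linalg.LinAlgError:
        vcov_beta = np.full((p, p), np.nan)
    return ll, {"beta": v[:p], "vcov_beta": vcov_beta}


def fit_binomial_mixed(
    successes: np.ndarray,
    trials: np.ndarray,
    X: np.ndarray,
    species: np.ndarray,
    population: np.ndarray,
    start_beta: np.ndarray | None = None,
    start_theta: np.ndarray | None = None,
) -> MixedFit:
    """Fit the nested binomial GLMM by Laplace-approximate ML.

    ``start_theta`` may carry ``[beta..., log_sd_species, log_sd_pop]`` from
    a nested fit to warm-start the search (the beta part seeds the inner
    Newton, the tail seeds the outer variance search).
    """
    yy = np.asarray(successes, dtype=float)
    nn = np.asarray(trials, dtype=float)
    if np.any(yy < 0) or np.any(yy > nn):
        raise ValueError("successes must lie in [0, trials]")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sp, n_sp = _group_codes(np.asarray(species))
    pop, n_pop = _group_codes(np.asarray(population))
    q = n_sp + n_pop
    Z = np.zeros((n, q))
    Z[np.arange(n), sp] = 1.0
    Z[np.arange(n), n_sp + pop] = 1.0
    lnconst = float(
        (special.gammaln(nn + 1) - special.gammaln(yy + 1) - special.gammaln(nn - yy + 1)).sum()
    )

    v_cache = np.zeros(p + q)
    if start_theta is not None:
        v_cache[:p] = np.asarray(start_theta[:p], dtype=float)
        lg0 = np.asarray(start_theta[p:p + 2], dtype=float)
    else:
        pbar = (yy.sum() + 0.5) / (nn.sum() + 1.0)
        v_cache[0] = special.logit(pbar) if p else 0.0
        lg0 = np.array([np.log(0.3), np.log(0.3)])
    if start_beta is not None:
        v_cache[:p] = np.asarray(start_beta, dtype=float)

    def nll_sigma(sg):
        sg = np.maximum(np.asarray(sg, dtype=float), 1e-8)
        return -_laplace_profiled(
            np.log(sg), yy, nn, X, Z, n_sp, n_pop, lnconst, v_cache
        )[0]

    # bounded quasi-Newton over the two sd parameters handles the sigma -> 0
    # boundary that a log-scale search cannot reach
    best = None
    for x0 in (np.exp(lg0), np.array([0.3, 0.3]), np.array([0.02, 0.02])):
        res = optimize.minimize(
            nll_sigma,
            x0=x0,
            method="L-BFGS-B",
            bounds=[(0.0, 50.0)] * 2,
            options={"ftol": 1e-13, "gtol": 1e-9, "eps": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    sg = np.maximum(best.x, 1e-8)
    ll, aux = _laplace_profiled(np.log(sg), yy, nn, X, Z, n_sp, n_pop, lnconst, v_cache)
    return MixedFit(
        beta=aux["beta"],
        vcov_beta=aux["vcov_beta"],
        loglik=float(ll),
        sigma_species=float(best.x[0]),
        sigma_population=float(best.x[1]),
        sigma_resid=None,
        method="Laplace-ML",
        converged=bool(best.success),
        n_obs=n,
        family="binomial",
        messages=[] if best.success else [best.message],
    )
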