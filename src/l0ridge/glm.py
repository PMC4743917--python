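"""Adaptive ridge for Poisson regression.

Counts follow ``y_i ~ Poisson(mu_i)`` with log link ``mu_i = exp(X_i beta +
offset_i)`` and no intercept unless one is supplied as a forced-in column.
Each AR step maximises the weighted-ridge penalized log-likelihood

    l(beta; lam, w) = beta' X' y - u' mu(beta) - (lam / 2) beta' diag(w) beta

by damped Newton-Raphson: gradient ``X'(y - mu) - lam diag(w) beta`` and
Hessian ``-X' diag(mu) X - lam diag(w)``, with step-halving so an accepted
step never decreases the penalized log-likelihood (the bare Newton update
can diverge for poorly scaled designs; the safeguard does not move the fixed
point).  The outer AR loop warm-starts each Newton solve from the previous
outer ``beta``.

Other one-parameter exponential families (e.g. logistic regression) fit the
same scheme — only ``mu``, the gradient and the Hessian change — but Poisson
is the only family wired up here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .core import ARConfig, ARState, support, update_weights
from .linear import RegularizationPath

__all__ = [
    "PoissonProblem",
    "GLMARFit",
    "PoissonSolverError",
    "poisson_loglik",
    "poisson_weighted_ridge",
    "ar_poisson",
    "ar_poisson_path",
]

# linear predictors above this overflow exp() in double precision
_ETA_MAX = 700.0


class PoissonSolverError(RuntimeError):
    """Newton solver failed; ``beta`` carries the last iterate."""

    def __init__(self, message: str, beta: np.ndarray):
        super().__init__(message)
        self.beta = beta


@dataclass
class PoissonProblem:
    """Design matrix, non-negative integer counts and optional log-offset."""

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray | None = None
    _xty: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if self.y.shape != (n,):
            raise ValueError(f"y must have length {n}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must be finite")
        yf = np.asarray(self.y, dtype=float)
        if np.any(yf < 0) or not np.all(np.isfinite(yf)) or np.any(yf != np.round(yf)):
            raise ValueError("y must be non-negative integer counts")
        self.y = yf
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape != (n,):
                raise ValueError(f"offset must have length {n}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def offset_vec(self) -> np.ndarray:
        return self.offset if self.offset is not None else np.zeros(self.n)

    @property
    def xty(self) -> np.ndarray:
        if self._xty is None:
            self._xty = self.X.T @ self.y
        return self._xty

    def subproblem(self, cols: np.ndarray) -> "PoissonProblem":
        return PoissonProblem(self.X[:, np.asarray(cols)], self.y, offset=self.offset)


@dataclass
class GLMARFit:
    """Converged AR state plus the unpenalized Poisson ML refit on the support."""

    state: ARState
    lambda_tilde: float
    support: np.ndarray
    beta_refit: np.ndarray
    loglik_refit: float
    newton_iters_total: int = 0

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.support)


def poisson_loglik(problem: PoissonProblem, beta: np.ndarray) -> float:
    """Poisson log-likelihood ``beta' X' y - u' exp(X beta + offset)``.

    The ``sum(log y_i!)`` constant is dropped; the convention is consistent
    across all comparisons within the package.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = problem.X @ beta + problem.offset_vec
    if eta.size and float(eta.max()) > _ETA_MAX:
        raise OverflowError(
            "linear predictor overflows exp(); rescale the covariates or "
            "shrink beta"
        )
    return float(beta @ problem.xty - np.exp(eta).sum())


def _penalized_loglik(problem, beta, lam, w):
    """Penalized log-likelihood; -inf on overflow (used inside line search)."""
    eta = problem.X @ beta + problem.offset_vec
    if eta.size and float(eta.max()) > _ETA_MAX:
        return -np.inf
    return float(beta @ problem.xty - np.exp(eta).sum() - 0.5 * lam * np.sum(w * beta**2))


def poisson_weighted_ridge(
    problem: PoissonProblem,
    lam: float,
    weights: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    return_iters: bool = False,
):
    """Maximize the weighted-ridge Poisson log-likelihood by damped Newton.

    Stops when the sup-norm of the penalized gradient drops below ``tol`` or
    after ``max_iter`` Newton steps (the latter raises
    :class:`PoissonSolverError` carrying the last iterate).  Step-halving
    guarantees the penalized log-likelihood never decreases along accepted
    steps.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    w = np.broadcast_to(np.asarray(weights, dtype=float), (problem.p,)).copy()
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    X = problem.X
    beta = np.zeros(problem.p) if init is None else np.asarray(init, dtype=float).copy()
    f = _penalized_loglik(problem, beta, lam, w)
    if not np.isfinite(f):
        raise ValueError("initial beta overflows the linear predictor")
    iters = 0
    for _ in range(max_iter):
        eta = X @ beta + problem.offset_vec
        mu = np.exp(eta)
        grad = problem.xty - X.T @ mu - lam * w * beta
        gnorm = float(np.max(np.abs(grad), initial=0.0))
        if gnorm < tol:
            break
        H = (X * mu[:, None]).T @ X
        H[np.diag_indices_from(H)] += lam * w
        try:
            c, low = sla.cho_factor(H, check_finite=False)
        except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
            raise np.linalg.LinAlgError(f"singular Hessian in Poisson solver: {exc}")
        step = sla.cho_solve((c, low), grad, check_finite=False)
        t = 1.0
        accepted = False
        while t >= 2.0**-40:
            cand = beta + t * step
            fc = _penalized_loglik(problem, cand, lam, w)
            if fc >= f - 1e-12 * max(1.0, abs(f)):
                accepted = True
                break
            t /= 2.0
        if not accepted:
            if gnorm < 1e-6:
                break  # at numerical precision of the optimum
            raise PoissonSolverError(
                f"line search failed with gradient norm {gnorm:.3g}", beta
            )
        beta = cand
        f = fc
        iters += 1
    else:
        raise PoissonSolverError(
            f"Newton did not converge in {max_iter} steps "
            f"(gradient norm {gnorm:.3g})",
            beta,
        )
    if return_iters:
        return beta, iters
    return beta


def _refit_poisson(problem: PoissonProblem, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Unpenalized ML refit on the masked columns; full-length coefficients."""
    mask = np.asarray(mask, dtype=bool)
    coef = np.zeros(problem.p)
    if not mask.any():
        return coef, poisson_loglik(problem, coef)
    sub = problem.subproblem(np.flatnonzero(mask))
    try:
        sol = poisson_weighted_ridge(sub, 0.0, np.zeros(sub.p))
    except PoissonSolverError as err:
        warnings.warn(
            "Poisson ML refit did not fully converge; using the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
        sol = err.beta
    coef[mask] = sol
    return coef, poisson_loglik(sub, sol)


def ar_poisson(
    problem: PoissonProblem,
    lambda_tilde: float,
    config: ARConfig | None = None,
    *,
    beta0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> GLMARFit:
    """AR for Poisson regression: alternate Newton solves and weight updates.

    The inner Newton solver is warm-started from the previous outer ``beta``
    (the penalty changes smoothly between outer iterations, so one or two
    Newton steps usually suffice).  Convergence is declared on the selection
    indicators as in the linear case.
    """
    cfg = config if config is not None else ARConfig()
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be >= 0")
    p = problem.p
    forced = cfg.forced_mask(p)
    if w0 is not None:
        w = np.asarray(w0, dtype=float).copy()
        w[forced] = 0.0
    else:
        w = cfg.initial_weights(p)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    prev_ind = None
    converged = False
    newton_total = 0
    k = 0
    for k in range(1, cfg.max_iter + 1):
        beta, it = poisson_weighted_ridge(
            problem, lambda_tilde, w, init=beta, return_iters=True
        )
        newton_total += it
        w = update_weights(beta, cfg)
        ind = w * beta**2
        if prev_ind is not None and np.max(np.abs(ind - prev_ind), initial=0.0) < cfg.tol:
            converged = True
            break
        prev_ind = ind
    if not converged:
        warnings.warn(
            f"AR (Poisson) did not converge within {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    state = ARState(beta=beta, weights=w, iteration=k, converged=converged)
    mask = support(state)
    coef, ll = _refit_poisson(problem, mask)
    return GLMARFit(
        state=state,
        lambda_tilde=lambda_tilde,
        support=mask,
        beta_refit=coef,
        loglik_refit=ll,
        newton_iters_total=newton_total,
    )


def ar_poisson_path(
    problem: PoissonProblem,
    lambdas: np.ndarray,
    config: ARConfig | None = None,
) -> RegularizationPath:
    """Warm-started Poisson AR fits over an increasing penalty grid."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty penalty grid")
    if lambdas.size > 1 and not np.all(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be strictly increasing")
    cfg = config if config is not None else ARConfig()
    fits = []
    beta_start = None
    w_start = None
    for lam in lambdas:
        fit = ar_poisson(problem, float(lam), cfg, beta0=beta_start, w0=w_start)
        beta_start = fit.state.beta.copy()
        w_start = fit.state.weights.copy()
        fits.append(fit)
    return RegularizationPath(lambdas=lambdas, fits=fits)
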