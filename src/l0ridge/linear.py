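"""Adaptive ridge for Gaussian linear regression.

The model is ``y = X beta + eps`` with i.i.d. ``N(0, sigma^2)`` errors,
``y`` centered and every column of ``X`` centered and scaled to squared norm
``n`` (so there is no intercept).  With known error variance the contrast is
``C(beta) = RSS(beta) / sigma^2`` and each AR step has the closed form

    beta = (X'X + lambda_tilde * sigma^2 * diag(w))^{-1} X'y,

an explicit dynamic system in ``(beta, w)``.  Under an orthogonal design the
system decouples per coordinate and AR with penalty ``lambda_tilde`` selects
exactly the coordinates an L0 criterion with penalty ``lambda = 4 *
lambda_tilde`` would select (valid for ``lambda_tilde < n / sigma^2``); the
surviving coefficients converge to the stable root
``(beta_hat + sqrt(beta_hat^2 - 4 lambda_tilde sigma^2 / n)) / 2``, i.e. they
are shrunk relative to the OLS estimate.  :func:`orthogonal_fixed_point`
exposes that closed form; it is the reference oracle for the iterative path.

Regularization paths are traversed over *increasing* penalties (the reverse
of the usual LASSO convention), warm-starting each fit from the previous
``(beta, w)`` so that coordinates absorbed at zero stay there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .core import ARConfig, ARState, check_convergence, support, update_weights

__all__ = [
    "LinearProblem",
    "LinearARFit",
    "RegularizationPath",
    "standardize",
    "estimate_sigma2",
    "weighted_ridge_solve",
    "ar_fit",
    "ar_fit_restarts",
    "ar_path",
    "l0_equivalent_penalty",
    "orthogonal_fixed_point",
    "default_lambda_grid",
    "refit_ols",
    "path_to_frame",
]


@dataclass
class LinearProblem:
    """Design matrix, response and (known) error variance for AR.

    ``sigma2`` is an explicit input defaulting to 1, matching the
    known-variance form of the contrast; see
    :func:`estimate_sigma2` for an optional plug-in that is never applied
    silently.  When ``standardized`` is set, columns of ``X`` have mean 0 and
    squared norm ``n`` and ``y`` has mean 0.
    """

    X: np.ndarray
    y: np.ndarray
    sigma2: float = 1.0
    standardized: bool = False
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_center: float | None = None
    _gram: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)
    _xty: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if self.y.shape[0] != n:
            raise ValueError(f"y has length {self.y.shape[0]}, expected {n}")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.X.T @ self.X
        return self._gram

    @property
    def xty(self) -> np.ndarray:
        if self._xty is None:
            self._xty = self.X.T @ self.y
        return self._xty

    def subproblem(self, cols: np.ndarray) -> "LinearProblem":
        """Restriction to a subset of columns (same response and variance)."""
        cols = np.asarray(cols)
        return LinearProblem(
            self.X[:, cols], self.y, sigma2=self.sigma2, standardized=self.standardized
        )


@dataclass
class LinearARFit:
    """Converged AR state plus the ML refit on the selected support."""

    state: ARState
    lambda_tilde: float
    support: np.ndarray
    beta_refit: np.ndarray
    rss: float
    history: dict | None = None

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.support)


@dataclass
class RegularizationPath:
    """AR solutions over a strictly increasing penalty grid, warm-started."""

    lambdas: np.ndarray
    fits: list
    criterion_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.fits) != self.lambdas.size:
            raise ValueError("fits must align with lambdas")
        if self.lambdas.size > 1 and not np.all(np.diff(self.lambdas) > 0):
            raise ValueError("lambdas must be strictly increasing")

    def supports(self) -> list:
        return [f.support for f in self.fits]


def standardize(X: np.ndarray, y: np.ndarray, sigma2: float = 1.0) -> LinearProblem:
    """Center/scale columns of ``X`` to squared norm ``n`` and center ``y``.

    The column centers and scales are retained on the returned problem so
    coefficients can be mapped back to the original scale.  Raises on
    zero-variance columns (they cannot be scaled and carry no signal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p and y length n")
    n = X.shape[0]
    center = X.mean(axis=0)
    Xc = X - center
    ss = np.einsum("ij,ij->j", Xc, Xc)
    bad = np.flatnonzero(ss <= n * np.finfo(float).eps * max(1.0, float(np.abs(X).max())) ** 2)
    if bad.size:
        raise ValueError(f"column {bad[0]} has zero variance and cannot be standardized")
    scale = np.sqrt(ss / n)
    y_center = float(y.mean())
    return LinearProblem(
        Xc / scale,
        y - y_center,
        sigma2=sigma2,
        standardized=True,
        x_center=center,
        x_scale=scale,
        y_center=y_center,
    )


def estimate_sigma2(problem: LinearProblem) -> float:
    """Plug-in residual-variance estimate from the full OLS model (p < n only)."""
    n, p = problem.n, problem.p
    if p >= n:
        raise ValueError("full-model variance estimate requires p < n")
    coef, rss = refit_ols(problem, np.ones(p, dtype=bool))
    dof = n - p
    return float(rss / dof)


def weighted_ridge_solve(
    problem: LinearProblem,
    lambda_tilde: float,
    weights: np.ndarray,
    jitter_on_singular: bool = False,
) -> np.ndarray:
    """Solve ``(X'X + lambda_tilde sigma^2 diag(w)) beta = X'y`` (SPD solve).

    Never forms an explicit inverse.  A singular system (e.g. an
    unpenalized solve with rank-deficient ``X``) raises unless
    ``jitter_on_singular`` is set, in which case a ridge of ``1e-10 * n`` is
    added to the diagonal with a warning.
    """
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be >= 0")
    w = np.broadcast_to(np.asarray(weights, dtype=float), (problem.p,))
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    A = problem.gram + (lambda_tilde * problem.sigma2) * np.diag(w)
    try:
        c, low = sla.cho_factor(A, check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        if not jitter_on_singular:
            raise np.linalg.LinAlgError(
                "singular ridge system (rank-deficient X with an effectively "
                "zero penalty); increase lambda_tilde"
            )
        warnings.warn(
            "singular ridge system; adding a 1e-10 * n diagonal jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        A = A + (1e-10 * problem.n) * np.eye(problem.p)
        c, low = sla.cho_factor(A, check_finite=False)
    return sla.cho_solve((c, low), problem.xty, check_finite=False)


def refit_ols(problem: LinearProblem, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-likelihood (OLS) refit on the masked columns.

    Returns the full-length coefficient vector (zero off-support) and the
    residual sum of squares.  An empty support gives the null model.
    """
    mask = np.asarray(mask, dtype=bool)
    coef = np.zeros(problem.p)
    if not mask.any():
        return coef, float(problem.y @ problem.y)
    sol, _, _, _ = np.linalg.lstsq(problem.X[:, mask], problem.y, rcond=None)
    coef[mask] = sol
    resid = problem.y - problem.X[:, mask] @ sol
    return coef, float(resid @ resid)


def l0_equivalent_penalty(lam: float) -> float:
    """AR penalty matching L0 selection at penalty ``lam`` (orthogonal design).

    Selection with an L0 penalty ``lam`` (e.g. ``2`` for AIC, ``log n`` for
    BIC) corresponds to running AR with the four-fold smaller penalty
    ``lam / 4``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return lam / 4.0


def default_lambda_grid(problem: LinearProblem, num: int = 100, lo_frac: float = 1e-4) -> np.ndarray:
    """Log-spaced increasing grid from ``lo_frac * n/sigma^2`` to ``n/sigma^2``."""
    hi = problem.n / problem.sigma2
    return np.geomspace(lo_frac * hi, hi, num)


def ar_fit(
    problem: LinearProblem,
    lambda_tilde: float,
    config: ARConfig | None = None,
    *,
    beta0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    record_history: bool = False,
) -> LinearARFit:
    """Run the AR iteration to convergence and refit ML on the support.

    Alternates the closed-form weighted ridge solve with the weight update
    until the selection indicators stabilise.  ``w0`` warm-starts the weight
    vector (used along regularization paths); ``beta0`` is accepted for
    interface symmetry with the GLM solver but is unused here because the
    inner solve is exact given the weights.  Non-convergence at ``max_iter``
    warns and returns the last state.
    """
    del beta0  # exact inner solve: only the weights carry state
    cfg = config if config is not None else ARConfig()
    n, p = problem.n, problem.p
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be >= 0")
    if lambda_tilde > n / problem.sigma2:
        warnings.warn(
            "lambda_tilde > n / sigma^2: outside the regime where AR "
            "selection matches L0 selection at 4 * lambda_tilde",
            RuntimeWarning,
            stacklevel=2,
        )
    forced = cfg.forced_mask(p)
    if w0 is not None:
        w = np.asarray(w0, dtype=float).copy()
        w[forced] = 0.0
    else:
        w = cfg.initial_weights(p)
    jitter = lambda_tilde == 0.0
    prev_ind = None
    hist_ind: list[np.ndarray] = []
    hist_beta: list[np.ndarray] = []
    converged = False
    k = 0
    for k in range(1, cfg.max_iter + 1):
        beta = weighted_ridge_solve(problem, lambda_tilde, w, jitter_on_singular=jitter)
        w = update_weights(beta, cfg)
        ind = w * beta**2
        if record_history:
            hist_ind.append(ind)
            hist_beta.append(beta)
        if prev_ind is not None and np.max(np.abs(ind - prev_ind), initial=0.0) < cfg.tol:
            converged = True
            break
        prev_ind = ind
    if not converged:
        warnings.warn(
            f"AR did not converge within {cfg.max_iter} iterations "
            f"(lambda_tilde={lambda_tilde:g}); returning the last state",
            RuntimeWarning,
            stacklevel=2,
        )
    state = ARState(beta=beta, weights=w, iteration=k, converged=converged)
    mask = support(state)
    coef, rss = refit_ols(problem, mask)
    history = None
    if record_history:
        history = {"indicators": np.array(hist_ind), "beta": np.array(hist_beta)}
    return LinearARFit(
        state=state,
        lambda_tilde=lambda_tilde,
        support=mask,
        beta_refit=coef,
        rss=rss,
        history=history,
    )


def ar_fit_restarts(
    problem: LinearProblem,
    lambda_tilde: float,
    config: ARConfig | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
    score=None,
) -> LinearARFit:
    """Best-of-several AR fits over random initial weights.

    The AR limit can depend on ``w^(0)``; this helper re-runs the fit from
    ``w^(0) ~ U(0.5, 1.5)`` draws (plus the all-ones default) and keeps the
    fit with the smallest score.  The default score is the L0 objective the
    penalty targets, ``rss / sigma^2 + 4 * lambda_tilde * |M|``.
    """
    cfg = config if config is not None else ARConfig()
    rng = np.random.default_rng(rng)
    if score is None:

        def score(prob, fit):
            return fit.rss / prob.sigma2 + 4.0 * lambda_tilde * int(fit.support.sum())

    best = ar_fit(problem, lambda_tilde, cfg)
    best_score = score(problem, best)
    forced = cfg.forced_mask(problem.p)
    for _ in range(n_restarts):
        w0 = rng.uniform(0.5, 1.5, size=problem.p)
        w0[forced] = 0.0
        fit = ar_fit(problem, lambda_tilde, cfg, w0=w0)
        s = score(problem, fit)
        if s < best_score:
            best, best_score = fit, s
    return best


def ar_path(
    problem: LinearProblem,
    lambdas: np.ndarray,
    config: ARConfig | None = None,
) -> RegularizationPath:
    """Warm-started AR fits over a strictly increasing penalty grid.

    Each fit starts from the previous fit's final weights, so coordinates
    already absorbed at zero (huge weight) remain there and the support
    shrinks as the penalty grows.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty penalty grid")
    if lambdas.size > 1 and not np.all(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be strictly increasing")
    cfg = config if config is not None else ARConfig()
    fits = []
    w_start = None
    for lam in lambdas:
        fit = ar_fit(problem, float(lam), cfg, w0=w_start)
        w_start = fit.state.weights.copy()
        fits.append(fit)
    return RegularizationPath(lambdas=lambdas, fits=fits)


def orthogonal_fixed_point(
    beta_hat: float | np.ndarray, n: int, sigma2: float, lambda_tilde: float
) -> float | np.ndarray:
    """Limit of the scalar AR map under an orthogonal design (delta -> 0).

    Returns 0 when ``beta_hat^2 < 4 lambda_tilde sigma^2 / n``; otherwise the
    stable root ``sign(beta_hat) (|beta_hat| + sqrt(beta_hat^2 - 4 lambda_tilde
    sigma^2 / n)) / 2``.  At the boundary (zero discriminant) the double root
    ``beta_hat / 2`` is returned.
    """
    bh = np.asarray(beta_hat, dtype=float)
    c = 4.0 * lambda_tilde * sigma2 / n
    disc = bh**2 - c
    out = np.where(
        disc < 0,
        0.0,
        np.sign(bh) * (np.abs(bh) + np.sqrt(np.clip(disc, 0.0, None))) / 2.0,
    )
    if np.isscalar(beta_hat) or np.ndim(beta_hat) == 0:
        return float(out)
    return out


def path_to_frame(path: RegularizationPath) -> pd.DataFrame:
    """Tabular view of a path: penalty, support size/indices, RSS, criterion."""
    rows = []
    for i, (lam, fit) in enumerate(zip(path.lambdas, path.fits)):
        rows.append(
            {
                "lambda_tilde": lam,
                "n_selected": int(fit.support.sum()),
                "support": ",".join(map(str, np.flatnonzero(fit.support))),
                "rss": fit.rss,
                "criterion": (
                    float(path.criterion_values[i])
                    if path.criterion_values is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
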