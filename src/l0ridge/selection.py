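"""Model-selection criteria and baseline selectors.

A model is a support ``M`` (set of non-zero coefficients).  Every criterion
here has the form ``-2 log L(M) + |M| * lam_crit`` evaluated at the maximum
likelihood *refit* on ``M`` (never at the shrunken AR coefficients, which
would misstate the likelihood term).  Per-parameter penalties:

* AIC:   ``lam_crit = 2``
* BIC:   ``lam_crit = log n``
* mBIC:  ``lam_crit = log(n * p_total^2 / c^2)`` — the modified BIC for
  sparse high-dimensional selection, with ``c`` the a-priori expected number
  of true regressors (default 4) and ``p_total`` the number of candidate
  regressors *before* any marginal preselection (preselection is part of the
  search, not of the model space).

For Gaussian problems with known variance ``-2 log L = RSS / sigma^2`` up to
an additive constant (dropped consistently); with estimated variance it is
``n log(RSS / n)``.  For Poisson problems it is ``-2`` times the
log-likelihood of :func:`l0ridge.glm.poisson_loglik`.

Besides criterion evaluation this module hosts the baseline selectors used
to benchmark AR: exhaustive all-subset search (p <= 20), a marginal-screen
stepwise search (backward from the top-``top_m`` marginal regressors, then
greedy forward), and marginal preselection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from . import glm as _glm
from . import linear as _linear

__all__ = [
    "CriterionSpec",
    "ModelFit",
    "evaluate_criterion",
    "choose_on_path",
    "stepwise_select",
    "all_subset_select",
    "marginal_preselect",
    "marginal_statistics",
]

_NAMES = ("aic", "bic", "mbic")


@dataclass
class CriterionSpec:
    """A selection criterion: name, mBIC prior ``c``, and variance handling.

    ``p_total`` is the regressor count entering the mBIC penalty; when left
    unset it is filled from the problem at evaluation time, which is only
    correct if no preselection took place.
    """

    name: str = "bic"
    c: float = 4.0
    p_total: int | None = None
    variance_mode: str = "known"

    def __post_init__(self) -> None:
        self.name = self.name.lower()
        if self.name not in _NAMES:
            raise ValueError(f"criterion must be one of {_NAMES}, got {self.name!r}")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.p_total is not None and self.p_total < 1:
            raise ValueError("p_total must be >= 1")
        if self.variance_mode not in ("known", "estimated"):
            raise ValueError("variance_mode must be 'known' or 'estimated'")

    def per_parameter_penalty(self, n: int, p_default: int | None = None) -> float:
        """The per-parameter penalty ``lam_crit`` of the criterion."""
        if self.name == "aic":
            return 2.0
        if self.name == "bic":
            return float(np.log(n))
        p_total = self.p_total if self.p_total is not None else p_default
        if p_total is None:
            raise ValueError("mBIC requires p_total")
        return float(np.log(n * p_total**2 / self.c**2))


@dataclass
class ModelFit:
    """A refitted support with its criterion value."""

    support: np.ndarray
    coefficients: np.ndarray
    minus2loglik: float
    criterion_value: float

    @property
    def size(self) -> int:
        return self.support.size


def _as_indices(support, p: int) -> np.ndarray:
    support = np.asarray(support)
    if support.dtype == bool:
        if support.size != p:
            raise ValueError("boolean support mask must have length p")
        return np.flatnonzero(support)
    idx = np.unique(support.astype(np.intp))
    if idx.size and (idx[0] < 0 or idx[-1] >= p):
        raise ValueError("support indices out of range")
    return idx


def _is_poisson(problem) -> bool:
    return isinstance(problem, _glm.PoissonProblem)


def _gaussian_m2ll(problem, rss: float, spec: CriterionSpec) -> float:
    if spec.variance_mode == "known":
        return rss / problem.sigma2
    return problem.n * float(np.log(max(rss, 1e-300) / problem.n))


def evaluate_criterion(problem, support, spec: CriterionSpec) -> ModelFit:
    """ML refit on ``support`` and criterion value ``-2 log L + |M| lam_crit``."""
    p = problem.p
    idx = _as_indices(support, p)
    if idx.size >= problem.n:
        raise ValueError(f"support size {idx.size} >= n = {problem.n}: refit infeasible")
    pen = spec.per_parameter_penalty(problem.n, p_default=p)
    mask = np.zeros(p, dtype=bool)
    mask[idx] = True
    if _is_poisson(problem):
        coef, ll = _glm._refit_poisson(problem, mask)
        m2ll = -2.0 * ll
    else:
        coef, rss = _linear.refit_ols(problem, mask)
        m2ll = _gaussian_m2ll(problem, rss, spec)
    return ModelFit(
        support=idx,
        coefficients=coef,
        minus2loglik=m2ll,
        criterion_value=m2ll + idx.size * pen,
    )


def choose_on_path(problem, path, spec: CriterionSpec) -> ModelFit:
    """Evaluate the criterion at every distinct support on a path; return the best.

    Duplicate supports along the path are evaluated once.  Ties are broken
    toward smaller supports, then larger penalties.  As a side effect the
    per-penalty criterion values are stored on ``path.criterion_values``.
    """
    if not path.fits:
        raise ValueError("empty path")
    cache: dict[bytes, ModelFit] = {}
    values = np.empty(len(path.fits))
    best = None
    best_key = None
    for i, fit in enumerate(path.fits):
        key = np.asarray(fit.support, dtype=bool).tobytes()
        mf = cache.get(key)
        if mf is None:
            mf = evaluate_criterion(problem, fit.support, spec)
            cache[key] = mf
        values[i] = mf.criterion_value
        cand_key = (mf.criterion_value, mf.size, -i)
        if best is None or cand_key < best_key:
            best, best_key = mf, cand_key
    path.criterion_values = values
    return best


def marginal_statistics(problem) -> tuple[np.ndarray, np.ndarray]:
    """Per-column marginal test statistics and two-sided p-values.

    Gaussian: single-regressor OLS t statistics (response already centered,
    no intercept).  Poisson: score statistics against the intercept-only
    (constant-rate ``ybar``) null, standard-normal reference.
    """
    if _is_poisson(problem):
        ybar = float(problem.y.mean())
        ybar = max(ybar, 1e-12)
        Xc = problem.X - problem.X.mean(axis=0)
        u = Xc.T @ (problem.y - ybar)
        v = ybar * np.einsum("ij,ij->j", Xc, Xc)
        z = u / np.sqrt(np.maximum(v, 1e-300))
        return z, 2.0 * stats.norm.sf(np.abs(z))
    X, y = problem.X, problem.y
    n = problem.n
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = X.T @ y
    b = sxy / sxx
    rss = float(y @ y) - b * sxy
    dof = max(n - 1, 1)
    s2 = np.maximum(rss, 1e-300) / dof
    t = b / np.sqrt(s2 / sxx)
    return t, 2.0 * stats.t.sf(np.abs(t), dof)


def marginal_preselect(problem, m: int | None = None, alpha: float | None = None) -> np.ndarray:
    """Columns passing a marginal-test screen, as indices into the full matrix.

    Exactly one of ``m`` (keep the ``m`` marginally most significant columns)
    or ``alpha`` (keep columns with marginal p-value below ``alpha``) must be
    given.  Note the mBIC penalty must keep using the *original* ``p``.
    """
    if (m is None) == (alpha is None):
        raise ValueError("give exactly one of m or alpha")
    _, pvals = marginal_statistics(problem)
    if m is not None:
        if m > problem.p:
            warnings.warn(
                f"m={m} exceeds p={problem.p}; keeping all columns",
                RuntimeWarning,
                stacklevel=2,
            )
            m = problem.p
        order = np.argsort(pvals, kind="stable")[:m]
        return np.sort(order)
    return np.flatnonzero(pvals < alpha)


@lru_cache(maxsize=64)
def _combos(p: int, k: int) -> np.ndarray:
    arr = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(p), k)),
        dtype=np.intp,
    )
    return arr.reshape(-1, k)


def all_subset_select(problem, spec: CriterionSpec) -> ModelFit:
    """Exhaustive criterion minimization over all ``2^p`` supports (p <= 20).

    Gaussian problems use batched per-size solves of the normal equations on
    the precomputed Gram matrix; Poisson problems refit each subset.  Ties
    prefer smaller supports, then lexicographically earliest subsets.
    """
    p = problem.p
    if p > 20:
        raise ValueError(
            f"all-subset search over 2^{p} models is infeasible; use stepwise_select"
        )
    if _is_poisson(problem):
        best = evaluate_criterion(problem, np.array([], dtype=int), spec)
        for k in range(1, p + 1):
            for comb in itertools.combinations(range(p), k):
                mf = evaluate_criterion(problem, np.array(comb), spec)
                if mf.criterion_value < best.criterion_value:
                    best = mf
        return best
    n = problem.n
    pen = spec.per_parameter_penalty(n, p_default=p)
    G = problem.gram
    b = problem.xty
    yty = float(problem.y @ problem.y)
    best_crit = _gaussian_m2ll(problem, yty, spec)
    best_idx = np.array([], dtype=np.intp)
    for k in range(1, p + 1):
        subs = _combos(p, k)
        Gs = G[subs[:, :, None], subs[:, None, :]]
        bs = b[subs]
        coef = np.linalg.solve(Gs, bs[..., None])[..., 0]
        rss = np.maximum(yty - np.einsum("ij,ij->i", bs, coef), 0.0)
        if spec.variance_mode == "known":
            m2ll = rss / problem.sigma2
        else:
            m2ll = n * np.log(np.maximum(rss, 1e-300) / n)
        crit = m2ll + k * pen
        i = int(np.argmin(crit))  # first occurrence -> lexicographically smallest
        if crit[i] < best_crit:
            best_crit = float(crit[i])
            best_idx = subs[i]
    return evaluate_criterion(problem, best_idx, spec)


def stepwise_select(problem, spec: CriterionSpec, top_m: int = 40) -> ModelFit:
    """Marginal screen + greedy backward elimination + greedy forward addition.

    Starts from the ``min(top_m, p)`` marginally strongest regressors,
    eliminates greedily all the way down to a single regressor while
    recording the criterion at every visited model, then adds regressors
    greedily (over all ``p``) from the best visited model until no further
    improvement.
    """
    p = problem.p
    stat, _ = marginal_statistics(problem)
    order = np.argsort(-np.abs(stat), kind="stable")
    current = list(np.sort(order[: min(top_m, p)]))
    best = evaluate_criterion(problem, np.array(current), spec)
    # backward to size one, visiting the best removal at each step
    while len(current) > 1:
        step_best = None
        step_set = None
        for j in current:
            trial = [i for i in current if i != j]
            mf = evaluate_criterion(problem, np.array(trial), spec)
            if step_best is None or mf.criterion_value < step_best.criterion_value:
                step_best, step_set = mf, trial
        current = step_set
        if step_best.criterion_value < best.criterion_value:
            best = step_best
    # greedy forward from the best visited model
    current = list(best.support)
    while True:
        step_best = None
        step_set = None
        in_model = set(current)
        for j in range(p):
            if j in in_model:
                continue
            trial = sorted(current + [j])
            if len(trial) >= problem.n:
                continue
            mf = evaluate_criterion(problem, np.array(trial), spec)
            if step_best is None or mf.criterion_value < step_best.criterion_value:
                step_best, step_set = mf, trial
        if step_best is None or step_best.criterion_value >= best.criterion_value:
            break
        best, current = step_best, step_set
    return best
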