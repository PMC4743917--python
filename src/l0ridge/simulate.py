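"""Synthetic-data generators and the benchmark harness.

The generators emulate the four study designs used to characterise the
adaptive-ridge selector:

* ``gen_correlated_gaussian`` — small-p linear regression (n=50, p=15) with
  compound-symmetry or AR(1) correlated standard-normal regressors, five
  effects of 0.5 and unit noise.  The true support sits on the first five
  coordinates (the "leading" layout, paired with compound symmetry) or on
  every third coordinate (the "spaced" layout, paired with AR(1)
  correlation between neighbours).
* ``gen_highdim_gaussian`` — n=100 with p up to 10000 independent
  standard-normal regressors, 24 effects drawn N(0, 0.5) (variance), unit
  noise.
* ``gen_large_effects`` — n=300 with X_ij ~ N(0, 0.1^2) and non-zero effects
  N(0, 1.5^2) on the first k coordinates; Gaussian response with unit noise
  (the noise level is an assumption: the generating family is described only
  as a standard linear model) or Poisson counts with rate exp(X beta).
* ``gen_segmentation_signal`` — n=500 piecewise-constant signal with
  breakpoints at 100/250/375, segment means (-0.3, 0.7, 1.5, 0.5), unit
  noise.

Gaussian designs are returned standardized (columns centered and scaled to
squared norm n, response centered); Poisson designs are returned raw, since
centering the covariates of an intercept-free log-linear model would change
the model being fit.  All generators are deterministic given an
``np.random.Generator``; the replicate runners derive one generator per
replicate from ``(seed, stream tag, replicate)`` so any subset of replicates
is reproducible on its own.

Classification metrics follow the benchmark conventions: power = TP / k*,
FP = |selected \\ truth|, FDR = FP / max(1, |selected|) (0 on an empty
selection), Mis = (k* - TP) + FP.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import PoissonProblem, ar_poisson_path
from .linear import (
    LinearProblem,
    ar_fit,
    ar_path,
    default_lambda_grid,
    standardize,
)
from .segmentation import Signal, ar_segment, dp_exact_segment, penalized_cost
from .selection import (
    CriterionSpec,
    all_subset_select,
    choose_on_path,
    marginal_preselect,
)

__all__ = [
    "ScenarioSpec",
    "BenchmarkMetrics",
    "gen_correlated_gaussian",
    "gen_highdim_gaussian",
    "gen_large_effects",
    "gen_segmentation_signal",
    "evaluate_selection",
    "run_benchmark",
    "run_smallp_benchmark",
    "run_linear_path_benchmark",
    "run_poisson_path_benchmark",
    "run_segmentation_calibration",
]

SUPPORT_LEADING = (0, 1, 2, 3, 4)
SUPPORT_SPACED = (1, 4, 7, 10, 13)

# stream tags keeping the replicate RNG streams of different scenarios apart
_TAG_SMALLP = 11
_TAG_PATH_LINEAR = 31
_TAG_PATH_POISSON = 32
_TAG_SEGMENT = 41


def _corr_matrix(p: int, rho: float, structure: str) -> np.ndarray:
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if structure == "cs":
        return (1.0 - rho) * np.eye(p) + rho * np.ones((p, p))
    if structure == "ar1":
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    raise ValueError(f"unknown correlation structure {structure!r}")


def gen_correlated_gaussian(
    n: int = 50,
    p: int = 15,
    rho: float = 0.0,
    structure: str = "cs",
    support: tuple = SUPPORT_LEADING,
    beta: float = 0.5,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Correlated-design linear regression draw, standardized.

    Rows of ``X`` are zero-mean Gaussian with unit variances and correlation
    ``rho`` between all pairs (``structure='cs'``) or ``rho^|i-j|``
    (``'ar1'``).  Returns ``(X, y, truth)`` with ``truth`` the 0-based true
    support indices.
    """
    rng = np.random.default_rng(rng)
    C = _corr_matrix(p, rho, structure)
    L = np.linalg.cholesky(C)
    X = rng.standard_normal((n, p)) @ L.T
    b = np.zeros(p)
    b[list(support)] = beta
    y = X @ b + sigma * rng.standard_normal(n)
    prob = standardize(X, y, sigma2=sigma**2)
    return prob.X, prob.y, np.array(support, dtype=int)


def gen_highdim_gaussian(
    n: int = 100,
    p: int = 1000,
    k_star: int = 24,
    beta_var: float = 0.5,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """High-dimensional i.i.d.-design draw with random N(0, beta_var) effects."""
    rng = np.random.default_rng(rng)
    if k_star > p:
        raise ValueError("k_star must not exceed p")
    X = rng.standard_normal((n, p))
    b = np.zeros(p)
    if k_star:
        b[:k_star] = rng.normal(0.0, np.sqrt(beta_var), size=k_star)
    y = X @ b + sigma * rng.standard_normal(n)
    prob = standardize(X, y, sigma2=sigma**2)
    return prob.X, prob.y, np.arange(k_star)


def gen_large_effects(
    n: int = 300,
    p: int = 50,
    k: int = 10,
    family: str = "gaussian",
    x_sd: float = 0.1,
    beta_sd: float = 1.5,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Small-covariate design with large random effects on the first ``k`` coordinates.

    Gaussian responses add ``N(0, sigma^2)`` noise and come back standardized;
    Poisson responses are counts ``Poisson(exp(X beta))`` over the raw design.
    """
    rng = np.random.default_rng(rng)
    X = rng.normal(0.0, x_sd, size=(n, p))
    b = np.zeros(p)
    b[:k] = rng.normal(0.0, beta_sd, size=k)
    truth = np.arange(k)
    if family == "gaussian":
        y = X @ b + sigma * rng.standard_normal(n)
        prob = standardize(X, y, sigma2=sigma**2)
        return prob.X, prob.y, truth
    if family == "poisson":
        lam = np.exp(X @ b)
        y = rng.poisson(lam).astype(float)
        return X, y, truth
    raise ValueError(f"unknown family {family!r}")


def gen_segmentation_signal(
    n: int = 500,
    breakpoints: tuple = (100, 250, 375),
    means: tuple = (-0.3, 0.7, 1.5, 0.5),
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Noisy piecewise-constant signal; truth holds breakpoints and means."""
    rng = np.random.default_rng(rng)
    bkps = np.asarray(breakpoints, dtype=int)
    if len(means) != bkps.size + 1:
        raise ValueError("need one more segment mean than breakpoints")
    lengths = np.diff(np.concatenate(([0], bkps, [n])))
    if np.any(lengths <= 0):
        raise ValueError("breakpoints must be strictly increasing within (0, n)")
    mu = np.repeat(np.asarray(means, dtype=float), lengths)
    y = mu + sigma * rng.standard_normal(n)
    truth = {"breakpoints": bkps, "means": np.asarray(means, dtype=float), "mu": mu}
    return Signal(y=y, positions=None), truth


def evaluate_selection(selected, truth, k_star: int) -> dict:
    """Per-replicate power/FP/FDR/Mis for one selected index set."""
    sel = set(np.asarray(selected, dtype=int).tolist())
    tru = set(np.asarray(truth, dtype=int).tolist())
    tp = len(sel & tru)
    fp = len(sel - tru)
    power = tp / k_star if k_star else 0.0
    fdr = fp / max(1, len(sel))
    mis = (k_star - tp) + fp
    return {"tp": tp, "fp": fp, "power": power, "fdr": fdr, "mis": mis}


# ---------------------------------------------------------------------------
# generic benchmark harness


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario for :func:`run_benchmark`."""

    family: str = "gaussian"
    n: int = 50
    p: int = 15
    k_star: int = 5
    true_support: tuple | None = SUPPORT_LEADING
    beta_scheme: tuple = ("fixed", 0.5)
    corr: tuple = ("none", 0.0)
    sigma: float = 1.0
    x_sd: float = 1.0
    seed: int = 0
    replications: int = 100

    def generate(self, rep: int):
        rng = np.random.default_rng([self.seed, rep])
        kind, val = self.beta_scheme
        structure, rho = self.corr
        if self.family == "gaussian" and kind == "fixed":
            return gen_correlated_gaussian(
                n=self.n,
                p=self.p,
                rho=rho,
                structure="cs" if structure == "none" else structure,
                support=tuple(self.true_support),
                beta=val,
                sigma=self.sigma,
                rng=rng,
            )
        return gen_large_effects(
            n=self.n,
            p=self.p,
            k=self.k_star,
            family=self.family,
            x_sd=self.x_sd,
            beta_sd=val,
            sigma=self.sigma,
            rng=rng,
        )


@dataclass
class BenchmarkMetrics:
    """Aggregated benchmark row for one method."""

    method: str
    power: float
    fp: float
    fdr: float
    mis: float
    mse_crit: float
    best_frac: float
    time: float
    n_failed: int = 0


def run_benchmark(spec: ScenarioSpec, methods: dict, k_star: int | None = None):
    """Run each method on the same replicates and aggregate the usual metrics.

    ``methods`` maps a name to a callable ``method(problem) -> ModelFit``
    (anything with ``support`` indices and a ``criterion_value``).  Per
    replicate the criterion values are compared across methods: ``mse_crit``
    is the mean squared gap to the per-replicate best criterion and
    ``best_frac`` the fraction of replicates in which the method attains the
    minimum (ties count for every tied method).  A method failure on a
    replicate is recorded and excluded with a count.

    Returns ``(aggregate, per_replicate)`` data frames.
    """
    k_star = k_star if k_star is not None else spec.k_star
    rows = []
    for rep in range(spec.replications):
        X, y, truth = spec.generate(rep)
        if spec.family == "poisson":
            problem = PoissonProblem(X, y)
        else:
            problem = LinearProblem(X, y, sigma2=spec.sigma**2, standardized=True)
        crits = {}
        for name, method in methods.items():
            t0 = time.perf_counter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mf = method(problem)
            except Exception:
                rows.append(
                    {"rep": rep, "method": name, "failed": True, "time": np.nan}
                )
                continue
            elapsed = time.perf_counter() - t0
            sel = np.asarray(mf.support, dtype=int)
            m = evaluate_selection(sel, truth, k_star)
            crits[name] = mf.criterion_value
            rows.append(
                {
                    "rep": rep,
                    "method": name,
                    "failed": False,
                    "criterion": mf.criterion_value,
                    "time": elapsed,
                    **m,
                }
            )
        if crits:
            best = min(crits.values())
            for r in rows[-len(crits):]:
                if not r.get("failed"):
                    gap = r["criterion"] - best
                    r["crit_gap"] = gap
                    r["is_best"] = bool(np.isclose(gap, 0.0, atol=1e-9))
    per_rep = pd.DataFrame(rows)
    agg_rows = []
    for name in methods:
        sub = per_rep[(per_rep["method"] == name) & (~per_rep["failed"])]
        n_failed = int((per_rep["method"] == name).sum() - len(sub))
        agg_rows.append(
            BenchmarkMetrics(
                method=name,
                power=float(sub["power"].mean()),
                fp=float(sub["fp"].mean()),
                fdr=float(sub["fdr"].mean()),
                mis=float(sub["mis"].mean()),
                mse_crit=float((sub["crit_gap"] ** 2).mean()),
                best_frac=float(sub["is_best"].mean()),
                time=float(sub["time"].mean()),
                n_failed=n_failed,
            )
        )
    agg = pd.DataFrame([vars(r) for r in agg_rows]).set_index("method")
    return agg, per_rep


# ---------------------------------------------------------------------------
# study-condition runners (fixed designs of the benchmark tables)


def _sem(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def run_smallp_benchmark(
    rho: float = 0.0,
    structure: str = "cs",
    layout: str = "leading",
    n_reps: int = 500,
    seed: int = 0,
) -> dict:
    """Small-p benchmark: AR at ``log(n)/4`` vs exhaustive all-subset BIC.

    n=50, p=15, five effects of 0.5, unit known variance.  ``layout``
    places the true support on the first five coordinates (``"leading"``,
    paired with compound symmetry) or on every third coordinate
    (``"spaced"``, paired with AR(1) correlation).  The AR support is read
    directly off the converged fit; the competitor enumerates all 2^15
    supports and minimises BIC.  Returns mean power/FP/FDR/Mis (with
    standard errors) per method.
    """
    n, p = 50, 15
    support = SUPPORT_LEADING if layout == "leading" else SUPPORT_SPACED
    lam_tilde = np.log(n) / 4.0
    spec = CriterionSpec("bic")
    records = {"ar": [], "all_subset": []}
    layout_tag = 1 if layout == "leading" else 2
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, _TAG_SMALLP, layout_tag, int(round(rho * 100)), rep])
        X, y, truth = gen_correlated_gaussian(
            n=n, p=p, rho=rho, structure=structure, support=support, rng=rng
        )
        prob = LinearProblem(X, y, sigma2=1.0, standardized=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ar_fit(prob, lam_tilde)
        records["ar"].append(evaluate_selection(fit.support_indices, truth, len(support)))
        mf = all_subset_select(prob, spec)
        records["all_subset"].append(evaluate_selection(mf.support, truth, len(support)))
    out = {"n_reps": n_reps, "rho": rho, "layout": layout}
    for name, recs in records.items():
        df = pd.DataFrame(recs)
        out[name] = {
            key: float(df[key].mean()) for key in ("power", "fp", "fdr", "mis")
        }
        out[name]["power_se"] = _sem(df["power"])
        out[name]["mis_se"] = _sem(df["mis"])
    return out


def run_linear_path_benchmark(
    p: int = 50,
    k: int = 10,
    n_reps: int = 200,
    seed: int = 0,
    criteria: tuple = ("bic",),
    preselect: int | None = None,
    grid_num: int = 100,
) -> dict:
    """Path-based AR selection on the large-effect/small-covariate design.

    For each replicate a warm-started AR path over the default increasing
    penalty grid is computed (after optional marginal preselection), every
    criterion in ``criteria`` is minimised along the same path, and
    classification metrics are recorded against the true support.
    """
    n = 300
    records = {c: [] for c in criteria}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, _TAG_PATH_LINEAR, p, rep])
        X, y, truth = gen_large_effects(n=n, p=p, k=k, family="gaussian", rng=rng)
        prob = LinearProblem(X, y, sigma2=1.0, standardized=True)
        if preselect is not None:
            cols = marginal_preselect(prob, m=preselect)
            sub = prob.subproblem(cols)
        else:
            cols = np.arange(p)
            sub = prob
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = ar_path(sub, default_lambda_grid(sub, num=grid_num))
            for crit in criteria:
                spec = CriterionSpec(crit, p_total=p)
                mf = choose_on_path(sub, path, spec)
                selected = cols[mf.support]
                records[crit].append(evaluate_selection(selected, truth, k))
    out = {"n_reps": n_reps, "p": p, "k": k, "preselect": preselect}
    for crit, recs in records.items():
        df = pd.DataFrame(recs)
        out[crit] = {key: float(df[key].mean()) for key in ("power", "fp", "fdr", "mis")}
        out[crit]["power_se"] = _sem(df["power"])
        out[crit]["mis_se"] = _sem(df["mis"])
        out[crit]["fp_se"] = _sem(df["fp"])
    return out


def run_poisson_path_benchmark(
    p: int = 50,
    k: int = 10,
    n_reps: int = 200,
    seed: int = 0,
    criteria: tuple = ("bic",),
    preselect: int | None = None,
    grid_num: int = 50,
) -> dict:
    """Poisson analogue of :func:`run_linear_path_benchmark` (Newton inner solver)."""
    n = 300
    records = {c: [] for c in criteria}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, _TAG_PATH_POISSON, p, rep])
        X, y, truth = gen_large_effects(n=n, p=p, k=k, family="poisson", rng=rng)
        prob = PoissonProblem(X, y)
        if preselect is not None:
            cols = marginal_preselect(prob, m=preselect)
            sub = prob.subproblem(cols)
        else:
            cols = np.arange(p)
            sub = prob
        grid = np.geomspace(1e-4 * n, n, grid_num)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = ar_poisson_path(sub, grid)
            for crit in criteria:
                spec = CriterionSpec(crit, p_total=p)
                mf = choose_on_path(sub, path, spec)
                selected = cols[mf.support]
                records[crit].append(evaluate_selection(selected, truth, k))
    out = {"n_reps": n_reps, "p": p, "k": k, "preselect": preselect}
    for crit, recs in records.items():
        df = pd.DataFrame(recs)
        out[crit] = {key: float(df[key].mean()) for key in ("power", "fp", "fdr", "mis")}
        out[crit]["power_se"] = _sem(df["power"])
    return out


def run_segmentation_calibration(
    n_reps: int = 200,
    seed: int = 0,
    scales: tuple = tuple(range(2, 11)),
    kmax: int = 20,
) -> dict:
    """Calibrate the AR segmentation penalty against the exact DP optimum.

    For each replicate of the piecewise-constant scenario the exact
    penalized criterion at ``lam = 2 log n`` is computed by dynamic
    programming; AR segmentation is run at ``lam / s`` for each candidate
    divisor ``s`` and its penalized criterion (own breakpoints, refit
    segment means) compared with the optimum.  The calibrated rescaling is
    the divisor minimising the mean excess criterion.
    """
    excess = {s: [] for s in scales}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, _TAG_SEGMENT, rep])
        signal, _ = gen_segmentation_signal(rng=rng)
        lam = 2.0 * np.log(signal.n)
        dp = dp_exact_segment(signal, lam, kmax=kmax)
        dp_cost = penalized_cost(signal, dp.breakpoints, lam)
        for s in scales:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ar_segment(signal, lam / s)
            cost = penalized_cost(signal, fit.breakpoints, lam)
            excess[s].append(cost - dp_cost)
    mean_excess = {s: float(np.mean(v)) for s, v in excess.items()}
    best_scale = min(mean_excess, key=mean_excess.get)
    ex6 = np.asarray(excess.get(6, excess[best_scale]))
    return {
        "n_reps": n_reps,
        "scales": list(scales),
        "mean_excess": mean_excess,
        "best_scale": int(best_scale),
        "frac_excess_le_5_at_6": float(np.mean(ex6 <= 5.0)),
        "median_excess_at_6": float(np.median(ex6)),
    }
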