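"""Least-squares segmentation of an ordered signal by adaptive ridge.

Fitting a piecewise-constant mean to an ordered signal ``y_1..y_n`` with a
per-breakpoint L0 penalty,

    min_mu  sum_i (y_i - mu_i)^2 + lam * sum_i 1(mu_i != mu_{i+1}),

is the L0 problem on *successive differences*.  The AR relaxation replaces
the indicator with a weighted quadratic,

    SL(mu; lam, w) = sum_i (y_i - mu_i)^2 + lam * sum_i w_i (mu_{i+1} - mu_i)^2,

whose minimizer solves a symmetric tridiagonal system.  Writing
``mu_i = a_i + b_i mu_{i+1}`` the system is solved by a forward/backward
recursion in O(n) — no matrix factorization — and the difference weights are
refreshed as ``w_i = (delta^2 + (mu_{i+1} - mu_i)^2)^{-1}`` from all-ones
initial weights until the difference indicators ``w_i (mu_{i+1} - mu_i)^2``
stabilise at 0/1.

An exact dynamic-programming solver over segmentations with at most ``kmax``
segments (O(kmax * n^2) with prefix-sum segment costs) is provided as the
reference: the AR solution's penalized criterion can never beat it.  In
practice AR run at the rescaled penalty ``lam_tilde = lam / 6`` (for
``lam = 2 log n``) tracks the exact optimum closely at a fraction of the
cost.

Breakpoints are reported as 1-based indices ``i`` meaning "the mean changes
between positions i and i+1"; equivalently they are the 0-based start
indices of each new segment, so ``numpy.split(y, breakpoints)`` recovers the
segments.  BED output (0-based half-open intervals) is handled by
:mod:`l0ridge.cli`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ARConfig, update_weights

__all__ = [
    "Signal",
    "SegmentationFit",
    "weighted_smooth",
    "ar_segment",
    "extract_breakpoints",
    "dp_exact_segment",
    "penalized_cost",
    "segment_means_from_breakpoints",
]


@dataclass
class Signal:
    """Ordered measurements with optional strictly increasing coordinates."""

    y: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.size < 2:
            raise ValueError("signal needs at least 2 observations")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal values must be finite")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != self.y.shape:
                raise ValueError("positions must match the signal length")
            if not np.all(np.diff(self.positions) > 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class SegmentationFit:
    """Fitted mean, difference weights, breakpoints and refit segment means."""

    mu: np.ndarray
    diff_weights: np.ndarray | None
    breakpoints: np.ndarray
    segment_means: np.ndarray
    lambda_tilde: float
    converged: bool = True
    n_iter: int = 0

    @property
    def n_segments(self) -> int:
        return self.breakpoints.size + 1


def _values(signal) -> np.ndarray:
    return signal.y if isinstance(signal, Signal) else np.asarray(signal, dtype=float).ravel()


def weighted_smooth(signal, lam: float, weights: np.ndarray) -> np.ndarray:
    """Exact minimizer of the weighted-ridge square loss in O(n).

    Forward pass: ``a_1 = y_1 / (1 + lam w_1)``, ``b_1 = lam w_1 / (1 + lam
    w_1)`` and for ``1 < i < n`` ``a_i = (y_i + lam w_{i-1} a_{i-1}) / D_i``,
    ``b_i = lam w_i / D_i`` with ``D_i = 1 + lam w_i + lam w_{i-1} (1 -
    b_{i-1})``; then ``mu_n = (y_n + lam w_{n-1} a_{n-1}) / (1 + lam w_{n-1}
    (1 - b_{n-1}))`` and back-substitution ``mu_i = a_i + b_i mu_{i+1}``.
    """
    y = _values(signal)
    n = y.size
    if lam < 0:
        raise ValueError("lam must be >= 0")
    w = np.broadcast_to(np.asarray(weights, dtype=float), (n - 1,))
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if lam == 0:
        return y.copy()
    # plain-float recursion: sequential, so numpy buys nothing here
    yl = y.tolist()
    lw = (lam * w).tolist()
    a = [0.0] * (n - 1)
    b = [0.0] * (n - 1)
    d0 = 1.0 + lw[0]
    a[0] = yl[0] / d0
    b[0] = lw[0] / d0
    for i in range(1, n - 1):
        D = 1.0 + lw[i] + lw[i - 1] * (1.0 - b[i - 1])
        a[i] = (yl[i] + lw[i - 1] * a[i - 1]) / D
        b[i] = lw[i] / D
    mu = [0.0] * n
    mu[n - 1] = (yl[n - 1] + lw[n - 2] * a[n - 2]) / (1.0 + lw[n - 2] * (1.0 - b[n - 2]))
    for i in range(n - 2, -1, -1):
        mu[i] = a[i] + b[i] * mu[i + 1]
    return np.asarray(mu)


def extract_breakpoints(
    mu: np.ndarray, diff_weights: np.ndarray, config: ARConfig | None = None
) -> np.ndarray:
    """Breakpoint indices: difference indicator strictly above 1/2.

    Returns 1-based indices ``i`` (change between positions ``i`` and
    ``i+1``); a difference sitting exactly at ``|mu_{i+1} - mu_i| = delta``
    (indicator exactly 1/2) is not a breakpoint.
    """
    del config  # the decision rule has no tunables beyond the indicator
    mu = np.asarray(mu, dtype=float)
    d = np.diff(mu)
    ind = np.asarray(diff_weights, dtype=float) * d * d
    return np.flatnonzero(ind > 0.5) + 1


def segment_means_from_breakpoints(y: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    """Arithmetic mean of each segment delimited by the breakpoints."""
    y = np.asarray(y, dtype=float)
    return np.array([seg.mean() for seg in np.split(y, np.asarray(breakpoints, dtype=int))])


def penalized_cost(signal, breakpoints: np.ndarray, lam: float) -> float:
    """L0 segmentation objective: segment-refit RSS plus ``lam`` per breakpoint."""
    y = _values(signal)
    bkps = np.asarray(breakpoints, dtype=int)
    rss = 0.0
    for seg in np.split(y, bkps):
        rss += float(np.sum((seg - seg.mean()) ** 2))
    return rss + lam * bkps.size


def ar_segment(
    signal, lambda_tilde: float, config: ARConfig | None = None
) -> SegmentationFit:
    """AR segmentation: iterate the O(n) smoother and difference-weight update.

    Starts from all-ones difference weights, updates
    ``w_i = (delta^2 + (mu_{i+1} - mu_i)^2)^{-1}`` after each smoothing pass,
    and stops when the difference indicators stabilise.  Segment means are
    refit (arithmetic means) after breakpoint extraction rather than read
    from the final ``mu``, which retains residual shrinkage.
    """
    y = _values(signal)
    n = y.size
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be >= 0")
    cfg = config if config is not None else ARConfig()
    w = cfg.initial_weights(n - 1)
    prev_ind = None
    converged = False
    k = 0
    mu = y.copy()
    for k in range(1, cfg.max_iter + 1):
        mu = weighted_smooth(y, lambda_tilde, w)
        d = np.diff(mu)
        w = update_weights(d, cfg)
        ind = w * d * d
        if prev_ind is not None and np.max(np.abs(ind - prev_ind), initial=0.0) < cfg.tol:
            converged = True
            break
        prev_ind = ind
    if not converged:
        warnings.warn(
            f"AR segmentation did not converge within {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    bkps = extract_breakpoints(mu, w)
    means = segment_means_from_breakpoints(y, bkps)
    return SegmentationFit(
        mu=mu,
        diff_weights=w,
        breakpoints=bkps,
        segment_means=means,
        lambda_tilde=lambda_tilde,
        converged=converged,
        n_iter=k,
    )


def dp_exact_segment(signal, lam: float, kmax: int | None = None) -> SegmentationFit:
    """Exact minimizer of the L0 segmentation objective by dynamic programming.

    Classical k-segment DP with prefix-sum segment costs, O(kmax * n^2):
    ``D[k][j]`` is the best RSS of splitting ``y[0..j]`` into ``k + 1``
    segments; the returned segmentation minimises ``RSS + lam * (#segments -
    1)`` over at most ``kmax`` segments.  Ties prefer fewer segments, then
    earlier (leftmost) segment starts during backtracking.
    """
    y = _values(signal)
    n = y.size
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if kmax is None:
        kmax = n
    if not 1 <= kmax <= n:
        raise ValueError(f"kmax must lie in [1, {n}], got {kmax}")
    S1 = np.concatenate(([0.0], np.cumsum(y)))
    S2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def cost(i: np.ndarray, j: int) -> np.ndarray:
        # RSS of single segments y[i..j] (0-based inclusive), vectorized over i
        length = (j + 1) - i
        s = S1[j + 1] - S1[i]
        s2 = S2[j + 1] - S2[i]
        return s2 - s * s / length

    D = np.full((kmax, n), np.inf)
    P = np.zeros((kmax, n), dtype=np.intp)
    D[0] = S2[1:] - S1[1:] ** 2 / np.arange(1, n + 1)
    for k in range(1, kmax):
        prev = D[k - 1]
        for j in range(k, n):
            starts = np.arange(k, j + 1)
            tot = prev[starts - 1] + cost(starts, j)
            m = int(np.argmin(tot))  # first occurrence -> leftmost start
            D[k, j] = tot[m]
            P[k, j] = starts[m]
    totals = D[:, n - 1] + lam * np.arange(kmax)
    kbest = int(np.argmin(totals))  # first occurrence -> fewest segments
    bkps = []
    j = n - 1
    for k in range(kbest, 0, -1):
        i = int(P[k, j])
        bkps.append(i)
        j = i - 1
    bkps = np.array(sorted(bkps), dtype=int)
    means = segment_means_from_breakpoints(y, bkps)
    mu = np.repeat(means, np.diff(np.concatenate(([0], bkps, [n]))))
    return SegmentationFit(
        mu=mu,
        diff_weights=None,
        breakpoints=bkps,
        segment_means=means,
        lambda_tilde=lam,
        converged=True,
        n_iter=0,
    )
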