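"""Two-boundary Wiener first-passage process with unbiased start.

This module evaluates, integrates, and samples from the joint defective
density of a binary choice ``x`` (upper/lower boundary) and its decision
time for a diffusion process with drift ``mu``, boundary separation
``alpha``, nondecision time ``ter``, diffusion coefficient fixed at 1 and
starting point fixed midway between the boundaries (``z = alpha/2``).

Under these conventions the joint density of responding ``x`` at time ``t``
is

    h(x, t) = (pi / alpha**2) * exp(alpha*mu*(x - 0.5) - mu**2/2 * (t - ter))
              * sum_k k * sin(pi*k/2) * exp(-pi**2 k**2 / (2 alpha**2) * (t - ter))

(the large-time series; only odd ``k`` contribute), and the marginal
probability of the upper boundary is the logistic function of
``alpha * mu``.  The series converges poorly just above ``ter``, so a
Gaussian-mirror (small-time) representation is used there.

All computations reduce to the unit-boundary process via the diffusion
scaling ``T = ter + alpha**2 * S`` where ``S`` is the first-passage time of
a unit-boundary walk with drift ``m = mu * alpha``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

__all__ = [
    "DiffusionParams",
    "ddm_density",
    "choice_prob",
    "mean_decision_time",
    "sample_response",
    "sample_responses",
    "random_walk_sample",
]

# series bookkeeping
_S_SWITCH = 0.35          # scaled-time boundary between small- and large-time forms
_SERIES_TOL = 1e-12       # relative size at which series terms are dropped
_MAX_TERMS = 500


class SeriesConvergenceError(RuntimeError):
    """Raised when the first-passage series fails to converge within the term cap."""


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the two-boundary Wiener process.

    mu:    drift rate (evidence units per sqrt-second)
    alpha: boundary separation (> 0)
    ter:   nondecision time in seconds (>= 0)
    """

    mu: float
    alpha: float
    ter: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.ter < 0:
            raise ValueError(f"ter must be nonnegative, got {self.ter}")


def _n_terms_small(s_max: float) -> int:
    # neglected |0.5 + 2k| must satisfy exp(-(0.5+2k)^2 / (2 s)) < tol
    c = math.sqrt(2.0 * s_max * (-math.log(_SERIES_TOL)))
    k = int(math.ceil((c - 0.5) / 2.0)) + 1
    return max(k, 2)


def _n_terms_large(s_min: float) -> int:
    # neglected odd k must satisfy exp(-k^2 pi^2 s / 2) < tol
    k = math.sqrt(2.0 * (-math.log(_SERIES_TOL)) / (math.pi**2 * s_min))
    n = int(math.ceil((k + 1.0) / 2.0)) + 1
    if n > _MAX_TERMS:
        raise SeriesConvergenceError(
            f"first-passage series needs more than {_MAX_TERMS} terms at scaled time {s_min}"
        )
    return max(n, 2)


def _log_f_center(s: np.ndarray) -> np.ndarray:
    """log density of the unit-boundary, zero-drift first passage at the upper
    boundary with unbiased start, evaluated at scaled time ``s`` (> 0).

    Selects the small-time (Gaussian mirror) or large-time (sine series)
    representation elementwise; both are evaluated in log space with the
    leading term factored out for stability.
    """
    s = np.asarray(s, dtype=float)
    out = np.full(s.shape, -np.inf)
    pos = s > 0

    small = pos & (s < _S_SWITCH)
    if np.any(small):
        ss = s[small]
        nk = _n_terms_small(float(ss.max()))
        # sum_k (0.5+2k) exp(-(0.5+2k)^2/(2s)), k = -nk..nk; factor out k=0 term
        ratio = np.ones_like(ss)
        for k in range(1, nk + 1):
            for c in (0.5 + 2 * k, 0.5 - 2 * k):
                ratio += (c / 0.5) * np.exp(-(c**2 - 0.25) / (2.0 * ss))
        out[small] = (
            -0.5 * np.log(2.0 * np.pi * ss**3)
            + np.log(0.5)
            - 0.125 / ss
            + np.log(np.maximum(ratio, 1e-300))
        )

    large = pos & ~small
    if np.any(large):
        sl = s[large]
        nk = _n_terms_large(float(sl.min()))
        # pi * sum_{j>=0} (2j+1) (-1)^j exp(-(2j+1)^2 pi^2 s/2); factor out j=0
        ratio = np.ones_like(sl)
        for j in range(1, nk + 1):
            k = 2 * j + 1
            ratio += ((-1) ** j) * k * np.exp(-(k**2 - 1) * np.pi**2 * sl / 2.0)
        out[large] = (
            np.log(np.pi) - np.pi**2 * sl / 2.0 + np.log(np.maximum(ratio, 1e-300))
        )
    return out


def log_joint_density(x, t, mu, alpha, ter):
    """Vectorized log of the joint defective density h(x, t).

    ``x`` is 0 (lower boundary) or 1 (upper); all arguments broadcast.
    Returns ``-inf`` for ``t <= ter``.
    """
    x, t, mu, alpha, ter = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (x, t, mu, alpha, ter))
    )
    tau = t - ter
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(tau > 0, tau, np.nan) / alpha**2
        logf = _log_f_center(np.where(np.isnan(s), 1.0, s))
        m = mu * alpha
        out = (
            logf
            - 2.0 * np.log(alpha)
            + m * (x - 0.5)
            - 0.5 * mu**2 * tau
        )
    return np.where(tau > 0, out, -np.inf)


def ddm_density(x, t, params: DiffusionParams):
    """Joint defective density of choice ``x`` (0/1) and response time ``t``.

    Returns 0 for ``t <= ter``.  Accepts scalars or arrays for ``x``/``t``.
    """
    out = np.exp(log_joint_density(x, t, params.mu, params.alpha, params.ter))
    if np.ndim(out) == 0:
        return float(out)
    return out


def choice_prob(mu, alpha):
    """Probability of the upper-boundary (affirmative) response.

    With an unbiased start this is the logistic function of ``alpha * mu``;
    in the item-response parameterization (``mu = theta - v``,
    ``alpha = gamma / a``) it is the D-diffusion item response function.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    out = expit(alpha * np.asarray(mu, dtype=float))
    if np.ndim(out) == 0:
        return float(out)
    return out


def mean_decision_time(mu, alpha):
    """Expected decision time (excluding ter): (alpha/(2 mu)) tanh(mu alpha / 2).

    Continuous limit ``alpha**2 / 4`` at ``mu = 0``.  Identical for both
    boundaries with an unbiased start, hence also the unconditional mean.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    m = mu * alpha
    small = np.abs(m) < 1e-8
    safe_mu = np.where(small, 1.0, mu)
    out = np.where(
        small,
        alpha**2 / 4.0,
        (alpha / (2.0 * safe_mu)) * np.tanh(m / 2.0),
    )
    if np.ndim(out) == 0:
        return float(out)
    return out


def _conditional_time_grid(abs_m: np.ndarray, grid_size: int) -> np.ndarray:
    """Per-draw scaled-time grids covering essentially all conditional mass.

    The slowest decay rate of the first-passage density is
    ``(pi**2 + m**2)/2``; the grid extends the conditional mean by 32/rate,
    leaving relative tail mass far below 1e-10.
    """
    lam = (np.pi**2 + abs_m**2) / 2.0
    mean_s = np.where(abs_m < 1e-9, 0.25, np.tanh(abs_m / 2.0) / (2.0 * np.maximum(abs_m, 1e-9)))
    s_max = mean_s + 32.0 / lam
    return np.linspace(0.0, 1.0, grid_size)[None, :] * s_max[:, None]


def sample_responses(mu, alpha, ter, rng: np.random.Generator,
                     grid_size: int = 768, chunk: int = 4096):
    """Draw one (x, t) pair per element of ``mu``/``alpha``/``ter``.

    Boundary choices are Bernoulli with the logistic probability; decision
    times use inverse-CDF sampling on a per-parameter adaptive grid of the
    conditional first-passage distribution.  With an unbiased start the
    conditional time distribution is identical for the two boundaries and
    depends only on ``|mu * alpha|``, so one grid per draw suffices.
    Deterministic given the generator state.
    """
    mu, alpha, ter = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu, alpha, ter))
    )
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    mu = mu.ravel()
    alpha_f = alpha.ravel()
    ter_f = ter.ravel()
    n = mu.size
    x = np.empty(n, dtype=np.int8)
    t = np.empty(n, dtype=float)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = mu[lo:hi] * alpha_f[lo:hi]
        x[lo:hi] = rng.random(hi - lo) < expit(m)
        am = np.abs(m)
        grid = _conditional_time_grid(am, grid_size)
        logpdf = -0.5 * am[:, None] ** 2 * grid + _log_f_center(grid)
        pdf = np.exp(logpdf)
        pdf[:, 0] = 0.0
        cdf = cumulative_trapezoid(pdf, grid, axis=1, initial=0.0)
        u = rng.random(hi - lo) * cdf[:, -1]
        idx = np.clip((cdf < u[:, None]).sum(axis=1), 1, grid_size - 1)
        rows = np.arange(hi - lo)
        c0 = cdf[rows, idx - 1]
        c1 = cdf[rows, idx]
        g0 = grid[rows, idx - 1]
        g1 = grid[rows, idx]
        frac = np.where(c1 > c0, (u - c0) / np.maximum(c1 - c0, 1e-300), 0.0)
        s = g0 + frac * (g1 - g0)
        t[lo:hi] = ter_f[lo:hi] + alpha_f[lo:hi] ** 2 * s
    x_out = x.reshape(alpha.shape)
    t_out = t.reshape(alpha.shape)
    return x_out, t_out


def sample_response(params: DiffusionParams, rng: np.random.Generator):
    """Draw a single (x, t) pair from the joint law of choice and time."""
    x, t = sample_responses(params.mu, params.alpha, params.ter, rng)
    return int(x), float(t)


def random_walk_sample(params: DiffusionParams, rng: np.random.Generator,
                       dt: float = 1e-3, max_steps: int = 2_000_000):
    """Fine-step Euler random-walk draw; cross-validation fallback only."""
    z = params.alpha / 2.0
    sqdt = math.sqrt(dt)
    pos = z
    for step in range(1, max_steps + 1):
        pos += params.mu * dt + sqdt * rng.standard_normal()
        if pos >= params.alpha:
            return 1, params.ter + step * dt
        if pos <= 0.0:
            return 0, params.ter + step * dt
    raise RuntimeError("random walk did not terminate within max_steps")
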