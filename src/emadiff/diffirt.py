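"""D-diffusion item response model: estimation, scoring, and fit diagnostics.

Each person-occasion provides binary responses x_h and response times t_h on
a small set of items.  The measurement model couples them through a Wiener
diffusion: the effective drift toward the affirmative boundary on item h is
``theta - v_h`` (person drift minus item "difficulty") and the effective
boundary separation is ``gamma / a_h`` (person response caution over item
"time pressure").  Responses are therefore fastest for people far from an
item's difficulty (the distance-difficulty principle) and slower the more
caution a person applies.

Item parameters and the population spreads of ``theta`` and ``log gamma``
are estimated by marginal maximum likelihood over all person-occasion rows,
with independent normal random effects integrated out on a tensor
Gauss-Hermite grid.  Per-occasion person scores are expected a posteriori
(EAP) values on the same grid.  The nondecision time of a row is profiled
as a fixed fraction ``kappa`` of its fastest retained RT, since a free
nondecision time is weakly identified from five RTs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import logit, logsumexp
from scipy.stats import multivariate_normal, norm

from .ddm import _log_f_center, sample_responses

__all__ = [
    "DiffusionItemParams",
    "DiffIRTFit",
    "OccasionScores",
    "FitError",
    "fit_item_parameters",
    "score_occasions",
    "scores_to_frame",
    "qq_diagnostic",
    "unidimensionality_check",
    "tetrachoric",
    "marginal_loglik",
]


class FitError(RuntimeError):
    """Marginal-likelihood optimization did not converge."""


@dataclass(frozen=True)
class DiffusionItemParams:
    """Item drift difficulty v (location) and item boundary a ("time pressure")."""

    item_id: str
    v: float
    a: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("item boundary a must be positive")


@dataclass
class DiffIRTFit:
    """Converged marginal-ML fit of the D-diffusion measurement model."""

    items: list            # DiffusionItemParams, in fitting order
    omega_theta: float     # population SD of person drift theta
    omega_gamma: float     # population SD of log person boundary gamma
    loglik: float
    converged: bool
    n_rows: int
    n_quad: int
    kappa: float
    message: str = ""
    flags: list = field(default_factory=list)

    @property
    def item_ids(self):
        return [it.item_id for it in self.items]

    @property
    def v(self):
        return np.array([it.v for it in self.items])

    @property
    def a(self):
        return np.array([it.a for it in self.items])

    def to_dict(self):
        return {
            "items": [
                {"item_id": it.item_id, "v": it.v, "a": it.a} for it in self.items
            ],
            "omega_theta": self.omega_theta,
            "omega_gamma": self.omega_gamma,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_rows": self.n_rows,
            "n_quad": self.n_quad,
            "kappa": self.kappa,
            "message": self.message,
            "flags": list(self.flags),
        }


@dataclass
class OccasionScores:
    """Per-occasion EAP person scores and the derived transformed variables."""

    person_id: str
    occasion_id: int
    day: int
    theta: float           # signed person drift
    gamma: float           # person boundary separation (> 0)
    ter: float             # profiled nondecision time (s)
    abs_drift: float       # mean_h |theta - v_h|
    log_abs_drift: float
    log_gamma: float
    mean_log_rt: float
    n_items: int
    outlier: bool = False


# ---------------------------------------------------------------------------
# data preparation and the marginal likelihood


def _prepare(occasions, item_ids, kappa, min_items):
    H = len(item_ids)
    idx = {it: h for h, it in enumerate(item_ids)}
    R = len(occasions)
    X = np.full((R, H), np.nan)
    T = np.full((R, H), np.nan)
    for i, occ in enumerate(occasions):
        for it, x in occ.binary_responses.items():
            if it in idx and it in occ.rts:
                X[i, idx[it]] = x
                T[i, idx[it]] = occ.rts[it]
    obs = ~np.isnan(T)
    n_obs = obs.sum(axis=1)
    usable = n_obs >= min_items
    with np.errstate(all="ignore"):
        ter = kappa * np.nanmin(np.where(obs, T, np.inf), axis=1)
    ter[~usable] = np.nan
    tau = T - ter[:, None]
    return X, T, tau, obs, ter, usable


def _row_logliks(X, tau, obs, v, a, om_th, om_g, gh_x, gh_w):
    """Marginal log-likelihood of every row on the tensor quadrature grid.

    Returns (row logliks, posterior weight tensor of shape (Tq, Gq, R),
    theta nodes, log-gamma nodes).
    """
    th_nodes = np.sqrt(2.0) * om_th * gh_x          # (Tq,)
    lg_nodes = np.sqrt(2.0) * om_g * gh_x           # (Gq,)
    log_w = np.log(gh_w) - 0.5 * np.log(np.pi)      # per-dimension GH weight

    alpha = np.exp(lg_nodes)[:, None] / a[None, :]          # (Gq, H)
    tau_f = np.where(obs, tau, 1.0)
    with np.errstate(divide="ignore"):
        s = tau_f[None, :, :] / alpha[:, None, :] ** 2      # (Gq, R, H)
        logf = _log_f_center(s) - 2.0 * np.log(alpha)[:, None, :]
    logf = np.where(obs[None, :, :], logf, 0.0)
    A = logf.sum(axis=2)                                    # (Gq, R)

    mu = th_nodes[:, None] - v[None, :]                     # (Tq, H)
    m = mu[:, None, :] * alpha[None, :, :]                  # (Tq, Gq, H)
    xc = np.where(obs, X - 0.5, 0.0)                        # (R, H)
    tau_m = np.where(obs, tau, 0.0)
    B = np.einsum("tgh,ih->tgi", m, xc)                     # (Tq, Gq, R)
    C = -0.5 * np.einsum("th,ih->ti", mu**2, tau_m)         # (Tq, R)

    L = A[None, :, :] + B + C[:, None, :]                   # (Tq, Gq, R)
    Lw = L + (log_w[:, None] + log_w[None, :])[:, :, None]
    row_ll = logsumexp(Lw.reshape(-1, Lw.shape[2]), axis=0)
    return row_ll, Lw, th_nodes, lg_nodes


def _unpack(params, H):
    v = params[:H]
    a = np.exp(params[H : 2 * H])
    om_th = np.exp(params[2 * H])
    om_g = np.exp(params[2 * H + 1])
    return v, a, om_th, om_g


def marginal_loglik(occasions, item_ids, v, a, omega_theta, omega_gamma,
                    n_quad: int = 15, kappa: float = 0.9, min_items: int = 2) -> float:
    """Marginal log-likelihood of the data at the given parameter values."""
    X, _, tau, obs, _, usable = _prepare(occasions, item_ids, kappa, min_items)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    row_ll, _, _, _ = _row_logliks(
        X[usable], tau[usable], obs[usable],
        np.asarray(v, float), np.asarray(a, float),
        float(omega_theta), float(omega_gamma), gh_x, gh_w,
    )
    return float(row_ll.sum())


def fit_item_parameters(occasions, item_ids=None, n_quad: int = 15,
                        kappa: float = 0.9, min_items: int = 2,
                        maxiter: int = 300, gtol: float = 5e-3) -> DiffIRTFit:
    """Estimate item parameters and population spreads by marginal ML.

    Person drift is theta ~ N(0, omega_theta^2) and log person boundary is
    log gamma ~ N(0, omega_gamma^2), independent; their zero means anchor
    the translation/scale-confounded item parameters.  Every person-occasion
    row is treated as an exchangeable unit.
    """
    if item_ids is None:
        seen = []
        for occ in occasions:
            for it in occ.binary_responses:
                if it not in seen:
                    seen.append(it)
        item_ids = seen
    H = len(item_ids)
    if H < 3:
        raise ValueError(f"need at least 3 items, got {H}")
    if len(occasions) < 50:
        warnings.warn("fewer than 50 occasions; estimates will be unstable")

    X, _, tau, obs, _, usable = _prepare(occasions, item_ids, kappa, min_items)
    Xu, tauu, obsu = X[usable], tau[usable], obs[usable]
    R = int(usable.sum())
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)

    flags = []
    p_hat = np.array(
        [np.nanmean(np.where(obsu[:, h], Xu[:, h], np.nan)) for h in range(H)]
    )
    for h, p in enumerate(p_hat):
        if p in (0.0, 1.0):
            flags.append(
                f"item {item_ids[h]!r}: all responses identical; "
                "difficulty estimate is a boundary value"
            )
    p0 = np.clip(p_hat, 0.02, 0.98)

    x0 = np.concatenate(
        [-logit(p0) / 2.0, np.zeros(H), [np.log(0.8)], [np.log(0.4)]]
    )

    def negll(params):
        v, a, om_th, om_g = _unpack(params, H)
        row_ll, _, _, _ = _row_logliks(Xu, tauu, obsu, v, a, om_th, om_g, gh_x, gh_w)
        val = -row_ll.sum()
        if not np.isfinite(val):
            return 1e12
        return val

    res = minimize(
        negll, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 10 * maxiter * (2 * H + 2)},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < gtol * max(1.0, abs(res.fun)))
    if not converged:
        raise FitError(
            f"marginal ML did not converge after {res.nit} iterations: "
            f"{res.message} (|grad|={grad_norm:.3g})"
        )
    v, a, om_th, om_g = _unpack(res.x, H)
    items = [DiffusionItemParams(item_ids[h], float(v[h]), float(a[h])) for h in range(H)]
    return DiffIRTFit(
        items=items,
        omega_theta=float(om_th),
        omega_gamma=float(om_g),
        loglik=float(-res.fun),
        converged=converged,
        n_rows=R,
        n_quad=n_quad,
        kappa=kappa,
        message=str(res.message),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# scoring


def score_occasions(occasions, fit: DiffIRTFit, min_items: int = 2,
                    outlier_iqr: float = 5.0) -> list[OccasionScores]:
    """EAP person scores per person-occasion under the fitted model.

    ``abs_drift`` plugs the EAP of theta into mean_h |theta - v_h| over the
    fitted item set.  Boundary scores more than ``outlier_iqr`` interquartile
    ranges below the median log gamma are flagged and their log fields set
    missing (emulating the removal of extreme negative boundary outliers).
    """
    item_ids = fit.item_ids
    X, _, tau, obs, ter, usable = _prepare(occasions, item_ids, fit.kappa, min_items)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(fit.n_quad)
    theta_eap = np.full(len(occasions), np.nan)
    lg_eap = np.full(len(occasions), np.nan)
    if usable.any():
        _, Lw, th_nodes, lg_nodes = _row_logliks(
            X[usable], tau[usable], obs[usable],
            fit.v, fit.a, fit.omega_theta, fit.omega_gamma, gh_x, gh_w,
        )
        flat = Lw.reshape(-1, Lw.shape[2])
        w = np.exp(flat - logsumexp(flat, axis=0, keepdims=True))
        grid_th = np.broadcast_to(
            th_nodes[:, None], (len(th_nodes), len(lg_nodes))
        ).reshape(-1)
        grid_lg = np.broadcast_to(
            lg_nodes[None, :], (len(th_nodes), len(lg_nodes))
        ).reshape(-1)
        theta_eap[usable] = grid_th @ w
        lg_eap[usable] = grid_lg @ w

    finite = np.isfinite(lg_eap)
    outlier = np.zeros(len(occasions), dtype=bool)
    if finite.sum() >= 4:
        med = np.median(lg_eap[finite])
        q1, q3 = np.percentile(lg_eap[finite], [25, 75])
        iqr = q3 - q1
        outlier = finite & (lg_eap < med - outlier_iqr * iqr)

    out = []
    for i, occ in enumerate(occasions):
        th = theta_eap[i]
        lg = lg_eap[i]
        if np.isfinite(th):
            abs_drift = float(np.mean(np.abs(th - fit.v)))
            log_abs = float(np.log(abs_drift)) if abs_drift > 0 else float("nan")
        else:
            abs_drift, log_abs = float("nan"), float("nan")
        is_out = bool(outlier[i])
        out.append(
            OccasionScores(
                person_id=occ.person_id,
                occasion_id=occ.occasion_id,
                day=occ.day,
                theta=float(th),
                gamma=float(np.exp(lg)) if np.isfinite(lg) else float("nan"),
                ter=float(ter[i]) if usable[i] else float("nan"),
                abs_drift=abs_drift,
                log_abs_drift=float("nan") if is_out else log_abs,
                log_gamma=float("nan") if is_out else float(lg),
                mean_log_rt=occ.mean_log_rt,
                n_items=int(obs[i].sum()),
                outlier=is_out,
            )
        )
    return out


def scores_to_frame(scores) -> pd.DataFrame:
    """Scored-occasion table ready for the multilevel and growth analyses."""
    return pd.DataFrame(
        [
            {
                "person_id": s.person_id,
                "occasion_id": s.occasion_id,
                "day": s.day,
                "theta": s.theta,
                "gamma": s.gamma,
                "ter": s.ter,
                "abs_drift": s.abs_drift,
                "log_abs_drift": s.log_abs_drift,
                "log_gamma": s.log_gamma,
                "mean_log_rt": s.mean_log_rt,
                "n_items": s.n_items,
                "outlier": s.outlier,
            }
            for s in scores
        ]
    )


# ---------------------------------------------------------------------------
# diagnostics


def qq_diagnostic(occasions, fit: DiffIRTFit, scores=None,
                  rng: np.random.Generator | None = None,
                  percentiles=None) -> pd.DataFrame:
    """Observed-vs-model RT quantiles per item at matched sample size.

    Model quantiles come from simulating one RT per observed (row, item)
    pair at the row's posterior-mean person parameters and profiled
    nondecision time.  Returns a tidy table of paired quantiles at the
    1..99 percentiles.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if percentiles is None:
        percentiles = np.arange(1, 100)
    if scores is None:
        scores = score_occasions(occasions, fit)
    item_ids = fit.item_ids
    theta = np.array([s.theta for s in scores])
    gamma = np.array([s.gamma for s in scores])
    ter = np.array([s.ter for s in scores])
    rows = []
    for h, item in enumerate(item_ids):
        obs_rt, sim_mu, sim_alpha, sim_ter = [], [], [], []
        for i, occ in enumerate(occasions):
            if item in occ.rts and np.isfinite(theta[i]) and np.isfinite(gamma[i]):
                obs_rt.append(occ.rts[item])
                sim_mu.append(theta[i] - fit.v[h])
                sim_alpha.append(gamma[i] / fit.a[h])
                sim_ter.append(ter[i])
        if not obs_rt:
            continue
        _, t_sim = sample_responses(
            np.array(sim_mu), np.array(sim_alpha), np.array(sim_ter), rng
        )
        oq = np.percentile(obs_rt, percentiles)
        mq = np.percentile(t_sim, percentiles)
        for p, o, m_ in zip(percentiles, oq, mq):
            rows.append(
                {"item_id": item, "percentile": int(p), "observed": float(o), "model": float(m_)}
            )
    return pd.DataFrame(rows)


def tetrachoric(x, y) -> float:
    """Tetrachoric correlation of two binary vectors (pairwise complete).

    Matches the observed 1-1 cell probability to a thresholded bivariate
    normal; a 0.5 continuity correction is applied to empty cells.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n == 0:
        return float("nan")
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    if min(n11, n10, n01, n00) == 0:
        n11 += 0.5
        n10 += 0.5
        n01 += 0.5
        n00 += 0.5
    tot = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / tot
    p2 = (n11 + n01) / tot
    p11 = n11 / tot
    h1 = norm.ppf(1.0 - p1)
    h2 = norm.ppf(1.0 - p2)

    def gap(rho):
        bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        joint_upper = 1.0 - norm.cdf(h1) - norm.cdf(h2) + bvn.cdf([h1, h2])
        return joint_upper - p11

    lo, hi = -0.999, 0.999
    if gap(lo) * gap(hi) > 0:
        return 1.0 if abs(gap(hi)) < abs(gap(lo)) else -1.0
    return float(brentq(gap, lo, hi, xtol=1e-6))


@dataclass
class UnidimResult:
    """First-factor summary of the tetrachoric correlation matrix (advisory)."""

    corr: pd.DataFrame
    eigenvalues: np.ndarray
    eigen_ratio: float       # first / second eigenvalue
    loadings: pd.Series
    excluded_items: list


def unidimensionality_check(binary_responses: pd.DataFrame) -> UnidimResult:
    """Essential-unidimensionality diagnostic on the binary response matrix.

    Computes the tetrachoric correlation matrix and a one-factor principal
    summary (first/second eigenvalue ratio and loadings).  Items with a
    single observed category are excluded with a warning.  Advisory output
    only; it gates nothing.
    """
    df = pd.DataFrame(binary_responses)
    if df.shape[1] < 3:
        raise ValueError("need at least 3 items")
    excluded = []
    for c in df.columns:
        vals = df[c].dropna().unique()
        if len(vals) < 2:
            excluded.append(c)
    if excluded:
        warnings.warn(f"items with a single observed category excluded: {excluded}")
        df = df.drop(columns=excluded)
    cols = list(df.columns)
    H = len(cols)
    R = np.eye(H)
    for i in range(H):
        for j in range(i + 1, H):
            R[i, j] = R[j, i] = tetrachoric(df[cols[i]], df[cols[j]])
    # symmetrize onto the PSD cone so the factor summary is well defined
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-6, None)
    Rp = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(Rp))
    Rp = Rp / np.outer(d, d)
    w, V = np.linalg.eigh(Rp)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    v1 = V[:, 0] * np.sign(V[:, 0].sum() or 1.0)
    loadings = pd.Series(np.sqrt(w[0]) * v1, index=cols)
    return UnidimResult(
        corr=pd.DataFrame(Rp, index=cols, columns=cols),
        eigenvalues=w,
        eigen_ratio=float(w[0] / w[1]),
        loadings=loadings,
        excluded_items=excluded,
    )
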