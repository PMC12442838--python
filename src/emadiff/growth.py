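"""Negative exponential growth curves for practice effects.

Repeated responding speeds up early and then levels off, a pattern captured
by the negative exponential trajectory.  We parameterize it as

    y_ij = a_j - g_j * exp(-r * occasion_ij) + e_ij,

where ``a_j`` is the person's asymptote (level approached with unlimited
occasions), the gain ``g_j = a_j - initial level`` is the signed change
accumulated from the first occasion to the asymptote, and ``r > 0`` governs
how quickly the asymptote is approached.  Response times shrinking from
1.86 to about 1.40 log-seconds thus carry a negative gain near -0.45, a
rising drift rate a positive gain, and declining response caution a
negative gain.  Occasions are coded 0, 1, 2, ... in scheduled prompt order
(missed prompts leave gaps).

(a_j, g_j) are bivariate normal random effects; the rate is a fixed effect
by default because person-specific rates are fragile with at most ~42
occasions (a log-normal random rate, integrated by Gauss-Hermite
quadrature, is available but off by default).  Estimation is full ML:
given the rate, the model is a linear mixed model, so the fixed means are
profiled by GLS inside the likelihood.

``compare_gains`` refits two z-scored series jointly (one 4-dimensional
random-effect block across the two outcomes) and Wald-tests the equality of
the absolute mean gains.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = ["GrowthFit", "GainComparison", "fit_negative_exponential", "compare_gains"]


@dataclass
class GrowthFit:
    """ML fit of the negative exponential growth model to one variable."""

    mean_asymptote: float
    mean_gain: float           # asymptote minus initial level (signed change)
    rate: float
    var_asymptote: float
    var_gain: float
    cov_asymptote_gain: float
    resid_var: float
    se_asymptote: float
    se_gain: float
    rate_sd: float             # SD of log person rates (0 unless random_rate)
    loglik: float
    converged: bool
    n_persons: int
    n_obs: int
    rate_boundary: bool = False
    _series: tuple = field(repr=False, default=None)   # (person codes, occ, y)
    _beta_cov: np.ndarray = field(repr=False, default=None)

    def predict_mean(self, occasion):
        """Population-mean trajectory at the given 0-based occasion index."""
        occ = np.asarray(occasion, float)
        return self.mean_asymptote - self.mean_gain * np.exp(-self.rate * occ)

    def observed_vs_fitted(self) -> pd.DataFrame:
        _, occ, y = self._series
        df = pd.DataFrame({"occasion": occ, "observed": y})
        out = df.groupby("occasion", as_index=False)["observed"].mean()
        out["fitted"] = self.predict_mean(out["occasion"].to_numpy())
        return out

    def to_dict(self):
        return {k: getattr(self, k) for k in (
            "mean_asymptote", "mean_gain", "rate", "var_asymptote", "var_gain",
            "cov_asymptote_gain", "resid_var", "se_asymptote", "se_gain",
            "rate_sd", "loglik", "converged", "n_persons", "n_obs",
            "rate_boundary")}


@dataclass
class GainComparison:
    """Wald test of |gain_1| = |gain_2| from the joint bivariate-outcome fit."""

    gain_1: float
    gain_2: float
    se_gain_1: float
    se_gain_2: float
    abs_diff: float
    se_abs_diff: float
    chi2: float
    df: int
    pvalue: float
    converged: bool


def _clean_series(person_ids, occasions, values):
    df = pd.DataFrame({
        "p": np.asarray(person_ids),
        "occ": np.asarray(occasions, float),
        "y": np.asarray(values, float),
    }).dropna()
    if df.empty:
        raise ValueError("no complete observations")
    if df["occ"].nunique() < 2:
        raise ValueError("series has no time variation")
    codes, _ = pd.factorize(df["p"])
    return codes, df["occ"].to_numpy(), df["y"].to_numpy(), df["p"].to_numpy()


def _gather_clusters(codes, occ, y):
    clusters = {}
    for j in np.unique(codes):
        m = codes == j
        key = tuple(occ[m])
        clusters.setdefault(key, []).append(y[m])
    return [(np.array(k, float), np.column_stack(v)) for k, v in clusters.items()]


class _SeriesStats:
    """Per-person sufficient statistics for the fixed-rate likelihood.

    With the rate given, the model is linear mixed with design
    X_j = [1, -exp(-r * occ_j)], so each person enters the likelihood only
    through n_j, sums of exp(-r occ) and exp(-2r occ), y sums, and
    cross-products -- all computable by segment sums for any r.  Woodbury
    and the matrix determinant lemma reduce every per-person solve to a
    2x2 problem, vectorized across persons.
    """

    def __init__(self, codes, occ, y):
        self.codes = codes
        self.occ = occ
        self.y = y
        self.J = int(codes.max()) + 1
        self.n_j = np.bincount(codes, minlength=self.J).astype(float)
        self.S_y = np.bincount(codes, weights=y, minlength=self.J)
        self.S_y2 = np.bincount(codes, weights=y * y, minlength=self.J)
        self.n_total = len(y)

    def design_sums(self, r):
        w = np.exp(-r * self.occ)
        S_w = np.bincount(self.codes, weights=w, minlength=self.J)
        S_w2 = np.bincount(self.codes, weights=w * w, minlength=self.J)
        S_wy = np.bincount(self.codes, weights=w * self.y, minlength=self.J)
        XtX = np.empty((self.J, 2, 2))
        XtX[:, 0, 0] = self.n_j
        XtX[:, 0, 1] = XtX[:, 1, 0] = -S_w
        XtX[:, 1, 1] = S_w2
        Xty = np.stack([self.S_y, -S_wy], axis=1)
        return XtX, Xty


def _profile_ll_blocks(XtX, Xty, S_y2, n_j, Sig, s2, n_total):
    """Profile log-likelihood pieces for V_j = X_j Sig X_j' + s2 I."""
    k = Sig.shape[0]
    sign, logdet_sig = np.linalg.slogdet(Sig)
    if sign <= 0 or s2 <= 0:
        return None
    Sig_inv = np.linalg.inv(Sig)
    A = Sig_inv[None, :, :] + XtX / s2                     # (J, k, k)
    sgn, logdet_A = np.linalg.slogdet(A)
    if np.any(sgn <= 0):
        return None
    A_inv = np.linalg.inv(A)
    # X' V^-1 X = (XtX - XtX A^-1 XtX / s2) / s2, etc.
    XtX_Ainv = np.einsum("jab,jbc->jac", XtX, A_inv)
    XtVX = (XtX - np.einsum("jab,jbc->jac", XtX_Ainv, XtX) / s2) / s2
    XtVy = (Xty - np.einsum("jab,jb->ja", XtX_Ainv, Xty) / s2) / s2
    ytVy = (S_y2 - np.einsum("ja,jab,jb->j", Xty, A_inv, Xty) / s2) / s2
    logdet_V = n_j * np.log(s2) + logdet_A + logdet_sig
    XtVX_tot = XtVX.sum(axis=0)
    XtVy_tot = XtVy.sum(axis=0)
    try:
        beta = np.linalg.solve(XtVX_tot, XtVy_tot)
    except np.linalg.LinAlgError:
        return None
    quad = ytVy.sum() - 2.0 * beta @ XtVy_tot + beta @ XtVX_tot @ beta
    ll = -0.5 * (n_total * np.log(2 * np.pi) + logdet_V.sum() + quad)
    return ll, beta, XtVX_tot


def _negll_fixed_rate(params, stats: _SeriesStats):
    """Profile negative log-likelihood; params = (log r, chol(3), log sigma)."""
    r = np.exp(np.clip(params[0], -12, 4))
    L = np.array([[np.exp(np.clip(params[1], -12, 12)), 0.0],
                  [params[2], np.exp(np.clip(params[3], -12, 12))]])
    Sig = L @ L.T
    s2 = np.exp(np.clip(2.0 * params[4], -24, 24))
    XtX, Xty = stats.design_sums(r)
    return _profile_ll_blocks(XtX, Xty, stats.S_y2, stats.n_j, Sig, s2,
                              stats.n_total)


def fit_negative_exponential(person_ids, occasions, values,
                             random_rate: bool = False,
                             n_quad: int = 9,
                             maxiter: int = 600) -> GrowthFit:
    """Fit the negative exponential growth model by ML.

    ``occasions`` are 0-based scheduled prompt indices.  Returns population
    means and random-effect (co)variances of the asymptote and gain, the
    rate, and the residual variance.  With ``random_rate=True`` the person
    rate is log-normal and integrated out by Gauss-Hermite quadrature.
    """
    codes, occ, y, pids = _clean_series(person_ids, occasions, values)
    counts = np.bincount(codes)
    if np.mean(counts >= 3) < 0.5:
        warnings.warn("fewer than half of the persons have >= 3 occasions")
    stats = _SeriesStats(codes, occ, y)
    n_total = len(y)
    sd_y = float(np.std(y))
    x0 = np.array([np.log(0.25), np.log(max(0.5 * sd_y, 1e-3)), 0.0,
                   np.log(max(0.3 * sd_y, 1e-3)), np.log(max(0.6 * sd_y, 1e-3))])

    if not random_rate:
        def neg(params):
            out = _negll_fixed_rate(params, stats)
            if out is None or not np.isfinite(out[0]):
                return 1e12
            return -out[0]

        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter * 10, "fatol": 1e-9, "xatol": 1e-7})
        ll, beta, XtVX = _negll_fixed_rate(res.x, stats)
        beta_cov = np.linalg.inv(XtVX)
        r = float(np.exp(res.x[0]))
        L = np.array([[np.exp(res.x[1]), 0.0], [res.x[2], np.exp(res.x[3])]])
        Sig = L @ L.T
        s2 = float(np.exp(2.0 * res.x[4]))
        rate_sd = 0.0
        converged = bool(res.success)
    else:
        clusters = _gather_clusters(codes, occ, y)
        gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
        log_w = np.log(gh_w) - 0.5 * np.log(np.pi)

        def neg(params):
            # params: beta(2), log r, log omega_r, chol(3), log sigma
            beta = params[:2]
            log_r = np.clip(params[2], -12, 4)
            om_r = np.exp(np.clip(params[3], -12, 3))
            L = np.array([[np.exp(np.clip(params[4], -12, 12)), 0.0],
                          [params[5], np.exp(np.clip(params[6], -12, 12))]])
            Sig = L @ L.T
            s2 = np.exp(np.clip(2.0 * params[7], -24, 24))
            total = 0.0
            for occ_v, Y in clusters:
                n = len(occ_v)
                J_n = Y.shape[1]
                node_ll = np.empty((n_quad, J_n))
                for qi, zx in enumerate(gh_x):
                    r = np.exp(log_r + np.sqrt(2.0) * om_r * zx)
                    X = np.column_stack([np.ones(n), -np.exp(-r * occ_v)])
                    V = X @ Sig @ X.T + s2 * np.eye(n)
                    try:
                        Lv = np.linalg.cholesky(V)
                    except np.linalg.LinAlgError:
                        return 1e12
                    Rc = Y - (X @ beta)[:, None]
                    sol = np.linalg.solve(Lv, Rc)
                    node_ll[qi] = (
                        -np.sum(np.log(np.diag(Lv)))
                        - 0.5 * np.sum(sol**2, axis=0)
                        - 0.5 * n * np.log(2 * np.pi)
                        + log_w[qi]
                    )
                m = node_ll.max(axis=0)
                total += np.sum(m + np.log(np.sum(np.exp(node_ll - m), axis=0)))
            return -total if np.isfinite(total) else 1e12

        x0r = np.concatenate([[np.mean(y), 0.0], [np.log(0.25)], [np.log(0.1)],
                              x0[1:4], [x0[4]]])
        res = minimize(neg, x0r, method="Nelder-Mead",
                       options={"maxiter": maxiter * 20, "fatol": 1e-8})
        beta = res.x[:2]
        r = float(np.exp(res.x[2]))
        rate_sd = float(np.exp(res.x[3]))
        L = np.array([[np.exp(res.x[4]), 0.0], [res.x[5], np.exp(res.x[6])]])
        Sig = L @ L.T
        s2 = float(np.exp(2.0 * res.x[7]))
        ll = -res.fun
        # fixed-effect covariance at the modal rate
        out = _negll_fixed_rate(
            np.array([res.x[2], res.x[4], res.x[5], res.x[6], res.x[7]]), stats)
        beta_cov = np.linalg.inv(out[2]) if out is not None else np.full((2, 2), np.nan)
        converged = bool(res.success)

    rate_boundary = r < 2e-3
    if rate_boundary:
        warnings.warn(
            "rate collapsed toward 0; the trajectory degenerates to an "
            "intercept-plus-slope trend"
        )
    return GrowthFit(
        mean_asymptote=float(beta[0]),
        mean_gain=float(beta[1]),
        rate=r,
        var_asymptote=float(Sig[0, 0]),
        var_gain=float(Sig[1, 1]),
        cov_asymptote_gain=float(Sig[0, 1]),
        resid_var=s2,
        se_asymptote=float(np.sqrt(beta_cov[0, 0])),
        se_gain=float(np.sqrt(beta_cov[1, 1])),
        rate_sd=rate_sd,
        loglik=float(ll),
        converged=converged,
        n_persons=int(len(counts)),
        n_obs=int(n_total),
        rate_boundary=rate_boundary,
        _series=(pids, occ, y),
        _beta_cov=beta_cov,
    )


# ---------------------------------------------------------------------------
# joint bivariate-outcome comparison of gains


def _joint_stats(s1, s2):
    """Align the two series on their common persons; one _SeriesStats each,
    with identical person indexing."""
    ids1, occ1, y1 = s1
    ids2, occ2, y2 = s2
    common = np.intersect1d(np.unique(ids1), np.unique(ids2))
    if len(common) < 2:
        raise ValueError("fewer than 2 persons present in both series")
    pos = {p: j for j, p in enumerate(common)}
    m1 = np.isin(ids1, common)
    m2 = np.isin(ids2, common)
    c1 = np.array([pos[p] for p in ids1[m1]])
    c2 = np.array([pos[p] for p in ids2[m2]])
    st1 = _SeriesStats(c1, occ1[m1], y1[m1])
    st2 = _SeriesStats(c2, occ2[m2], y2[m2])
    st1.J = st2.J = len(common)
    return st1, st2, len(common)


def _negll_joint(params, st1: _SeriesStats, st2: _SeriesStats):
    """params: log r1, log r2, chol4 (10), log s1, log s2; beta(4) profiled.

    V_j = X_j Sig4 X_j' + D_j with X_j block-diagonal across the two
    outcomes and D_j the outcome-specific residual variances; Woodbury on
    4x4 capacitance matrices, vectorized across persons.
    """
    r1 = np.exp(np.clip(params[0], -12, 4))
    r2 = np.exp(np.clip(params[1], -12, 4))
    L = np.zeros((4, 4))
    k = 2
    for i in range(4):
        for j in range(i + 1):
            L[i, j] = np.exp(np.clip(params[k], -10, 10)) if i == j else params[k]
            k += 1
    Sig = L @ L.T
    s1v = np.exp(np.clip(2.0 * params[k], -24, 24))
    s2v = np.exp(np.clip(2.0 * params[k + 1], -24, 24))
    XtX1, Xty1 = st1.design_sums(r1)
    XtX2, Xty2 = st2.design_sums(r2)
    J = st1.J
    XtDX = np.zeros((J, 4, 4))
    XtDX[:, :2, :2] = XtX1 / s1v
    XtDX[:, 2:, 2:] = XtX2 / s2v
    XtDy = np.concatenate([Xty1 / s1v, Xty2 / s2v], axis=1)
    ytDy = st1.S_y2 / s1v + st2.S_y2 / s2v
    sign, logdet_sig = np.linalg.slogdet(Sig)
    if sign <= 0:
        return None
    A = np.linalg.inv(Sig)[None, :, :] + XtDX
    sgn, logdet_A = np.linalg.slogdet(A)
    if np.any(sgn <= 0):
        return None
    A_inv = np.linalg.inv(A)
    XtDX_Ainv = np.einsum("jab,jbc->jac", XtDX, A_inv)
    XtVX = XtDX - np.einsum("jab,jbc->jac", XtDX_Ainv, XtDX)
    XtVy = XtDy - np.einsum("jab,jb->ja", XtDX_Ainv, XtDy)
    ytVy = ytDy - np.einsum("ja,jab,jb->j", XtDy, A_inv, XtDy)
    logdet_V = st1.n_j * np.log(s1v) + st2.n_j * np.log(s2v) + logdet_A + logdet_sig
    XtVX_tot = XtVX.sum(axis=0)
    XtVy_tot = XtVy.sum(axis=0)
    try:
        beta = np.linalg.solve(XtVX_tot, XtVy_tot)
    except np.linalg.LinAlgError:
        return None
    quad = ytVy.sum() - 2.0 * beta @ XtVy_tot + beta @ XtVX_tot @ beta
    n_total = st1.n_total + st2.n_total
    ll = -0.5 * (n_total * np.log(2 * np.pi) + logdet_V.sum() + quad)
    return ll, beta, XtVX_tot


def compare_gains(fit_1: GrowthFit, fit_2: GrowthFit,
                  maxiter: int = 400) -> GainComparison:
    """Wald test of equal absolute mean gains across two z-scored variables.

    Both inputs must have been fit on z-scored series (pooled variance 1
    within 0.01); the two series are refit jointly with one 4-dimensional
    random-effect block (asymptote and gain of each outcome, freely
    correlated across outcomes since the persons are shared), and
    |gain_1| - |gain_2| is tested by the delta method.
    """
    for i, f in enumerate((fit_1, fit_2), start=1):
        y = f._series[2]
        if abs(float(np.var(y)) - 1.0) > 0.01:
            raise ValueError(
                f"series {i} is not z-scored (variance {np.var(y):.3f}); "
                "z-score on the pooled sample first"
            )
    st1, st2, n_persons = _joint_stats(fit_1._series, fit_2._series)

    def chol_init(f):
        S = np.array([[f.var_asymptote, f.cov_asymptote_gain],
                      [f.cov_asymptote_gain, f.var_gain]])
        w, V = np.linalg.eigh(S)
        S = V @ np.diag(np.clip(w, 1e-4, None)) @ V.T
        return np.linalg.cholesky(S)

    L1 = chol_init(fit_1)
    L2 = chol_init(fit_2)
    L4 = np.zeros((4, 4))
    L4[:2, :2] = L1
    L4[2:, 2:] = L2
    packed = []
    for i in range(4):
        for j in range(i + 1):
            packed.append(np.log(max(L4[i, i], 1e-4)) if i == j else L4[i, j])
    x0 = np.concatenate([
        [np.log(max(fit_1.rate, 1e-3)), np.log(max(fit_2.rate, 1e-3))],
        packed,
        [0.5 * np.log(max(fit_1.resid_var, 1e-8)),
         0.5 * np.log(max(fit_2.resid_var, 1e-8))],
    ])

    def neg(params):
        out = _negll_joint(params, st1, st2)
        if out is None or not np.isfinite(out[0]):
            return 1e12
        return -out[0]

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter * 20, "fatol": 1e-8})
    out = _negll_joint(res.x, st1, st2)
    if out is None:
        raise RuntimeError("joint growth fit failed")
    _, beta, XtVX = out
    cov_b = np.linalg.inv(XtVX)
    g1, g2 = float(beta[1]), float(beta[3])
    grad = np.array([0.0, np.sign(g1) if g1 != 0 else 1.0,
                     0.0, -np.sign(g2) if g2 != 0 else -1.0])
    diff = abs(g1) - abs(g2)
    var_diff = float(grad @ cov_b @ grad)
    stat = diff**2 / var_diff if var_diff > 0 else 0.0
    return GainComparison(
        gain_1=g1,
        gain_2=g2,
        se_gain_1=float(np.sqrt(cov_b[1, 1])),
        se_gain_2=float(np.sqrt(cov_b[3, 3])),
        abs_diff=float(diff),
        se_abs_diff=float(np.sqrt(var_diff)),
        chi2=float(stat),
        df=1,
        pvalue=float(chi2.sf(stat, 1)),
        converged=bool(res.success),
    )
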