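"""Two-level analyses of scored occasions.

Everything here is built on the maximum-likelihood fit of a two-level
multivariate normal: each occasion-level variable is decomposed into a
latent person mean and an occasion deviation,

    y_ij = delta_y + U_yj + R_yij,   U ~ N(0, Sigma_b),  R ~ N(0, Sigma_w),

with unbalanced cluster sizes.  The level-specific covariance matrices then
yield, in closed form, the intraclass correlation (null model), the latent
covariate regression of observed RTs on drift and boundary scores at each
level, level-specific correlation matrices, and the path coefficients of
1-1-1 / 2-1-1 mediation models with drift and boundary as simultaneous
mediators.  Using latent (rather than computed/manifest) person means as
between-level predictors avoids the well-known bias of manifest cluster
means measured with finite reliability.

Indirect-effect intervals use the Monte-Carlo method: the a- and b-paths
are sampled jointly from their asymptotic normal distribution (delta method
on the ML fit) and the product's percentiles form the interval.  The
dependent-correlation test uses a person-resampling bootstrap of Fisher-z
differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm

__all__ = [
    "VarianceComponents",
    "TwoLevelFit",
    "LatentCovariateFit",
    "CorrelationMatrixPair",
    "DependentCorrelationTest",
    "MediationFit",
    "icc",
    "fit_null_model",
    "fit_twolevel_mvn",
    "fit_latent_regression",
    "multilevel_correlations",
    "compare_dependent_correlations",
    "fit_mediation",
]


def icc(tau2: float, sigma2: float) -> float:
    """Intraclass correlation tau2 / (tau2 + sigma2).

    The expected correlation between any two randomly chosen occasions of
    the same person; the between-person share of the total variance.
    """
    if tau2 < 0 or sigma2 < 0:
        raise ValueError("variance components must be nonnegative")
    total = tau2 + sigma2
    if total <= 0:
        raise ValueError("tau2 + sigma2 must be positive")
    return float(tau2 / total)


# ---------------------------------------------------------------------------
# univariate null model (random-intercept-only)


@dataclass
class VarianceComponents:
    """Null-model decomposition of one occasion-level variable."""

    grand_mean: float
    tau2: float          # between-person variance
    sigma2: float        # within-person variance
    icc: float
    se_grand_mean: float
    se_tau2: float
    se_sigma2: float
    se_icc: float
    loglik: float
    method: str
    n_persons: int
    n_obs: int

    def to_dict(self):
        return {k: getattr(self, k) for k in (
            "grand_mean", "tau2", "sigma2", "icc", "se_grand_mean",
            "se_tau2", "se_sigma2", "se_icc", "loglik", "method",
            "n_persons", "n_obs")}


def _null_suffstats(values, groups):
    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    df = df.dropna()
    agg = df.groupby("g")["y"].agg(["count", "mean", "var"])
    n_j = agg["count"].to_numpy(float)
    ybar = agg["mean"].to_numpy()
    ss_w = (agg["var"].fillna(0.0) * (n_j - 1)).to_numpy()
    return n_j, ybar, ss_w


def _null_loglik(tau2, sigma2, n_j, ybar, ss_w, reml: bool):
    if tau2 < 0 or sigma2 <= 0:
        return -np.inf
    v_j = tau2 + sigma2 / n_j
    w_j = 1.0 / v_j
    delta = np.sum(w_j * ybar) / np.sum(w_j)
    dev = ybar - delta
    ll = -0.5 * (
        np.sum((n_j - 1)) * np.log(sigma2)
        + np.sum(ss_w) / sigma2
        + np.sum(np.log(v_j))
        + np.sum(dev**2 / v_j)
        + np.log(2 * np.pi) * np.sum(n_j)
    )
    if reml:
        ll += -0.5 * np.log(np.sum(w_j)) + 0.5 * np.log(2 * np.pi)
    return ll


def _num_hessian(f, x, rel_step=1e-4):
    x = np.asarray(x, float)
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_null_model(values, groups, method: str = "ml") -> VarianceComponents:
    """Random-intercept null model of one variable; variance components + ICC.

    ``method`` is "ml" (default) or "reml".  Standard errors come from the
    numerical Hessian of the (restricted) likelihood; the ICC standard error
    uses the delta method.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    n_j, ybar, ss_w = _null_suffstats(values, groups)
    if len(n_j) < 2:
        raise ValueError("need at least 2 persons")
    if np.all(n_j < 2):
        raise ValueError(
            "every person has a single occasion; tau2 and sigma2 are not identified"
        )
    reml = method == "reml"
    y_all_var = (np.sum(ss_w) + np.sum(n_j * (ybar - np.average(ybar, weights=n_j)) ** 2)) / np.sum(n_j)
    s0 = max(y_all_var, 1e-8)

    def neg(params):
        t2, s2 = np.exp(params)
        return -_null_loglik(t2, s2, n_j, ybar, ss_w, reml)

    res = minimize(neg, np.log([s0 / 3, 2 * s0 / 3]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    tau2, sigma2 = np.exp(res.x)
    v_j = tau2 + sigma2 / n_j
    w_j = 1.0 / v_j
    delta = float(np.sum(w_j * ybar) / np.sum(w_j))
    ll = _null_loglik(tau2, sigma2, n_j, ybar, ss_w, reml)

    # clip keeps boundary estimates (tau2 ~ 0) inside the domain
    H = _num_hessian(
        lambda p: -_null_loglik(max(p[0], 1e-12), max(p[1], 1e-12),
                                n_j, ybar, ss_w, reml),
        [tau2, sigma2],
    )
    try:
        cov = np.linalg.inv(H)
        se_t2, se_s2 = np.sqrt(np.clip(np.diag(cov), 0, None))
        tot = tau2 + sigma2
        grad = np.array([sigma2, -tau2]) / tot**2
        se_icc = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_t2 = se_s2 = se_icc = float("nan")
    return VarianceComponents(
        grand_mean=delta,
        tau2=float(tau2),
        sigma2=float(sigma2),
        icc=icc(tau2, sigma2),
        se_grand_mean=float(np.sqrt(1.0 / np.sum(w_j))),
        se_tau2=float(se_t2),
        se_sigma2=float(se_s2),
        se_icc=se_icc,
        loglik=float(ll),
        method=method,
        n_persons=int(len(n_j)),
        n_obs=int(np.sum(n_j)),
    )


# ---------------------------------------------------------------------------
# multivariate two-level engine


def _pack_chol(L):
    """Lower-triangular matrix -> parameter vector (log diagonal)."""
    p = L.shape[0]
    out = []
    for i in range(p):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _unpack_chol(params, p):
    L = np.zeros((p, p))
    k = 0
    for i in range(p):
        for j in range(i + 1):
            L[i, j] = np.exp(np.clip(params[k], -30, 30)) if i == j else params[k]
            k += 1
    return L


def _safe_chol(S, ridge=1e-8):
    S = 0.5 * (S + S.T)
    for tries in range(8):
        try:
            return np.linalg.cholesky(S + ridge * (10**tries) * np.eye(len(S)))
        except np.linalg.LinAlgError:
            continue
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 1e-6, None)
    return np.linalg.cholesky(V @ np.diag(w) @ V.T)


@dataclass
class TwoLevelFit:
    """ML fit of the two-level multivariate normal decomposition."""

    variables: list
    between_only: tuple
    mean: np.ndarray
    sigma_w: np.ndarray      # within (occasion) covariance; zero rows/cols for
                             # person-level variables
    sigma_b: np.ndarray      # between (person) covariance
    loglik: float
    converged: bool
    n_persons: int
    n_obs: int
    _params: np.ndarray = field(repr=False, default=None)
    _suff: tuple = field(repr=False, default=None)

    def level_cov(self, level: str) -> pd.DataFrame:
        S = self.sigma_w if level == "within" else self.sigma_b
        return pd.DataFrame(S, index=self.variables, columns=self.variables)

    def level_corr(self, level: str, min_var: float = 1e-10) -> pd.DataFrame:
        S = np.array(self.level_cov(level))
        d = np.sqrt(np.clip(np.diag(S), 0, None))
        bad = d < np.sqrt(min_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = S / np.outer(d, d)
        C[bad, :] = np.nan
        C[:, bad] = np.nan
        np.fill_diagonal(C, np.where(bad, np.nan, 1.0))
        return pd.DataFrame(C, index=self.variables, columns=self.variables)

    def param_cov(self) -> np.ndarray:
        """Asymptotic covariance of the packed parameter vector (inverse Hessian)."""
        H = _num_hessian(lambda p: _twolevel_negll(p, *self._suff), self._params,
                         rel_step=1e-4)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)


def _twolevel_suffstats(df, variables, group, between_only):
    data = df[list(variables) + [group]].dropna()
    w_vars = [v for v in variables if v not in between_only]
    w_idx = [variables.index(v) for v in w_vars]
    g = data.groupby(group, sort=False)
    n_j = g.size().to_numpy(float)
    means = g[list(variables)].mean().to_numpy()
    # pooled within sums of squares over occasion-level variables
    W = data[w_vars].to_numpy()
    Wc = W - g[w_vars].transform("mean").to_numpy()
    ss_w = Wc.T @ Wc
    for v in between_only:
        j = variables.index(v)
        cluster_sd = g[v].std().fillna(0.0)
        if (cluster_sd > 1e-10).any():
            raise ValueError(f"variable {v!r} declared person-level but varies within persons")
    return n_j, means, ss_w, np.array(w_idx, int)


def _twolevel_negll(params, n_j, means, ss_w, w_idx, p):
    q = len(w_idx)
    k = 0
    delta = params[:p]; k = p
    nw = q * (q + 1) // 2
    Lw = _unpack_chol(params[k:k + nw], q); k += nw
    Lb = _unpack_chol(params[k:], p)
    Sw = Lw @ Lw.T
    Sb = Lb @ Lb.T
    dfw = np.sum(n_j - 1.0)
    try:
        sign, logdet_w = np.linalg.slogdet(Sw)
        if sign <= 0:
            return 1e12
        Sw_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError:
        return 1e12
    ll = -0.5 * (dfw * logdet_w + np.sum(Sw_inv * ss_w)
                 + dfw * q * np.log(2 * np.pi))
    Sw_emb = np.zeros((p, p))
    Sw_emb[np.ix_(w_idx, w_idx)] = Sw
    dev = means - delta
    for n in np.unique(n_j):
        mask = n_j == n
        V = Sb + Sw_emb / n
        try:
            Lv = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        sol = np.linalg.solve(Lv, dev[mask].T)
        ll += -0.5 * (mask.sum() * (2 * np.sum(np.log(np.diag(Lv)))
                                    + p * np.log(2 * np.pi))
                      + np.sum(sol**2))
    return -ll if np.isfinite(ll) else 1e12


def fit_twolevel_mvn(df: pd.DataFrame, variables, group: str,
                     between_only=(), maxiter: int = 1500) -> TwoLevelFit:
    """ML fit of the latent within/between decomposition of ``variables``.

    ``between_only`` names variables that are constant within persons
    (person-level covariates); they carry no within-level component.
    """
    variables = list(variables)
    p = len(variables)
    between_only = tuple(between_only)
    n_j, means, ss_w, w_idx = _twolevel_suffstats(df, variables, group, between_only)
    if len(n_j) < 2:
        raise ValueError("need at least 2 persons")
    q = len(w_idx)
    dfw = np.sum(n_j - 1.0)
    if q and dfw < q + 1:
        raise ValueError("too few within-person degrees of freedom")

    Sw0 = ss_w / max(dfw, 1.0)
    mean0 = np.average(means, axis=0, weights=n_j)
    Sb0 = np.cov(means.T, ddof=1).reshape(p, p)
    Sw_emb = np.zeros((p, p))
    Sw_emb[np.ix_(w_idx, w_idx)] = Sw0
    Sb0 = Sb0 - Sw_emb * np.mean(1.0 / n_j)
    w, V = np.linalg.eigh(0.5 * (Sb0 + Sb0.T))
    Sb0 = V @ np.diag(np.clip(w, 1e-4 * max(np.max(w), 1e-6), None)) @ V.T

    x0 = np.concatenate([mean0, _pack_chol(_safe_chol(Sw0)), _pack_chol(_safe_chol(Sb0))])
    suff = (n_j, means, ss_w, w_idx, p)
    res = minimize(_twolevel_negll, x0, args=suff, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": maxiter * (len(x0) + 1) * 3})
    k = p
    nw = q * (q + 1) // 2
    Lw = _unpack_chol(res.x[k:k + nw], q)
    Lb = _unpack_chol(res.x[k + nw:], p)
    Sw = np.zeros((p, p))
    Sw[np.ix_(w_idx, w_idx)] = Lw @ Lw.T
    return TwoLevelFit(
        variables=variables,
        between_only=between_only,
        mean=res.x[:p].copy(),
        sigma_w=Sw,
        sigma_b=Lb @ Lb.T,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_persons=int(len(n_j)),
        n_obs=int(np.sum(n_j)),
        _params=res.x.copy(),
        _suff=suff,
    )


# ---------------------------------------------------------------------------
# latent covariate regression (RTs on drift & boundary)


@dataclass
class LatentCovariateFit:
    """Level-specific regression of y on (x, z) from the latent decomposition."""

    outcome: str
    predictors: tuple
    beta_within: dict         # raw coefficients
    beta_between: dict
    beta_within_std: dict     # standardized within level
    beta_between_std: dict
    r2_within: float
    r2_between: float
    cov_within: pd.DataFrame
    cov_between: pd.DataFrame
    n_persons: int
    n_obs: int

    def to_dict(self):
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "beta_within": self.beta_within,
            "beta_between": self.beta_between,
            "beta_within_std": self.beta_within_std,
            "beta_between_std": self.beta_between_std,
            "r2_within": self.r2_within,
            "r2_between": self.r2_between,
            "n_persons": self.n_persons,
            "n_obs": self.n_obs,
        }


def _level_regression(S: np.ndarray, yi: int, xi: list):
    Sxx = S[np.ix_(xi, xi)]
    Sxy = S[np.ix_(xi, [yi])].ravel()
    cond = np.linalg.cond(Sxx)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError
    beta = np.linalg.solve(Sxx, Sxy)
    syy = S[yi, yi]
    r2 = float(beta @ Sxy / syy) if syy > 0 else float("nan")
    return beta, r2


def fit_latent_regression(y, x, z, groups) -> LatentCovariateFit:
    """Regress observed RT summaries on drift and boundary scores at both levels.

    All three variables are decomposed into latent person means and occasion
    deviations; within- and between-level coefficients come from the
    level-specific covariance matrices of the joint ML fit.
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float),
                       "z": np.asarray(z, float), "g": np.asarray(groups)})
    sub = df.dropna()
    wc = sub[["x", "z"]] - sub.groupby("g")[["x", "z"]].transform("mean")
    cw = np.corrcoef(wc["x"], wc["z"])[0, 1]
    if abs(cw) > 0.999:
        raise ValueError("collinear predictors at the within level: ('x', 'z')")
    fit = fit_twolevel_mvn(df, ["y", "x", "z"], "g")
    out = {}
    for level in ("within", "between"):
        S = np.array(fit.level_cov(level))
        try:
            beta, r2 = _level_regression(S, 0, [1, 2])
        except np.linalg.LinAlgError:
            raise ValueError(
                f"collinear predictors at the {level} level: ('x', 'z')"
            ) from None
        sd = np.sqrt(np.diag(S))
        beta_std = beta * sd[1:] / sd[0]
        out[level] = (dict(zip(("x", "z"), map(float, beta))),
                      dict(zip(("x", "z"), map(float, beta_std))), float(r2))
    return LatentCovariateFit(
        outcome="y",
        predictors=("x", "z"),
        beta_within=out["within"][0],
        beta_between=out["between"][0],
        beta_within_std=out["within"][1],
        beta_between_std=out["between"][1],
        r2_within=out["within"][2],
        r2_between=out["between"][2],
        cov_within=fit.level_cov("within"),
        cov_between=fit.level_cov("between"),
        n_persons=fit.n_persons,
        n_obs=fit.n_obs,
    )


# ---------------------------------------------------------------------------
# multilevel correlations and the dependent-correlation test


@dataclass
class CorrelationMatrixPair:
    """Within- and between-person correlation matrices with Fisher z values."""

    within: pd.DataFrame
    between: pd.DataFrame
    fisher_z_within: pd.DataFrame
    fisher_z_between: pd.DataFrame
    n_persons: int
    n_obs: int


def multilevel_correlations(df: pd.DataFrame, variables, group: str) -> CorrelationMatrixPair:
    """Level-specific correlation matrices from the two-level ML fit.

    A variable with (numerically) no variance at a level yields missing
    entries at that level, with a warning.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    fit = fit_twolevel_mvn(df, variables, group)
    out = {}
    for level in ("within", "between"):
        C = fit.level_corr(level)
        if C.isna().any().any():
            const = [v for v in variables if np.isnan(C.loc[v, v])]
            if const:
                warnings.warn(
                    f"variables with no {level}-level variance: {const}; "
                    "entries set missing"
                )
        out[level] = C
    with np.errstate(divide="ignore", invalid="ignore"):
        zw = np.arctanh(np.clip(out["within"], -1, 1))
        zb = np.arctanh(np.clip(out["between"], -1, 1))
    return CorrelationMatrixPair(
        within=out["within"],
        between=out["between"],
        fisher_z_within=pd.DataFrame(zw, index=variables, columns=variables),
        fisher_z_between=pd.DataFrame(zb, index=variables, columns=variables),
        n_persons=fit.n_persons,
        n_obs=fit.n_obs,
    )


def _moment_level_corrs(n_j, means, ss_w):
    """Closed-form moment estimators of the within/between correlation
    matrices from per-person sufficient statistics (bootstrap workhorse)."""
    dfw = np.sum(n_j - 1.0)
    Sw = ss_w / max(dfw, 1.0)
    mbar = np.average(means, axis=0, weights=n_j)
    dev = means - mbar
    Sm = (dev.T * n_j) @ dev / np.sum(n_j)
    Sb = Sm - Sw * np.mean(1.0 / n_j)
    def corr(S):
        d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        return S / np.outer(d, d)
    return corr(Sw), corr(Sb)


@dataclass
class DependentCorrelationTest:
    """Fisher-z difference of two dependent correlations with bootstrap SE."""

    pair_a: tuple
    pair_b: tuple
    level: str
    r_a: float
    r_b: float
    z_diff: float
    se_boot: float
    statistic: float
    pvalue: float
    n_boot: int
    n_persons: int


def compare_dependent_correlations(df: pd.DataFrame, group: str,
                                   pair_a, pair_b, level: str,
                                   n_boot: int = 1999, seed: int = 0,
                                   fit: TwoLevelFit | None = None) -> DependentCorrelationTest:
    """Test whether two correlations sharing data differ at one level.

    Point estimates come from the two-level ML fit; the standard error of
    the Fisher-z difference comes from resampling persons with replacement
    and recomputing moment-based level correlations per replicate.
    """
    if level not in ("within", "between"):
        raise ValueError("level must be 'within' or 'between'")
    variables = sorted(set(pair_a) | set(pair_b))
    if fit is None:
        fit = fit_twolevel_mvn(df, variables, group)
    C = fit.level_corr(level)
    r_a = float(C.loc[pair_a[0], pair_a[1]])
    r_b = float(C.loc[pair_b[0], pair_b[1]])
    z_diff = float(np.arctanh(r_a) - np.arctanh(r_b))

    data = df[variables + [group]].dropna()
    g = data.groupby(group, sort=False)
    n_j = g.size().to_numpy(float)
    J = len(n_j)
    if J < 50:
        warnings.warn("fewer than 50 persons; bootstrap SE may be unstable")
    means = g[variables].mean().to_numpy()
    W = data[variables].to_numpy() - g[variables].transform("mean").to_numpy()
    # per-person within SS tensors for fast resampling; factorize order matches
    # groupby(sort=False) first-appearance order
    codes = pd.factorize(data[group])[0]
    ss_pp = np.zeros((J, len(variables), len(variables)))
    np.add.at(ss_pp, codes, W[:, :, None] * W[:, None, :])
    ia = [variables.index(v) for v in pair_a]
    ib = [variables.index(v) for v in pair_b]
    rng = np.random.default_rng(seed)
    zs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, J, J)
        Cw, Cb = _moment_level_corrs(n_j[idx], means[idx], ss_pp[idx].sum(axis=0))
        Cl = Cw if level == "within" else Cb
        ra = np.clip(Cl[ia[0], ia[1]], -0.9999, 0.9999)
        rb = np.clip(Cl[ib[0], ib[1]], -0.9999, 0.9999)
        zs[b] = np.arctanh(ra) - np.arctanh(rb)
    se = float(np.std(zs, ddof=1))
    stat = z_diff / se if se > 0 else 0.0
    p = float(2 * norm.sf(abs(stat))) if se > 0 else 1.0
    if z_diff == 0.0:
        stat, p = 0.0, 1.0
    return DependentCorrelationTest(
        pair_a=tuple(pair_a), pair_b=tuple(pair_b), level=level,
        r_a=r_a, r_b=r_b, z_diff=z_diff, se_boot=se,
        statistic=float(stat), pvalue=p, n_boot=n_boot, n_persons=J,
    )


# ---------------------------------------------------------------------------
# multilevel mediation


@dataclass
class MediationFit:
    """1-1-1 or 2-1-1 mediation with drift and boundary as simultaneous mediators."""

    predictor: str
    predictor_level: str      # "within" (1-1-1) or "between" (2-1-1)
    binary_predictor: bool
    mediators: tuple
    outcome: str
    a_paths: dict             # predictor -> mediator (raw)
    b_paths: dict             # mediator -> outcome given predictor (raw)
    direct: float             # c'
    total: float              # c
    indirect: dict            # mediator -> a*b (raw)
    a_paths_std: dict
    b_paths_std: dict
    direct_std: float
    total_std: float
    indirect_std: dict
    indirect_ci: dict         # mediator -> (lo, hi), standardized scale
    total_ci: tuple
    n_mc: int
    seed: int
    n_persons: int
    n_obs: int

    def to_dict(self):
        d = {k: getattr(self, k) for k in (
            "predictor", "predictor_level", "binary_predictor", "outcome",
            "a_paths", "b_paths", "direct", "total", "indirect",
            "a_paths_std", "b_paths_std", "direct_std", "total_std",
            "indirect_std", "n_mc", "seed", "n_persons", "n_obs")}
        d["mediators"] = list(self.mediators)
        d["indirect_ci"] = {k: list(v) for k, v in self.indirect_ci.items()}
        d["total_ci"] = list(self.total_ci)
        return d


def _paths_from_cov(S, ip, im, iy):
    a = np.array([S[ip, m] / S[ip, ip] for m in im])
    xi = [ip] + list(im)
    beta, _ = _level_regression(S, iy, xi)
    cprime = beta[0]
    b = beta[1:]
    total = S[ip, iy] / S[ip, ip]
    return a, b, float(cprime), float(total)


def fit_mediation(df: pd.DataFrame, predictor: str, mediators, outcome: str,
                  group: str, predictor_level: str = "within",
                  binary_predictor: bool | None = None,
                  n_mc: int = 100_000, seed: int = 0) -> MediationFit:
    """Multiple-mediator multilevel mediation by the product-of-coefficients
    method on the latent two-level decomposition.

    The a-paths (predictor -> mediator), b-paths (mediator -> outcome,
    adjusting for the predictor and the other mediator), direct effect c'
    and total effect c are all computed at the predictor's level.  The
    identity c = c' + sum(a*b) holds exactly at the estimates.  95%
    intervals for the indirect effects sample the paths jointly from their
    asymptotic normal distribution (Monte-Carlo method, seeded).

    Standardization: continuous predictors are standardized with respect to
    both variables; binary (0/1) predictors only with respect to the
    dependent variable of each path.
    """
    mediators = tuple(mediators)
    if predictor_level not in ("within", "between"):
        raise ValueError("predictor_level must be 'within' or 'between'")
    variables = [predictor, *mediators, outcome]
    sub = df[[predictor, group]].dropna()
    vals = sub[predictor].to_numpy(float)
    if np.nanstd(vals) < 1e-12:
        raise ValueError(f"predictor {predictor!r} is constant")
    if binary_predictor is None:
        binary_predictor = set(np.unique(vals)) <= {0.0, 1.0}
    if predictor_level == "between":
        if (sub.groupby(group)[predictor].std().fillna(0.0) > 1e-10).any():
            raise ValueError(
                f"predictor {predictor!r} varies within persons but was declared person-level"
            )
        between_only = (predictor,)
    else:
        wvar = (sub[predictor] - sub.groupby(group)[predictor].transform("mean")).var()
        if wvar < 1e-12:
            raise ValueError(
                f"predictor {predictor!r} has no within-person variance but was declared occasion-level"
            )
        between_only = ()
    fit = fit_twolevel_mvn(df, variables, group, between_only=between_only)
    S = np.array(fit.level_cov(predictor_level))
    ip, iy = 0, len(variables) - 1
    im = list(range(1, 1 + len(mediators)))
    a, b, cprime, total = _paths_from_cov(S, ip, im, iy)

    sd = np.sqrt(np.clip(np.diag(S), 1e-300, None))
    sd_p = 1.0 if binary_predictor else sd[ip]
    a_std = a * sd_p / sd[im]
    b_std = b * sd[im] / sd[iy]
    cprime_std = cprime * sd_p / sd[iy]
    total_std = total * sd_p / sd[iy]

    # Monte-Carlo interval: delta-method covariance of (a..., b..., c')
    cov_params = fit.param_cov()

    def path_vec(params):
        k = len(fit.variables)
        q = len([v for v in fit.variables if v not in fit.between_only])
        nw = q * (q + 1) // 2
        Lw = _unpack_chol(params[k:k + nw], q)
        Lb = _unpack_chol(params[k + nw:], k)
        Sw = np.zeros((k, k))
        w_idx = [i for i, v in enumerate(fit.variables) if v not in fit.between_only]
        Sw[np.ix_(w_idx, w_idx)] = Lw @ Lw.T
        Sl = Sw if predictor_level == "within" else Lb @ Lb.T
        aa, bb, cp, _ = _paths_from_cov(Sl, ip, im, iy)
        return np.concatenate([aa, bb, [cp]])

    eps = 1e-5
    x0 = fit._params
    J = np.zeros((2 * len(mediators) + 1, len(x0)))
    for k in range(len(x0)):
        step = eps * max(abs(x0[k]), 1.0)
        e = np.zeros(len(x0)); e[k] = step
        J[:, k] = (path_vec(x0 + e) - path_vec(x0 - e)) / (2 * step)
    cov_paths = J @ cov_params @ J.T
    cov_paths = 0.5 * (cov_paths + cov_paths.T)

    rng = np.random.default_rng(seed)
    point = np.concatenate([a, b, [cprime]])
    w, V = np.linalg.eigh(cov_paths)
    draw = point + rng.standard_normal((n_mc, len(point))) @ (V * np.sqrt(np.clip(w, 0, None))).T
    nm = len(mediators)
    ind_draws = draw[:, :nm] * draw[:, nm:2 * nm]
    scale = sd_p / sd[iy]
    indirect_ci = {}
    for j, mname in enumerate(mediators):
        lo, hi = np.percentile(ind_draws[:, j] * scale, [2.5, 97.5])
        indirect_ci[mname] = (float(lo), float(hi))
    tot_draws = (ind_draws.sum(axis=1) + draw[:, -1]) * scale
    total_ci = tuple(float(v) for v in np.percentile(tot_draws, [2.5, 97.5]))

    return MediationFit(
        predictor=predictor,
        predictor_level=predictor_level,
        binary_predictor=bool(binary_predictor),
        mediators=mediators,
        outcome=outcome,
        a_paths={m: float(a[j]) for j, m in enumerate(mediators)},
        b_paths={m: float(b[j]) for j, m in enumerate(mediators)},
        direct=float(cprime),
        total=float(total),
        indirect={m: float(a[j] * b[j]) for j, m in enumerate(mediators)},
        a_paths_std={m: float(a_std[j]) for j, m in enumerate(mediators)},
        b_paths_std={m: float(b_std[j]) for j, m in enumerate(mediators)},
        direct_std=float(cprime_std),
        total_std=float(total_std),
        indirect_std={m: float(a_std[j] * b_std[j]) for j, m in enumerate(mediators)},
        indirect_ci=indirect_ci,
        total_ci=total_ci,
        n_mc=n_mc,
        seed=seed,
        n_persons=fit.n_persons,
        n_obs=fit.n_obs,
    )
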