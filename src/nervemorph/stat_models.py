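"""Inference layer: correlations, adjusted OLS, a penalized-spline mixed
smoother, and heteroscedastic Gaussian mixed regression.

Two estimators here are bespoke:

``fit_spline_mixed``
    y = f(x) + u_participant + eps, with f a cubic B-spline (interior
    knots at x-quantiles), a second-derivative penalty on f, and a
    Gaussian participant random intercept.  The smoothing parameter and
    the variance ratio are chosen by REML (coarse log-grid, then
    golden-section coordinate refinement).  The effective degrees of
    freedom (EDF) is the trace of the smoother matrix restricted to the
    spline block.

``fit_hetero_mixed``
    y_i = x_i' beta + u_g(i) + eps_i with eps_i ~ N(0, exp(2 z_i' gamma))
    and u_g ~ N(0, tau^2): a Gaussian location-scale model (identity link
    for the mean, log link for the SD) with a participant random
    intercept.  The exact marginal likelihood is maximized by L-BFGS with
    analytic gradients (per-group Woodbury identities keep the cost
    linear in n); Wald inference comes from the numerical Hessian.

OLS and Spearman are thin wrappers over statsmodels/scipy kept behind a
stable result surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats
from statsmodels.api import OLS
from statsmodels.tools.numdiff import approx_hess

from .exceptions import DesignError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "OlsFit", "SmoothFit", "HeteroFit",
    "spearman", "fit_ols", "fit_spline_mixed", "fit_hetero_mixed",
    "dispersion_age_test", "effect_size_projection",
    "alr_model_frame", "gratio_model_frame",
]


# --------------------------------------------------------------------------
# simple wrappers

@dataclass
class OlsFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    r2: float
    resid: np.ndarray = field(repr=False)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with the
    t-approximation p-value.  Constant input raises ``ValueError``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _check_full_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the columns whose removal restores the rank deficit
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(str(name))
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> OlsFit:
    """Least-squares fit of y on the given design (stable decomposition).

    Rank-deficient designs raise :class:`DesignError` naming the
    collinear columns.
    """
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
    _check_full_rank(X)
    res = OLS(np.asarray(y, float), X).fit()
    return OlsFit(params=res.params, bse=res.bse, pvalues=res.pvalues,
                  n=int(res.nobs), r2=float(res.rsquared),
                  resid=np.asarray(res.resid))


def effect_size_projection(intercept: float, slope: float,
                           delta_years: float) -> float:
    """Projected outcome after ``delta_years``: intercept + slope * delta."""
    return intercept + slope * delta_years


# --------------------------------------------------------------------------
# penalized-spline mixed smoother

@dataclass
class SmoothFit:
    """Fitted penalized-spline mixed smooth."""
    knots: np.ndarray
    coef: np.ndarray
    lam: float
    edf: float
    sigma2: float
    tau2: float
    reml: float
    var_explained: float
    n: int
    curve: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    derivative: Callable[[np.ndarray], np.ndarray] = field(repr=False)


def _bspline_basis(x: np.ndarray, n_interior: int):
    lo, hi = float(np.min(x)), float(np.max(x))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    B = interpolate.BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()
    return t, B


def _second_deriv_penalty(t: np.ndarray) -> np.ndarray:
    """S_ij = integral of B_i'' B_j'' dx (exact Gauss-Legendre per span)."""
    k = len(t) - 4
    xs, ws = [], []
    gl_x, gl_w = np.polynomial.legendre.leggauss(3)
    for a, b in zip(t[3:-4], t[4:-3]):
        if b > a:
            xs.append((b - a) / 2 * gl_x + (a + b) / 2)
            ws.append((b - a) / 2 * gl_w)
    xs = np.concatenate(xs)
    ws = np.concatenate(ws)
    D2 = np.empty((xs.size, k))
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        D2[:, j] = interpolate.splev(xs, (t, c, 3), der=2)
    return (D2 * ws[:, None]).T @ D2


def _spline_reml(y, B, Z, S, logdetS_plus, log_lam, log_r):
    """Profiled (-2/2) REML criterion and the solved coefficients."""
    n, k = B.shape
    q = 0 if Z is None else Z.shape[1]
    lam, r = np.exp(log_lam), np.exp(log_r)
    X = B if Z is None else np.hstack([B, Z])
    P = np.zeros((k + q, k + q))
    P[:k, :k] = lam * S
    if q:
        P[k:, k:] = r * np.eye(q)
    XtX = X.T @ X
    C = XtX + P
    Xty = X.T @ y
    cL, low = None, None
    try:
        cho = np.linalg.cholesky(C + 1e-10 * np.eye(k + q))
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    chat = np.linalg.solve(C, Xty)
    pen_rss = float(y @ y - chat @ Xty)
    nstar = n - 2  # penalty null space: constants + linears
    sigma2 = max(pen_rss / nstar, 1e-300)
    logdetC = 2 * np.sum(np.log(np.diag(cho)))
    logdetP = (k - 2) * log_lam + logdetS_plus + q * log_r
    reml = -0.5 * (nstar * (np.log(2 * np.pi * sigma2) + 1)
                   - logdetP + logdetC)
    return reml, chat, sigma2


def fit_spline_mixed(y, x, groups=None, *, n_interior_knots: int = 20,
                     lam: float | None = None,
                     grid: tuple[float, float, int] = (-6.0, 10.0, 9)) -> SmoothFit:
    """Penalized cubic-spline smooth of y on x with a random intercept.

    Parameters
    ----------
    y, x : array-like
        Outcome and covariate (x must be positive-length, any scale).
    groups : array-like, optional
        Participant labels; omit for a plain penalized spline.
    n_interior_knots : int
        Interior knots placed at x-quantiles (default 20; dense enough to
        resolve a slope change sitting in a sparse region of x).
    lam : float, optional
        Fix the smoothing parameter instead of selecting it by REML
        (used by the lambda->infinity limit checks).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.size != x.size or y.size < 10:
        raise ValueError("x and y must have equal length >= 10")
    t, B = _bspline_basis(x, n_interior_knots)
    k = B.shape[1]
    S = _second_deriv_penalty(t)
    eig = np.linalg.eigvalsh(S)
    logdetS_plus = float(np.sum(np.log(eig[eig > eig.max() * 1e-10])))

    Z = None
    if groups is not None:
        _, gidx = np.unique(np.asarray(groups), return_inverse=True)
        q = gidx.max() + 1
        if q >= 2:
            Z = np.zeros((y.size, q))
            Z[np.arange(y.size), gidx] = 1.0
        else:
            logger.info("single group supplied; dropping random intercept")

    lo, hi, npts = grid
    lam_grid = np.linspace(lo, hi, npts) if lam is None else [np.log(lam)]
    r_grid = np.linspace(-4.0, 8.0, 7) if Z is not None else [0.0]

    def crit(ll, lr):
        return _spline_reml(y, B, Z, S, logdetS_plus, ll, lr)[0]

    best = (-np.inf, lam_grid[0], r_grid[0])
    for ll in lam_grid:
        for lr in r_grid:
            v = crit(ll, lr)
            if v > best[0]:
                best = (v, ll, lr)
    _, ll, lr = best
    # golden-section refinement, coordinate-wise
    for _ in range(3):
        if lam is None:
            res = optimize.minimize_scalar(
                lambda u: -crit(u, lr), bracket=None,
                bounds=(ll - 2.0, ll + 2.0), method="bounded",
                options={"xatol": 1e-4})
            ll = float(res.x)
        if Z is not None:
            res = optimize.minimize_scalar(
                lambda u: -crit(ll, u),
                bounds=(lr - 2.0, lr + 2.0), method="bounded",
                options={"xatol": 1e-4})
            lr = float(res.x)
    reml, chat, sigma2 = _spline_reml(y, B, Z, S, logdetS_plus, ll, lr)
    if chat is None:
        raise FitError("spline REML system is singular", trace=(ll, lr))
    theta = chat[:k]

    # EDF of the smooth: trace of the smoother restricted to spline coords
    lam_hat, r_hat = np.exp(ll), np.exp(lr)
    X = B if Z is None else np.hstack([B, Z])
    P = np.zeros((X.shape[1], X.shape[1]))
    P[:k, :k] = lam_hat * S
    if Z is not None:
        P[k:, k:] = r_hat * np.eye(Z.shape[1])
    F = np.linalg.solve(X.T @ X + P, X.T @ X)
    edf = float(np.trace(F[:k, :k]))

    spl = interpolate.BSpline(t, theta, 3, extrapolate=False)
    dspl = spl.derivative(1)
    fitted = spl(np.clip(x, t[0], t[-1]))
    var_explained = float(1.0 - np.var(y - fitted) / np.var(y))
    return SmoothFit(
        knots=t, coef=theta, lam=float(lam_hat), edf=edf,
        sigma2=float(sigma2),
        tau2=float(sigma2 / r_hat) if Z is not None else 0.0,
        reml=float(reml), var_explained=var_explained, n=y.size,
        curve=lambda xx: spl(np.clip(np.asarray(xx, float), t[0], t[-1])),
        derivative=lambda xx: dspl(np.clip(np.asarray(xx, float), t[0], t[-1])),
    )


# --------------------------------------------------------------------------
# heteroscedastic Gaussian mixed regression

@dataclass
class HeteroFit:
    """ML fit of the location-scale random-intercept Gaussian model."""
    beta: pd.Series
    gamma: pd.Series
    tau2: float
    loglik: float
    se_beta: pd.Series
    se_gamma: pd.Series
    p_beta: pd.Series
    p_gamma: pd.Series
    n: int
    n_groups: int
    converged: bool
    theta: np.ndarray = field(repr=False)
    cov: np.ndarray | None = field(repr=False, default=None)


def _hetero_nll_grad(theta, y, X, Z, gidx, ngrp, want_grad=True):
    p, q = X.shape[1], Z.shape[1]
    beta, gamma, rho = theta[:p], theta[p:p + q], theta[-1]
    tau2 = np.exp(2.0 * rho)
    e = y - X @ beta
    logd = 2.0 * (Z @ gamma)
    logd = np.clip(logd, -60, 60)
    w = np.exp(-logd)
    we = w * e
    S0 = np.bincount(gidx, weights=w, minlength=ngrp)
    S1 = np.bincount(gidx, weights=we, minlength=ngrp)
    Swe2 = np.bincount(gidx, weights=we * e, minlength=ngrp)
    Slogd = np.bincount(gidx, weights=logd, minlength=ngrp)
    A = 1.0 + tau2 * S0
    Q = Swe2 - tau2 * S1**2 / A
    nll = 0.5 * (y.size * np.log(2 * np.pi) + np.sum(Slogd + np.log(A) + Q))
    if not np.isfinite(nll):
        # off-scale parameters during a line search: steer back with a
        # large finite value instead of overflowing
        nll = 1e12
        if not want_grad:
            return nll
        return nll, np.zeros_like(theta)
    if not want_grad:
        return nll
    c = (tau2 * S1 / A)[gidx]          # per-row group shrinkage target
    r_tilde = e - c
    g_beta = -X.T @ (w * r_tilde)
    g_gamma = Z.T @ (1.0 - w * r_tilde**2 - (tau2 * w) / A[gidx])
    g_rho = tau2 * np.sum((S0 * A - S1**2) / A**2)
    return nll, np.concatenate([g_beta, g_gamma, [g_rho]])


def _hetero_start(y, X, Z, gidx, ngrp):
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta0
    target = 0.5 * np.log(e**2 + 1e-8)
    gamma0, *_ = np.linalg.lstsq(Z, target, rcond=None)
    gm = np.bincount(gidx, weights=e, minlength=ngrp) / np.bincount(gidx, minlength=ngrp)
    tau0 = np.sqrt(max(np.var(gm) - np.var(e - gm[gidx]) / max(np.bincount(gidx).mean(), 1.0), 1e-4))
    return np.concatenate([beta0, gamma0, [np.log(tau0)]])


def fit_hetero_mixed(y, X_mean, Z_disp, groups, *, seed: int = 0,
                     n_restarts: int = 3, start: np.ndarray | None = None,
                     compute_se: bool = True) -> HeteroFit:
    """Maximum likelihood for the heteroscedastic random-intercept model.

    The exact marginal Gaussian log-likelihood (per-participant covariance
    diag(exp(2 Z gamma)) + tau^2 J) is maximized over (beta, gamma,
    log tau) by L-BFGS with analytic gradients, from an OLS start plus
    ``n_restarts`` seeded jittered restarts.  Wald SEs and two-sided
    normal p-values come from the numerical Hessian at the optimum; a
    singular Hessian flags SEs as unavailable (NaN) rather than failing.
    """
    Xdf = pd.DataFrame(X_mean)
    Zdf = pd.DataFrame(Z_disp)
    _check_full_rank(Xdf)
    _check_full_rank(Zdf)
    y = np.asarray(y, float)
    X = Xdf.to_numpy(dtype=float)
    Z = Zdf.to_numpy(dtype=float)
    groups = np.asarray(groups)
    if not (y.size == X.shape[0] == Z.shape[0] == groups.size):
        raise DesignError("y, X_mean, Z_disp and groups must have equal row counts")
    _, gidx = np.unique(groups, return_inverse=True)
    ngrp = int(gidx.max()) + 1
    p, q = X.shape[1], Z.shape[1]

    theta0 = _hetero_start(y, X, Z, gidx, ngrp)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    if start is not None:
        starts.insert(0, np.asarray(start, float))
    starts += [theta0 + 0.1 * rng.standard_normal(theta0.size)
               for _ in range(n_restarts)]

    best = None
    for s in starts:
        res = optimize.minimize(
            _hetero_nll_grad, s, args=(y, X, Z, gidx, ngrp), jac=True,
            method="L-BFGS-B",
            bounds=([(None, None)] * p + [(-30.0, 30.0)] * q
                    + [(-12.0, 6.0)]),
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("heteroscedastic fit failed on all restarts", trace=best)
    theta = best.x
    nan = pd.Series(np.nan, index=Xdf.columns)
    se_b = se_g = None
    cov = None
    if compute_se:
        H = approx_hess(theta, lambda t: _hetero_nll_grad(
            t, y, X, Z, gidx, ngrp, want_grad=False))
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
            se_b = pd.Series(se[:p], index=Xdf.columns)
            se_g = pd.Series(se[p:p + q], index=Zdf.columns)
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian: Wald SEs unavailable")
    if se_b is None:
        se_b = nan
        se_g = pd.Series(np.nan, index=Zdf.columns)
    beta = pd.Series(theta[:p], index=Xdf.columns)
    gamma = pd.Series(theta[p:p + q], index=Zdf.columns)
    z_b = beta / se_b
    z_g = gamma / se_g
    two_sided = lambda z: pd.Series(
        2 * stats.norm.sf(np.abs(np.asarray(z, float))), index=z.index)
    return HeteroFit(
        beta=beta, gamma=gamma, tau2=float(np.exp(2 * theta[-1])),
        loglik=float(-best.fun), se_beta=se_b, se_gamma=se_g,
        p_beta=two_sided(z_b), p_gamma=two_sided(z_g),
        n=y.size, n_groups=ngrp, converged=bool(best.success),
        theta=theta, cov=cov)


def dispersion_age_test(y, X_mean, groups,
                        Z_variants: dict[str, pd.DataFrame],
                        seed: int = 0) -> pd.DataFrame:
    """Fit nested dispersion designs and report gamma plus LR statistics.

    ``Z_variants`` maps a name to a dispersion design; designs must be
    nested by column names in the given order (each design's columns are
    a subset of the next).  The larger model is warm-started from the
    embedded smaller-model optimum, so each LR statistic is >= 0 up to
    optimizer tolerance.
    """
    names = list(Z_variants)
    cols_prev: list | None = None
    fits: dict[str, HeteroFit] = {}
    rows = []
    prev_fit = None
    for name in names:
        Zdf = pd.DataFrame(Z_variants[name])
        if cols_prev is not None and not set(cols_prev) <= set(Zdf.columns):
            raise DesignError(
                f"dispersion design '{name}' is not nested in the previous one")
        start = None
        if prev_fit is not None:
            p = prev_fit.beta.size
            g_full = pd.Series(0.0, index=Zdf.columns)
            g_full[prev_fit.gamma.index] = prev_fit.gamma.to_numpy()
            start = np.concatenate([prev_fit.beta.to_numpy(),
                                    g_full.to_numpy(),
                                    [prev_fit.theta[-1]]])
        fit = fit_hetero_mixed(y, X_mean, Zdf, groups, seed=seed,
                               start=start, compute_se=True)
        lr = np.nan if prev_fit is None else 2.0 * (fit.loglik - prev_fit.loglik)
        df_extra = np.nan if prev_fit is None else Zdf.shape[1] - len(cols_prev)
        rows.append({"design": name, "loglik": fit.loglik,
                     "n_disp_terms": Zdf.shape[1],
                     "lr_vs_previous": lr, "df": df_extra,
                     "p_lr": (np.nan if prev_fit is None
                              else float(stats.chi2.sf(max(lr, 0.0), df_extra)))})
        fits[name] = fit
        prev_fit = fit
        cols_prev = list(Zdf.columns)
    out = pd.DataFrame(rows)
    out.attrs["fits"] = fits
    return out


# --------------------------------------------------------------------------
# model frames for the two study layouts

def alr_model_frame(composition: pd.DataFrame, participants: pd.DataFrame,
                    age_center: float = 92.0):
    """Long-format design for the compositional log-ratio model.

    Stacks the five reference log-ratios (ln p_k/p_1, k=2..6) of each
    participant, with the k=2 ratio as the reference category; fixed
    effects are centred age, sex (female = 1), category dummies and
    age x category interactions; the dispersion design is intercept plus
    the category dummies.  Returns ``(y, X_mean, Z_disp, groups)``.
    """
    merged = composition.merge(
        participants[["participant_id", "age_at_death", "sex"]],
        on="participant_id")
    frames = []
    for k in range(2, 7):
        frames.append(pd.DataFrame({
            "participant_id": merged["participant_id"],
            "y": merged[f"lr{k}"],
            "age": merged["age_at_death"] - age_center,
            "sex": (merged["sex"] == "female").astype(float),
            "cat": k,
        }))
    long = pd.concat(frames, ignore_index=True)
    X = pd.DataFrame({"intercept": 1.0, "age": long["age"], "sex": long["sex"]})
    Z = pd.DataFrame({"intercept": np.ones(len(long))})
    for k in range(3, 7):
        dummy = (long["cat"] == k).astype(float)
        X[f"cat{k}"] = dummy
        Z[f"cat{k}"] = dummy
    for k in range(3, 7):
        X[f"age:cat{k}"] = X["age"] * X[f"cat{k}"]
    return long["y"].to_numpy(), X, Z, long["participant_id"].to_numpy()


def gratio_model_frame(fibres: pd.DataFrame, participants: pd.DataFrame,
                       age_center: float = 92.0):
    """Design for the g-ratio by diameter-group model.

    One row per (subsampled) fibre; fixed effects are centred age, sex,
    dummies for the five smaller diameter bins (reference: >= 10 um) and
    age x bin interactions; dispersion design is intercept + bin dummies.
    Returns ``(y, X_mean, Z_disp, groups)``.
    """
    from .aggregation import BIN_EDGES_UM
    merged = fibres.merge(
        participants[["participant_id", "age_at_death", "sex"]],
        on="participant_id")
    d = merged["fibre_diameter_um"].to_numpy(dtype=float)
    bins = np.digitize(d, BIN_EDGES_UM[1:-1], right=False)  # 0..5, 5 = >=10
    X = pd.DataFrame({
        "intercept": 1.0,
        "age": merged["age_at_death"] - age_center,
        "sex": (merged["sex"] == "female").astype(float),
    })
    Z = pd.DataFrame({"intercept": np.ones(len(merged))})
    for b in range(5):
        dummy = (bins == b).astype(float)
        X[f"bin{b + 1}"] = dummy
        Z[f"bin{b + 1}"] = dummy
    for b in range(5):
        X[f"age:bin{b + 1}"] = X["age"] * X[f"bin{b + 1}"]
    return (merged["g_ratio"].to_numpy(dtype=float), X, Z,
            merged["participant_id"].to_numpy())
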