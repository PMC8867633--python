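"""On-top trend estimation from standardized prevalences.

The region x year standardized prevalences are decomposed by the
meta-regression

    p_hat_rt = alpha_t + beta_r + theta_tilde_r * t + gamma_rt + eps_rt,
    gamma_rt ~ N(0, tau^2),  eps_rt ~ N(0, sigma_hat_rt^2),

with side conditions sum_t alpha_t = 0 and sum_r theta_tilde_r = 0.
The within-cell variances sigma_hat_rt^2 are plugged in from the
standardization step; a single additive heterogeneity tau^2 is
estimated (REML by default, method of moments available).  Cross-cell
correlations of the p_hat_rt are deliberately not modeled.

theta_tilde_r is a region's linear trend on top of the common, possibly
nonlinear, time profile alpha_t.  To make trends comparable with what a
line plot shows, the overall linear trend theta (the OLS slope of
alpha_t on t) is added back and the result scaled to five years:

    theta_r = 5 * (theta_tilde_r + theta),

reported in percentage points.  Standard errors follow from the joint
covariance of (alpha_t, theta_tilde_r).

An acceleration analysis replaces the intervention region's linear
on-top term by a two-piece linear spline with the knot exactly at the
middle of the observation period; the slope change quantifies
acceleration or deceleration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .standardization import StandardizedPrevalences

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design construction with sum-to-zero (deviation) codings


def _deviation_columns(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Deviation coding: n_levels-1 columns, last level = -1 everywhere."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        out[:, j] = (codes == j).astype(float)
    out[codes == n_levels - 1, :] = -1.0
    return out


def _expand_transform(n_levels: int) -> np.ndarray:
    """Map reduced deviation coefficients to the full sum-to-zero vector."""
    L = np.vstack([np.eye(n_levels - 1), -np.ones((1, n_levels - 1))])
    return L


def _reml_objective(tau2: float, y, X, sig2) -> float:
    v = sig2 + tau2
    w = 1.0 / v
    XtW = X.T * w
    A = XtW @ X
    sign, logdet_A = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, XtW @ y)
    r = y - X @ beta
    return 0.5 * (np.log(v).sum() + logdet_A + float(r * w @ r))


def _mom_tau2(y, X, sig2) -> float:
    """DerSimonian-Laird-type method of moments for the regression case."""
    w = 1.0 / sig2
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    r = y - X @ beta
    Q = float(r * w @ r)
    n, p = X.shape
    H_trace = float(np.trace(np.linalg.solve(A, (X.T * w**2) @ X)))
    denom = w.sum() - H_trace
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - (n - p)) / denom)


def _fit_gls(y, X, sig2, tau_method: str = "reml"):
    """Estimate tau^2 and the GLS coefficients with known within variances."""
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"fewer observations ({n}) than parameters ({p})")
    if tau_method == "mom":
        tau2 = _mom_tau2(y, X, sig2)
    elif tau_method == "reml":
        scale = max(float(np.var(y)), float(np.max(sig2)), 1e-12)
        res = optimize.minimize_scalar(
            _reml_objective,
            bounds=(0.0, 10.0 * scale),
            args=(y, X, sig2),
            method="bounded",
            options={"xatol": 1e-14},
        )
        tau2 = max(0.0, float(res.x))
        # profile ties at the boundary: prefer 0 when indistinguishable
        if _reml_objective(0.0, y, X, sig2) <= res.fun + 1e-10:
            tau2 = 0.0
    else:
        raise ValidationError("tau_method must be 'reml' or 'mom'")
    w = 1.0 / (sig2 + tau2)
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    cov = np.linalg.inv(A)
    return beta, cov, tau2


@dataclass
class TrendFit:
    """Fitted decomposition into common profile and on-top trends."""

    regions: list
    years: np.ndarray
    alpha_t: np.ndarray  # full, sums to 0
    beta_r: np.ndarray
    theta_tilde: np.ndarray  # full, sums to 0
    tau: float
    cov_alpha: np.ndarray
    cov_theta: np.ndarray
    cov_alpha_theta: np.ndarray  # years x regions
    tau_method: str


@dataclass
class TrendEstimates:
    """Five-year trends per region, percentage points."""

    regions: list
    theta_r: np.ndarray  # pp per 5 years
    se_r: np.ndarray
    theta_overall: float  # per year, fraction scale
    ci_low: np.ndarray = None
    ci_high: np.ndarray = None

    def __post_init__(self):
        if self.ci_low is None:
            self.ci_low = self.theta_r - 1.96 * self.se_r
            self.ci_high = self.theta_r + 1.96 * self.se_r

    def for_region(self, region: str) -> tuple[float, float]:
        i = self.regions.index(region)
        return float(self.theta_r[i]), float(self.se_r[i])


def _observations(sp: StandardizedPrevalences):
    ok = sp.estimable & np.isfinite(sp.se)
    rows = np.argwhere(ok)
    if len(rows) == 0:
        raise ValidationError("no usable cells (need p_hat and se)")
    y = sp.p_hat[ok]
    sig2 = sp.se[ok] ** 2
    regions = [sp.regions[i] for i in sorted(set(rows[:, 0]))]
    years = np.array(sorted({int(sp.years[j]) for j in set(rows[:, 1])}))
    rmap = {sp.regions[i]: k for k, i in enumerate(sorted(set(rows[:, 0])))}
    ymap = {int(t): k for k, t in enumerate(years)}
    r_codes = np.array([rmap[sp.regions[i]] for i, _ in rows])
    y_codes = np.array([ymap[int(sp.years[j])] for _, j in rows])
    t_vals = np.array([float(sp.years[j]) for _, j in rows])
    return y, sig2, regions, years, r_codes, y_codes, t_vals


def fit_trend_model(
    sp: StandardizedPrevalences,
    tau_method: str = "reml",
    extra_columns: np.ndarray | None = None,
):
    """Fit the on-top-trend meta-regression; returns a :class:`TrendFit`.

    ``extra_columns`` (internal) appends additional slope terms, used by
    the acceleration analysis; when present the function also returns
    the extra coefficients with their covariance block.
    """
    y, sig2, regions, years, r_codes, y_codes, t_vals = _observations(sp)
    nR, nT = len(regions), len(years)
    if nR < 2 or nT < 2:
        raise ValidationError("need >= 2 regions and >= 2 years")
    Xy = _deviation_columns(y_codes, nT)
    Xr = np.zeros((len(y), nR))
    Xr[np.arange(len(y)), r_codes] = 1.0
    Xs = _deviation_columns(r_codes, nR) * t_vals[:, None]
    blocks = [Xy, Xr, Xs]
    if extra_columns is not None:
        blocks.append(np.atleast_2d(extra_columns.T).T)
    X = np.column_stack(blocks)
    beta, cov, tau2 = _fit_gls(y, X, sig2, tau_method)

    iY = slice(0, nT - 1)
    iR = slice(nT - 1, nT - 1 + nR)
    iS = slice(nT - 1 + nR, nT - 1 + nR + nR - 1)
    Ly = _expand_transform(nT)
    Ls = _expand_transform(nR)
    alpha = Ly @ beta[iY]
    theta_tilde = Ls @ beta[iS]
    cov_alpha = Ly @ cov[iY, iY] @ Ly.T
    cov_theta = Ls @ cov[iS, iS] @ Ls.T
    cov_at = Ly @ cov[iY, iS] @ Ls.T
    fit = TrendFit(
        regions=regions,
        years=years.astype(float),
        alpha_t=alpha,
        beta_r=beta[iR].copy(),
        theta_tilde=theta_tilde,
        tau=float(np.sqrt(tau2)),
        cov_alpha=cov_alpha,
        cov_theta=cov_theta,
        cov_alpha_theta=cov_at,
        tau_method=tau_method,
    )
    assert abs(alpha.sum()) < 1e-8 and abs(theta_tilde.sum()) < 1e-8
    if extra_columns is None:
        return fit
    iE = slice(nT - 1 + nR + nR - 1, X.shape[1])
    extra = {
        "coef": beta[iE].copy(),
        "cov": cov[iE, iE].copy(),
        "cov_with_theta": (cov[iS, iE].T @ Ls.T),
        "cov_with_alpha": (cov[iY, iE].T @ Ly.T),
    }
    return fit, extra


def overall_linear_trend(
    alpha_t: np.ndarray, years: np.ndarray, cov_alpha: np.ndarray | None = None
):
    """OLS slope of the common year effects on the year index.

    Because the alpha_t sum to zero, the slope has the closed form
    ``sum_t t * alpha_t / sum_t (t - tbar)^2``; its variance is the
    quadratic form of the same weights in Cov(alpha).
    Returns ``(theta, var_theta, c)`` with ``c`` the weight vector.
    """
    years = np.asarray(years, dtype=float)
    if len(years) < 2:
        raise ValidationError("overall trend needs >= 2 years")
    denom = float(((years - years.mean()) ** 2).sum())
    c = years / denom
    theta = float(c @ alpha_t)
    var = float(c @ cov_alpha @ c) if cov_alpha is not None else np.nan
    return theta, var, c


def five_year_trends(fit: TrendFit) -> TrendEstimates:
    """Five-year trends theta_r = 5 (theta_tilde_r + theta), percentage points.

    Var(theta_r) combines the slope variance, the overall-trend
    variance and their covariance through the joint covariance of
    (alpha_t, theta_tilde_r).
    """
    theta, var_theta, c = overall_linear_trend(fit.alpha_t, fit.years, fit.cov_alpha)
    cov_theta_overall = c @ fit.cov_alpha_theta  # Cov(theta_hat, theta_tilde_r)
    est = 5.0 * (fit.theta_tilde + theta) * 100.0
    var = 25.0 * (np.diag(fit.cov_theta) + var_theta + 2.0 * cov_theta_overall)
    neg = var < 0
    if neg.any():
        logger.warning("negative trend variance floored at 0 (%d regions)", neg.sum())
        var = np.where(neg, 0.0, var)
    se = 5.0 * np.sqrt(var / 25.0) * 100.0
    return TrendEstimates(
        regions=list(fit.regions),
        theta_r=est,
        se_r=se,
        theta_overall=theta,
    )


@dataclass
class AccelerationEstimates:
    """Early/late on-top trends of the intervention region (pp per 5 years)."""

    theta_early: float
    se_early: float
    theta_late: float
    se_late: float
    delta: float
    se_delta: float
    ci_delta: tuple
    p_value: float
    knot: float


def acceleration_fit(
    sp: StandardizedPrevalences,
    intervention: str,
    tau_method: str = "reml",
) -> AccelerationEstimates:
    """Mid-period linear-spline analysis of the intervention's on-top trend.

    The intervention region's linear on-top term is replaced by a
    two-piece linear spline with the knot exactly at the middle of the
    observation period: slope theta_E before, theta_L after; the change
    delta = theta_L - theta_E is reported with a Wald interval and
    p-value.  All results in percentage points per five years.
    """
    y, sig2, regions, years, r_codes, y_codes, t_vals = _observations(sp)
    if intervention not in regions:
        raise ValidationError(f"no fitted cells for intervention region {intervention!r}")
    knot = (float(years.min()) + float(years.max())) / 2.0
    is_kt = np.array([regions[c] == intervention for c in r_codes])
    kt_years = np.unique(t_vals[is_kt])
    if (kt_years <= knot).sum() < 2 or (kt_years > knot).sum() < 2:
        raise ValidationError("need >= 2 intervention years in each half-period")
    hinge = np.where(is_kt, np.maximum(t_vals - knot, 0.0), 0.0)
    fit, extra = fit_trend_model(sp, tau_method=tau_method, extra_columns=hinge[:, None])
    i_kt = fit.regions.index(intervention)
    theta_e = float(fit.theta_tilde[i_kt])
    var_e = float(fit.cov_theta[i_kt, i_kt])
    delta = float(extra["coef"][0])
    var_d = float(extra["cov"][0, 0])
    cov_ed = float(extra["cov_with_theta"][0, i_kt])
    theta_l = theta_e + delta
    var_l = var_e + var_d + 2.0 * cov_ed
    s = 500.0  # fraction/year -> pp per 5 years
    se_d = np.sqrt(max(var_d, 0.0))
    zstat = delta / se_d if se_d > 0 else np.inf * np.sign(delta)
    return AccelerationEstimates(
        theta_early=s * theta_e,
        se_early=s * np.sqrt(max(var_e, 0.0)),
        theta_late=s * theta_l,
        se_late=s * np.sqrt(max(var_l, 0.0)),
        delta=s * delta,
        se_delta=s * se_d,
        ci_delta=(s * (delta - 1.96 * se_d), s * (delta + 1.96 * se_d)),
        p_value=float(2.0 * stats.norm.sf(abs(zstat))),
        knot=knot,
    )
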