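"""Random-effects pooling of control-region trends and key figures.

The estimated five-year trends of the control regions are pooled with
the DerSimonian-Laird random-effects model

    theta_hat_r = gamma_r + eps_r,
    gamma_r ~ N(mu_C, sigma_C^2),  eps_r ~ N(0, sigma_hat_r^2),

yielding the mean trend mu_C of the controls and the between-region
standard deviation sigma_C of the true trends.  Three key figures
compare the intervention region with the controls:

    Delta_C  = theta_KT - mu_C        (Wald CI, independence assumed)
    z        = Delta_C / sigma_C      (Fieller CI, independence assumed)
    Delta_BW = theta_KT - theta_BW    (Wald CI)

The z-score expresses how exceptional the intervention trend is
relative to the natural inter-region variation of trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class PooledTrends:
    """DerSimonian-Laird pooling result (percentage points)."""

    mu_C: float
    se_mu: float
    sigma_C: float
    var_sigma: float
    Q: float
    tau2: float
    var_tau2: float
    n: int


@dataclass
class DifferenceEstimate:
    """A difference of two trends with Wald interval and p-value."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ZEstimate:
    """The trend z-score with a Fieller confidence set."""

    z: float
    ci_low: float | None
    ci_high: float | None
    degenerate: bool


def _dl_var_tau2(w: np.ndarray, tau2: float) -> float:
    """Large-sample variance of the DL tau^2 estimator.

    Based on the variance of Cochran's Q under the random-effects model
    (a quadratic form in the trend estimates under normality, evaluated
    at the estimates):

        Var(Q) = 2(k-1) + 4 tau^2 (S1 - S2/S1)
                 + 2 tau^4 (S2 - 2 S3/S1 + S2^2/S1^2)

    with S_m = sum_r w_r^m, and Var(tau2_hat) = Var(Q)/(S1 - S2/S1)^2.
    """
    k = len(w)
    s1 = float(w.sum())
    s2 = float((w**2).sum())
    s3 = float((w**3).sum())
    denom = s1 - s2 / s1
    var_q = (
        2.0 * (k - 1)
        + 4.0 * tau2 * denom
        + 2.0 * tau2**2 * (s2 - 2.0 * s3 / s1 + (s2 / s1) ** 2)
    )
    return var_q / denom**2


def pool_control_trends(
    theta: np.ndarray, se: np.ndarray, tau2_floor: float = 1e-8
) -> PooledTrends:
    """DerSimonian-Laird random-effects pooling of control-region trends.

    Fixed weights ``w_r = 1/se_r^2`` give Cochran's
    ``Q = sum w_r (theta_r - theta_bar_w)^2``; the moment estimator is
    ``tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1))``; the pooled mean
    uses the random-effects weights ``1/(se_r^2 + tau^2)``.
    ``sigma_C = sqrt(tau^2)`` with its sampling variance from the
    delta method, ``Var(sigma_C) ~= Var(tau^2)/(4 tau^2)`` (tau^2
    floored at a small positive value).
    """
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    if len(theta) < 2:
        raise ValidationError("pooling needs >= 2 control regions")
    if not (np.isfinite(theta).all() and np.isfinite(se).all() and (se > 0).all()):
        raise ValidationError("trends and standard errors must be finite, se > 0")
    k = len(theta)
    w = 1.0 / se**2
    mean_w = float((w * theta).sum() / w.sum())
    Q = float((w * (theta - mean_w) ** 2).sum())
    s1, s2 = float(w.sum()), float((w**2).sum())
    denom = s1 - s2 / s1
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    mu = float((w_star * theta).sum() / w_star.sum())
    se_mu = float(1.0 / np.sqrt(w_star.sum()))
    var_tau2 = _dl_var_tau2(w, tau2)
    var_sigma = var_tau2 / (4.0 * max(tau2, tau2_floor))
    return PooledTrends(
        mu_C=mu,
        se_mu=se_mu,
        sigma_C=float(np.sqrt(tau2)),
        var_sigma=float(var_sigma),
        Q=Q,
        tau2=float(tau2),
        var_tau2=float(var_tau2),
        n=k,
    )


def delta_difference(
    theta_a: float, se_a: float, theta_b: float, se_b: float
) -> DifferenceEstimate:
    """Wald difference a - b assuming independence of the two estimates."""
    est = theta_a - theta_b
    se = float(np.sqrt(se_a**2 + se_b**2))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    else:
        p = 1.0 if est == 0 else 0.0
    return DifferenceEstimate(
        estimate=float(est),
        se=se,
        ci_low=float(est - Z95 * se),
        ci_high=float(est + Z95 * se),
        p_value=p,
    )


def z_with_fieller(
    delta: DifferenceEstimate, pooled: PooledTrends, crit: float = Z95
) -> ZEstimate:
    """z = Delta_C / sigma_C with a Fieller confidence set.

    The Fieller set is {rho : (Delta - rho sigma)^2 <=
    crit^2 (Var(Delta) + rho^2 Var(sigma))}, assuming independence of
    the numerator and denominator estimates.  When the quadratic's
    leading coefficient sigma^2 - crit^2 Var(sigma) is non-positive,
    the set is unbounded or a complement of an interval and the result
    is flagged degenerate (no finite bounds reported).
    """
    s = pooled.sigma_C
    if s <= 0:
        raise ValidationError("sigma_C = 0: z-score undefined")
    d, var_d = delta.estimate, delta.se**2
    var_s = max(pooled.var_sigma, 0.0)
    z = d / s
    a = s**2 - crit**2 * var_s
    b = -2.0 * d * s
    c = d**2 - crit**2 * var_d
    if a <= 0:
        return ZEstimate(z=float(z), ci_low=None, ci_high=None, degenerate=True)
    disc = b**2 - 4.0 * a * c
    if disc < 0:
        # empty solution set: cannot happen when z itself solves the
        # inequality, but guard against numerical noise
        return ZEstimate(z=float(z), ci_low=None, ci_high=None, degenerate=True)
    r = np.sqrt(disc)
    lo = (-b - r) / (2.0 * a)
    hi = (-b + r) / (2.0 * a)
    return ZEstimate(z=float(z), ci_low=float(lo), ci_high=float(hi), degenerate=False)


@dataclass
class KeyFigures:
    """The per-indicator key figures (undirected, percentage points)."""

    delta_C: DifferenceEstimate
    z: ZEstimate | None  # None when sigma_C = 0
    delta_BW: DifferenceEstimate
    pooled: PooledTrends

    def to_dict(self) -> dict:
        return {
            "delta_C": vars(self.delta_C),
            "z": vars(self.z) if self.z is not None else None,
            "delta_BW": vars(self.delta_BW),
            "mu_C": self.pooled.mu_C,
            "se_mu_C": self.pooled.se_mu,
            "sigma_C": self.pooled.sigma_C,
        }


def key_figures(
    theta_kt: float,
    se_kt: float,
    theta_bw: float,
    se_bw: float,
    control_theta: np.ndarray,
    control_se: np.ndarray,
) -> KeyFigures:
    """Pool the controls and compute Delta_C, z (Fieller) and Delta_BW."""
    pooled = pool_control_trends(control_theta, control_se)
    d_c = delta_difference(theta_kt, se_kt, pooled.mu_C, pooled.se_mu)
    d_bw = delta_difference(theta_kt, se_kt, theta_bw, se_bw)
    z = z_with_fieller(d_c, pooled) if pooled.sigma_C > 0 else None
    return KeyFigures(delta_C=d_c, z=z, delta_BW=d_bw, pooled=pooled)
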