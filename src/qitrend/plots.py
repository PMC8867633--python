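"""The four standard visualizations of the analysis chain.

* prevalence line plot per region (roles distinguished by color, no
  confidence bands to keep the plot readable),
* forest plot of the five-year trends with 95% intervals,
* key-figure plot: one vertical line per region trend with the fitted
  N(mu_C, sigma_C) density of the control trends superposed,
* evidence plot: the observed summary statistic, the 13 region-swap
  values, and the approximating normal density.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .errors import ValidationError
from .evidence import EvidenceSummary
from .panel import RegionRegistry
from .pooling import PooledTrends
from .standardization import StandardizedPrevalences
from .trends import TrendEstimates

ROLE_COLORS = {"intervention": "tab:red", "control": "0.6", "reference": "tab:blue"}


def _role(region: str, registry: RegionRegistry) -> str:
    if region == registry.intervention:
        return "intervention"
    if region == registry.reference:
        return "reference"
    return "control"


def plot_prevalences(sp: StandardizedPrevalences, registry: RegionRegistry, ax=None):
    """Line plot of standardized prevalences, one line per region."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    seen = set()
    for i, region in enumerate(sp.regions):
        role = _role(region, registry)
        label = role if role not in seen else None
        seen.add(role)
        lw = 2.0 if role != "control" else 1.0
        ax.plot(sp.years, sp.p_hat[i], color=ROLE_COLORS[role], lw=lw, label=label)
    ax.set_xlabel("year index")
    ax.set_ylabel("standardized prevalence")
    ax.legend(frameon=False)
    return ax


def plot_forest(te: TrendEstimates, registry: RegionRegistry, ax=None):
    """Forest plot of the five-year trends with 95% confidence intervals."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(te.regions) + 1.5))
    ypos = np.arange(len(te.regions))[::-1]
    for y, region, est, lo, hi in zip(ypos, te.regions, te.theta_r, te.ci_low, te.ci_high):
        color = ROLE_COLORS[_role(region, registry)]
        ax.plot([lo, hi], [y, y], color=color, lw=1.5)
        ax.plot([est], [y], "o", color=color)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(te.regions)
    ax.set_xlabel("five-year trend (percentage points)")
    return ax


def plot_key_figures(
    te: TrendEstimates, pooled: PooledTrends, registry: RegionRegistry, ax=None
):
    """Vertical line per region trend plus the N(mu_C, sigma_C) density."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for region, est in zip(te.regions, te.theta_r):
        ax.axvline(est, color=ROLE_COLORS[_role(region, registry)], lw=1.2)
    if pooled.sigma_C > 0:
        lo = min(te.theta_r.min(), pooled.mu_C - 4 * pooled.sigma_C)
        hi = max(te.theta_r.max(), pooled.mu_C + 4 * pooled.sigma_C)
        x = np.linspace(lo, hi, 400)
        ax.plot(x, stats.norm.pdf(x, pooled.mu_C, pooled.sigma_C), color="k", lw=1.0)
    ax.set_xlabel("five-year trend (percentage points)")
    ax.set_ylabel("density of control-region trends")
    return ax


def plot_evidence(summary: EvidenceSummary, ax=None):
    """Observed S, the scenario values, and the approximating normal curve."""
    if summary.scenario_values.size == 0:
        raise ValidationError("evidence summary has no scenario values")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for v in summary.scenario_values:
        ax.axvline(v, color="0.6", lw=1.0)
    ax.axvline(summary.observed, color="tab:red", lw=2.0, label="intervention region")
    if summary.normal_sd > 0:
        lo = min(summary.scenario_values.min(), summary.observed)
        hi = max(summary.scenario_values.max(), summary.observed)
        span = max(hi - lo, 4 * summary.normal_sd)
        x = np.linspace(lo - 0.2 * span, hi + 0.2 * span, 400)
        ax.plot(
            x,
            stats.norm.pdf(x, summary.normal_mean, summary.normal_sd),
            color="k",
            lw=1.0,
        )
    ax.set_xlabel(summary.statistic_kind)
    ax.legend(frameon=False)
    return ax
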