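"""Per-indicator orchestration of the five analysis steps.

For one indicator the pipeline runs, in order:

  (i)   standardized annual region-specific prevalences,
  (ii)  five-year time trends per region,
  (iii) random-effects pooling of the control-region trends,
  (iv)  key figures (Delta_C with Wald CI, z with Fieller CI,
        Delta_BW), and
  (v)   verbal classification against the relevance limit.

Each step writes its artifact when an output directory is given.  The
whole chain is deterministic given the configuration (including the
Monte-Carlo seed of the standard-error step).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import grading, panel as panel_mod, pooling, standardization, trends
from .errors import ValidationError
from .evidence import IndicatorTrends
from .panel import AnalysisPanel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable settings of the per-indicator analysis.

    The grading constants default to the published rule (z cut-offs
    1.96 and 1, half-limit factor 0.5, 10% relevance share with a
    0.1 pp floor, sigma_C threshold 0.001); the sensitivity toggles
    reproduce the conceptual sensitivity analyses.
    """

    # standardization (None: size rules n1=min(n,10000), n2=min(n/2,20000))
    n1: int | None = None
    n2: int | None = None
    mc_seed: int = 0
    cluster_level: str = "subject"  # or "practice"
    reference: str = "bw_sample"  # or "intervention_region"
    max_iter: int = 200
    # trend model
    tau_method: str = "reml"
    # grading
    sigma_c_threshold: float = grading.SIGMA_C_THRESHOLD
    # sensitivity toggles
    first_five_years: bool = False
    network_controls: tuple = ()  # restrict controls to these codes if non-empty
    # evidence
    swap_mode: str = "exchange"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network_controls"] = list(self.network_controls)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class IndicatorResult:
    """Everything the pipeline derives for one indicator."""

    indicator: panel_mod.IndicatorDefinition
    pi_baseline: float  # percent, reference sample in the initial year
    l_rel: float | None
    prevalences: standardization.StandardizedPrevalences
    trend_estimates: trends.TrendEstimates
    key_figures: pooling.KeyFigures
    grade: grading.VerbalGrade | None
    config_hash: str = ""

    def to_indicator_trends(self) -> IndicatorTrends:
        return IndicatorTrends(
            indicator_id=self.indicator.id,
            direction=self.indicator.direction,
            regions=list(self.trend_estimates.regions),
            theta_r=self.trend_estimates.theta_r,
            se_r=self.trend_estimates.se_r,
            pi_baseline=self.pi_baseline,
        )

    def summary_dict(self) -> dict:
        kf = self.key_figures.to_dict()
        return {
            "indicator": self.indicator.id,
            "direction": self.indicator.direction,
            "pi_baseline_percent": self.pi_baseline,
            "l_rel": self.l_rel,
            **kf,
            "grade": self.grade.grade if self.grade else None,
            "conditions_log": self.grade.conditions_log if self.grade else None,
            "config_hash": self.config_hash,
        }


def baseline_prevalence(panel: AnalysisPanel, config: PipelineConfig) -> float:
    """Reference-sample prevalence (percent) in the indicator's first year."""
    ref = panel.records[panel.records["in_reference_sample"]]
    first = ref[ref["t"] == panel.indicator.t_min]
    if len(first) == 0:
        raise ValidationError("reference sample empty in the initial year")
    return float(first["outcome"].mean() * 100.0)


def run_indicator(
    panel: AnalysisPanel,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> IndicatorResult:
    """Run steps (i)-(v) for one indicator panel."""
    config = config or PipelineConfig()
    panel = panel.validate()
    panel = panel_mod.apply_exclusions(panel)
    if config.first_five_years:
        t0 = panel.indicator.t_min
        keep = panel.records["t"] <= t0 + 4
        ind = dataclasses.replace(panel.indicator, T=min(panel.indicator.T, t0 + 4))
        panel = AnalysisPanel(panel.records.loc[keep], ind, panel.registry, panel.meta)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # (i) standardized prevalences with MC standard errors
    design = standardization.build_design(panel)
    fit = standardization.fit_outcome_model(
        panel, design, cluster_level=config.cluster_level, max_iter=config.max_iter
    )
    sp = standardization.standardize(fit, panel, reference=config.reference)
    sp = standardization.mc_standard_errors(
        fit,
        panel,
        sp,
        n1=config.n1,
        n2=config.n2,
        seed=config.mc_seed,
        reference=config.reference,
    )
    if out is not None:
        sp.to_frame().to_csv(out / "standardized_prevalences.csv", index=False)

    # (ii) trends
    tfit = trends.fit_trend_model(sp, tau_method=config.tau_method)
    te = trends.five_year_trends(tfit)
    if out is not None:
        te_frame(te).to_csv(out / "trends.csv", index=False)
        with open(out / "trend_fit.json", "w") as fh:
            json.dump(
                {
                    "alpha_t": tfit.alpha_t.tolist(),
                    "theta_tilde": tfit.theta_tilde.tolist(),
                    "tau": tfit.tau,
                    "tau_method": tfit.tau_method,
                },
                fh,
                indent=1,
            )

    # (iii)-(iv) pooling and key figures
    registry = panel.registry
    controls = [
        c
        for c in registry.controls
        if (not config.network_controls or c in config.network_controls)
        and c in te.regions
    ]
    th_c = np.array([te.for_region(c)[0] for c in controls])
    se_c = np.array([te.for_region(c)[1] for c in controls])
    th_kt, se_kt = te.for_region(registry.intervention)
    th_bw, se_bw = te.for_region(registry.reference)
    kf = pooling.key_figures(th_kt, se_kt, th_bw, se_bw, th_c, se_c)

    # (v) relevance limit and verbal classification
    pi = baseline_prevalence(panel, config)
    direction = panel.indicator.direction
    if direction in ("increase", "decrease"):
        l_rel = grading.relevance_limit(pi, direction).l_rel
        dd, dz = grading.direct(kf.delta_C, kf.z, direction)
        g = grading.grade(
            dd, dz, l_rel, kf.pooled.sigma_C, sigma_threshold=config.sigma_c_threshold
        )
    else:
        l_rel, g = None, None

    result = IndicatorResult(
        indicator=panel.indicator,
        pi_baseline=pi,
        l_rel=l_rel,
        prevalences=sp,
        trend_estimates=te,
        key_figures=kf,
        grade=g,
        config_hash=config.config_hash(),
    )
    if out is not None:
        with open(out / "key_figures.json", "w") as fh:
            json.dump(result.summary_dict(), fh, indent=1, default=_json_default)
    return result


def te_frame(te: trends.TrendEstimates):
    import pandas as pd

    return pd.DataFrame(
        {
            "region": te.regions,
            "theta_r_pp": te.theta_r,
            "se": te.se_r,
            "ci_low": te.ci_low,
            "ci_high": te.ci_high,
        }
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
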