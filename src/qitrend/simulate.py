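"""Synthetic subject-year panels with known ground-truth trends.

The generator emulates the statistical structure the analysis pipeline
assumes: ~15 regions (one intervention, a set of controls, one
reference region built from a population sample), annual denominator
populations with entry/exit churn and movers, individual event
probabilities on the logit scale driven by confounders (age, gender,
comorbidity at entry, area-level deprivation), and region x year
intercepts composed of a common (possibly nonlinear) time profile,
region baselines, and region-specific linear "on-top" trends.

Ground truth is defined on the scale the pipeline estimates: the
region x year intercept is solved numerically so that the prevalence
standardized to the reference sample equals a target
``p*_rt = b_r + g_t + s_r (t - tbar)`` exactly, where ``g_t`` is the
common profile and ``s_r`` the per-year on-top slope of region ``r``.
The true five-year trend of region ``r`` is then
``100 * 5 * (s_r + slope_OLS(g))`` percentage points, free of any
first-order approximation, so recovery tests are limited only by
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .panel import AnalysisPanel, IndicatorDefinition, RegionRegistry

PRESETS = ("null", "linear_trend", "change_point", "structural_break", "intervention_effect")

#: deprivation-score range observed in the study population
GISD_RANGE = (4.76, 8.72)


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic scenario.

    Trend quantities (``sigma_C_true``, ``delta_intervention``) are in
    percentage points per five years, the unit in which the pipeline
    reports trends.  ``alpha_profile`` is the common time profile of
    the standardized prevalence on the fraction scale (one value per
    year; any shape).
    """

    n_controls: int = 13
    subjects_per_region: int = 2000
    reference_subjects: int = 4000
    T: int = 9
    t_min: int = 0
    base_prevalence: float = 0.30
    region_baseline_sd: float = 0.02
    region_baselines: np.ndarray | None = None
    alpha_profile: np.ndarray | None = None  # default: slight upward drift
    sigma_C_true: float = 1.0
    delta_intervention: float = 0.0
    covariate_effects: dict = field(
        default_factory=lambda: {
            "gender": 0.20,
            "gisd": 0.10,
            "age_per_year": 0.02,
            "comorb_per_unit": 0.15,
        }
    )
    age_mean: float = 55.0
    age_region_sd: float = 3.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (30.0, 92.0)
    comorbidity_mean: float = 1.2
    area_size: int = 500
    mover_rate: float = 0.01
    exit_rate: float = 0.05
    contract_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_region <= 0 or self.reference_subjects <= 0:
            raise ValidationError("subject counts must be positive")
        if self.sigma_C_true < 0:
            raise ValidationError("sigma_C_true must be non-negative")
        for name in ("mover_rate", "exit_rate", "contract_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.alpha_profile is None:
            # slight upward drift: +1.5 pp over the full period
            years = np.arange(self.t_min, self.T + 1)
            prof = 0.015 * (years - years.mean()) / max(len(years) - 1, 1)
            self.alpha_profile = prof
        self.alpha_profile = np.asarray(self.alpha_profile, dtype=float)
        if len(self.alpha_profile) != self.T - self.t_min + 1:
            raise ValidationError("alpha_profile must have one entry per year")

    @property
    def region_codes(self) -> list[str]:
        return ["KT"] + [f"C{i:02d}" for i in range(1, self.n_controls + 1)] + ["BW"]

    @property
    def registry(self) -> RegionRegistry:
        codes = self.region_codes
        return RegionRegistry(codes[0], tuple(codes[1:-1]), codes[-1])


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one generated panel.

    ``true_theta`` holds the true five-year trends per region
    (percentage points, canonical region order: intervention, controls,
    reference); ``true_mu_C``/``true_sigma_C`` are the mean and SD
    (ddof=1) of the control-region values; ``true_delta_C`` is the
    intervention excess.
    """

    true_theta: np.ndarray
    true_mu_C: float
    true_sigma_C: float
    true_delta_C: float
    target_prevalences: np.ndarray  # regions x years, fraction scale

    def to_dict(self) -> dict:
        return {
            "true_theta": self.true_theta.tolist(),
            "true_mu_C": self.true_mu_C,
            "true_sigma_C": self.true_sigma_C,
            "true_delta_C": self.true_delta_C,
        }


def _simulate_population(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    n0: int,
    regions: list[str],
    is_reference: bool,
    id_prefix: str,
) -> pd.DataFrame:
    """Simulate subject-years for one pool (analysis regions or reference).

    Subjects enter at t_min (or later, replacing exits), persist with
    annual exit probability, may move between analysis regions, and age
    by one year per year.  Covariates are drawn at entry; comorbidity is
    fixed at its entry value; the deprivation score is an area-level
    variable shared by blocks of subjects.
    """
    years = np.arange(cfg.t_min, cfg.T + 1)
    n_regions = len(regions)
    counter = 0

    def new_subjects(n: int, region_idx: np.ndarray, year: int) -> dict:
        nonlocal counter
        ids = np.array([f"{id_prefix}{counter + i:07d}" for i in range(n)])
        counter += n
        # region-specific age distributions induce the confounding the
        # standardization step must remove
        mean = cfg.age_mean + (
            0.0
            if is_reference
            else cfg.age_region_sd * np.cos(2 * np.pi * region_idx / max(n_regions, 1))
        )
        age = np.clip(rng.normal(mean, cfg.age_sd, n), *cfg.age_bounds)
        n_areas = max(n0 // cfg.area_size, 2)
        area = rng.integers(0, n_areas, n)
        gisd_levels = rng.uniform(*GISD_RANGE, n_areas)
        return {
            "subject_id": ids,
            "region_idx": region_idx.copy(),
            "age": age,
            "gender": rng.integers(0, 2, n),
            "comorbidity_entry": rng.poisson(cfg.comorbidity_mean, n),
            "gisd": gisd_levels[area],
            "family_contract": rng.random(n) < cfg.contract_rate,
        }

    if is_reference:
        region_idx0 = np.zeros(n0, dtype=int)
    else:
        region_idx0 = np.repeat(np.arange(n_regions), n0 // n_regions)
    state = new_subjects(len(region_idx0), region_idx0, years[0])
    rows = []
    for t in years:
        n = len(state["subject_id"])
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": state["subject_id"],
                    "t": t,
                    "region": np.asarray(regions)[state["region_idx"]],
                    "age": state["age"],
                    "gender": state["gender"],
                    "comorbidity_entry": state["comorbidity_entry"],
                    "gisd": state["gisd"],
                    "family_contract": state["family_contract"],
                }
            )
        )
        if t == years[-1]:
            break
        stay = rng.random(n) >= cfg.exit_rate
        for key in state:
            state[key] = state[key][stay]
        if not is_reference and cfg.mover_rate > 0:
            move = rng.random(len(state["subject_id"])) < cfg.mover_rate
            if move.any():
                shift = rng.integers(1, n_regions, move.sum())
                state["region_idx"][move] = (state["region_idx"][move] + shift) % n_regions
        n_exited = int(n - stay.sum())
        if n_exited:
            if is_reference:
                idx = np.zeros(n_exited, dtype=int)
            else:
                idx = rng.integers(0, n_regions, n_exited)
            fresh = new_subjects(n_exited, idx, t + 1)
            for key in state:
                state[key] = np.concatenate([state[key], fresh[key]])
        state["age"] = state["age"] + 1.0
    return pd.concat(rows, ignore_index=True)


def _covariate_logit(df: pd.DataFrame, eff: dict) -> np.ndarray:
    return (
        eff["gender"] * df["gender"].to_numpy()
        + eff["gisd"] * df["gisd"].to_numpy()
        + eff["age_per_year"] * df["age"].to_numpy()
        + eff["comorb_per_unit"] * df["comorbidity_entry"].to_numpy()
    )


def generate_panel(
    config: ScenarioConfig,
    indicator: IndicatorDefinition | None = None,
) -> tuple[AnalysisPanel, TruthRecord]:
    """Generate one synthetic panel plus its ground truth.

    Deterministic given ``config.seed``.  The region x year intercepts
    are calibrated so that the prevalence standardized to the reference
    sample matches the target trajectory exactly (see module docstring).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    regions = cfg.region_codes
    analysis_regions = regions[:-1]
    years = np.arange(cfg.t_min, cfg.T + 1)
    n_years = len(years)
    n_all = len(regions)

    # --- ground-truth trajectory on the fraction scale -----------------
    if cfg.region_baselines is not None:
        baselines = np.asarray(cfg.region_baselines, dtype=float)
        if len(baselines) != n_all:
            raise ValidationError("region_baselines must cover every region")
    else:
        baselines = rng.normal(cfg.base_prevalence, cfg.region_baseline_sd, n_all)
        baselines[-1] = cfg.base_prevalence  # reference region at the nominal level
    slopes = np.zeros(n_all)  # per-year on-top slopes, fraction scale
    slopes[:-1] = rng.normal(0.0, cfg.sigma_C_true / 100.0 / 5.0, n_all - 1)
    slopes[0] += cfg.delta_intervention / 100.0 / 5.0
    tc = years - years.mean()
    targets = baselines[:, None] + cfg.alpha_profile[None, :] + slopes[:, None] * tc[None, :]
    if (targets <= 0.005).any() or (targets >= 0.995).any():
        raise ValidationError(
            "target prevalences leave (0.005, 0.995); adjust baselines/profile"
        )
    g_slope = np.polyfit(years, cfg.alpha_profile, 1)[0] if n_years > 1 else 0.0
    true_theta = 100.0 * 5.0 * (slopes + g_slope)
    mu_c = float(true_theta[1:-1].mean())
    sigma_c = float(true_theta[1:-1].std(ddof=1)) if cfg.n_controls > 1 else 0.0
    truth = TruthRecord(
        true_theta=true_theta,
        true_mu_C=mu_c,
        true_sigma_C=sigma_c,
        true_delta_C=float(true_theta[0] - mu_c),
        target_prevalences=targets,
    )

    # --- subject-year tables -------------------------------------------
    pool = _simulate_population(
        cfg,
        rng,
        cfg.subjects_per_region * len(analysis_regions),
        analysis_regions,
        is_reference=False,
        id_prefix="S",
    )
    pool["in_reference_sample"] = False
    ref = _simulate_population(
        cfg, rng, cfg.reference_subjects, [regions[-1]], is_reference=True, id_prefix="B"
    )
    ref["in_reference_sample"] = True
    df = pd.concat([pool, ref], ignore_index=True)

    # --- calibrate region x year intercepts ----------------------------
    eff = cfg.covariate_effects
    cov_logit = _covariate_logit(df, eff)
    ref_mask = df["in_reference_sample"].to_numpy()
    alpha = np.zeros((n_all, n_years))
    for j, t in enumerate(years):
        ref_cov = cov_logit[ref_mask & (df["t"].to_numpy() == t)]
        for r in range(n_all):

            def gap(a: float, _c=ref_cov, _p=targets[r, j]) -> float:
                return float(expit(a + _c).mean() - _p)

            alpha[r, j] = brentq(gap, -30.0, 30.0, xtol=1e-12)

    # --- draw outcomes --------------------------------------------------
    region_pos = {code: i for i, code in enumerate(regions)}
    r_idx = df["region"].map(region_pos).to_numpy()
    t_idx = df["t"].to_numpy() - cfg.t_min
    prob = expit(alpha[r_idx, t_idx] + cov_logit)
    df["outcome"] = (rng.random(len(df)) < prob).astype(np.int64)
    df["practice_id"] = (
        df["region"] + "-P" + (pd.util.hash_pandas_object(df["subject_id"], index=False) % 20).astype(str)
    )

    if indicator is None:
        indicator = IndicatorDefinition(
            id="synthetic", label="synthetic indicator", t_min=cfg.t_min, T=cfg.T
        )
    from .panel import PANEL_COLUMNS, _coerce_records

    panel = AnalysisPanel(_coerce_records(df)[PANEL_COLUMNS], indicator, cfg.registry)
    return panel.validate(), truth


def simulate_trend_estimates(
    n_indicators: int = 6,
    n_controls: int = 13,
    mu_C: float = 1.0,
    sigma_C: float = 1.0,
    se: float = 0.3,
    pi_baseline: float = 95.0,
    delta_intervention: float = 0.0,
    direction: str = "increase",
    seed: int = 0,
):
    """Draw per-indicator five-year trend estimates at the trend stage.

    Emulates what the pipeline hands to the pooling/evidence steps:
    for each indicator, true region trends are exchangeable draws from
    N(mu_C, sigma_C^2) (percentage points per five years), the
    intervention region optionally shifted by ``delta_intervention``,
    and estimates add independent N(0, se^2) noise.  The reference
    region receives the mean trend.  Because all upstream pipeline
    stages treat regions symmetrically, exchangeability at this stage
    is exactly the null the region-swap inference assumes, at a tiny
    fraction of the cost of a full panel replicate.

    Returns a list of :class:`~qitrend.evidence.IndicatorTrends`.
    """
    from .evidence import IndicatorTrends

    rng = np.random.default_rng(seed)
    regions = ["KT"] + [f"C{i:02d}" for i in range(1, n_controls + 1)] + ["BW"]
    out = []
    for k in range(n_indicators):
        true = rng.normal(mu_C, sigma_C, n_controls + 1)
        true[0] += delta_intervention
        theta = np.concatenate([true, [mu_C]]) + rng.normal(0.0, se, n_controls + 2)
        out.append(
            IndicatorTrends(
                indicator_id=f"ind{k:02d}",
                direction=direction,
                regions=regions,
                theta_r=theta,
                se_r=np.full(n_controls + 2, se),
                pi_baseline=pi_baseline,
            )
        )
    return out


def scenario_presets(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named scenarios reproducing the qualitative patterns of interest.

    ``null``
        Common slight upward drift, heterogeneous control trends,
        no intervention effect.
    ``linear_trend``
        Pronounced common linear increase.
    ``change_point``
        High-baseline indicator whose common trend rises and then
        reverses mid-period.
    ``structural_break``
        A jump in the common profile between two consecutive years
        (e.g. a reimbursement-rule change).
    ``intervention_effect``
        As ``null`` plus an injected excess five-year trend in the
        intervention region.
    """
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose one of {PRESETS}")
    kw: dict = {"seed": seed}
    T = int(overrides.get("T", 9))
    t = np.arange(0, T + 1, dtype=float)
    if name == "null":
        pass
    elif name == "linear_trend":
        prof = 0.05 * (t - t.mean()) / max(T, 1)
        kw.update(alpha_profile=prof)
    elif name == "change_point":
        mid = T / 2.0
        prof = 0.04 * (mid - np.abs(t - mid)) / max(mid, 1.0)
        kw.update(alpha_profile=prof - prof.mean(), base_prevalence=0.85)
    elif name == "structural_break":
        jump_at = max(T - 2, 1)
        prof = np.where(t >= jump_at, 0.15, 0.0)
        kw.update(alpha_profile=prof - prof.mean(), base_prevalence=0.20)
    elif name == "intervention_effect":
        kw.update(delta_intervention=3.0)
    kw.update(overrides)
    return ScenarioConfig(**kw)
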