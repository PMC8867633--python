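import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline
from scipy.special import expit, logit

import qitrend as q
from qitrend.errors import ModelInfeasibleError, ValidationError
from qitrend.standardization import (
    ModelDesign,
    _reference_design,
    _reference_frame,
    comorbidity_code,
    natural_spline_basis,
)


def _flat_panel(**kw):
    defaults = dict(
        subjects_per_region=60, reference_subjects=100, n_controls=2, T=3, seed=9
    )
    defaults.update(kw)
    return q.generate_panel(q.ScenarioConfig(**defaults))[0]


class TestBuildDesign:
    def _panel_with(self, ages=None, comorb=None, gender=None, outcome=None, n=400):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "t": [0] * n,
                "region": ["KT"] * n,
                "outcome": outcome if outcome is not None else rng.integers(0, 2, n),
                "age": ages if ages is not None else rng.uniform(40, 80, n),
                "gender": gender if gender is not None else rng.integers(0, 2, n),
                "comorbidity_entry": comorb if comorb is not None else rng.poisson(1, n),
                "gisd": rng.uniform(5, 8, n),
                "in_reference_sample": [False] * n,
                "family_contract": [False] * n,
                "practice_id": [None] * n,
            }
        )
        ind = q.IndicatorDefinition(id="d", T=0)
        return q.AnalysisPanel(df, ind, q.RegionRegistry("KT", ("C1",), "BW"))

    def test_wide_age_spread_gives_four_knots_at_stated_percentiles(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(40, 80, 2000)
        panel = self._panel_with(ages=ages, n=2000)
        design = q.build_design(panel)
        # P99 - P1 ~ 39 -> k = 4
        for g in design.genders():
            sel = panel.records["gender"].to_numpy() == g if design.gender_specific else slice(None)
            expected = np.percentile(ages[sel], [5, 35, 65, 95])
            assert np.allclose(design.age_knots[g], expected)

    def test_narrow_age_spread_gives_linear_age(self):
        rng = np.random.default_rng(2)
        panel = self._panel_with(ages=rng.uniform(60, 75, 400))
        design = q.build_design(panel)
        for g in design.genders():
            assert len(design.age_knots[g]) == 2

    def test_two_comorbidity_values_force_linear(self):
        rng = np.random.default_rng(3)
        panel = self._panel_with(comorb=rng.integers(0, 2, 400))
        design = q.build_design(panel)
        for g in design.genders():
            assert design.L[g] == 0

    def test_constant_comorbidity_dropped(self):
        panel = self._panel_with(comorb=np.zeros(400, dtype=int))
        design = q.build_design(panel)
        assert design.comorb_dropped

    def test_L_capped_at_second_largest_value(self):
        # 90th percentile would be 9, but second largest observed is 3
        comorb = np.array([0] * 100 + [1] * 200 + [2] * 60 + [3] * 39 + [9])
        panel = self._panel_with(comorb=comorb, gender=np.zeros(400, dtype=int), n=400)
        design = q.build_design(panel)
        g = design.genders()[0]
        assert design.L[g] <= 3

    def test_rare_gender_events_pool_the_effects(self):
        outcome = np.zeros(400, dtype=int)
        gender = np.array([0] * 350 + [1] * 50)
        outcome[:200] = 1  # all events in gender 0; gender 1 has <100 events
        panel = self._panel_with(outcome=outcome, gender=gender)
        design = q.build_design(panel)
        assert not design.gender_specific

    def test_all_outcomes_identical_is_infeasible(self):
        panel = self._panel_with(outcome=np.ones(400, dtype=int))
        with pytest.raises(ModelInfeasibleError):
            q.build_design(panel)


class TestSplineBasis:
    def test_two_knots_reduce_to_identity(self):
        x = np.linspace(-3, 7, 30)
        basis = natural_spline_basis(x, np.array([0.0, 5.0]))
        assert basis.shape == (30, 1)
        assert np.array_equal(basis[:, 0], x)

    def test_nonlinear_columns_vanish_at_and_below_first_knot(self):
        knots = np.array([-1.0, 0.5, 2.0, 4.0])
        x = np.array([-5.0, -1.0])
        basis = natural_spline_basis(x, knots)
        assert np.allclose(basis[:, 1:], 0.0)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValidationError):
            natural_spline_basis(np.array([0.0]), np.array([1.0, 1.0, 2.0]))

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 1.0, 3.0, 6.0])
        for lo, hi in [(-10, -0.01), (6.01, 20)]:
            x = np.linspace(lo, hi, 50)
            basis = natural_spline_basis(x, knots)
            for col in basis.T:
                second_diff = np.diff(col, 2)
                assert np.abs(second_diff).max() < 1e-9

    def test_spans_natural_cubic_splines(self):
        """Any natural cubic spline on the knots lies in span{1, basis}."""
        rng = np.random.default_rng(8)
        knots = np.array([-2.0, 0.0, 1.5, 4.0])
        # compare inside the boundary knots: scipy extrapolates its end
        # pieces cubically, a natural regression basis extrapolates linearly
        x = np.linspace(-2.0, 4.0, 200)
        basis = np.column_stack([np.ones_like(x), natural_spline_basis(x, knots)])
        for _ in range(5):
            vals = rng.normal(size=len(knots))
            oracle = CubicSpline(knots, vals, bc_type="natural")(x)
            coef, *_ = np.linalg.lstsq(basis, oracle, rcond=None)
            assert np.abs(basis @ coef - oracle).max() < 1e-8


class TestComorbidityCode:
    @pytest.mark.parametrize(
        "x, L, expected",
        [
            (3, 5, [0, 0, 0, 1, 0, 0.0]),  # dummy for value 3 set, tail 0
            (7, 5, [0, 0, 0, 0, 0, 2.0]),  # all dummies 0, tail x - L = 2
        ],
    )
    def test_dummy_plus_tail(self, x, L, expected):
        coded = comorbidity_code(np.array([x]), L)
        assert coded.shape == (1, L + 1)
        assert np.allclose(coded[0], expected)

    def test_L_zero_is_linear(self):
        coded = comorbidity_code(np.array([0, 4]), 0)
        assert coded.shape == (2, 1) and coded[0, 0] == 0.0 and coded[1, 0] == 4.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            comorbidity_code(np.array([-1]), 2)


class TestOutcomeFit:
    def test_saturated_intercept_equals_crude_logit(self, small_panel):
        panel, _ = small_panel
        fit = q.fit_outcome_model(panel, ModelDesign.saturated())
        cp = q.crude_prevalences(panel)
        row = cp[(cp.denominator > 0) & (cp.events > 0) & (cp.events < cp.denominator)].iloc[0]
        alpha = fit.cell_alpha(row.region, row.t)
        assert alpha == pytest.approx(logit(row.prevalence), abs=1e-6)

    def test_singleton_clusters_match_hand_rolled_hc0(self):
        """With one record per subject the cluster sandwich is plain HC0."""
        panel = _flat_panel(T=0, seed=21)
        design = q.build_design(panel)
        fit = q.fit_outcome_model(panel, design)
        # independent HC0 computation from the fitted coefficients
        from qitrend.standardization import covariate_matrix

        df = panel.records
        cells = fit.fitted_cells
        pos = {c: i for i, c in enumerate(cells)}
        keep = [
            (r, int(t)) in pos for r, t in zip(df["region"], df["t"])
        ]
        df = df.loc[keep]
        Xc, _ = covariate_matrix(df, design)
        Xc = Xc[:, fit.kept_cov]
        n = len(df)
        X = np.zeros((n, len(cells) + Xc.shape[1]))
        for i, (r, t) in enumerate(zip(df["region"], df["t"])):
            X[i, pos[(r, int(t))]] = 1.0
        X[:, len(cells):] = Xc
        mu = expit(X @ fit.params)
        y = df["outcome"].to_numpy()
        bread = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
        score = X * (y - mu)[:, None]
        meat = score.T @ score
        hc0 = bread @ meat @ bread
        assert np.allclose(fit.cov, hc0, atol=1e-8)

    def test_standardization_removes_age_confounding(self):
        """Regions with equal intercept structure but different age mixes:
        crude prevalences differ, standardized ones agree."""
        cfg = q.ScenarioConfig(
            subjects_per_region=3000,
            reference_subjects=2000,
            n_controls=2,
            T=1,
            sigma_C_true=0.0,
            region_baseline_sd=0.0,
            alpha_profile=np.zeros(2),
            covariate_effects={"gender": 0.2, "gisd": 0.0, "age_per_year": 0.05, "comorb_per_unit": 0.1},
            age_region_sd=6.0,
            seed=17,
        )
        ind = q.IndicatorDefinition(id="conf", T=1)
        panel, _ = q.generate_panel(cfg, indicator=ind)
        cp = q.crude_prevalences(panel)
        crude = cp[cp.t == 0].set_index("region").prevalence
        crude_spread = crude.loc[["KT", "C01"]].max() - crude.loc[["KT", "C01"]].min()
        design = q.build_design(panel)
        fit = q.fit_outcome_model(panel, design)
        sp = q.mc_standard_errors(fit, panel, seed=0)
        i_kt, i_c1 = sp.regions.index("KT"), sp.regions.index("C01")
        std_diff = abs(sp.p_hat[i_kt, 0] - sp.p_hat[i_c1, 0])
        comb_se = np.hypot(sp.se[i_kt, 0], sp.se[i_c1, 0])
        assert crude_spread > 0.03  # the confounding is material
        assert std_diff < max(4 * comb_se, 0.02)
        assert std_diff < crude_spread / 2


class TestStandardize:
    def test_hand_enumeration_on_small_reference(self, small_fit):
        panel, fit = small_fit
        sp = q.standardize(fit, panel)
        ref = panel.records[panel.records["in_reference_sample"]]
        t0 = int(sp.years[0])
        ref0 = ref[ref["t"] == t0]
        Xr = _reference_design(fit, ref0)
        r = sp.regions[1]
        alpha = fit.cell_alpha(r, t0)
        manual = np.mean(
            [expit(alpha + float(x @ fit.params[fit.n_cells :])) for x in Xr]
        )
        assert sp.p_hat[sp.regions.index(r), 0] == pytest.approx(manual, abs=1e-12)

    def test_empty_reference_year_is_an_error(self, small_fit):
        panel, fit = small_fit
        records = panel.records[
            ~(panel.records["in_reference_sample"] & (panel.records["t"] == 0))
        ]
        broken = q.AnalysisPanel(records, panel.indicator, panel.registry)
        with pytest.raises(ValidationError, match="year 0"):
            q.standardize(fit, broken)


class TestMonteCarloSE:
    def test_zero_coefficient_covariance_gives_zero_se(self, small_fit):
        panel, fit = small_fit
        import dataclasses

        fit0 = dataclasses.replace(fit, cov=np.zeros_like(fit.cov))
        sp = q.mc_standard_errors(fit0, panel, seed=3)
        assert np.nanmax(sp.se) == 0.0

    def test_seed_determinism(self, small_fit):
        panel, fit = small_fit
        a = q.mc_standard_errors(fit, panel, n1=50, n2=100, seed=5)
        b = q.mc_standard_errors(fit, panel, n1=50, n2=100, seed=5)
        assert np.array_equal(a.se, b.se, equal_nan=True)

    def test_relabeling_invariance_in_exact_mode(self, small_fit):
        panel, fit = small_fit
        sp1 = q.mc_standard_errors(fit, panel, n1=10**9, n2=10**9, seed=0)
        rng = np.random.default_rng(0)
        perm = panel.records.sample(frac=1.0, random_state=1)
        shuffled = q.AnalysisPanel(perm, panel.indicator, panel.registry)
        sp2 = q.mc_standard_errors(fit, shuffled, n1=10**9, n2=10**9, seed=99)
        assert np.allclose(sp1.se, sp2.se, atol=1e-12, equal_nan=True)

    def test_two_seeds_agree_on_large_reference(self):
        cfg = q.ScenarioConfig(
            subjects_per_region=100, reference_subjects=2000, n_controls=2, T=1, seed=23
        )
        ind = q.IndicatorDefinition(id="mc", T=1)
        panel, _ = q.generate_panel(cfg, indicator=ind)
        design = q.build_design(panel)
        fit = q.fit_outcome_model(panel, design)
        sp = q.standardize(fit, panel)
        a = q.mc_standard_errors(fit, panel, sp, n1=2000, n2=20000, seed=1)
        b = q.mc_standard_errors(fit, panel, sp, n1=2000, n2=20000, seed=2)
        rel = np.abs(a.se - b.se) / np.where(a.se > 0, a.se, 1)
        assert np.nanmax(rel) < 0.05
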