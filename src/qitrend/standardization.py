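"""Confounder-adjusted outcome model and direct standardization.

One logistic regression is fitted to the whole analysis population
(all regions, all years) with a free intercept for every region x year
cell and common covariate effects:

    logit P(Y_it = 1) = alpha_{r t}
                        + beta_gender 1{gender_i = 1}
                        + beta_gisd^g * gisd_it
                        + f_age^g(age_it) + f_comorb^g(comorb_i)

The age effect is a restricted cubic (natural) spline of the
mean-centered age with 2-4 knots chosen from the spread of the age
distribution; the comorbidity effect combines dummies for the low
values with a linear tail (no own intercept, for identifiability).
Covariate effects are gender-specific unless one gender has fewer than
100 events or non-events.

Standardized prevalences are obtained by applying each cell's
prediction rule to every member of the reference sample in that year
and averaging the predicted probabilities.  Standard errors come from
the delta method with the cluster-robust (by subject) coefficient
covariance; because the double sum over reference-subject pairs is
expensive, both averages are Monte-Carlo approximated on subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ConvergenceError, ModelInfeasibleError, ValidationError
from .panel import AnalysisPanel

logger = logging.getLogger(__name__)

#: knot percentiles by number of knots
KNOT_PERCENTILES = {2: (10, 90), 3: (10, 50, 90), 4: (5, 35, 65, 95)}


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic (natural) spline basis, linear beyond the boundary knots.

    With ``k`` knots ``t_1 < ... < t_k`` the basis has ``k - 1``
    columns: the identity plus, for j = 1..k-2,

        [(x-t_j)^3_+ - (x-t_{k-1})^3_+ (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)^3_+ (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    (Harrell's normalization).  ``k = 2`` returns the single linear
    column ``x`` itself.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 2 or (np.diff(knots) <= 0).any():
        raise ValidationError("knots must be strictly increasing (>= 2 of them)")
    k = len(knots)
    cols = [x]
    if k > 2:
        tk, tk1 = knots[-1], knots[-2]
        norm = (knots[-1] - knots[0]) ** 2
        for j in range(k - 2):
            tj = knots[j]
            term = (
                np.maximum(x - tj, 0.0) ** 3
                - np.maximum(x - tk1, 0.0) ** 3 * (tk - tj) / (tk - tk1)
                + np.maximum(x - tk, 0.0) ** 3 * (tk1 - tj) / (tk - tk1)
            )
            cols.append(term / norm)
    return np.column_stack(cols)


def comorbidity_code(x: np.ndarray, L: int) -> np.ndarray:
    """Dummy-plus-linear-tail coding of an integer comorbidity score.

    ``L`` dummy columns for the values 0..L-1 plus one linear column
    ``max(x - L, 0)``; with ``L = 0`` a single linear column ``x``.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValidationError("comorbidity values must be non-negative")
    if L < 0:
        raise ValidationError("L must be >= 0")
    if L == 0:
        return x[:, None]
    cols = [(x == l).astype(float) for l in range(L)]
    cols.append(np.maximum(x - L, 0.0))
    return np.column_stack(cols)


@dataclass
class ModelDesign:
    """Resolved design rules of the outcome model for one panel.

    All percentile computations use linear-interpolation sample
    quantiles and pool over regions and years.
    """

    gender_specific: bool
    age_knots: dict  # gender -> knot vector (original age scale)
    age_center: dict  # gender -> mean age used for centering
    L: dict  # gender -> comorbidity threshold
    comorb_dropped: bool = False
    dropped_terms: list = field(default_factory=list)
    quantile_method: str = "linear"
    intercept_only: bool = False  # saturated cell model without covariates

    def genders(self) -> list[int]:
        return [0, 1] if self.gender_specific else [-1]  # -1 = pooled

    @classmethod
    def saturated(cls) -> "ModelDesign":
        """Pure cell-intercept design without covariate adjustment."""
        return cls(
            gender_specific=False,
            age_knots={},
            age_center={},
            L={},
            comorb_dropped=True,
            dropped_terms=["all covariates"],
            intercept_only=True,
        )


def _age_rules(age: np.ndarray, method: str) -> tuple[np.ndarray, float]:
    p1, p99 = np.percentile(age, [1, 99], method=method)
    k = int(np.clip(np.ceil((p99 - p1) / 10.0), 2, 4))
    knots = np.percentile(age, KNOT_PERCENTILES[k], method=method)
    # degenerate age spread: fall back to a linear effect
    if (np.diff(knots) <= 0).any():
        k = 2
        knots = np.array([np.min(age), np.max(age)], dtype=float)
        if knots[0] == knots[1]:
            knots = knots + [0.0, 1.0]
    return np.asarray(knots, dtype=float), float(age.mean())


def _comorb_L(x: np.ndarray, method: str) -> int:
    values = np.unique(x)
    if len(values) <= 2:
        return 0
    p90 = np.floor(np.percentile(x, 90, method=method))
    return int(min(p90, values[-2]))


def build_design(panel: AnalysisPanel, quantile_method: str = "linear") -> ModelDesign:
    """Derive knot positions, comorbidity thresholds and gender pooling.

    The number of age knots is ``ceil((P99 - P1)/10)`` clamped to
    [2, 4]; the comorbidity threshold is the (floored) 90th percentile
    capped at the second-largest observed value, 0 if only two distinct
    values occur; covariate effects are pooled across genders when one
    gender has fewer than 100 events or 100 non-events.
    """
    df = panel.records
    if len(df) == 0:
        raise ValidationError("panel is empty")
    y = df["outcome"].to_numpy()
    if y.min() == y.max():
        raise ModelInfeasibleError("all outcomes identical; model not estimable")
    gender = df["gender"].to_numpy()
    gender_specific = True
    for g in (0, 1):
        yg = y[gender == g]
        if (yg == 1).sum() < 100 or (yg == 0).sum() < 100:
            gender_specific = False
    age = df["age"].to_numpy()
    comorb = df["comorbidity_entry"].to_numpy()
    comorb_dropped = len(np.unique(comorb)) == 1
    age_knots: dict = {}
    age_center: dict = {}
    L: dict = {}
    if gender_specific:
        for g in (0, 1):
            sel = gender == g
            age_knots[g], age_center[g] = _age_rules(age[sel], quantile_method)
            L[g] = 0 if comorb_dropped else _comorb_L(comorb[sel], quantile_method)
    else:
        age_knots[-1], age_center[-1] = _age_rules(age, quantile_method)
        L[-1] = 0 if comorb_dropped else _comorb_L(comorb, quantile_method)
    dropped = ["comorbidity"] if comorb_dropped else []
    return ModelDesign(
        gender_specific=gender_specific,
        age_knots=age_knots,
        age_center=age_center,
        L=L,
        comorb_dropped=comorb_dropped,
        dropped_terms=dropped,
        quantile_method=quantile_method,
    )


def covariate_matrix(df: pd.DataFrame, design: ModelDesign) -> tuple[np.ndarray, list]:
    """Covariate columns (everything except the cell intercepts).

    The same construction serves model fitting (analysis records) and
    standardization (reference records).
    """
    n = len(df)
    if design.intercept_only:
        return np.empty((n, 0)), []
    gender = df["gender"].to_numpy()
    cols: list[np.ndarray] = [gender.astype(float)[:, None]]
    names: list[str] = ["gender"]
    for g in design.genders():
        mask = np.ones(n, dtype=bool) if g == -1 else gender == g
        tag = "" if g == -1 else f"_g{g}"
        gisd = df["gisd"].to_numpy() * mask
        cols.append(gisd[:, None])
        names.append(f"gisd{tag}")
        centered = df["age"].to_numpy() - design.age_center[g]
        basis = natural_spline_basis(centered, design.age_knots[g] - design.age_center[g])
        basis = basis * mask[:, None]
        cols.append(basis)
        names += [f"age{tag}_s{j}" for j in range(basis.shape[1])]
        if not design.comorb_dropped:
            cb = comorbidity_code(df["comorbidity_entry"].to_numpy(), design.L[g])
            cb = cb * mask[:, None]
            cols.append(cb)
            names += [f"comorb{tag}_c{j}" for j in range(cb.shape[1])]
    X = np.column_stack(cols)
    return X, names


@dataclass
class OutcomeFit:
    """Fitted outcome model: coefficients, robust covariance, bookkeeping."""

    params: np.ndarray
    cov: np.ndarray
    names: list
    design: ModelDesign
    fitted_cells: list  # [(region, t), ...] in column order
    n_cov: int
    converged: bool
    cluster_level: str
    kept_cov: np.ndarray = None  # covariate-column indices kept in the fit

    @property
    def n_cells(self) -> int:
        return len(self.fitted_cells)

    def cell_alpha(self, region: str, t: int) -> float:
        i = self.fitted_cells.index((region, int(t)))
        return float(self.params[i])

    @property
    def cov_params(self) -> np.ndarray:
        return self.cov


def fit_outcome_model(
    panel: AnalysisPanel,
    design: ModelDesign,
    cluster_level: str = "subject",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> OutcomeFit:
    """ML logistic fit with one intercept per estimable region x year cell.

    Cells whose records are all events or all non-events have no finite
    intercept; their rows are excluded and the cell flagged
    non-estimable.  The coefficient covariance is the cluster-robust
    sandwich with clusters defined by subject (or, for sensitivity
    analyses, by practice); no small-sample correction is applied, so
    with singleton clusters it equals the HC0 covariance.
    """
    if cluster_level not in ("subject", "practice"):
        raise ValidationError("cluster_level must be 'subject' or 'practice'")
    df = panel.records
    y = df["outcome"].to_numpy().astype(float)
    cell_key = pd.MultiIndex.from_arrays([df["region"], df["t"]])
    cell_mean = pd.Series(y).groupby(cell_key.to_flat_index()).mean()
    estimable = cell_mean[(cell_mean > 0) & (cell_mean < 1)].index
    dropped_cells = [c for c in cell_mean.index if c not in set(estimable)]
    if dropped_cells:
        logger.warning("%d region-year cells non-estimable (all 0/1)", len(dropped_cells))
    keep = cell_key.to_flat_index().isin(set(estimable))
    df = df.loc[keep]
    y = y[keep]
    if len(df) == 0 or y.min() == y.max():
        raise ModelInfeasibleError("no estimable cells")

    cells = sorted(estimable, key=lambda c: (str(c[0]), int(c[1])))
    cell_pos = {c: i for i, c in enumerate(cells)}
    row_cell = np.array(
        [cell_pos[c] for c in zip(df["region"].to_numpy(), df["t"].to_numpy())]
    )
    n, n_cells = len(df), len(cells)
    X_cov, cov_names = covariate_matrix(df, design)
    # a covariate constant over the whole panel is collinear with the
    # cell intercepts: drop it (and remember, for standardization)
    if X_cov.shape[1]:
        kept_cov = np.flatnonzero(X_cov.std(axis=0) > 0)
        if len(kept_cov) < X_cov.shape[1]:
            dropped = [cov_names[i] for i in range(X_cov.shape[1]) if i not in kept_cov]
            logger.info("dropping constant covariate column(s): %s", dropped)
        X_cov = X_cov[:, kept_cov]
        cov_names = [cov_names[i] for i in kept_cov]
    else:
        kept_cov = np.array([], dtype=int)
    X = np.zeros((n, n_cells + X_cov.shape[1]))
    X[np.arange(n), row_cell] = 1.0
    X[:, n_cells:] = X_cov
    names = [f"alpha[{r},{t}]" for r, t in cells] + cov_names

    if cluster_level == "subject":
        groups = pd.factorize(df["subject_id"])[0]
    else:
        groups = pd.factorize(df["practice_id"].astype(str))[0]
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(
            maxiter=max_iter,
            tol=tol,
            cov_type="cluster",
            cov_kwds={"groups": groups, "use_correction": False},
        )
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(deviance {res.deviance:.4g})"
        )
    params = np.asarray(res.params, dtype=float)
    if np.abs(params).max() > 30:
        raise ConvergenceError("extreme coefficients suggest complete separation")
    cov = np.asarray(res.cov_params(), dtype=float)
    return OutcomeFit(
        params=params,
        cov=cov,
        names=names,
        design=design,
        fitted_cells=[(str(r), int(t)) for r, t in cells],
        n_cov=X_cov.shape[1],
        converged=bool(res.converged),
        cluster_level=cluster_level,
        kept_cov=kept_cov,
    )


@dataclass
class StandardizedPrevalences:
    """Region x year standardized prevalences with standard errors."""

    regions: list
    years: np.ndarray
    p_hat: np.ndarray  # regions x years, NaN where not estimable
    se: np.ndarray  # same shape, NaN until mc_standard_errors ran
    n_reference: dict  # year -> reference-sample size
    mc_components: dict = field(default_factory=dict)  # (region, t) -> record

    @property
    def estimable(self) -> np.ndarray:
        return ~np.isnan(self.p_hat)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.regions):
            for j, t in enumerate(self.years):
                rows.append(
                    {
                        "region": r,
                        "t": int(t),
                        "p_hat": self.p_hat[i, j],
                        "se": self.se[i, j],
                        "n_reference": self.n_reference.get(int(t), 0),
                        "estimable": bool(self.estimable[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _reference_frame(panel: AnalysisPanel, reference: str) -> pd.DataFrame:
    if reference == "bw_sample":
        ref = panel.records[panel.records["in_reference_sample"]]
    elif reference == "intervention_region":
        ref = panel.records[panel.records["region"] == panel.registry.intervention]
    else:
        raise ValidationError("reference must be 'bw_sample' or 'intervention_region'")
    if len(ref) == 0:
        raise ValidationError(f"reference population {reference!r} is empty")
    return ref


def standardize(
    fit: OutcomeFit,
    panel: AnalysisPanel,
    reference: str = "bw_sample",
) -> StandardizedPrevalences:
    """Directly standardized prevalences (point estimates).

    For every fitted cell (r, t) the cell's prediction rule is applied
    to all reference-population members present in year t and the
    predicted probabilities are averaged.
    """
    ref = _reference_frame(panel, reference)
    regions = list(panel.registry.all_regions)
    years = np.array(sorted({t for _, t in fit.fitted_cells}))
    p_hat = np.full((len(regions), len(years)), np.nan)
    n_ref: dict = {}
    Xr = _reference_design(fit, ref)
    beta_cov = fit.params[fit.n_cells :]
    lp_cov_all = Xr @ beta_cov
    t_arr = ref["t"].to_numpy()
    for j, t in enumerate(years):
        lp_cov = lp_cov_all[t_arr == t]
        if len(lp_cov) == 0:
            raise ValidationError(f"reference sample empty in year {t}")
        n_ref[int(t)] = int(len(lp_cov))
        for i, r in enumerate(regions):
            if (r, int(t)) in fit.fitted_cells:
                a = fit.cell_alpha(r, t)
                p_hat[i, j] = float(expit(a + lp_cov).mean())
    return StandardizedPrevalences(
        regions=regions,
        years=years,
        p_hat=p_hat,
        se=np.full_like(p_hat, np.nan),
        n_reference=n_ref,
    )


def _reference_design(fit: OutcomeFit, ref: pd.DataFrame) -> np.ndarray:
    X, _ = covariate_matrix(ref, fit.design)
    if fit.kept_cov is not None and X.shape[1]:
        X = X[:, fit.kept_cov]
    return X


def _sample_ordered_pairs(
    n: int, n2: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered pairs (i, i') with i != i', without replacement among pairs."""
    total = n * (n - 1)
    if n2 >= total:
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = i != j
        return i[mask], j[mask]
    if total <= 4_000_000:
        codes = rng.choice(total, size=n2, replace=False)
    else:
        # rejection sampling of unique codes; collisions are rare (n2 << total)
        codes = np.unique(rng.integers(0, total, size=int(n2 * 1.2) + 100))
        while len(codes) < n2:
            extra = rng.integers(0, total, size=n2)
            codes = np.unique(np.concatenate([codes, extra]))
        codes = rng.permutation(codes)[:n2]
    i = codes // (n - 1)
    jr = codes % (n - 1)
    j = jr + (jr >= i)
    return i, j


def mc_standard_errors(
    fit: OutcomeFit,
    panel: AnalysisPanel,
    sp: StandardizedPrevalences | None = None,
    n1: int | None = None,
    n2: int | None = None,
    seed: int = 0,
    reference: str = "bw_sample",
) -> StandardizedPrevalences:
    """Monte-Carlo delta-method standard errors of the standardized prevalences.

    With eta_i the linear predictor of reference subject i under a
    cell's rule, l_i = Lambda(eta_i)(1 - Lambda(eta_i)) and C the
    robust coefficient covariance,

        Var(p_hat) = (1/n) * (v_bar + (n - 1) * c_bar)

    where v_bar averages l_i^2 z_i' C z_i over a without-replacement
    subsample and c_bar averages l_i l_i' z_i' C z_i' over ordered
    pairs drawn without replacement.  By default the subsample sizes
    follow the rule n1 = min(n, 10000), n2 = min(floor(n/2), 20000);
    explicit values cap at the population (n subjects, n(n-1) pairs).
    If the pair count covers all pairs, the computation is exact
    (full-enumeration delta method).  The variance is floored at zero
    before the square root.
    """
    if sp is None:
        sp = standardize(fit, panel, reference=reference)
    ref = _reference_frame(panel, reference)
    rng = np.random.default_rng(seed)
    Xr = _reference_design(fit, ref)
    beta_cov = fit.params[fit.n_cells :]
    C = fit.cov
    nc = fit.n_cells
    C_cov = C[nc:, nc:]
    t_arr = ref["t"].to_numpy()
    se = np.full_like(sp.p_hat, np.nan)
    comps: dict = {}
    for j, t in enumerate(sp.years):
        sel = t_arr == t
        X = Xr[sel]
        n = X.shape[0]
        lp_cov = X @ beta_cov
        n1_t = min(n, 10_000) if n1 is None else min(n, n1)
        n2_t = min(n // 2, 20_000) if n2 is None else min(n * (n - 1), n2)
        s1 = rng.choice(n, size=n1_t, replace=False) if n1_t < n else np.arange(n)
        pi, pj = _sample_ordered_pairs(n, max(n2_t, 1), rng)
        # pieces reused across cells in this year
        qf = np.einsum("ij,ij->i", X @ C_cov, X)  # x_i' C_cov x_i
        P = X @ C_cov  # rows: x_i' C_cov
        cross = np.einsum("ij,ij->i", P[pi], X[pj])  # x_i' C_cov x_j
        A = X @ C[nc:, :nc]  # n x n_cells: a_i per cell
        for i_r, r in enumerate(sp.regions):
            key = (r, int(t))
            if key not in fit.fitted_cells:
                continue
            c_idx = fit.fitted_cells.index(key)
            alpha = fit.params[c_idx]
            lam = expit(alpha + lp_cov)
            l = lam * (1.0 - lam)
            ccc = C[c_idx, c_idx]
            a = A[:, c_idx]
            v = l**2 * (ccc + 2.0 * a + qf)
            v_bar = float(v[s1].mean())
            c_pair = l[pi] * l[pj] * (ccc + a[pi] + a[pj] + cross)
            c_bar = float(c_pair.mean())
            var = (v_bar + (n - 1) * c_bar) / n
            if var < 0:
                logger.warning("variance floored at 0 for cell %s", key)
                var = 0.0
            se[i_r, j] = np.sqrt(var)
            comps[key] = {
                "v_bar": v_bar,
                "c_bar": c_bar,
                "n1": int(n1_t),
                "n2": int(len(pi)),
                "seed": int(seed),
            }
    return StandardizedPrevalences(
        regions=sp.regions,
        years=sp.years,
        p_hat=sp.p_hat,
        se=se,
        n_reference=sp.n_reference,
        mc_components=comps,
    )
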