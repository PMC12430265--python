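"""Cox proportional-hazards analysis of diet-index exposures.

Person-time construction with a time-varying (two-segment) dietary exposure,
multivariable Cox models with quartile indicators, median-score trend tests,
restricted cubic-spline dose-response curves, Schoenfeld-residual
proportional-hazards diagnostics, effect-modification Wald tests with a
Bonferroni threshold, and an early-event sensitivity analysis.

The time scale is follow-up time since baseline with age entered as a
covariate.  Competing CVD subtypes censor (cause-specific hazards); ties in
event times use the Efron approximation.  Partial-likelihood estimation is
delegated to :class:`statsmodels.duration.hazard_regression.PHReg`, which
supports the counting-process (delayed-entry) rows produced by the segment
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .synthetic_cohort import OUTCOMES

Z975 = stats.norm.ppf(0.975)

#: covariates of the fully adjusted model, in design order
MULTIVARIABLE_COVARIATES = (
    "age", "sex_male", "area_urban",
    "income_2", "income_3", "income_4",
    "education_2", "education_3", "education_4",
    "smoking_packyears", "alcohol_g_day",
    "family_history_cvd", "hypertension",
    "bmi", "physical_activity", "energy",
)

AGE_SEX_COVARIATES = ("age", "sex_male")

#: the seven effect modifiers examined for multiplicative interaction
DEFAULT_MODIFIERS = (
    "age_band", "sex", "family_history_cvd", "physical_activity_median",
    "bmi_band", "smoking_ever", "hypertension",
)
BONFERRONI_ALPHA = 0.05
N_INTERACTION_TESTS = len(DEFAULT_MODIFIERS)


class ConvergenceError(RuntimeError):
    """Raised when a Cox fit fails to converge or is degenerate."""


# ---------------------------------------------------------------------------
# person-time construction
# ---------------------------------------------------------------------------

def build_persontime(
    participants: pd.DataFrame,
    followup: pd.DataFrame,
    exposure_a: pd.DataFrame,
    exposure_b: pd.DataFrame | None,
    outcome: str,
    split_time: float | None = None,
) -> pd.DataFrame:
    """Build the counting-process analysis dataset for one outcome.

    ``exposure_a``/``exposure_b`` are indexed by participant id with columns
    ``total``, ``quartile`` and ``energy`` — the scored exposure of the
    baseline segment and of the post-wave-2 (cumulative-average) segment.
    Each participant contributes one row ``(0, exit]`` if censored or
    failing before ``split_time`` (or if no second segment is supplied), and
    otherwise two contiguous rows split at ``split_time``, each carrying its
    segment's exposure.  The event indicator is set only on the terminal
    segment; for subtype analyses the competing subtype censors at its
    occurrence.  ``outcome`` is ``'CVD'`` (composite) or one of
    ``'CHD'``/``'stroke'``/``'CVD_other'``.
    """
    if outcome not in ("CVD",) + OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")

    fu = followup.set_index("id")
    pt = participants.set_index("id")
    ids = pt.index
    if not set(ids) <= set(fu.index):
        raise KeyError("follow-up table does not cover all participants")
    exit_time = fu.loc[ids, "exit_time"].to_numpy(dtype=float)
    if (exit_time <= 0).any():
        raise ValueError("non-positive follow-up time")
    terminal = fu.loc[ids, "event"]
    if outcome == "CVD":
        ev = terminal.isin(OUTCOMES).to_numpy()
    else:
        ev = (terminal == outcome).to_numpy()

    cov = _covariate_frame(pt)

    def segment_rows(seg_ids, start, stop, event, exposure):
        seg = cov.loc[seg_ids].reset_index()
        seg["start"] = start
        seg["stop"] = stop
        seg["event"] = np.asarray(event, dtype=int)
        exp_rows = exposure.loc[seg_ids]
        seg["total"] = exp_rows["total"].to_numpy(dtype=float)
        seg["quartile"] = exp_rows["quartile"].to_numpy(dtype=int)
        if "energy" in exp_rows:
            seg["energy"] = exp_rows["energy"].to_numpy(dtype=float)
        return seg

    if exposure_b is None or split_time is None:
        return segment_rows(ids, 0.0, exit_time, ev, exposure_a).reset_index(drop=True)

    if split_time <= 0:
        raise ValueError("split_time must be positive")
    early = exit_time <= split_time
    parts = [segment_rows(ids[early], 0.0, exit_time[early], ev[early], exposure_a)]
    late = ~early
    if late.any():
        parts.append(segment_rows(ids[late], 0.0, np.full(late.sum(), split_time), False, exposure_a))
        parts.append(segment_rows(ids[late], split_time, exit_time[late], ev[late], exposure_b))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["id", "start"], kind="stable").reset_index(drop=True)


def _covariate_frame(pt: pd.DataFrame) -> pd.DataFrame:
    """Expand raw participant covariates into numeric design columns."""
    cov = pd.DataFrame(index=pt.index)
    cov["age"] = pt["age"].astype(float)
    cov["sex_male"] = (pt["sex"] == "male").astype(float)
    cov["area_urban"] = (pt["area"] == "urban").astype(float)
    for k in (2, 3, 4):
        cov[f"income_{k}"] = (pt["income"] == k).astype(float)
        cov[f"education_{k}"] = (pt["education"] == k).astype(float)
    for c in ("smoking_packyears", "alcohol_g_day", "bmi", "physical_activity"):
        cov[c] = pt[c].astype(float)
    cov["family_history_cvd"] = pt["family_history_cvd"].astype(float)
    cov["hypertension"] = pt["hypertension"].astype(float)
    return cov


def person_years(dataset: pd.DataFrame) -> float:
    return float((dataset["stop"] - dataset["start"]).sum())


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxFitResult:
    """Quartile-exposure Cox fit: hazard ratios, Wald CIs and diagnostics."""

    hr_by_quartile: dict[int, tuple[float, float, float]]
    log_partial_likelihood: float
    n_events: int
    person_years: float
    params: pd.Series
    cov: pd.DataFrame
    model: str
    converged: bool
    p_trend: float | None = None
    ph_test_p: float | None = None
    design: pd.DataFrame = field(default=None, repr=False)
    dataset: pd.DataFrame = field(default=None, repr=False)


def _model_covariates(model: str) -> tuple[str, ...]:
    if model == "age_sex":
        return AGE_SEX_COVARIATES
    if model == "multivariable":
        return MULTIVARIABLE_COVARIATES
    raise ValueError(f"unknown model {model!r}")


def _phreg(dataset: pd.DataFrame, design: pd.DataFrame):
    model = PHReg(
        dataset["stop"].to_numpy(dtype=float),
        design.to_numpy(dtype=float),
        status=dataset["event"].to_numpy(dtype=int),
        entry=dataset["start"].to_numpy(dtype=float),
        ties="efron",
    )
    try:
        res = model.fit()
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular design in Cox fit: {exc}") from exc
    params = pd.Series(res.params, index=design.columns)
    cov = pd.DataFrame(res.cov_params(), index=design.columns, columns=design.columns)
    llf = float(model.loglike(res.params))
    ok = bool(np.isfinite(params).all() and np.isfinite(np.diag(cov)).all()
              and np.abs(params).max() < 50)
    return params, cov, llf, ok


def _exposure_design(dataset: pd.DataFrame, model: str, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    design = pd.DataFrame(index=dataset.index)
    if extra is not None:
        for c in extra.columns:
            design[c] = extra[c].to_numpy(dtype=float)
    for c in _model_covariates(model):
        design[c] = dataset[c].to_numpy(dtype=float)
    return design


def fit_cox(dataset: pd.DataFrame, model: str = "multivariable") -> CoxFitResult:
    """Fit the Cox model with quartile-indicator exposure (quartile 1 reference).

    ``model='age_sex'`` adjusts for age and sex only; ``'multivariable'``
    adjusts for the full covariate set.  Degenerate fits (non-finite or
    exploding coefficients, e.g. from complete separation or zero events in
    a stratum) are flagged, never returned silently.
    """
    n_events = int(dataset["event"].sum())
    if n_events < 1:
        raise ConvergenceError("no events in dataset")
    q = dataset["quartile"].to_numpy(dtype=int)
    dummies = pd.DataFrame(
        {f"quartile_{k}": (q == k).astype(float) for k in (2, 3, 4) if (q == k).any()},
        index=dataset.index,
    )
    design = _exposure_design(dataset, model, dummies)
    params, cov, llf, ok = _phreg(dataset, design)
    if not ok:
        raise ConvergenceError("Cox fit did not converge (flagged, not silent)")
    se = np.sqrt(np.diag(cov))
    se = pd.Series(se, index=params.index)
    hr = {}
    for k in (2, 3, 4):
        name = f"quartile_{k}"
        if name in params.index:
            b, s = params[name], se[name]
            hr[k] = (float(np.exp(b)), float(np.exp(b - Z975 * s)), float(np.exp(b + Z975 * s)))
    return CoxFitResult(
        hr_by_quartile=hr,
        log_partial_likelihood=llf,
        n_events=n_events,
        person_years=person_years(dataset),
        params=params,
        cov=cov,
        model=model,
        converged=ok,
        design=design,
        dataset=dataset,
    )


def trend_test(
    dataset: pd.DataFrame,
    quartile_medians: dict[int, float],
    model: str = "multivariable",
) -> float:
    """Linear trend test across quartiles.

    Replaces the quartile indicators with the per-quartile median index
    score, entered as a single continuous covariate, and returns the Wald
    p-value of its coefficient.
    """
    q = dataset["quartile"].to_numpy(dtype=int)
    if len(np.unique(q)) < 2:
        raise ValueError("trend test needs at least two quartile levels")
    trend = pd.DataFrame(
        {"trend": np.array([quartile_medians[int(k)] for k in q], dtype=float)},
        index=dataset.index,
    )
    design = _exposure_design(dataset, model, trend)
    params, cov, _, ok = _phreg(dataset, design)
    if not ok:
        raise ConvergenceError("trend-test Cox fit did not converge")
    z = params["trend"] / np.sqrt(cov.loc["trend", "trend"])
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: tuple[float, float, float]) -> np.ndarray:
    """Restricted cubic-spline nonlinear basis term for three knots.

    With knots k1 < k2 < k3 the basis is the linear term plus one nonlinear
    term that is linear beyond the boundary knots (Harrell's normalization
    by (k3 - k1)^2).
    """
    k1, k2, k3 = knots
    d = lambda u: np.maximum(u, 0.0) ** 3
    return (d(x - k1) - d(x - k2) * (k3 - k1) / (k3 - k2)
            + d(x - k3) * (k2 - k1) / (k3 - k2)) / (k3 - k1) ** 2


@dataclass
class SplineResult:
    """Dose-response curve of an index total on the log-hazard scale."""

    grid: np.ndarray
    log_hr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    p_linear: float
    p_nonlinear: float
    knots: tuple[float, float, float] | None
    reference: float
    loglik_spline: float
    loglik_linear: float


def fit_spline(
    dataset: pd.DataFrame,
    model: str = "multivariable",
    n_grid: int = 100,
) -> SplineResult:
    """Restricted cubic-spline dose-response for the continuous index total.

    Knots sit at the 10th/50th/90th percentiles of the totals.  The
    nonlinearity p-value is a likelihood-ratio test of the spline model
    against the linear-only model; the linearity p-value is the Wald test of
    the linear term in the linear-only model.  The curve is the log hazard
    ratio relative to the median total, with a pointwise 95% band.  If the
    knots collapse (massive ties) the fit reduces to the linear model with a
    warning.
    """
    x = dataset["total"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("spline fit needs at least 3 distinct index values")
    knots = tuple(np.percentile(x, [10, 50, 90], method="linear"))
    reference = float(knots[1])

    lin = pd.DataFrame({"total_lin": x}, index=dataset.index)
    params_l, cov_l, llf_l, ok_l = _phreg(dataset, _exposure_design(dataset, model, lin))
    if not ok_l:
        raise ConvergenceError("linear Cox fit did not converge")
    z = params_l["total_lin"] / np.sqrt(cov_l.loc["total_lin", "total_lin"])
    p_linear = float(2 * stats.norm.sf(abs(z)))

    grid = np.union1d(np.linspace(x.min(), x.max(), n_grid), [reference])
    if len(set(knots)) < 3:
        warnings.warn("spline knots collapsed; reducing to linear fit")
        b = params_l["total_lin"]
        s = np.sqrt(cov_l.loc["total_lin", "total_lin"])
        curve = b * (grid - reference)
        half = Z975 * s * np.abs(grid - reference)
        return SplineResult(grid, curve, curve - half, curve + half,
                            p_linear, np.nan, None, reference, llf_l, llf_l)

    spl = pd.DataFrame({"total_lin": x, "total_rcs": rcs_basis(x, knots)}, index=dataset.index)
    params_s, cov_s, llf_s, ok_s = _phreg(dataset, _exposure_design(dataset, model, spl))
    if not ok_s:
        raise ConvergenceError("spline Cox fit did not converge")
    lr = max(0.0, 2.0 * (llf_s - llf_l))
    p_nonlinear = float(stats.chi2.sf(lr, df=1))

    # contrast of the exposure terms against the reference value
    basis_grid = np.column_stack([grid - reference,
                                  rcs_basis(grid, knots) - rcs_basis(np.array([reference]), knots)])
    beta = params_s[["total_lin", "total_rcs"]].to_numpy()
    sig = cov_s.loc[["total_lin", "total_rcs"], ["total_lin", "total_rcs"]].to_numpy()
    curve = basis_grid @ beta
    half = Z975 * np.sqrt(np.einsum("ij,jk,ik->i", basis_grid, sig, basis_grid))
    return SplineResult(grid, curve, curve - half, curve + half,
                        p_linear, p_nonlinear, knots, reference, llf_s, llf_l)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics (Schoenfeld residuals)
# ---------------------------------------------------------------------------

@dataclass
class PHTestResult:
    global_p: float
    global_stat: float
    df: int
    per_covariate: pd.DataFrame  # columns: stat, p


def ph_test(fit: CoxFitResult, transform: str = "identity") -> PHTestResult:
    """Grambsch-Therneau score test of the proportional-hazards assumption.

    Tests whether the effect of each covariate drifts with a transform of
    event time (``'identity'`` or ``'rank'``), i.e. the score test for
    adding ``x * g(t)`` interactions at the fitted coefficients.  Schoenfeld
    residuals and risk-set covariances are computed at each event time on
    the counting-process risk sets (entry < t <= stop); the score-test
    variance profiles out the main-effect information, matching the exact
    formulation of modern implementations.  The global statistic is
    chi-square with one degree of freedom per covariate.
    """
    dataset, design = fit.dataset, fit.design
    X = design.to_numpy(dtype=float)
    beta = fit.params.to_numpy()
    start = dataset["start"].to_numpy(dtype=float)
    stop = dataset["stop"].to_numpy(dtype=float)
    event = dataset["event"].to_numpy(dtype=int).astype(bool)
    d = int(event.sum())
    if d == 0:
        raise ValueError("PH test needs at least one event")

    eta = X @ beta
    w = np.exp(eta - eta.max())
    ev_order = np.argsort(stop[event], kind="stable")
    ev_times = stop[event][ev_order]
    ev_x = X[event][ev_order]
    uniq_times, first_idx = np.unique(ev_times, return_index=True)

    if transform == "identity":
        g_ev = ev_times.copy()
    elif transform == "rank":
        g_ev = stats.rankdata(ev_times)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g_ev = g_ev - g_ev.mean()
    if float(g_ev @ g_ev) == 0.0:
        raise ValueError("degenerate time transform (single event time)")

    p = X.shape[1]
    resid = np.empty((d, p))
    a = np.zeros((p, p))   # sum of risk-set covariances V_k
    b = np.zeros((p, p))   # sum of g_k V_k
    c = np.zeros((p, p))   # sum of g_k^2 V_k
    for t in uniq_times:
        at_risk = (start < t) & (stop >= t)
        wr = w[at_risk]
        xr = X[at_risk]
        sw = wr.sum()
        xbar = (wr[:, None] * xr).sum(axis=0) / sw
        xc = xr - xbar
        v = (wr[:, None] * xc).T @ xc / sw
        block = ev_times == t
        resid[block] = ev_x[block] - xbar
        gs = g_ev[block]
        m = int(block.sum())
        a += m * v
        b += gs.sum() * v
        c += (gs ** 2).sum() * v

    # score and profiled information for the x * g(t) augmentation
    u = resid.T @ g_ev
    dmat = c - b @ np.linalg.solve(a, b)
    global_stat = float(u @ np.linalg.solve(dmat, u))
    global_p = float(stats.chi2.sf(global_stat, df=p))
    per = u ** 2 / np.diag(dmat)
    per_p = stats.chi2.sf(per, df=1)
    per_df = pd.DataFrame({"stat": per, "p": per_p}, index=design.columns)
    return PHTestResult(global_p, global_stat, p, per_df)


# ---------------------------------------------------------------------------
# effect modification
# ---------------------------------------------------------------------------

def _modifier_columns(dataset: pd.DataFrame, modifier: str) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Return (indicator columns for products, main-effect columns to add).

    Main effects already present in the multivariable design (sex, family
    history, hypertension) are not re-added.
    """
    idx = dataset.index
    if modifier == "sex":
        ind = pd.DataFrame({"sex_male": dataset["sex_male"]}, index=idx)
        return ind, None
    if modifier == "family_history_cvd":
        return pd.DataFrame({"family_history_cvd": dataset["family_history_cvd"]}, index=idx), None
    if modifier == "hypertension":
        return pd.DataFrame({"hypertension": dataset["hypertension"]}, index=idx), None
    if modifier == "age_band":
        age = dataset["age"].to_numpy(dtype=float)
        ind = pd.DataFrame({
            "age_50_64": ((age >= 50) & (age < 65)).astype(float),
            "age_65plus": (age >= 65).astype(float),
        }, index=idx)
        return ind, ind.add_prefix("mod_")
    if modifier == "physical_activity_median":
        pa = dataset["physical_activity"].to_numpy(dtype=float)
        ind = pd.DataFrame({"pa_high": (pa > np.median(pa)).astype(float)}, index=idx)
        return ind, ind.add_prefix("mod_")
    if modifier == "bmi_band":
        # reference band 18.5-22.9; sparse bands (underweight in a
        # middle-aged cohort) are dropped to avoid separation
        bmi = dataset["bmi"].to_numpy(dtype=float)
        ind = pd.DataFrame({
            "bmi_under": (bmi < 18.5).astype(float),
            "bmi_23_25": ((bmi >= 23.0) & (bmi < 25.0)).astype(float),
            "bmi_25plus": (bmi >= 25.0).astype(float),
        }, index=idx)
        n = len(ind)
        ind = ind.loc[:, (ind.sum(axis=0) >= 20) & (ind.sum(axis=0) <= n - 20)]
        return ind, ind.add_prefix("mod_")
    if modifier == "smoking_ever":
        ind = pd.DataFrame(
            {"smoker": (dataset["smoking_packyears"].to_numpy(dtype=float) > 0).astype(float)},
            index=idx,
        )
        return ind, ind.add_prefix("mod_")
    raise ValueError(f"unknown modifier {modifier!r}")


def interaction_tests(
    dataset: pd.DataFrame,
    quartile_medians: dict[int, float],
    modifiers: tuple[str, ...] = DEFAULT_MODIFIERS,
    model: str = "multivariable",
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Wald tests of multiplicative exposure-by-modifier interaction.

    The exposure enters as the continuous quartile-median trend variable;
    each modifier is tested in its own model via the joint Wald statistic of
    the product terms.  Significance is flagged against the Bonferroni
    threshold alpha / (number of modifiers).
    """
    threshold = alpha / len(modifiers)
    q = dataset["quartile"].to_numpy(dtype=int)
    trend = np.array([quartile_medians[int(k)] for k in q], dtype=float)
    trend = trend - trend.mean()
    rows = []
    for modifier in modifiers:
        ind, main = _modifier_columns(dataset, modifier)
        if ind.shape[1] == 0 or any(ind[c].nunique() < 2 for c in ind.columns):
            raise ValueError(f"modifier {modifier!r} has a single level")
        extra = pd.DataFrame({"trend": trend}, index=dataset.index)
        if main is not None:
            extra = pd.concat([extra, main], axis=1)
        prod_cols = []
        for c in ind.columns:
            name = f"trend_x_{c}"
            extra[name] = trend * ind[c].to_numpy(dtype=float)
            prod_cols.append(name)
        design = _exposure_design(dataset, model, extra)
        params, cov, _, ok = _phreg(dataset, design)
        if not ok:
            raise ConvergenceError(f"interaction fit for {modifier!r} did not converge")
        b = params[prod_cols].to_numpy()
        c = cov.loc[prod_cols, prod_cols].to_numpy()
        wald = float(b @ np.linalg.solve(c, b))
        pval = float(stats.chi2.sf(wald, df=len(prod_cols)))
        rows.append({"modifier": modifier, "wald_chi2": wald, "df": len(prod_cols),
                     "p": pval, "significant": pval < threshold})
    out = pd.DataFrame(rows).set_index("modifier")
    out.attrs["bonferroni_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_exclude_early(
    dataset: pd.DataFrame,
    window_years: float = 2.0,
    model: str = "multivariable",
) -> CoxFitResult:
    """Refit after excluding participants with events in the first years.

    Participants whose event occurred before ``window_years`` are removed
    entirely (all their person-time is dropped); everyone else is retained
    unchanged.  ``window_years=0`` reproduces the main fit.
    """
    if window_years >= dataset["stop"].max():
        raise ValueError("exclusion window exceeds the maximum follow-up time")
    early_ids = dataset.loc[
        (dataset["event"] == 1) & (dataset["stop"] < window_years), "id"
    ].unique()
    kept = dataset.loc[~dataset["id"].isin(set(early_ids))].reset_index(drop=True)
    return fit_cox(kept, model=model)
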