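"""Shared fixtures and small simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pbdi import assign_quartiles, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


def make_participants(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Minimal valid participant table with all covariate columns."""
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": rng.uniform(40, 69, n).round(1),
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "area": np.where(rng.random(n) < 0.5, "urban", "rural"),
        "income": rng.integers(1, 5, n).astype(float),
        "education": rng.integers(1, 5, n).astype(float),
        "smoking_packyears": np.where(rng.random(n) < 0.4, rng.gamma(2, 6, n), 0.0),
        "alcohol_g_day": np.where(rng.random(n) < 0.5, rng.gamma(2, 6, n), 0.0),
        "bmi": rng.normal(24.5, 3.0, n).round(1),
        "physical_activity": rng.gamma(3, 8, n),
        "hypertension": rng.random(n) < 0.3,
        "family_history_cvd": rng.random(n) < 0.15,
        "baseline_disease": np.zeros(n, dtype=bool),
        "no_followup": np.zeros(n, dtype=bool),
    })


def simulate_dataset(
    rng: np.random.Generator,
    n: int = 250,
    beta_by_quartile: tuple[float, float, float] = (0.0, 0.0, 0.0),
    base_hazard: float = 0.02,
    followup_years: float = 18.0,
    sex_interaction: float = 0.0,
    quadratic: float = 0.0,
    double_after: float | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Small counting-process dataset with a directly planted hazard model.

    The exposure is an integer index total ~ N(51, 6) with cohort quartiles;
    the log hazard is the quartile effect plus optional sex-by-trend
    interaction or a quadratic term in the (standardized) total, and with
    ``double_after`` set, the quartile log-HRs double from that time onward
    (a planted proportional-hazards violation).  Returns the analysis
    dataset (single segment per participant) and the quartile medians.
    """
    pt = make_participants(n, rng)
    total = np.clip(np.round(rng.normal(51, 6, n)), 17, 85)
    quart, medians, _ = assign_quartiles(total)
    beta = np.concatenate([[0.0], beta_by_quartile])
    lp = beta[quart - 1]
    trend = np.array([medians[int(q)] for q in quart])
    trend_c = trend - trend.mean()
    if sex_interaction:
        lp = lp + sex_interaction * trend_c * (pt["sex"] == "male").to_numpy()
    if quadratic:
        z = (total - total.mean()) / total.std()
        lp = lp + quadratic * z ** 2
    lam1 = base_hazard * np.exp(lp)
    u = rng.exponential(1.0, n)
    if double_after is None:
        t = u / lam1
    else:
        lam2 = base_hazard * np.exp(2.0 * lp)
        t_first = u / lam1
        t = np.where(
            t_first < double_after,
            t_first,
            double_after + (u - double_after * lam1) / lam2,
        )
    event = (t < followup_years).astype(int)
    stop = np.minimum(t, followup_years)

    from pbdi.survival_analysis import _covariate_frame
    ds = _covariate_frame(pt.set_index("id")).reset_index()
    ds["start"] = 0.0
    ds["stop"] = stop
    ds["event"] = event
    ds["total"] = total.astype(float)
    ds["quartile"] = quart
    ds["energy"] = rng.normal(1900, 400, n)
    return ds, {int(k): float(v) for k, v in medians.items()}
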