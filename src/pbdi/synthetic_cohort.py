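"""Synthetic prospective-cohort generator.

Emulates the data structure of a middle-aged Korean community cohort with
two FFQ waves and long-term cardiovascular follow-up: 17 food-group intake
distributions in three classes, within-person correlation between dietary
waves with partial wave-2 missingness, the covariate set used for
multivariable adjustment, and time-to-event outcomes (coronary heart
disease, stroke, other CVD) generated under a proportional-hazards model
with configurable planted quartile effects, independent dropout, non-CVD
death, and administrative censoring.

Planted exposure effects act on TRUE quartiles computed from the generator's
own scoring pass, so parameter-recovery experiments isolate the inference
stage from exposure-measurement noise.  Event times are continuous in years
under a constant (exponential) baseline hazard; an optional Weibull shape
parameter steepens or flattens the hazard while preserving proportionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ffq_processing import FoodGroupTaxonomy, default_taxonomy

OUTCOMES = ("CHD", "stroke", "CVD_other")
TERMINAL_STATES = ("none",) + OUTCOMES + ("death", "dropout")

#: covariates that must be non-missing for inclusion in the analysis
COVARIATE_COLUMNS = (
    "age", "sex", "area", "income", "education", "smoking_packyears",
    "alcohol_g_day", "physical_activity", "bmi", "family_history_cvd",
    "hypertension",
)

#: default mean servings/day per food group (class sums approximate the
#: cohort margins: ~12 healthful plant, ~8 less-healthful plant, ~3.7 animal)
DEFAULT_GROUP_MEANS = {
    "whole_grains": 1.5, "vegetables": 4.5, "fruits": 2.0, "legumes": 1.2,
    "nuts": 0.5, "tea_coffee": 2.0,
    "refined_grains": 3.0, "potatoes": 0.8, "sugar_sweetened_beverages": 0.6,
    "sweets_desserts": 1.2, "pickled_vegetables_sauces": 2.5,
    "meat": 1.0, "fish": 0.9, "eggs": 0.5, "dairy": 0.7,
    "animal_fats": 0.3, "other_animal_foods": 0.3,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Rates declared as proportions lie in [0, 1]; ``dropout_rate`` and
    ``death_rate`` are per-year hazards.  Defaults reflect the study
    conditions being emulated: n = 7820 analysis participants recruited at
    ages 40–69, an 18-year administrative horizon, a second dietary wave
    four years after baseline, and a dropout hazard giving a mean follow-up
    of ~12.8 years.
    """

    n_participants: int = 7820
    baseline_year: int = 2001
    followup_years: float = 18.0
    wave2_offset_years: float = 4.0
    wave2_missing_rate: float = 0.15
    dropout_rate: float = 0.04
    death_rate: float = 0.004
    seed: int = 0
    # dietary-exposure structure
    group_means: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    intake_log_sd: float = 0.6
    intake_energy_exponent: float = 0.5
    intake_wave_corr: float = 0.7
    energy_mean: float = 1920.0
    energy_log_sd: float = 0.25
    extreme_energy_fraction: float = 0.011
    # data-defect rates exercised by the exclusion cascade
    missing_ffq_rate: float = 0.033
    baseline_disease_rate: float = 0.047
    no_followup_rate: float = 0.085
    missing_covariate_rate: float = 0.058
    # optional Weibull shape for the baseline hazard (1.0 = exponential)
    weibull_shape: float = 1.0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not (0 < self.wave2_offset_years < self.followup_years):
            raise ValueError("wave2_offset_years must lie in (0, followup_years)")
        for name in ("wave2_missing_rate", "extreme_energy_fraction",
                     "missing_ffq_rate", "baseline_disease_rate",
                     "no_followup_rate", "missing_covariate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dropout_rate < 0 or self.death_rate < 0:
            raise ValueError("hazard rates must be non-negative")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


@dataclass
class EffectSpec:
    """Planted cause-specific hazard structure for one outcome.

    ``log_hr_by_quartile`` holds the log hazard ratios of quartiles 2–4 of
    ``exposure_index`` versus quartile 1 (the implicit reference, log-HR 0).
    ``covariate_log_hrs`` maps participant-covariate names to per-unit log
    hazard ratios; continuous covariates enter centered at the cohort mean,
    so ``baseline_hazard`` is the event rate (per person-year) of a
    quartile-1 participant with average covariates.
    """

    outcome: str
    exposure_index: str
    log_hr_by_quartile: tuple[float, float, float]
    baseline_hazard: float
    covariate_log_hrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        self.log_hr_by_quartile = tuple(float(b) for b in self.log_hr_by_quartile)
        if len(self.log_hr_by_quartile) != 3:
            raise ValueError("log_hr_by_quartile gives quartiles 2-4 vs quartile 1")
        self.baseline_hazard = float(self.baseline_hazard)
        self.covariate_log_hrs = {k: float(v) for k, v in self.covariate_log_hrs.items()}


#: modest covariate effects used by default in planted followup models
DEFAULT_COVARIATE_LOG_HRS = {
    "age": 0.06,            # per year
    "sex_male": 0.40,
    "smoking_packyears": 0.008,
    "hypertension": 0.45,
    "bmi": 0.03,            # per kg/m2
    "family_history_cvd": 0.25,
}


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the participant table and the two-wave exposure table.

    Returns ``(participants, exposures)``.  ``participants`` has one row per
    person with demographics, lifestyle covariates and data-defect flags;
    ``exposures`` is wide-format with columns ``id``, ``wave``, one column
    per food group (servings/day) and ``energy`` (kcal/day).  A wave-2 row
    is present with probability ``1 − wave2_missing_rate``; wave-2 intakes
    correlate with wave 1 on the log scale at ``intake_wave_corr``.
    Identical config and seed give byte-identical tables.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    n = config.n_participants
    ids = np.arange(1, n + 1)

    age = np.round(_truncnorm(rng, 52.0, 8.8, 40.0, 69.0, n), 1)
    female = rng.random(n) < 0.524
    urban = rng.random(n) < 0.518
    income = rng.choice([1, 2, 3, 4], size=n, p=[0.30, 0.30, 0.20, 0.20]).astype(float)
    education = rng.choice([1, 2, 3, 4], size=n, p=[0.28, 0.22, 0.33, 0.17]).astype(float)

    # pack-years constructed as packs/day x years smoked, by definition
    smoker = rng.random(n) < np.where(female, 0.06, 0.55)
    packs_per_day = np.where(smoker, rng.lognormal(np.log(0.7), 0.45, n), 0.0)
    max_years = np.maximum(age - 18.0, 1.0)
    years_smoked = np.where(smoker, rng.uniform(0.2, 1.0, n) * max_years, 0.0)
    smoking_packyears = packs_per_day * years_smoked

    drinker = rng.random(n) < np.where(female, 0.25, 0.72)
    alcohol = np.where(drinker, rng.lognormal(np.log(np.where(female, 4.0, 16.0)), 0.9, n), 0.0)

    bmi = np.round(_truncnorm(rng, 24.6, 3.1, 15.0, 40.0, n), 1)
    mets = rng.gamma(3.0, 8.0, n)
    hypertension = rng.random(n) < 0.31
    famhist = rng.random(n) < 0.15
    baseline_disease = rng.random(n) < config.baseline_disease_rate
    no_followup = rng.random(n) < config.no_followup_rate

    participants = pd.DataFrame({
        "id": ids,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "area": np.where(urban, "urban", "rural"),
        "income": income,
        "education": education,
        "smoking_packs_per_day": packs_per_day,
        "smoking_years": years_smoked,
        "smoking_packyears": smoking_packyears,
        "alcohol_g_day": alcohol,
        "bmi": bmi,
        "physical_activity": mets,
        "hypertension": hypertension,
        "family_history_cvd": famhist,
        "baseline_disease": baseline_disease,
        "no_followup": no_followup,
    })

    # missing-covariate defects: blank one covariate for flagged participants
    miss_cov = rng.random(n) < config.missing_covariate_rate
    which = rng.integers(0, 3, n)
    for k, col in enumerate(("income", "alcohol_g_day", "physical_activity")):
        participants.loc[miss_cov & (which == k), col] = np.nan

    exposures = _generate_exposures(rng, participants, config)
    return participants, exposures


def _generate_exposures(rng, participants: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    n = len(participants)
    groups = list(config.group_means)
    sigma = config.intake_log_sd
    rho = config.intake_wave_corr

    # total energy, with a configurable fraction of implausible extremes
    mu_e = np.log(config.energy_mean) - config.energy_log_sd ** 2 / 2.0
    z_e1 = rng.normal(size=n)
    z_e2 = rho * z_e1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    energy1 = np.exp(mu_e + config.energy_log_sd * z_e1)
    energy2 = np.exp(mu_e + config.energy_log_sd * z_e2)
    energy1 = np.clip(energy1, 520.0, 4980.0)
    energy2 = np.clip(energy2, 520.0, 4980.0)
    extreme = rng.random(n) < config.extreme_energy_fraction
    low = rng.random(n) < 0.5
    energy1 = np.where(extreme & low, rng.uniform(250.0, 495.0, n), energy1)
    energy1 = np.where(extreme & ~low, rng.uniform(5010.0, 6500.0, n), energy1)

    efac1 = (energy1 / config.energy_mean) ** config.intake_energy_exponent
    efac2 = (energy2 / config.energy_mean) ** config.intake_energy_exponent

    data1 = {"id": participants["id"].to_numpy(), "wave": np.ones(n, dtype=int)}
    data2 = {"id": participants["id"].to_numpy(), "wave": np.full(n, 2, dtype=int)}
    for g in groups:
        mu_g = np.log(config.group_means[g]) - sigma ** 2 / 2.0
        z1 = rng.normal(size=n)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        data1[g] = np.exp(mu_g + sigma * z1) * efac1
        data2[g] = np.exp(mu_g + sigma * z2) * efac2
    data1["energy"] = energy1
    data2["energy"] = energy2

    wave1 = pd.DataFrame(data1)
    wave2 = pd.DataFrame(data2)

    # missing-FFQ defects: blank one random group in wave 1
    miss = rng.random(n) < config.missing_ffq_rate
    gidx = rng.integers(0, len(groups), n)
    for k, g in enumerate(groups):
        wave1.loc[miss & (gidx == k), g] = np.nan

    present2 = rng.random(n) >= config.wave2_missing_rate
    wave2 = wave2.loc[present2]
    return pd.concat([wave1, wave2], ignore_index=True)


def _covariate_linear_predictor(
    participants: pd.DataFrame, covariate_log_hrs: dict
) -> np.ndarray:
    """Planted covariate contribution to the log hazard (continuous
    covariates centered at the cohort mean)."""
    lp = np.zeros(len(participants))
    for name, beta in covariate_log_hrs.items():
        if name == "sex_male":
            x = (participants["sex"] == "male").to_numpy(dtype=float)
        elif name in ("hypertension", "family_history_cvd"):
            x = participants[name].to_numpy(dtype=float)
        elif name == "area_urban":
            x = (participants["area"] == "urban").to_numpy(dtype=float)
        elif name in participants.columns:
            x = participants[name].to_numpy(dtype=float)
            x = x - np.nanmean(x)
        else:
            raise KeyError(f"unknown covariate {name!r} in planted effect")
        lp += beta * np.nan_to_num(x)
    return lp


def _cause_hazards(
    participants: pd.DataFrame,
    true_quartiles: pd.DataFrame,
    effects: list[EffectSpec],
) -> dict[str, np.ndarray]:
    """Per-participant constant hazard for each cause with a planted effect."""
    hazards: dict[str, np.ndarray] = {}
    for eff in effects:
        if eff.exposure_index not in true_quartiles.columns:
            raise KeyError(
                f"effect on {eff.outcome} references exposure index "
                f"{eff.exposure_index!r} absent from true_quartiles"
            )
        q = true_quartiles[eff.exposure_index].to_numpy()
        log_hr = np.zeros(len(q))
        for j, b in enumerate(eff.log_hr_by_quartile, start=2):
            log_hr[q == j] = b
        lp = log_hr + _covariate_linear_predictor(participants, eff.covariate_log_hrs)
        hazards[eff.outcome] = hazards.get(eff.outcome, 0.0) + eff.baseline_hazard * np.exp(lp)
    return hazards


def simulate_followup(
    participants: pd.DataFrame,
    true_quartiles: pd.DataFrame,
    effects: list[EffectSpec],
    config: CohortConfig,
) -> pd.DataFrame:
    """Draw time-to-event outcomes under the planted proportional-hazards model.

    Each cause with an :class:`EffectSpec` gets an exponential event time at
    hazard ``baseline_hazard x exp(planted quartile log-HR + covariate
    terms)``; dropout and non-CVD death are independent exponentials; the
    first occurring cause terminates follow-up, with administrative
    censoring at ``followup_years`` (event ``'none'``).  With
    ``weibull_shape`` k != 1 the times are warped as ``T -> T0 (T/T0)^{1/k}``
    about ``T0 = followup_years``, which preserves hazard proportionality.
    """
    rng = np.random.default_rng([int(config.seed), 202])
    n = len(participants)
    tq = true_quartiles.set_index(true_quartiles.index)
    if not tq.index.equals(pd.Index(participants["id"])):
        tq = true_quartiles.loc[participants["id"]]

    hazards = _cause_hazards(participants, tq, effects)
    times = {}
    for cause, lam in hazards.items():
        with np.errstate(divide="ignore"):
            times[cause] = np.where(lam > 0, rng.exponential(1.0, n) / np.where(lam > 0, lam, 1.0), np.inf)
    for cause, rate in (("dropout", config.dropout_rate), ("death", config.death_rate)):
        times[cause] = rng.exponential(1.0 / rate, n) if rate > 0 else np.full(n, np.inf)

    if config.weibull_shape != 1.0:
        t0 = config.followup_years
        for cause in hazards:
            t = times[cause]
            times[cause] = np.where(np.isfinite(t), t0 * (t / t0) ** (1.0 / config.weibull_shape), t)

    causes = list(times)
    tmat = np.column_stack([times[c] for c in causes])
    first = np.argmin(tmat, axis=1)
    tmin = tmat[np.arange(n), first]
    admin = tmin >= config.followup_years
    exit_time = np.where(admin, config.followup_years, tmin)
    event = np.where(admin, "none", np.array(causes, dtype=object)[first])

    # participants flagged as never returning after baseline contribute no
    # usable follow-up; they exit immediately as dropouts and are removed by
    # the exclusion cascade
    nofu = participants["no_followup"].to_numpy(dtype=bool)
    exit_time = np.where(nofu, 1e-6, exit_time)
    event = np.where(nofu, "dropout", event)

    return pd.DataFrame({
        "id": participants["id"].to_numpy(),
        "exit_time": exit_time,
        "event": event,
    })


def expected_event_count(
    participants: pd.DataFrame,
    true_quartiles: pd.DataFrame,
    effects: list[EffectSpec],
    config: CohortConfig,
    outcomes: tuple[str, ...] | None = None,
) -> float:
    """Closed-form expected number of events among ``outcomes``.

    Under the all-cause exponential model, a participant with cause hazard
    ``lam_c`` and total hazard ``Lam`` (all planted causes + dropout + death)
    experiences cause c first with probability
    ``lam_c / Lam * (1 - exp(-Lam * T))`` before the administrative horizon
    ``T``.  Used to calibrate baseline hazards to a target case count.
    """
    hazards = _cause_hazards(participants, true_quartiles, effects)
    if outcomes is None:
        outcomes = tuple(hazards)
    total = sum(hazards.values()) + config.dropout_rate + config.death_rate
    keep = ~participants["no_followup"].to_numpy(dtype=bool)
    expected = 0.0
    for c in outcomes:
        if c not in hazards:
            continue
        frac = hazards[c] / total * (1.0 - np.exp(-total * config.followup_years))
        expected += float(frac[keep].sum())
    return expected


def calibrate_baseline_hazard(
    participants: pd.DataFrame,
    true_quartiles: pd.DataFrame,
    effects: list[EffectSpec],
    config: CohortConfig,
    target_events: float,
    outcomes: tuple[str, ...] | None = None,
) -> list[EffectSpec]:
    """Rescale all baseline hazards so the expected event count hits a target.

    Finds the common multiplier s on every effect's ``baseline_hazard`` such
    that the closed-form expected count of ``outcomes`` equals
    ``target_events``; returns rescaled copies of the effects.
    """
    def count_at(log_s: float) -> float:
        s = np.exp(log_s)
        scaled = [
            EffectSpec(e.outcome, e.exposure_index, e.log_hr_by_quartile,
                       e.baseline_hazard * s, e.covariate_log_hrs)
            for e in effects
        ]
        return expected_event_count(participants, true_quartiles, scaled, config, outcomes)

    sol = optimize.brentq(lambda ls: count_at(ls) - target_events, -12.0, 6.0, xtol=1e-10)
    s = float(np.exp(sol))
    return [
        EffectSpec(e.outcome, e.exposure_index, e.log_hr_by_quartile,
                   e.baseline_hazard * s, e.covariate_log_hrs)
        for e in effects
    ]


EXCLUSION_CRITERIA = (
    "missing_ffq",
    "extreme_energy",
    "baseline_disease",
    "no_followup",
    "missing_covariates",
)


def apply_exclusions(
    participants: pd.DataFrame,
    exposures: pd.DataFrame,
    followup: pd.DataFrame | None = None,
    group_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, dict[str, int]]:
    """Apply the participant exclusion cascade in its stated order.

    Participants are removed if they have (1) any missing wave-1 FFQ intake,
    (2) wave-1 energy intake < 500 or > 5000 kcal/day, (3) a baseline
    CVD/cancer diagnosis, (4) no follow-up after baseline, or (5) any missing
    covariate.  Each participant is tallied at the first criterion they meet.
    Returns the retained tables and the per-criterion tally; tally counts
    plus the retained count always sum to the input count.
    """
    if group_names is None:
        group_names = [g for g in default_taxonomy().group_names if g in exposures.columns]
    wave1 = exposures.loc[exposures["wave"] == 1].set_index("id")
    missing_ids = set(participants["id"]) - set(wave1.index)
    if missing_ids:
        raise KeyError(f"participants without a wave-1 exposure record: {sorted(missing_ids)[:5]}")
    w1 = wave1.loc[participants["id"]]

    masks = {
        "missing_ffq": w1[group_names].isna().any(axis=1).to_numpy(),
        "extreme_energy": ((w1["energy"] < 500) | (w1["energy"] > 5000)).to_numpy(),
        "baseline_disease": participants["baseline_disease"].to_numpy(dtype=bool)
        if "baseline_disease" in participants else np.zeros(len(participants), bool),
        "no_followup": participants["no_followup"].to_numpy(dtype=bool)
        if "no_followup" in participants else np.zeros(len(participants), bool),
        "missing_covariates": participants[
            [c for c in COVARIATE_COLUMNS if c in participants.columns]
        ].isna().any(axis=1).to_numpy(),
    }

    assigned = np.zeros(len(participants), dtype=bool)
    tally: dict[str, int] = {}
    for crit in EXCLUSION_CRITERIA:
        hit = masks[crit] & ~assigned
        tally[crit] = int(hit.sum())
        assigned |= masks[crit]

    keep_ids = participants.loc[~assigned, "id"]
    kept_p = participants.loc[~assigned].reset_index(drop=True)
    kept_e = exposures.loc[exposures["id"].isin(set(keep_ids))].reset_index(drop=True)
    kept_f = None
    if followup is not None:
        kept_f = followup.loc[followup["id"].isin(set(keep_ids))].reset_index(drop=True)
    return kept_p, kept_e, kept_f, tally
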