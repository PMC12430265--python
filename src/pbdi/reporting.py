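"""Cohort summary tables, risk tables, and the end-to-end pipeline.

Assembles baseline-characteristics tables across index quartiles, risk
tables (cases / person-years / HRs / p-trend per index and outcome), spline
curve exports, and a ``run_pipeline`` driver that wires
simulate -> exclude -> score -> fit -> report with every seed, threshold and
convention echoed to a provenance log.  Numeric outputs are deterministic
under a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diet_index, survival_analysis as surv
from .diet_index import INDICES, QUANTILE_DEF, score_cohort
from .ffq_processing import (
    FOOD_CLASSES,
    FoodGroupTaxonomy,
    cumulative_average_table,
    default_taxonomy,
)
from .synthetic_cohort import (
    CohortConfig,
    EffectSpec,
    apply_exclusions,
    calibrate_baseline_hazard,
    generate_cohort,
    simulate_followup,
)

logger = logging.getLogger("pbdi")

CONTINUOUS_SUMMARY = (
    "age", "smoking_packyears", "alcohol_g_day", "bmi", "physical_activity",
)
CATEGORICAL_SUMMARY = {
    "female": lambda p: p["sex"] == "female",
    "urban": lambda p: p["area"] == "urban",
    "hypertensive": lambda p: p["hypertension"].astype(bool),
    "family_history_cvd": lambda p: p["family_history_cvd"].astype(bool),
}


def _content_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=float).encode()
    ).hexdigest()[:12]


def make_table1(
    participants: pd.DataFrame,
    scores: diet_index.IndexScores,
    exposures_wave1: pd.DataFrame,
    taxonomy: FoodGroupTaxonomy,
    quartiles: tuple[int, ...] = (1, 4),
) -> pd.DataFrame:
    """Baseline characteristics across extreme quartiles of each index.

    Continuous covariates as mean +/- SD, categoricals as n (%), plus the
    three food-class servings/day and total energy.  Quartile sizes across
    all four quartiles always partition the cohort.
    """
    pt = participants.set_index("id")
    w1 = exposures_wave1.set_index("id").loc[pt.index]
    class_servings = {
        cls: w1[taxonomy.names_of_class(cls)].sum(axis=1) for cls in FOOD_CLASSES
    }
    rows = []
    for index_name in INDICES:
        q = scores.quartiles[index_name]
        totals = scores.totals[index_name]
        for qk in quartiles:
            sel = q.index[q == qk]
            if len(sel) == 0:
                raise ValueError(f"empty quartile {qk} for {index_name}")
            sub = pt.loc[sel]
            row = {
                "index": index_name,
                "quartile": qk,
                "n": len(sel),
                "median_score": float(totals.loc[sel].median()),
                "score_min": float(totals.loc[sel].min()),
                "score_max": float(totals.loc[sel].max()),
                "energy_mean": float(w1.loc[sel, "energy"].mean()),
                "energy_sd": float(w1.loc[sel, "energy"].std()),
            }
            for c in CONTINUOUS_SUMMARY:
                row[f"{c}_mean"] = float(sub[c].mean())
                row[f"{c}_sd"] = float(sub[c].std())
            for name, fn in CATEGORICAL_SUMMARY.items():
                flag = fn(sub)
                row[f"{name}_n"] = int(flag.sum())
                row[f"{name}_pct"] = float(100.0 * flag.mean())
            for cls in FOOD_CLASSES:
                row[f"{cls}_servings_mean"] = float(class_servings[cls].loc[sel].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def make_table3(
    fits: dict[tuple[str, str], dict],
) -> pd.DataFrame:
    """Risk table: cases/total, person-years, HRs with CIs and p-trend.

    ``fits`` maps (index, outcome) to a dict with keys ``multivariable``
    and optionally ``age_sex`` (CoxFitResult), ``p_trend``, ``cases_by_quartile``,
    ``total_by_quartile``, ``person_years_by_quartile``.  Non-converged fits
    are rendered as flagged cells, never fabricated.
    """
    rows = []
    for (index_name, outcome), d in fits.items():
        for qk in (1, 2, 3, 4):
            row = {
                "index": index_name,
                "outcome": outcome,
                "quartile": qk,
                "cases": d["cases_by_quartile"].get(qk, 0),
                "total": d["total_by_quartile"].get(qk, 0),
                "person_years": d["person_years_by_quartile"].get(qk, 0.0),
            }
            for model_key in ("age_sex", "multivariable"):
                fit = d.get(model_key)
                if fit is None:
                    continue
                if qk == 1:
                    row[f"hr_{model_key}"], row[f"ci_lo_{model_key}"], row[f"ci_hi_{model_key}"] = 1.0, np.nan, np.nan
                elif not fit.converged:
                    row[f"hr_{model_key}"] = np.nan
                    row[f"flag_{model_key}"] = "non-converged"
                else:
                    hr, lo, hi = fit.hr_by_quartile[qk]
                    row[f"hr_{model_key}"] = hr
                    row[f"ci_lo_{model_key}"] = lo
                    row[f"ci_hi_{model_key}"] = hi
            row["p_trend"] = d.get("p_trend", np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Configuration of a full simulate -> report run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: list[EffectSpec] = field(default_factory=list)
    indices: tuple[str, ...] = INDICES
    outcomes: tuple[str, ...] = ("CVD", "CHD", "stroke")
    target_events: float | None = None      # calibrate baseline hazards if set
    target_outcomes: tuple[str, ...] | None = None
    sensitivity_window_years: float = 2.0
    run_spline: bool = True
    run_ph_test: bool = True
    run_interactions: bool = False          # heavy; off by default

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort = CohortConfig(**d.get("cohort", {}))
        effects = [EffectSpec(**e) for e in d.get("effects", [])]
        kw = {k: v for k, v in d.items() if k not in ("cohort", "effects")}
        if "indices" in kw:
            kw["indices"] = tuple(kw["indices"])
        if "outcomes" in kw:
            kw["outcomes"] = tuple(kw["outcomes"])
        return cls(cohort=cohort, effects=effects, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def score_analysis_cohort(
    participants: pd.DataFrame,
    exposures: pd.DataFrame,
    taxonomy: FoodGroupTaxonomy,
):
    """Score both exposure segments of the analysis cohort.

    Returns ``(scores_a, scores_b, exposure_frames)`` where
    ``exposure_frames[index] = (frame_a, frame_b)`` each holding ``total``,
    ``quartile`` and ``energy`` per participant — the inputs to
    person-time construction.  Quintiles and quartiles are computed
    separately on each segment's cohort-wide distribution, through the same
    code path.
    """
    groups = taxonomy.group_names
    seg_a, seg_b = cumulative_average_table(exposures, groups)
    seg_a = seg_a.loc[participants["id"]]
    seg_b = seg_b.loc[participants["id"]]
    scores_a = score_cohort(seg_a, taxonomy)
    scores_b = score_cohort(seg_b, taxonomy)
    frames = {}
    for index_name in INDICES:
        fa = pd.DataFrame({
            "total": scores_a.totals[index_name],
            "quartile": scores_a.quartiles[index_name],
            "energy": seg_a["energy"],
        })
        fb = pd.DataFrame({
            "total": scores_b.totals[index_name],
            "quartile": scores_b.quartiles[index_name],
            "energy": seg_b["energy"],
        })
        frames[index_name] = (fa, fb)
    return scores_a, scores_b, frames


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    taxonomy: FoodGroupTaxonomy | None = None,
    write_png: bool = False,
) -> dict:
    """Run the full pipeline and write all artifacts to ``out_dir``.

    Stages: simulate -> exclude -> score -> fit -> report.  Any stage
    failure aborts with the stage name.  Returns a dict of in-memory
    results (tables, fits, spline curves) in addition to the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = taxonomy or default_taxonomy()

    log_path = out / "log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "configure"
    try:
        cfg_dict = {
            "cohort": asdict(config.cohort),
            "effects": [asdict(e) for e in config.effects],
            "indices": list(config.indices),
            "outcomes": list(config.outcomes),
        }
        taxo_dict = [
            {"name": g.name, "class": g.food_class, "items": list(g.items)}
            for g in taxonomy.groups
        ]
        logger.info("config hash %s", _content_hash(cfg_dict))
        logger.info("taxonomy hash %s", _content_hash(taxo_dict))
        logger.info("quantile convention: %s", QUANTILE_DEF)
        logger.info("seed %d", config.cohort.seed)

        stage = "simulate"
        participants, exposures = generate_cohort(config.cohort)
        wave1 = exposures.loc[exposures["wave"] == 1]
        clean = wave1.set_index("id")[taxonomy.group_names + ["energy"]].dropna()
        truth_scores = score_cohort(clean, taxonomy)
        effects = config.effects
        if effects and config.target_events:
            effects = calibrate_baseline_hazard(
                participants, truth_scores.quartiles.reindex(participants["id"]).fillna(1).astype(int),
                effects, config.cohort, config.target_events,
                config.target_outcomes,
            )
            logger.info("calibrated baseline hazards: %s",
                        {e.outcome: e.baseline_hazard for e in effects})
        true_q = truth_scores.quartiles.reindex(participants["id"]).fillna(1).astype(int)
        followup = simulate_followup(participants, true_q, effects, config.cohort)

        stage = "exclude"
        kept_p, kept_e, kept_f, tally = apply_exclusions(
            participants, exposures, followup, taxonomy.group_names
        )
        logger.info("exclusion tally %s retained %d", tally, len(kept_p))

        stage = "score"
        scores_a, scores_b, frames = score_analysis_cohort(kept_p, kept_e, taxonomy)

        stage = "fit"
        fits: dict[tuple[str, str], dict] = {}
        splines = {}
        for index_name in config.indices:
            fa, fb = frames[index_name]
            for outcome in config.outcomes:
                ds = surv.build_persontime(
                    kept_p, kept_f, fa, fb, outcome,
                    split_time=config.cohort.wave2_offset_years,
                )
                entry: dict = {}
                entry["age_sex"] = surv.fit_cox(ds, model="age_sex")
                fit = surv.fit_cox(ds, model="multivariable")
                entry["multivariable"] = fit
                _, medians, _ = diet_index.assign_quartiles(
                    ds.loc[ds["start"] == 0, "total"]
                )
                qm = {int(k): v for k, v in medians.items()}
                entry["p_trend"] = surv.trend_test(ds, qm)
                if config.run_ph_test:
                    entry["ph_test"] = surv.ph_test(fit)
                    fit.ph_test_p = entry["ph_test"].global_p
                if config.run_spline:
                    spline = surv.fit_spline(ds)
                    splines[(index_name, outcome)] = spline
                if config.run_interactions:
                    entry["interactions"] = surv.interaction_tests(ds, qm)
                entry["sensitivity"] = surv.sensitivity_exclude_early(
                    ds, config.sensitivity_window_years
                )
                last = ds.loc[ds.groupby("id")["stop"].idxmax()]
                entry["cases_by_quartile"] = last.loc[last["event"] == 1].groupby("quartile").size().to_dict()
                entry["total_by_quartile"] = last.groupby("quartile").size().to_dict()
                entry["person_years_by_quartile"] = (
                    (ds["stop"] - ds["start"]).groupby(ds["quartile"]).sum().to_dict()
                )
                fits[(index_name, outcome)] = entry

        stage = "report"
        table1 = make_table1(kept_p, scores_a, kept_e.loc[kept_e["wave"] == 1], taxonomy)
        table3 = make_table3(fits)

        participants.to_csv(out / "participants.csv", index=False)
        exposures.to_csv(out / "exposures.csv", index=False)
        followup.to_csv(out / "followup.csv", index=False)
        scores_csv = scores_a.totals.join(
            scores_a.quartiles, lsuffix="_total", rsuffix="_quartile"
        )
        scores_csv.to_csv(out / "scores.csv")
        table1.to_csv(out / "table1.csv", index=False)
        table3.to_csv(out / "table3.csv", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump({"tally": tally, "retained": len(kept_p)}, fh, indent=2)
        for (index_name, outcome), entry in fits.items():
            payload = _fit_payload(entry, index_name, outcome, config)
            with open(out / f"fit_{index_name}_{outcome}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
        for (index_name, outcome), spline in splines.items():
            curve = pd.DataFrame({
                "total": spline.grid, "log_hr": spline.log_hr,
                "ci_lo": spline.lo, "ci_hi": spline.hi,
            })
            curve.to_csv(out / f"spline_{index_name}_{outcome}.csv", index=False)
            if write_png:
                _spline_png(curve, out / f"spline_{index_name}_{outcome}.png",
                            index_name, outcome)

        logger.info("pipeline complete: %d fits", len(fits))
        return {
            "participants": kept_p, "followup": kept_f, "scores": scores_a,
            "fits": fits, "splines": splines, "table1": table1,
            "table3": table3, "exclusion_tally": tally,
        }
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _fit_payload(entry: dict, index_name: str, outcome: str, config: PipelineConfig) -> dict:
    fit = entry["multivariable"]
    payload = {
        "index": index_name,
        "outcome": outcome,
        "model": "multivariable",
        "hr_by_quartile": {str(k): list(v) for k, v in fit.hr_by_quartile.items()},
        "p_trend": entry.get("p_trend"),
        "ph_test_p": fit.ph_test_p,
        "n_events": fit.n_events,
        "person_years": fit.person_years,
        "log_partial_likelihood": fit.log_partial_likelihood,
        "covariates": list(surv.MULTIVARIABLE_COVARIATES),
        "quantile_convention": QUANTILE_DEF,
        "seed": config.cohort.seed,
    }
    if "age_sex" in entry:
        payload["hr_by_quartile_age_sex"] = {
            str(k): list(v) for k, v in entry["age_sex"].hr_by_quartile.items()
        }
    sens = entry.get("sensitivity")
    if sens is not None:
        payload["sensitivity_hr_by_quartile"] = {
            str(k): list(v) for k, v in sens.hr_by_quartile.items()
        }
        payload["sensitivity_n_events"] = sens.n_events
    return payload


def _spline_png(curve: pd.DataFrame, path: Path, index_name: str, outcome: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["total"], np.exp(curve["log_hr"]), color="C0")
    ax.fill_between(curve["total"], np.exp(curve["ci_lo"]), np.exp(curve["ci_hi"]),
                    alpha=0.25, color="C0")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel(f"{index_name} score")
    ax.set_ylabel("Hazard ratio")
    ax.set_title(f"{index_name} vs {outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
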