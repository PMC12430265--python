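"""Plant-based diet index scoring: PDI, hPDI and uPDI.

Each of the 17 food groups is energy-adjusted with the residual method,
ranked into cohort quintiles, and scored 1–5.  Which groups are scored
positively (highest quintile → 5) and which in reverse (highest quintile → 1)
depends on the index:

* PDI  — all plant groups positive, animal groups reverse;
* hPDI — healthful plant groups positive, less-healthful plant and animal
  groups reverse;
* uPDI — less-healthful plant groups positive, healthful plant and animal
  groups reverse.

Totals are the sum of the 17 group scores, so every index spans 17–85.
Totals are grouped into cohort quartiles for the survival analysis, with the
per-quartile median score retained for trend modeling.

Conventions (fixed so results reproduce bit-for-bit): sample percentiles use
linear interpolation between order statistics; cutpoint intervals are
left-open/right-closed with the lowest interval closed, so equal adjusted
values always receive equal scores and tied totals never split across
quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ffq_processing import (
    ANIMAL,
    HEALTHY_PLANT,
    UNHEALTHY_PLANT,
    FoodGroupTaxonomy,
)

INDICES = ("PDI", "hPDI", "uPDI")

#: scoring direction per (index, food class); True = positive, False = reverse
SCORING_DIRECTION = {
    ("PDI", HEALTHY_PLANT): True,
    ("PDI", UNHEALTHY_PLANT): True,
    ("PDI", ANIMAL): False,
    ("hPDI", HEALTHY_PLANT): True,
    ("hPDI", UNHEALTHY_PLANT): False,
    ("hPDI", ANIMAL): False,
    ("uPDI", HEALTHY_PLANT): False,
    ("uPDI", UNHEALTHY_PLANT): True,
    ("uPDI", ANIMAL): False,
}

QUANTILE_DEF = "linear interpolation between order statistics; intervals (lo, hi]"


def residual_adjust(exposures: pd.DataFrame, group_names: list[str]) -> pd.DataFrame:
    """Energy-adjust group intakes with the residual method.

    For each food group, servings/day are regressed on total energy intake
    (kcal/day) by ordinary least squares across the cohort; the adjusted
    value is the residual plus the predicted intake at the cohort-mean
    energy, which for OLS with intercept equals ``raw − b·(energy − mean
    energy)``.  The cohort mean of each group is preserved exactly and the
    adjusted values are uncorrelated with energy.  Adjusted intakes may be
    negative; scoring uses ranks so no floor is applied.

    Degenerate inputs: if energy is constant across the cohort (fewer than
    two distinct values) the regression is undefined and raw intakes pass
    through unchanged; an all-constant group has slope zero and likewise
    passes through.
    """
    energy = exposures["energy"].to_numpy(dtype=float)
    if len(energy) < 3:
        raise ValueError("residual adjustment needs at least 3 participants")
    out = exposures.copy()
    e_centered = energy - energy.mean()
    denom = float(e_centered @ e_centered)
    if denom == 0.0:  # constant energy: passthrough
        return out
    for g in group_names:
        y = exposures[g].to_numpy(dtype=float)
        slope = float(e_centered @ (y - y.mean())) / denom
        out[g] = y - slope * e_centered
    return out


def quintile_scores(values: np.ndarray | pd.Series, direction: str = "positive") -> np.ndarray:
    """Score a cohort vector 1–5 by sample quintile.

    Cutpoints are the 20/40/60/80 sample percentiles (linear interpolation).
    ``direction='positive'`` maps the lowest fifth to 1 and the highest to 5;
    ``direction='reverse'`` mirrors the mapping.  Values equal to a cutpoint
    fall in the lower bin (left-open/right-closed intervals), so ties always
    share a score.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot score an empty vector")
    if direction not in ("positive", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    cuts = np.percentile(v, [20, 40, 60, 80], method="linear")
    scores = np.searchsorted(cuts, v, side="left") + 1
    if direction == "reverse":
        scores = 6 - scores
    return scores.astype(int)


@dataclass
class IndexScores:
    """Per-participant group scores, index totals and cohort quartiles."""

    group_scores: dict[str, pd.DataFrame]  # index name -> (participant x group) scores
    totals: pd.DataFrame                   # columns PDI, hPDI, uPDI (int)
    quartiles: pd.DataFrame | None = None  # columns PDI, hPDI, uPDI in {1..4}
    quartile_medians: dict[str, dict[int, float]] | None = None
    quartile_ranges: dict[str, dict[int, tuple[float, float]]] | None = None


def compute_indices(adjusted: pd.DataFrame, taxonomy: FoodGroupTaxonomy) -> IndexScores:
    """Compute PDI/hPDI/uPDI group scores and totals for a cohort.

    ``adjusted`` is the energy-adjusted wide table (one row per participant,
    one column per food group, indexed by participant id).
    """
    groups = taxonomy.group_names
    missing = [g for g in groups if g not in adjusted.columns]
    if missing:
        raise KeyError(f"adjusted intake table lacks groups: {missing}")

    group_scores: dict[str, pd.DataFrame] = {}
    totals = {}
    for index_name in INDICES:
        cols = {}
        for g in groups:
            positive = SCORING_DIRECTION[(index_name, taxonomy.class_of(g))]
            cols[g] = quintile_scores(
                adjusted[g], "positive" if positive else "reverse"
            )
        sc = pd.DataFrame(cols, index=adjusted.index)
        group_scores[index_name] = sc
        totals[index_name] = sc.sum(axis=1)
    return IndexScores(group_scores, pd.DataFrame(totals, index=adjusted.index))


def assign_quartiles(totals: pd.Series | np.ndarray) -> tuple[np.ndarray, dict[int, float], dict[int, tuple[float, float]]]:
    """Assign cohort quartiles of an index total.

    Cutpoints are the 25/50/75 sample percentiles; intervals are
    left-open/right-closed so participants with identical totals always share
    a quartile (quartile sizes may therefore be unequal).  Returns the labels
    (1–4), the per-quartile median, and the per-quartile (min, max) range —
    the medians feed the trend test.
    """
    v = np.asarray(totals, dtype=float)
    if v.size == 0:
        raise ValueError("cannot assign quartiles of an empty vector")
    cuts = np.percentile(v, [25, 50, 75], method="linear")
    labels = (np.searchsorted(cuts, v, side="left") + 1).astype(int)
    medians: dict[int, float] = {}
    ranges: dict[int, tuple[float, float]] = {}
    for q in np.unique(labels):
        vals = v[labels == q]
        medians[int(q)] = float(np.median(vals))
        ranges[int(q)] = (float(vals.min()), float(vals.max()))
    return labels, medians, ranges


def score_cohort(
    exposures: pd.DataFrame, taxonomy: FoodGroupTaxonomy
) -> IndexScores:
    """Full scoring pass on one cohort-wide exposure table.

    ``exposures`` has one row per participant (indexed by id) with one column
    per food group plus ``energy``.  Runs residual adjustment, quintile
    scoring for the three indices, and quartile categorization of the totals.
    """
    groups = taxonomy.group_names
    adjusted = residual_adjust(exposures, groups)
    scores = compute_indices(adjusted[groups], taxonomy)
    quart = {}
    medians = {}
    ranges = {}
    for index_name in INDICES:
        labels, med, rng = assign_quartiles(scores.totals[index_name])
        quart[index_name] = labels
        medians[index_name] = med
        ranges[index_name] = rng
    scores.quartiles = pd.DataFrame(quart, index=scores.totals.index)
    scores.quartile_medians = medians
    scores.quartile_ranges = ranges
    return scores
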