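"""Food-group taxonomy and longitudinal FFQ exposure processing.

Food-frequency-questionnaire (FFQ) items are collapsed into 17 food groups,
each belonging to one of three classes — healthful plant foods, less-healthful
plant foods, and animal-derived foods.  Group-level daily servings, together
with total energy intake, are the exposure unit for the plant-based diet
indices.  Two dietary waves are combined into a cumulative-average exposure
timeline: events before the second assessment relate to wave-1 intake, events
after it to the mean of the two waves; participants missing wave 2 carry
wave 1 forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

HEALTHY_PLANT = "healthy_plant"
UNHEALTHY_PLANT = "unhealthy_plant"
ANIMAL = "animal"

FOOD_CLASSES = (HEALTHY_PLANT, UNHEALTHY_PLANT, ANIMAL)

#: energy density of the macronutrients, kcal per gram
KCAL_PER_GRAM = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class FoodGroup:
    name: str
    food_class: str
    items: tuple[str, ...] = ()

    def __post_init__(self):
        if self.food_class not in FOOD_CLASSES:
            raise ValueError(f"unknown food class {self.food_class!r}")


@dataclass(frozen=True)
class FoodGroupTaxonomy:
    """Ordered collection of food groups with class labels and member items."""

    groups: tuple[FoodGroup, ...]

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in taxonomy")
        items = [it for g in self.groups for it in g.items]
        if len(set(items)) != len(items):
            raise ValueError("an FFQ item may belong to only one group")
        for cls in FOOD_CLASSES:
            if not any(g.food_class == cls for g in self.groups):
                raise ValueError(f"taxonomy has no group of class {cls!r}")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def names_of_class(self, food_class: str) -> list[str]:
        return [g.name for g in self.groups if g.food_class == food_class]

    @property
    def plant_groups(self) -> list[str]:
        return self.names_of_class(HEALTHY_PLANT) + self.names_of_class(UNHEALTHY_PLANT)

    def class_of(self, group: str) -> str:
        for g in self.groups:
            if g.name == group:
                return g.food_class
        raise KeyError(group)

    def item_to_group(self) -> dict[str, str]:
        return {it: g.name for g in self.groups for it in g.items}

    def to_yaml(self, path) -> None:
        payload = [
            {"name": g.name, "class": g.food_class, "items": list(g.items)}
            for g in self.groups
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FoodGroupTaxonomy":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            tuple(
                FoodGroup(d["name"], d["class"], tuple(d.get("items", ())))
                for d in payload
            )
        )


def default_taxonomy() -> FoodGroupTaxonomy:
    """The default 17-group taxonomy.

    Six healthful-plant groups (tea and coffee combined into one), five
    less-healthful-plant groups (pickled vegetables and fermented sauces
    combined), and six animal groups.  Member items are representative FFQ
    items of a Korean cohort questionnaire; the taxonomy is user-overridable
    via YAML.
    """
    g = FoodGroup
    return FoodGroupTaxonomy((
        g("whole_grains", HEALTHY_PLANT, ("barley_rice", "brown_rice", "multigrain_rice", "oats")),
        g("vegetables", HEALTHY_PLANT, ("spinach", "cabbage", "radish", "cucumber", "carrot", "pumpkin", "mushroom", "seaweed")),
        g("fruits", HEALTHY_PLANT, ("apple", "pear", "persimmon", "citrus", "grape", "watermelon", "banana")),
        g("legumes", HEALTHY_PLANT, ("tofu", "soymilk", "soybeans", "mung_beans")),
        g("nuts", HEALTHY_PLANT, ("peanut", "pine_nut", "almond")),
        g("tea_coffee", HEALTHY_PLANT, ("green_tea", "coffee")),
        g("refined_grains", UNHEALTHY_PLANT, ("white_rice", "noodles", "white_bread", "rice_cake")),
        g("potatoes", UNHEALTHY_PLANT, ("potato", "sweet_potato")),
        g("sugar_sweetened_beverages", UNHEALTHY_PLANT, ("soda", "sweetened_juice", "sports_drink")),
        g("sweets_desserts", UNHEALTHY_PLANT, ("candy", "chocolate", "cookies", "ice_cream")),
        g("pickled_vegetables_sauces", UNHEALTHY_PLANT, ("kimchi", "pickled_radish", "soybean_paste", "red_pepper_paste")),
        g("meat", ANIMAL, ("beef", "pork", "chicken", "processed_meat")),
        g("fish", ANIMAL, ("mackerel", "anchovy", "squid", "shellfish", "fish_paste")),
        g("eggs", ANIMAL, ("egg",)),
        g("dairy", ANIMAL, ("milk", "yogurt", "cheese")),
        g("animal_fats", ANIMAL, ("butter", "lard")),
        g("other_animal_foods", ANIMAL, ("organ_meat", "animal_broth")),
    ))


N_GROUPS = 17


def map_items_to_groups(
    item_intakes: dict[str, float], taxonomy: FoodGroupTaxonomy
) -> dict[str, float]:
    """Collapse item-level servings/day into group-level servings/day.

    Every reported item must belong to the taxonomy; unmapped items raise
    ``KeyError`` rather than being silently dropped, so that totals are
    conserved (sum over groups equals sum over items).
    """
    lookup = taxonomy.item_to_group()
    out = {name: 0.0 for name in taxonomy.group_names}
    for item, servings in item_intakes.items():
        if item not in lookup:
            raise KeyError(f"FFQ item {item!r} is not in the taxonomy")
        out[lookup[item]] += float(servings)
    return out


@dataclass
class ExposureTimeline:
    """Two-segment exposure series for one participant.

    ``segment_a`` applies from baseline to the wave-2 assessment date,
    ``segment_b`` from the wave-2 date onward (cumulative average of the two
    waves, or wave 1 carried forward when wave 2 is missing).
    """

    id: object
    segment_a: dict[str, float]
    segment_b: dict[str, float]
    energy_a: float
    energy_b: float


def cumulative_average(
    wave1: pd.Series | dict, wave2: pd.Series | dict | None, group_names: list[str]
) -> ExposureTimeline:
    """Build the two-segment cumulative-average timeline for one participant.

    Segment A always carries wave-1 intake.  Segment B carries the arithmetic
    mean of the two waves when wave 2 was collected, and wave 1 carried
    forward otherwise.  Segment A never depends on wave 2.
    """
    w1 = dict(wave1)
    seg_a = {g: float(w1[g]) for g in group_names}
    energy_a = float(w1["energy"])
    if wave2 is None:
        return ExposureTimeline(w1.get("id"), seg_a, dict(seg_a), energy_a, energy_a)
    w2 = dict(wave2)
    if "id" in w1 and "id" in w2 and w1["id"] != w2["id"]:
        raise ValueError(f"wave-1 id {w1['id']!r} does not match wave-2 id {w2['id']!r}")
    seg_b = {g: (seg_a[g] + float(w2[g])) / 2.0 for g in group_names}
    energy_b = (energy_a + float(w2["energy"])) / 2.0
    return ExposureTimeline(w1.get("id"), seg_a, seg_b, energy_a, energy_b)


def cumulative_average_table(
    exposures: pd.DataFrame, group_names: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized two-segment timeline for a whole cohort.

    ``exposures`` is wide-format with columns ``id``, ``wave`` (1 or 2), one
    column per food group, and ``energy``.  Returns ``(segment_a, segment_b)``
    tables indexed by participant id.
    """
    cols = group_names + ["energy"]
    w1 = exposures.loc[exposures["wave"] == 1].set_index("id")[cols]
    w2 = exposures.loc[exposures["wave"] == 2].set_index("id")[cols]
    seg_a = w1.copy()
    # participants without a wave-2 record keep wave 1 (carry-forward)
    common = w1.index.intersection(w2.index)
    seg_b = w1.copy()
    seg_b.loc[common] = (w1.loc[common] + w2.loc[common]) / 2.0
    return seg_a, seg_b


@dataclass
class NutrientSummary:
    """Macronutrients as % of energy; micronutrients per 1000 kcal."""

    macronutrient_pct_energy: dict[str, float]
    micronutrients_per_1000kcal: dict[str, float]
    energy: float

    @property
    def macronutrient_closure(self) -> float:
        return sum(self.macronutrient_pct_energy.values())


def nutrient_summary(
    group_servings: dict[str, float],
    energy: float,
    nutrient_table: pd.DataFrame,
) -> NutrientSummary:
    """Summarize nutrient density of one exposure record.

    ``nutrient_table`` is indexed by food-group name with one column per
    nutrient: ``carbohydrate``/``protein``/``fat`` in grams per serving and
    any further columns in amount per serving.  Macronutrients are converted
    to percent of total energy using 4/4/9 kcal per gram; all other nutrients
    are scaled to amount per 1000 kcal.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    missing = set(group_servings) - set(nutrient_table.index)
    if missing:
        raise KeyError(f"nutrient table lacks groups: {sorted(missing)}")
    servings = pd.Series(group_servings, dtype=float)
    totals = nutrient_table.loc[servings.index].mul(servings, axis=0).sum(axis=0)
    macro = {
        m: 100.0 * totals[m] * KCAL_PER_GRAM[m] / energy
        for m in KCAL_PER_GRAM
        if m in totals.index
    }
    micro = {
        c: 1000.0 * totals[c] / energy
        for c in totals.index
        if c not in KCAL_PER_GRAM
    }
    return NutrientSummary(macro, micro, energy)
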