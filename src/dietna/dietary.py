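"""Dietary sodium estimation instruments.

Five scorers are implemented:

* ``mean_recall_na`` — mean sodium over up to three itemised 24-h dietary
  recalls (if fewer than three are available the mean of the rest is used);
* ``dr_plus_sq_na`` — the recall mean plus discretionary salt quantified
  from two per-meal questions (cooking salt on a four-level scale, table
  salt yes/no with "yes" worth two dashes of salt = 775 mg Na);
* ``dr_plus_15_na`` — the recall mean corrected for discretionary salt
  under the assumption that cooking/table salt is 15% of total intake;
* ``ffq_total_na`` on a standard semi-quantitative FFQ — frequency weight
  x portion x sodium density from a food-composition table;
* the same scorer on the sodium-extended NaFFQ, whose food list adds
  Na-rich items and whose question b quantifies salt added to cooked meals
  and salads on a five-level mg-per-100 g scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Daily-frequency weights of the six FFQ consumption categories.
FREQUENCY_WEIGHTS = {
    "never": 0.0,
    "1-3_per_month": 0.07,
    "1-2_per_week": 0.21,
    "3-6_per_week": 0.64,
    "1_per_day": 1.0,
    "2plus_per_day": 2.0,
}

#: Cooking-salt question (Q1): mg of Na per 100 g of food for each answer.
Q1_RATES = {"none": 0.0, "little": 50.0, "moderate": 350.0, "a_lot": 600.0}

#: Table-salt question (Q2): one dash of salt contributes 387.5 mg Na, so
#: the default "yes" (two dashes) is worth 775 mg.
NA_MG_PER_DASH = 387.5

#: NaFFQ question b: mg of Na per 100 g of cooked meal / salad.
QUESTION_B_RATES = {
    "none": 0.0,
    "little": 50.0,
    "moderate": 350.0,
    "much": 600.0,
    "very_much": 900.0,
}

MAIN_MEALS = ("breakfast", "lunch", "dinner")


@dataclass(frozen=True)
class Meal:
    name: str  # breakfast | lunch | dinner | other
    items: tuple  # of (grams, na_mg_per_100g)
    q1: str | None = None
    q2: str | None = None

    def __post_init__(self):
        if self.name not in MAIN_MEALS + ("other",):
            raise ValueError(f"unknown meal name {self.name!r}")
        if self.name == "other" and (self.q1 is not None or self.q2 is not None):
            raise ValueError("salt questions are only asked for breakfast/lunch/dinner")
        for grams, na100 in self.items:
            if grams < 0 or na100 < 0:
                raise ValueError("grams and na_mg_per_100g must be non-negative")

    @property
    def grams(self) -> float:
        return sum(g for g, _ in self.items)

    @property
    def na_mg(self) -> float:
        return sum(g * c / 100.0 for g, c in self.items)


@dataclass(frozen=True)
class DietaryRecall:
    participant_id: str
    recall_idx: int
    meals: tuple

    def __post_init__(self):
        if not 1 <= self.recall_idx <= 3:
            raise ValueError("recall_idx must be in 1..3")
        names = [m.name for m in self.meals]
        if len(names) != len(set(names)):
            raise ValueError("meal names must be unique within a recall")


@dataclass(frozen=True)
class FfqResponse:
    participant_id: str
    version: str  # "standard" | "naffq"
    items: tuple  # of (item_id, freq_cat, portion_g)
    question_b: str | None = None

    def __post_init__(self):
        if self.version not in ("standard", "naffq"):
            raise ValueError(f"unknown FFQ version {self.version!r}")
        if self.version == "naffq" and self.question_b is None:
            raise ValueError("question_b is required for the naffq version")
        if self.version == "standard" and self.question_b is not None:
            raise ValueError("question_b is only defined for the naffq version")
        for _, _, portion in self.items:
            if not portion > 0:
                raise ValueError("portion_g must be positive")


@dataclass(frozen=True)
class FoodCompositionTable:
    """item_id -> (Na mg/100 g, cooked-meal/salad flag, food group, NaFFQ flag)."""

    table: pd.DataFrame = field(repr=False)

    @classmethod
    def bundled(cls) -> "FoodCompositionTable":
        with resources.as_file(resources.files("dietna.data") / "composition.csv") as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path) -> "FoodCompositionTable":
        df = pd.read_csv(path)
        required = {"item_id", "na_mg_per_100g", "is_cooked_meal_or_salad"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"composition table missing columns {sorted(missing)}")
        if (df["na_mg_per_100g"] < 0).any():
            raise ValueError("na_mg_per_100g must be non-negative")
        return cls(df.set_index("item_id"))

    def na_per_100g(self, item_id: str) -> float:
        try:
            return float(self.table.loc[item_id, "na_mg_per_100g"])
        except KeyError:
            raise KeyError(f"unresolvable composition item {item_id!r}") from None

    def is_cooked_or_salad(self, item_id: str) -> bool:
        try:
            return bool(self.table.loc[item_id, "is_cooked_meal_or_salad"])
        except KeyError:
            raise KeyError(f"unresolvable composition item {item_id!r}") from None

    def is_naffq_addition(self, item_id: str) -> bool:
        if "naffq_addition" not in self.table.columns:
            return False
        return bool(self.table.loc[item_id, "naffq_addition"])


# ---------------------------------------------------------------------------
# recall scoring


def frequency_weight(cat: str) -> float:
    """Times-per-day weight of an FFQ frequency category."""
    try:
        return FREQUENCY_WEIGHTS[cat]
    except KeyError:
        raise ValueError(f"unknown frequency category {cat!r}") from None


def recall_na(recall: DietaryRecall) -> float:
    """Total sodium (mg) of one itemised 24-h recall."""
    return sum(m.na_mg for m in recall.meals)


def mean_recall_na(recalls) -> float:
    """Mean recall sodium (mg/day) over the available recalls.

    Zero recalls yield NaN (a missing estimate, not zero intake).
    """
    recalls = list(recalls)
    if not recalls:
        return float("nan")
    return float(np.mean([recall_na(r) for r in recalls]))


def q1_na(answer: str, meal_food_grams: float) -> float:
    """Cooking-salt sodium (mg) for one meal from the Q1 answer."""
    if answer not in Q1_RATES:
        raise ValueError(f"unknown Q1 answer {answer!r}")
    if meal_food_grams < 0:
        raise ValueError("meal_food_grams must be non-negative")
    return Q1_RATES[answer] * meal_food_grams / 100.0


def q2_na(answer: str, dashes_per_yes: int = 2) -> float:
    """Table-salt sodium (mg) for one meal from the Q2 answer."""
    if answer not in ("yes", "no"):
        raise ValueError(f"unknown Q2 answer {answer!r}")
    if dashes_per_yes not in (1, 2):
        raise ValueError("dashes_per_yes must be 1 or 2")
    return NA_MG_PER_DASH * dashes_per_yes if answer == "yes" else 0.0


def dr_plus_sq_na(recalls, dashes_per_yes: int = 2) -> float:
    """Recall mean plus discretionary salt from the two salt questions.

    For each recall, Q1 and Q2 sodium is summed over breakfast, lunch and
    dinner; the mean over recalls is added to the plain recall mean.
    Meals with missing answers contribute 0 with a warning.
    """
    recalls = list(recalls)
    base = mean_recall_na(recalls)
    if not recalls:
        return base
    per_recall = []
    for r in recalls:
        total = 0.0
        for meal in r.meals:
            if meal.name not in MAIN_MEALS:
                continue
            if meal.q1 is None or meal.q2 is None:
                warnings.warn(
                    f"recall {r.recall_idx} ({r.participant_id}): missing salt-question "
                    f"answer for {meal.name}; scored as 0",
                    stacklevel=2,
                )
            if meal.q1 is not None:
                total += q1_na(meal.q1, meal.grams)
            if meal.q2 is not None:
                total += q2_na(meal.q2, dashes_per_yes)
        per_recall.append(total)
    return base + float(np.mean(per_recall))


def dr_plus_15_na(mean_dr: float, share: float = 0.15, mode: str = "share_of_total") -> float:
    """Discretionary-salt correction of the recall mean.

    share_of_total (default): the recall captures (1 - share) of intake, so
    the corrected total is mean_dr / (1 - share). markup: mean_dr x (1 + share).
    """
    if mean_dr < 0:
        raise ValueError("mean_dr must be non-negative")
    if not 0 <= share < 0.5:
        raise ValueError("share must be in [0, 0.5)")
    if mode == "share_of_total":
        return mean_dr / (1.0 - share)
    if mode == "markup":
        return mean_dr * (1.0 + share)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# FFQ scoring


def ffq_item_na(freq_cat: str, portion_g: float, na_per_100g: float) -> float:
    """Daily sodium (mg/day) of one FFQ item."""
    if portion_g < 0 or na_per_100g < 0:
        raise ValueError("portion_g and na_per_100g must be non-negative")
    return frequency_weight(freq_cat) * portion_g * na_per_100g / 100.0


def ffq_total_na(response: FfqResponse, table: FoodCompositionTable) -> float:
    """Total daily sodium (mg/day) of an FFQ or NaFFQ response.

    NaFFQ responses additionally receive question-b sodium on every item
    flagged as a cooked meal or salad, at the answer's mg/100 g rate
    applied to the item's daily grams.
    """
    total = 0.0
    for item_id, freq_cat, portion_g in response.items:
        total += ffq_item_na(freq_cat, portion_g, table.na_per_100g(item_id))
    if response.version == "naffq":
        if response.question_b not in QUESTION_B_RATES:
            raise ValueError(f"unknown question_b answer {response.question_b!r}")
        rate = QUESTION_B_RATES[response.question_b]
        for item_id, freq_cat, portion_g in response.items:
            if table.is_cooked_or_salad(item_id):
                daily_grams = frequency_weight(freq_cat) * portion_g
                total += rate * daily_grams / 100.0
    return total
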