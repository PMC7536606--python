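"""Concrete diet-guideline knowledge: MIND lists and HHS/ADA meal bounds.

Three guideline families drive the recommender:

* **MIND diet** (Mediterranean–DASH Intervention for Neurodegenerative
  Delay): encourage vegetables, berries, nuts, olive oil, whole grains,
  fish, beans, poultry; limit butter, margarine, cheese, red meat,
  fried food, pastries, sweets.
* **HHS Dietary Guidelines**: for a man eating three meals per day, one
  meal should contain 800–850 kcal.
* **ADA Diabetes Guidelines**: dinner energy should be 25% of the
  Estimated Energy Requirement (EER); protein 20%–30% of meal energy;
  sugar below 10% of meal energy.

Percent-of-energy shares use the Atwater conversion factors (4/4/9 kcal
per gram of protein/carbohydrate/fat; sugar counts as carbohydrate at
4 kcal/g) against the tabulated meal energy. The guidelines are exposed
both as direct constraint functions and as Horn rules for the inference
engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .ontology_kb import (CaregiverProfile, KnowledgeBase, LookupError_,
                          PatientProfile, Recipe, ancestors_of_concept)

# Atwater energy conversion factors, kcal per gram
ATWATER_KCAL_PER_G = {"protein": 4.0, "carb": 4.0, "fat": 9.0}

# MIND food-category lists (class identifiers in the shipped ontology)
MIND_ENCOURAGE = frozenset({
    "Vegetables", "Berries", "Nuts", "OliveOil", "WholeGrains",
    "Fish", "Beans", "Poultry",
})
MIND_LIMIT = frozenset({
    "Butter", "Margarine", "Cheese", "RedMeat", "FriedFood",
    "Pastries", "Sweets",
})

PROV_MIND = "MIND diet"
PROV_HHS = "HHS Dietary Guidelines"
PROV_ADA = "ADA Diabetes Guidelines"
PROV_PROFILE = "patient/caregiver profile"

DIABETES_CONDITIONS = frozenset({"type2_diabetes", "type1_diabetes", "diabetes"})

# a recipe matches a point calorie target when within this fraction of it
DEFAULT_CALORIE_TOLERANCE = 0.05


class MissingDataError(Exception):
    """A rule needs a profile datum (e.g. EER) that is absent.

    The dialogue layer catches this to elicit the datum from the user.
    """

    def __init__(self, field: str, message: str = ""):
        self.field = field
        super().__init__(message or f"missing profile data: {field}")


@dataclass(frozen=True)
class MindClassification:
    value: str  # encourage | limit | neutral

    def __post_init__(self):
        if self.value not in ("encourage", "limit", "neutral"):
            raise ValueError(f"invalid MIND classification {self.value!r}")


@dataclass(frozen=True)
class Violation:
    """One failed guideline check, with the citation that backs it."""

    constraint: str
    observed: object
    bound: str
    provenance: str

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("violation must carry a provenance citation")

    def __str__(self):
        return (f"{self.constraint}: observed {self.observed}, "
                f"bound {self.bound} [{self.provenance}]")


def mind_classify(kb: KnowledgeBase, food_or_category: str) -> MindClassification:
    """Classify a food or category under the MIND encourage/limit lists.

    Classification is inherited through IS-A; when an item has both an
    encouraged and a limited ancestor, *limit* wins (conservative), but
    an item's own listing overrides any ancestor's.
    """
    concepts = ancestors_of_concept(kb, food_or_category)
    if food_or_category in MIND_LIMIT:
        return MindClassification("limit")
    if food_or_category in MIND_ENCOURAGE:
        return MindClassification("encourage")
    if concepts & MIND_LIMIT:
        return MindClassification("limit")
    if concepts & MIND_ENCOURAGE:
        return MindClassification("encourage")
    return MindClassification("neutral")


def is_diabetic(patient: PatientProfile) -> bool:
    return bool(patient.comorbidities & DIABETES_CONDITIONS)


# IOM physical-activity coefficients for adults (sedentary .. very active)
_PA_COEF = {
    "male": {"sedentary": 1.00, "low_active": 1.11,
             "active": 1.25, "very_active": 1.48},
    "female": {"sedentary": 1.00, "low_active": 1.12,
               "active": 1.27, "very_active": 1.45},
}
# reference anthropometrics for an older adult, used when the profile
# carries neither EER nor weight/height
_REFERENCE_BODY = {"male": (75.0, 176.0), "female": (65.0, 163.0)}


def estimated_energy_requirement(patient: PatientProfile) -> float:
    """Daily kcal need: profile EER if present, else the IOM adult equations.

    IOM (Institute of Medicine) adult EER:
      men:   662 − 9.53·age + PA·(15.91·weight_kg + 539.6·height_m)
      women: 354 − 6.91·age + PA·(9.36·weight_kg + 726·height_m)
    """
    if patient.eer is not None:
        return float(patient.eer)
    wt = patient.weight_kg
    ht_cm = patient.height_cm
    if wt is None or ht_cm is None:
        wt, ht_cm = _REFERENCE_BODY[patient.sex]
    ht = ht_cm / 100.0
    pa = _PA_COEF[patient.sex].get(patient.activity, 1.11 if patient.sex == "male" else 1.12)
    if patient.sex == "male":
        return 662.0 - 9.53 * patient.age + pa * (15.91 * wt + 539.6 * ht)
    return 354.0 - 6.91 * patient.age + pa * (9.36 * wt + 726.0 * ht)


def meal_calorie_target(patient: PatientProfile, meal: str) -> tuple[float, float]:
    """Target kcal range for one meal of the given type.

    Precedence: the disease-specific ADA rule (diabetic dinner = 25% of
    EER, a point target) wins over the HHS rule (man on three meals/day:
    800–850 kcal); every other demographic falls back to EER divided by
    meals per day, ±10% (a documented extension — the guidelines only
    state the two specific cases).
    """
    if is_diabetic(patient) and meal == "dinner":
        if patient.eer is None:
            raise MissingDataError(
                "eer", "the diabetic dinner target needs the patient's EER")
        t = 0.25 * patient.eer
        return (t, t)
    if patient.sex == "male" and patient.meals_per_day == 3:
        return (800.0, 850.0)
    eer = estimated_energy_requirement(patient)
    per_meal = eer / patient.meals_per_day
    return (0.9 * per_meal, 1.1 * per_meal)


def recipe_nutrients_per_serving(recipe: Recipe, kb: KnowledgeBase) -> dict[str, float]:
    """Sum ingredient nutrients (per 100 g basis) and divide by servings."""
    totals = {k: 0.0 for k in ("energy_kcal", "protein_g", "carb_g", "sugar_g",
                               "fat_g", "satfat_g", "fiber_g", "sodium_mg")}
    for fid, grams in recipe.ingredients:
        food = kb.foods.get(fid)
        if food is None:
            raise LookupError_(f"recipe {recipe.id!r}: unknown food {fid!r}")
        for k in totals:
            totals[k] += food.nutrients_per_100g[k] * grams / 100.0
    return {k: v / recipe.servings for k, v in totals.items()}


def energy_shares(nutrients: dict[str, float]) -> dict[str, float]:
    """Percent of tabulated meal energy from protein, sugar, fat (Atwater)."""
    energy = nutrients["energy_kcal"]
    if energy <= 0:
        return {"protein": 0.0, "sugar": 0.0, "fat": 0.0}
    return {
        "protein": 100.0 * ATWATER_KCAL_PER_G["protein"] * nutrients["protein_g"] / energy,
        "sugar": 100.0 * ATWATER_KCAL_PER_G["carb"] * nutrients["sugar_g"] / energy,
        "fat": 100.0 * ATWATER_KCAL_PER_G["fat"] * nutrients["fat_g"] / energy,
    }


def _excluded_by(kb: KnowledgeBase, food_id: str,
                 excluded: frozenset[str]) -> str | None:
    """The excluded concept hit by the food itself or an IS-A ancestor."""
    if food_id in excluded:
        return food_id
    hits = ancestors_of_concept(kb, food_id) & excluded
    return sorted(hits)[0] if hits else None


def check_meal_constraints(
        recipe: Recipe, patient: PatientProfile, caregiver: CaregiverProfile,
        kb: KnowledgeBase, meal: str = "dinner",
        tolerance: float = DEFAULT_CALORIE_TOLERANCE) -> list[Violation]:
    """Evaluate every guideline and profile constraint against one recipe.

    Returns one Violation per failed check; an empty list means the
    recipe is admissible for this patient, caregiver and meal slot.
    Checks: calorie target, ADA protein/sugar shares (diabetic meals),
    allergy / religious / dislike exclusions (IS-A aware), prep time,
    and cost per serving against the caregiver's budget.
    """
    violations: list[Violation] = []
    nutrients = recipe_nutrients_per_serving(recipe, kb)
    energy = nutrients["energy_kcal"]

    lo, hi = meal_calorie_target(patient, meal)
    if lo == hi:  # point target (ADA): apply the ± tolerance band
        lo, hi = lo * (1 - tolerance), hi * (1 + tolerance)
        prov = PROV_ADA
    elif patient.sex == "male" and patient.meals_per_day == 3 and not (
            is_diabetic(patient) and meal == "dinner"):
        prov = PROV_HHS
    else:
        prov = PROV_HHS + " (EER/meals extension)"
    if not (lo <= energy <= hi):
        violations.append(Violation(
            "calorie_target", round(energy, 1),
            f"[{lo:.1f}, {hi:.1f}] kcal", prov))

    if is_diabetic(patient):
        shares = energy_shares(nutrients)
        if not (20.0 <= shares["protein"] <= 30.0):
            violations.append(Violation(
                "protein_share", round(shares["protein"], 1),
                "[20%, 30%] of meal energy", PROV_ADA))
        if not (shares["sugar"] < 10.0):
            violations.append(Violation(
                "sugar_share", round(shares["sugar"], 1),
                "< 10% of meal energy", PROV_ADA))

    for fid, _ in recipe.ingredients:
        hit = _excluded_by(kb, fid, patient.allergies)
        if hit is not None:
            violations.append(Violation(
                "allergy", fid, f"excluded: allergic to {hit}", PROV_PROFILE))
        hit = _excluded_by(kb, fid, patient.religious_constraints)
        if hit is not None:
            violations.append(Violation(
                "religious_exclusion", fid,
                f"excluded by religious constraint on {hit}", PROV_PROFILE))
        if fid in patient.dislikes:
            violations.append(Violation(
                "dislike", fid, "patient dislikes this food", PROV_PROFILE))

    if recipe.prep_time > caregiver.time_limit:
        violations.append(Violation(
            "prep_time", recipe.prep_time,
            f"<= {caregiver.time_limit} min available", PROV_PROFILE))
    if recipe.cost > caregiver.budget:
        violations.append(Violation(
            "cost", recipe.cost,
            f"<= {caregiver.budget} per meal", PROV_PROFILE))
    return violations


def builtin_rule_text() -> str:
    """The guideline knowledge as an SWRL-like rule file (text form).

    The same lists that back the direct constraint functions, rendered
    for the inference engine so suitability questions can be answered by
    backward chaining with a citable trace.
    """
    lines = ["# provenance: " + PROV_MIND]
    for cls in sorted(MIND_ENCOURAGE):
        lines.append(f"{cls}(?f) -> MindEncouraged(?f)")
    for cls in sorted(MIND_LIMIT):
        lines.append(f"{cls}(?f) -> MindLimited(?f)")
    lines.append("# provenance: " + PROV_ADA)
    lines.append(
        "Food(?f) ^ sugar_g(?f, ?s) ^ energy_kcal(?f, ?e) ^ "
        "greaterThan(?e, 0) -> HasSugarData(?f)")
    return "\n".join(lines) + "\n"
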