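"""Back-end diet management services.

Each service combines the knowledge base, the inference engine and the
guideline constraints into a personalized answer:

* suitability checks ("is cheese good as a snack?") yield a Verdict
  with cited reasons;
* snack suggestion ranks admissible snack-class foods, MIND-encouraged
  first;
* recipe recommendation filters by meal type, profile exclusions and
  every guideline bound, ranks the survivors, and honors rejections
  within the session;
* diet history records meals append-only and recalls daily or weekly
  summaries;
* the tip service cycles deterministically through tips matching a
  category and ADRD stage, rendered per education tier.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .dialogue_manager import DialogueSession
from .guideline_rules import (PROV_ADA, PROV_MIND, PROV_PROFILE, Violation,
                              check_meal_constraints, energy_shares,
                              is_diabetic, meal_calorie_target, mind_classify,
                              recipe_nutrients_per_serving, _excluded_by)
from .inference_engine import Atom, Rule, query
from .ontology_kb import (CaregiverProfile, KnowledgeBase, LookupError_,
                          PatientProfile, Recipe)

SNACK_CLASS = "SnackFood"


@dataclass(frozen=True)
class Verdict:
    """Suitability outcome with its cited reasons."""

    suitable: str  # recommended | not_recommended | caution
    reasons: tuple[tuple[str, str], ...]  # (provenance, explanation)

    def __post_init__(self):
        if self.suitable not in ("recommended", "not_recommended", "caution"):
            raise ValueError(f"invalid verdict {self.suitable!r}")
        if self.suitable == "not_recommended" and not self.reasons:
            raise ValueError("a negative verdict must cite at least one reason")


@dataclass(frozen=True)
class MealRecord:
    date: dt.date
    meal_type: str
    items: tuple[str, ...]
    energy_kcal: float

    def __post_init__(self):
        if not isinstance(self.date, dt.date):
            raise ValueError(f"invalid date {self.date!r}")
        if self.energy_kcal < 0:
            raise ValueError("energy must be >= 0")


# ---------------------------------------------------------------------------
# Food suitability
# ---------------------------------------------------------------------------

def check_food_suitability(food: str, meal: str, patient: PatientProfile,
                           kb: KnowledgeBase,
                           rules: Iterable[Rule] = ()) -> Verdict:
    """Judge one food (or food category) for one meal slot.

    Precedence: hard profile exclusions (allergy, religious) veto
    everything; a MIND-limit listing makes the food not recommended for
    a suitability query; diabetes adds a sugar caution for sugary
    foods; MIND-encouraged foods are recommended with the citation.
    """
    if food not in kb.classes and food not in kb.individuals:
        raise LookupError_(f"unknown food or category {food!r}")
    reasons: list[tuple[str, str]] = []

    hit = _excluded_by(kb, food, patient.allergies) \
        if food in kb.individuals else (food if food in patient.allergies else None)
    if hit is not None:
        return Verdict("not_recommended", (
            (PROV_PROFILE, f"the patient is allergic to {hit}"),))
    hit = _excluded_by(kb, food, patient.religious_constraints) \
        if food in kb.individuals else (
            food if food in patient.religious_constraints else None)
    if hit is not None:
        return Verdict("not_recommended", (
            (PROV_PROFILE, f"{hit} is excluded by a religious constraint"),))

    mind = mind_classify(kb, food)
    if mind.value == "limit":
        reasons.append((PROV_MIND,
                        f"{food} is on the MIND diet limit list; its "
                        "consumption should be limited"))
        return Verdict("not_recommended", tuple(reasons))
    if mind.value == "encourage":
        reasons.append((PROV_MIND,
                        f"{food} is on the MIND diet encourage list"))

    caution = False
    item = kb.foods.get(food)
    # single foods are flagged on sugar density; the ADA 10%-of-energy
    # bound applies to whole meals, not to items that are mostly sugar
    # by energy (e.g. fruit)
    if is_diabetic(patient) and item is not None:
        sugar = item.nutrients_per_100g["sugar_g"]
        if sugar >= 15.0:
            caution = True
            reasons.append((PROV_ADA,
                            f"{food} is sugary ({sugar:.0f} g sugar per "
                            "100 g); with diabetes, keep sugar below 10% "
                            "of meal energy"))
    if food in patient.dislikes:
        caution = True
        reasons.append((PROV_PROFILE, f"the patient dislikes {food}"))

    if caution:
        return Verdict("caution", tuple(reasons))
    if not reasons:
        reasons.append(("general dietary guidance",
                        f"no guideline restricts {food}; fine in moderation"))
    return Verdict("recommended", tuple(reasons))


# ---------------------------------------------------------------------------
# Snack suggestion
# ---------------------------------------------------------------------------

def suggest_snack(patient: PatientProfile, caregiver: CaregiverProfile,
                  kb: KnowledgeBase, rules: Iterable[Rule] = (),
                  session: DialogueSession | None = None
                  ) -> tuple[str, Verdict] | None:
    """Highest-ranked admissible snack, or None when every snack is excluded.

    Candidates are the snack-class foods found by the inference engine;
    hard exclusions, dislikes and MIND-limited foods are filtered, a
    diabetic profile filters sugary foods, and the survivors rank
    MIND-encouraged first with lexicographic ids breaking ties.
    """
    rules = list(rules)
    if SNACK_CLASS not in kb.classes:
        return None
    bindings = query([Atom(SNACK_CLASS, ("?f",))], kb, rules)
    scored: list[tuple[int, str]] = []
    rejected = session.rejected if session is not None else frozenset()
    for b in bindings:
        fid = b["?f"]
        if fid not in kb.foods or fid in rejected:
            continue
        verdict = check_food_suitability(fid, "snack", patient, kb, rules)
        if verdict.suitable != "recommended":
            continue
        mind = mind_classify(kb, fid)
        score = 2 if mind.value == "encourage" else 1
        scored.append((-score, fid))
    if not scored:
        return None
    scored.sort()
    best = scored[0][1]
    return best, check_food_suitability(best, "snack", patient, kb, rules)


# ---------------------------------------------------------------------------
# Recipe recommendation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Recommendation:
    recipe: Recipe
    rationale: tuple[tuple[str, str], ...]  # (provenance, satisfied guideline)
    nutrients_per_serving: Mapping[str, float]


def admissible_recipes(meal: str, patient: PatientProfile,
                       caregiver: CaregiverProfile, kb: KnowledgeBase,
                       exclude: frozenset[str] = frozenset(),
                       max_time: float | None = None,
                       min_servings: float | None = None
                       ) -> list[Recipe]:
    """Recipes of the meal type passing every constraint, unranked."""
    effective_caregiver = caregiver
    if max_time is not None and max_time < caregiver.time_limit:
        effective_caregiver = CaregiverProfile(
            time_limit=max_time, budget=caregiver.budget,
            education_level=caregiver.education_level)
    out = []
    for rid in sorted(kb.recipes):
        recipe = kb.recipes[rid]
        if meal not in recipe.meal_types or rid in exclude:
            continue
        if min_servings is not None and recipe.servings < min_servings:
            continue
        if not check_meal_constraints(recipe, patient, effective_caregiver,
                                      kb, meal=meal):
            out.append(recipe)
    return out


def _encouraged_ingredient_count(recipe: Recipe, kb: KnowledgeBase) -> int:
    return sum(1 for fid, _ in recipe.ingredients
               if mind_classify(kb, fid).value == "encourage")


def recommend_recipe(slots: Mapping[str, object], patient: PatientProfile,
                     caregiver: CaregiverProfile, kb: KnowledgeBase,
                     rules: Iterable[Rule] = (),
                     session: DialogueSession | None = None
                     ) -> Recommendation | None:
    """Top-ranked admissible recipe for the filled slots, or None.

    Ranking: most MIND-encouraged ingredients first, then closeness of
    per-serving energy to the calorie-target midpoint, then recipe id.
    Recipes the session already rejected are excluded before ranking.
    """
    meal = str(slots["meal"])
    rejected = frozenset(session.rejected) if session is not None else frozenset()
    max_time = slots.get("max_time")
    min_servings = slots.get("servings")
    candidates = admissible_recipes(
        meal, patient, caregiver, kb, exclude=rejected,
        max_time=float(max_time) if max_time is not None else None,
        min_servings=float(min_servings) if min_servings is not None else None)
    if not candidates:
        return None
    lo, hi = meal_calorie_target(patient, meal)
    mid = (lo + hi) / 2.0

    def rank(r: Recipe):
        n = recipe_nutrients_per_serving(r, kb)
        return (-_encouraged_ingredient_count(r, kb),
                abs(n["energy_kcal"] - mid), r.id)

    best = min(candidates, key=rank)
    nutrients = recipe_nutrients_per_serving(best, kb)
    rationale: list[tuple[str, str]] = []
    if is_diabetic(patient) and meal == "dinner":
        shares = energy_shares(nutrients)
        rationale.append((PROV_ADA,
                          f"dinner energy {nutrients['energy_kcal']:.0f} kcal "
                          f"is within the 25%-of-EER target [{lo:.0f}, {hi:.0f}]"))
        rationale.append((PROV_ADA,
                          f"protein supplies {shares['protein']:.0f}% of meal "
                          "energy (target 20-30%)"))
        rationale.append((PROV_ADA,
                          f"sugar supplies {shares['sugar']:.0f}% of meal "
                          "energy (below 10%)"))
    else:
        rationale.append(("HHS Dietary Guidelines" if (
            patient.sex == "male" and patient.meals_per_day == 3)
            else "EER-based target",
            f"meal energy {nutrients['energy_kcal']:.0f} kcal is within "
            f"[{lo:.0f}, {hi:.0f}] kcal"))
    n_enc = _encouraged_ingredient_count(best, kb)
    if n_enc:
        rationale.append((PROV_MIND,
                          f"{n_enc} ingredient(s) from MIND-encouraged groups"))
    rationale.append((PROV_PROFILE,
                      "no allergy, religious, or preference conflict; fits "
                      f"the caregiver's time ({best.prep_time:.0f} min) and "
                      f"budget ({best.cost:.2f})"))
    return Recommendation(best, tuple(rationale), nutrients)


# ---------------------------------------------------------------------------
# Diet history
# ---------------------------------------------------------------------------

class DietHistory:
    """Append-only meal log with daily and weekly recall.

    Optionally persists each record as a JSONL line so a session can be
    replayed or audited.
    """

    def __init__(self, path: str | Path | None = None):
        self.records: list[MealRecord] = []
        self.path = Path(path) if path is not None else None
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    d = json.loads(line)
                    self.records.append(MealRecord(
                        date=dt.date.fromisoformat(d["date"]),
                        meal_type=d["meal_type"], items=tuple(d["items"]),
                        energy_kcal=float(d["energy_kcal"])))

    def record_meal(self, record: MealRecord) -> None:
        self.records.append(record)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps({
                    "date": record.date.isoformat(),
                    "meal_type": record.meal_type,
                    "items": list(record.items),
                    "energy_kcal": record.energy_kcal}) + "\n")

    def recall_history(self, window: str, date: dt.date) -> dict:
        """Summary over one day or the 7 days ending at ``date``."""
        if window not in ("day", "week"):
            raise ValueError(f"unknown recall window {window!r}")
        start = date if window == "day" else date - dt.timedelta(days=6)
        matching = [r for r in self.records if start <= r.date <= date]
        matching.sort(key=lambda r: (r.date, r.meal_type))
        return {
            "window": window,
            "start": start,
            "end": date,
            "records": matching,
            "total_energy_kcal": sum(r.energy_kcal for r in matching),
        }


# ---------------------------------------------------------------------------
# Tips
# ---------------------------------------------------------------------------

TIP_CATEGORIES = ("proper_diet", "eating_challenge")


class TipBank:
    """Stage- and tier-aware tips, cycling deterministically per session.

    Bank format (YAML)::

        tips:
          - id: t1
            tags: [proper_diet, early]
            text:
              basic: ...
              standard: ...
              advanced: ...
    """

    def __init__(self, tips: Sequence[Mapping]):
        if not tips:
            raise ValueError("tip bank is empty")
        self.tips = list(tips)
        self._cursors: dict[tuple, int] = {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TipBank":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(doc["tips"])

    def get_tip_entry(self, category: str, stage: str,
                      education_tier: str = "standard") -> tuple[Mapping, str]:
        """Next (tip record, rendered text) for (category, stage).

        Consecutive calls with the same arguments cycle through every
        matching tip before repeating. Falls back to stage-agnostic
        tips when none is tagged for the stage.
        """
        if category not in TIP_CATEGORIES:
            raise ValueError(f"unknown tip category {category!r}")
        matching = [t for t in self.tips
                    if category in t["tags"] and stage in t["tags"]]
        if not matching:
            matching = [t for t in self.tips
                        if category in t["tags"] and "any" in t["tags"]]
        if not matching:
            matching = [t for t in self.tips if category in t["tags"]]
        if not matching:
            raise ValueError(f"no tip available for category {category!r}")
        key = (category, stage, education_tier)
        i = self._cursors.get(key, 0)
        self._cursors[key] = i + 1
        tip = matching[i % len(matching)]
        text = tip["text"]
        rendered = text.get(education_tier) or text.get("standard") or \
            next(iter(text.values()))
        return tip, rendered

    def get_tip(self, category: str, stage: str,
                education_tier: str = "standard") -> str:
        """Next tip text for (category, stage), rendered for the tier."""
        return self.get_tip_entry(category, stage, education_tier)[1]
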