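"""Deterministic synthetic-data generator for every system input.

No download is required anywhere in the package: this module fabricates
a food composition table shaped like FoodData Central extracts, the
diet ontology, recipes with controlled macro profiles, patient and
caregiver profiles (including the reference persona: a female caregiver
cooking for her 65-year-old father, early-stage ADRD with type 2
diabetes), a tip bank, the guideline rule file, and scripted
conversations for batch evaluation.

Everything is a pure function of the :class:`FixtureSpec` — the same
seed yields byte-identical artifacts. Nutrient ranges per category are
invented but realistic per 100 g (cooked basis); recipes are *solved*
against the guideline bounds at generation time, so the bundle always
contains exactly the advertised mix of admissible recipes and
single-constraint violators, recorded in ``manifest.json``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .guideline_rules import builtin_rule_text, check_meal_constraints
from .ontology_kb import (CaregiverProfile, KnowledgeBase, PatientProfile,
                          load_kb, load_profiles)


class FixtureError(Exception):
    """The requested fixture spec is infeasible."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_foods: int = 50
    n_recipes: int = 20

    def __post_init__(self):
        if self.n_foods < 0 or self.n_recipes < 0:
            raise FixtureError("counts must be >= 0")


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

# class -> (parents, synonyms); SnackFood parents mark categories whose
# members are sensible between-meal snacks
_ONTOLOGY_CLASSES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Thing": ((), ()),
    "Food": (("Thing",), ()),
    "SnackFood": (("Food",), ("snack food",)),
    "Vegetables": (("Food",), ("vegetable", "veggies")),
    "Fruits": (("Food", "SnackFood"), ("fruit",)),
    "Berries": (("Fruits",), ("berry",)),
    "Nuts": (("Food", "SnackFood"), ("nut",)),
    "Oils": (("Food",), ("oil",)),
    "OliveOil": (("Oils",), ("olive oils",)),
    "Grains": (("Food",), ("grain",)),
    "WholeGrains": (("Grains",), ("whole grain", "whole grains")),
    "Seafood": (("Food",), ()),
    "Fish": (("Seafood",), ()),
    "Beans": (("Food",), ("legumes", "bean")),
    "Meat": (("Food",), ()),
    "Poultry": (("Meat",), ()),
    "RedMeat": (("Meat",), ("red meat",)),
    "Dairy": (("Food",), ()),
    "Cheese": (("Dairy", "SnackFood"), ("cheeses",)),
    "Butter": (("Dairy",), ()),
    "Margarine": (("Food",), ()),
    "FriedFood": (("Food",), ("fried food", "fried foods")),
    "Pastries": (("Food", "SnackFood"), ("pastry",)),
    "Sweets": (("Food", "SnackFood"), ("dessert", "desserts", "sweet")),
    "Beverages": (("Food",), ("drink", "drinks", "beverage")),
    # user-profile and condition concepts (the other two ontologies)
    "Person": (("Thing",), ()),
    "Patient": (("Person",), ()),
    "Caregiver": (("Person",), ()),
    "Condition": (("Thing",), ()),
    "Diabetes": (("Condition",), ("type 2 diabetes",)),
    "Hypertension": (("Condition",), ()),
    "Nutrient": (("Thing",), ()),
}

# Vegetables and Meat never share members in this KB; the axiom gives the
# satisfiability check something real to verify
_DISJOINT = {"Vegetables": ("Meat",), "Meat": ("Vegetables",)}

# food categories that receive generated items, in allocation order
# (categories whose rank-3 names feed crafted recipes come first)
FOOD_CATEGORIES = (
    "Vegetables", "WholeGrains", "Fish", "Poultry", "Berries", "Nuts",
    "OliveOil", "Beans", "Butter", "Margarine", "Cheese", "RedMeat",
    "FriedFood", "Pastries", "Sweets", "Fruits", "Beverages",
)

MANDATORY_CATEGORIES = FOOD_CATEGORIES  # >= 1 item each

_FOOD_NAMES: dict[str, tuple[str, ...]] = {
    "Vegetables": ("spinach", "broccoli", "carrots", "kale", "green beans",
                   "cauliflower", "zucchini", "bell pepper"),
    "WholeGrains": ("brown rice", "quinoa", "whole wheat bread", "oatmeal"),
    "Fish": ("salmon", "tuna", "cod", "sardines"),
    "Poultry": ("chicken breast", "turkey breast", "chicken thigh",
                "ground turkey"),
    "Berries": ("blueberries", "strawberries", "raspberries", "blackberries"),
    "Nuts": ("almonds", "walnuts", "cashews", "pistachios"),
    "OliveOil": ("olive oil", "extra virgin olive oil"),
    "Beans": ("lentils", "black beans", "chickpeas", "kidney beans"),
    "Butter": ("butter", "salted butter"),
    "Margarine": ("margarine", "soft margarine"),
    "Cheese": ("cheddar cheese", "mozzarella", "swiss cheese", "cream cheese"),
    "RedMeat": ("beef steak", "ground beef", "pork chop", "lamb"),
    "FriedFood": ("french fries", "fried chicken", "onion rings"),
    "Pastries": ("croissant", "danish pastry", "doughnut"),
    "Sweets": ("ice cream", "milk chocolate", "cookies", "candy"),
    "Fruits": ("apple", "banana", "orange", "grapes"),
    "Beverages": ("water", "milk", "orange juice", "coffee"),
}

_FOOD_SYNONYMS: dict[str, tuple[str, ...]] = {
    "cheddar cheese": ("cheddar",),
    "blueberries": ("blueberry",),
    "strawberries": ("strawberry",),
    "almonds": ("almond",),
    "olive oil": ("evoo",),
    "salmon": ("salmon fillet",),
    "chicken breast": ("chicken",),
    "beef steak": ("steak",),
    "french fries": ("fries", "chips"),
    "ice cream": ("icecream",),
    "whole wheat bread": ("wholemeal bread",),
    "oatmeal": ("porridge", "oats"),
}

# per-100 g ranges: protein, carb, sugar, fat, fiber, sodium (cooked basis)
_NUTRIENT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "Vegetables": {"p": (1.0, 3.5), "c": (4, 10), "s": (1, 4),
                   "f": (0.2, 0.8), "fib": (1.5, 4), "na": (10, 80)},
    "WholeGrains": {"p": (2.5, 5), "c": (20, 26), "s": (0.3, 1.5),
                    "f": (0.8, 2.5), "fib": (1.5, 4), "na": (1, 10)},
    "Fish": {"p": (20, 26), "c": (0, 0), "s": (0, 0),
             "f": (4, 14), "fib": (0, 0), "na": (40, 120)},
    "Poultry": {"p": (25, 31), "c": (0, 0), "s": (0, 0),
                "f": (3, 10), "fib": (0, 0), "na": (60, 90)},
    "Berries": {"p": (0.7, 1.5), "c": (8, 15), "s": (5, 10),
                "f": (0.3, 0.7), "fib": (2, 6), "na": (1, 5)},
    "Nuts": {"p": (15, 25), "c": (15, 25), "s": (3, 6),
             "f": (45, 65), "fib": (7, 12), "na": (1, 10)},
    "OliveOil": {"p": (0, 0), "c": (0, 0), "s": (0, 0),
                 "f": (99, 100), "fib": (0, 0), "na": (0, 2)},
    "Beans": {"p": (7, 10), "c": (14, 24), "s": (0.3, 2),
              "f": (0.4, 1.5), "fib": (6, 9), "na": (1, 15)},
    "Butter": {"p": (0.5, 1), "c": (0, 1), "s": (0, 0.8),
               "f": (78, 83), "fib": (0, 0), "na": (500, 700)},
    "Margarine": {"p": (0, 0.5), "c": (0, 1), "s": (0, 0),
                  "f": (60, 80), "fib": (0, 0), "na": (600, 800)},
    "Cheese": {"p": (20, 26), "c": (1, 4), "s": (0.3, 2),
               "f": (25, 34), "fib": (0, 0), "na": (500, 800)},
    "RedMeat": {"p": (22, 28), "c": (0, 0), "s": (0, 0),
                "f": (10, 22), "fib": (0, 0), "na": (50, 80)},
    "FriedFood": {"p": (3, 15), "c": (25, 40), "s": (0.3, 3),
                  "f": (12, 20), "fib": (1, 3), "na": (200, 500)},
    "Pastries": {"p": (5, 8), "c": (45, 60), "s": (12, 25),
                 "f": (15, 25), "fib": (1, 3), "na": (300, 500)},
    "Sweets": {"p": (2, 6), "c": (55, 75), "s": (40, 60),
               "f": (8, 30), "fib": (0, 3), "na": (50, 200)},
    "Fruits": {"p": (0.3, 1.2), "c": (12, 23), "s": (10, 18),
               "f": (0.1, 0.5), "fib": (1.5, 4), "na": (0, 5)},
    "Beverages": {"p": (0, 3.4), "c": (0, 12), "s": (0, 12),
                  "f": (0, 3.6), "fib": (0, 0), "na": (0, 50)},
}


def food_id(name: str) -> str:
    return name.replace(" ", "_")


def generate_ontology() -> dict:
    """The diet ontology in the canonical JSON dialect (static by design)."""
    classes = []
    for name in sorted(_ONTOLOGY_CLASSES):
        parents, synonyms = _ONTOLOGY_CLASSES[name]
        entry = {"name": name, "label": name,
                 "parents": sorted(parents), "synonyms": sorted(synonyms)}
        if name in _DISJOINT:
            entry["disjoint_with"] = sorted(_DISJOINT[name])
        classes.append(entry)
    return {"classes": classes, "individuals": []}


def generate_food_db(spec: FixtureSpec) -> tuple[str, dict]:
    """The food composition CSV plus the ontology fragment it references.

    ``spec.n_foods`` items are allocated over the MIND categories (at
    least one per encourage and limit category), nutrients drawn from
    per-category ranges with tabulated energy jittered ±10% around the
    Atwater value. Synonyms cover well over 20% of items.
    """
    if spec.n_foods < len(MANDATORY_CATEGORIES):
        raise FixtureError(
            f"n_foods={spec.n_foods} cannot cover the "
            f"{len(MANDATORY_CATEGORIES)} mandatory food categories")
    rng = random.Random(spec.seed)
    taken: dict[str, int] = {c: 0 for c in FOOD_CATEGORIES}
    rows: list[str] = []
    header = ("id,name,category,energy_kcal,protein_g,carb_g,sugar_g,"
              "fat_g,satfat_g,fiber_g,sodium_mg,synonyms")
    n_emitted = 0
    while n_emitted < spec.n_foods:
        progressed = False
        for cat in FOOD_CATEGORIES:
            if n_emitted >= spec.n_foods:
                break
            names = _FOOD_NAMES[cat]
            k = taken[cat]
            if k >= len(names):
                continue
            taken[cat] = k + 1
            name = names[k]
            r = _NUTRIENT_RANGES[cat]
            p = rng.uniform(*r["p"])
            c = rng.uniform(*r["c"])
            s = min(rng.uniform(*r["s"]), c)
            f = rng.uniform(*r["f"])
            fib = rng.uniform(*r["fib"])
            na = rng.uniform(*r["na"])
            satfat = f * rng.uniform(0.15, 0.5)
            energy = (4 * p + 4 * c + 9 * f) * rng.uniform(0.9, 1.1)
            syns = ";".join(_FOOD_SYNONYMS.get(name, ()))
            rows.append(
                f"{food_id(name)},{name},{cat},{energy:.1f},{p:.2f},{c:.2f},"
                f"{s:.2f},{f:.2f},{satfat:.2f},{fib:.2f},{na:.1f},{syns}")
            n_emitted += 1
            progressed = True
        if not progressed:
            raise FixtureError(
                f"name lists exhausted after {n_emitted} foods; "
                f"n_foods={spec.n_foods} is too large")
    return header + "\n" + "\n".join(rows) + "\n", generate_ontology()


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def generate_profiles() -> dict:
    """Patient/caregiver profiles, led by the reference persona."""
    return {
        "patients": {
            "p_default": {
                "age": 65, "sex": "male", "adrd_stage": "early",
                "comorbidities": ["type2_diabetes"],
                "allergies": ["Nuts"],
                "dislikes": ["sardines"],
                "preferences": ["Fish", "Vegetables"],
                "religious_constraints": [],
                "eer": 2000, "meals_per_day": 3,
            },
            "p_nondiabetic": {
                "age": 68, "sex": "male", "adrd_stage": "middle",
                "comorbidities": [], "allergies": [], "dislikes": [],
                "preferences": [], "religious_constraints": [],
                "meals_per_day": 3,
            },
        },
        "caregivers": {
            "c_default": {"time_limit": 45, "budget": 12,
                          "education_level": "standard"},
            "c_basic": {"time_limit": 45, "budget": 12,
                        "education_level": "basic"},
            "c_advanced": {"time_limit": 45, "budget": 12,
                           "education_level": "advanced"},
        },
    }


def persona_profiles() -> tuple[PatientProfile, CaregiverProfile]:
    doc = generate_profiles()
    p = doc["patients"]["p_default"]
    c = doc["caregivers"]["c_default"]
    patient = PatientProfile(
        age=p["age"], sex=p["sex"], adrd_stage=p["adrd_stage"],
        comorbidities=frozenset(p["comorbidities"]),
        allergies=frozenset(p["allergies"]),
        dislikes=frozenset(p["dislikes"]),
        preferences=frozenset(p["preferences"]),
        eer=p["eer"], meals_per_day=p["meals_per_day"])
    caregiver = CaregiverProfile(
        time_limit=c["time_limit"], budget=c["budget"],
        education_level=c["education_level"])
    return patient, caregiver


# ---------------------------------------------------------------------------
# Recipes: solved against the guideline bounds
# ---------------------------------------------------------------------------

def _solve2(a11, a12, a21, a22, b1, b2) -> tuple[float, float]:
    det = a11 * a22 - a12 * a21
    if abs(det) < 1e-9:
        raise FixtureError("singular 2x2 system in recipe construction")
    return ((b1 * a22 - a12 * b2) / det, (a11 * b2 - b1 * a21) / det)


def _solve3(a, b) -> tuple[float, float, float]:
    (a11, a12, a13), (a21, a22, a23), (a31, a32, a33) = a
    det = (a11 * (a22 * a33 - a23 * a32)
           - a12 * (a21 * a33 - a23 * a31)
           + a13 * (a21 * a32 - a22 * a31))
    if abs(det) < 1e-9:
        raise FixtureError("singular 3x3 system in recipe construction")

    def rep(col):
        m = [list(row) for row in a]
        for i in range(3):
            m[i][col] = b[i]
        (x11, x12, x13), (x21, x22, x23), (x31, x32, x33) = m
        return (x11 * (x22 * x33 - x23 * x32)
                - x12 * (x21 * x33 - x23 * x31)
                + x13 * (x21 * x32 - x22 * x31))

    return tuple(rep(i) / det for i in range(3))


class _Foods:
    def __init__(self, kb: KnowledgeBase):
        self.kb = kb

    def __getitem__(self, name: str):
        fid = food_id(name)
        food = self.kb.foods.get(fid)
        if food is None:
            raise FixtureError(
                f"recipe construction needs food {name!r}, absent from the "
                "generated table (n_foods too small?)")
        return food

    def density(self, name: str, key: str) -> float:
        """Nutrient per gram."""
        return self[name].nutrients_per_100g[key] / 100.0


def _solved_dinner(foods: _Foods, protein_src: str, grain: str, veg: str,
                   energy_total: float, protein_share: float,
                   veg_grams: float = 150.0, oil_grams: float = 10.0
                   ) -> list[tuple[str, float]]:
    """Grams of (protein source, grain) hitting an exact energy and
    protein-share target, with fixed vegetable and olive-oil amounts."""
    e = lambda n: foods.density(n, "energy_kcal")
    p = lambda n: foods.density(n, "protein_g")
    protein_total_g = protein_share * energy_total / 4.0
    e_rem = energy_total - veg_grams * e(veg) - oil_grams * e("olive oil")
    p_rem = protein_total_g - veg_grams * p(veg) - oil_grams * p("olive oil")
    x, y = _solve2(e(protein_src), e(grain), p(protein_src), p(grain),
                   e_rem, p_rem)
    if x <= 0 or y <= 0:
        raise FixtureError(
            f"infeasible dinner construction ({protein_src}, {grain})")
    return [(food_id(protein_src), round(x, 1)), (food_id(grain), round(y, 1)),
            (food_id(veg), veg_grams), (food_id("olive oil"), oil_grams)]


def _sugar_violator(foods: _Foods, energy_total: float,
                    protein_share: float, sugar_share: float
                    ) -> list[tuple[str, float]]:
    names = ("turkey breast", "brown rice", "ice cream")
    e = [foods.density(n, "energy_kcal") for n in names]
    p = [foods.density(n, "protein_g") for n in names]
    s = [foods.density(n, "sugar_g") for n in names]
    b = [energy_total, protein_share * energy_total / 4.0,
         sugar_share * energy_total / 4.0]
    x, y, z = _solve3([e, p, s], b)
    if min(x, y, z) <= 0:
        raise FixtureError("infeasible sugar-violator construction")
    return [(food_id(n), round(g, 1)) for n, g in zip(names, (x, y, z))]


def generate_recipes(spec: FixtureSpec, kb: KnowledgeBase
                     ) -> tuple[dict, dict]:
    """Recipes with controlled macro profiles, plus the manifest.

    By construction the set contains exactly two dinner recipes
    admissible for the reference persona (diabetic dinner, EER 2000 →
    500 kcal/serving, protein 20–30%, sugar < 10%) and one dinner
    violating each single constraint class (sugar, protein, calorie,
    time, cost, allergy); remaining recipes fill other meal slots. The
    manifest records who violates what, and the claims are re-verified
    against the constraint checker before returning.
    """
    foods = _Foods(kb)
    patient, caregiver = persona_profiles()
    target = 0.25 * patient.eer          # ADA diabetic dinner, per serving
    servings = 2
    e_total = target * servings

    recipes: list[dict] = []
    violators: dict[str, str] = {}

    def add(rid, name, ingredients, prep_time, cost,
            meal_types, servings_=servings):
        recipes.append({
            "id": rid, "name": name,
            "ingredients": [{"food": f, "grams": g} for f, g in ingredients],
            "servings": servings_, "prep_time": prep_time, "cost": cost,
            "meal_types": meal_types, "cuisine_tags": ["home"]})

    add("r_adm_salmon", "Baked salmon with brown rice and spinach",
        _solved_dinner(foods, "salmon", "brown rice", "spinach",
                       e_total, 0.25), 25, 8.0, ["dinner"])
    add("r_adm_chicken", "Chicken breast with quinoa and broccoli",
        _solved_dinner(foods, "chicken breast", "quinoa", "broccoli",
                       e_total, 0.27), 30, 9.0, ["dinner"])
    admissible = ["r_adm_chicken", "r_adm_salmon"]

    add("r_v_sugar", "Turkey rice bowl with ice cream dessert",
        _sugar_violator(foods, e_total, 0.25, 0.13), 30, 8.0, ["dinner"])
    violators["sugar_share"] = "r_v_sugar"

    # low-protein dinner: grains + vegetables scaled to the energy target
    e = lambda n: foods.density(n, "energy_kcal")
    base = [("brown rice", 300.0), ("carrots", 200.0), ("olive oil", 15.0)]
    e_base = sum(g * e(n) for n, g in base)
    scale = e_total / e_base
    add("r_v_protein", "Carrot rice pilaf",
        [(food_id(n), round(g * scale, 1)) for n, g in base],
        20, 6.0, ["dinner"])
    violators["protein_share"] = "r_v_protein"

    add("r_v_calorie", "Hearty turkey quinoa platter",
        _solved_dinner(foods, "turkey breast", "quinoa", "spinach",
                       1.6 * e_total, 0.25), 30, 8.0, ["dinner"])
    violators["calorie_target"] = "r_v_calorie"

    add("r_v_time", "Slow-cooked cod with brown rice",
        _solved_dinner(foods, "cod", "brown rice", "broccoli",
                       e_total, 0.25), 75, 9.0, ["dinner"])
    violators["prep_time"] = "r_v_time"

    add("r_v_cost", "Seared tuna with quinoa",
        _solved_dinner(foods, "tuna", "quinoa", "carrots",
                       e_total, 0.25), 30, 20.0, ["dinner"])
    violators["cost"] = "r_v_cost"

    # almond-crusted: fixed nut amount, remainder solved around it
    nut_grams = 15.0
    e_nut = nut_grams * foods.density("almonds", "energy_kcal")
    p_nut = nut_grams * foods.density("almonds", "protein_g")
    ing = _solved_dinner(foods, "salmon", "brown rice", "spinach",
                         e_total - e_nut,
                         (0.25 * e_total / 4.0 - p_nut) * 4.0 / (e_total - e_nut))
    add("r_v_allergy", "Almond-crusted salmon with rice",
        ing + [(food_id("almonds"), nut_grams)], 30, 9.0, ["dinner"])
    violators["allergy"] = "r_v_allergy"

    # one HHS-sized lunch (male, three meals/day: 800-850 kcal)
    add("r_lunch_hhs", "Beef steak lunch with rice and spinach",
        _solved_dinner(foods, "beef steak", "brown rice", "spinach",
                       825.0 * servings, 0.24), 35, 10.0, ["lunch"])

    # filler recipes for the other meal slots, never dinner
    rng = random.Random(spec.seed + 1)
    filler_pool = [
        ("Berry toast", [("whole wheat bread", 90.0),
                         ("blueberries", 80.0)], "breakfast"),
        ("Lentil soup", [("lentils", 250.0), ("carrots", 100.0),
                         ("olive oil", 10.0)], "lunch"),
        ("Fruit plate", [("apple", 150.0), ("strawberries", 100.0)], "snack"),
        ("Grilled cheese sandwich", [("whole wheat bread", 120.0),
                                     ("cheddar cheese", 60.0),
                                     ("butter", 15.0)], "lunch"),
        ("Berry bowl", [("raspberries", 120.0),
                        ("blueberries", 80.0)], "snack"),
        ("Tuna salad", [("tuna", 120.0), ("spinach", 80.0),
                        ("olive oil", 12.0)], "lunch"),
        ("Veggie toast", [("whole wheat bread", 90.0),
                          ("broccoli", 80.0),
                          ("margarine", 10.0)], "breakfast"),
        ("Chicken wrap", [("chicken breast", 100.0),
                          ("whole wheat bread", 80.0),
                          ("carrots", 50.0)], "lunch"),
        ("Rice pudding", [("brown rice", 150.0), ("milk", 150.0),
                          ("milk chocolate", 30.0)], "snack"),
        ("Bean chili", [("black beans", 220.0), ("carrots", 80.0),
                        ("olive oil", 10.0)], "lunch"),
        ("Banana toast", [("banana", 120.0),
                          ("whole wheat bread", 90.0)], "breakfast"),
        ("Cod sandwich", [("cod", 100.0), ("whole wheat bread", 90.0)],
         "lunch"),
    ]
    i = 0
    while len(recipes) < spec.n_recipes and i < len(filler_pool):
        name, ings, meal = filler_pool[i]
        grams = [(food_id(n), round(g * rng.uniform(0.9, 1.1), 1))
                 for n, g in ings]
        add(f"r_fill_{i:02d}", name, grams,
            prep_time=round(rng.uniform(10, 40), 0),
            cost=round(rng.uniform(3, 10), 2),
            meal_types=[meal], servings_=rng.choice([1, 2]))
        i += 1

    doc = {"recipes": recipes}

    # independent verification of the manifest claims before shipping
    check_kb = KnowledgeBase()
    check_kb.classes = kb.classes
    check_kb.foods = dict(kb.foods)
    check_kb.individuals = dict(kb.individuals)
    for r in recipes:
        from .ontology_kb import Recipe
        check_kb.add_recipe(Recipe(
            id=r["id"], name=r["name"],
            ingredients=tuple((d["food"], d["grams"])
                              for d in r["ingredients"]),
            servings=r["servings"], prep_time=r["prep_time"], cost=r["cost"],
            meal_types=frozenset(r["meal_types"])))
    dinner_ok = []
    for rid in sorted(check_kb.recipes):
        recipe = check_kb.recipes[rid]
        if "dinner" not in recipe.meal_types:
            continue
        v = check_meal_constraints(recipe, patient, caregiver, check_kb,
                                   meal="dinner")
        if not v:
            dinner_ok.append(rid)
        elif rid in violators.values():
            expected = next(k for k, v_ in violators.items() if v_ == rid)
            if expected not in {x.constraint for x in v}:
                raise FixtureError(
                    f"{rid} was built to violate {expected} but violates "
                    f"{[x.constraint for x in v]}")
    if sorted(dinner_ok) != sorted(admissible):
        raise FixtureError(
            f"expected admissible dinners {sorted(admissible)}, "
            f"checker found {dinner_ok}")

    manifest = {
        "persona": {"patient": "p_default", "caregiver": "c_default"},
        "dinner_calorie_target_kcal": target,
        "admissible_dinner_recipes": sorted(admissible),
        "violators": violators,
        "n_recipes": len(recipes),
    }
    return doc, manifest


# ---------------------------------------------------------------------------
# Tip bank
# ---------------------------------------------------------------------------

def generate_tip_bank() -> dict:
    def tip(tid, tags, basic, standard, advanced=None):
        return {"id": tid, "tags": tags,
                "text": {"basic": basic, "standard": standard,
                         "advanced": advanced or standard}}

    return {"tips": [
        tip("t_pd_1", ["proper_diet", "early"],
            "Serve colorful vegetables and fish often.",
            "Follow the MIND pattern: vegetables, berries, whole grains and "
            "fish most days; keep butter, cheese and sweets occasional.",
            "Aim for the MIND pattern: 6+ servings/week of leafy greens, "
            "2+ of berries, fish weekly; limit saturated fat to under 10% "
            "of energy."),
        tip("t_pd_2", ["proper_diet", "early"],
            "Offer water through the day so he drinks enough.",
            "Encourage regular fluids; mild dehydration worsens confusion.",
            "Target roughly 1.5-2 L of fluids daily; dehydration is a "
            "common, reversible cause of worsened cognition."),
        tip("t_pd_3", ["proper_diet", "middle"],
            "Keep meals at the same times every day.",
            "A steady meal routine reduces agitation and skipped meals.",
            "Consistent meal timing stabilizes intake; track weight weekly "
            "to catch decline early."),
        tip("t_pd_4", ["proper_diet", "middle"],
            "Cook with olive oil instead of butter.",
            "Swap butter and margarine for olive oil when cooking.",
            "Replacing saturated spreads with olive oil improves the fat "
            "profile while keeping energy density."),
        tip("t_pd_5", ["proper_diet", "late"],
            "Offer soft foods that are easy to swallow.",
            "Choose soft, moist textures and check swallowing comfort.",
            "Dysphagia risk rises in late stage; prefer soft textures and "
            "consider a swallowing assessment."),
        tip("t_pd_6", ["proper_diet", "any"],
            "Small portions more often can work better than big meals.",
            "Several small meals may beat three large ones if appetite is low.",
            "Energy-dense small meals (5-6/day) help maintain weight when "
            "appetite declines."),
        tip("t_ec_1", ["eating_challenge", "early"],
            "Eat together; he will often copy you.",
            "Share mealtimes: modeling eating helps when attention drifts.",
            "Social facilitation measurably increases intake; eat the same "
            "food at the same table."),
        tip("t_ec_2", ["eating_challenge", "middle"],
            "Use plain plates so food is easy to see.",
            "High-contrast, plain tableware makes food easier to recognize.",
            "Visual contrast between plate and food can raise intake; avoid "
            "patterned dishes."),
        tip("t_ec_3", ["eating_challenge", "middle"],
            "Give one food at a time to avoid confusion.",
            "Serve one item at a time and keep the table quiet.",
            "Reduce choice overload: one course at a time, minimal table "
            "clutter, no television."),
        tip("t_ec_4", ["eating_challenge", "late"],
            "Gently remind him to chew and swallow.",
            "Cue each step: small bites, chew, swallow, pause.",
            "Verbal and physical cueing for each swallow reduces choking "
            "risk in late-stage ADRD."),
        tip("t_ec_5", ["eating_challenge", "any"],
            "If he refuses food, try again a little later.",
            "Refusals often pass; retry after 15-30 minutes without pressure.",
            "Avoid confrontation over refusals; short delays and a calm "
            "retry preserve mealtime mood and intake."),
    ]}


# ---------------------------------------------------------------------------
# Conversation scripts
# ---------------------------------------------------------------------------

_GARBAGE_LINES = (
    "the weather is nice today is it not",
    "purple elephants dance on tuesdays",
    "my neighbor bought a new lawnmower yesterday",
    "seventeen clouds drifted past the window",
    "that television show was quite something",
)


def _script(*records) -> list[dict]:
    return list(records)


def _u(text: str) -> dict:
    return {"user": text}


def _x(action: str) -> dict:
    return {"expect_action": action}


def generate_scripts(spec: FixtureSpec) -> dict[str, list[dict]]:
    """Scripted conversations per evaluated service category.

    Each of the three evaluated categories gets ten regular scripts
    (happy paths, synonym usage, slot elicitation, over-answering,
    rejection-then-alternative) plus one adversarial script that never
    supplies what the assistant asks for and must fail at the turn
    threshold.
    """
    scripts: dict[str, list[dict]] = {}

    fe = "food_explanation"
    suit = [
        ("is cheddar cheese good as a snack for my dad", None),
        ("is blueberries good for breakfast", None),
        ("is butter ok for a breakfast", None),
        ("is cheddar ok for a snack", None),                 # synonym
        ("is spinach good for dinner", None),
        ("is ice cream good as a snack for my dad", None),
        ("can he have almonds as a snack", None),            # allergy
        ("is water good for lunch", None),
        ("is olive oil ok for a dinner", None),
    ]
    for i, (utt, _) in enumerate(suit):
        scripts[f"{fe}__{i:02d}"] = _script(
            _u(utt), _x("suitability_verdict"))
    # elicitation: the meal slot arrives on the second turn
    scripts[f"{fe}__09"] = _script(
        _u("tell me about salmon"), _x("elicit_slot"),
        _u("for dinner"), _x("suitability_verdict"))
    scripts[f"{fe}__10_adversarial"] = _script(
        *(_u(_GARBAGE_LINES[j % len(_GARBAGE_LINES)]) for j in range(25)),
        _x("suitability_verdict"))

    ms = "meal_suggestion"
    scripts[f"{ms}__00"] = _script(
        _u("recommend a recipe for dinner"), _x("recipe_recommendation"),
        _u("yes please"), _x("confirm"))
    scripts[f"{ms}__01"] = _script(  # rejection, then the alternative
        _u("recommend a recipe for dinner"), _x("recipe_recommendation"),
        _u("no not that one"), _x("acknowledge_rejection"),
        _u("yes that sounds good"), _x("confirm"))
    scripts[f"{ms}__02"] = _script(  # over-answering after elicitation
        _u("what should i cook"), _x("elicit_slot"),
        _u("dinner for two servings in 30 minutes"),
        _x("recipe_recommendation"),
        _u("yes"), _x("confirm"))
    scripts[f"{ms}__03"] = _script(
        _u("suggest a dinner recipe"), _x("recipe_recommendation"),
        _u("yes"), _x("confirm"))
    scripts[f"{ms}__04"] = _script(
        _u("i need a recipe for dinner tonight"),
        _x("recipe_recommendation"), _u("sure"), _x("confirm"))
    scripts[f"{ms}__05"] = _script(
        _u("any recipe idea for dinner"), _x("recipe_recommendation"),
        _u("ok"), _x("confirm"))
    scripts[f"{ms}__06"] = _script(
        _u("can you suggest a good snack"), _x("snack_suggestion"))
    scripts[f"{ms}__07"] = _script(
        _u("suggest a healthy snack for him"), _x("snack_suggestion"))
    scripts[f"{ms}__08"] = _script(
        _u("what is a good snack"), _x("snack_suggestion"))
    scripts[f"{ms}__09"] = _script(
        _u("give me a snack idea"), _x("snack_suggestion"))
    scripts[f"{ms}__10_adversarial"] = _script(
        _u("recommend a recipe"),
        *(_u(_GARBAGE_LINES[(j + 1) % len(_GARBAGE_LINES)])
          for j in range(24)),
        _x("confirm"))

    td = "proper_diet_tips"
    tip_utts = (
        "give me a tip on proper diet",
        "any advice on healthy eating",
        "share a diet tip",
        "how can i improve his diet",
    )
    for i in range(8):
        scripts[f"{td}__{i:02d}"] = _script(
            _u(tip_utts[i % len(tip_utts)]), _x("tip"))
    scripts[f"{td}__08"] = _script(  # consecutive tips cycle
        _u("give me a tip on proper diet"), _x("tip"),
        _u("share a diet tip"), _x("tip"))
    scripts[f"{td}__09"] = _script(
        _u("any advice on healthy eating"), _x("tip"),
        _u("how can i improve his diet"), _x("tip"))
    scripts[f"{td}__10_adversarial"] = _script(
        *(_u(_GARBAGE_LINES[(j + 2) % len(_GARBAGE_LINES)])
          for j in range(25)),
        _x("tip"))
    return scripts


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

def write_bundle(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Emit the complete input bundle plus manifest.json; returns outdir.

    Layout: ``ontology.json``, ``foods.csv``, ``recipes.json``,
    ``profiles.json``, ``tips.yaml``, ``rules.txt``,
    ``scripts/<category>__<n>.jsonl``, ``manifest.json``.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_text, ontology = generate_food_db(spec)
    (outdir / "foods.csv").write_text(csv_text)
    (outdir / "ontology.json").write_text(
        json.dumps(ontology, indent=2, sort_keys=True) + "\n")
    (outdir / "recipes.json").write_text(json.dumps({"recipes": []}) + "\n")
    kb = load_kb(outdir / "foods.csv", outdir / "recipes.json",
                 outdir / "ontology.json")
    recipes_doc, manifest = generate_recipes(spec, kb)
    (outdir / "recipes.json").write_text(
        json.dumps(recipes_doc, indent=2, sort_keys=True) + "\n")
    (outdir / "profiles.json").write_text(
        json.dumps(generate_profiles(), indent=2, sort_keys=True) + "\n")
    (outdir / "tips.yaml").write_text(
        yaml.safe_dump(generate_tip_bank(), sort_keys=True))
    (outdir / "rules.txt").write_text(builtin_rule_text())
    scripts_dir = outdir / "scripts"
    scripts_dir.mkdir(exist_ok=True)
    for name, records in sorted(generate_scripts(spec).items()):
        (scripts_dir / f"{name}.jsonl").write_text(
            "\n".join(json.dumps(r, sort_keys=True) for r in records) + "\n")
    manifest["spec"] = {"seed": spec.seed, "n_foods": spec.n_foods,
                        "n_recipes": spec.n_recipes}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def load_bundle(bundle_dir: str | Path):
    """Load a written bundle back into live objects.

    Returns (kb, rules, patients, caregivers, tip_bank, manifest).
    """
    from .diet_services import TipBank
    from .inference_engine import load_rules

    d = Path(bundle_dir)
    kb = load_kb(d / "foods.csv", d / "recipes.json", d / "ontology.json")
    rules = load_rules(d / "rules.txt")
    patients, caregivers = load_profiles(d / "profiles.json")
    tip_bank = TipBank.from_yaml(d / "tips.yaml")
    manifest = json.loads((d / "manifest.json").read_text())
    return kb, rules, patients, caregivers, tip_bank, manifest
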