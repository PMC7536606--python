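"""Ontology-style knowledge base for the diet assistant.

The knowledge base fuses three ontologies — user profiles, ADRD diet
support, and food/nutrition — into a single typed concept graph:

* **classes** connected by the IS-A (specialization/generalization)
  relation, optionally carrying synonyms and disjointness axioms;
* **individuals** attached to classes by the *type* relation, carrying
  (predicate, value) property assertions;
* **food items** (nutrient records per 100 g, following the FoodData
  Central convention) and **recipes** (ingredient lists in grams),
  which are individuals with structured payloads;
* **profiles** for the patient and the caregiver, the evidence used for
  personalization.

The KB can be partitioned into a TBox (terminological assertions:
class declarations, IS-A links, disjointness) and an ABox (assertional
facts about individuals), and losslessly merged back.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")

FOOD_CSV_COLUMNS = [
    "id", "name", "category", "energy_kcal", "protein_g", "carb_g",
    "sugar_g", "fat_g", "satfat_g", "fiber_g", "sodium_mg",
]

NUTRIENT_FIELDS = (
    "energy_kcal", "protein_g", "carb_g", "sugar_g",
    "fat_g", "satfat_g", "fiber_g", "sodium_mg",
)


class KBError(Exception):
    """Base class for knowledge-base errors."""


class FormatError(KBError):
    """A file failed to parse; message names the file and line/field."""


class IntegrityError(KBError):
    """A reference does not resolve or an axiom is violated."""


class LookupError_(KBError):
    """A concept identifier is unknown to the KB."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OntClass:
    """A named concept with IS-A parents, synonyms and disjointness axioms."""

    name: str
    label: str = ""
    parents: frozenset[str] = frozenset()
    synonyms: frozenset[str] = frozenset()
    disjoint_with: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.name:
            raise IntegrityError("class name must be non-empty")
        if self.name in self.parents:
            raise IntegrityError(f"class {self.name!r} is its own parent")


@dataclass(frozen=True)
class Individual:
    """An instance assertion: an id, its classes, and property facts."""

    id: str
    types: frozenset[str] = frozenset()
    properties: frozenset[tuple] = frozenset()
    synonyms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FoodItem:
    """A food with nutrients per 100 g (FoodData Central convention)."""

    id: str
    name: str
    category: str
    nutrients_per_100g: Mapping[str, float]
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self):
        for k in NUTRIENT_FIELDS:
            v = self.nutrients_per_100g.get(k)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise IntegrityError(f"food {self.id!r}: missing nutrient {k!r}")
            if v < 0:
                raise IntegrityError(f"food {self.id!r}: nutrient {k}={v} < 0")


@dataclass(frozen=True)
class Recipe:
    """A dish: ingredients in grams, servings, prep time, cost per serving."""

    id: str
    name: str
    ingredients: tuple[tuple[str, float], ...]
    servings: int
    prep_time: float
    cost: float
    meal_types: frozenset[str] = frozenset()
    cuisine_tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.servings < 1:
            raise IntegrityError(f"recipe {self.id!r}: servings must be >= 1")
        for fid, grams in self.ingredients:
            if grams <= 0:
                raise IntegrityError(
                    f"recipe {self.id!r}: ingredient {fid!r} grams must be > 0")
        bad = set(self.meal_types) - set(MEAL_TYPES)
        if bad:
            raise IntegrityError(f"recipe {self.id!r}: unknown meal types {sorted(bad)}")


@dataclass(frozen=True)
class PatientProfile:
    """The person with ADRD: stage, comorbidities, and food restrictions.

    ``eer`` is the Estimated Energy Requirement in kcal/day if known;
    ``weight_kg``/``height_cm``/``activity`` let it be computed from the
    Institute of Medicine equations when absent.
    """

    age: float
    sex: str
    adrd_stage: str
    comorbidities: frozenset[str] = frozenset()
    allergies: frozenset[str] = frozenset()
    dislikes: frozenset[str] = frozenset()
    preferences: frozenset[str] = frozenset()
    religious_constraints: frozenset[str] = frozenset()
    eer: float | None = None
    meals_per_day: int = 3
    weight_kg: float | None = None
    height_cm: float | None = None
    activity: str = "low_active"

    def __post_init__(self):
        if self.age <= 0:
            raise IntegrityError("patient age must be > 0")
        if self.sex not in ("male", "female"):
            raise IntegrityError(f"unknown sex {self.sex!r}")
        if self.adrd_stage not in ("early", "middle", "late"):
            raise IntegrityError(f"unknown ADRD stage {self.adrd_stage!r}")
        if self.meals_per_day < 1:
            raise IntegrityError("meals_per_day must be >= 1")
        if self.eer is not None and self.eer <= 0:
            raise IntegrityError("eer, if present, must be > 0")


@dataclass(frozen=True)
class CaregiverProfile:
    """The caregiver's practical constraints: time, money, education."""

    time_limit: float
    budget: float
    education_level: str = "standard"

    def __post_init__(self):
        if self.time_limit <= 0:
            raise IntegrityError("time_limit must be > 0")
        if self.budget <= 0:
            raise IntegrityError("budget must be > 0")
        if self.education_level not in ("basic", "standard", "advanced"):
            raise IntegrityError(
                f"unknown education level {self.education_level!r}")


# ---------------------------------------------------------------------------
# The knowledge base
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeBase:
    classes: dict[str, OntClass] = field(default_factory=dict)
    individuals: dict[str, Individual] = field(default_factory=dict)
    foods: dict[str, FoodItem] = field(default_factory=dict)
    recipes: dict[str, Recipe] = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    def add_class(self, cls: OntClass) -> None:
        if cls.name in self.classes:
            raise IntegrityError(f"duplicate class {cls.name!r}")
        self.classes[cls.name] = cls

    def add_individual(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise IntegrityError(f"duplicate individual {ind.id!r}")
        self.individuals[ind.id] = ind

    def add_food(self, food: FoodItem) -> None:
        if food.id in self.foods:
            raise IntegrityError(f"duplicate food {food.id!r}")
        if food.category not in self.classes:
            raise IntegrityError(
                f"food {food.id!r}: unknown category class {food.category!r}")
        self.foods[food.id] = food
        # a food participates in the concept graph as an individual of its
        # category, carrying its nutrients as numeric property assertions
        props = frozenset(
            (k, float(food.nutrients_per_100g[k])) for k in NUTRIENT_FIELDS)
        self.add_individual(Individual(
            id=food.id, types=frozenset({food.category}),
            properties=props, synonyms=food.synonyms))

    def add_recipe(self, recipe: Recipe) -> None:
        if recipe.id in self.recipes:
            raise IntegrityError(f"duplicate recipe {recipe.id!r}")
        missing = [fid for fid, _ in recipe.ingredients if fid not in self.foods]
        if missing:
            raise IntegrityError(
                f"recipe {recipe.id!r}: unknown ingredient food ids {missing}")
        self.recipes[recipe.id] = recipe

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise IntegrityError on the first hit."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for cls in self.classes.values():
            for p in cls.parents:
                if p not in self.classes:
                    raise IntegrityError(
                        f"class {cls.name!r}: unknown parent {p!r}")
                g.add_edge(cls.name, p)
            for d in cls.disjoint_with:
                if d not in self.classes:
                    raise IntegrityError(
                        f"class {cls.name!r}: unknown disjoint class {d!r}")
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise IntegrityError(f"IS-A cycle detected: {path}")
        for ind in self.individuals.values():
            for t in ind.types:
                if t not in self.classes:
                    raise IntegrityError(
                        f"individual {ind.id!r}: unknown type {t!r}")
        # synonym uniqueness: each surface term maps to exactly one concept
        seen: dict[str, str] = {}
        for concept, terms in self._synonym_pairs():
            for term in terms:
                key = term.lower()
                prior = seen.get(key)
                if prior is not None and prior != concept:
                    raise IntegrityError(
                        f"synonym collision: {term!r} maps to both "
                        f"{prior!r} and {concept!r}")
                seen[key] = concept

    def _synonym_pairs(self) -> Iterable[tuple[str, set[str]]]:
        for cls in self.classes.values():
            yield cls.name, set(cls.synonyms)
        for ind in self.individuals.values():
            yield ind.id, set(ind.synonyms)

    # -- lookups ------------------------------------------------------------

    def require_class(self, name: str) -> OntClass:
        try:
            return self.classes[name]
        except KeyError:
            raise LookupError_(f"unknown class {name!r}") from None

    def instances_of(self, cls: str) -> list[str]:
        """Ids of individuals whose asserted or inherited type includes cls."""
        self.require_class(cls)
        out = []
        for ind in self.individuals.values():
            for t in ind.types:
                if t == cls or cls in superclasses(self, t):
                    out.append(ind.id)
                    break
        return sorted(out)


# ---------------------------------------------------------------------------
# IS-A reasoning helpers
# ---------------------------------------------------------------------------

def superclasses(kb: KnowledgeBase, cls: str) -> list[str]:
    """Transitive IS-A ancestors of ``cls``, excluding ``cls`` itself.

    Order is deterministic: breadth-first from the class, lexicographic
    among ties at the same depth; a class reached at several depths is
    listed once, at its shallowest.
    """
    kb.require_class(cls)
    out: list[str] = []
    seen = {cls}
    frontier = deque([cls])
    while frontier:
        level = sorted(
            {p for c in frontier for p in kb.classes[c].parents} - seen)
        out.extend(level)
        seen.update(level)
        frontier = deque(level)
    return out


def ancestors_of_concept(kb: KnowledgeBase, concept: str) -> set[str]:
    """All classes the concept belongs to: types plus their IS-A closure.

    Accepts a class, food, or individual id; for a class the set includes
    the class itself.
    """
    if concept in kb.classes:
        return {concept, *superclasses(kb, concept)}
    ind = kb.individuals.get(concept)
    if ind is None:
        raise LookupError_(f"unknown concept {concept!r}")
    out: set[str] = set()
    for t in ind.types:
        out.add(t)
        out.update(superclasses(kb, t))
    return out


def build_matching_vocabulary(
        kb: KnowledgeBase, top_classes: Iterable[str]) -> dict[str, str]:
    """Surface-term → canonical-concept-id map under the given top classes.

    Covers every descendant class of each top class (IS-A), every
    individual of those classes (type), and all their labels and
    synonyms. Keys are lowercase; ids stay case-sensitive.
    """
    tops = list(top_classes)
    for t in tops:
        kb.require_class(t)
    in_scope: set[str] = set()
    for name in kb.classes:
        anc = {name, *superclasses(kb, name)}
        if anc & set(tops):
            in_scope.add(name)
    vocab: dict[str, str] = {}

    def register(term: str, concept: str) -> None:
        vocab[term.lower()] = concept

    for name in sorted(in_scope):
        cls = kb.classes[name]
        register(name, name)
        if cls.label:
            register(cls.label, name)
        for s in cls.synonyms:
            register(s, name)
    for ind in sorted(kb.individuals.values(), key=lambda i: i.id):
        if ind.types & in_scope:
            register(ind.id, ind.id)
            food = kb.foods.get(ind.id)
            if food is not None:
                register(food.name, ind.id)
            for s in ind.synonyms:
                register(s, ind.id)
    return vocab


# ---------------------------------------------------------------------------
# TBox / ABox partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TBox:
    """Terminological half: class declarations and class axioms."""
    classes: tuple[OntClass, ...]


@dataclass(frozen=True)
class ABox:
    """Assertional half: individuals, foods, recipes."""
    individuals: tuple[Individual, ...]
    foods: tuple[FoodItem, ...]
    recipes: tuple[Recipe, ...]


def partition_kb(kb: KnowledgeBase) -> tuple[TBox, ABox]:
    tbox = TBox(classes=tuple(
        kb.classes[n] for n in sorted(kb.classes)))
    abox = ABox(
        individuals=tuple(kb.individuals[i] for i in sorted(kb.individuals)),
        foods=tuple(kb.foods[i] for i in sorted(kb.foods)),
        recipes=tuple(kb.recipes[i] for i in sorted(kb.recipes)),
    )
    return tbox, abox


def merge_kb(tbox: TBox, abox: ABox) -> KnowledgeBase:
    """Inverse of partition_kb: rebuild the KB from its two halves."""
    kb = KnowledgeBase()
    for cls in tbox.classes:
        kb.add_class(cls)
    food_ids = {f.id for f in abox.foods}
    for food in abox.foods:
        kb.add_food(food)
    for ind in abox.individuals:
        if ind.id not in food_ids:  # food individuals re-created by add_food
            kb.add_individual(ind)
    for recipe in abox.recipes:
        kb.add_recipe(recipe)
    kb.validate()
    return kb


def assertion_set(kb: KnowledgeBase) -> frozenset[tuple]:
    """The KB as a flat set of assertions, for equality checks."""
    out: set[tuple] = set()
    for cls in kb.classes.values():
        out.add(("class", cls.name, cls.label))
        out.update(("subclass_of", cls.name, p) for p in cls.parents)
        out.update(("synonym", cls.name, s) for s in cls.synonyms)
        out.update(("disjoint_with", cls.name, d) for d in cls.disjoint_with)
    for ind in kb.individuals.values():
        out.update(("type", ind.id, t) for t in ind.types)
        out.update(("prop", ind.id, p, v) for p, v in ind.properties)
        out.update(("synonym", ind.id, s) for s in ind.synonyms)
    for f in kb.foods.values():
        out.add(("food", f.id, f.name, f.category,
                 tuple(sorted(f.nutrients_per_100g.items()))))
    for r in kb.recipes.values():
        out.add(("recipe", r.id, r.name, r.ingredients, r.servings,
                 r.prep_time, r.cost, tuple(sorted(r.meal_types)),
                 tuple(sorted(r.cuisine_tags))))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_ontology_json(path: str | Path, kb: KnowledgeBase) -> None:
    """Read the canonical JSON ontology dialect into ``kb``.

    Schema::

        {"classes": [{"name", "label"?, "parents"?, "synonyms"?,
                      "disjoint_with"?}, ...],
         "individuals": [{"id", "types", "properties"?, "synonyms"?}, ...]}
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path.name}: line {e.lineno}: {e.msg}") from None
    for i, c in enumerate(doc.get("classes", [])):
        if "name" not in c:
            raise FormatError(f"{path.name}: classes[{i}]: missing 'name'")
        kb.add_class(OntClass(
            name=c["name"], label=c.get("label", ""),
            parents=frozenset(c.get("parents", [])),
            synonyms=frozenset(c.get("synonyms", [])),
            disjoint_with=frozenset(c.get("disjoint_with", []))))
    for i, d in enumerate(doc.get("individuals", [])):
        if "id" not in d:
            raise FormatError(f"{path.name}: individuals[{i}]: missing 'id'")
        props = frozenset(
            (p, tuple(v) if isinstance(v, list) else v)
            for p, v in (tuple(pv) for pv in d.get("properties", [])))
        kb.add_individual(Individual(
            id=d["id"], types=frozenset(d.get("types", [])),
            properties=props, synonyms=frozenset(d.get("synonyms", []))))


def load_ontology_turtle(path: str | Path, kb: KnowledgeBase) -> None:
    """Read a Turtle subset (rdfs:subClassOf, rdf:type, rdfs:label) into kb."""
    from rdflib import Graph, RDF, RDFS, URIRef

    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as e:  # rdflib raises several parser exception types
        raise FormatError(f"{Path(path).name}: {e}") from None

    def local(term) -> str:
        s = str(term)
        for sep in ("#", "/"):
            if sep in s:
                s = s.rsplit(sep, 1)[1]
        return s

    class_names: set[str] = set()
    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    inst_types: dict[str, set[str]] = {}
    for s, p, o in g:
        if p == RDFS.subClassOf:
            class_names.update((local(s), local(o)))
            parents.setdefault(local(s), set()).add(local(o))
        elif p == RDF.type and o != RDFS.Class and isinstance(o, URIRef):
            if local(o) in ("Class",):
                class_names.add(local(s))
            else:
                inst_types.setdefault(local(s), set()).add(local(o))
        elif p == RDFS.label:
            labels[local(s)] = str(o)
    class_names.update(t for ts in inst_types.values() for t in ts)
    for name in sorted(class_names):
        kb.add_class(OntClass(
            name=name, label=labels.get(name, ""),
            parents=frozenset(parents.get(name, set()))))
    for iid in sorted(inst_types):
        kb.add_individual(Individual(
            id=iid, types=frozenset(inst_types[iid])))


def load_food_table(path: str | Path, kb: KnowledgeBase) -> None:
    """Read the food composition CSV (FoodData Central-style columns)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"{path.name}: {e}") from None
    missing = [c for c in FOOD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    for row in df.to_dict("records"):
        nutrients = {k: float(row[k]) for k in NUTRIENT_FIELDS}
        syns = frozenset()
        raw = row.get("synonyms")
        if isinstance(raw, str) and raw:
            syns = frozenset(s.strip() for s in raw.split(";") if s.strip())
        kb.add_food(FoodItem(
            id=str(row["id"]), name=str(row["name"]),
            category=str(row["category"]),
            nutrients_per_100g=nutrients, synonyms=syns))


def load_recipes(path: str | Path, kb: KnowledgeBase) -> None:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path.name}: line {e.lineno}: {e.msg}") from None
    for i, r in enumerate(doc.get("recipes", doc if isinstance(doc, list) else [])):
        for key in ("id", "name", "ingredients", "servings"):
            if key not in r:
                raise FormatError(f"{path.name}: recipes[{i}]: missing {key!r}")
        kb.add_recipe(Recipe(
            id=r["id"], name=r["name"],
            ingredients=tuple((ing["food"], float(ing["grams"]))
                              for ing in r["ingredients"]),
            servings=int(r["servings"]),
            prep_time=float(r.get("prep_time", 30.0)),
            cost=float(r.get("cost", 5.0)),
            meal_types=frozenset(r.get("meal_types", [])),
            cuisine_tags=frozenset(r.get("cuisine_tags", []))))


def load_profiles(path: str | Path) -> tuple[dict[str, PatientProfile],
                                             dict[str, CaregiverProfile]]:
    """Read patient and caregiver profiles from a JSON bundle."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path.name}: line {e.lineno}: {e.msg}") from None
    patients = {}
    for pid, p in doc.get("patients", {}).items():
        patients[pid] = PatientProfile(
            age=p["age"], sex=p["sex"], adrd_stage=p["adrd_stage"],
            comorbidities=frozenset(p.get("comorbidities", [])),
            allergies=frozenset(p.get("allergies", [])),
            dislikes=frozenset(p.get("dislikes", [])),
            preferences=frozenset(p.get("preferences", [])),
            religious_constraints=frozenset(p.get("religious_constraints", [])),
            eer=p.get("eer"), meals_per_day=p.get("meals_per_day", 3),
            weight_kg=p.get("weight_kg"), height_cm=p.get("height_cm"),
            activity=p.get("activity", "low_active"))
    caregivers = {}
    for cid, c in doc.get("caregivers", {}).items():
        caregivers[cid] = CaregiverProfile(
            time_limit=c["time_limit"], budget=c["budget"],
            education_level=c.get("education_level", "standard"))
    return patients, caregivers


def load_kb(food_table: str | Path, recipes: str | Path,
            ontology: str | Path) -> KnowledgeBase:
    """Assemble and validate a KnowledgeBase from the three input files.

    The ontology may be the canonical JSON dialect (``.json``) or a
    Turtle subset (``.ttl``). Raises FormatError on parse failure and
    IntegrityError on dangling references or axiom violations.
    """
    kb = KnowledgeBase()
    ontology = Path(ontology)
    if ontology.suffix in (".ttl", ".turtle"):
        load_ontology_turtle(ontology, kb)
    else:
        load_ontology_json(ontology, kb)
    kb.validate()  # catch IS-A cycles before dependent loads
    load_food_table(food_table, kb)
    load_recipes(recipes, kb)
    kb.validate()
    return kb
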