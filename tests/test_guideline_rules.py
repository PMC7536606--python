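import pytest

from adrd_diet.guideline_rules import (MissingDataError, check_meal_constraints,
                                       energy_shares,
                                       estimated_energy_requirement,
                                       meal_calorie_target, mind_classify,
                                       recipe_nutrients_per_serving)
from adrd_diet.ontology_kb import (CaregiverProfile, FoodItem, KnowledgeBase,
                                   OntClass, PatientProfile, Recipe)


def _nutrients(energy, protein, carb, sugar, fat, satfat=0.0, fiber=0.0,
               sodium=0.0):
    return {"energy_kcal": energy, "protein_g": protein, "carb_g": carb,
            "sugar_g": sugar, "fat_g": fat, "satfat_g": satfat,
            "fiber_g": fiber, "sodium_mg": sodium}


@pytest.fixture()
def macro_kb():
    """Foods with round macros so meal arithmetic is checkable by hand."""
    kb = KnowledgeBase()
    for name in ("Food", "Fish", "Grains", "Vegetables", "Nuts", "Sweets"):
        parents = frozenset({"Food"}) if name != "Food" else frozenset()
        kb.add_class(OntClass(name=name, parents=parents))
    # per 100 g: lean fish 150 kcal / 25 g protein; grain 120 kcal / 25 g
    # carb; veg 40 kcal / 2 g sugar; syrup-like sweet 300 kcal all sugar
    kb.add_food(FoodItem(id="fish", name="fish", category="Fish",
                         nutrients_per_100g=_nutrients(150, 25, 0, 0, 5)))
    kb.add_food(FoodItem(id="grain", name="grain", category="Grains",
                         nutrients_per_100g=_nutrients(120, 3, 25, 1, 1)))
    kb.add_food(FoodItem(id="veg", name="veg", category="Vegetables",
                         nutrients_per_100g=_nutrients(40, 2, 7, 2, 0.3)))
    kb.add_food(FoodItem(id="syrup", name="syrup", category="Sweets",
                         nutrients_per_100g=_nutrients(300, 0, 75, 75, 0)))
    kb.add_food(FoodItem(id="nutmix", name="nutmix", category="Nuts",
                         nutrients_per_100g=_nutrients(600, 20, 20, 4, 50)))
    kb.validate()
    return kb


@pytest.fixture()
def diabetic_patient():
    return PatientProfile(age=65, sex="male", adrd_stage="early",
                          comorbidities=frozenset({"type2_diabetes"}),
                          allergies=frozenset({"Nuts"}), eer=2000,
                          meals_per_day=3)


@pytest.fixture()
def caregiver():
    return CaregiverProfile(time_limit=40, budget=12)


class TestMindClassification:
    @pytest.mark.parametrize("concept,expected", [
        ("Berries", "encourage"),
        ("Cheese", "limit"),
        ("blueberries", "encourage"),      # via IS-A from Berries
        ("cheddar_cheese", "limit"),       # via IS-A from Cheese
        ("water", "neutral"),              # unlisted, no listed ancestor
        ("olive_oil", "encourage"),
        ("butter", "limit"),
    ])
    def test_bundle_concepts(self, kb, concept, expected):
        assert mind_classify(kb, concept).value == expected

    def test_limit_wins_over_encourage_when_both_inherited(self):
        kb = KnowledgeBase()
        kb.add_class(OntClass(name="Food"))
        kb.add_class(OntClass(name="Nuts", parents=frozenset({"Food"})))
        kb.add_class(OntClass(name="Sweets", parents=frozenset({"Food"})))
        kb.add_class(OntClass(name="CandiedNuts",
                              parents=frozenset({"Nuts", "Sweets"})))
        kb.validate()
        assert mind_classify(kb, "CandiedNuts").value == "limit"

    def test_unknown_identifier_is_lookup_error(self, kb):
        from adrd_diet.ontology_kb import LookupError_
        with pytest.raises(LookupError_):
            mind_classify(kb, "unobtainium")


class TestMealCalorieTarget:
    def test_hhs_rule_for_male_on_three_meals(self):
        p = PatientProfile(age=65, sex="male", adrd_stage="early",
                           meals_per_day=3)
        assert meal_calorie_target(p, "lunch") == (800.0, 850.0)

    def test_ada_diabetic_dinner_is_quarter_of_eer(self, diabetic_patient):
        lo, hi = meal_calorie_target(diabetic_patient, "dinner")
        assert lo == hi == 500.0

    def test_ada_rule_wins_over_hhs_for_diabetic_dinner(self, diabetic_patient):
        # the patient is also male on three meals/day
        assert meal_calorie_target(diabetic_patient, "dinner") == (500.0, 500.0)
        assert meal_calorie_target(diabetic_patient, "lunch") == (800.0, 850.0)

    def test_diabetic_dinner_without_eer_asks_for_it(self):
        p = PatientProfile(age=65, sex="male", adrd_stage="early",
                           comorbidities=frozenset({"type2_diabetes"}))
        with pytest.raises(MissingDataError) as exc:
            meal_calorie_target(p, "dinner")
        assert exc.value.field == "eer"

    def test_fallback_is_eer_over_meals_within_ten_percent(self):
        p = PatientProfile(age=70, sex="female", adrd_stage="middle",
                           eer=1800, meals_per_day=3)
        lo, hi = meal_calorie_target(p, "lunch")
        assert lo == pytest.approx(540.0) and hi == pytest.approx(660.0)

    def test_eer_computed_from_iom_equation_when_absent(self):
        p = PatientProfile(age=65, sex="male", adrd_stage="early",
                           weight_kg=75, height_cm=176, activity="low_active")
        eer = estimated_energy_requirement(p)
        # 662 - 9.53*65 + 1.11*(15.91*75 + 539.6*1.76)
        assert eer == pytest.approx(662 - 9.53 * 65 +
                                    1.11 * (15.91 * 75 + 539.6 * 1.76))


class TestMealConstraints:
    def _recipe(self, ingredients, **kw):
        defaults = dict(id="r", name="r", servings=2, prep_time=25, cost=8.0,
                        meal_types=frozenset({"dinner"}))
        defaults.update(kw)
        return Recipe(ingredients=tuple(ingredients), **defaults)

    def test_compliant_dinner_has_no_violations(self, macro_kb,
                                                diabetic_patient, caregiver):
        # per serving: fish 170 g, grain 220 g, veg 100 g
        # energy = (1.7*150 + 2.2*120 + 1.0*40) = 559 ... solve by hand:
        # choose fish 160 g, grain 180 g, veg 100 g per serving:
        # energy = 240 + 216 + 40 = 496 kcal (inside 500 +/- 5%)
        # protein = 40 + 5.4 + 2 = 47.4 g -> 4*47.4/496 = 38% too high;
        # use fish 100 g, grain 250 g, veg 100 g:
        # energy = 150 + 300 + 40 = 490; protein = 25+7.5+2 = 34.5 ->
        # share 28.2% (in [20,30]); sugar = 0+2.5+2 = 4.5 g -> 3.7% < 10%
        recipe = self._recipe([("fish", 200), ("grain", 500), ("veg", 200)])
        violations = check_meal_constraints(recipe, diabetic_patient,
                                            caregiver, macro_kb, meal="dinner")
        assert violations == []

    def test_sugary_dinner_names_the_sugar_bound(self, macro_kb,
                                                 diabetic_patient, caregiver):
        # add syrup: sugar energy share rises above 10% of meal energy
        recipe = self._recipe([("fish", 200), ("grain", 400), ("veg", 200),
                               ("syrup", 40)])
        violations = check_meal_constraints(recipe, diabetic_patient,
                                            caregiver, macro_kb, meal="dinner")
        names = {v.constraint for v in violations}
        assert "sugar_share" in names

    def test_allergy_via_isa_ancestor(self, macro_kb, diabetic_patient,
                                      caregiver):
        recipe = self._recipe([("fish", 200), ("grain", 500), ("veg", 200),
                               ("nutmix", 5)])
        violations = check_meal_constraints(recipe, diabetic_patient,
                                            caregiver, macro_kb, meal="dinner")
        allergy = [v for v in violations if v.constraint == "allergy"]
        assert allergy and allergy[0].observed == "nutmix"

    def test_time_and_cost_violations_cite_profile(self, macro_kb,
                                                   diabetic_patient,
                                                   caregiver):
        recipe = self._recipe([("fish", 200), ("grain", 500), ("veg", 200)],
                              prep_time=90, cost=30.0)
        names = {v.constraint: v for v in check_meal_constraints(
            recipe, diabetic_patient, caregiver, macro_kb, meal="dinner")}
        assert {"prep_time", "cost"} <= set(names)
        assert all(v.provenance for v in names.values())

    def test_every_violation_carries_provenance(self, kb, persona):
        patient, caregiver = persona
        for recipe in kb.recipes.values():
            meal = sorted(recipe.meal_types)[0]
            for v in check_meal_constraints(recipe, patient, caregiver, kb,
                                            meal=meal):
                assert v.provenance


class TestEnergyAccounting:
    def test_atwater_energy_within_thirty_percent_of_tabulated(self, kb):
        for food in kb.foods.values():
            n = food.nutrients_per_100g
            atwater = 4 * n["protein_g"] + 4 * n["carb_g"] + 9 * n["fat_g"]
            assert abs(atwater - n["energy_kcal"]) <= 0.3 * n["energy_kcal"] \
                + 1e-9, food.id

    def test_shares_computed_from_tabulated_energy(self):
        shares = energy_shares(_nutrients(400, 25, 30, 10, 10))
        assert shares["protein"] == pytest.approx(25.0)
        assert shares["sugar"] == pytest.approx(10.0)
        assert shares["fat"] == pytest.approx(22.5)

    def test_recipe_nutrients_scale_by_grams_and_servings(self, macro_kb):
        recipe = Recipe(id="r", name="r",
                        ingredients=(("fish", 200), ("veg", 100)),
                        servings=2, prep_time=10, cost=5,
                        meal_types=frozenset({"lunch"}))
        n = recipe_nutrients_per_serving(recipe, macro_kb)
        assert n["energy_kcal"] == pytest.approx((2 * 150 + 40) / 2)
        assert n["protein_g"] == pytest.approx((2 * 25 + 2) / 2)


class TestManifestAgreement:
    def test_checker_reproduces_the_generator_manifest(self, kb, persona,
                                                       manifest):
        patient, caregiver = persona
        admissible = [
            rid for rid in sorted(kb.recipes)
            if "dinner" in kb.recipes[rid].meal_types
            and not check_meal_constraints(kb.recipes[rid], patient,
                                           caregiver, kb, meal="dinner")]
        assert admissible == manifest["admissible_dinner_recipes"]

    def test_each_marked_violator_violates_its_constraint(self, kb, persona,
                                                          manifest):
        patient, caregiver = persona
        for constraint, rid in manifest["violators"].items():
            violations = check_meal_constraints(kb.recipes[rid], patient,
                                                caregiver, kb, meal="dinner")
            assert constraint in {v.constraint for v in violations}
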