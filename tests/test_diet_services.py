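import datetime as dt

import pytest

from adrd_diet.diet_services import (DietHistory, MealRecord, TipBank,
                                     check_food_suitability, recommend_recipe,
                                     suggest_snack)
from adrd_diet.dialogue_manager import DialogueSession
from adrd_diet.guideline_rules import check_meal_constraints
from adrd_diet.ontology_kb import (CaregiverProfile, FoodItem, KnowledgeBase,
                                   OntClass, PatientProfile)


class TestSuitability:
    def test_cheese_not_recommended_citing_mind_limit(self, kb, rules,
                                                      persona):
        patient, _ = persona
        verdict = check_food_suitability("Cheese", "snack", patient, kb, rules)
        assert verdict.suitable == "not_recommended"
        assert any("MIND" in prov for prov, _ in verdict.reasons)

    def test_berries_recommended_citing_mind_encourage(self, kb, rules,
                                                       persona):
        patient, _ = persona
        verdict = check_food_suitability("blueberries", "snack", patient,
                                         kb, rules)
        assert verdict.suitable == "recommended"
        assert any("MIND" in prov for prov, _ in verdict.reasons)

    def test_allergy_overrides_mind_status(self, kb, rules, persona):
        patient, _ = persona  # allergic to Nuts; almonds are encouraged
        verdict = check_food_suitability("almonds", "snack", patient, kb,
                                         rules)
        assert verdict.suitable == "not_recommended"
        assert any("allergic" in why for _, why in verdict.reasons)

    def test_every_verdict_cites_a_reason(self, kb, rules, persona):
        patient, _ = persona
        for fid in sorted(kb.foods)[:20]:
            verdict = check_food_suitability(fid, "snack", patient, kb, rules)
            assert verdict.reasons


class TestSnackSuggestion:
    def _toy(self):
        kb = KnowledgeBase()
        kb.add_class(OntClass(name="Food"))
        kb.add_class(OntClass(name="SnackFood", parents=frozenset({"Food"})))
        kb.add_class(OntClass(name="Nuts",
                              parents=frozenset({"Food", "SnackFood"})))
        kb.add_class(OntClass(name="Sweets",
                              parents=frozenset({"Food", "SnackFood"})))

        def nut(fid):
            kb.add_food(FoodItem(id=fid, name=fid, category="Nuts",
                                 nutrients_per_100g={
                                     "energy_kcal": 600, "protein_g": 20,
                                     "carb_g": 20, "sugar_g": 4, "fat_g": 50,
                                     "satfat_g": 5, "fiber_g": 8,
                                     "sodium_mg": 2}))

        nut("walnuts")
        kb.add_food(FoodItem(id="candy", name="candy", category="Sweets",
                             nutrients_per_100g={
                                 "energy_kcal": 400, "protein_g": 1,
                                 "carb_g": 90, "sugar_g": 60, "fat_g": 5,
                                 "satfat_g": 3, "fiber_g": 0,
                                 "sodium_mg": 50}))
        kb.validate()
        return kb

    def _patient(self, **kw):
        defaults = dict(age=65, sex="male", adrd_stage="early", eer=2000)
        defaults.update(kw)
        return PatientProfile(**defaults)

    def test_only_encouraged_non_excluded_snack_wins(self, simple_caregiver):
        kb = self._toy()
        found = suggest_snack(self._patient(), simple_caregiver, kb)
        assert found is not None and found[0] == "walnuts"

    def test_all_snacks_excluded_gives_none(self, simple_caregiver):
        kb = self._toy()
        patient = self._patient(allergies=frozenset({"Nuts"}))
        # candy is MIND-limited, walnuts allergic: nothing remains
        assert suggest_snack(patient, simple_caregiver, kb) is None

    def test_tie_breaks_on_lexicographic_id(self, simple_caregiver):
        kb = self._toy()
        kb.add_food(FoodItem(id="almonds", name="almonds", category="Nuts",
                             nutrients_per_100g={
                                 "energy_kcal": 600, "protein_g": 20,
                                 "carb_g": 20, "sugar_g": 4, "fat_g": 50,
                                 "satfat_g": 5, "fiber_g": 8, "sodium_mg": 2}))
        found = suggest_snack(self._patient(), simple_caregiver, kb)
        assert found[0] == "almonds"

    def test_bundle_persona_gets_a_berry(self, kb, rules, persona):
        patient, caregiver = persona
        found = suggest_snack(patient, caregiver, kb, rules)
        assert found is not None
        fid, verdict = found
        assert verdict.suitable == "recommended"
        from adrd_diet.guideline_rules import mind_classify
        assert mind_classify(kb, fid).value == "encourage"


class TestRecipeRecommendation:
    def test_top_candidate_is_admissible_and_deterministic(self, kb, rules,
                                                           persona, manifest):
        patient, caregiver = persona
        rec = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                               rules)
        assert rec is not None
        assert rec.recipe.id in manifest["admissible_dinner_recipes"]
        rec2 = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                                rules)
        assert rec2.recipe.id == rec.recipe.id

    def test_soundness_returned_recipe_has_no_violations(self, kb, rules,
                                                         persona):
        patient, caregiver = persona
        rec = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                               rules)
        assert check_meal_constraints(rec.recipe, patient, caregiver, kb,
                                      meal="dinner") == []

    def test_rejection_yields_the_other_admissible_recipe(self, kb, rules,
                                                          persona, manifest):
        patient, caregiver = persona
        session = DialogueSession(session_id="s")
        first = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                                 rules, session)
        session.rejected.add(first.recipe.id)
        second = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                                  rules, session)
        assert second.recipe.id != first.recipe.id
        assert {first.recipe.id, second.recipe.id} == \
            set(manifest["admissible_dinner_recipes"])
        session.rejected.add(second.recipe.id)
        assert recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                                rules, session) is None

    def test_impossible_time_limit_gives_none(self, kb, rules, persona):
        patient, _ = persona
        tight = CaregiverProfile(time_limit=1, budget=12)
        assert recommend_recipe({"meal": "dinner"}, patient, tight, kb,
                                rules) is None

    def test_rationale_cites_guideline_provenance(self, kb, rules, persona):
        patient, caregiver = persona
        rec = recommend_recipe({"meal": "dinner"}, patient, caregiver, kb,
                               rules)
        provs = {prov for prov, _ in rec.rationale}
        assert any("ADA" in p for p in provs)

    def test_brute_force_equivalence_with_constraint_checker(self, kb, rules,
                                                             persona):
        from adrd_diet.diet_services import admissible_recipes
        patient, caregiver = persona
        expected = [rid for rid in sorted(kb.recipes)
                    if "dinner" in kb.recipes[rid].meal_types
                    and not check_meal_constraints(
                        kb.recipes[rid], patient, caregiver, kb,
                        meal="dinner")]
        got = [r.id for r in admissible_recipes("dinner", patient, caregiver,
                                                kb)]
        assert got == expected


class TestDietHistory:
    def test_daily_recall_sums_the_day(self):
        h = DietHistory()
        d = dt.date(2025, 3, 10)
        for meal, e in (("breakfast", 400), ("lunch", 820), ("dinner", 500)):
            h.record_meal(MealRecord(date=d, meal_type=meal,
                                     items=("x",), energy_kcal=e))
        summary = h.recall_history("day", d)
        assert len(summary["records"]) == 3
        assert summary["total_energy_kcal"] == 1720

    def test_weekly_recall_covers_seven_days(self):
        h = DietHistory()
        end = dt.date(2025, 3, 10)
        for i in range(10):
            h.record_meal(MealRecord(date=end - dt.timedelta(days=i),
                                     meal_type="dinner", items=("x",),
                                     energy_kcal=500))
        summary = h.recall_history("week", end)
        assert len(summary["records"]) == 7

    def test_empty_history_recall_is_not_an_error(self):
        h = DietHistory()
        summary = h.recall_history("day", dt.date(2025, 1, 1))
        assert summary["records"] == [] and summary["total_energy_kcal"] == 0

    def test_jsonl_persistence_round_trip(self, tmp_path):
        path = tmp_path / "history.jsonl"
        h = DietHistory(path)
        h.record_meal(MealRecord(date=dt.date(2025, 3, 10),
                                 meal_type="lunch", items=("a", "b"),
                                 energy_kcal=640.0))
        again = DietHistory(path)
        assert again.records == h.records

    def test_invalid_date_rejected(self):
        with pytest.raises(ValueError):
            MealRecord(date="2025-03-10", meal_type="lunch", items=(),
                       energy_kcal=1)


class TestTips:
    def test_tip_matches_category_and_stage(self, bundle):
        tips = bundle[4]
        tip, text = tips.get_tip_entry("eating_challenge", "middle")
        assert "eating_challenge" in tip["tags"]
        assert "middle" in tip["tags"] or "any" in tip["tags"]
        assert text

    def test_unknown_category_is_an_error(self, bundle):
        with pytest.raises(ValueError):
            bundle[4].get_tip("horoscopes", "early")

    def test_consecutive_calls_cycle_through_tips(self, bundle):
        tips = bundle[4]
        t1 = tips.get_tip("proper_diet", "early")
        t2 = tips.get_tip("proper_diet", "early")
        assert t1 != t2

    def test_stage_fallback_to_stage_agnostic(self, bundle):
        # no late-stage proper-diet tip would still yield a tip
        text = bundle[4].get_tip("proper_diet", "late")
        assert text

    def test_empty_bank_is_an_error(self):
        with pytest.raises(ValueError):
            TipBank([])
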