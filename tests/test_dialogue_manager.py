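import pytest

from adrd_diet.dialogue_manager import (SERVICE_CATEGORIES, ContextEntry,
                                        DialogueError, DialogueSession,
                                        TemplatingError, default_registry,
                                        default_state_graph, detect_intent,
                                        expire_context, extract_slot_values,
                                        generate_response, next_state,
                                        registered_categories)
from adrd_diet.ontology_kb import CaregiverProfile, build_matching_vocabulary


@pytest.fixture(scope="module")
def vocabulary(kb):
    return build_matching_vocabulary(kb, {"Food"})


class TestIntentDetection:
    def test_cheese_snack_question_yields_suitability_intent(self, vocabulary):
        result = detect_intent("Is cheese good as a snack for my dad?",
                               default_registry(), vocabulary)
        assert result is not None
        intent, slots, score = result
        assert intent.name == "FoodSuitability"
        assert slots["food"] == "Cheese"
        assert slots["meal"] == "snack"
        assert score >= 0.5

    def test_synonym_resolves_to_canonical_food(self, vocabulary):
        result = detect_intent("is cheddar ok for a snack",
                               default_registry(), vocabulary)
        intent, slots, _ = result
        assert intent.name == "FoodSuitability"
        assert slots["food"] == "cheddar_cheese"

    def test_gibberish_is_no_match(self, vocabulary):
        assert detect_intent("purple elephants dance on tuesdays",
                             default_registry(), vocabulary) is None

    def test_empty_utterance_is_no_match(self, vocabulary):
        assert detect_intent("   ", default_registry(), vocabulary) is None

    def test_detection_is_deterministic(self, vocabulary):
        args = ("recommend a recipe for dinner", default_registry(),
                vocabulary)
        r1, r2 = detect_intent(*args), detect_intent(*args)
        assert r1[0].name == r2[0].name and r1[1] == r2[1] and r1[2] == r2[2]

    def test_exactly_five_service_categories_registered(self):
        cats = registered_categories(default_registry())
        assert len(cats) == 5
        assert set(cats) == set(SERVICE_CATEGORIES)


class TestSlotExtraction:
    def test_over_answering_fills_several_slots_at_once(self, vocabulary):
        intent = next(i for i in default_registry()
                      if i.name == "RecipeRecommendation")
        values = extract_slot_values(
            "dinner for two servings in 30 minutes", intent.slots, vocabulary)
        assert values == {"meal": "dinner", "servings": 2.0,
                          "max_time": 30.0}

    def test_minutes_distinguished_from_plain_numbers(self, vocabulary):
        intent = next(i for i in default_registry()
                      if i.name == "RecipeRecommendation")
        values = extract_slot_values("45 minutes", intent.slots, vocabulary)
        assert values == {"max_time": 45.0}

    def test_window_words(self, vocabulary):
        intent = next(i for i in default_registry()
                      if i.name == "HistoryRecall")
        assert extract_slot_values("for the week", intent.slots,
                                   vocabulary) == {"window": "week"}
        assert extract_slot_values("just today", intent.slots,
                                   vocabulary) == {"window": "day"}


class TestStateGraph:
    def test_fresh_session_starts_at_s0(self):
        session = DialogueSession(session_id="s")
        assert session.current_state == "S0"
        assert session.history == ["S0"]

    def test_s3_successors_chosen_by_condition_order(self):
        graph = default_state_graph("meal_suggestion")
        session = DialogueSession(session_id="s", current_state="S3",
                                  history=["S0", "S1", "S2", "S3"])
        state, action = next_state(session, {"input_yes": True}, graph)
        assert (state, action) == ("S4", "confirm")
        session = DialogueSession(session_id="s", current_state="S3",
                                  history=["S0", "S1", "S2", "S3"])
        state, action = next_state(session, {"input_no": True}, graph)
        assert (state, action) == ("S5", "acknowledge_rejection")

    def test_unmatched_input_self_loops_with_reprompt(self):
        graph = default_state_graph("meal_suggestion")
        session = DialogueSession(session_id="s", current_state="S3",
                                  history=["S0", "S1", "S2", "S3"])
        state, action = next_state(session, {"input_yes": False}, graph)
        assert state == "S3" and action == "reprompt"

    def test_corrupted_state_resets_to_s0(self):
        graph = default_state_graph("food_explanation")
        session = DialogueSession(session_id="s", current_state="S99",
                                  history=["S0"])
        state, _ = next_state(session, {}, graph)
        assert state == "S0"

    def test_every_successor_is_declared(self):
        for category in SERVICE_CATEGORIES:
            graph = default_state_graph(category)
            for state in graph.values():
                for _, succ in state.transitions:
                    assert succ in graph


class TestContext:
    def test_short_entry_expires_after_its_countdown(self):
        session = DialogueSession(session_id="s")
        session.set_context(ContextEntry("meal", "lunch", scope="short",
                                         expires_after=2))
        expire_context(session)
        assert session.get_context("meal") == "lunch"
        expire_context(session)
        assert session.get_context("meal") is None

    def test_long_entry_never_expires(self):
        session = DialogueSession(session_id="s")
        session.set_context(ContextEntry("allergies", ["Nuts"], scope="long"))
        for _ in range(30):
            expire_context(session)
        assert session.get_context("allergies") == ["Nuts"]

    def test_empty_context_is_unchanged(self):
        session = DialogueSession(session_id="s")
        expire_context(session)
        assert session.context == {}

    def test_short_entry_requires_positive_expiry(self):
        with pytest.raises(DialogueError):
            ContextEntry("k", 1, scope="short", expires_after=0)


class TestResponseGeneration:
    PAYLOAD = {"recipe": "Baked salmon", "recipe_id": "r1",
               "prep_time": "25", "energy": "505",
               "numbers": "protein 25% and sugar 4% of meal energy",
               "rationale": "fits the dinner target"}

    def test_advanced_tier_includes_numeric_rationale(self):
        text = generate_response(
            "recipe_recommendation", self.PAYLOAD,
            CaregiverProfile(time_limit=30, budget=10,
                             education_level="advanced"))
        assert "kcal" in text and "%" in text

    def test_basic_tier_avoids_percent_figures(self):
        text = generate_response(
            "recipe_recommendation", self.PAYLOAD,
            CaregiverProfile(time_limit=30, budget=10,
                             education_level="basic"))
        assert "%" not in text

    def test_missing_template_is_an_error_naming_the_action(self):
        with pytest.raises(TemplatingError, match="no_such_action"):
            generate_response("no_such_action", {})

    def test_missing_payload_field_is_an_error(self):
        with pytest.raises(TemplatingError, match="recipe"):
            generate_response("confirm", {})

    def test_deterministic_for_fixed_inputs(self):
        cg = CaregiverProfile(time_limit=30, budget=10)
        assert generate_response("greet", {"patient_name": "x"}, cg) == \
            generate_response("greet", {"patient_name": "x"}, cg)
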