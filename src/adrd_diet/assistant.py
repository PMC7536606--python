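"""The conversation engine: one object that runs whole dialogues.

`Assistant` wires the conversation layer (intent detection, the
finite-state dialogue graphs, slot filling, context expiry, response
templates) to the back-end diet services (suitability, snack and recipe
recommendation, tips, history) for one patient/caregiver pair. Each
call to :meth:`respond` processes one user turn and returns the
system's text, the speech act behind it, and the payload it rendered —
the eval harness and the chat CLI both drive this surface.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .dialogue_manager import (DEFAULT_MAX_TURNS, DEFAULT_SIMILARITY_THRESHOLD,
                               DEFAULT_TEMPLATES, ContextEntry, DialogueSession,
                               Intent, Slot, default_registry,
                               default_state_graph, detect_intent,
                               extract_slot_values, generate_response,
                               interpret_decision, is_quit, next_state)
from .diet_services import (DietHistory, MealRecord, Recommendation, TipBank,
                            check_food_suitability, recommend_recipe,
                            suggest_snack)
from .guideline_rules import MissingDataError
from .inference_engine import Rule
from .ontology_kb import (CaregiverProfile, KnowledgeBase, LookupError_,
                          PatientProfile)

_VERDICT_PLAIN = {
    "recommended": "a good choice",
    "not_recommended": "not a good choice",
    "caution": "okay, but only with care",
}

_EER_SLOT = Slot("eer", "number", True,
                 "What is the patient's daily energy requirement, in calories?")


@dataclass
class TurnResult:
    text: str
    action: str
    payload: dict = field(default_factory=dict)
    state: str = "S0"


class Assistant:
    """A diet assistant bound to one knowledge base and one user pair."""

    def __init__(self, kb: KnowledgeBase, rules: Iterable[Rule],
                 patient: PatientProfile, caregiver: CaregiverProfile,
                 tip_bank: TipBank, history: DietHistory | None = None,
                 vocabulary: Mapping[str, str] | None = None,
                 registry: tuple[Intent, ...] | None = None,
                 max_turns: int = DEFAULT_MAX_TURNS,
                 threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                 today: dt.date | None = None):
        self.kb = kb
        self.rules = list(rules)
        self.patient = patient
        self.caregiver = caregiver
        self.tip_bank = tip_bank
        self.history = history if history is not None else DietHistory()
        self.registry = registry if registry is not None else default_registry()
        if vocabulary is None:
            from .ontology_kb import build_matching_vocabulary
            tops = [c for c in ("Food", "Nutrient", "Meal") if c in kb.classes]
            vocabulary = build_matching_vocabulary(kb, tops)
        self.vocabulary = dict(vocabulary)
        self.max_turns = max_turns
        self.threshold = threshold
        self.today = today or dt.date.today()
        self._sessions = 0

    # -- session lifecycle --------------------------------------------------

    def new_session(self, session_id: str | None = None) -> DialogueSession:
        """Fresh session; the profile enters as permanent long-term context."""
        self._sessions += 1
        session = DialogueSession(
            session_id=session_id or f"session-{self._sessions}")
        session.set_context(ContextEntry(
            "allergies", sorted(self.patient.allergies), scope="long"))
        session.set_context(ContextEntry(
            "adrd_stage", self.patient.adrd_stage, scope="long"))
        session.set_context(ContextEntry(
            "comorbidities", sorted(self.patient.comorbidities), scope="long"))
        return session

    def greeting(self) -> str:
        return generate_response("greet", {"patient_name": "your loved one"},
                                 self.caregiver)

    # -- the turn loop ------------------------------------------------------

    def respond(self, session: DialogueSession, user_text: str) -> TurnResult:
        session.turn_count += 1
        try:
            result = self._respond_inner(session, user_text)
        finally:
            from .dialogue_manager import expire_context
            expire_context(session)
        if (session.turn_count >= self.max_turns and not session.done
                and result.action not in self._SATISFYING_ACTIONS):
            session.failed = True
        return result

    _SATISFYING_ACTIONS = frozenset({
        "suitability_verdict", "snack_suggestion", "confirm", "tip",
        "history_summary", "meal_recorded"})

    def _graph_for(self, intent: Intent):
        if intent.name == "RecipeRecommendation":
            return default_state_graph("meal_suggestion")
        return default_state_graph("food_explanation")

    def _respond_inner(self, session: DialogueSession,
                       user_text: str) -> TurnResult:
        if is_quit(user_text):
            session.done = True
            return self._render(session, "goodbye", {})

        # awaiting a yes/no decision on an offered recipe
        if session.active_intent is not None and session.current_state == "S3":
            return self._handle_decision(session, user_text)

        if session.active_intent is None:
            detected = detect_intent(user_text, self.registry,
                                     self.vocabulary, self.threshold)
            if detected is None:
                return self._render(session, "clarify", {})
            intent, slot_values, _score = detected
            session.active_intent = intent
            session.reprompts = 0
            graph = self._graph_for(intent)
            if session.current_state not in graph:
                session.current_state = "S0"
                session.history.append("S0")
            next_state(session, {"has_intent": True}, graph)
            for name, value in slot_values.items():
                session.slots.setdefault(name, value)
            # long-term context pre-fills matching slots without asking
            for slot in intent.slots:
                if slot.name not in session.slots:
                    ctx = session.get_context(slot.name)
                    if ctx is not None:
                        session.slots[slot.name] = ctx
            return self._advance(session)

        # an elicitation is outstanding: read the reply as slot values
        intent = session.active_intent
        pending = [s for s in self._required_slots(session, intent)
                   if s.name not in session.slots]
        values = extract_slot_values(user_text, pending, self.vocabulary)
        for name, value in values.items():
            session.slots.setdefault(name, value)  # never overwrite
        still_pending = session.pending_slot is not None and \
            session.pending_slot not in session.slots
        if still_pending:
            session.reprompts += 1
            if session.reprompts >= 3:
                return self._abandon(session)
            slot = next(s for s in intent.slots
                        if s.name == session.pending_slot)
            return self._render(session, "reprompt", {"prompt": slot.prompt})
        session.reprompts = 0
        return self._advance(session)

    def _required_slots(self, session: DialogueSession,
                        intent: Intent) -> list[Slot]:
        slots = [s for s in intent.slots if s.required]
        if session.get_context("need_eer"):
            slots.append(_EER_SLOT)
        return slots

    def _advance(self, session: DialogueSession) -> TurnResult:
        """Elicit the next required slot, or fulfill when all are filled."""
        intent = session.active_intent
        graph = self._graph_for(intent)
        for slot in self._required_slots(session, intent):
            if slot.name not in session.slots:
                session.pending_slot = slot.name
                return self._render(session, "elicit_slot",
                                    {"prompt": slot.prompt})
        session.pending_slot = None
        next_state(session, {"slots_complete": True}, graph)
        return self._fulfill(session)

    def _abandon(self, session: DialogueSession) -> TurnResult:
        graph = self._graph_for(session.active_intent)
        next_state(session, {"retries_exhausted": True}, graph)
        session.active_intent = None
        session.pending_slot = None
        session.slots.clear()
        session.failed = True
        return self._render(session, "apologize", {})

    def _finish_request(self, session: DialogueSession) -> None:
        """A request completed; reopen the session for the next one."""
        session.active_intent = None
        session.pending_slot = None
        session.slots.clear()
        session.reprompts = 0
        session.current_state = "S0"
        session.history.append("S0")

    # -- fulfillment per intent ---------------------------------------------

    def _fulfill(self, session: DialogueSession) -> TurnResult:
        intent = session.active_intent
        name = intent.name
        try:
            if name == "FoodSuitability":
                return self._fulfill_suitability(session)
            if name == "SnackSuggestion":
                return self._fulfill_snack(session)
            if name == "RecipeRecommendation":
                return self._fulfill_recipe(session, first=True)
            if name in ("ProperDietTip", "EatingChallengeTip"):
                return self._fulfill_tip(session, intent)
            if name == "RecordMeal":
                return self._fulfill_record(session)
            if name == "HistoryRecall":
                return self._fulfill_recall(session)
        except LookupError_ as e:
            self._finish_request(session)
            return self._render(session, "clarify", {"error": str(e)})
        raise RuntimeError(f"no handler for intent {name!r}")

    def _current_patient(self, session: DialogueSession) -> PatientProfile:
        eer = session.slots.get("eer")
        if eer is not None and self.patient.eer is None:
            return replace(self.patient, eer=float(eer))
        return self.patient

    def _fulfill_suitability(self, session: DialogueSession) -> TurnResult:
        food = str(session.slots["food"])
        meal = str(session.slots["meal"])
        verdict = check_food_suitability(food, meal, self.patient,
                                         self.kb, self.rules)
        display = self.kb.foods[food].name if food in self.kb.foods else food
        payload = {
            "food": display, "meal": meal,
            "verdict": verdict.suitable,
            "verdict_plain": _VERDICT_PLAIN[verdict.suitable],
            "reasons": "; ".join(f"{why} [{prov}]"
                                 for prov, why in verdict.reasons),
            "reason_plain": verdict.reasons[0][1] if verdict.reasons else "",
            "numbers": "",
            "provenances": [prov for prov, _ in verdict.reasons],
        }
        # remember the topic briefly so follow-ups can refer to it
        session.set_context(ContextEntry("last_food", food, scope="short",
                                         expires_after=5))
        self._finish_request(session)
        return self._render(session, "suitability_verdict", payload)

    def _fulfill_snack(self, session: DialogueSession) -> TurnResult:
        found = suggest_snack(self.patient, self.caregiver, self.kb,
                              self.rules, session)
        if found is None:
            self._finish_request(session)
            session.failed = True
            return self._render(session, "no_recipe",
                                {"binding": "every snack is excluded for "
                                            "this patient"})
        fid, verdict = found
        food = self.kb.foods[fid]
        shares_txt = ""
        n = food.nutrients_per_100g
        shares_txt = (f"({n['energy_kcal']:.0f} kcal, "
                      f"{n['sugar_g']:.1f} g sugar per 100 g)")
        payload = {
            "food": food.name,
            "food_id": fid,
            "reasons": "; ".join(f"{why} [{prov}]"
                                 for prov, why in verdict.reasons),
            "numbers": shares_txt,
            "provenances": [prov for prov, _ in verdict.reasons],
        }
        self._finish_request(session)
        return self._render(session, "snack_suggestion", payload)

    def _fulfill_recipe(self, session: DialogueSession,
                        first: bool) -> TurnResult:
        patient = self._current_patient(session)
        try:
            rec = recommend_recipe(session.slots, patient, self.caregiver,
                                   self.kb, self.rules, session)
        except MissingDataError:
            # elicit the EER and come back through slot filling
            session.set_context(ContextEntry("need_eer", True, scope="short",
                                             expires_after=10))
            session.pending_slot = "eer"
            # leave S2 back to the slot-filling state
            session.current_state = "S1"
            session.history.append("S1")
            return self._render(session, "elicit_slot",
                                {"prompt": _EER_SLOT.prompt})
        graph = self._graph_for(session.active_intent)
        if rec is None:
            next_state(session, {"no_candidate": True}, graph)
            session.failed = True
            binding = self._binding_constraint(session, patient)
            self._finish_request(session)
            return self._render(session, "no_recipe", {"binding": binding})
        session.set_context(ContextEntry(
            "offered_recipe", rec.recipe.id, scope="short", expires_after=5))
        payload = self._recipe_payload(rec)
        action = "recipe_recommendation" if first else "acknowledge_rejection"
        next_state(session, {"offer_made": True}, graph)
        return self._render(session, action, payload)

    def _recipe_payload(self, rec: Recommendation) -> dict:
        n = rec.nutrients_per_serving
        shares = (f"protein {4 * n['protein_g'] / n['energy_kcal'] * 100:.0f}% "
                  f"and sugar {4 * n['sugar_g'] / n['energy_kcal'] * 100:.0f}% "
                  "of meal energy")
        return {
            "recipe": rec.recipe.name,
            "recipe_id": rec.recipe.id,
            "prep_time": f"{rec.recipe.prep_time:.0f}",
            "energy": f"{n['energy_kcal']:.0f}",
            "numbers": shares,
            "rationale": "; ".join(f"{why} [{prov}]"
                                   for prov, why in rec.rationale),
            "provenances": [prov for prov, _ in rec.rationale],
        }

    def _binding_constraint(self, session: DialogueSession,
                            patient: PatientProfile) -> str:
        from .guideline_rules import check_meal_constraints
        meal = str(session.slots.get("meal", "dinner"))
        counts: dict[str, int] = {}
        for rid in sorted(self.kb.recipes):
            recipe = self.kb.recipes[rid]
            if meal not in recipe.meal_types:
                continue
            for v in check_meal_constraints(recipe, patient, self.caregiver,
                                            self.kb, meal=meal):
                counts[v.constraint] = counts.get(v.constraint, 0) + 1
        if not counts:
            return "no recipe is registered for this meal"
        top = max(sorted(counts), key=lambda k: counts[k])
        return f"the {top} constraint excluded the available recipes"

    def _handle_decision(self, session: DialogueSession,
                         user_text: str) -> TurnResult:
        decision = interpret_decision(user_text)
        graph = self._graph_for(session.active_intent)
        state, action = next_state(session, decision, graph)
        if action == "confirm":
            payload = {"recipe": self.kb.recipes[
                session.get_context("offered_recipe")].name}
            self._finish_request(session)
            return self._render(session, "confirm", payload)
        if action == "acknowledge_rejection":
            offered = session.get_context("offered_recipe")
            if offered is not None:
                session.rejected.add(offered)
            return self._fulfill_recipe(session, first=False)
        # unmatched: re-prompt for the decision
        return self._render(session, "reprompt", {
            "prompt": "Would you like this recipe? Please say yes or no."})

    def _fulfill_tip(self, session: DialogueSession,
                     intent: Intent) -> TurnResult:
        category = ("eating_challenge" if intent.name == "EatingChallengeTip"
                    else "proper_diet")
        entry, tip = self.tip_bank.get_tip_entry(
            category, self.patient.adrd_stage,
            self.caregiver.education_level)
        self._finish_request(session)
        return self._render(session, "tip", {
            "tip": tip, "tip_id": entry["id"], "tip_category": category})

    def _fulfill_record(self, session: DialogueSession) -> TurnResult:
        food = str(session.slots["food"])
        meal = str(session.slots["meal"])
        if food in self.kb.foods:
            energy = self.kb.foods[food].nutrients_per_100g["energy_kcal"]
        else:
            energy = 0.0
        self.history.record_meal(MealRecord(
            date=self.today, meal_type=meal, items=(food,),
            energy_kcal=energy))
        payload = {"meal": meal, "date": self.today.isoformat(),
                   "energy": f"{energy:.0f}"}
        self._finish_request(session)
        return self._render(session, "meal_recorded", payload)

    def _fulfill_recall(self, session: DialogueSession) -> TurnResult:
        window = str(session.slots["window"])
        summary = self.history.recall_history(window, self.today)
        lines = [f"{r.date.isoformat()} {r.meal_type}: "
                 f"{', '.join(r.items)} ({r.energy_kcal:.0f} kcal)"
                 for r in summary["records"]]
        text = (f"{len(summary['records'])} meal(s) recorded this {window}, "
                f"{summary['total_energy_kcal']:.0f} kcal in total. "
                + " | ".join(lines))
        plain = (f"I noted {len(summary['records'])} meal(s) this {window}. "
                 + " | ".join(lines))
        self._finish_request(session)
        return self._render(session, "history_summary",
                            {"summary": text, "summary_plain": plain,
                             "n_records": len(summary["records"]),
                             "total_energy": summary["total_energy_kcal"]})

    # -- rendering ----------------------------------------------------------

    def _render(self, session: DialogueSession, action: str,
                payload: dict) -> TurnResult:
        text = generate_response(action, payload, self.caregiver)
        return TurnResult(text=text, action=action, payload=payload,
                          state=session.current_state)
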