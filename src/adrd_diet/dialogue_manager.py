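"""Text-mode conversation layer: intent detection, FSM dialogue, responses.

Three cooperating pieces replace the voice platform's conversation
stack:

* **UID** — `detect_intent` matches a normalized utterance against each
  intent's sample utterances by token-overlap (Jaccard) similarity,
  after expanding surface terms through the ontology vocabulary
  (synonyms, IS-A/type concepts), and extracts slot values.
* **DM** — a finite-state graph per service category; `next_state`
  evaluates declared transition conditions in order against the
  interpreted input, history and context; unmatched input self-loops
  with a re-prompt. Slot filling elicits required slots one per turn,
  accepts over-answering, and abandons after three re-prompts.
  Context entries carry expiry: short-term entries lapse after a few
  turns, long-term entries persist for the session.
* **RG** — `generate_response` renders the chosen action's template for
  the caregiver's education tier (basic: short, no technical nutrient
  terms; advanced: includes the numeric rationale).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .ontology_kb import MEAL_TYPES, CaregiverProfile

SERVICE_CATEGORIES = (
    "proper_diet_tips",
    "eating_challenge",
    "food_explanation",
    "meal_suggestion",
    "diet_history",
)

DEFAULT_SIMILARITY_THRESHOLD = 0.5
DEFAULT_MAX_TURNS = 20
DEFAULT_SHORT_CONTEXT_TURNS = 5
MAX_SLOT_REPROMPTS = 3

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}
_QUIT_WORDS = frozenset({"quit", "exit", "bye", "goodbye", "stop"})
_YES_WORDS = frozenset({"yes", "yeah", "yep", "sure", "ok", "okay", "sounds",
                        "good", "great", "perfect", "fine"})
_NO_WORDS = frozenset({"no", "nope", "nah", "another", "else", "different",
                       "reject"})


class DialogueError(Exception):
    pass


class TemplatingError(DialogueError):
    """No response template is registered for an action."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slot:
    name: str
    semantic_type: str  # food | meal | number | minutes | window | tip_topic
    required: bool
    prompt: str


@dataclass(frozen=True)
class Intent:
    name: str
    category: str
    slots: tuple[Slot, ...] = ()
    sample_utterances: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in SERVICE_CATEGORIES:
            raise DialogueError(
                f"intent {self.name}: unknown category {self.category!r}")
        names = [s.name for s in self.slots]
        if len(names) != len(set(names)):
            raise DialogueError(f"intent {self.name}: duplicate slot names")
        if not self.sample_utterances:
            raise DialogueError(
                f"intent {self.name}: needs at least one sample utterance")


@dataclass(frozen=True)
class DialogueState:
    id: str
    action: str
    transitions: tuple[tuple[Mapping[str, object], str], ...] = ()
    terminal: bool = False


@dataclass
class ContextEntry:
    key: str
    value: object
    scope: str = "short"  # short | long
    expires_after: int | None = DEFAULT_SHORT_CONTEXT_TURNS

    def __post_init__(self):
        if self.scope == "short":
            if not self.expires_after or self.expires_after <= 0:
                raise DialogueError(
                    f"short context {self.key!r} needs finite expiry > 0")
        elif self.scope == "long":
            self.expires_after = None
        else:
            raise DialogueError(f"unknown context scope {self.scope!r}")


@dataclass
class DialogueSession:
    session_id: str
    current_state: str = "S0"
    history: list[str] = field(default_factory=lambda: ["S0"])
    slots: dict[str, object] = field(default_factory=dict)
    context: dict[str, ContextEntry] = field(default_factory=dict)
    turn_count: int = 0
    rejected: set[str] = field(default_factory=set)
    active_intent: Intent | None = None
    pending_slot: str | None = None
    reprompts: int = 0
    failed: bool = False
    done: bool = False

    def set_context(self, entry: ContextEntry) -> None:
        self.context[entry.key] = entry

    def get_context(self, key: str, default=None):
        entry = self.context.get(key)
        return entry.value if entry is not None else default

    def move_to(self, state_id: str) -> None:
        self.current_state = state_id
        self.history.append(state_id)


# ---------------------------------------------------------------------------
# UID: utterance normalization, slot extraction, intent scoring
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^\w\s?]")
_TEMPLATE_PUNCT_RE = re.compile(r"[^\w\s?{}]")


def normalize(utterance: str, keep_placeholders: bool = False) -> list[str]:
    """Lowercase, strip punctuation, split into tokens.

    ``keep_placeholders`` preserves ``{slot}`` markers when tokenizing
    sample-utterance templates.
    """
    pattern = _TEMPLATE_PUNCT_RE if keep_placeholders else _PUNCT_RE
    text = pattern.sub(" ", utterance.lower())
    return [t for t in text.split() if t]


def _canonicalize(tokens: list[str], vocabulary: Mapping[str, str]
                  ) -> tuple[list[str], dict[str, str]]:
    """Replace vocabulary n-grams (longest first) with canonical concept ids.

    Returns the rewritten token list and a map canonical-id → matched
    surface term.
    """
    out: list[str] = []
    hits: dict[str, str] = {}
    i = 0
    while i < len(tokens):
        matched = False
        for n in (3, 2, 1):
            if i + n > len(tokens):
                continue
            surface = " ".join(tokens[i:i + n])
            concept = vocabulary.get(surface)
            if concept is not None:
                out.append(concept.lower())
                hits[concept] = surface
                i += n
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return out, hits


def extract_slot_values(utterance: str, slots: Sequence[Slot],
                        vocabulary: Mapping[str, str]) -> dict[str, object]:
    """Pull values for the given slots out of one utterance.

    Used both at intent detection and during slot filling, so a reply
    that over-answers (supplies several slots at once) fills them all.
    """
    tokens = normalize(utterance)
    _, hits = _canonicalize(tokens, vocabulary)
    meal_words = [t.rstrip("s") for t in tokens if t.rstrip("s") in MEAL_TYPES]
    numbers: list[float] = []
    minute_values: list[float] = []
    for j, t in enumerate(tokens):
        value = None
        if t.isdigit():
            value = float(t)
        elif t in _NUMBER_WORDS:
            value = float(_NUMBER_WORDS[t])
        if value is None:
            continue
        nxt = tokens[j + 1] if j + 1 < len(tokens) else ""
        if nxt.startswith(("min", "hour")):
            minute_values.append(value * (60 if nxt.startswith("hour") else 1))
        else:
            numbers.append(value)
    found: dict[str, object] = {}
    used_numbers = 0
    for slot in slots:
        if slot.semantic_type == "meal" and meal_words:
            found[slot.name] = meal_words[0]
        elif slot.semantic_type == "food":
            foods = [c for c in hits if c.lower() not in MEAL_TYPES]
            if foods:
                found[slot.name] = foods[0]
        elif slot.semantic_type == "minutes" and minute_values:
            found[slot.name] = minute_values[0]
        elif slot.semantic_type == "number" and used_numbers < len(numbers):
            found[slot.name] = numbers[used_numbers]
            used_numbers += 1
        elif slot.semantic_type == "window":
            if any(t in ("week", "weekly") for t in tokens):
                found[slot.name] = "week"
            elif any(t in ("day", "daily", "today") for t in tokens):
                found[slot.name] = "day"
        elif slot.semantic_type == "tip_topic":
            if any(t in ("eating", "chewing", "swallowing", "appetite")
                   for t in tokens):
                found[slot.name] = "eating_challenge"
            elif any(t in ("diet", "nutrition", "food") for t in tokens):
                found[slot.name] = "proper_diet"
    return found


def _jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def detect_intent(utterance: str, registry: Sequence[Intent],
                  vocabulary: Mapping[str, str],
                  threshold: float = DEFAULT_SIMILARITY_THRESHOLD
                  ) -> tuple[Intent, dict[str, object], float] | None:
    """Best-matching intent for an utterance, or None below threshold.

    The utterance is normalized, vocabulary terms are rewritten to
    canonical concept ids (synonym expansion), and each intent's sample
    utterances are scored by Jaccard token overlap with slot
    placeholders substituted by the extracted values. Deterministic:
    ties break lexicographically on intent name.
    """
    if not registry:
        raise DialogueError("intent registry is empty")
    tokens = normalize(utterance)
    if not tokens:
        return None
    canon_tokens, _ = _canonicalize(tokens, vocabulary)
    best: tuple[float, str, Intent, dict] | None = None
    for intent in registry:
        slot_values = extract_slot_values(utterance, intent.slots, vocabulary)
        score = 0.0
        for template in intent.sample_utterances:
            t_tokens: list[str] = []
            for tok in normalize(template, keep_placeholders=True):
                m = re.fullmatch(r"\{(\w+)\}", tok)
                if m:
                    value = slot_values.get(m.group(1))
                    if value is not None:
                        t_tokens.append(str(value).lower())
                else:
                    t_tokens.append(tok)
            score = max(score, _jaccard(canon_tokens, t_tokens))
        key = (-score, intent.name)
        if best is None or key < (-best[0], best[1]):
            best = (score, intent.name, intent, slot_values)
    if best is None or best[0] < threshold:
        return None
    return best[2], best[3], best[0]


def analyze_sentiment(utterance: str) -> str:
    """Sentiment hook for the reasoner; currently always neutral.

    Kept as an explicit extension point: the dialogue layer passes its
    result alongside the intent, but no rule consumes it yet.
    """
    return "neutral"


# ---------------------------------------------------------------------------
# DM: state graphs and transitions
# ---------------------------------------------------------------------------

def default_state_graph(category: str) -> dict[str, DialogueState]:
    """The finite-state graph for one service category.

    All categories share the spine S0 (start) → S1 (slot filling) → S2
    (fulfill); the meal-suggestion graph adds the offer/decision loop
    S2 → S3 with successors S4 (accept → confirm) and S5 (reject →
    alternative offer, back to S3), and every graph has a failure sink
    S9.
    """
    common = {
        "S0": DialogueState("S0", "greet", (
            ({"has_intent": True}, "S1"),
        )),
        "S9": DialogueState("S9", "apologize", (), terminal=True),
    }
    if category == "meal_suggestion":
        graph = {
            **common,
            "S1": DialogueState("S1", "elicit_slot", (
                ({"slots_complete": True}, "S2"),
                ({"retries_exhausted": True}, "S9"),
            )),
            "S2": DialogueState("S2", "offer", (
                ({"offer_made": True}, "S3"),
                ({"no_candidate": True}, "S9"),
            )),
            "S3": DialogueState("S3", "await_decision", (
                ({"input_yes": True}, "S4"),
                ({"input_no": True}, "S5"),
            )),
            "S4": DialogueState("S4", "confirm", (), terminal=True),
            "S5": DialogueState("S5", "acknowledge_rejection", (
                ({"offer_made": True}, "S3"),
                ({"no_candidate": True}, "S9"),
            )),
        }
    else:
        graph = {
            **common,
            "S1": DialogueState("S1", "elicit_slot", (
                ({"slots_complete": True}, "S2"),
                ({"retries_exhausted": True}, "S9"),
            )),
            "S2": DialogueState("S2", "emit", (), terminal=True),
        }
    _check_graph(graph)
    return graph


def _check_graph(graph: Mapping[str, DialogueState]) -> None:
    if "S0" not in graph:
        raise DialogueError("state graph must declare S0")
    for state in graph.values():
        for _, succ in state.transitions:
            if succ not in graph:
                raise DialogueError(
                    f"state {state.id}: undeclared successor {succ!r}")


def next_state(session: DialogueSession, interpreted: Mapping[str, object],
               graph: Mapping[str, DialogueState]
               ) -> tuple[str, str]:
    """First transition whose condition matches, else self-loop re-prompt.

    Conditions are flat key→expected maps evaluated against the
    interpreted input merged with session context; declaration order
    decides ties. The session's state and history are updated.
    """
    state = graph.get(session.current_state)
    if state is None:
        # corrupted state: reset to S0 per the session-error contract
        session.current_state = "S0"
        session.history.append("S0")
        return "S0", graph["S0"].action
    env = dict(interpreted)
    for key, entry in session.context.items():
        env.setdefault(f"ctx:{key}", entry.value)
    for cond, succ in state.transitions:
        if all(env.get(k) == v for k, v in cond.items()):
            session.move_to(succ)
            return succ, graph[succ].action
    return state.id, "reprompt"


def expire_context(session: DialogueSession) -> DialogueSession:
    """End-of-turn bookkeeping: short entries count down and lapse."""
    expired = []
    for key, entry in session.context.items():
        if entry.scope == "short":
            entry.expires_after -= 1
            if entry.expires_after <= 0:
                expired.append(key)
    for key in expired:
        del session.context[key]
    return session


# ---------------------------------------------------------------------------
# RG: templated responses per education tier
# ---------------------------------------------------------------------------

# Each action maps to {tier: template}. Basic-tier wording avoids
# technical nutrient terms and percent figures; the advanced tier spells
# out the numeric rationale.
DEFAULT_TEMPLATES: dict[str, dict[str, str]] = {
    "greet": {
        "basic": "Hello! I can help with meals and food questions for {patient_name}.",
        "standard": "Hello! I am your diet assistant. Ask me about foods, meals, or tips.",
        "advanced": "Hello! I am your diet assistant. I can check food suitability, recommend recipes against the guidelines, and share tips.",
    },
    "clarify": {
        "basic": "Sorry, I did not get that. Can you say it another way?",
        "standard": "Sorry, I did not understand. Could you rephrase your request?",
        "advanced": "Sorry, I could not match that to a supported request. Could you rephrase?",
    },
    "reprompt": {
        "basic": "{prompt}",
        "standard": "{prompt}",
        "advanced": "{prompt}",
    },
    "elicit_slot": {
        "basic": "{prompt}",
        "standard": "{prompt}",
        "advanced": "{prompt}",
    },
    "apologize": {
        "basic": "I am sorry, I cannot help with that right now.",
        "standard": "I am sorry, I could not complete that request.",
        "advanced": "I am sorry, I could not complete that request with the information available.",
    },
    "suitability_verdict": {
        "basic": "{food} is {verdict_plain} for {meal}. {reason_plain}",
        "standard": "{food} is {verdict_plain} as a {meal}: {reasons}",
        "advanced": "{food} is {verdict_plain} as a {meal}: {reasons} {numbers}",
    },
    "snack_suggestion": {
        "basic": "How about {food}? It is a healthy choice.",
        "standard": "I suggest {food} as a snack: {reasons}",
        "advanced": "I suggest {food} as a snack: {reasons} {numbers}",
    },
    "recipe_recommendation": {
        "basic": "I suggest {recipe}. It takes {prep_time} minutes. Would you like it?",
        "standard": "I recommend {recipe} ({prep_time} min, {energy} kcal per serving). Would you like it?",
        "advanced": "I recommend {recipe}: {energy} kcal per serving, {numbers} ({prep_time} min, {rationale}). Would you like it?",
    },
    "confirm": {
        "basic": "Great! Enjoy {recipe}.",
        "standard": "Great! {recipe} it is. Enjoy your meal.",
        "advanced": "Great! {recipe} it is. It meets every guideline we checked.",
    },
    "acknowledge_rejection": {
        "basic": "Okay, not that one. How about {recipe}? Would you like it?",
        "standard": "Understood. As an alternative, I recommend {recipe} ({prep_time} min, {energy} kcal per serving). Would you like it?",
        "advanced": "Understood. As an alternative: {recipe}, {energy} kcal per serving, {numbers} ({prep_time} min). Would you like it?",
    },
    "no_recipe": {
        "basic": "I am sorry, I have no meal that fits right now. {binding}",
        "standard": "I could not find a recipe satisfying every constraint: {binding}",
        "advanced": "No candidate recipe satisfies all constraints; the binding constraint was: {binding}",
    },
    "tip": {
        "basic": "{tip}",
        "standard": "{tip}",
        "advanced": "{tip}",
    },
    "history_summary": {
        "basic": "{summary_plain}",
        "standard": "{summary}",
        "advanced": "{summary}",
    },
    "meal_recorded": {
        "basic": "Got it, I noted that meal.",
        "standard": "Recorded: {meal} on {date}.",
        "advanced": "Recorded: {meal} on {date}, {energy} kcal.",
    },
    "goodbye": {
        "basic": "Goodbye! Take care.",
        "standard": "Goodbye! Take care.",
        "advanced": "Goodbye! Take care.",
    },
}


def generate_response(action: str, payload: Mapping[str, object],
                      caregiver: CaregiverProfile | None = None,
                      templates: Mapping[str, Mapping[str, str]] | None = None
                      ) -> str:
    """Render the template for an action at the caregiver's education tier.

    Deterministic for fixed inputs; raises TemplatingError when no
    template is registered for the action or a required payload field is
    absent.
    """
    templates = templates or DEFAULT_TEMPLATES
    tier = caregiver.education_level if caregiver is not None else "standard"
    per_action = templates.get(action)
    if per_action is None:
        raise TemplatingError(f"no template registered for action {action!r}")
    template = per_action.get(tier) or per_action["standard"]
    try:
        return template.format(**payload)
    except KeyError as e:
        raise TemplatingError(
            f"action {action!r}: payload missing field {e.args[0]!r}") from None


def is_quit(utterance: str) -> bool:
    toks = normalize(utterance)
    return bool(toks) and toks[0] in _QUIT_WORDS


def interpret_decision(utterance: str) -> dict[str, bool]:
    toks = set(normalize(utterance))
    return {"input_yes": bool(toks & _YES_WORDS) and not (toks & _NO_WORDS),
            "input_no": bool(toks & _NO_WORDS)}


# ---------------------------------------------------------------------------
# Default intent registry (five service categories)
# ---------------------------------------------------------------------------

def default_registry() -> tuple[Intent, ...]:
    """The intents shipped with the assistant, covering all five
    service categories: proper-diet tips, eating-challenge handling,
    food/nutrition explanation, meal suggestion, diet-history recall."""
    return (
        Intent(
            name="FoodSuitability", category="food_explanation",
            slots=(
                Slot("food", "food", True, "Which food do you mean?"),
                Slot("meal", "meal", True,
                     "For which meal: breakfast, lunch, dinner, or a snack?"),
            ),
            sample_utterances=(
                "is {food} good as a {meal} for my dad",
                "is {food} ok for a {meal}",
                "is {food} good for {meal}",
                "can he have {food} as a {meal}",
                "tell me about {food} for {meal}",
            )),
        Intent(
            name="SnackSuggestion", category="meal_suggestion",
            slots=(),
            sample_utterances=(
                "can you suggest a good snack",
                "what is a good snack",
                "suggest a healthy snack for him",
                "give me a snack idea",
            )),
        Intent(
            name="RecipeRecommendation", category="meal_suggestion",
            slots=(
                Slot("meal", "meal", True,
                     "Which meal is this for: breakfast, lunch, or dinner?"),
                Slot("servings", "number", False, "How many servings do you need?"),
                Slot("max_time", "minutes", False,
                     "How much time do you have for cooking, in minutes?"),
            ),
            sample_utterances=(
                "recommend a recipe for {meal}",
                "what should i cook for {meal}",
                "suggest a {meal} recipe",
                "i need a recipe for {meal} tonight",
                "any recipe idea for {meal}",
            )),
        Intent(
            name="ProperDietTip", category="proper_diet_tips",
            slots=(),
            sample_utterances=(
                "give me a tip on proper diet",
                "any advice on healthy eating",
                "share a diet tip",
                "how can i improve his diet",
            )),
        Intent(
            name="EatingChallengeTip", category="eating_challenge",
            slots=(),
            sample_utterances=(
                "he has trouble eating what can i do",
                "tips for eating challenges",
                "he refuses to eat help me",
                "how to handle chewing problems",
            )),
        Intent(
            name="RecordMeal", category="diet_history",
            slots=(
                Slot("meal", "meal", True, "Which meal was it?"),
                Slot("food", "food", True, "What did he eat?"),
            ),
            sample_utterances=(
                "he had {food} for {meal}",
                "record {food} for {meal}",
                "log that he ate {food} at {meal}",
            )),
        Intent(
            name="HistoryRecall", category="diet_history",
            slots=(
                Slot("window", "window", True,
                     "For the day or for the week?"),
            ),
            sample_utterances=(
                "what did he eat this {window}",
                "recall his diet for the {window}",
                "show me the {window} history",
            )),
    )


def registered_categories(registry: Sequence[Intent]) -> tuple[str, ...]:
    """The distinct service categories present in a registry, in the
    canonical order."""
    present = {i.category for i in registry}
    return tuple(c for c in SERVICE_CATEGORIES if c in present)
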