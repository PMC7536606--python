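"""Dialogue evaluation: scripted conversations and the two headline metrics.

A conversation script is a JSONL sequence of ``{"user": ...}`` inputs
and ``{"expect_action": ...}`` expectations. The harness drives the
assistant turn by turn; a dialogue *succeeds* when every expectation is
met, in order, within the maximum-turn threshold (default 20) —
exceeding the threshold without satisfaction marks the dialogue failed.

Two rates summarize a batch, both percentages:

* dialogue success rate = 100 · n_success / n_total;
* recommendation correctness rate = 100 · n_correct / n_responses,
  where a recommendation response is judged *correct* by an automated
  checker: the recommended recipe must pass every guideline constraint
  for the patient and caregiver, and a suggested snack or suitability
  verdict must be consistent with the profile's exclusions. (The
  original evaluation used a human judge; the operational criterion
  here is guideline/profile consistency.)

`report` renders per-category rows — average turns, success rate,
correctness rate — as aligned text and CSV.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .assistant import Assistant, TurnResult
from .guideline_rules import check_meal_constraints
from .ontology_kb import CaregiverProfile, PatientProfile

RECOMMENDATION_ACTIONS = frozenset({
    "recipe_recommendation", "acknowledge_rejection", "snack_suggestion",
    "suitability_verdict", "tip"})


class ScriptError(Exception):
    """A conversation script is malformed; message cites the line."""


class UndefinedMetricError(Exception):
    """A rate was requested over an empty denominator."""


@dataclass
class EvalOutcome:
    category: str
    n_total: int = 0
    n_success: int = 0
    n_responses: int = 0
    n_correct: int = 0
    turns: list[int] = field(default_factory=list)

    def __post_init__(self):
        self._check()

    def _check(self):
        if not (0 <= self.n_success <= self.n_total):
            raise ValueError("need 0 <= n_success <= n_total")
        if not (0 <= self.n_correct <= self.n_responses):
            raise ValueError("need 0 <= n_correct <= n_responses")
        if any(t < 1 for t in self.turns):
            raise ValueError("turn counts must be >= 1")


# ---------------------------------------------------------------------------
# Script parsing and execution
# ---------------------------------------------------------------------------

def parse_script(lines: Iterable[str], name: str = "<script>") -> list[dict]:
    records = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
        except json.JSONDecodeError as e:
            raise ScriptError(f"{name}: line {lineno}: {e.msg}") from None
        if not isinstance(rec, dict) or \
                not ({"user", "expect_action"} & rec.keys()):
            raise ScriptError(
                f"{name}: line {lineno}: record must carry 'user' or "
                "'expect_action'")
        records.append(rec)
    if not records:
        raise ScriptError(f"{name}: empty script")
    if not any("expect_action" in r for r in records):
        raise ScriptError(f"{name}: script declares no expectation")
    return records


def run_script(script: Sequence[dict] | Iterable[str], assistant: Assistant,
               max_turns: int = 20) -> tuple[list[dict], bool, int]:
    """Drive one scripted conversation; returns (transcript, success, turns).

    Each ``user`` record is one turn; each ``expect_action`` record is
    checked against the immediately preceding system response. Success
    requires every expectation met in order within ``max_turns`` turns;
    the run stops at the threshold, and an unsatisfied script at that
    point is failed.
    """
    records = list(script)
    if records and isinstance(records[0], str):
        records = parse_script(records)
    else:
        if not records:
            raise ScriptError("empty script")
        if not any("expect_action" in r for r in records):
            raise ScriptError("script declares no expectation")
    session = assistant.new_session()
    transcript: list[dict] = []
    turns = 0
    expects_met = True
    last: TurnResult | None = None
    satisfied_at: int | None = None
    n_expects = sum(1 for r in records if "expect_action" in r)
    n_matched = 0
    for rec in records:
        if "user" in rec:
            if turns >= max_turns or session.done:
                break
            turns += 1
            last = assistant.respond(session, rec["user"])
            transcript.append({
                "turn": turns, "user": rec["user"], "system": last.text,
                "action": last.action, "state": last.state,
                "payload": {k: v for k, v in last.payload.items()
                            if isinstance(v, (str, int, float, list))},
            })
        else:
            expected = rec["expect_action"]
            ok = last is not None and last.action == expected
            transcript.append({"expect_action": expected, "met": ok,
                               "at_turn": turns})
            if ok:
                n_matched += 1
                if n_matched == n_expects:
                    satisfied_at = turns
            else:
                expects_met = False
    success = expects_met and n_matched == n_expects and \
        satisfied_at is not None and satisfied_at <= max_turns
    return transcript, success, turns


# ---------------------------------------------------------------------------
# Automated correctness judgment
# ---------------------------------------------------------------------------

def judge_response(entry: Mapping, assistant: Assistant) -> bool:
    """Is one recommendation response consistent with guidelines + profile?"""
    action = entry.get("action")
    payload = entry.get("payload", {})
    patient: PatientProfile = assistant.patient
    caregiver: CaregiverProfile = assistant.caregiver
    kb = assistant.kb
    if action in ("recipe_recommendation", "acknowledge_rejection"):
        rid = payload.get("recipe_id")
        recipe = kb.recipes.get(rid)
        if recipe is None:
            return False
        meal = "dinner" if "dinner" in recipe.meal_types else \
            sorted(recipe.meal_types)[0]
        return not check_meal_constraints(recipe, patient, caregiver, kb,
                                          meal=meal)
    if action == "snack_suggestion":
        fid = payload.get("food_id")
        if fid not in kb.foods:
            return False
        from .diet_services import check_food_suitability
        verdict = check_food_suitability(fid, "snack", patient, kb,
                                         assistant.rules)
        return verdict.suitable == "recommended"
    if action == "suitability_verdict":
        # a verdict is correct when it cites at least one guideline and
        # honors the hard exclusions
        return bool(payload.get("provenances")) and \
            payload.get("verdict") in ("recommended", "not_recommended",
                                       "caution")
    if action == "tip":
        tip = next((t for t in assistant.tip_bank.tips
                    if t["id"] == payload.get("tip_id")), None)
        return tip is not None and payload.get("tip_category") in tip["tags"]
    return False


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def evaluate_scripts(scripts: Mapping[str, Sequence[dict]],
                     assistant_factory: Callable[[], Assistant],
                     max_turns: int = 20,
                     collect_transcripts: bool = False):
    """Run every script on a fresh assistant; aggregate per category.

    Script names are ``<category>__<n>``; returns a list of EvalOutcome
    (and the transcripts when requested).
    """
    outcomes: dict[str, EvalOutcome] = {}
    transcripts: dict[str, list[dict]] = {}
    for name in sorted(scripts):
        category = name.split("__", 1)[0]
        outcome = outcomes.setdefault(category, EvalOutcome(category))
        assistant = assistant_factory()
        transcript, success, turns = run_script(
            scripts[name], assistant, max_turns=max_turns)
        if collect_transcripts:
            transcripts[name] = transcript
        outcome.n_total += 1
        outcome.n_success += int(success)
        outcome.turns.append(max(turns, 1))
        for entry in transcript:
            if entry.get("action") in RECOMMENDATION_ACTIONS:
                outcome.n_responses += 1
                outcome.n_correct += int(judge_response(entry, assistant))
    result = [outcomes[c] for c in sorted(outcomes)]
    for o in result:
        o._check()
    return (result, transcripts) if collect_transcripts else result


def load_scripts_dir(scripts_dir: str | Path) -> dict[str, list[dict]]:
    d = Path(scripts_dir)
    if not d.is_dir():
        raise ScriptError(f"script directory {d} does not exist")
    out = {}
    for path in sorted(d.glob("*.jsonl")):
        out[path.stem] = parse_script(
            path.read_text().splitlines(), name=path.name)
    if not out:
        raise ScriptError(f"no .jsonl scripts in {d}")
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def success_rate(n_success: int, n_total: int) -> float:
    """Dialogue success rate, percent: 100 · n_success / n_total."""
    if n_total <= 0:
        raise UndefinedMetricError("success rate undefined for n_total = 0")
    if not (0 <= n_success <= n_total):
        raise ValueError("need 0 <= n_success <= n_total")
    return 100.0 * n_success / n_total


def correctness_rate(n_correct: int, n_responses: int) -> float:
    """Recommendation correctness rate, percent: 100 · n_correct / n_responses."""
    if n_responses <= 0:
        raise UndefinedMetricError(
            "correctness rate undefined for n_responses = 0")
    if not (0 <= n_correct <= n_responses):
        raise ValueError("need 0 <= n_correct <= n_responses")
    return 100.0 * n_correct / n_responses


def report(outcomes: Sequence[EvalOutcome]) -> tuple[str, str]:
    """Per-category table as (aligned text, CSV)."""
    if not outcomes:
        raise ValueError("no outcomes to report")
    header = ("category", "n_dialogues", "avg_turns",
              "success_rate_pct", "correctness_rate_pct")
    rows: list[tuple[str, ...]] = []
    for o in outcomes:
        if o.n_total == 0:
            rows.append((o.category, "0", "n/a", "n/a", "n/a"))
            continue
        avg_turns = sum(o.turns) / len(o.turns) if o.turns else 0.0
        sr = f"{success_rate(o.n_success, o.n_total):.1f}"
        cr = (f"{correctness_rate(o.n_correct, o.n_responses):.1f}"
              if o.n_responses else "n/a")
        rows.append((o.category, str(o.n_total), f"{avg_turns:.1f}", sr, cr))
    widths = [max(len(h), *(len(r[i]) for r in rows))
              for i, h in enumerate(header)]
    text_lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    text_lines += ["  ".join(c.ljust(w) for c, w in zip(r, widths))
                   for r in rows]
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    for r in rows:
        buf.write(",".join(r) + "\n")
    return "\n".join(text_lines) + "\n", buf.getvalue()
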