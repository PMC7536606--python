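# Methods

This note documents the models and procedures behind `adrd-diet`, the
parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Knowledge representation

The knowledge base is a typed concept graph rather than a full OWL-DL
ontology. Classes carry IS-A parents (the subsumption hierarchy),
synonyms, and pairwise disjointness axioms; individuals carry *type*
links and (predicate, value) assertions. Foods enter the graph as
individuals of their category with their per-100 g nutrients attached
as numeric property assertions, so rules can quantify over them.
The IS-A relation must be a strict partial order: cycles are a hard
load-time error (the message names the cycle), because the reasoner
and the MIND classification both rely on a well-founded class order.

`partition_kb` splits the KB into a TBox (class declarations and
axioms) and an ABox (instance assertions); `merge_kb` inverts it
exactly, checked by assertion-set equality. Surface-term matching is
case-insensitive while concept identifiers stay case-sensitive —
utterances originate as free text, identifiers do not. Two ontology
serializations are read: a canonical JSON dialect (documented in
`ontology_kb.load_ontology_json`) and a Turtle subset (subclass, type,
label triples) via rdflib.

## Inference

Rules are safe Horn clauses in a function-free Datalog subset of SWRL:
unary class predicates, binary property predicates, numeric comparison
built-ins (`lessThan` … `greaterThan`), and stratified
negation-as-failure (needed only by exclusion-style guideline rules;
a negation cycle is rejected). Safety requires every head variable,
and every variable of a comparison or negated atom, to be bound by a
positive body atom.

`prove` and `query` use tabled, goal-directed evaluation: only
predicates in the backward dependency closure of the goal are
activated, and within that closure a semi-naive fixpoint saturates the
answer table stratum by stratum. Repeated subgoals hit the table;
cyclic rule graphs terminate because the table over a finite Herbrand
base is finite. Class-membership facts are expanded through the IS-A
closure before evaluation, so ABox reasoning composes with TBox
subsumption. Proof traces are reconstructed from derivation
provenance (first derivation wins), goal rule first; asserted facts
need no trace. Answer enumeration is sorted lexicographically on the
bound constants for reproducibility.

Correctness is established against an independent oracle: a naive
forward-chaining fixpoint evaluator (tests/oracle.py, sharing no code
with the engine) must agree with `query` on every derivable atom of
randomly generated safe Datalog programs (≤ 8 predicates, ≤ 12 rules,
≤ 20 constants) — 150 programs in the unit suite, 500 in the
acceptance script.

The satisfiability check is deliberately limited: it reports every
individual entailed (facts + rules + IS-A) into two classes declared
disjoint, with both entailment traces. No tableau reasoning, property
chains, cardinality restrictions, or nominals.

## Guideline model

Percent-of-energy bounds use the Atwater factors (4/4/9 kcal per gram
of protein/carbohydrate/fat; sugar counts as carbohydrate at 4 kcal/g)
against the *tabulated* meal energy, never against a re-derived one.
Tabulated food energies are kept within 30% of their Atwater value by
the generator, mirroring the spread in real composition tables.

Meal calorie targets, in precedence order:

1. diabetic patient + dinner → a point target of 25% of EER (the
   disease-specific rule wins when both apply — the source guidelines
   do not state a composition rule, so this precedence is a documented
   choice);
2. man on three meals/day → the printed 800–850 kcal range;
3. otherwise → EER / meals-per-day ± 10%, a documented extension, since
   the guidelines only state the two specific cases.

A recipe matches a point target within ±5% (configurable); printed or
derived ranges are used as-is. EER comes from the profile when
present, else from the Institute of Medicine adult equations (the
profile optionally carries weight, height and activity; reference
anthropometrics for a 65-year-old are the fallback).

`check_meal_constraints` evaluates, per recipe and meal slot: the
calorie target; protein share ∈ [20%, 30%] and sugar share < 10% for
diabetic meals; allergy, religious and dislike exclusions (a food is
excluded if it or any IS-A ancestor is listed); prep time against the
caregiver's limit; and cost per serving against the per-meal budget
(recipe cost is defined per serving to keep the units consistent).
Every violation carries the guideline provenance string.

Suitability verdicts order their evidence: hard profile exclusions
veto everything; a MIND-limit listing makes a food not recommended for
a suitability query (advisory elsewhere); single foods get a diabetic
sugar *caution* on sugar density (≥ 15 g/100 g) rather than on their
own energy share, because the ADA share bound is a meal-level rule and
fruit is mostly sugar by energy.

## Dialogue model

Intent detection replaces an opaque commercial NLU with a transparent
scorer: utterances are lowercased, punctuation-stripped, rewritten
through the ontology vocabulary (synonyms and concepts under the
food-related top classes map to canonical ids), and scored against
each intent's sample utterances by Jaccard token overlap with slot
placeholders substituted by the extracted values. The acceptance
threshold is 0.5 (configurable); ties break on intent name. Slot
values are typed (food concepts, meal words, numbers, minutes,
day/week windows) and extracted by the same machinery during filling,
so a reply can over-answer and fill several slots at once; a confirmed
slot is never overwritten.

Dialogue structure is a finite-state graph per service request type:
S0 (start) → S1 (slot filling) → S2 (fulfill), with the
meal-suggestion graph adding the offer/decision loop S2 → S3 and the
successors S4 (accept → confirm) and S5 (reject → acknowledge and
offer an alternative), plus a failure sink. Transition conditions are
flat key→value maps evaluated in declaration order; unmatched input
self-loops with a re-prompt, and a required slot unfilled after three
re-prompts abandons the intent with an apology. Context entries carry
scope: short-term entries expire after 5 turns by default ("a few
dialogue states"), long-term entries (allergies, stage, comorbidities)
persist for the session and pre-fill matching slots without asking.
A sentiment hook exists but always returns neutral; no rule consumes
it yet. Responses are deterministic templates per education tier:
the basic tier avoids percent figures and technical nutrient terms,
the advanced tier spells out the numeric rationale.

Recommendation ranking — the sources say only that multiple factors
are considered — is a documented three-key order: most MIND-encouraged
ingredients, then closeness of per-serving energy to the target
midpoint, then recipe id. Rejection memory is session-scoped and
cleared at session end; a rejected recipe is never re-offered within
the session.

## Evaluation

A script is a JSONL sequence of user turns and expected actions; each
processed user input is one turn. Success means every expectation met,
in order, within the 20-turn threshold; the run stops at the
threshold, so a never-satisfied adversarial script fails at exactly 20
turns. The correctness of a recommendation response is judged
automatically (the original study used human judges): a recipe must
pass every guideline constraint for the profiles, a snack must be
suitability-clean, a verdict must cite provenance, a tip must match
the requested category. Timing columns are not reported — they are
hardware-dependent.

## Synthetic data

The generator is a pure function of `FixtureSpec(seed, n_foods=50,
n_recipes=20)`; identical specs yield byte-identical bundles. Nutrient
ranges per category are invented but realistic on a cooked, per-100 g
basis, chosen so constraint checks get a nontrivial pass/fail mix.
Recipes are *solved*, not sampled: linear systems in the actual drawn
nutrient densities pin each crafted recipe to its target energy and
protein share, so the bundle contains exactly two dinners admissible
for the reference persona (65-year-old man, early-stage ADRD, type 2
diabetes, EER 2000, nut allergy; caregiver with 45 min and a 12-unit
budget) and one dinner violating each single constraint class — the
manifest records which, and the generator re-verifies its own claims
against the constraint checker before writing. Conversation scripts
(3 categories × 11) cover happy paths, synonym use, elicitation,
over-answering, rejection-then-alternative, and one adversarial script
per category.

What the synthetic data does not emulate: real FoodData Central
records and their measurement noise, free-form spoken language (the
scripts stay near the sample-utterance distribution, as scripted lab
testing did), multi-intent utterances, and population-scale profile
diversity. Passing tests therefore demonstrate the correctness of the
reasoning, constraint and dialogue machinery under controlled
conditions — not NLU robustness on wild utterances.

## Numerical and degenerate-input choices

Ties break lexicographically everywhere (query enumeration, snack and
recipe ranking, proof witnesses). Point calorie targets use a ±5%
band; range targets none. Zero-energy foods (water) contribute zero
shares. Empty food tables, empty recipe sets, empty histories and
empty contexts are valid; empty tip banks, zero evaluation
denominators, unknown categories and malformed scripts raise typed
errors that cite the offending file, line or field.

## Known limitations

No full OWL-DL semantics; no SPARQL endpoint or triple-store SQL
layer (in-memory indexes instead); no live UMLS/SNOMED CT/ICD-10/
DrugBank integration; no micronutrient guidelines beyond the carried
fields; no wine-moderation modeling; no statistical or neural NLU; no
speech I/O; no multi-patient households; history persists to JSONL
rather than a database. The dialogue success rates measured here are
over scripted conversations and are not comparable to human-subject
usability results.
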