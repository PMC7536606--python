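# adrd-diet

A knowledge-based diet assistant back end for caregivers of people with
Alzheimer disease and related dementias (ADRD), implemented as a
text-mode conversational system. It is aimed at health-informatics
researchers and engineers studying knowledge-driven clinical decision
support: everything a voice front end would delegate to "the back end"
is here — the knowledge base, the reasoner, the guideline rules, the
dialogue manager, and the evaluation harness — with no cloud services,
no speech I/O, and no external downloads (a deterministic generator
fabricates all inputs).

## What it implements

**Knowledge base (`ontology_kb`).** Three ontologies — user profiles,
ADRD diet support, and food/nutrition — as one typed concept graph:
classes linked by the IS-A relation, individuals linked by the *type*
relation, foods carrying nutrients per 100 g (FoodData Central
convention), recipes, and patient/caregiver profiles. The KB partitions
into a TBox (classes, axioms) and an ABox (instances) and merges back
losslessly.

**Inference engine (`inference_engine`).** A backward-chaining prover
and conjunctive-query answerer over safe Horn rules (a function-free
Datalog subset of SWRL with numeric comparison built-ins and stratified
negation-as-failure). Evaluation is tabled and goal-directed; proofs
carry replayable traces. A satisfiability check reports every
individual entailed into two disjoint classes. The canonical worked
example: from facts `D(x), A(x)` and rules `A(y) ∧ D(y) → C(y)`,
`C(y) → B(y)`, the engine proves `B(x)` with a depth-2 trace.

**Guideline rules (`guideline_rules`).** The citable dietary knowledge:

* *MIND diet* — encourage vegetables, berries, nuts, olive oil, whole
  grains, fish, beans, poultry; limit butter, margarine, cheese, red
  meat, fried food, pastries, sweets (inherited through IS-A; limit
  wins on conflict).
* *HHS Dietary Guidelines* — a man on three meals/day: 800–850 kcal per
  meal.
* *ADA Diabetes Guidelines* — diabetic dinner energy = 25% of the
  Estimated Energy Requirement (EER); protein 20–30% of meal energy;
  sugar < 10% of meal energy (Atwater factors 4/4/9 kcal/g).

**Dialogue manager (`dialogue_manager`).** Intent detection by
Jaccard token overlap after ontology/synonym expansion, finite-state
dialogue graphs (S0 start; offer/decision loop with accept and reject
branches), slot filling with over-answering, short/long-term context
with per-entry expiry, and education-tier response templates. Exactly
five service categories are registered: proper-diet tips,
eating-challenge handling, food/nutrition explanation, meal suggestion,
diet-history recall.

**Diet services (`diet_services`).** Suitability verdicts with cited
reasons, snack suggestion, constraint-filtered and ranked recipe
recommendation with session-scoped rejection memory, meal history
recording/recall, and a cycling tip bank.

**Evaluation harness (`eval_harness`).** Scripted conversations with a
20-turn failure threshold, dialogue success rate
(100·n_success/n_total), recommendation correctness rate
(100·n_correct/n_responses, judged by an automated
guideline-consistency checker), and a per-category report.

## Worked example

Generate the synthetic bundle and chat:

```bash
adrd-diet fixtures generate --seed 1 --out bundle
printf 'Is cheese good as a snack for my dad?\nCan you suggest a good snack?\nRecommend a recipe for dinner\nyes\nquit\n' \
  | adrd-diet chat --bundle bundle
```

```
Hello! I am your diet assistant. Ask me about foods, meals, or tips.
Cheese is not a good choice as a snack: Cheese is on the MIND diet limit list; its consumption should be limited [MIND diet]
I suggest blueberries as a snack: blueberries is on the MIND diet encourage list [MIND diet]
I recommend Baked salmon with brown rice and spinach (25 min, 500 kcal per serving). Would you like it?
Great! Baked salmon with brown rice and spinach it is. Enjoy your meal.
Goodbye! Take care.
```

The default profile is the reference persona: a 65-year-old man with
early-stage ADRD and type 2 diabetes (EER 2000 kcal/day), cared for by
a caregiver with 45 minutes and a 12-unit budget per meal. Cheese is
refused because it sits on the MIND limit list; the snack is the
lexicographically first MIND-encouraged, non-allergenic snack food; the
dinner hits the ADA target of 0.25 × 2000 = 500 kcal per serving with
protein at 25% and sugar at 5% of meal energy (`adrd-diet recommend
--bundle bundle --meal dinner` prints the full rationale as JSON).

Batch evaluation over the 33 shipped conversation scripts:

```bash
adrd-diet eval --bundle bundle
```

```
category          n_dialogues  avg_turns  success_rate_pct  correctness_rate_pct
food_explanation  11           2.8        90.9              100.0
meal_suggestion   11           3.5        90.9              100.0
proper_diet_tips  11           2.9        90.9              100.0
```

Each category contains ten regular scripts and one adversarial script
that never supplies the elicited slot and is marked failed at the
20-turn threshold, hence 10/11 = 90.9% success; every recommendation
the system produced passes the automated guideline check, hence 100%
correctness.

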