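"""Independent forward-chaining fixpoint oracle for Datalog programs.

Deliberately naive: repeatedly grounds every rule against the current
fact set until nothing new is derived. Used only to cross-check the
goal-directed tabled evaluator; shares no code with it.
"""

from __future__ import annotations

import itertools
import random

from adrd_diet.inference_engine import (COMPARISON_PREDICATES, Atom, Rule,
                                        is_variable)


def forward_chain(facts: set[Atom], rules: list[Rule]) -> set[Atom]:
    """Least fixpoint of the rules over the facts (positive programs)."""
    derived = set(facts)
    changed = True
    while changed:
        changed = False
        new: set[Atom] = set()
        for rule in rules:
            for binding in _all_groundings(rule.body, frozenset(derived)):
                head = rule.head.substitute(binding)
                if head not in derived:
                    new.add(head)
        if new:
            derived |= new
            changed = True
    return derived


def _all_groundings(body, facts):
    def rec(i, binding):
        if i == len(body):
            yield dict(binding)
            return
        atom = body[i]
        if atom.predicate in COMPARISON_PREDICATES:
            bound = atom.substitute(binding)
            a, b = bound.args
            try:
                ok = COMPARISON_PREDICATES[bound.predicate](float(a), float(b))
            except (TypeError, ValueError):
                ok = COMPARISON_PREDICATES[bound.predicate](str(a), str(b))
            if ok != bound.negated:
                yield from rec(i + 1, binding)
            return
        if atom.negated:
            if atom.substitute(binding) not in facts:
                yield from rec(i + 1, binding)
            return
        for fact in facts:
            if fact.predicate != atom.predicate or \
                    len(fact.args) != len(atom.args):
                continue
            new = dict(binding)
            ok = True
            for pat, val in zip(atom.args, fact.args):
                if is_variable(pat):
                    if new.get(pat, val) != val:
                        ok = False
                        break
                    new[pat] = val
                elif pat != val:
                    ok = False
                    break
            if ok:
                yield from rec(i + 1, new)

    yield from rec(0, {})


def random_program(rng: random.Random, n_preds: int = 8, n_rules: int = 12,
                   n_consts: int = 20, n_facts: int = 25
                   ) -> tuple[set[Atom], list[Rule]]:
    """A random safe positive Datalog program (possibly recursive)."""
    preds = [(f"p{i}", rng.choice([1, 1, 2])) for i in range(
        rng.randint(2, n_preds))]
    consts = [f"c{i}" for i in range(rng.randint(2, n_consts))]
    facts = set()
    for _ in range(rng.randint(1, n_facts)):
        name, arity = rng.choice(preds)
        facts.add(Atom(name, tuple(rng.choice(consts)
                                   for _ in range(arity))))
    rules = []
    variables = ["?x", "?y", "?z"]
    for ri in range(rng.randint(1, n_rules)):
        body = []
        bound_vars: list[str] = []
        for _ in range(rng.randint(1, 3)):
            name, arity = rng.choice(preds)
            args = []
            for _ in range(arity):
                v = rng.choice(variables + consts[:3])
                args.append(v)
                if is_variable(v):
                    bound_vars.append(v)
            body.append(Atom(name, tuple(args)))
        name, arity = rng.choice(preds)
        head_args = tuple(
            rng.choice(bound_vars) if bound_vars and rng.random() < 0.8
            else rng.choice(consts[:3])
            for _ in range(arity))
        rules.append(Rule(id=f"r{ri}", body=tuple(body),
                          head=Atom(name, head_args)))
    return facts, rules
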