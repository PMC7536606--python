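"""Goal-driven inference over Horn rules and the knowledge base.

The rule language is a function-free Datalog subset of SWRL: rules are
safe Horn clauses ``body1 ^ body2 ^ ... -> head`` whose atoms are

* unary class predicates, e.g. ``Dairy(?f)``;
* binary property predicates, e.g. ``sugar_g(?f, ?v)``;
* numeric comparison built-ins ``lessThan / lessThanOrEqual / equal /
  notEqual / greaterThanOrEqual / greaterThan`` over bound constants;
* optionally negated atoms (``not Pred(...)``) under stratified
  negation-as-failure, used by guideline rules with exclusion lists.

Proving is *tabled, goal-directed* evaluation: the answer table is
populated only for predicates in the backward dependency closure of the
goal (rules whose consequent can contribute, recursively), and within
that closure a semi-naive fixpoint saturates the table stratum by
stratum. Repeated subgoals hit the table instead of re-deriving, and
cyclic rule graphs terminate because the table is finite. Successful
derivations are replayed from provenance into a proof trace.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ontology_kb import KnowledgeBase, LookupError_, superclasses

COMPARISON_PREDICATES = {
    "lessThan": lambda a, b: a < b,
    "lessThanOrEqual": lambda a, b: a <= b,
    "equal": lambda a, b: a == b,
    "notEqual": lambda a, b: a != b,
    "greaterThanOrEqual": lambda a, b: a >= b,
    "greaterThan": lambda a, b: a > b,
}
# symbol aliases accepted by the parser
_COMPARISON_ALIASES = {
    "<": "lessThan", "<=": "lessThanOrEqual", "=": "equal", "==": "equal",
    "!=": "notEqual", ">=": "greaterThanOrEqual", ">": "greaterThan",
}


class RuleError(Exception):
    """A rule or goal is malformed (unsafe, wrong arity, parse failure)."""


def is_variable(term) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass(frozen=True)
class Atom:
    """A predicate applied to terms; terms are ``?var`` strings or constants."""

    predicate: str
    args: tuple
    negated: bool = False

    def __post_init__(self):
        if self.predicate in COMPARISON_PREDICATES and len(self.args) != 2:
            raise RuleError(
                f"comparison {self.predicate} needs 2 args, got {len(self.args)}")

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(a for a in self.args if is_variable(a))

    def substitute(self, binding: Mapping[str, object]) -> "Atom":
        return Atom(self.predicate,
                    tuple(binding.get(a, a) if is_variable(a) else a
                          for a in self.args),
                    self.negated)

    def is_ground(self) -> bool:
        return not self.variables

    def __str__(self):
        inner = ", ".join(str(a) for a in self.args)
        s = f"{self.predicate}({inner})"
        return f"not {s}" if self.negated else s


@dataclass(frozen=True)
class Rule:
    """A safe Horn clause: conjunction of body atoms entailing one head atom."""

    id: str
    body: tuple[Atom, ...]
    head: Atom
    provenance: str = ""

    def __post_init__(self):
        if self.head.negated:
            raise RuleError(f"rule {self.id}: head must be a positive atom")
        if self.head.predicate in COMPARISON_PREDICATES:
            raise RuleError(f"rule {self.id}: head cannot be a comparison")
        positive_vars = frozenset(
            v for a in self.body
            if not a.negated and a.predicate not in COMPARISON_PREDICATES
            for v in a.variables)
        unsafe = self.head.variables - positive_vars
        if unsafe:
            raise RuleError(
                f"rule {self.id}: unsafe head variables {sorted(unsafe)}")
        for a in self.body:
            if (a.negated or a.predicate in COMPARISON_PREDICATES) and \
                    not (a.variables <= positive_vars):
                raise RuleError(
                    f"rule {self.id}: atom {a} uses variables not bound "
                    f"by a positive body atom")

    def __str__(self):
        return " ^ ".join(map(str, self.body)) + " -> " + str(self.head)


@dataclass
class ProofResult:
    """Outcome of proving a goal: status, one witness binding, derivation trace."""

    goal: Atom
    proven: bool
    bindings: dict[str, object] = field(default_factory=dict)
    trace: list[tuple[str, Atom]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Facts from the knowledge base
# ---------------------------------------------------------------------------

def kb_facts(kb: KnowledgeBase) -> set[Atom]:
    """Ground atoms asserted by the KB.

    Unary class membership respects IS-A subsumption: an individual of
    Cheese is also a Dairy and a Food. Property assertions become binary
    atoms.
    """
    facts: set[Atom] = set()
    for ind in kb.individuals.values():
        classes: set[str] = set()
        for t in ind.types:
            classes.add(t)
            classes.update(superclasses(kb, t))
        for c in classes:
            facts.add(Atom(c, (ind.id,)))
        for pred, value in ind.properties:
            facts.add(Atom(pred, (ind.id, value)))
    return facts


# ---------------------------------------------------------------------------
# Tabled goal-directed evaluation
# ---------------------------------------------------------------------------

def _relevant_predicates(goal_preds: set[str], rules: Sequence[Rule]) -> set[str]:
    """Backward closure: predicates that can contribute to the goal."""
    by_head: dict[str, list[Rule]] = {}
    for r in rules:
        by_head.setdefault(r.head.predicate, []).append(r)
    seen: set[str] = set()
    todo = list(goal_preds)
    while todo:
        p = todo.pop()
        if p in seen:
            continue
        seen.add(p)
        for r in by_head.get(p, []):
            todo.extend(a.predicate for a in r.body)
    return seen


def _stratify(rules: Sequence[Rule]) -> list[list[Rule]]:
    """Order rules into negation strata; raise RuleError if unstratifiable."""
    preds = {r.head.predicate for r in rules}
    stratum = {p: 0 for p in preds}
    n = max(1, len(preds))
    for _ in range(n * 2 + 1):
        changed = False
        for r in rules:
            h = r.head.predicate
            for a in r.body:
                if a.predicate not in stratum:
                    continue
                need = stratum[a.predicate] + (1 if a.negated else 0)
                if stratum[h] < need:
                    stratum[h] = need
                    changed = True
        if not changed:
            break
    else:
        raise RuleError("rule set is not stratifiable (negation cycle)")
    out: dict[int, list[Rule]] = {}
    for r in rules:
        out.setdefault(stratum[r.head.predicate], []).append(r)
    return [out[k] for k in sorted(out)]


class _Table:
    """Derived-fact table with rule provenance for trace reconstruction."""

    def __init__(self, facts: Iterable[Atom]):
        self.by_pred: dict[str, set[tuple]] = {}
        self.provenance: dict[Atom, tuple[str, tuple[Atom, ...]]] = {}
        for f in facts:
            self.by_pred.setdefault(f.predicate, set()).add(f.args)

    def holds(self, atom: Atom) -> bool:
        return atom.args in self.by_pred.get(atom.predicate, ())

    def add(self, atom: Atom, rule_id: str, premises: tuple[Atom, ...]) -> bool:
        s = self.by_pred.setdefault(atom.predicate, set())
        if atom.args in s:
            return False
        s.add(atom.args)
        self.provenance[atom] = (rule_id, premises)
        return True

    def match(self, atom: Atom, binding: Mapping[str, object]
              ) -> Iterable[dict]:
        """Extend ``binding`` with every table match of ``atom``."""
        bound = atom.substitute(binding)
        # snapshot: the fixpoint loop may add facts while we iterate
        for args in tuple(self.by_pred.get(atom.predicate, ())):
            if len(args) != len(bound.args):
                continue
            new = dict(binding)
            ok = True
            for pat, val in zip(bound.args, args):
                if is_variable(pat):
                    if new.get(pat, val) != val:
                        ok = False
                        break
                    new[pat] = val
                elif pat != val:
                    ok = False
                    break
            if ok:
                yield new


def _eval_comparison(atom: Atom, binding: Mapping[str, object]) -> bool:
    bound = atom.substitute(binding)
    if not bound.is_ground():
        raise RuleError(f"comparison {atom} evaluated with unbound variables")
    a, b = bound.args
    try:
        result = COMPARISON_PREDICATES[bound.predicate](float(a), float(b))
    except (TypeError, ValueError):
        result = COMPARISON_PREDICATES[bound.predicate](str(a), str(b))
    return result != bound.negated


def _saturate(table: _Table, rules: Sequence[Rule], relevant: set[str]) -> None:
    """Semi-naive fixpoint over the relevant rules, stratum by stratum."""
    active = [r for r in rules if r.head.predicate in relevant]
    for stratum in _stratify(active):
        changed = True
        while changed:
            changed = False
            for rule in stratum:
                for binding, premises in _ground_body(table, rule.body):
                    head = rule.head.substitute(binding)
                    if table.add(head, rule.id, premises):
                        changed = True


def _ground_body(table: _Table, body: tuple[Atom, ...]
                 ) -> Iterable[tuple[dict, tuple[Atom, ...]]]:
    """Enumerate (binding, positive premises) satisfying the whole body."""

    def rec(i: int, binding: dict, premises: tuple[Atom, ...]):
        if i == len(body):
            yield binding, premises
            return
        atom = body[i]
        if atom.predicate in COMPARISON_PREDICATES:
            if _eval_comparison(atom, binding):
                yield from rec(i + 1, binding, premises)
        elif atom.negated:
            if not table.holds(atom.substitute(binding)):
                yield from rec(i + 1, binding, premises)
        else:
            for new in table.match(atom, binding):
                yield from rec(i + 1, new,
                               premises + (atom.substitute(new),))

    yield from rec(0, {}, ())


def _build_table(kb_or_facts, rules: Sequence[Rule],
                 goal_preds: set[str]) -> _Table:
    facts = (kb_or_facts if isinstance(kb_or_facts, (set, frozenset, list))
             else kb_facts(kb_or_facts))
    table = _Table(facts)
    relevant = _relevant_predicates(set(goal_preds), rules)
    _saturate(table, rules, relevant)
    return table


def _trace_for(table: _Table, atom: Atom) -> list[tuple[str, Atom]]:
    """Replay the derivation of ``atom`` from provenance, goal-rule first."""
    out: list[tuple[str, Atom]] = []
    seen: set[Atom] = set()

    def rec(a: Atom):
        if a in seen or a not in table.provenance:
            return
        seen.add(a)
        rule_id, premises = table.provenance[a]
        out.append((rule_id, a))
        for p in premises:
            rec(p)

    rec(atom)
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def prove(goal: Atom, kb, rules: Iterable[Rule] = ()) -> ProofResult:
    """Prove a goal atom against the KB facts and Horn rules.

    ``proven`` is true iff the goal (or some grounding of it, when it
    contains variables) lies in the least fixpoint of the rules over the
    facts. The trace lists the rule applications of the successful
    derivation, goal rule first; a goal matched directly by an asserted
    fact has an empty trace.
    """
    if goal.negated:
        raise RuleError("goal must be a positive atom")
    if goal.predicate in COMPARISON_PREDICATES:
        if not goal.is_ground():
            raise RuleError("comparison goal must be ground")
        return ProofResult(goal, _eval_comparison(goal, {}))
    rules = list(rules)
    table = _build_table(kb, rules, {goal.predicate})
    matches = sorted(
        table.match(goal, {}),
        key=lambda b: tuple(str(b[v]) for v in sorted(b)))
    if not matches:
        return ProofResult(goal, False)
    binding = matches[0]
    witness = goal.substitute(binding)
    return ProofResult(goal, True, bindings=binding,
                       trace=_trace_for(table, witness))


def query(conjunction: Sequence[Atom], kb,
          rules: Iterable[Rule] = ()) -> list[dict]:
    """Answer a conjunctive query: every substitution grounding all atoms.

    Set semantics, deterministic enumeration (lexicographic on the bound
    constants in variable-name order). Comparison or negated atoms must
    have their variables bound by a positive atom of the conjunction.
    """
    conjunction = tuple(conjunction)
    if not conjunction:
        return [{}]
    positive_vars = frozenset(
        v for a in conjunction
        if not a.negated and a.predicate not in COMPARISON_PREDICATES
        for v in a.variables)
    for a in conjunction:
        if (a.negated or a.predicate in COMPARISON_PREDICATES) and \
                not (a.variables <= positive_vars):
            raise RuleError(f"unsafe query atom {a}: unbound variable")
    rules = list(rules)
    preds = {a.predicate for a in conjunction
             if a.predicate not in COMPARISON_PREDICATES}
    table = _build_table(kb, rules, preds)
    results: list[dict] = []
    seen: set[tuple] = set()
    for binding, _ in _ground_body(table, conjunction):
        key = tuple(sorted(binding.items(), key=lambda kv: kv[0]))
        if key not in seen:
            seen.add(key)
            results.append(binding)
    results.sort(key=lambda b: tuple(str(b[v]) for v in sorted(b)))
    return results


def is_subsumed(kb: KnowledgeBase, sub: str, sup: str) -> bool:
    """TBox subsumption: sub ⊑ sup iff sup is an IS-A ancestor (or sub itself)."""
    kb.require_class(sub)
    kb.require_class(sup)
    return sub == sup or sup in superclasses(kb, sub)


@dataclass(frozen=True)
class Conflict:
    """An individual entailed to belong to two disjoint classes."""

    individual: str
    class_a: str
    class_b: str
    trace: tuple[tuple[str, Atom], ...] = ()

    def __str__(self):
        return (f"{self.individual} is entailed both {self.class_a} and "
                f"{self.class_b}, declared disjoint")


def check_satisfiability(kb: KnowledgeBase,
                         rules: Iterable[Rule] = ()) -> list[Conflict]:
    """Find every disjointness violation entailed by facts + rules.

    This is a deliberately limited satisfiability check: only pairwise
    class disjointness axioms are tested, against the full entailment
    closure (IS-A inheritance plus rule derivations).
    """
    rules = list(rules)
    # disjointness is symmetric; normalize each axiom to an ordered pair
    axioms: set[tuple[str, str]] = set()
    for cls in kb.classes.values():
        for d in cls.disjoint_with:
            axioms.add(tuple(sorted((cls.name, d))))
    if not axioms:
        return []
    preds = {c for pair in axioms for c in pair}
    table = _build_table(kb, rules, preds)
    conflicts: list[Conflict] = []
    for a, b in sorted(axioms):
        members_a = {args[0] for args in table.by_pred.get(a, ())
                     if len(args) == 1}
        members_b = {args[0] for args in table.by_pred.get(b, ())
                     if len(args) == 1}
        for ind in sorted(members_a & members_b,
                          key=str):
            trace = tuple(_trace_for(table, Atom(a, (ind,))) +
                          _trace_for(table, Atom(b, (ind,))))
            conflicts.append(Conflict(str(ind), a, b, trace))
    return conflicts


# ---------------------------------------------------------------------------
# Rule parsing: SWRL-like text and JSON forms
# ---------------------------------------------------------------------------

_ATOM_RE = re.compile(r"^(not\s+)?([A-Za-z_][\w.-]*)\s*\(([^()]*)\)$")


def _parse_term(tok: str):
    tok = tok.strip()
    if tok.startswith("?"):
        return tok
    if tok.startswith('"') and tok.endswith('"') and len(tok) >= 2:
        return tok[1:-1]
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        pass
    return tok


def parse_atom(text: str) -> Atom:
    text = text.strip()
    m = _ATOM_RE.match(text)
    if m is None:
        # infix comparison form: "?x < 5"
        for sym in ("<=", ">=", "!=", "==", "<", ">", "="):
            if sym in text:
                lhs, rhs = text.split(sym, 1)
                return Atom(_COMPARISON_ALIASES[sym],
                            (_parse_term(lhs), _parse_term(rhs)))
        raise RuleError(f"cannot parse atom: {text!r}")
    negated, pred, args = m.groups()
    pred = _COMPARISON_ALIASES.get(pred, pred)
    terms = tuple(_parse_term(t) for t in args.split(",")) if args.strip() else ()
    return Atom(pred, terms, negated=bool(negated))


def parse_rule(line: str, rule_id: str, provenance: str = "") -> Rule:
    if "->" not in line:
        raise RuleError(f"rule {rule_id}: missing '->' in {line!r}")
    body_txt, head_txt = line.split("->", 1)
    body = tuple(parse_atom(p) for p in body_txt.split("^") if p.strip())
    return Rule(id=rule_id, body=body, head=parse_atom(head_txt),
                provenance=provenance)


def load_rules(path: str | Path) -> list[Rule]:
    """Read a rule file: plain SWRL-like text (.rules/.txt) or JSON.

    Text format, one rule per line::

        # provenance: MIND diet
        Berries(?f) ^ sugar_g(?f, ?s) ^ lessThan(?s, 15) -> GoodSnack(?f)

    A ``# provenance:`` comment sets the provenance of subsequent rules.
    JSON form: ``[{"id", "body": [...], "head": ..., "provenance"?}]``
    where atoms are ``{"predicate", "args", "negated"?}``.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        out = []
        for i, r in enumerate(doc):
            def mk(a):
                return Atom(a["predicate"], tuple(
                    _parse_term(x) if isinstance(x, str) else x
                    for x in a["args"]), a.get("negated", False))
            out.append(Rule(
                id=r.get("id", f"r{i + 1}"),
                body=tuple(mk(a) for a in r["body"]), head=mk(r["head"]),
                provenance=r.get("provenance", "")))
        return out
    rules: list[Rule] = []
    provenance = ""
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "provenance:" in line:
                provenance = line.split("provenance:", 1)[1].strip()
            continue
        try:
            rules.append(parse_rule(line, f"r{len(rules) + 1}", provenance))
        except RuleError as e:
            raise RuleError(f"{path.name}: line {lineno}: {e}") from None
    return rules
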