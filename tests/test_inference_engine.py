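import random

import pytest

from adrd_diet.inference_engine import (Atom, Conflict, Rule, RuleError,
                                        check_satisfiability, is_subsumed,
                                        kb_facts, load_rules, parse_atom,
                                        parse_rule, prove, query)
from adrd_diet.ontology_kb import Individual, KnowledgeBase, OntClass

from oracle import forward_chain, random_program


def atoms(*specs):
    return {Atom(p, tuple(args)) for p, *args in specs}


class TestProve:
    def test_chained_rules_prove_goal_with_depth_two_trace(self):
        """A member of D and A is provable to be a B through C."""
        facts = atoms(("A", "x"), ("D", "x"))
        rules = [
            parse_rule("A(?y) ^ D(?y) -> C(?y)", "r1"),
            parse_rule("C(?y) -> B(?y)", "r2"),
        ]
        result = prove(Atom("B", ("x",)), facts, rules)
        assert result.proven
        assert len(result.trace) == 2
        assert result.trace[0][0] == "r2"  # goal rule first
        assert result.trace[1][0] == "r1"

    def test_asserted_fact_needs_no_rule_expansion(self):
        result = prove(Atom("B", ("x",)), atoms(("B", "x")), [])
        assert result.proven and result.trace == []

    def test_unreachable_goal_is_not_proven(self):
        facts = atoms(("A", "x"))
        rules = [parse_rule("A(?y) -> C(?y)", "r1")]
        assert not prove(Atom("E", ("x",)), facts, rules).proven

    def test_open_goal_binds_a_witness(self):
        facts = atoms(("A", "b"), ("A", "a"))
        result = prove(Atom("A", ("?v",)), facts, [])
        assert result.proven
        assert result.bindings == {"?v": "a"}  # lexicographic witness

    def test_cyclic_rules_terminate(self):
        facts = atoms(("P", "x"))
        rules = [parse_rule("P(?y) -> Q(?y)", "r1"),
                 parse_rule("Q(?y) -> P(?y)", "r2")]
        assert prove(Atom("Q", ("x",)), facts, rules).proven
        assert not prove(Atom("Q", ("z",)), facts, rules).proven

    def test_trace_replays_to_the_goal(self):
        facts = atoms(("A", "x"), ("D", "x"))
        rules = [parse_rule("A(?y) ^ D(?y) -> C(?y)", "r1"),
                 parse_rule("C(?y) -> B(?y)", "r2")]
        by_id = {r.id: r for r in rules}
        result = prove(Atom("B", ("x",)), facts, rules)
        derived = set(facts)
        for rule_id, head in reversed(result.trace):
            rule = by_id[rule_id]
            assert head.predicate == rule.head.predicate
            derived.add(head)
        assert Atom("B", ("x",)) in derived


class TestQuery:
    def test_conjunction_enumerates_exactly_the_joint_members(self):
        facts = atoms(("Snack", "nuts"), ("Snack", "berries"),
                      ("Snack", "candy"), ("Encouraged", "nuts"),
                      ("Encouraged", "berries"), ("Encouraged", "kale"))
        result = query([Atom("Snack", ("?f",)), Atom("Encouraged", ("?f",))],
                       facts, [])
        assert [b["?f"] for b in result] == ["berries", "nuts"]

    def test_contradictory_comparisons_give_empty_set(self):
        facts = atoms(("V", "a", 5))
        result = query([Atom("V", ("?x", "?v")),
                        Atom("lessThan", ("?v", 1)),
                        Atom("greaterThan", ("?v", 2))], facts, [])
        assert result == []

    def test_single_atom_query_counts_all_foods(self, kb, rules):
        result = query([Atom("Food", ("?f",))], kb, rules)
        assert len(result) == len(kb.foods)

    def test_unsafe_query_is_rejected(self):
        with pytest.raises(RuleError, match="unsafe"):
            query([Atom("lessThan", ("?v", 3))], set(), [])

    def test_deterministic_enumeration_order(self):
        facts = atoms(("P", "b"), ("P", "a"), ("P", "c"))
        r1 = query([Atom("P", ("?x",))], facts, [])
        r2 = query([Atom("P", ("?x",))], facts, [])
        assert r1 == r2 == [{"?x": "a"}, {"?x": "b"}, {"?x": "c"}]


class TestSubsumption:
    def test_chain_subsumption(self, toy_kb):
        assert is_subsumed(toy_kb, "Cheese", "Food")

    def test_reflexive(self, toy_kb):
        assert is_subsumed(toy_kb, "Cheese", "Cheese")

    def test_not_symmetric(self, toy_kb):
        assert not is_subsumed(toy_kb, "Food", "Cheese")


class TestSatisfiability:
    def _conflicted_kb(self):
        kb = KnowledgeBase()
        kb.add_class(OntClass(name="VegetarianMeal",
                              disjoint_with=frozenset({"ContainsMeat"})))
        kb.add_class(OntClass(name="ContainsMeat"))
        kb.add_class(OntClass(name="Meat"))
        kb.add_individual(Individual(
            id="m1", types=frozenset({"VegetarianMeal"}),
            properties=frozenset({("hasIngredient", "beef")})))
        kb.add_individual(Individual(id="beef", types=frozenset({"Meat"})))
        kb.validate()
        return kb

    def test_entailed_disjoint_membership_is_one_conflict(self):
        kb = self._conflicted_kb()
        rules = [parse_rule(
            "hasIngredient(?m, ?i) ^ Meat(?i) -> ContainsMeat(?m)", "r1")]
        conflicts = check_satisfiability(kb, rules)
        assert len(conflicts) == 1
        c = conflicts[0]
        assert c.individual == "m1"
        assert {c.class_a, c.class_b} == {"VegetarianMeal", "ContainsMeat"}
        assert any(rid == "r1" for rid, _ in c.trace)

    def test_no_disjointness_axioms_means_no_conflicts(self, toy_kb):
        assert check_satisfiability(toy_kb, []) == []

    def test_shipped_bundle_is_satisfiable(self, kb, rules):
        assert check_satisfiability(kb, rules) == []


class TestRuleLanguage:
    def test_unsafe_head_variable_rejected(self):
        with pytest.raises(RuleError, match="unsafe"):
            parse_rule("A(?x) -> B(?z)", "r1")

    def test_comparison_variable_must_be_bound(self):
        with pytest.raises(RuleError):
            parse_rule("A(?x) ^ lessThan(?q, 3) -> B(?x)", "r1")

    def test_text_rule_file_round_trip(self, tmp_path):
        path = tmp_path / "r.rules"
        path.write_text(
            "# provenance: MIND diet\n"
            "Berries(?f) ^ sugar_g(?f, ?s) ^ lessThan(?s, 15) -> Good(?f)\n")
        rules = load_rules(path)
        assert len(rules) == 1
        assert rules[0].provenance == "MIND diet"
        assert rules[0].body[2].predicate == "lessThan"

    def test_parse_error_cites_line_number(self, tmp_path):
        path = tmp_path / "r.rules"
        path.write_text("A(?x) -> B(?x)\nthis is not a rule\n")
        with pytest.raises(RuleError, match="line 2"):
            load_rules(path)

    def test_infix_comparison_form_accepted(self):
        atom = parse_atom("?v < 10")
        assert atom.predicate == "lessThan" and atom.args == ("?v", 10)


class TestOracleEquivalence:
    """The tabled backward chainer must agree with naive forward chaining."""

    N_PROGRAMS = 150

    def test_random_programs_agree_with_forward_fixpoint(self):
        rng = random.Random(20240901)
        for _ in range(self.N_PROGRAMS):
            facts, rules = random_program(rng)
            expected = forward_chain(facts, rules)
            preds = {f.predicate for f in expected} | \
                    {r.head.predicate for r in rules}
            for pred in sorted(preds):
                arities = {len(f.args) for f in expected
                           if f.predicate == pred} or {1}
                for arity in arities:
                    vars_ = tuple(f"?v{i}" for i in range(arity))
                    got = {tuple(b[v] for v in vars_)
                           for b in query([Atom(pred, vars_)], facts, rules)}
                    want = {f.args for f in expected
                            if f.predicate == pred and len(f.args) == arity}
                    assert got == want, (pred, facts, rules)

    def test_monotone_in_facts(self):
        rng = random.Random(7)
        for _ in range(30):
            facts, rules = random_program(rng)
            expected = forward_chain(facts, rules)
            goal = sorted(expected, key=str)[0] if expected else None
            if goal is None:
                continue
            assert prove(goal, facts, rules).proven
            extra = facts | {Atom("p0", ("c_new",))}
            assert prove(goal, extra, rules).proven


class TestKBFacts:
    def test_class_membership_respects_subsumption(self, toy_kb):
        facts = kb_facts(toy_kb)
        assert Atom("Cheese", ("cheddar",)) in facts
        assert Atom("Dairy", ("cheddar",)) in facts
        assert Atom("Food", ("cheddar",)) in facts

    def test_negation_as_failure_in_guideline_style_rule(self, toy_kb):
        rules = [Rule(id="r1",
                      body=(Atom("Food", ("?f",)),
                            Atom("Banned", ("?f",), negated=True)),
                      head=Atom("Allowed", ("?f",)))]
        result = query([Atom("Allowed", ("?f",))], toy_kb, rules)
        assert [b["?f"] for b in result] == ["cheddar"]
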