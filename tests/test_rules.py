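"""Rule-language tests: parsing, semantics, and the MILP linearization."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from geneforce import rules as rl
from geneforce._milp import OPTIMAL, LinearProblem
from geneforce.rules import (
    AmbiguousPrecedenceWarning,
    And,
    Const,
    Not,
    Or,
    Ref,
    RuleSyntaxError,
    SymbolKind,
    SymbolRef,
    evaluate,
    free_symbols,
    linearize,
    parse_rule,
)


class TestParsing:
    def test_negated_tf_or_environmental_predicate(self):
        expr = parse_rule("(NOT ArgR) OR (arg-L(e)>0)")
        assert expr == Or((
            Not(Ref(SymbolRef("ArgR"))),
            Ref(SymbolRef("arg-L", SymbolKind.ENV, 0.0)),
        ))

    def test_constant_on(self):
        assert parse_rule("(ON)") == Const(True)
        assert parse_rule("OFF") == Const(False)

    def test_not_binds_tighter_than_and(self):
        assert parse_rule("NOT A AND B") == And(
            (Not(Ref(SymbolRef("A"))), Ref(SymbolRef("B")))
        )

    def test_and_binds_tighter_than_or_and_chains_flatten(self):
        expr = parse_rule("A OR B AND C OR D")
        assert isinstance(expr, Or) and len(expr.children) == 3
        assert isinstance(expr.children[1], And)

    def test_flux_predicates(self):
        expr = parse_rule("(NOT (AGMT>0))")
        (sym,) = free_symbols(expr)
        assert sym == SymbolRef("AGMT", SymbolKind.FLUX, 0.0)
        growth = parse_rule("NOT(Growth>0) AND RpoS")
        kinds = {s.name: s.kind for s in free_symbols(growth)}
        assert kinds == {"Growth": SymbolKind.FLUX, "RpoS": SymbolKind.IDENTIFIER}

    def test_environmental_shorthand_without_threshold(self):
        # bare met(e) is met(e)>0
        assert parse_rule("man(e)") == parse_rule("man(e)>0")

    def test_quoted_symbols_are_atomic(self):
        expr = parse_rule('(("CRP noMAN") AND NOT(ArcA) AND (DcuR))')
        assert SymbolRef("CRP noMAN") in free_symbols(expr)

    def test_nonzero_threshold_is_stored_not_hardcoded(self):
        (sym,) = free_symbols(parse_rule("glc-D(e)>2.5"))
        assert sym.threshold == 2.5

    @pytest.mark.parametrize("bad", ["", "   ", "(A OR ", "A AND", "OR B",
                                     "A B", "(()"])
    def test_syntax_errors_with_offset(self, bad):
        with pytest.raises(RuleSyntaxError):
            parse_rule(bad)

    def test_error_carries_character_offset(self):
        with pytest.raises(RuleSyntaxError) as err:
            parse_rule("A AND AND B")
        assert err.value.offset is not None

    def test_mixed_precedence_warns(self):
        with pytest.warns(AmbiguousPrecedenceWarning):
            parse_rule("NOT A OR B")

    def test_roundtrip_on_published_rule_strings(self, published_rule_strings):
        for text in published_rule_strings:
            ast = parse_rule(text)
            assert parse_rule(ast.to_text()) == ast, text


class TestEvaluation:
    def test_or_of_negation_and_predicate(self):
        expr = parse_rule("(NOT ArgR) OR (arg-L(e)>0)")
        assert evaluate(expr, {"ArgR": True, "arg-L(e)>0": True}) is True
        assert evaluate(expr, {"ArgR": True, "arg-L(e)>0": False}) is False
        assert evaluate(expr, {"ArgR": False, "arg-L(e)>0": False}) is True

    def test_constants_need_no_assignment(self):
        assert evaluate(Const(True), {}) is True
        assert evaluate(Const(False), {}) is False

    def test_unresolved_symbol_is_named(self):
        with pytest.raises(rl.UnresolvedSymbolError, match="ArgR"):
            evaluate(parse_rule("NOT ArgR"), {})

    def test_free_symbols_dedupe_and_preserve_kind(self):
        assert {s.name for s in free_symbols(parse_rule("(RhaR OR (RhaR AND Crp))"))} \
            == {"RhaR", "Crp"}
        assert free_symbols(parse_rule("(ON)")) == set()
        assert {s.name for s in free_symbols(parse_rule("(NOT (PurR AND Crp))"))} \
            == {"PurR", "Crp"}


def _milp_feasible_outputs(expr, leaves, assignment):
    """All values of z feasible in the linearized system given fixed leaves."""
    lp = LinearProblem()
    lp.add_binary("z")
    for name, val in zip(leaves, assignment):
        lp.add_var(f"l_{name}", float(val), float(val), integer=True)
    counter = itertools.count()

    def fresh():
        name = f"aux{next(counter)}"
        lp.add_binary(name)
        return name

    for row in linearize(expr, "z", lambda s: f"l_{s.key}", fresh):
        lp.add_constraint(row.coeffs, row.lb, row.ub)
    outputs = set()
    for maximize in (False, True):
        lp.set_objective({"z": 1.0}, maximize=maximize)
        sol = lp.solve()
        if sol.status == OPTIMAL:
            outputs.add(round(sol.values["z"]))
    return outputs


@pytest.mark.parametrize("text", [
    "A",
    "NOT A",
    "A AND B",
    "A OR B",
    "(A AND B) OR NOT C",
    "NOT (A OR (B AND NOT C))",
    "(A OR (A AND B))",
    "((NOT A AND B) OR (C AND D)) AND (NOT B OR A)",
    "(ON)",
    "OFF OR A",
])
def test_linearization_matches_truth_table(text):
    """For every leaf assignment, the only feasible output is evaluate()."""
    expr = parse_rule(text)
    leaves = sorted({s.key for s in free_symbols(expr)})
    for assignment in itertools.product([0, 1], repeat=len(leaves)):
        truth = dict(zip(leaves, map(bool, assignment)))
        expected = evaluate(expr, truth)
        outputs = _milp_feasible_outputs(expr, leaves, assignment)
        assert outputs == {int(expected)}, (text, assignment)


_names = st.sampled_from(["A", "B", "C", "D", "E", "F"])


def _exprs(depth):
    if depth == 0:
        return st.one_of(
            _names.map(lambda n: Ref(SymbolRef(n))),
            st.sampled_from([Const(True), Const(False)]),
        )
    sub = _exprs(depth - 1)
    return st.one_of(
        sub,
        sub.map(Not),
        st.tuples(sub, sub).map(And),
        st.tuples(sub, sub).map(Or),
    )


@settings(max_examples=120, deadline=None, derandomize=True)
@given(_exprs(4))
def test_random_ast_roundtrip_and_linearization(expr):
    """Random ASTs: text round-trip identity and exact MILP encodings."""
    assert parse_rule(expr.to_text()) == expr
    leaves = sorted({s.key for s in free_symbols(expr)})
    if len(leaves) > 4:
        return
    for assignment in itertools.product([0, 1], repeat=len(leaves)):
        truth = dict(zip(leaves, map(bool, assignment)))
        expected = evaluate(expr, truth)
        assert _milp_feasible_outputs(expr, leaves, assignment) == {int(expected)}
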