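"""Argument construction and grounded evaluation with confidence defeat."""

import itertools
import random

import pytest

from argudas.engine import (
    ArgumentCapExceeded,
    Argument,
    Fact,
    GroundLiteral,
    Rule,
    assert_facts,
    compile_schemes,
    construct_arguments,
    evaluate,
    grounded_labelling,
    tag_origins,
)
from argudas.schemes import load_schemes


def _rule(rule_id, antecedents, consequent, confidence, positive=True):
    return Rule(
        rule_id=rule_id,
        antecedents=tuple(antecedents),
        consequent_positive=positive,
        consequent_predicate=consequent[0],
        consequent_args=tuple(consequent[1]),
        confidence=confidence,
    )


def _argument(arg_id, conclusion, confidence, origin="direct"):
    return Argument(
        argument_id=arg_id,
        conclusion=conclusion,
        premises=frozenset(),
        rules_used=("r",),
        confidence=confidence,
        origin=origin,
    )


_EXPR = GroundLiteral(True, "expressed", ("bmp4", "future_brain", "15"))
_NOT_EXPR = _EXPR.negated()


class TestAssertFacts:
    def test_single_annotation_emits_asserts_and_flags(self, make_annotation):
        facts = assert_facts([make_annotation("E:1", levels=("strong",))], "presence")
        preds = {f.predicate for f in facts}
        assert Fact("asserts", ("E:1", "bmp4", "future_brain", "15")) in facts
        assert "asserts_expressed" in preds
        assert "origin_is_direct" in preds
        assert "probe_info_present" in preds
        assert Fact("asserts_level", ("E:1", "bmp4", "future_brain", "15", "strong")) in facts

    def test_presence_agreement_pair_emitted(self, make_annotation):
        anns = [
            make_annotation("E:1", levels=("strong",)),
            make_annotation("G:1", resource="GXD", levels=("weak",)),
        ]
        facts = assert_facts(anns, "presence")
        assert Fact("agreement_pair", ("E:1", "G:1")) in facts
        assert Fact("agreement_pair", ("G:1", "E:1")) in facts
        assert Fact("cross_resource_corroboration", ("E:1", "G:1")) in facts
        # the same pair is a conflict at level granularity
        level_facts = assert_facts(anns, "level")
        assert Fact("conflict_pair", ("E:1", "G:1")) in level_facts
        assert Fact("agreement_pair", ("E:1", "G:1")) not in level_facts

    def test_empty_input_yields_no_facts(self):
        assert assert_facts([], "presence") == []

    def test_output_is_deterministically_ordered(self, make_annotation):
        anns = [
            make_annotation("E:1", levels=("strong",)),
            make_annotation("G:1", resource="GXD", levels=("not_detected",)),
        ]
        assert assert_facts(anns, "presence") == assert_facts(anns[::-1], "presence")


class TestConstructArguments:
    def test_single_rule_single_fact(self):
        rule = _rule("r1", [("probe_info_absent", ("?a",))], ("trust", ("?a",)),
                     confidence=3, positive=False)
        facts = [Fact("probe_info_absent", ("E:1",))]
        (arg,) = construct_arguments(facts, [rule])
        assert arg.conclusion == GroundLiteral(False, "trust", ("E:1",))
        assert arg.confidence == 3
        assert arg.rules_used == ("r1",)

    def test_chain_takes_weakest_link(self):
        # A -> B at good(3)=rank 4, B -> C at weak(1)=rank 2: C argues at rank 2
        r_ab = _rule("r_ab", [("a", ("?x",))], ("b", ("?x",)), confidence=4)
        r_bc = _rule("r_bc", [("b", ("?x",))], ("c", ("?x",)), confidence=2)
        args = construct_arguments([Fact("a", ("k",))], [r_ab, r_bc])
        by_pred = {a.conclusion.predicate: a for a in args}
        assert by_pred["b"].confidence == 4
        assert by_pred["c"].confidence == 2
        assert by_pred["c"].rules_used == ("r_ab", "r_bc")

    def test_no_applicable_rules_no_arguments(self):
        rule = _rule("r1", [("never", ("?x",))], ("c", ("?x",)), confidence=2)
        assert construct_arguments([Fact("a", ("k",))], [rule]) == []

    def test_one_argument_per_distinct_derivation(self):
        rule = _rule(
            "r1",
            [("asserts_expressed", ("?a", "?g", "?s", "?t"))],
            ("expressed", ("?g", "?s", "?t")),
            confidence=3,
        )
        facts = [
            Fact("asserts_expressed", ("E:1", "bmp4", "fb", "15")),
            Fact("asserts_expressed", ("E:2", "bmp4", "fb", "15")),
        ]
        args = construct_arguments(facts, [rule])
        assert len(args) == 2  # same conclusion, two derivations
        assert {a.conclusion for a in args} == {
            GroundLiteral(True, "expressed", ("bmp4", "fb", "15"))
        }

    def test_cap_raises_explicit_error(self):
        rule = _rule(
            "r1",
            [("asserts_expressed", ("?a", "?g", "?s", "?t"))],
            ("expressed", ("?g", "?s", "?t")),
            confidence=3,
        )
        facts = [
            Fact("asserts_expressed", (f"E:{i}", "bmp4", "fb", "15"))
            for i in range(20)
        ]
        with pytest.raises(ArgumentCapExceeded, match="too high"):
            construct_arguments(facts, [rule], cap=10)

    def test_compiled_schemes_drive_derivation(self, tmp_path, make_annotation):
        import json

        schemes = [
            {
                "id": "s_sup",
                "text": "",
                "conditions": [
                    {"predicate": "asserts_expressed", "args": ["?a", "?g", "?s", "?t"]}
                ],
                "conclusion": {"polarity": "supports", "target": "expressed",
                               "args": ["?g", "?s", "?t"]},
                "score": "3",
            },
            {
                "id": "s_rejected",
                "text": "",
                "conditions": [
                    {"predicate": "asserts_expressed", "args": ["?a", "?g", "?s", "?t"]}
                ],
                "conclusion": {"polarity": "supports", "target": "expressed",
                               "args": ["?g", "?s", "?t"]},
                "score": "0",
            },
        ]
        p = tmp_path / "schemes.json"
        p.write_text(json.dumps(schemes))
        rules = compile_schemes(load_schemes(str(p)))
        assert [r.source_scheme_id for r in rules] == ["s_sup"]  # rejected dropped
        facts = assert_facts([make_annotation("E:1", levels=("weak",))], "presence")
        (arg,) = construct_arguments(facts, rules)
        assert arg.conclusion == _EXPR
        assert arg.confidence == 4  # rank of token "3"


class TestEvaluate:
    def test_higher_confidence_rebuttal_wins(self):
        strong = _argument("A1", _EXPR, confidence=4)
        weak = _argument("A2", _NOT_EXPR, confidence=2)
        args, defeat = evaluate([strong, weak])
        assert strong.status == "undefeated"
        assert weak.status == "defeated"
        assert defeat.edges == frozenset({("A1", "A2")})

    def test_equal_confidence_rebuttals_both_undecided(self):
        a = _argument("A1", _EXPR, confidence=3)
        b = _argument("A2", _NOT_EXPR, confidence=3)
        evaluate([a, b])
        assert a.status == b.status == "undecided"

    def test_reinstatement_chain(self):
        # A defeats B defeats C: C is reinstated
        a = _argument("A", _EXPR, confidence=4)
        b = _argument("B", _NOT_EXPR, confidence=3)
        c = _argument("C", _EXPR, confidence=2)
        args, defeat = evaluate([a, b, c])
        assert ("A", "B") in defeat.edges and ("B", "C") in defeat.edges
        assert a.status == "undefeated"
        assert b.status == "defeated"
        assert c.status == "undefeated"

    def test_direct_beats_propagated_regardless_of_confidence(self):
        lifted = _argument("A1", _EXPR, confidence=4, origin="propagated")
        direct_nd = _argument("A2", _NOT_EXPR, confidence=2, origin="direct")
        args, defeat = evaluate([lifted, direct_nd])
        assert direct_nd.status == "undefeated"
        assert lifted.status == "defeated"
        assert defeat.edges == frozenset({("A2", "A1")})

    def test_disjoint_level_claims_rebut_only_in_level_mode(self):
        strong = _argument(
            "A1", GroundLiteral(True, "level", ("bmp4", "fb", "15", "strong")), 3
        )
        weak = _argument(
            "A2", GroundLiteral(True, "level", ("bmp4", "fb", "15", "weak")), 3
        )
        _, defeat_presence = evaluate([strong, weak], mode="presence")
        assert defeat_presence.edges == frozenset()
        _, defeat_level = evaluate([strong, weak], mode="level")
        assert defeat_level.edges == frozenset({("A1", "A2"), ("A2", "A1")})
        assert strong.status == weak.status == "undecided"

    def test_tag_origins_marks_propagated_support(self, make_annotation):
        direct = make_annotation("E:1", levels=("weak",))
        lifted = make_annotation(
            "E:2", levels=("weak",), origin="propagated", source_annotation_id="E:1"
        )
        arg = _argument("A1", _EXPR, 3)
        arg.premises = frozenset(
            [Fact("asserts_expressed", ("E:2", "bmp4", "future_brain", "15"))]
        )
        tag_origins([arg], [direct, lifted])
        assert arg.origin == "propagated"


def _oracle_grounded(ids, edges):
    """Independent grounded oracle: least fixpoint of the defence operator.

    IN = lfp of F(S) = {a : every attacker of a is attacked by S};
    OUT = attacked by IN; everything else UNDEC.
    """
    attackers = {i: {a for a, t in edges if t == i} for i in ids}
    defended = set()
    while True:
        nxt = {
            a
            for a in ids
            if all(
                any((d, b) in edges for d in defended) for b in attackers[a]
            )
        }
        if nxt == defended:
            break
        defended = nxt
    out = {t for t in ids if any(a in defended for a in attackers[t])}
    return {
        i: "IN" if i in defended else "OUT" if i in out else "UNDEC" for i in ids
    }


class TestGroundedSemantics:
    @pytest.mark.parametrize("trial", range(60))
    def test_matches_characteristic_function_oracle(self, trial):
        rng = random.Random(4000 + trial)
        n = rng.randint(1, 12)
        ids = [f"A{i}" for i in range(n)]
        edges = {
            (a, b)
            for a in ids
            for b in ids
            if a != b and rng.random() < 0.25
        }
        assert grounded_labelling(ids, edges) == _oracle_grounded(ids, edges)

    @pytest.mark.parametrize("trial", range(20))
    def test_isolated_argument_never_changes_others(self, trial):
        rng = random.Random(5000 + trial)
        ids = [f"A{i}" for i in range(rng.randint(1, 8))]
        edges = {
            (a, b) for a in ids for b in ids if a != b and rng.random() < 0.3
        }
        base = grounded_labelling(ids, edges)
        extended = grounded_labelling(ids + ["LONER"], edges)
        assert extended["LONER"] == "IN"
        assert {i: extended[i] for i in ids} == base

    @pytest.mark.parametrize("trial", range(20))
    def test_monotone_preference(self, trial):
        """Raising the confidence of an undefeated argument never sinks it."""
        rng = random.Random(6000 + trial)
        n = rng.randint(2, 8)
        args = [
            _argument(f"A{i}", _EXPR if i % 2 == 0 else _NOT_EXPR, rng.randint(0, 4))
            for i in range(n)
        ]
        evaluate(args)
        winners = [a for a in args if a.status == "undefeated"]
        if not winners:
            return
        chosen = rng.choice(winners)
        boosted = [
            _argument(
                a.argument_id,
                a.conclusion,
                min(4, a.confidence + 1) if a is chosen else a.confidence,
            )
            for a in args
        ]
        evaluate(boosted)
        assert next(
            b for b in boosted if b.argument_id == chosen.argument_id
        ).status == "undefeated"

    @pytest.mark.parametrize("trial", range(15))
    def test_no_undefeated_target_of_undefeated_attacker(self, trial):
        rng = random.Random(7000 + trial)
        args = [
            _argument(f"A{i}", _EXPR if rng.random() < 0.5 else _NOT_EXPR,
                      rng.randint(0, 4))
            for i in range(rng.randint(2, 10))
        ]
        _, defeat = evaluate(args)
        status = {a.argument_id: a.status for a in args}
        for attacker, target in defeat.edges:
            assert not (
                status[attacker] == "undefeated" and status[target] == "undefeated"
            )
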