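"""Defeasible reasoning core: argument construction and grounded evaluation.

Annotations are translated into ground *facts*; schemes compile into
defeasible *rules* whose confidence they inherit. Forward chaining over facts
and rules builds one argument per distinct minimal derivation; an argument's
confidence is its weakest link — the minimum confidence among the rules it
uses (facts count as axiomatic, above every rule rank).

Arguments with complementary conclusions rebut each other. An attacker
defeats its target when its confidence is at least the target's, with one
domain-specific exception: a direct-origin argument takes precedence over a
propagated-origin one outright — many biologists prefer direct annotations
over propagated ones, so a direct "not detected" on a structure overrides a
claim lifted into that structure from one of its parts, whatever the
confidence ranks say.

Statuses are the unique grounded labelling of the defeat graph: an argument is
undefeated (IN) when every attacker is defeated, defeated (OUT) when some
undefeated argument attacks it, and undecided (UNDEC) otherwise — mutual
defeat between equal-confidence rebuttals leaves both undecided, which the
summariser surfaces as unresolved conflict rather than hiding it.

The number of arguments can explode on busy queries (a single well-studied
gene/structure pair can yield hundreds), so construction is guarded by a
configurable cap with an explicit error rather than an unreadable dump.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal as TypingLiteral, Optional, Sequence

from .annotations import AGREE, AgreementMode, Annotation, CONFLICT, agreement
from .schemes import Scheme

#: Rank assigned to facts: strictly above every rule rank (0..4).
FACT_RANK = 5

DEFAULT_ARGUMENT_CAP = 1000


class EngineError(ValueError):
    pass


class ArgumentCapExceeded(EngineError):
    """Raised when a query would construct more arguments than the cap allows."""


@dataclass(frozen=True, order=True)
class Fact:
    """A ground predicate instance derived from annotations/context."""

    predicate: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(str(a) for a in self.args))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.predicate}({', '.join(self.args)})"


@dataclass(frozen=True, order=True)
class GroundLiteral:
    """A (possibly negated) ground claim, e.g. ``not expressed(bmp4, S, 15)``."""

    positive: bool
    predicate: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(str(a) for a in self.args))

    def negated(self) -> "GroundLiteral":
        return GroundLiteral(not self.positive, self.predicate, self.args)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        body = f"{self.predicate}({', '.join(self.args)})"
        return body if self.positive else f"not {body}"


@dataclass(frozen=True)
class Rule:
    """A compiled defeasible rule; inherits its scheme's confidence."""

    rule_id: str
    antecedents: tuple[tuple[str, tuple[str, ...]], ...]
    consequent_positive: bool
    consequent_predicate: str
    consequent_args: tuple[str, ...]  # may contain ?variables bound by antecedents
    confidence: int
    source_scheme_id: str = ""

    def __post_init__(self) -> None:
        bound = {
            a for _, args in self.antecedents for a in args if a.startswith("?")
        }
        free = {
            a for a in self.consequent_args if a.startswith("?") and a not in bound
        }
        if free:
            raise EngineError(
                f"rule {self.rule_id}: consequent variables {sorted(free)} unbound"
            )


@dataclass
class Argument:
    argument_id: str
    conclusion: GroundLiteral
    premises: frozenset[Fact]
    rules_used: tuple[str, ...]
    confidence: int
    #: direct unless the argument rests on any propagated annotation
    origin: TypingLiteral["direct", "propagated"] = "direct"
    status: TypingLiteral["undefeated", "defeated", "undecided", "unknown"] = "unknown"

    def to_dict(self) -> dict:
        return {
            "argument_id": self.argument_id,
            "conclusion": str(self.conclusion),
            "premises": sorted(str(f) for f in self.premises),
            "rules_used": list(self.rules_used),
            "confidence": self.confidence,
            "origin": self.origin,
            "status": self.status,
        }


@dataclass(frozen=True)
class DefeatRelation:
    """Ordered defeat edges (attacker_argument_id, target_argument_id)."""

    edges: frozenset[tuple[str, str]] = frozenset()

    def attackers_of(self, target_id: str) -> list[str]:
        return sorted(a for a, t in self.edges if t == target_id)

    def to_tsv(self) -> str:
        lines = ["attacker\ttarget"]
        lines += [f"{a}\t{t}" for a, t in sorted(self.edges)]
        return "\n".join(lines) + "\n"


def compile_schemes(schemes: Iterable[Scheme]) -> list[Rule]:
    """Compile non-rejected schemes into engine rules.

    The rule inherits the scheme's confidence rank; a supporting conclusion
    becomes a positive literal and an attacking one a negated literal.
    """
    rules = []
    for s in schemes:
        if not s.compilable:
            continue
        rules.append(
            Rule(
                rule_id=f"r_{s.scheme_id}",
                antecedents=tuple((c.predicate, c.args) for c in s.conditions),
                consequent_positive=s.conclusion.polarity == "supports",
                consequent_predicate=s.conclusion.target,
                consequent_args=s.conclusion.args,
                confidence=s.score.rank,
                source_scheme_id=s.scheme_id,
            )
        )
    return rules


# --------------------------------------------------------------------------
# fact assertion

_ANNOTATION_SCOPED = {
    "asserts": (0,),
    "asserts_expressed": (0,),
    "asserts_not_detected": (0,),
    "asserts_level": (0,),
    "origin_is_direct": (0,),
    "origin_is_propagated": (0,),
    "probe_info_absent": (0,),
    "probe_info_present": (0,),
    "from_resource": (0,),
    "agreement_pair": (0, 1),
    "conflict_pair": (0, 1),
    "conflicting_annotation_exists": (0,),
    "multiple_agreeing_annotations": (0,),
    "cross_resource_corroboration": (0, 1),
}


def assert_facts(annotations: Sequence[Annotation], mode: AgreementMode) -> list[Fact]:
    """Translate annotation records into the ground fact base.

    Emits one ``asserts`` fact per annotation plus its flag facts (polarity,
    per-level claims, origin, probe info, resource) and the derived relational
    facts the predicate catalogue needs: agreement and conflict pairs at the
    chosen granularity, cross-resource corroboration, and existence flags.
    Output is deterministically ordered.
    """
    facts: set[Fact] = set()
    for a in annotations:
        key = (a.annotation_id, a.gene, a.structure_id, str(a.stage))
        facts.add(Fact("asserts", key))
        if a.level.is_positive:
            facts.add(Fact("asserts_expressed", key))
        else:
            facts.add(Fact("asserts_not_detected", key))
        for lvl in a.level.sorted_levels():
            facts.add(Fact("asserts_level", key + (lvl,)))
        facts.add(Fact(f"origin_is_{a.origin}", (a.annotation_id,)))
        if a.probe_info_present == "no":
            facts.add(Fact("probe_info_absent", (a.annotation_id,)))
        elif a.probe_info_present == "yes":
            facts.add(Fact("probe_info_present", (a.annotation_id,)))
        facts.add(Fact("from_resource", (a.annotation_id, a.resource)))

    for a, b in itertools.combinations(annotations, 2):
        rel = agreement(a, b, mode)
        pair = (a.annotation_id, b.annotation_id)
        rev = (b.annotation_id, a.annotation_id)
        if rel == AGREE:
            facts.add(Fact("agreement_pair", pair))
            facts.add(Fact("agreement_pair", rev))
            facts.add(Fact("multiple_agreeing_annotations", pair[:1]))
            facts.add(Fact("multiple_agreeing_annotations", rev[:1]))
            if a.resource != b.resource:
                facts.add(Fact("cross_resource_corroboration", pair))
                facts.add(Fact("cross_resource_corroboration", rev))
        elif rel == CONFLICT:
            facts.add(Fact("conflict_pair", pair))
            facts.add(Fact("conflict_pair", rev))
            facts.add(Fact("conflicting_annotation_exists", pair[:1]))
            facts.add(Fact("conflicting_annotation_exists", rev[:1]))
    return sorted(facts)


# --------------------------------------------------------------------------
# argument construction (forward chaining)

def _match(
    pattern_args: tuple[str, ...],
    ground_args: tuple[str, ...],
    subst: dict[str, str],
) -> Optional[dict[str, str]]:
    """Unify a pattern against a ground tuple under an existing substitution."""
    if len(pattern_args) != len(ground_args):
        return None
    out = dict(subst)
    for p, g in zip(pattern_args, ground_args):
        if p.startswith("?"):
            if out.setdefault(p, g) != g:
                return None
        elif p != g:
            return None
    return out


def construct_arguments(
    facts: Sequence[Fact],
    rules: Sequence[Rule],
    cap: int = DEFAULT_ARGUMENT_CAP,
) -> list[Argument]:
    """Build every argument derivable from the facts by the rules.

    Forward chaining to fixpoint: antecedents match against facts and against
    positive conclusions of already-built arguments, so rules chain and the
    weakest link determines the chained argument's confidence. Each distinct
    minimal derivation (rule + specific sub-arguments) yields one argument;
    derivations in which a conclusion would feed its own support are skipped.
    Termination is guaranteed (function-free rules over finitely many
    constants); the ``cap`` bounds the output with an explicit error because
    busy queries can otherwise produce unreadably many arguments.
    """
    # internal support nodes: facts are axiomatic arguments of rank FACT_RANK
    @dataclass(frozen=True)
    class _Node:
        conclusion: GroundLiteral
        premises: frozenset[Fact]
        rules_used: tuple[str, ...]
        confidence: int
        sub_conclusions: frozenset[GroundLiteral]
        derivation_key: tuple

    nodes: list[_Node] = []
    keys: set[tuple] = set()
    for f in sorted(facts):
        node = _Node(
            conclusion=GroundLiteral(True, f.predicate, f.args),
            premises=frozenset([f]),
            rules_used=(),
            confidence=FACT_RANK,
            sub_conclusions=frozenset(),
            derivation_key=("fact", f),
        )
        nodes.append(node)
        keys.add(node.derivation_key)

    sorted_rules = sorted(rules, key=lambda r: r.rule_id)
    n_derived = 0
    changed = True
    while changed:
        changed = False
        for rule in sorted_rules:
            # candidate supports per antecedent under growing substitutions
            partials: list[tuple[dict[str, str], tuple[int, ...]]] = [({}, ())]
            for pred, pargs in rule.antecedents:
                nxt = []
                for subst, support in partials:
                    for idx, node in enumerate(nodes):
                        c = node.conclusion
                        if not c.positive or c.predicate != pred:
                            continue
                        s2 = _match(pargs, c.args, subst)
                        if s2 is not None:
                            nxt.append((s2, support + (idx,)))
                partials = nxt
                if not partials:
                    break
            for subst, support in partials:
                concl = GroundLiteral(
                    rule.consequent_positive,
                    rule.consequent_predicate,
                    tuple(subst.get(a, a) for a in rule.consequent_args),
                )
                key = (rule.rule_id, support)
                if key in keys:
                    continue
                subs = [nodes[i] for i in support]
                # acyclic support: the conclusion must not feed its own derivation
                feeds = {s.conclusion for s in subs}
                feeds |= frozenset().union(*(s.sub_conclusions for s in subs)) \
                    if subs else frozenset()
                if concl in feeds:
                    continue
                keys.add(key)
                node = _Node(
                    conclusion=concl,
                    premises=frozenset().union(*(s.premises for s in subs))
                    if subs else frozenset(),
                    rules_used=tuple(
                        sorted(set(sum((s.rules_used for s in subs), (rule.rule_id,))))
                    ),
                    confidence=min([rule.confidence] + [s.confidence for s in subs]),
                    sub_conclusions=frozenset(feeds),
                    derivation_key=key,
                )
                nodes.append(node)
                n_derived += 1
                if n_derived > cap:
                    raise ArgumentCapExceeded(
                        f"more than {cap} arguments would be constructed for "
                        "this query; the potential number of arguments is too "
                        "high — raise the cap or narrow the query"
                    )
                changed = True

    derived = [n for n in nodes if n.rules_used]
    derived.sort(key=lambda n: (n.conclusion, n.rules_used, sorted(n.premises)))
    out = []
    for i, n in enumerate(derived, start=1):
        out.append(
            Argument(
                argument_id=f"A{i}",
                conclusion=n.conclusion,
                premises=n.premises,
                rules_used=n.rules_used,
                confidence=n.confidence,
            )
        )
    return out


def tag_origins(arguments: Sequence[Argument], annotations: Sequence[Annotation]) -> None:
    """Mark each argument propagated-origin if it rests on a propagated record."""
    origin = {a.annotation_id: a.origin for a in annotations}
    for arg in arguments:
        ids: set[str] = set()
        for f in arg.premises:
            for pos in _ANNOTATION_SCOPED.get(f.predicate, ()):
                if pos < len(f.args):
                    ids.add(f.args[pos])
        arg.origin = (
            "propagated"
            if any(origin.get(i) == "propagated" for i in ids)
            else "direct"
        )


# --------------------------------------------------------------------------
# evaluation under grounded semantics

def _rebuts(a: Argument, b: Argument, mode: AgreementMode) -> bool:
    ca, cb = a.conclusion, b.conclusion
    if ca == cb.negated():
        return True
    if (
        mode == "level"
        and ca.positive
        and cb.positive
        and ca.predicate == cb.predicate == "level"
        and ca.args[:3] == cb.args[:3]
        and ca.args[3] != cb.args[3]
    ):
        return True  # disjoint level claims for the same (gene, structure, stage)
    return False


def grounded_labelling(
    ids: Sequence[str], edges: Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Grounded statuses of a defeat graph.

    Iterates to fixpoint: IN when every attacker is OUT, OUT when some
    attacker is IN; whatever never stabilises is UNDEC.
    """
    attackers: dict[str, set[str]] = {i: set() for i in ids}
    for a, t in edges:
        attackers[t].add(a)
    label: dict[str, str] = {}
    changed = True
    while changed:
        changed = False
        for i in ids:
            if i in label:
                continue
            if all(label.get(x) == "OUT" for x in attackers[i]):
                label[i] = "IN"
                changed = True
            elif any(label.get(x) == "IN" for x in attackers[i]):
                label[i] = "OUT"
                changed = True
    for i in ids:
        label.setdefault(i, "UNDEC")
    return label


_STATUS = {"IN": "undefeated", "OUT": "defeated", "UNDEC": "undecided"}


def evaluate(
    arguments: Sequence[Argument], mode: AgreementMode = "presence"
) -> tuple[list[Argument], DefeatRelation]:
    """Assign dialectical statuses to rebutting arguments.

    Rebuttals hold between complementary conclusions (and, in level mode,
    between distinct positive level claims for the same gene/structure/stage).
    An attacker defeats its target when its confidence is at least the
    target's; a direct-origin argument defeats a propagated-origin rebuttal
    outright, and the propagated side gains no edge back — the direct
    annotation takes precedence. Statuses are the grounded labelling, so
    equal-confidence mutual rebuttals come out undecided on both sides.
    """
    edges: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(arguments, 2):
        if not _rebuts(a, b, mode):
            continue
        if a.origin == "direct" and b.origin == "propagated":
            edges.add((a.argument_id, b.argument_id))
        elif b.origin == "direct" and a.origin == "propagated":
            edges.add((b.argument_id, a.argument_id))
        else:
            if a.confidence >= b.confidence:
                edges.add((a.argument_id, b.argument_id))
            if b.confidence >= a.confidence:
                edges.add((b.argument_id, a.argument_id))
    ids = [arg.argument_id for arg in arguments]
    label = grounded_labelling(ids, edges)
    for arg in arguments:
        arg.status = _STATUS[label[arg.argument_id]]
    return list(arguments), DefeatRelation(frozenset(edges))


def arguments_to_json(arguments: Sequence[Argument], defeat: DefeatRelation) -> str:
    """Structured dump of an argument graph for inspection."""
    return json.dumps(
        {
            "arguments": [a.to_dict() for a in arguments],
            "defeats": sorted(list(e) for e in defeat.edges),
        },
        indent=2,
    )
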