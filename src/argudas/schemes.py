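"""Argumentation schemes: expert if-then patterns with ordinal confidence.

A scheme captures one piece of curatorial expertise about when to trust or
doubt an expression annotation — e.g. "if several annotations agree, the
finding is more likely correct" — as a defeasible if-then rule. Each scheme
carries an expert confidence score on the five-point ordinal scale

    0 (reject)  <  ? (borderline)  <  1 (weak)  <  2 (moderate)  <  3 (good)

ranked 0..4. Schemes scored 0 are loaded but never compiled into engine
rules; borderline schemes compile with the lowest usable preference.

Two experts scoring the same scheme list rarely coincide exactly, so the
module also implements score reconciliation: per scheme the two scores are
classified as *exact*, *adjacent* (differing by one rank — if one expert says
2, either 1 or 3 counts as similar) or *disagree*, and the combined score
defaults to the conservative minimum of the two ranks.

Scheme conditions reference a closed catalogue of predicates over annotation
facts; scheme files are data, not code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml

#: Printed score tokens in scale order; index == rank.
SCORE_TOKENS: tuple[str, ...] = ("0", "?", "1", "2", "3")
SCORE_LABELS: tuple[str, ...] = ("rejected", "borderline", "weak", "moderate", "good")

AgreementClass = Literal["exact", "adjacent", "disagree"]


class SchemeError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ConfidenceScore:
    """One point on the ordinal expert-confidence scale, rank 0..4."""

    rank: int

    def __post_init__(self) -> None:
        if self.rank not in range(5):
            raise SchemeError(f"confidence rank must be 0..4, got {self.rank}")

    @classmethod
    def from_token(cls, token: str) -> "ConfidenceScore":
        token = str(token).strip()
        if token not in SCORE_TOKENS:
            raise SchemeError(
                f"unknown confidence token {token!r}; expected one of "
                f"{list(SCORE_TOKENS)}"
            )
        return cls(SCORE_TOKENS.index(token))

    @property
    def token(self) -> str:
        return SCORE_TOKENS[self.rank]

    @property
    def label(self) -> str:
        return SCORE_LABELS[self.rank]

    @property
    def rejected(self) -> bool:
        return self.rank == 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}({self.token})"


#: Closed catalogue of condition predicates usable in scheme files, with
#: arity. Variables in scheme conditions are ``?name`` tokens.
PREDICATE_CATALOGUE: dict[str, int] = {
    "asserts": 4,              # (ann, gene, structure, stage)
    "asserts_expressed": 4,    # (ann, gene, structure, stage)
    "asserts_not_detected": 4,  # (ann, gene, structure, stage)
    "asserts_level": 5,        # (ann, gene, structure, stage, level)
    "origin_is_direct": 1,
    "origin_is_propagated": 1,
    "probe_info_absent": 1,
    "probe_info_present": 1,
    "from_resource": 2,        # (ann, resource)
    "agreement_pair": 2,       # (ann, other) — symmetric, both orders asserted
    "conflict_pair": 2,
    "conflicting_annotation_exists": 1,
    "multiple_agreeing_annotations": 1,
    "cross_resource_corroboration": 2,
}

#: Conclusion targets a scheme may support or attack, with arity.
CONCLUSION_TARGETS: dict[str, int] = {
    "expressed": 3,  # (gene, structure, stage)
    "level": 4,      # (gene, structure, stage, level)
    "trust": 1,      # (annotation_id)
}


@dataclass(frozen=True)
class Condition:
    predicate: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(str(a) for a in self.args))
        arity = PREDICATE_CATALOGUE.get(self.predicate)
        if arity is None:
            raise SchemeError(f"unknown condition predicate {self.predicate!r}")
        if len(self.args) != arity:
            raise SchemeError(
                f"predicate {self.predicate} takes {arity} argument(s), "
                f"got {len(self.args)}"
            )

    def variables(self) -> set[str]:
        return {a for a in self.args if a.startswith("?")}


@dataclass(frozen=True)
class Conclusion:
    polarity: Literal["supports", "attacks"]
    target: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(str(a) for a in self.args))
        if self.polarity not in ("supports", "attacks"):
            raise SchemeError(f"polarity must be supports/attacks, got {self.polarity!r}")
        arity = CONCLUSION_TARGETS.get(self.target)
        if arity is None:
            raise SchemeError(f"unknown conclusion target {self.target!r}")
        if len(self.args) != arity:
            raise SchemeError(
                f"conclusion {self.target} takes {arity} argument(s), "
                f"got {len(self.args)}"
            )

    def variables(self) -> set[str]:
        return {a for a in self.args if a.startswith("?")}


@dataclass(frozen=True)
class Scheme:
    scheme_id: str
    text: str
    conditions: tuple[Condition, ...]
    conclusion: Conclusion
    score: ConfidenceScore
    #: optional raw per-expert scores, when the file carries both vectors
    expert_scores: Optional[tuple[ConfidenceScore, ConfidenceScore]] = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise SchemeError(f"scheme {self.scheme_id}: conditions must be non-empty")
        bound = set().union(*(c.variables() for c in self.conditions))
        free = self.conclusion.variables() - bound
        if free:
            raise SchemeError(
                f"scheme {self.scheme_id}: conclusion variables {sorted(free)} "
                "not bound by any condition"
            )

    @property
    def compilable(self) -> bool:
        """Rejected (score 0) schemes are excluded from rule compilation."""
        return not self.score.rejected


def _parse_scheme(obj: dict, where: str) -> Scheme:
    try:
        conditions = tuple(
            Condition(c["predicate"], tuple(c.get("args", ()))) for c in obj["conditions"]
        )
        conclusion = Conclusion(
            obj["conclusion"]["polarity"],
            obj["conclusion"]["target"],
            tuple(obj["conclusion"].get("args", ())),
        )
        expert = None
        if "score_a" in obj or "score_b" in obj:
            if not ("score_a" in obj and "score_b" in obj):
                raise SchemeError("score_a and score_b must be given together")
            expert = (
                ConfidenceScore.from_token(obj["score_a"]),
                ConfidenceScore.from_token(obj["score_b"]),
            )
        return Scheme(
            scheme_id=str(obj["id"]),
            text=str(obj.get("text", "")),
            conditions=conditions,
            conclusion=conclusion,
            score=ConfidenceScore.from_token(obj["score"]),
            expert_scores=expert,
        )
    except KeyError as exc:
        raise SchemeError(f"{where}: missing field {exc.args[0]!r}") from None
    except SchemeError as exc:
        raise SchemeError(f"{where}: {exc}") from None


def load_schemes(path: str) -> list[Scheme]:
    """Load schemes from a JSON or YAML file (a list of scheme objects).

    Duplicate ids are rejected; rejected-score schemes load but are flagged
    non-compilable.
    """
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if isinstance(data, dict) and "schemes" in data:
        data = data["schemes"]
    if not isinstance(data, list):
        raise SchemeError(f"{path}: expected a list of scheme objects")
    out: list[Scheme] = []
    seen: set[str] = set()
    for i, obj in enumerate(data):
        scheme = _parse_scheme(obj, f"{path}, scheme {i + 1}")
        if scheme.scheme_id in seen:
            raise SchemeError(f"{path}: duplicate scheme id {scheme.scheme_id!r}")
        seen.add(scheme.scheme_id)
        out.append(scheme)
    return out


def classify_agreement(a: ConfidenceScore, b: ConfidenceScore) -> AgreementClass:
    """Exact iff equal ranks; adjacent iff ranks differ by one; else disagree.

    Adjacency is taken on the scale exactly as printed, so borderline (?) is
    adjacent to both rejected (0) and weak (1).
    """
    d = abs(a.rank - b.rank)
    if d == 0:
        return "exact"
    if d == 1:
        return "adjacent"
    return "disagree"


@dataclass(frozen=True)
class AgreementStats:
    """Between-expert agreement over a scored scheme list."""

    n_schemes: int
    n_exact: int
    n_adjacent: int
    n_disagree: int
    pct_broad_agreement: int
    pct_disagree: int

    def __post_init__(self) -> None:
        if self.n_exact + self.n_adjacent + self.n_disagree != self.n_schemes:
            raise SchemeError("agreement categories must partition the schemes")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


CombinePolicy = Literal["min", "max", "midpoint"]


def reconcile(
    scores_a: Sequence[ConfidenceScore],
    scores_b: Sequence[ConfidenceScore],
    policy: CombinePolicy = "min",
) -> tuple[AgreementStats, list[ConfidenceScore]]:
    """Reconcile two experts' score vectors over the same scheme list.

    Returns per-category agreement statistics (percentages rounded half-up to
    integers) and a combined score per scheme. The default combination is the
    conservative minimum rank — where the experts never resolved their
    disagreement the weaker opinion prevails; ``max`` and ``midpoint``
    (rounded down to a rank) are available as alternatives.
    """
    if len(scores_a) != len(scores_b):
        raise SchemeError(
            f"score vectors differ in length: {len(scores_a)} vs {len(scores_b)}"
        )
    n_exact = n_adjacent = n_disagree = 0
    combined: list[ConfidenceScore] = []
    for a, b in zip(scores_a, scores_b):
        cls = classify_agreement(a, b)
        if cls == "exact":
            n_exact += 1
        elif cls == "adjacent":
            n_adjacent += 1
        else:
            n_disagree += 1
        if policy == "min":
            rank = min(a.rank, b.rank)
        elif policy == "max":
            rank = max(a.rank, b.rank)
        elif policy == "midpoint":
            rank = (a.rank + b.rank) // 2
        else:
            raise SchemeError(f"unknown combine policy {policy!r}")
        combined.append(ConfidenceScore(rank))
    n = len(combined)
    stats = AgreementStats(
        n_schemes=n,
        n_exact=n_exact,
        n_adjacent=n_adjacent,
        n_disagree=n_disagree,
        pct_broad_agreement=_round_half_up(100 * (n_exact + n_adjacent) / n) if n else 0,
        pct_disagree=_round_half_up(100 * n_disagree / n) if n else 0,
    )
    return stats, combined
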