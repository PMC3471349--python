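"""Canonical expression-level vocabulary across EMAGE, GXD, GENSAT and ABA.

The four resources describe in-situ expression strength in incompatible ways:
EMAGE and GXD with near-identical natural-language terms (EMAGE says *not
detected* where GXD says *absent*), GENSAT with its own phrases including the
compound "moderate to strong signal", and the Allen Brain Atlas (ABA) with raw
floating-point measurements that only become categorical through
structure-specific cut-off tables.

Everything is normalised onto one canonical scale::

    not_detected  <  weak  <  moderate  <  strong

A :class:`LevelAssertion` holds a *set* of possible levels rather than a single
one, so "moderate to strong signal" is ``{moderate, strong}`` and an
unqualified "detected"/"present" is the full positive set — the finding asserts
expression without committing to a strength. Set semantics lets downstream
agreement logic treat "detected" as compatible with any positive level.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import AnatomyOntology

NOT_DETECTED = "not_detected"
WEAK = "weak"
MODERATE = "moderate"
STRONG = "strong"

#: Positive levels in increasing order of strength.
POSITIVE_LEVELS: tuple[str, ...] = (WEAK, MODERATE, STRONG)
#: Full canonical scale, weakest first.
CANONICAL_LEVELS: tuple[str, ...] = (NOT_DETECTED,) + POSITIVE_LEVELS

_LEVEL_RANK = {lvl: i for i, lvl in enumerate(CANONICAL_LEVELS)}


class VocabularyError(ValueError):
    """Base class for level/structure mapping failures."""


class UnknownLevelTermError(VocabularyError):
    """A raw term is not in the stated resource's published vocabulary."""


class NoApplicableCutoffsError(VocabularyError):
    """Neither the structure nor any ancestor has an ABA cut-off row."""


@dataclass(frozen=True)
class LevelAssertion:
    """A claim about expression strength as a set of possible canonical levels.

    Parameters
    ----------
    levels
        Non-empty subset of the canonical scale. ``not_detected`` is mutually
        exclusive with any positive level: absence and expression cannot be
        asserted at once.
    no_data
        True for records like GENSAT's "not done" that carry no finding at
        all; such assertions are excluded from all downstream reasoning and
        ``levels`` is ignored.
    """

    levels: frozenset[str] = frozenset()
    no_data: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", frozenset(self.levels))
        if self.no_data:
            return
        if not self.levels:
            raise VocabularyError("a level assertion needs at least one level")
        unknown = self.levels - set(CANONICAL_LEVELS)
        if unknown:
            raise VocabularyError(f"unknown canonical levels: {sorted(unknown)}")
        if NOT_DETECTED in self.levels and len(self.levels) > 1:
            raise VocabularyError(
                "not_detected is mutually exclusive with positive levels"
            )

    @classmethod
    def single(cls, level: str) -> "LevelAssertion":
        return cls(frozenset([level]))

    @classmethod
    def detected(cls) -> "LevelAssertion":
        """The unqualified positive finding: any strength, but expressed."""
        return cls(frozenset(POSITIVE_LEVELS))

    @classmethod
    def missing(cls) -> "LevelAssertion":
        return cls(no_data=True)

    @property
    def is_positive(self) -> bool:
        return not self.no_data and NOT_DETECTED not in self.levels

    @property
    def is_not_detected(self) -> bool:
        return not self.no_data and self.levels == frozenset([NOT_DETECTED])

    def intersects(self, other: "LevelAssertion") -> bool:
        return bool(self.levels & other.levels)

    def supports(self, level: str) -> bool:
        """Whether this assertion is compatible with the given canonical level."""
        return not self.no_data and level in self.levels

    def sorted_levels(self) -> list[str]:
        return sorted(self.levels, key=_LEVEL_RANK.__getitem__)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.no_data:
            return "no_data"
        return "|".join(self.sorted_levels())


_ND = LevelAssertion.single(NOT_DETECTED)

#: Published level vocabularies, fixed. GXD mirrors EMAGE apart from the
#: documented absent/present substitutions.
RESOURCE_VOCABULARY: Mapping[str, Mapping[str, LevelAssertion]] = {
    "EMAGE": {
        "not detected": _ND,
        "detected": LevelAssertion.detected(),
        "weak": LevelAssertion.single(WEAK),
        "moderate": LevelAssertion.single(MODERATE),
        "strong": LevelAssertion.single(STRONG),
    },
    "GXD": {
        "absent": _ND,
        "present": LevelAssertion.detected(),
        "weak": LevelAssertion.single(WEAK),
        "moderate": LevelAssertion.single(MODERATE),
        "strong": LevelAssertion.single(STRONG),
    },
    "GENSAT": {
        "not done": LevelAssertion.missing(),
        "undetectable": _ND,
        "weak signal": LevelAssertion.single(WEAK),
        "moderate to strong signal": LevelAssertion(
            frozenset([MODERATE, STRONG])
        ),
    },
}


def canonicalize_level(resource: str, raw_term: str) -> LevelAssertion:
    """Map a resource's raw level term onto the canonical scale.

    The mapping is total over the published vocabularies and idempotent under
    case-folding/trimming of the raw term.
    """
    table = RESOURCE_VOCABULARY.get(resource)
    if table is None:
        raise UnknownLevelTermError(
            f"no level vocabulary for resource {resource!r} "
            f"(expected one of {sorted(RESOURCE_VOCABULARY)})"
        )
    key = raw_term.strip().casefold()
    try:
        return table[key]
    except KeyError:
        raise UnknownLevelTermError(
            f"unknown level term {raw_term!r} for resource {resource}"
        ) from None


@dataclass(frozen=True)
class AbaCutoffTable:
    """Per-structure ABA cut-offs splitting raw values into canonical levels.

    Each row maps a structure to ascending thresholds
    ``weak_min < moderate_min < strong_min``. Structures without a row inherit
    the row of their nearest part-of ancestor (the cut-offs are propagated
    down the brain hierarchy just like the expression findings are propagated
    up).
    """

    rows: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", dict(self.rows))
        for sid, (w, m, s) in self.rows.items():
            if not (w < m < s):
                raise VocabularyError(
                    f"cutoffs for {sid} must be strictly ascending, got {(w, m, s)}"
                )

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self.rows


def load_cutoffs(path: str) -> AbaCutoffTable:
    """Read a cut-off TSV with columns structure_id, weak_min, moderate_min, strong_min."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["structure_id", "weak_min", "moderate_min", "strong_min"],
        dtype={"structure_id": str},
    )
    rows = {
        r.structure_id: (float(r.weak_min), float(r.moderate_min), float(r.strong_min))
        for r in df.itertuples()
    }
    return AbaCutoffTable(rows)


def map_aba_value(
    raw_level: float,
    structure_id: str,
    cutoffs: AbaCutoffTable,
    ont: "AnatomyOntology",
) -> LevelAssertion:
    """Categorise a raw ABA expression value using inherited cut-offs.

    Uses the cut-off row of ``structure_id`` itself if present, otherwise the
    row of the nearest ancestor possessing one (breadth-first over part-of
    parents, ties broken by identifier sort). Intervals are lower-inclusive,
    upper-exclusive.
    """
    if raw_level < 0:
        raise VocabularyError(f"raw ABA level must be >= 0, got {raw_level}")
    row = None
    if structure_id in cutoffs:
        row = cutoffs.rows[structure_id]
    else:
        for anc in ont.ancestors(structure_id):
            if anc in cutoffs:
                row = cutoffs.rows[anc]
                break
    if row is None:
        raise NoApplicableCutoffsError(
            f"no applicable cutoffs for {structure_id} or any of its ancestors"
        )
    weak_min, moderate_min, strong_min = row
    if raw_level < weak_min:
        return _ND
    if raw_level < moderate_min:
        return LevelAssertion.single(WEAK)
    if raw_level < strong_min:
        return LevelAssertion.single(MODERATE)
    return LevelAssertion.single(STRONG)


@dataclass(frozen=True)
class AnatomyAlignment:
    """Cross-anatomy alignment: (resource, foreign structure) -> EMAP ids.

    GENSAT and ABA use their own, finer-grained brain anatomies; mapping onto
    EMAP commonly loses precision. Each target carries a declared
    precision-loss flag from the alignment table.
    """

    rows: Mapping[tuple[str, str], tuple[tuple[str, bool], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", dict(self.rows))


def load_alignment(path: str) -> AnatomyAlignment:
    """Read an alignment TSV: resource, foreign_id, emap_id, precision_loss_flag."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["resource", "foreign_id", "emap_id", "precision_loss"],
        dtype={"resource": str, "foreign_id": str, "emap_id": str},
    )
    rows: dict[tuple[str, str], list[tuple[str, bool]]] = {}
    for r in df.itertuples():
        rows.setdefault((r.resource, r.foreign_id), []).append(
            (r.emap_id, bool(int(r.precision_loss)))
        )
    return AnatomyAlignment({k: tuple(v) for k, v in rows.items()})


def map_structure(
    resource: str, foreign_id: str, alignment: AnatomyAlignment
) -> tuple[set[str], bool]:
    """Map a foreign structure id onto EMAP.

    Returns the mapped EMAP id set and a precision-loss flag. The flag is true
    when any alignment row is declared many-to-one or the id maps to more than
    one target. Unmapped ids yield the empty set without precision loss —
    being unmapped is a valid outcome, not an error.
    """
    targets = alignment.rows.get((resource, foreign_id), ())
    ids = {emap_id for emap_id, _ in targets}
    loss = any(flag for _, flag in targets) or len(ids) > 1
    return ids, bool(loss and ids)
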