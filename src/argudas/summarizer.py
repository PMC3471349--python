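"""Key-attribute evidence tables: ticks, crosses, and unavailable dashes.

Instead of issuing a verdict on whether a gene is expressed, the summariser
lays out the evidence and lets the biologist argue for themselves. Two tables
are produced for a (gene, structure, stage) query:

* a *level* table with one row per expression level that has at least one
  supporting annotation, scored on three attributes — is the level
  corroborated by multiple annotations, is it unopposed by conflicting
  findings, and does it have direct (non-propagated) support;
* an *annotation* table with one row per record, scored on the key attributes
  the most important schemes encode: probe information, direct vs propagated
  origin, cross-resource corroboration, agreement with other annotations, and
  curator confidence.

Each cell is positive (a reason to trust), negative (a reason to doubt) or
unavailable (the datum is missing), and carries the annotation ids that
justify it — the machine-readable counterpart of a mouse-over. No overall
expressed/not-expressed conclusion is ever emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .annotations import (
    AGREE,
    AgreementMode,
    Annotation,
    CONFLICT,
    agreement,
)
from .vocabulary import CANONICAL_LEVELS, LevelAssertion

Verdict = Literal["positive", "negative", "unavailable"]

#: Default curator-confidence ordinal range and midpoint threshold.
CURATOR_CONFIDENCE_RANGE = (1, 5)
DEFAULT_CURATOR_THRESHOLD = 3

#: Fixed per-annotation attribute catalogue (table columns, in order).
ANNOTATION_ATTRIBUTES = (
    "probe_info_present",
    "direct_annotation",
    "cross_resource_corroboration",
    "multiple_annotations_agree",
    "curator_confidence",
)

#: Fixed per-level attribute catalogue.
LEVEL_ATTRIBUTES = ("corroboration", "unopposed", "direct_support")


class SummariserError(ValueError):
    pass


@dataclass(frozen=True)
class AttributeIndicator:
    attribute: str
    verdict: Verdict
    evidence: tuple[str, ...] = ()
    detail: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", tuple(self.evidence))
        if self.verdict == "unavailable" and self.evidence:
            raise SummariserError(
                f"{self.attribute}: unavailable indicators carry no evidence"
            )


@dataclass(frozen=True)
class LevelSummaryRow:
    level: str
    indicators: tuple[AttributeIndicator, ...]

    def __post_init__(self) -> None:
        if len(self.indicators) != len(LEVEL_ATTRIBUTES):
            raise SummariserError(
                f"level row needs exactly {len(LEVEL_ATTRIBUTES)} indicators"
            )


@dataclass(frozen=True)
class AnnotationSummaryRow:
    annotation_id: str
    level: LevelAssertion
    indicators: tuple[AttributeIndicator, ...]


def _require_single_key(annotations: Sequence[Annotation]) -> None:
    keys = {a.key() for a in annotations}
    if len(keys) > 1:
        raise SummariserError(
            "summaries cover one (gene, structure, stage) at a time; "
            f"got {len(keys)} distinct keys — query first"
        )


def summarize_levels(
    annotations: Sequence[Annotation], mode: AgreementMode = "presence"
) -> list[LevelSummaryRow]:
    """One row per expression level with at least one supporting annotation.

    The three attributes per level: *corroboration* is positive when two or
    more annotations support the level and negative when exactly one does;
    *unopposed* is positive when no annotation conflicts with the level under
    the chosen granularity; *direct_support* is positive when at least one
    direct (non-propagated) record supports the level. An empty input yields
    an empty table.
    """
    _require_single_key(annotations)
    rows = []
    for level in CANONICAL_LEVELS:
        supporters = [a for a in annotations if a.level.supports(level)]
        if not supporters:
            continue
        sup_ids = tuple(sorted(a.annotation_id for a in supporters))
        # a hypothetical single-level claim at the shared key, for conflicts
        probe = Annotation(
            annotation_id="__level_probe__",
            resource=supporters[0].resource,
            gene=supporters[0].gene,
            structure_id=supporters[0].structure_id,
            stage=supporters[0].stage,
            level=LevelAssertion.single(level),
        )
        opponents = tuple(
            sorted(
                a.annotation_id
                for a in annotations
                if agreement(a, probe, mode) == CONFLICT
            )
        )
        direct = tuple(
            sorted(a.annotation_id for a in supporters if a.origin == "direct")
        )
        corroborated = len(supporters) >= 2
        indicators = (
            AttributeIndicator(
                "corroboration",
                "positive" if corroborated else "negative",
                sup_ids,
                "multiple annotations agree on this level"
                if corroborated
                else "a single annotation supports this level",
            ),
            AttributeIndicator(
                "unopposed",
                "negative" if opponents else "positive",
                opponents if opponents else sup_ids,
                f"conflicting annotations: {', '.join(opponents)}"
                if opponents
                else "no annotation conflicts with this level",
            ),
            AttributeIndicator(
                "direct_support",
                "positive" if direct else "negative",
                direct if direct else sup_ids,
                "direct annotations support this level"
                if direct
                else "only propagated annotations support this level",
            ),
        )
        rows.append(LevelSummaryRow(level, indicators))
    return rows


def summarize_annotations(
    annotations: Sequence[Annotation],
    mode: AgreementMode = "presence",
    curator_threshold: int = DEFAULT_CURATOR_THRESHOLD,
) -> list[AnnotationSummaryRow]:
    """One row per annotation, one column per key attribute.

    Columns: probe information recorded (yes -> tick, no -> cross, unknown ->
    dash); direct vs propagated origin; cross-resource corroboration (an
    agreeing record from a different resource; dash when only one resource is
    present at all); multiple annotations agree (any agreeing record); curator
    confidence against an ordinal threshold (dash when the resource supplied
    none).
    """
    _require_single_key(annotations)
    resources = {a.resource for a in annotations}
    rows = []
    for a in sorted(annotations, key=lambda x: (x.resource, x.annotation_id)):
        agreeing = sorted(
            b.annotation_id
            for b in annotations
            if b.annotation_id != a.annotation_id and agreement(a, b, mode) == AGREE
        )
        cross = sorted(
            b.annotation_id
            for b in annotations
            if b.annotation_id != a.annotation_id
            and b.resource != a.resource
            and agreement(a, b, mode) == AGREE
        )
        own = (a.annotation_id,)

        if a.probe_info_present == "unknown":
            probe = AttributeIndicator(
                "probe_info_present", "unavailable", (), "probe information not recorded"
            )
        else:
            probe = AttributeIndicator(
                "probe_info_present",
                "positive" if a.probe_info_present == "yes" else "negative",
                own,
                "probe information is published"
                if a.probe_info_present == "yes"
                else "probe information is absent",
            )

        direct = AttributeIndicator(
            "direct_annotation",
            "positive" if a.origin == "direct" else "negative",
            own if a.origin == "direct" else (a.source_annotation_id,),
            "curated directly on this structure"
            if a.origin == "direct"
            else f"propagated from {a.source_annotation_id}",
        )

        if len(resources) <= 1:
            xres = AttributeIndicator(
                "cross_resource_corroboration",
                "unavailable",
                (),
                "only one resource reports on this query",
            )
        else:
            xres = AttributeIndicator(
                "cross_resource_corroboration",
                "positive" if cross else "negative",
                tuple(cross) if cross else own,
                f"agreeing records from other resources: {', '.join(cross)}"
                if cross
                else "no other resource agrees with this record",
            )

        multi = AttributeIndicator(
            "multiple_annotations_agree",
            "positive" if agreeing else "negative",
            tuple(agreeing) if agreeing else own,
            f"agreeing records: {', '.join(agreeing)}"
            if agreeing
            else "no other annotation agrees with this record",
        )

        if a.curator_confidence is None:
            curator = AttributeIndicator(
                "curator_confidence", "unavailable", (), "no curator confidence given"
            )
        else:
            good = a.curator_confidence >= curator_threshold
            curator = AttributeIndicator(
                "curator_confidence",
                "positive" if good else "negative",
                own,
                f"curator confidence {a.curator_confidence} "
                f"{'meets' if good else 'is below'} threshold {curator_threshold}",
            )

        rows.append(
            AnnotationSummaryRow(
                a.annotation_id, a.level, (probe, direct, xres, multi, curator)
            )
        )
    return rows


# --------------------------------------------------------------------------
# rendering

_ASCII = {"positive": "+", "negative": "x", "unavailable": "-"}
_UNICODE = {"positive": "✓", "negative": "✗", "unavailable": "–"}


def _sym(verdict: Verdict, unicode: bool) -> str:
    return (_UNICODE if unicode else _ASCII)[verdict]


def _fixed_width(header: list[str], body: list[list[str]]) -> str:
    widths = [
        max(len(header[i]), *(len(r[i]) for r in body)) if body else len(header[i])
        for i in range(len(header))
    ]
    def fmt(row: list[str]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
    lines = [fmt(header), fmt(["-" * w for w in widths])]
    lines += [fmt(r) for r in body]
    return "\n".join(lines)


def render_level_table(
    rows: Sequence[LevelSummaryRow], fmt: str = "text", unicode: bool = False
) -> str:
    """Render the per-level table as text, TSV, or JSON (evidence inline)."""
    header = ["level", *LEVEL_ATTRIBUTES]
    if fmt == "json":
        return json.dumps(
            [
                {
                    "level": r.level,
                    "indicators": [
                        {
                            "attribute": i.attribute,
                            "verdict": i.verdict,
                            "evidence": list(i.evidence),
                            "detail": i.detail,
                        }
                        for i in r.indicators
                    ],
                }
                for r in rows
            ],
            indent=2,
        )
    if fmt == "tsv":
        lines = ["\t".join(header)]
        for r in rows:
            lines.append(
                "\t".join(
                    [r.level]
                    + [
                        f"{i.verdict}:{'|'.join(i.evidence)}" for i in r.indicators
                    ]
                )
            )
        return "\n".join(lines)
    body = [
        [r.level, *(_sym(i.verdict, unicode) for i in r.indicators)] for r in rows
    ]
    return _fixed_width(header, body)


def render_annotation_table(
    rows: Sequence[AnnotationSummaryRow], fmt: str = "text", unicode: bool = False
) -> str:
    """Render the per-annotation table as text, TSV, or JSON."""
    header = ["annotation", "level", *ANNOTATION_ATTRIBUTES]
    if fmt == "json":
        return json.dumps(
            [
                {
                    "annotation_id": r.annotation_id,
                    "level": str(r.level),
                    "indicators": [
                        {
                            "attribute": i.attribute,
                            "verdict": i.verdict,
                            "evidence": list(i.evidence),
                            "detail": i.detail,
                        }
                        for i in r.indicators
                    ],
                }
                for r in rows
            ],
            indent=2,
        )
    if fmt == "tsv":
        lines = ["\t".join(header)]
        for r in rows:
            lines.append(
                "\t".join(
                    [r.annotation_id, str(r.level)]
                    + [
                        f"{i.verdict}:{'|'.join(i.evidence)}" for i in r.indicators
                    ]
                )
            )
        return "\n".join(lines)
    body = [
        [r.annotation_id, str(r.level), *(_sym(i.verdict, unicode) for i in r.indicators)]
        for r in rows
    ]
    return _fixed_width(header, body)


def render_annotation_listing(
    annotations: Sequence[Annotation], fmt: str = "text"
) -> str:
    """The first-tier table: what each relevant annotation shows, one per row."""
    header = [
        "annotation", "resource", "gene", "structure", "stage",
        "level", "origin", "url",
    ]
    rows = [
        [
            a.annotation_id, a.resource, a.gene, a.structure_id, str(a.stage),
            str(a.level), a.origin, a.source_url or "-",
        ]
        for a in sorted(annotations, key=lambda x: (x.resource, x.annotation_id))
    ]
    if fmt == "json":
        return json.dumps([dict(zip(header, r)) for r in rows], indent=2)
    if fmt == "tsv":
        return "\n".join(["\t".join(header)] + ["\t".join(r) for r in rows])
    return _fixed_width(header, rows)
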