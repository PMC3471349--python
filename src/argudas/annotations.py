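"""Annotation records: loading, querying, and the agreement relation.

An annotation is one resource's curated record of an in-situ experiment: gene,
anatomical structure, Theiler stage, an expression-level claim, and quality
metadata (probe information, curator confidence, provenance URL). Records are
either *direct* (curated as such) or *propagated* (derived by lifting a
positive finding up the part-of hierarchy).

Whether two annotations agree depends on the question being asked. If the
biologist only wants to know whether the gene is expressed at all, a strong
and a weak finding agree; if the question is the level of expression, they
conflict. Both granularities are exposed as the ``presence`` and ``level``
modes of :func:`agreement`. Annotations for different (gene, structure, stage)
keys are *independent* — they are never compared.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, TYPE_CHECKING

from .vocabulary import (
    AbaCutoffTable,
    AnatomyAlignment,
    LevelAssertion,
    canonicalize_level,
    map_aba_value,
    map_structure,
)
from .ontology import MIN_STAGE, MAX_STAGE

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import AnatomyOntology

logger = logging.getLogger("argudas")

RESOURCES = ("EMAGE", "GXD", "GENSAT", "ABA")

AgreementRelation = Literal["agree", "conflict", "independent"]
AGREE: AgreementRelation = "agree"
CONFLICT: AgreementRelation = "conflict"
INDEPENDENT: AgreementRelation = "independent"

AgreementMode = Literal["presence", "level"]


class AnnotationError(ValueError):
    pass


class AnnotationLoadError(AnnotationError):
    """A row of an annotation file failed validation; names line and field."""


@dataclass(frozen=True)
class Annotation:
    annotation_id: str
    resource: str
    gene: str
    structure_id: str
    stage: int
    level: LevelAssertion
    origin: Literal["direct", "propagated"] = "direct"
    source_annotation_id: str = ""
    probe_info_present: Literal["yes", "no", "unknown"] = "unknown"
    curator_confidence: Optional[int] = None
    source_url: str = ""

    def __post_init__(self) -> None:
        if self.resource not in RESOURCES:
            raise AnnotationError(
                f"{self.annotation_id}: unknown resource {self.resource!r}"
            )
        if not MIN_STAGE <= self.stage <= MAX_STAGE:
            raise AnnotationError(
                f"{self.annotation_id}: stage {self.stage} outside Theiler range"
            )
        if self.level.no_data:
            raise AnnotationError(
                f"{self.annotation_id}: no-data level assertions are not "
                "admissible as annotations"
            )
        if self.origin == "propagated":
            if not self.source_annotation_id:
                raise AnnotationError(
                    f"{self.annotation_id}: propagated record lacks a source id"
                )
            if not self.level.is_positive:
                raise AnnotationError(
                    f"{self.annotation_id}: only positive findings propagate"
                )
        elif self.origin == "direct":
            if self.source_annotation_id:
                raise AnnotationError(
                    f"{self.annotation_id}: direct record carries a source id"
                )
        else:
            raise AnnotationError(
                f"{self.annotation_id}: origin must be direct or propagated"
            )
        if self.probe_info_present not in ("yes", "no", "unknown"):
            raise AnnotationError(
                f"{self.annotation_id}: probe_info must be yes/no/unknown"
            )

    def key(self) -> tuple[str, str, int]:
        """The comparison key: (case-folded gene, structure, stage)."""
        return (self.gene.casefold(), self.structure_id, self.stage)


_TSV_COLUMNS = [
    "annotation_id",
    "resource",
    "gene",
    "structure_id",
    "stage",
    "level_term_or_value",
    "origin",
    "source_annotation_id",
    "probe_info",
    "curator_confidence",
    "source_url",
]


def _build_annotation(
    row: dict,
    where: str,
    *,
    cutoffs: Optional[AbaCutoffTable],
    ont: Optional["AnatomyOntology"],
    alignment: Optional[AnatomyAlignment],
) -> list[Annotation]:
    """Validate one raw record; returns [] for no-data rows.

    May return several annotations when an alignment maps the foreign
    structure to more than one EMAP term.
    """

    def fail(fieldname: str, msg: str) -> AnnotationLoadError:
        return AnnotationLoadError(f"{where}, field {fieldname!r}: {msg}")

    for col in _TSV_COLUMNS:
        if col not in row or row[col] is None:
            raise fail(col, "missing value")
    resource = str(row["resource"]).strip()
    if resource not in RESOURCES:
        raise fail("resource", f"unknown resource {resource!r}")
    try:
        stage = int(row["stage"])
    except (TypeError, ValueError):
        raise fail("stage", f"{row['stage']!r} is not an integer") from None

    structure_ids: list[tuple[str, str]]  # (emap_id, id_suffix)
    structure_id = str(row["structure_id"]).strip()
    precision_loss = False
    if alignment is not None and (resource, structure_id) in alignment.rows:
        mapped, precision_loss = map_structure(resource, structure_id, alignment)
        if precision_loss:
            logger.warning(
                "%s: alignment of %s structure %s loses precision",
                where, resource, structure_id,
            )
        targets = sorted(mapped)
        structure_ids = [
            (t, "" if len(targets) == 1 else f"::{t}") for t in targets
        ]
        if not structure_ids:
            logger.warning(
                "%s: %s structure %s has no EMAP alignment; record kept as-is",
                where, resource, structure_id,
            )
            structure_ids = [(structure_id, "")]
    else:
        structure_ids = [(structure_id, "")]

    out = []
    for emap_id, suffix in structure_ids:
        raw = str(row["level_term_or_value"]).strip()
        if resource == "ABA":
            try:
                value = float(raw)
            except ValueError:
                raise fail(
                    "level_term_or_value",
                    f"ABA level {raw!r} is not a number",
                ) from None
            if cutoffs is None or ont is None:
                raise fail(
                    "level_term_or_value",
                    "ABA rows need a cutoff table and an ontology to be "
                    "categorised",
                )
            level = map_aba_value(value, emap_id, cutoffs, ont)
        else:
            try:
                level = canonicalize_level(resource, raw)
            except Exception as exc:
                raise fail("level_term_or_value", str(exc)) from None
        if level.no_data:
            return []

        conf_raw = str(row["curator_confidence"]).strip()
        conf = None
        if conf_raw not in ("", "-", "NA", "na", "None"):
            try:
                conf = int(conf_raw)
            except ValueError:
                raise fail(
                    "curator_confidence", f"{conf_raw!r} is not an integer"
                ) from None
        try:
            out.append(
                Annotation(
                    annotation_id=str(row["annotation_id"]).strip() + suffix,
                    resource=resource,
                    gene=str(row["gene"]).strip(),
                    structure_id=emap_id,
                    stage=stage,
                    level=level,
                    origin=str(row["origin"]).strip() or "direct",
                    source_annotation_id=str(row["source_annotation_id"]).strip(),
                    probe_info_present=str(row["probe_info"]).strip() or "unknown",
                    curator_confidence=conf,
                    source_url=str(row["source_url"]).strip(),
                )
            )
        except AnnotationError as exc:
            raise AnnotationLoadError(f"{where}: {exc}") from None
    return out


def load_annotations(
    path: str,
    *,
    cutoffs: Optional[AbaCutoffTable] = None,
    ont: Optional["AnatomyOntology"] = None,
    alignment: Optional[AnatomyAlignment] = None,
) -> list[Annotation]:
    """Load and validate annotations from TSV or JSON.

    Level terms are canonicalised on load (ABA numeric values through the
    cut-off table, which requires ``cutoffs`` and ``ont``); foreign structure
    ids are mapped through ``alignment`` when one is supplied. Rows whose
    level is "no data" (e.g. GENSAT "not done") are dropped with a logged
    count — they carry no finding to reason over.
    """
    rows: list[tuple[str, dict]] = []
    if str(path).endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise AnnotationLoadError(f"{path}: expected a JSON array of objects")
        rows = [(f"{path}, record {i + 1}", dict(obj)) for i, obj in enumerate(data)]
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            filtered = (ln for ln in fh if not ln.startswith("#"))
            reader = csv.DictReader(
                filtered, fieldnames=_TSV_COLUMNS, delimiter="\t"
            )
            for lineno, row in enumerate(reader, start=1):
                if row["annotation_id"] == "annotation_id":
                    continue  # optional header line
                if None in row.values() or None in row:
                    raise AnnotationLoadError(
                        f"{path}, line {lineno}: expected "
                        f"{len(_TSV_COLUMNS)} tab-separated fields"
                    )
                rows.append((f"{path}, line {lineno}", row))

    out: list[Annotation] = []
    n_dropped = 0
    seen_ids: set[str] = set()
    for where, row in rows:
        anns = _build_annotation(
            row, where, cutoffs=cutoffs, ont=ont, alignment=alignment
        )
        if not anns:
            n_dropped += 1
            continue
        for a in anns:
            if a.annotation_id in seen_ids:
                raise AnnotationLoadError(
                    f"{where}: duplicate annotation id {a.annotation_id!r}"
                )
            seen_ids.add(a.annotation_id)
            out.append(a)
    if n_dropped:
        logger.info(
            "dropped %d no-data annotation row(s) (e.g. GENSAT 'not done')",
            n_dropped,
        )
    return out


def query(
    store: Sequence[Annotation],
    gene: Optional[str] = None,
    structure_id: Optional[str] = None,
    stage: Optional[int] = None,
    include_propagated: bool = True,
) -> list[Annotation]:
    """Filter the store on any combination of gene, structure and stage.

    At least one of ``gene`` or ``structure_id`` must be given. Gene symbols
    compare case-insensitively but otherwise verbatim (no synonym resolution).
    Results come back in deterministic (resource, annotation_id) order; an
    empty result is valid — for some queries there are simply no annotations.
    """
    if gene is None and structure_id is None:
        raise AnnotationError("query needs at least a gene or a structure id")
    gene_cf = gene.casefold() if gene is not None else None
    hits = [
        a
        for a in store
        if (gene_cf is None or a.gene.casefold() == gene_cf)
        and (structure_id is None or a.structure_id == structure_id)
        and (stage is None or a.stage == stage)
        and (include_propagated or a.origin == "direct")
    ]
    return sorted(hits, key=lambda a: (a.resource, a.annotation_id))


def agreement(a: Annotation, b: Annotation, mode: AgreementMode) -> AgreementRelation:
    """Do two annotations agree, conflict, or concern different things?

    ``presence`` mode asks only expressed vs not expressed: two positive
    findings agree whatever their strengths, and absence conflicts with any
    positive finding (biologists treat absent and expressed as mutually
    exclusive). ``level`` mode compares the level sets themselves: agreement
    iff they intersect, conflict when both are positive but disjoint or when
    one side is not-detected. Annotations with different (gene, structure,
    stage) keys are independent.
    """
    if mode not in ("presence", "level"):
        raise ValueError(f"unknown agreement mode {mode!r}")
    if a.key() != b.key():
        return INDEPENDENT
    if mode == "presence":
        return AGREE if a.level.is_positive == b.level.is_positive else CONFLICT
    return AGREE if a.level.intersects(b.level) else CONFLICT
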