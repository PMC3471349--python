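"""Deterministic synthetic data bundles emulating the real resources.

The real inputs — EMAP-style staged anatomies, EMAGE/GXD/GENSAT/ABA
annotation tables, the 68 expert-scored schemes — are either live databases
or unpublished, so the package ships a generator that reproduces their
*statistical structure*: a staged part-of DAG; a focal (gene, structure,
stage) case with a configured number of pairwise-agreeing positive records
and conflicting not-detected records; a configurable share of propagated
records and records with missing probe information; a resource mix across the
four databases including numeric ABA values routed through a cut-off table
and an anatomy alignment; and two expert score vectors over the scheme list
that realise an exact/adjacent/disagree split precisely.

Every byte of the bundle is a pure function of the spec (seed included):
rerunning the generator reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .annotations import Annotation
from .ontology import AnatomyNode, AnatomyOntology
from .schemes import ConfidenceScore, classify_agreement
from .vocabulary import (
    MODERATE,
    NOT_DETECTED,
    POSITIVE_LEVELS,
    STRONG,
    WEAK,
    LevelAssertion,
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    Defaults encode the study conditions the package targets: Theiler stage
    15 (the bmp4/future-brain stage), two agreeing positive records plus one
    conflicting not-detected record at the focal key, and the 68-scheme
    16/33/19 exact/adjacent/disagree expert split.
    """

    seed: int = 0
    ontology_shape: tuple[int, int, int] = (30, 2, 15)  # (n_nodes, max_parents, stage)
    n_genes: int = 5
    n_agreeing: int = 2
    n_conflicting: int = 1
    fraction_propagated: float = 0.25
    fraction_probe_missing: float = 0.3
    resource_mix: Mapping[str, float] = field(
        default_factory=lambda: {"EMAGE": 0.4, "GXD": 0.4, "GENSAT": 0.1, "ABA": 0.1}
    )
    scheme_counts: tuple[int, int, int, int] = (68, 16, 33, 19)  # (n, exact, adj, dis)

    def __post_init__(self) -> None:
        n, e, a, d = self.scheme_counts
        if e + a + d != n:
            raise FixtureError(
                f"scheme counts must partition: {e}+{a}+{d} != {n}"
            )
        for name in ("fraction_propagated", "fraction_probe_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FixtureError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.resource_mix.values()) - 1.0) > 1e-9:
            raise FixtureError("resource_mix must sum to 1")
        n_nodes, max_parents, stage = self.ontology_shape
        if n_nodes < 3:
            raise FixtureError("ontology needs at least 3 nodes")
        if not 1 <= stage <= 28:
            raise FixtureError(f"stage {stage} outside Theiler range")
        if self.n_agreeing < 0 or self.n_conflicting < 0:
            raise FixtureError("case counts must be non-negative")
        non_aba = sum(v for k, v in self.resource_mix.items() if k != "ABA")
        if self.fraction_propagated > 0 and self.n_agreeing > 0 and non_aba <= 0:
            raise FixtureError(
                "propagated records need a term-based resource (EMAGE/GXD/"
                "GENSAT) in the mix; an all-ABA mix cannot express them"
            )


#: Ids of the named focal structures present in every generated ontology.
ROOT_ID = "embryo"
FOCAL_ID = "future_brain"
CHILD_ID = "telencephalon"

_FOCAL_GENE = "bmp4"

# reverse vocabulary: canonical level set -> raw term, per resource
_REVERSE_TERM = {
    "EMAGE": {
        frozenset([NOT_DETECTED]): "not detected",
        frozenset(POSITIVE_LEVELS): "detected",
        frozenset([WEAK]): "weak",
        frozenset([MODERATE]): "moderate",
        frozenset([STRONG]): "strong",
    },
    "GXD": {
        frozenset([NOT_DETECTED]): "absent",
        frozenset(POSITIVE_LEVELS): "present",
        frozenset([WEAK]): "weak",
        frozenset([MODERATE]): "moderate",
        frozenset([STRONG]): "strong",
    },
    "GENSAT": {
        frozenset([NOT_DETECTED]): "undetectable",
        frozenset([WEAK]): "weak signal",
        frozenset([MODERATE, STRONG]): "moderate to strong signal",
    },
}

#: One brain-wide cut-off row, attached to the root so every structure
#: inherits it (no real ABA limits are published; these are synthetic).
_CUTOFF_ROW = (1.0, 2.0, 3.0)
_ABA_VALUE_FOR = {
    frozenset([NOT_DETECTED]): 0.5,
    frozenset([WEAK]): 1.5,
    frozenset([MODERATE]): 2.5,
    frozenset([STRONG]): 3.5,
}

_SCHEME_TEMPLATES: list[dict] = [
    {
        "text": "If an annotation asserts expression and multiple annotations "
                "agree with it, the gene is expressed there.",
        "conditions": [
            {"predicate": "asserts_expressed", "args": ["?a", "?g", "?s", "?t"]},
            {"predicate": "multiple_agreeing_annotations", "args": ["?a"]},
        ],
        "conclusion": {"polarity": "supports", "target": "expressed",
                       "args": ["?g", "?s", "?t"]},
    },
    {
        "text": "If an annotation reports the gene as not detected, the gene "
                "is not expressed there.",
        "conditions": [
            {"predicate": "asserts_not_detected", "args": ["?a", "?g", "?s", "?t"]},
        ],
        "conclusion": {"polarity": "attacks", "target": "expressed",
                       "args": ["?g", "?s", "?t"]},
    },
    {
        "text": "An annotation asserting expression is a reason to believe "
                "the gene is expressed there.",
        "conditions": [
            {"predicate": "asserts_expressed", "args": ["?a", "?g", "?s", "?t"]},
        ],
        "conclusion": {"polarity": "supports", "target": "expressed",
                       "args": ["?g", "?s", "?t"]},
    },
    {
        "text": "If the probe information for an experiment is absent, doubt "
                "the annotation.",
        "conditions": [
            {"predicate": "asserts", "args": ["?a", "?g", "?s", "?t"]},
            {"predicate": "probe_info_absent", "args": ["?a"]},
        ],
        "conclusion": {"polarity": "attacks", "target": "trust", "args": ["?a"]},
    },
    {
        "text": "An annotation asserting a specific level supports that level "
                "of expression.",
        "conditions": [
            {"predicate": "asserts_level", "args": ["?a", "?g", "?s", "?t", "?l"]},
        ],
        "conclusion": {"polarity": "supports", "target": "level",
                       "args": ["?g", "?s", "?t", "?l"]},
    },
    {
        "text": "A propagated annotation is weaker evidence; doubt it.",
        "conditions": [
            {"predicate": "asserts", "args": ["?a", "?g", "?s", "?t"]},
            {"predicate": "origin_is_propagated", "args": ["?a"]},
        ],
        "conclusion": {"polarity": "attacks", "target": "trust", "args": ["?a"]},
    },
    {
        "text": "Corroboration from a different resource is a reason to trust "
                "the annotation.",
        "conditions": [
            {"predicate": "asserts", "args": ["?a", "?g", "?s", "?t"]},
            {"predicate": "cross_resource_corroboration", "args": ["?a", "?b"]},
        ],
        "conclusion": {"polarity": "supports", "target": "trust", "args": ["?a"]},
    },
    {
        "text": "If a conflicting annotation exists for a level claim, doubt "
                "that level.",
        "conditions": [
            {"predicate": "asserts_level", "args": ["?a", "?g", "?s", "?t", "?l"]},
            {"predicate": "conflicting_annotation_exists", "args": ["?a"]},
        ],
        "conclusion": {"polarity": "attacks", "target": "level",
                       "args": ["?g", "?s", "?t", "?l"]},
    },
]


def generate_score_vectors(
    counts: tuple[int, int, int, int], rng: random.Random
) -> tuple[list[ConfidenceScore], list[ConfidenceScore]]:
    """Two expert score vectors realising exact/adjacent/disagree counts.

    The per-scheme category sequence is shuffled so categories are not
    position-correlated, then each pair is drawn to classify back into its
    category.
    """
    n, n_exact, n_adjacent, n_disagree = counts
    categories = (
        ["exact"] * n_exact + ["adjacent"] * n_adjacent + ["disagree"] * n_disagree
    )
    rng.shuffle(categories)
    a_scores: list[ConfidenceScore] = []
    b_scores: list[ConfidenceScore] = []
    for cat in categories:
        a = rng.randrange(5)
        if cat == "exact":
            b = a
        elif cat == "adjacent":
            options = [r for r in (a - 1, a + 1) if 0 <= r <= 4]
            b = rng.choice(options)
        else:
            options = [r for r in range(5) if abs(r - a) >= 2]
            b = rng.choice(options)
        a_scores.append(ConfidenceScore(a))
        b_scores.append(ConfidenceScore(b))
    # sanity: the realised classification must match the request exactly
    realised = [classify_agreement(x, y) for x, y in zip(a_scores, b_scores)]
    if [realised.count(c) for c in ("exact", "adjacent", "disagree")] != [
        n_exact, n_adjacent, n_disagree,
    ]:  # pragma: no cover - construction guarantees this
        raise FixtureError("generated score vectors failed to realise the counts")
    return a_scores, b_scores


def _generate_ontology_edges(spec: FixtureSpec, rng: random.Random) -> list[tuple[str, str]]:
    """A per-stage part-of DAG: named focal chain plus random extra nodes."""
    n_nodes, max_parents, _stage = spec.ontology_shape
    ids = [ROOT_ID, FOCAL_ID, CHILD_ID]
    edges = [(FOCAL_ID, ROOT_ID), (CHILD_ID, FOCAL_ID)]
    for i in range(n_nodes - len(ids)):
        nid = f"structure_{i:03d}"
        k = rng.randint(1, max(1, max_parents))
        parents = rng.sample(ids, min(k, len(ids)))
        ids.append(nid)
        edges.extend((nid, p) for p in sorted(parents))
    return edges


def _term_for(resource: str, levels: frozenset[str]) -> Optional[str]:
    if resource == "ABA":
        value = _ABA_VALUE_FOR.get(levels)
        return None if value is None else repr(value)
    return _REVERSE_TERM[resource].get(levels)


def _pick_resource(rng: random.Random, mix: Mapping[str, float]) -> str:
    roll = rng.random()
    acc = 0.0
    for res in ("EMAGE", "GXD", "GENSAT", "ABA"):
        acc += mix.get(res, 0.0)
        if roll < acc:
            return res
    return "EMAGE"


def _annotation_rows(spec: FixtureSpec, rng: random.Random) -> list[list[str]]:
    """Raw TSV rows (terms in each resource's own vocabulary)."""
    _, _, stage = spec.ontology_shape
    rows: list[list[str]] = []
    counter = 0

    def next_id(resource: str) -> str:
        nonlocal counter
        counter += 1
        return f"{resource}:{counter:04d}"

    def probe(resource: str) -> str:
        if resource == "ABA":
            return "unknown"  # ABA publishes no probe metadata
        return "no" if rng.random() < spec.fraction_probe_missing else "yes"

    def curator(rng: random.Random) -> str:
        if rng.random() < 0.4:
            return ""
        return str(rng.randint(*CURATOR_RANGE))

    def emit(resource, gene, structure, levels, origin="direct", source=""):
        term = _term_for(resource, levels)
        if term is None:
            raise FixtureError(
                f"{resource} cannot express canonical level set {sorted(levels)}"
            )
        aid = next_id(resource)
        # ABA rows reference a foreign id routed through the alignment table
        sid = f"aba:{structure}" if resource == "ABA" else structure
        rows.append(
            [
                aid, resource, gene, sid, str(stage), term, origin, source,
                probe(resource), curator(rng),
                f"https://example.org/{resource.lower()}/{aid.split(':')[1]}",
            ]
        )
        return aid

    # --- focal case: n_agreeing positives + n_conflicting not-detected ---
    n_prop = round(spec.fraction_propagated * spec.n_agreeing)
    for i in range(spec.n_agreeing):
        resource = _pick_resource(rng, spec.resource_mix)
        if i < n_prop:
            # propagated slots need a term-based vocabulary; ABA rows are
            # always direct (a raw number cannot be honestly re-derived)
            while resource == "ABA":
                resource = _pick_resource(rng, spec.resource_mix)
        level = frozenset([rng.choice(POSITIVE_LEVELS)])
        if _term_for(resource, level) is None:
            level = frozenset([WEAK])  # every resource can say "weak"
        if i < n_prop:
            # curated on the child structure, lifted into the focal one
            src = emit(resource, _FOCAL_GENE, CHILD_ID, level)
            aid = next_id(resource)
            rows.append(
                [
                    aid, resource, _FOCAL_GENE, FOCAL_ID, str(stage),
                    _term_for(resource, level), "propagated", src,
                    "unknown", "", "",
                ]
            )
        else:
            emit(resource, _FOCAL_GENE, FOCAL_ID, level)
    for _ in range(spec.n_conflicting):
        resource = _pick_resource(rng, spec.resource_mix)
        emit(resource, _FOCAL_GENE, FOCAL_ID, frozenset([NOT_DETECTED]))

    # --- background noise: other genes scattered over the ontology ---
    structures = [ROOT_ID, FOCAL_ID, CHILD_ID] + [
        f"structure_{i:03d}" for i in range(spec.ontology_shape[0] - 3)
    ]
    for g in range(spec.n_genes - 1):
        gene = f"gene_{g:02d}"
        for _ in range(rng.randint(1, 3)):
            resource = _pick_resource(rng, spec.resource_mix)
            structure = rng.choice(structures)
            choices = [frozenset([lvl]) for lvl in POSITIVE_LEVELS] + [
                frozenset([NOT_DETECTED])
            ]
            level = rng.choice(choices)
            if _term_for(resource, level) is None:
                level = frozenset([WEAK])
            emit(resource, gene, structure, level)
    return rows


CURATOR_RANGE = (1, 5)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete, self-consistent bundle of input files.

    Produces ``ontology.tsv``, ``annotations.tsv``, ``schemes.json`` (with
    both expert score vectors and the combined min-rank score), ``cutoffs.tsv``
    and ``alignment.tsv`` under ``out_dir``. Deterministic: the same spec
    (seed included) yields byte-identical files.
    """
    import json as _json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    _, _, stage = spec.ontology_shape

    edges = _generate_ontology_edges(spec, rng)
    ontology_path = out / "ontology.tsv"
    ontology_path.write_text(
        "# child_id\tparent_id\tstage\n"
        + "".join(f"{c}\t{p}\t{stage}\n" for c, p in edges),
        encoding="utf-8",
    )

    rows = _annotation_rows(spec, rng)
    annotations_path = out / "annotations.tsv"
    annotations_path.write_text(
        "\t".join(
            [
                "annotation_id", "resource", "gene", "structure_id", "stage",
                "level_term_or_value", "origin", "source_annotation_id",
                "probe_info", "curator_confidence", "source_url",
            ]
        )
        + "\n"
        + "".join("\t".join(r) + "\n" for r in rows),
        encoding="utf-8",
    )

    # cut-offs on the root: every brain structure inherits them
    cutoffs_path = out / "cutoffs.tsv"
    w, m, s = _CUTOFF_ROW
    cutoffs_path.write_text(
        f"# structure_id\tweak_min\tmoderate_min\tstrong_min\n"
        f"{ROOT_ID}\t{w}\t{m}\t{s}\n",
        encoding="utf-8",
    )

    # alignment: every ABA foreign id maps onto its EMAP structure; the
    # focal-structure mapping is flagged as losing precision (finer anatomy)
    structures = sorted({e[0] for e in edges} | {e[1] for e in edges})
    alignment_path = out / "alignment.tsv"
    alignment_path.write_text(
        "# resource\tforeign_id\temap_id\tprecision_loss_flag\n"
        + "".join(
            f"ABA\taba:{sid}\t{sid}\t{1 if sid == FOCAL_ID else 0}\n"
            for sid in structures
        ),
        encoding="utf-8",
    )

    a_scores, b_scores = generate_score_vectors(spec.scheme_counts, rng)
    schemes = []
    for i, (sa, sb) in enumerate(zip(a_scores, b_scores)):
        template = _SCHEME_TEMPLATES[i % len(_SCHEME_TEMPLATES)]
        schemes.append(
            {
                "id": f"scheme_{i + 1:03d}",
                "text": template["text"],
                "conditions": template["conditions"],
                "conclusion": template["conclusion"],
                "score": ConfidenceScore(min(sa.rank, sb.rank)).token,
                "score_a": sa.token,
                "score_b": sb.token,
            }
        )
    schemes_path = out / "schemes.json"
    schemes_path.write_text(
        _json.dumps({"schemes": schemes}, indent=2) + "\n", encoding="utf-8"
    )

    return {
        "ontology": ontology_path,
        "annotations": annotations_path,
        "cutoffs": cutoffs_path,
        "alignment": alignment_path,
        "schemes": schemes_path,
    }
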