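"""Staged part-of anatomy hierarchy and upward propagation of findings.

The developmental mouse is divided into twenty-eight Theiler stages (stage 27
is the newborn, 28 the adult) and each stage has its own anatomy: a DAG of
structures related by *part-of*, in the style of the EMAP atlas ontology.
Because the relation is part-of, a positive expression finding in a structure
also holds in every structure it is part of — if *bmp4* is weakly expressed in
the telencephalon it is weakly expressed in the future brain. Negative
findings are never lifted: "not detected" in a part says nothing about the
whole.

Propagation here is single-hop from direct annotations over the full ancestor
closure: derived records are never re-propagated, which keeps provenance one
level deep and the output stable under repetition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

import networkx as nx
import obonet

if TYPE_CHECKING:  # pragma: no cover
    from .annotations import Annotation

MIN_STAGE, MAX_STAGE = 1, 28


class OntologyError(ValueError):
    """Base class for anatomy-ontology failures."""


class CyclicOntologyError(OntologyError):
    """The part-of graph restricted to one stage contains a cycle."""


class DanglingParentError(OntologyError):
    """A parent reference does not resolve to any node."""


class UnknownStructureError(OntologyError, KeyError):
    """A structure id is not present in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class AnatomyNode:
    """One anatomical structure at one Theiler stage."""

    node_id: str
    name: str
    stage: int
    parent_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_ids", frozenset(self.parent_ids))
        if not MIN_STAGE <= self.stage <= MAX_STAGE:
            raise OntologyError(
                f"stage {self.stage} for {self.node_id} outside Theiler range "
                f"[{MIN_STAGE}, {MAX_STAGE}]"
            )


class AnatomyOntology:
    """A staged part-of DAG of anatomical structures.

    Parameters
    ----------
    nodes
        The structures; every ``parent_id`` must resolve to a node of the same
        stage, and the graph restricted to each stage must be acyclic.
    """

    def __init__(self, nodes: Iterable[AnatomyNode]):
        self.nodes: dict[str, AnatomyNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise OntologyError(f"duplicate structure id {node.node_id}")
            self.nodes[node.node_id] = node

        self.stage_index: dict[int, set[str]] = {}
        graph = nx.DiGraph()  # edges child -> parent, within one stage
        graph.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            self.stage_index.setdefault(node.stage, set()).add(node.node_id)
            for pid in node.parent_ids:
                parent = self.nodes.get(pid)
                if parent is None:
                    raise DanglingParentError(
                        f"dangling parent reference: {node.node_id} -> {pid} "
                        f"({pid} is not defined)"
                    )
                if parent.stage != node.stage:
                    raise OntologyError(
                        f"part-of edge {node.node_id} -> {pid} crosses stages "
                        f"({node.stage} vs {parent.stage}); each stage has its "
                        "own anatomy"
                    )
                graph.add_edge(node.node_id, pid)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            child, parent = cycle[0][0], cycle[0][1]
            raise CyclicOntologyError(
                f"cyclic ontology: part-of edge {child} -> {parent} lies on a cycle"
            )
        self._graph = graph

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestors(self, node_id: str) -> list[str]:
        """All structures this one is (transitively) part of, excluding itself.

        Ordered breadth-first from the node, ties within a frontier broken by
        identifier sort, each ancestor listed once at its first visit.
        """
        if node_id not in self.nodes:
            raise UnknownStructureError(f"unknown structure {node_id!r}")
        out: list[str] = []
        seen = {node_id}
        frontier = [node_id]
        while frontier:
            nxt: list[str] = []
            for nid in frontier:
                for pid in sorted(self.nodes[nid].parent_ids):
                    if pid not in seen:
                        seen.add(pid)
                        out.append(pid)
                        nxt.append(pid)
            frontier = nxt
        return out

    def roots(self, stage: int) -> list[str]:
        """Structures of a stage with no part-of parents."""
        return sorted(
            nid for nid in self.stage_index.get(stage, ())
            if not self.nodes[nid].parent_ids
        )


def _load_edge_tsv(path: str) -> AnatomyOntology:
    parents: dict[str, set[str]] = {}
    stages: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OntologyError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(child_id, parent_id, stage), got {len(parts)}"
                )
            child, parent, stage_s = (p.strip() for p in parts)
            try:
                stage = int(stage_s)
            except ValueError:
                raise OntologyError(
                    f"{path}:{lineno}: stage {stage_s!r} is not an integer"
                ) from None
            for nid in (child, parent):
                if stages.setdefault(nid, stage) != stage:
                    raise OntologyError(
                        f"{path}:{lineno}: {nid} appears at stages "
                        f"{stages[nid]} and {stage}; ids are per-stage"
                    )
            parents.setdefault(parent, set())
            parents.setdefault(child, set()).add(parent)
    nodes = [
        AnatomyNode(nid, nid, stages[nid], frozenset(parents.get(nid, ())))
        for nid in sorted(stages)
    ]
    return AnatomyOntology(nodes)


def _load_obo_subset(path: str) -> AnatomyOntology:
    graph = obonet.read_obo(path, ignore_obsolete=True)
    nodes = []
    for nid, data in graph.nodes(data=True):
        stage = None
        for pv in data.get("property_value", ()):
            parts = pv.split()
            if len(parts) >= 2 and parts[0] == "theiler_stage":
                try:
                    stage = int(parts[1])
                except ValueError:
                    raise OntologyError(
                        f"term {nid}: theiler_stage {parts[1]!r} is not an integer"
                    ) from None
        if stage is None:
            raise OntologyError(
                f"term {nid}: missing 'property_value: theiler_stage <int>' line"
            )
        part_of = frozenset(
            rel.split()[1]
            for rel in data.get("relationship", ())
            if rel.split()[0] == "part_of"
        )
        nodes.append(AnatomyNode(nid, data.get("name", nid), stage, part_of))
    return AnatomyOntology(nodes)


def load_ontology(path: str, format: str = "auto") -> AnatomyOntology:
    """Load a staged part-of ontology.

    Parameters
    ----------
    path
        Either a three-column edge TSV (``child_id  parent_id  stage``, ``#``
        comments ignored) or an OBO 1.2 subset with ``[Term]`` stanzas carrying
        ``relationship: part_of`` lines and the stage in a
        ``property_value: theiler_stage <int>`` line. Unknown OBO tags are
        ignored.
    format
        ``"edge-tsv"``, ``"obo-subset"``, or ``"auto"`` to pick by extension.
    """
    if format == "auto":
        format = "obo-subset" if str(path).endswith(".obo") else "edge-tsv"
    if format == "edge-tsv":
        return _load_edge_tsv(path)
    if format == "obo-subset":
        return _load_obo_subset(path)
    raise ValueError(f"unknown ontology format {format!r}")


def propagate(
    annotations: Sequence["Annotation"], ont: AnatomyOntology
) -> list["Annotation"]:
    """Lift positive direct findings to every part-of ancestor.

    Returns the input annotations plus one derived record per (direct positive
    annotation, ancestor structure) pair, flagged ``origin="propagated"`` and
    recording the source annotation id. Not-detected findings are never
    propagated, already-propagated inputs are not re-propagated, and
    duplicates (same source, same target structure) collapse to one record.
    The operation is idempotent.
    """
    missing = sorted(
        a.annotation_id for a in annotations if a.structure_id not in ont
    )
    if missing:
        raise UnknownStructureError(
            "unknown structure for annotation(s): " + ", ".join(missing)
        )

    out = list(annotations)
    seen: set[tuple[str, str]] = {
        (a.source_annotation_id, a.structure_id)
        for a in annotations
        if a.origin == "propagated"
    }
    for a in annotations:
        if a.origin != "direct" or not a.level.is_positive:
            continue
        for anc in ont.ancestors(a.structure_id):
            key = (a.annotation_id, anc)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                dataclasses.replace(
                    a,
                    annotation_id=f"{a.annotation_id}::up::{anc}",
                    structure_id=anc,
                    origin="propagated",
                    source_annotation_id=a.annotation_id,
                )
            )
    return out
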