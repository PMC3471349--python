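import random

import pytest

from argudas.annotations import Annotation
from argudas.ontology import AnatomyNode, AnatomyOntology
from argudas.vocabulary import LevelAssertion


@pytest.fixture
def brain_ontology() -> AnatomyOntology:
    """telencephalon -> future_brain -> embryo, all at Theiler stage 15."""
    return AnatomyOntology(
        [
            AnatomyNode("embryo", "embryo", 15),
            AnatomyNode("future_brain", "future brain", 15, {"embryo"}),
            AnatomyNode("telencephalon", "telencephalon", 15, {"future_brain"}),
        ]
    )


@pytest.fixture
def make_annotation():
    """Annotation factory with sensible defaults for the bmp4/TS15 case."""

    def _make(
        annotation_id="EMAGE:1",
        resource="EMAGE",
        gene="bmp4",
        structure_id="future_brain",
        stage=15,
        levels=("strong",),
        origin="direct",
        source_annotation_id="",
        probe_info_present="yes",
        curator_confidence=None,
        source_url="",
    ) -> Annotation:
        return Annotation(
            annotation_id=annotation_id,
            resource=resource,
            gene=gene,
            structure_id=structure_id,
            stage=stage,
            level=LevelAssertion(frozenset(levels)),
            origin=origin,
            source_annotation_id=source_annotation_id,
            probe_info_present=probe_info_present,
            curator_confidence=curator_confidence,
            source_url=source_url,
        )

    return _make


def random_stage_dag(rng: random.Random, n_nodes: int, stage: int = 15):
    """A random per-stage part-of DAG as an AnatomyOntology.

    Node i may take parents only among nodes < i, which guarantees acyclicity;
    used as ground truth for reachability oracles.
    """
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    parents = {ids[0]: set()}
    for i in range(1, n_nodes):
        k = rng.randint(0, min(3, i))
        parents[ids[i]] = set(rng.sample(ids[:i], k))
    nodes = [AnatomyNode(nid, nid, stage, frozenset(parents[nid])) for nid in ids]
    return AnatomyOntology(nodes), parents
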