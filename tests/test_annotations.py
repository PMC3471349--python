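"""Annotation records: loading, querying, and the two-granularity agreement."""

import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from argudas.annotations import (
    AGREE,
    CONFLICT,
    INDEPENDENT,
    Annotation,
    AnnotationError,
    AnnotationLoadError,
    agreement,
    load_annotations,
    query,
)
from argudas.vocabulary import AbaCutoffTable, AnatomyAlignment, LevelAssertion

_HEADER = (
    "annotation_id\tresource\tgene\tstructure_id\tstage\tlevel_term_or_value\t"
    "origin\tsource_annotation_id\tprobe_info\tcurator_confidence\tsource_url\n"
)


def _tsv(tmp_path, rows):
    p = tmp_path / "ann.tsv"
    p.write_text(_HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return str(p)


class TestLoad:
    def test_valid_tsv_transcribes(self, tmp_path):
        path = _tsv(
            tmp_path,
            [
                ["E:1", "EMAGE", "bmp4", "future_brain", "15", "strong",
                 "direct", "", "yes", "3", "http://x"],
                ["G:1", "GXD", "bmp4", "future_brain", "15", "absent",
                 "direct", "", "no", "", ""],
            ],
        )
        anns = load_annotations(path)
        assert len(anns) == 2
        assert anns[0].level.levels == frozenset(["strong"])
        assert anns[1].level.is_not_detected
        assert anns[0].curator_confidence == 3 and anns[1].curator_confidence is None

    def test_not_done_rows_dropped_with_log(self, tmp_path, caplog):
        path = _tsv(
            tmp_path,
            [["N:1", "GENSAT", "bmp4", "future_brain", "15", "not done",
              "direct", "", "unknown", "", ""]],
        )
        with caplog.at_level("INFO", logger="argudas"):
            anns = load_annotations(path)
        assert anns == []
        assert any("dropped 1" in m for m in caplog.messages)

    def test_unknown_level_term_names_term_and_line(self, tmp_path):
        path = _tsv(
            tmp_path,
            [["E:1", "EMAGE", "bmp4", "future_brain", "15", "blazing",
              "direct", "", "yes", "", ""]],
        )
        with pytest.raises(AnnotationLoadError, match="line 2.*blazing"):
            load_annotations(path)

    def test_malformed_stage_names_field(self, tmp_path):
        path = _tsv(
            tmp_path,
            [["E:1", "EMAGE", "bmp4", "future_brain", "soon", "strong",
              "direct", "", "yes", "", ""]],
        )
        with pytest.raises(AnnotationLoadError, match="'stage'"):
            load_annotations(path)

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "ann.json"
        p.write_text(json.dumps([
            {
                "annotation_id": "E:1", "resource": "EMAGE", "gene": "bmp4",
                "structure_id": "future_brain", "stage": 15,
                "level_term_or_value": "weak", "origin": "direct",
                "source_annotation_id": "", "probe_info": "yes",
                "curator_confidence": "", "source_url": "",
            }
        ]))
        anns = load_annotations(str(p))
        assert len(anns) == 1 and anns[0].level.levels == frozenset(["weak"])

    def test_aba_value_categorised_through_cutoffs(self, tmp_path, brain_ontology):
        path = _tsv(
            tmp_path,
            [["A:1", "ABA", "bmp4", "aba:fine", "15", "2.5",
              "direct", "", "unknown", "", ""]],
        )
        cutoffs = AbaCutoffTable({"embryo": (1.0, 2.0, 3.0)})
        alignment = AnatomyAlignment({("ABA", "aba:fine"): (("telencephalon", True),)})
        anns = load_annotations(
            path, cutoffs=cutoffs, ont=brain_ontology, alignment=alignment
        )
        assert len(anns) == 1
        assert anns[0].structure_id == "telencephalon"
        assert anns[0].level.levels == frozenset(["moderate"])

    def test_propagated_record_requires_source_and_positive(self, make_annotation):
        with pytest.raises(AnnotationError, match="source"):
            make_annotation(origin="propagated")
        with pytest.raises(AnnotationError, match="positive"):
            make_annotation(
                origin="propagated",
                source_annotation_id="E:0",
                levels=("not_detected",),
            )


class TestQuery:
    @pytest.fixture
    def store(self, make_annotation):
        return [
            make_annotation("E:1", structure_id="future_brain", levels=("strong",)),
            make_annotation("E:2", structure_id="future_brain", levels=("weak",),
                            origin="propagated", source_annotation_id="E:4"),
            make_annotation("E:3", structure_id="telencephalon", levels=("weak",)),
            make_annotation("G:1", resource="GXD", gene="shh",
                            structure_id="future_brain", levels=("moderate",)),
        ]

    def test_filters_on_all_supplied_keys(self, store):
        hits = query(store, gene="bmp4", structure_id="future_brain", stage=15)
        assert [a.annotation_id for a in hits] == ["E:1", "E:2"]

    def test_direct_only_excludes_propagated(self, store):
        hits = query(
            store, gene="bmp4", structure_id="future_brain",
            include_propagated=False,
        )
        assert [a.annotation_id for a in hits] == ["E:1"]

    def test_absent_gene_yields_empty_list(self, store):
        assert query(store, gene="pax6") == []

    def test_gene_compares_case_insensitively(self, store):
        assert len(query(store, gene="BMP4")) == 3

    def test_needs_gene_or_structure(self, store):
        with pytest.raises(AnnotationError):
            query(store, stage=15)


class TestAgreement:
    def test_strong_vs_weak_agree_on_presence(self, make_annotation):
        a = make_annotation("E:1", levels=("strong",))
        b = make_annotation("E:2", levels=("weak",))
        assert agreement(a, b, "presence") == AGREE

    def test_strong_vs_weak_conflict_on_level(self, make_annotation):
        a = make_annotation("E:1", levels=("strong",))
        b = make_annotation("E:2", levels=("weak",))
        assert agreement(a, b, "level") == CONFLICT

    def test_detected_agrees_with_any_positive_level(self, make_annotation):
        detected = make_annotation("E:1", levels=("weak", "moderate", "strong"))
        moderate = make_annotation("E:2", levels=("moderate",))
        assert agreement(detected, moderate, "level") == AGREE

    def test_absent_conflicts_with_expressed_in_both_modes(self, make_annotation):
        nd = make_annotation("E:1", levels=("not_detected",))
        pos = make_annotation("E:2", levels=("weak",))
        assert agreement(nd, pos, "presence") == CONFLICT
        assert agreement(nd, pos, "level") == CONFLICT

    def test_different_structures_are_independent(self, make_annotation):
        a = make_annotation("E:1", structure_id="future_brain")
        b = make_annotation("E:2", structure_id="telencephalon")
        assert agreement(a, b, "presence") == INDEPENDENT

    _level_sets = st.sampled_from(
        [
            ("not_detected",),
            ("weak",), ("moderate",), ("strong",),
            ("weak", "moderate"), ("moderate", "strong"),
            ("weak", "moderate", "strong"),
        ]
    )

    @given(la=_level_sets, lb=_level_sets,
           mode=st.sampled_from(["presence", "level"]))
    @settings(deadline=None, max_examples=80)
    def test_symmetric_and_consistent_across_modes(self, la, lb, mode):
        a = Annotation("E:1", "EMAGE", "bmp4", "s", 15, LevelAssertion(frozenset(la)))
        b = Annotation("E:2", "EMAGE", "bmp4", "s", 15, LevelAssertion(frozenset(lb)))
        assert agreement(a, b, mode) == agreement(b, a, mode)
        # level-mode agreement between positives implies presence-mode agreement
        if (a.level.is_positive and b.level.is_positive
                and agreement(a, b, "level") == AGREE):
            assert agreement(a, b, "presence") == AGREE

    def test_identical_annotations_agree_in_both_modes(self, make_annotation):
        a = make_annotation("E:1")
        b = make_annotation("E:2")
        for mode in ("presence", "level"):
            assert agreement(a, b, mode) == AGREE
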