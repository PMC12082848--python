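import dataclasses

import pytest

from kgexplore.namespaces import CurieRef
from kgexplore.records import (Bioresource, GeneDiseaseAssociation,
                               KnowledgeGraph, MergeConflictError, merge,
                               validate_kg)
from kgexplore.synth import SynthParams, generate


def test_synthetic_kg_validates_strictly(synth_kg_gt):
    kg, _ = synth_kg_gt
    assert validate_kg(kg, strict=True) == []


def test_out_of_range_gda_score_flagged(synth_kg_gt):
    kg, _ = synth_kg_gt
    bad = dataclasses.replace(kg.gdas[0], score=1.2)
    broken = dataclasses.replace(kg, gdas=kg.gdas[1:] + [bad])
    issues = validate_kg(broken)
    assert len(issues) == 1 and "outside [0, 1]" in issues[0].rule


def test_dangling_gene_link_flagged_in_strict_mode_only(synth_kg_gt):
    kg, _ = synth_kg_gt
    ghost = Bioresource(resource_id=CurieRef("rbrc", "SYNGHOST1"),
                        gene_links=frozenset({CurieRef("mgi", "SYNMISSING")}))
    broken = dataclasses.replace(kg, bioresources=kg.bioresources + [ghost])
    assert validate_kg(broken) == []
    issues = validate_kg(broken, strict=True)
    assert len(issues) == 1 and "dangling" in issues[0].rule


def test_bad_enums_flagged(synth_kg_gt):
    kg, _ = synth_kg_gt
    bad = dataclasses.replace(kg.calls[0], confidence="medium", sex="unknown")
    broken = dataclasses.replace(kg, calls=[bad])
    rules = {i.field for i in validate_kg(broken)}
    assert rules == {"confidence", "sex"}


class TestMerge:
    def _shards(self, kg):
        empty = KnowledgeGraph()
        a = dataclasses.replace(empty, bioresources=kg.bioresources,
                                genes=kg.genes, uniprot_links=kg.uniprot_links)
        b = dataclasses.replace(empty, clusters=kg.clusters, gdas=kg.gdas,
                                diseases=kg.diseases, calls=kg.calls,
                                anatomy=kg.anatomy, genes=kg.genes)
        return a, b

    def test_union_of_shards_passes_strict_validation(self, synth_kg_gt):
        kg, _ = synth_kg_gt
        merged = merge(self._shards(kg))
        assert validate_kg(merged, strict=True) == []
        assert sorted(merged.gdas, key=str) == sorted(kg.gdas, key=str)

    def test_idempotent(self, synth_kg_gt):
        kg, _ = synth_kg_gt
        merged = merge([kg, kg])
        assert sorted(merged.genes, key=str) == sorted(kg.genes, key=str)
        assert len(merged.calls) == len(kg.calls)
        assert merged.anatomy == kg.anatomy

    def test_commutative_on_conflict_free_inputs(self, synth_kg_gt):
        kg, _ = synth_kg_gt
        a, b = self._shards(kg)
        ab, ba = merge([a, b]), merge([b, a])
        for field in ("bioresources", "genes", "clusters", "gdas", "calls", "diseases"):
            assert sorted(getattr(ab, field), key=str) == sorted(getattr(ba, field), key=str)

    def test_conflicting_labels_raise_naming_the_id(self):
        res_a = Bioresource(CurieRef("rbrc", "RBRC06344"), label="line A")
        res_b = Bioresource(CurieRef("rbrc", "RBRC06344"), label="line B")
        with pytest.raises(MergeConflictError, match="RBRC06344"):
            merge([KnowledgeGraph(bioresources=[res_a]),
                   KnowledgeGraph(bioresources=[res_b])])
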