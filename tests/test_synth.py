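import dataclasses

import numpy as np
import pytest

from kgexplore.io_rdf import default_dialect, write_named_graph
from kgexplore.pipeline import explore
from kgexplore.records import validate_kg
from kgexplore.synth import (NotPlantedError, SynthParams, expected_result,
                             focal_queryspec, generate)


def _serialize_all(kg):
    parts = []
    for kind, records in (("bioresource", kg.bioresources),
                          ("mgi_mapping", kg.genes),
                          ("orthology", kg.clusters),
                          ("expression", kg.calls)):
        parts.append(write_named_graph(records, default_dialect(kind)))
    return "".join(parts)


def test_same_seed_serializes_byte_identically():
    a, _ = generate(SynthParams(seed=0))
    b, _ = generate(SynthParams(seed=0))
    assert _serialize_all(a) == _serialize_all(b)


def test_different_seeds_differ():
    a, _ = generate(SynthParams(seed=0))
    b, _ = generate(SynthParams(seed=1))
    assert _serialize_all(a) != _serialize_all(b)


def test_generated_graphs_pass_strict_validation():
    for seed in range(5):
        kg, _ = generate(SynthParams(seed=seed))
        assert validate_kg(kg, strict=True) == []


def test_planted_fraction_zero_gives_empty_expectation():
    kg, gt = generate(SynthParams(seed=2, planted_disease_gene_frac=0.0))
    qspec = focal_queryspec(gt, use_closure=True, gda_threshold=0.5)
    assert len(expected_result(gt, qspec)) == 0
    assert len(explore(qspec, kg)) == 0


def test_planted_set_size_rounds_fraction():
    _, gt = generate(SynthParams(seed=0, n_human_genes=100,
                                 planted_disease_gene_frac=0.14))
    assert len(gt.planted[gt.focal_disease]) == 14


def test_threshold_one_keeps_almost_surely_nothing():
    kg, gt = generate(SynthParams(seed=4))
    qspec = focal_queryspec(gt, use_closure=True, gda_threshold=1.0)
    assert explore(qspec, kg) == expected_result(gt, qspec)
    assert all(score == 1.0
               for (gene, disease), score in gt.gda_scores.items()
               if disease == gt.focal_disease
               and gene in {r.human_gene for r in expected_result(gt, qspec)})


def test_unplanted_disease_signals():
    _, gt = generate(SynthParams(seed=0))
    from kgexplore.namespaces import CurieRef
    qspec = dataclasses.replace(focal_queryspec(gt),
                                disease=CurieRef("umls", "CNOTPLANTED"))
    with pytest.raises(NotPlantedError):
        expected_result(gt, qspec)


@pytest.mark.parametrize("seed", range(20))
def test_parameter_recovery_exact(seed):
    """explore() recovers the generator's bookkept expectation exactly."""
    kg, gt = generate(SynthParams(seed=seed))
    for closure in (False, True):
        qspec = focal_queryspec(gt, use_closure=closure)
        assert explore(qspec, kg) == expected_result(gt, qspec)


def test_closure_on_and_off_differ_by_construction(synth_kg_gt):
    """Planted calls on proper descendants make the closure matter."""
    kg, gt = synth_kg_gt
    off = explore(focal_queryspec(gt), kg)
    on = explore(focal_queryspec(gt, use_closure=True), kg)
    assert set(on.rows) > set(off.rows)


def test_annotation_fractions_within_binomial_error():
    """Empirical high-confidence and any-sex fractions track the parameters."""
    params = SynthParams(seed=6, n_human_genes=400, call_rate=4.0)
    _, gt = generate(params)
    calls = gt.call_table
    n = len(calls)
    assert n >= 1000
    for index, expected in ((2, params.high_conf_frac), (3, params.sex_any_frac)):
        values = {2: "high", 3: "any"}
        frac = sum(1 for c in calls if c[index] == values[index]) / n
        se = np.sqrt(expected * (1 - expected) / n)
        # planted calls are forced high/any, so allow their small excess
        planted_excess = len(gt.planted[gt.focal_disease]) / n
        assert abs(frac - expected) <= 3 * se + planted_excess


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SynthParams(n_human_genes=0)
    with pytest.raises(ValueError):
        SynthParams(high_conf_frac=1.5)
    with pytest.raises(ValueError):
        SynthParams(anatomy_depth=2)
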