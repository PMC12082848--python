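"""Synthetic knowledge graphs with planted ground truth.

The generator emulates the statistical structure of the six integrated
graph kinds: a bioresource catalogue linked to mouse genes, gene ID
mapping tables, hierarchical orthology clusters (some nested two levels
deep), scored gene-disease associations, anatomically annotated
expression calls, and a mixed subClassOf/part-of anatomy DAG with
multiple parents.  All identifiers are minted in reserved synthetic ID
ranges (``SYN…`` local parts) so they cannot collide with real
accessions.

For a focal disease a configurable fraction of human genes is planted
with association scores at or above 0.5; half of those genes receive a
guaranteed high-confidence call on the focal anatomy term itself, the
other half only on a proper descendant of it, so that closure-on and
closure-off explorations provably differ.  The :class:`GroundTruth`
records flat bookkeeping tables from which the expected exploration
result is derived by :func:`expected_result` without touching the
pipeline or the generated KG objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .anatomy import BroaderGraph
from .namespaces import CurieRef
from .pipeline import ExplorationResult, QuerySpec, ResultRow
from .records import (HUMAN_TAXON, MOUSE_TAXON, Bioresource, Disease,
                      ExpressionCall, GeneDiseaseAssociation, GeneRecord,
                      KnowledgeGraph, OrthologyCluster, UniProtLink)

__all__ = [
    "SynthParams",
    "GroundTruth",
    "NotPlantedError",
    "generate",
    "focal_queryspec",
    "expected_result",
]


class NotPlantedError(KeyError):
    """The query refers to a disease the generator did not plant."""


@dataclass(frozen=True)
class SynthParams:
    """Shape and rates of the synthetic knowledge graph."""

    n_bioresources: int = 30
    n_mouse_genes: int = 40
    n_human_genes: int = 100
    n_diseases: int = 3
    ortholog_coverage: float = 0.8
    mapping_coverage: float = 0.9
    gda_score_law: str = "uniform"
    planted_disease_gene_frac: float = 0.14
    anatomy_depth: int = 4
    anatomy_branching: int = 3
    partof_fraction: float = 0.4
    call_rate: float = 3.0
    high_conf_frac: float = 0.7
    sex_any_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("n_bioresources", "n_mouse_genes", "n_human_genes", "n_diseases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ortholog_coverage", "mapping_coverage", "planted_disease_gene_frac",
                     "partof_fraction", "high_conf_frac", "sex_any_frac"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.anatomy_depth < 3 or self.anatomy_branching < 2:
            raise ValueError("anatomy DAG needs depth >= 3 and branching >= 2")
        if self.call_rate < 0:
            raise ValueError("call_rate must be nonnegative")


@dataclass
class GroundTruth:
    """Flat bookkeeping tables recorded during generation."""

    focal_disease: CurieRef = None  # type: ignore[assignment]
    focal_anatomy: CurieRef = None  # type: ignore[assignment]
    #: resource -> linked mouse primary IDs
    resource_links: dict[CurieRef, set[CurieRef]] = field(default_factory=dict)
    #: mouse primary ID -> (ncbi, ensembl, uniprot accessions)
    mouse_mappings: dict[CurieRef, tuple[Optional[CurieRef], Optional[CurieRef], frozenset]] = field(default_factory=dict)
    #: human primary ID -> reported (Ensembl) display ID
    human_display: dict[CurieRef, CurieRef] = field(default_factory=dict)
    #: (mouse primary, human primary) orthologous pairs
    ortholog_pairs: set[tuple[CurieRef, CurieRef]] = field(default_factory=set)
    #: (human primary, disease) -> best association score
    gda_scores: dict[tuple[CurieRef, CurieRef], float] = field(default_factory=dict)
    #: (human primary, anatomical entity, confidence, sex)
    call_table: list[tuple[CurieRef, CurieRef, str, str]] = field(default_factory=list)
    #: anatomy edges (narrower, broader) regardless of source relation
    anatomy_edges: set[tuple[CurieRef, CurieRef]] = field(default_factory=set)
    #: disease -> planted human primary IDs
    planted: dict[CurieRef, set[CurieRef]] = field(default_factory=dict)

    def descendant_closure(self, root: CurieRef) -> set[CurieRef]:
        incoming: dict[CurieRef, set[CurieRef]] = {}
        for narrower, broader in self.anatomy_edges:
            incoming.setdefault(broader, set()).add(narrower)
        seen = {root}
        stack = [root]
        while stack:
            node = stack.pop()
            for child in incoming.get(node, ()):
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


def _draw_score(rng: np.random.Generator, law: str) -> float:
    if law == "uniform":
        return float(rng.uniform())
    if law.startswith("beta(") and law.endswith(")"):
        a, b = (float(x) for x in law[5:-1].split(","))
        return float(rng.beta(a, b))
    raise ValueError(f"unknown gda_score_law {law!r}")


def _build_anatomy(params: SynthParams, rng: np.random.Generator,
                   gt: GroundTruth) -> tuple[BroaderGraph, list[CurieRef]]:
    levels: list[list[CurieRef]] = []
    counter = 0
    for depth in range(params.anatomy_depth):
        width = 1 if depth == 0 else len(levels[-1]) * params.anatomy_branching
        level = []
        for _ in range(width):
            level.append(CurieRef("obo", f"SYNANAT{counter:04d}"))
            counter += 1
        levels.append(level)
    graph = BroaderGraph()

    def add_edge(narrower: CurieRef, broader: CurieRef) -> None:
        pair = (narrower, broader)
        if rng.uniform() < params.partof_fraction:
            graph.from_partof.add(pair)
        else:
            graph.from_subclassof.add(pair)
        gt.anatomy_edges.add(pair)

    for depth in range(1, params.anatomy_depth):
        for i, node in enumerate(levels[depth]):
            parent = levels[depth - 1][i // params.anatomy_branching]
            add_edge(node, parent)
            # occasional extra part-of parent at a strictly shallower level
            if rng.uniform() < 0.15:
                shallow = int(rng.integers(0, depth))
                candidates = [c for c in levels[shallow] if c != parent]
                if candidates:
                    extra = candidates[int(rng.integers(0, len(candidates)))]
                    graph.from_partof.add((node, extra))
                    gt.anatomy_edges.add((node, extra))
    all_nodes = [n for level in levels for n in level]
    gt.focal_anatomy = levels[1][0]
    return graph, all_nodes


def generate(params: SynthParams) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a strict-valid knowledge graph and its ground truth."""
    rng = np.random.default_rng(params.seed)
    gt = GroundTruth()
    anatomy, anatomy_nodes = _build_anatomy(params, rng, gt)

    # --- genes -------------------------------------------------------
    mouse_genes: list[GeneRecord] = []
    for i in range(params.n_mouse_genes):
        ncbi = CurieRef("ncbigene", f"91{i:06d}")
        has_ensembl = rng.uniform() < params.mapping_coverage
        has_uniprot = rng.uniform() < 0.7
        mouse_genes.append(GeneRecord(
            primary_id=CurieRef("mgi", f"SYN1{i:05d}"),
            taxon=MOUSE_TAXON,
            label=f"Syngene{i}",
            ncbi_id=ncbi,
            ensembl_id=CurieRef("ensembl", f"SYNMUSG{i:08d}") if has_ensembl else None,
            uniprot_accessions=frozenset(
                {CurieRef("uniprot", f"SYNPM{i:05d}")} if has_uniprot else ()),
        ))
    human_genes: list[GeneRecord] = []
    for i in range(params.n_human_genes):
        has_uniprot = rng.uniform() < 0.7
        human_genes.append(GeneRecord(
            primary_id=CurieRef("ensembl", f"SYNG{i:08d}"),
            taxon=HUMAN_TAXON,
            label=f"SYNGENE{i}",
            ncbi_id=CurieRef("ncbigene", f"92{i:06d}"),
            ensembl_id=CurieRef("ensembl", f"SYNG{i:08d}"),
            uniprot_accessions=frozenset(
                {CurieRef("uniprot", f"SYNPH{i:05d}")} if has_uniprot else ()),
        ))
    for gene in mouse_genes:
        gt.mouse_mappings[gene.primary_id] = (
            gene.ncbi_id, gene.ensembl_id, gene.uniprot_accessions)
    for gene in human_genes:
        gt.human_display[gene.primary_id] = gene.ensembl_id

    uniprot_links = [UniProtLink(g.ncbi_id, acc)
                     for g in mouse_genes + human_genes
                     for acc in sorted(g.uniprot_accessions)]

    # --- orthology ---------------------------------------------------
    clusters: list[OrthologyCluster] = []
    n_pairs = min(params.n_mouse_genes, params.n_human_genes)
    for i in range(n_pairs):
        if rng.uniform() >= params.ortholog_coverage:
            continue
        mouse, human = mouse_genes[i], human_genes[i]
        mouse_ref = mouse.ensembl_id or next(iter(sorted(mouse.uniprot_accessions)), None)
        if mouse_ref is None:
            continue
        mouse_member = (mouse_ref, MOUSE_TAXON)
        human_member = (human.primary_id, HUMAN_TAXON)
        if i % 5 == 0:
            # two-level nesting: members sit in sibling child clusters
            child_a = OrthologyCluster(CurieRef("omahog", f"SYNHOG{i:05d}A"),
                                       members=frozenset({mouse_member}))
            child_b = OrthologyCluster(CurieRef("omahog", f"SYNHOG{i:05d}B"),
                                       members=frozenset({human_member}))
            parent = OrthologyCluster(CurieRef("omahog", f"SYNHOG{i:05d}"),
                                      children=frozenset({child_a.cluster_id,
                                                          child_b.cluster_id}))
            clusters.extend([parent, child_a, child_b])
        else:
            clusters.append(OrthologyCluster(
                CurieRef("omahog", f"SYNHOG{i:05d}"),
                members=frozenset({mouse_member, human_member})))
        gt.ortholog_pairs.add((mouse.primary_id, human.primary_id))

    # --- diseases and associations -----------------------------------
    diseases = [Disease(CurieRef("umls", f"CSYN{i:04d}"), f"synthetic disease {i}")
                for i in range(params.n_diseases)]
    gt.focal_disease = diseases[0].cui
    gdas: list[GeneDiseaseAssociation] = []
    gda_counter = 0

    def add_gda(gene: GeneRecord, disease: Disease, score: float) -> None:
        nonlocal gda_counter
        gdas.append(GeneDiseaseAssociation(
            gda_id=CurieRef("gda", f"SYNGDA{gda_counter:06d}"),
            gene=gene.ncbi_id, disease=disease.cui, score=score))
        gda_counter += 1
        key = (gene.primary_id, disease.cui)
        gt.gda_scores[key] = max(gt.gda_scores.get(key, 0.0), score)

    n_planted = round(params.planted_disease_gene_frac * params.n_human_genes)
    planted_focal = human_genes[:n_planted]
    gt.planted[gt.focal_disease] = {g.primary_id for g in planted_focal}
    for gene in planted_focal:
        add_gda(gene, diseases[0], 0.5 + _draw_score(rng, params.gda_score_law) / 2.0)
    for gene in human_genes[n_planted:]:
        if rng.uniform() < 0.3:  # sub-threshold decoys for the focal disease
            add_gda(gene, diseases[0], _draw_score(rng, params.gda_score_law) / 2.001)
    for disease in diseases[1:]:
        gt.planted[disease.cui] = set()
        for gene in human_genes:
            if rng.uniform() < 0.2:
                score = _draw_score(rng, params.gda_score_law)
                add_gda(gene, disease, score)
                if score >= 0.5:
                    gt.planted[disease.cui].add(gene.primary_id)

    # --- expression calls --------------------------------------------
    focal_child = next(n for n, b in sorted(gt.anatomy_edges)
                       if b == gt.focal_anatomy)
    calls: list[ExpressionCall] = []

    def add_call(gene: GeneRecord, anat: CurieRef, conf: str, sex: str) -> None:
        calls.append(ExpressionCall(gene=gene.primary_id, anatomical_entity=anat,
                                    confidence=conf, sex=sex))
        gt.call_table.append((gene.primary_id, anat, conf, sex))

    for j, gene in enumerate(planted_focal):
        # even index: on the focal term; odd: only on a proper descendant,
        # so closure on/off explorations differ by construction
        add_call(gene, gt.focal_anatomy if j % 2 == 0 else focal_child, "high", "any")
    for gene in human_genes:
        for _ in range(int(rng.poisson(params.call_rate))):
            anat = anatomy_nodes[int(rng.integers(0, len(anatomy_nodes)))]
            conf = "high" if rng.uniform() < params.high_conf_frac else "low"
            sex = "any" if rng.uniform() < params.sex_any_frac else \
                ("male", "female")[int(rng.integers(0, 2))]
            add_call(gene, anat, conf, sex)

    # --- bioresources ------------------------------------------------
    kinds = ("knock-in mouse", "knock-out mouse", "transgenic mouse",
             "spontaneous mutation mouse")
    bioresources: list[Bioresource] = []
    for i in range(params.n_bioresources):
        n_links = 1 + int(rng.integers(0, 3))
        chosen = rng.choice(params.n_mouse_genes, size=min(n_links, params.n_mouse_genes),
                            replace=False)
        links = frozenset(mouse_genes[int(k)].primary_id for k in chosen)
        resource_id = CurieRef("rbrc", f"SYNRBRC{i:05d}")
        bioresources.append(Bioresource(
            resource_id=resource_id,
            label=f"synthetic mouse line {i}",
            resource_kind=kinds[int(rng.integers(0, len(kinds)))],
            gene_links=links,
        ))
        gt.resource_links[resource_id] = set(links)

    kg = KnowledgeGraph(
        bioresources=bioresources,
        genes=mouse_genes + human_genes,
        uniprot_links=uniprot_links,
        clusters=clusters,
        gdas=gdas,
        calls=sorted(set(calls), key=lambda c: (str(c.gene), str(c.anatomical_entity),
                                                c.confidence, c.sex)),
        diseases=diseases,
        anatomy=anatomy,
    )
    return kg, gt


def focal_queryspec(gt: GroundTruth, use_closure: bool = False, **kwargs) -> QuerySpec:
    """The exploration the generator plants: focal disease at the focal term."""
    return QuerySpec(disease=gt.focal_disease, anatomical_entity=gt.focal_anatomy,
                     use_closure=use_closure, **kwargs)


def expected_result(gt: GroundTruth, qspec: QuerySpec) -> ExplorationResult:
    """Derive the expected exploration result purely from the bookkeeping.

    Mirrors the query predicates over the flat tables recorded at
    generation time; it never traverses the generated KnowledgeGraph.
    """
    if not any(disease == qspec.disease for _, disease in gt.gda_scores) \
            and qspec.disease not in gt.planted:
        raise NotPlantedError(str(qspec.disease))
    allowed = gt.descendant_closure(qspec.anatomical_entity) if qspec.use_closure \
        else {qspec.anatomical_entity}
    qualifying = {gene for (gene, disease), score in gt.gda_scores.items()
                  if disease == qspec.disease and score >= qspec.gda_threshold}
    humans_of_mouse: dict[CurieRef, set[CurieRef]] = {}
    for mouse, human in gt.ortholog_pairs:
        humans_of_mouse.setdefault(mouse, set()).add(human)
    matching_calls: dict[CurieRef, set[CurieRef]] = {}
    # generated calls carry no stage/strain annotation, so any such
    # constraint excludes them all
    if qspec.dev_stage is None and qspec.strain is None:
        for gene, anat, conf, sex in gt.call_table:
            if conf == qspec.confidence and sex == qspec.sex and anat in allowed:
                matching_calls.setdefault(gene, set()).add(anat)
    rows = []
    for resource, mouse_ids in gt.resource_links.items():
        for mouse in mouse_ids:
            ncbi, ensembl, _ = gt.mouse_mappings[mouse]
            if ncbi is None or ensembl is None:
                continue
            for human in humans_of_mouse.get(mouse, ()):
                if human not in qualifying:
                    continue
                for anat in matching_calls.get(human, ()):
                    rows.append(ResultRow(
                        bioresource=resource,
                        mouse_gene=mouse,
                        human_gene=gt.human_display[human],
                        disease=qspec.disease,
                        anatomical_entity=anat,
                        confidence=qspec.confidence,
                    ))
    return ExplorationResult.from_rows(rows, limit=qspec.limit, offset=qspec.offset)
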