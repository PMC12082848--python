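"""The exploration pipeline: four composable query subparts.

Finding candidate disease-model mice decomposes into four joins:

1. bioresource -> mouse gene -> NCBI / Ensembl / UniProt IDs,
2. mouse gene -> orthologous human gene (shared orthology cluster,
   including nested clusters),
3. human gene -> disease, keeping associations scoring at or above a
   threshold (inclusive: a score of exactly 0.5 passes threshold 0.5),
4. human gene -> expression call filtered on anatomical entity (exact
   term, or its reflexive descendant closure), confidence and sex.

The stages can be materialized under different nesting plans (mirroring
SPARQL subquery arrangements); every plan returns the same canonical
result, and the per-plan :class:`StageTrace` records how many bindings
crossed each materialization boundary — the quantity that dominates the
cost of shipping bindings to a remote expression endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .anatomy import descendants
from .namespaces import CurieRef, default_table
from .records import (CONFIDENCE_LEVELS, HUMAN_TAXON, MOUSE_TAXON, SEX_VALUES,
                      GeneRecord, KnowledgeGraph, OrthologyCluster)

__all__ = [
    "QuerySpec",
    "PlanSpec",
    "ResultRow",
    "ExplorationResult",
    "StageTrace",
    "Binding",
    "PlanConfigError",
    "OracleTooLargeError",
    "NESTING_LEVELS",
    "stage1_bioresource_genes",
    "stage2_orthologs",
    "stage3_disease_filter",
    "stage4_expression_filter",
    "explore",
    "execute_plan",
    "brute_force_oracle",
    "effective_members",
]

NESTING_LEVELS = ("flat", "one_subquery", "two_subqueries", "three_subqueries")


class PlanConfigError(ValueError):
    pass


class OracleTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class QuerySpec:
    """The query conditions of one exploration."""

    disease: CurieRef
    anatomical_entity: CurieRef
    gda_threshold: float = 0.5
    confidence: str = "high"
    sex: str = "any"
    use_closure: bool = False
    dev_stage: Optional[CurieRef] = None
    strain: Optional[str] = None
    limit: Optional[int] = None
    offset: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.gda_threshold <= 1.0):
            raise ValueError(f"gda_threshold {self.gda_threshold} outside [0, 1]")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"confidence must be one of {CONFIDENCE_LEVELS}")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"sex must be one of {SEX_VALUES}")
        for name in ("limit", "offset"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PlanSpec:
    """Subquery nesting arrangement and evaluation mode."""

    nesting: str = "one_subquery"
    mode: str = "centralized"
    expression_endpoint: Optional[str] = None

    def __post_init__(self):
        if self.nesting not in NESTING_LEVELS:
            raise ValueError(f"nesting must be one of {NESTING_LEVELS}")
        if self.mode not in ("centralized", "federated"):
            raise ValueError("mode must be centralized or federated")
        if self.mode == "federated" and not self.expression_endpoint:
            raise PlanConfigError("federated mode requires expression_endpoint")


@dataclass(frozen=True)
class ResultRow:
    bioresource: CurieRef
    mouse_gene: CurieRef
    human_gene: CurieRef
    disease: CurieRef
    anatomical_entity: CurieRef
    confidence: str


_TABLE = default_table()


def _row_key(row: ResultRow) -> tuple[str, str, str, str]:
    # canonical order: (bioresource, human_gene, anatomical_entity,
    # mouse_gene) lexicographic on expanded IRIs
    return (
        _TABLE.expand(row.bioresource),
        _TABLE.expand(row.human_gene),
        _TABLE.expand(row.anatomical_entity),
        _TABLE.expand(row.mouse_gene),
    )


@dataclass
class ExplorationResult:
    """Duplicate-free, canonically ordered result rows."""

    rows: list[ResultRow] = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: Iterable[ResultRow],
                  limit: Optional[int] = None,
                  offset: Optional[int] = None) -> "ExplorationResult":
        ordered = sorted(set(rows), key=_row_key)
        start = offset or 0
        end = None if limit is None else start + limit
        return cls(ordered[start:end])

    def distinct_bioresources(self) -> int:
        return len({r.bioresource for r in self.rows})

    def distinct_human_genes(self) -> int:
        return len({r.human_gene for r in self.rows})

    def distinct_anatomical_entities(self) -> int:
        return len({r.anatomical_entity for r in self.rows})

    def __len__(self):
        return len(self.rows)

    def __eq__(self, other):
        if not isinstance(other, ExplorationResult):
            return NotImplemented
        return self.rows == other.rows

    def __iter__(self):
        return iter(self.rows)


@dataclass
class StageTrace:
    """Binding counts at each materialized boundary, and the final count."""

    boundaries: dict[str, int] = field(default_factory=dict)
    final_rows: int = 0


@dataclass(frozen=True)
class Binding:
    """An intermediate binding flowing between stages."""

    bioresource: CurieRef
    mgi: CurieRef
    ncbi: CurieRef
    ensembl_mouse: CurieRef
    uniprot_mouse: frozenset[CurieRef] = frozenset()
    human_gene: Optional[GeneRecord] = None


# ---------------------------------------------------------------------------
# stage 1: bioresource -> mouse gene ID mappings

def stage1_bioresource_genes(kg: KnowledgeGraph) -> list[Binding]:
    """One binding per (bioresource, linked mouse gene) with full ID mappings.

    Gene links whose records lack an NCBI or Ensembl cross-reference are
    dropped: the downstream joins require both ID spaces.
    """
    index = kg.gene_index()
    bindings = []
    for res in kg.bioresources:
        for gene_ref in sorted(res.gene_links):
            gene = index.get(gene_ref)
            if gene is None or gene.ncbi_id is None or gene.ensembl_id is None:
                continue
            uniprot = set(gene.uniprot_accessions)
            for link in kg.uniprot_links:
                if link.ncbi_gene == gene.ncbi_id:
                    uniprot.add(link.uniprot)
            bindings.append(Binding(
                bioresource=res.resource_id,
                mgi=gene.primary_id,
                ncbi=gene.ncbi_id,
                ensembl_mouse=gene.ensembl_id,
                uniprot_mouse=frozenset(uniprot),
            ))
    return bindings


# ---------------------------------------------------------------------------
# stage 2: orthology

def effective_members(cluster: OrthologyCluster,
                      by_id: dict[CurieRef, OrthologyCluster]) -> set[tuple[CurieRef, CurieRef]]:
    """Member closure of a cluster: own members plus all descendants'."""
    members = set(cluster.members)
    stack = list(cluster.children)
    seen = set()
    while stack:
        child_id = stack.pop()
        if child_id in seen:
            continue
        seen.add(child_id)
        child = by_id.get(child_id)
        if child is None:
            continue
        members |= child.members
        stack.extend(child.children)
    return members


def _ortholog_pairs(kg: KnowledgeGraph) -> set[tuple[CurieRef, CurieRef]]:
    """(mouse member ID, human member ID) pairs sharing a cluster closure."""
    by_id = kg.cluster_index()
    pairs: set[tuple[CurieRef, CurieRef]] = set()
    for cluster in kg.clusters:
        members = effective_members(cluster, by_id)
        mice = [g for g, t in members if t == MOUSE_TAXON]
        humans = [g for g, t in members if t == HUMAN_TAXON]
        for m in mice:
            for h in humans:
                pairs.add((m, h))
    return pairs


def stage2_orthologs(bindings: Iterable[Binding], kg: KnowledgeGraph) -> list[Binding]:
    """Extend each binding once per orthologous human gene.

    A binding's mouse gene is matched into cluster membership through
    its Ensembl ID or any of its UniProt accessions (both routes exist
    in the source graphs; their union is taken).  The human member
    resolves to its gene record through any registered ID.  Bindings
    with no ortholog are dropped.
    """
    index = kg.gene_index()
    pairs = _ortholog_pairs(kg)
    mouse_to_humans: dict[CurieRef, set[CurieRef]] = {}
    for m, h in pairs:
        mouse_to_humans.setdefault(m, set()).add(h)
    out = []
    for binding in bindings:
        probe_ids = sorted({binding.ensembl_mouse, *binding.uniprot_mouse}
                           & mouse_to_humans.keys())
        human_records: dict[CurieRef, GeneRecord] = {}
        for probe in probe_ids:
            for human_ref in mouse_to_humans[probe]:
                record = index.get(human_ref)
                if record is not None and record.taxon == HUMAN_TAXON:
                    human_records[record.primary_id] = record
        for _, record in sorted(human_records.items(), key=lambda kv: str(kv[0])):
            out.append(replace(binding, human_gene=record))
    return out


# ---------------------------------------------------------------------------
# stage 3: gene-disease filter

def stage3_disease_filter(bindings: Iterable[Binding], kg: KnowledgeGraph,
                          disease: CurieRef, threshold: float = 0.5) -> list[Binding]:
    """Keep bindings whose human gene has a qualifying disease association.

    The threshold is inclusive: a score exactly at the threshold passes.
    """
    index = kg.gene_index()
    qualifying: set[CurieRef] = set()
    for gda in kg.gdas:
        if gda.disease == disease and gda.score >= threshold:
            record = index.get(gda.gene)
            if record is not None:
                qualifying.add(record.primary_id)
    return [b for b in bindings
            if b.human_gene is not None and b.human_gene.primary_id in qualifying]


# ---------------------------------------------------------------------------
# stage 4: expression filter

def _call_matches(call, qspec: QuerySpec, allowed_terms) -> bool:
    if call.confidence != qspec.confidence or call.sex != qspec.sex:
        return False
    if call.anatomical_entity not in allowed_terms:
        return False
    if qspec.dev_stage is not None and call.dev_stage != qspec.dev_stage:
        return False
    if qspec.strain is not None and call.strain != qspec.strain:
        return False
    return True


def _allowed_terms(kg: KnowledgeGraph, qspec: QuerySpec) -> set[CurieRef]:
    if qspec.use_closure:
        return descendants(kg.anatomy, qspec.anatomical_entity, reflexive=True)
    return {qspec.anatomical_entity}


def stage4_expression_filter(bindings: Iterable[Binding], kg: KnowledgeGraph,
                             qspec: QuerySpec) -> list[ResultRow]:
    """Join bindings against matching expression calls, yielding result rows."""
    index = kg.gene_index()
    allowed = _allowed_terms(kg, qspec)
    calls_by_gene: dict[CurieRef, list] = {}
    for call in kg.calls:
        record = index.get(call.gene)
        if record is not None:
            calls_by_gene.setdefault(record.primary_id, []).append(call)
    rows = []
    for binding in bindings:
        assert binding.human_gene is not None
        for call in calls_by_gene.get(binding.human_gene.primary_id, ()):
            if _call_matches(call, qspec, allowed):
                rows.append(ResultRow(
                    bioresource=binding.bioresource,
                    mouse_gene=binding.mgi,
                    human_gene=_display_gene(binding.human_gene),
                    disease=qspec.disease,
                    anatomical_entity=call.anatomical_entity,
                    confidence=qspec.confidence,
                ))
    return rows


def _display_gene(record: GeneRecord) -> CurieRef:
    """Report human genes by Ensembl ID when available (the familiar key)."""
    return record.ensembl_id if record.ensembl_id is not None else record.primary_id


# ---------------------------------------------------------------------------
# composition

def explore(qspec: QuerySpec, kg: KnowledgeGraph) -> ExplorationResult:
    """Run all four stages, deduplicate, order canonically, then page."""
    b1 = stage1_bioresource_genes(kg)
    b2 = stage2_orthologs(b1, kg)
    b3 = stage3_disease_filter(b2, kg, qspec.disease, qspec.gda_threshold)
    rows = stage4_expression_filter(b3, kg, qspec)
    return ExplorationResult.from_rows(rows, limit=qspec.limit, offset=qspec.offset)


def execute_plan(plan: PlanSpec, qspec: QuerySpec, kg: KnowledgeGraph,
                 expression_shard: Optional[KnowledgeGraph] = None
                 ) -> tuple[ExplorationResult, StageTrace]:
    """Evaluate the exploration under a nesting plan, tracing boundary sizes.

    All plans produce the identical canonical result; they differ only
    in which stage outputs are materialized (and therefore traced).  In
    federated mode the expression subpart is evaluated against a
    separately supplied expression shard, emulating a remote endpoint
    holding only the expression graph.
    """
    if plan.mode == "federated":
        if not plan.expression_endpoint:
            raise PlanConfigError("federated mode requires expression_endpoint")
        if expression_shard is None:
            raise PlanConfigError("federated pipeline evaluation needs an expression shard")
        expr_kg = KnowledgeGraph(
            genes=kg.genes,
            uniprot_links=kg.uniprot_links,
            calls=expression_shard.calls,
            anatomy=expression_shard.anatomy if expression_shard.anatomy.logical_edges() else kg.anatomy,
        )
    else:
        expr_kg = kg

    trace = StageTrace()
    b1 = stage1_bioresource_genes(kg)
    if plan.nesting == "three_subqueries":
        trace.boundaries["subpart1"] = len(b1)
    b2 = stage2_orthologs(b1, kg)
    if plan.nesting in ("two_subqueries", "three_subqueries"):
        trace.boundaries["subpart2"] = len(b2)
    b3 = stage3_disease_filter(b2, kg, qspec.disease, qspec.gda_threshold)
    if plan.nesting in ("one_subquery", "two_subqueries", "three_subqueries"):
        # the binding volume crossing into the expression subpart — in the
        # federated setting, the quantity shipped to the remote endpoint
        trace.boundaries["subpart3"] = len({b.human_gene.primary_id for b in b3})
    rows = stage4_expression_filter(b3, expr_kg, qspec)
    result = ExplorationResult.from_rows(rows, limit=qspec.limit, offset=qspec.offset)
    if plan.nesting == "flat":
        trace.boundaries["flat"] = len(result)
    trace.final_rows = len(result)
    return result, trace


# ---------------------------------------------------------------------------
# oracle

_ORACLE_GUARD = 10_000


def brute_force_oracle(qspec: QuerySpec, kg: KnowledgeGraph) -> ExplorationResult:
    """Naive nested-loop evaluation of the same predicates (test oracle).

    Deliberately avoids the staged pipeline's indexes and join order;
    guarded to small graphs.
    """
    for name, collection in (("bioresources", kg.bioresources), ("genes", kg.genes),
                             ("clusters", kg.clusters), ("gdas", kg.gdas),
                             ("calls", kg.calls)):
        if len(collection) > _ORACLE_GUARD:
            raise OracleTooLargeError(f"{name} has {len(collection)} records (> {_ORACLE_GUARD})")

    by_id = kg.cluster_index()
    index = kg.gene_index()
    allowed = _allowed_terms(kg, qspec)
    rows = []
    for res in kg.bioresources:
        for gene_ref in res.gene_links:
            mouse = index.get(gene_ref)
            if mouse is None or mouse.ncbi_id is None or mouse.ensembl_id is None:
                continue
            mouse_ids = {mouse.ensembl_id} | {
                ref for ref, rec in index.items()
                if rec.primary_id == mouse.primary_id and ref.prefix == "uniprot"}
            for cluster in kg.clusters:
                members = effective_members(cluster, by_id)
                member_ids = {g for g, _ in members}
                if not (mouse_ids & member_ids):
                    continue
                for human_ref, taxon in members:
                    if taxon != HUMAN_TAXON:
                        continue
                    human = index.get(human_ref)
                    if human is None or human.taxon != HUMAN_TAXON:
                        continue
                    has_gda = any(
                        gda.disease == qspec.disease
                        and gda.score >= qspec.gda_threshold
                        and index.get(gda.gene) is not None
                        and index.get(gda.gene).primary_id == human.primary_id
                        for gda in kg.gdas)
                    if not has_gda:
                        continue
                    for call in kg.calls:
                        call_gene = index.get(call.gene)
                        if call_gene is None or call_gene.primary_id != human.primary_id:
                            continue
                        if _call_matches(call, qspec, allowed):
                            rows.append(ResultRow(
                                bioresource=res.resource_id,
                                mouse_gene=mouse.primary_id,
                                human_gene=_display_gene(human),
                                disease=qspec.disease,
                                anatomical_entity=call.anatomical_entity,
                                confidence=qspec.confidence,
                            ))
    return ExplorationResult.from_rows(rows, limit=qspec.limit, offset=qspec.offset)
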