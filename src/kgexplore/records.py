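"""Typed record collections for the integrated knowledge graphs.

A :class:`KnowledgeGraph` bundles six record collections (bioresources,
genes, orthology clusters, gene-disease associations, expression calls,
diseases) with an anatomy :class:`~kgexplore.anatomy.BroaderGraph`.
Records are plain frozen dataclasses keyed by :class:`CurieRef` IDs;
referential integrity across collections is checked by
:func:`validate_kg` rather than enforced at construction time, so that
partially loaded graph shards remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .anatomy import BroaderGraph
from .namespaces import CurieRef

__all__ = [
    "Bioresource",
    "GeneRecord",
    "UniProtLink",
    "OrthologyCluster",
    "GeneDiseaseAssociation",
    "ExpressionCall",
    "Disease",
    "KnowledgeGraph",
    "ValidationIssue",
    "MergeConflictError",
    "validate_kg",
    "merge",
    "MOUSE_TAXON",
    "HUMAN_TAXON",
]

MOUSE_TAXON = CurieRef("taxon", "10090")
HUMAN_TAXON = CurieRef("taxon", "9606")

CONFIDENCE_LEVELS = ("high", "low")
SEX_VALUES = ("any", "male", "female")


@dataclass(frozen=True)
class Bioresource:
    """A catalogued bioresource (here: a genetically modified mouse strain)."""

    resource_id: CurieRef
    label: str = ""
    resource_kind: str = ""
    gene_links: frozenset[CurieRef] = frozenset()


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its cross-references into the other ID spaces."""

    primary_id: CurieRef
    taxon: CurieRef
    label: str = ""
    ncbi_id: Optional[CurieRef] = None
    ensembl_id: Optional[CurieRef] = None
    uniprot_accessions: frozenset[CurieRef] = frozenset()

    def all_ids(self) -> Iterable[CurieRef]:
        yield self.primary_id
        if self.ncbi_id is not None:
            yield self.ncbi_id
        if self.ensembl_id is not None:
            yield self.ensembl_id
        yield from self.uniprot_accessions


@dataclass(frozen=True)
class UniProtLink:
    """An NCBI-gene -> UniProtKB accession mapping row."""

    ncbi_gene: CurieRef
    uniprot: CurieRef


@dataclass(frozen=True)
class OrthologyCluster:
    """A hierarchical orthologous group: genes homologous across species.

    ``members`` are (gene, taxon) pairs; ``children`` may nest further
    clusters.  A mouse and a human gene are orthologous here when some
    cluster's member closure (own members plus all descendants')
    contains both.
    """

    cluster_id: CurieRef
    members: frozenset[tuple[CurieRef, CurieRef]] = frozenset()
    children: frozenset[CurieRef] = frozenset()


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """A scored link between a human gene and a disease concept."""

    gda_id: CurieRef
    gene: CurieRef
    disease: CurieRef
    score: float


@dataclass(frozen=True)
class ExpressionCall:
    """An assertion that a gene is expressed in an anatomical entity."""

    gene: CurieRef
    anatomical_entity: CurieRef
    confidence: str = "high"
    sex: str = "any"
    dev_stage: Optional[CurieRef] = None
    strain: Optional[str] = None
    expression_score: Optional[float] = None


@dataclass(frozen=True)
class Disease:
    """A disease concept keyed by its UMLS CUI."""

    cui: CurieRef
    label: str = ""


@dataclass(frozen=True)
class ValidationIssue:
    record: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.record}.{self.field}: {self.rule}"


class MergeConflictError(ValueError):
    """Two graphs define the same ID with different field values."""

    def __init__(self, record_id: str):
        super().__init__(f"merge conflict on {record_id}")
        self.record_id = record_id


@dataclass
class KnowledgeGraph:
    """Container over the six record collections plus the anatomy graph."""

    bioresources: list[Bioresource] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    uniprot_links: list[UniProtLink] = field(default_factory=list)
    clusters: list[OrthologyCluster] = field(default_factory=list)
    gdas: list[GeneDiseaseAssociation] = field(default_factory=list)
    calls: list[ExpressionCall] = field(default_factory=list)
    diseases: list[Disease] = field(default_factory=list)
    anatomy: BroaderGraph = field(default_factory=BroaderGraph)

    # -- indexes ------------------------------------------------------
    def gene_index(self) -> dict[CurieRef, GeneRecord]:
        """Map every known cross-reference ID to its gene record.

        UniProt link rows are folded in: an accession linked to a gene's
        NCBI ID resolves to that gene even when the gene record itself
        does not carry the accession.
        """
        index: dict[CurieRef, GeneRecord] = {}
        by_ncbi: dict[CurieRef, GeneRecord] = {}
        for gene in self.genes:
            for ref in gene.all_ids():
                index.setdefault(ref, gene)
            if gene.ncbi_id is not None:
                by_ncbi.setdefault(gene.ncbi_id, gene)
        for link in self.uniprot_links:
            target = by_ncbi.get(link.ncbi_gene)
            if target is not None:
                index.setdefault(link.uniprot, target)
        return index

    def disease_index(self) -> dict[CurieRef, Disease]:
        return {d.cui: d for d in self.diseases}

    def cluster_index(self) -> dict[CurieRef, OrthologyCluster]:
        return {c.cluster_id: c for c in self.clusters}


def _field_issues(kg: KnowledgeGraph) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    seen_resources: set[CurieRef] = set()
    for res in kg.bioresources:
        if res.resource_id in seen_resources:
            issues.append(ValidationIssue(str(res.resource_id), "resource_id", "duplicate resource ID"))
        seen_resources.add(res.resource_id)
    per_ns: dict[str, set[CurieRef]] = {}
    seen_primary: set[CurieRef] = set()
    for gene in kg.genes:
        if gene.primary_id in seen_primary:
            issues.append(ValidationIssue(str(gene.primary_id), "primary_id", "duplicate gene ID"))
        seen_primary.add(gene.primary_id)
        if not gene.taxon.local_id:
            issues.append(ValidationIssue(str(gene.primary_id), "taxon", "taxon missing"))
        for ref in (gene.ncbi_id, gene.ensembl_id):
            if ref is None:
                continue
            bucket = per_ns.setdefault(ref.prefix, set())
            if ref in bucket:
                issues.append(ValidationIssue(str(gene.primary_id), "xref", f"cross-reference {ref} reused"))
            bucket.add(ref)
    for gda in kg.gdas:
        if not (0.0 <= gda.score <= 1.0):
            issues.append(ValidationIssue(str(gda.gda_id), "score", f"score {gda.score} outside [0, 1]"))
    for call in kg.calls:
        if call.confidence not in CONFIDENCE_LEVELS:
            issues.append(ValidationIssue(str(call.gene), "confidence", f"confidence {call.confidence!r} not in {CONFIDENCE_LEVELS}"))
        if call.sex not in SEX_VALUES:
            issues.append(ValidationIssue(str(call.gene), "sex", f"sex {call.sex!r} not in {SEX_VALUES}"))
    seen_cui: set[CurieRef] = set()
    for disease in kg.diseases:
        if disease.cui in seen_cui:
            issues.append(ValidationIssue(str(disease.cui), "cui", "duplicate disease CUI"))
        seen_cui.add(disease.cui)
    # cluster nesting must be acyclic
    children = {c.cluster_id: set(c.children) for c in kg.clusters}
    state: dict[CurieRef, int] = {}

    def has_cycle(node: CurieRef) -> bool:
        state[node] = 1
        for child in children.get(node, ()):  # unknown children checked in strict mode
            mark = state.get(child, 0)
            if mark == 1 or (mark == 0 and has_cycle(child)):
                return True
        state[node] = 2
        return False

    for cid in children:
        if state.get(cid, 0) == 0 and has_cycle(cid):
            issues.append(ValidationIssue(str(cid), "children", "cluster nesting cycle"))
            break
    return issues


def _referential_issues(kg: KnowledgeGraph) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    genes = kg.gene_index()
    diseases = kg.disease_index()
    clusters = kg.cluster_index()
    for res in kg.bioresources:
        for ref in sorted(res.gene_links):
            if ref not in genes:
                issues.append(ValidationIssue(str(res.resource_id), "gene_links", f"dangling gene reference {ref}"))
    for cluster in kg.clusters:
        for gene_ref, taxon in sorted(cluster.members):
            record = genes.get(gene_ref)
            if record is None:
                issues.append(ValidationIssue(str(cluster.cluster_id), "members", f"dangling member gene {gene_ref}"))
            elif record.taxon != taxon:
                issues.append(ValidationIssue(str(cluster.cluster_id), "members", f"member {gene_ref} taxon {taxon} != record taxon {record.taxon}"))
        for child in sorted(cluster.children):
            if child not in clusters:
                issues.append(ValidationIssue(str(cluster.cluster_id), "children", f"dangling child cluster {child}"))
    for gda in kg.gdas:
        if gda.gene not in genes:
            issues.append(ValidationIssue(str(gda.gda_id), "gene", f"dangling gene reference {gda.gene}"))
        if gda.disease not in diseases:
            issues.append(ValidationIssue(str(gda.gda_id), "disease", f"dangling disease reference {gda.disease}"))
    for call in kg.calls:
        if call.gene not in genes:
            issues.append(ValidationIssue(str(call.gene), "gene", "expression call references unknown gene"))
    return issues


def validate_kg(kg: KnowledgeGraph, strict: bool = False) -> list[ValidationIssue]:
    """Check type invariants, and referential integrity when ``strict``.

    Returns a list of issues (empty iff valid); never raises.
    """
    issues = _field_issues(kg)
    if strict:
        issues.extend(_referential_issues(kg))
    return issues


def _merge_keyed(records: Sequence, key) -> list:
    out: dict = {}
    for rec in records:
        k = key(rec)
        prev = out.get(k)
        if prev is None:
            out[k] = rec
        elif prev != rec:
            raise MergeConflictError(str(k))
    return list(out.values())


def _merge_plain(records: Sequence) -> list:
    out = []
    seen = set()
    for rec in records:
        if rec not in seen:
            seen.add(rec)
            out.append(rec)
    return out


def merge(kgs: Iterable[KnowledgeGraph]) -> KnowledgeGraph:
    """Union several graphs; equal records deduplicate.

    Records sharing an ID but differing in any field raise
    :class:`MergeConflictError` naming the ID.
    """
    kgs = list(kgs)
    anatomy = BroaderGraph()
    for kg in kgs:
        anatomy = anatomy.union(kg.anatomy)
    return KnowledgeGraph(
        bioresources=_merge_keyed([r for kg in kgs for r in kg.bioresources], lambda r: r.resource_id),
        genes=_merge_keyed([g for kg in kgs for g in kg.genes], lambda g: g.primary_id),
        uniprot_links=_merge_plain([u for kg in kgs for u in kg.uniprot_links]),
        clusters=_merge_keyed([c for kg in kgs for c in kg.clusters], lambda c: c.cluster_id),
        gdas=_merge_keyed([g for kg in kgs for g in kg.gdas], lambda g: g.gda_id),
        calls=_merge_plain([c for kg in kgs for c in kg.calls]),
        diseases=_merge_keyed([d for kg in kgs for d in kg.diseases], lambda d: d.cui),
        anatomy=anatomy,
    )
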