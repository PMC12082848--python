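"""Reading and writing the named-graph serializations and KGX edges.

Each of the integrated graph kinds (bioresource, gene ID mapping,
UniProt mapping, orthology, gene-disease association, expression,
flattened anatomy) has a :class:`GraphDialect` mapping record-field
roles to predicate IRIs.  The defaults follow the vocabularies the
source databases publish where those are well known (``lscr`` cross
references, ``orth`` homology, ``sio`` associations, ``genex``
expression conditions) and fall back to predicates minted under the
same namespaces where a source vocabulary is release-dependent; every
predicate is overridable, per dialect, from a YAML config.

Turtle output is emitted sorted by (subject, predicate, object) IRI so
that equal collections serialize byte-identically.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import rdflib
import yaml
from rdflib import URIRef

from .anatomy import (BROADER_PREDICATE, PARTOF_FILENAME, SUBCLASS_FILENAME,
                      AnatomyEdge, BroaderGraph, split_serialize, to_broader)
from .namespaces import CurieRef, NamespaceTable, default_table
from .records import (Bioresource, Disease, ExpressionCall,
                      GeneDiseaseAssociation, GeneRecord, KnowledgeGraph,
                      OrthologyCluster, UniProtLink)

__all__ = [
    "GraphDialect",
    "KgxEdgeRow",
    "KgxReadResult",
    "GdaCollection",
    "MalformedKgxError",
    "ParseFailureError",
    "InvalidRecordError",
    "default_dialect",
    "read_kgx_edges",
    "kgx_to_anatomy_edges",
    "read_named_graph",
    "write_named_graph",
    "read_kg",
    "write_kg",
    "load_config",
    "GRAPH_KINDS",
]

GRAPH_KINDS = (
    "bioresource",
    "mgi_mapping",
    "uniprot_mapping",
    "orthology",
    "gda",
    "expression",
    "anatomy_broader",
)


class MalformedKgxError(ValueError):
    """A KGX TSV stream is missing a mandatory column."""

    def __init__(self, column: str):
        super().__init__(f"KGX file missing mandatory column {column!r}")
        self.column = column


class ParseFailureError(ValueError):
    """A named-graph serialization could not be parsed."""


class InvalidRecordError(ValueError):
    """A record violates its type invariants and cannot be serialized."""


# ---------------------------------------------------------------------------
# dialects

_SIO = "http://semanticscience.org/resource/"
_LSCR = "http://purl.org/lscr#"
_ORTH = "http://purl.org/net/orth#"
_GENEX = "http://purl.org/genex#"
_BRSO = "http://purl.jp/bio/10/brso/"
_RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
_RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
_IN_TAXON = "http://purl.obolibrary.org/obo/RO_0002162"

_DEFAULT_PREDICATES: dict[str, dict[str, str]] = {
    "bioresource": {
        "type": _BRSO + "Bioresource",
        "label": _RDFS_LABEL,
        "resource_kind": _BRSO + "bioresourceType",
        "gene": _BRSO + "gene",
    },
    "mgi_mapping": {
        "type": _ORTH + "Gene",
        "label": _RDFS_LABEL,
        "taxon": _IN_TAXON,
        "xref_ncbi": _LSCR + "xrefNCBIGene",
        "xref_ensembl": _LSCR + "xrefEnsemblGene",
        "xref_uniprot": _LSCR + "xrefUniprot",
    },
    "uniprot_mapping": {
        "xref_uniprot": _LSCR + "xrefUniprot",
    },
    "orthology": {
        "type": _ORTH + "OrthologsCluster",
        "member": _ORTH + "hasHomologousMember",
        "child": _ORTH + "hasSubCluster",
        "taxon": _IN_TAXON,
    },
    "gda": {
        "type": _SIO + "SIO_001121",
        "refers_to": _SIO + "SIO_000628",
        "score": _SIO + "SIO_000300",
        "disease_type": _SIO + "SIO_010299",
        "label": _RDFS_LABEL,
    },
    "expression": {
        "type": _GENEX + "Expression",
        "gene": _GENEX + "hasSequenceUnit",
        "anatomical_entity": _GENEX + "hasAnatomicalEntity",
        "confidence": _GENEX + "hasConfidenceLevel",
        "sex": _GENEX + "hasSex",
        "dev_stage": _GENEX + "hasDevelopmentalStage",
        "strain": _GENEX + "hasStrain",
        "score": _GENEX + "hasExpressionScore",
    },
    "anatomy_broader": {
        "broader": BROADER_PREDICATE,
    },
}


@dataclass(frozen=True)
class GraphDialect:
    """Predicate vocabulary for one graph kind."""

    graph_kind: str
    predicate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.graph_kind not in GRAPH_KINDS:
            raise ValueError(f"unknown graph kind {self.graph_kind!r}")
        required = set(_DEFAULT_PREDICATES[self.graph_kind])
        missing = required - set(self.predicate_map)
        if missing:
            raise ValueError(f"dialect for {self.graph_kind} missing roles: {sorted(missing)}")

    def iri(self, role: str) -> str:
        return self.predicate_map[role]


def default_dialect(graph_kind: str, overrides: Optional[dict[str, str]] = None) -> GraphDialect:
    """The built-in dialect for a graph kind, with optional role overrides."""
    if graph_kind not in _DEFAULT_PREDICATES:
        raise ValueError(f"unknown graph kind {graph_kind!r}")
    pmap = dict(_DEFAULT_PREDICATES[graph_kind])
    pmap.update(overrides or {})
    return GraphDialect(graph_kind, pmap)


# ---------------------------------------------------------------------------
# KGX TSV

@dataclass(frozen=True)
class KgxEdgeRow:
    subject: CurieRef
    predicate: str
    object: CurieRef
    relation: Optional[str] = None


@dataclass
class KgxReadResult:
    rows: list[KgxEdgeRow]
    dropped: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def read_kgx_edges(stream: Union[str, io.TextIOBase]) -> KgxReadResult:
    """Parse a KGX edge TSV into rows; blank-field rows are dropped and counted.

    The header must name at least ``subject``, ``predicate`` and
    ``object`` columns; a ``relation`` column, when present, is kept and
    later treated as authoritative for part-of detection.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter="\t")
    header = reader.fieldnames or []
    for column in ("subject", "predicate", "object"):
        if column not in header:
            raise MalformedKgxError(column)
    has_relation = "relation" in header
    result = KgxReadResult(rows=[])
    for raw in reader:
        subject = (raw.get("subject") or "").strip()
        predicate = (raw.get("predicate") or "").strip()
        obj = (raw.get("object") or "").strip()
        if not subject or not predicate or not obj:
            result.dropped += 1
            continue
        relation = (raw.get("relation") or "").strip() if has_relation else ""
        result.rows.append(KgxEdgeRow(
            subject=_as_curie(subject),
            predicate=predicate,
            object=_as_curie(obj),
            relation=relation or None,
        ))
    return result


def _as_curie(text: str) -> CurieRef:
    if text.startswith("http://") or text.startswith("https://"):
        ref = default_table().try_compact(text)
        if ref is not None:
            return ref
        return CurieRef("_iri", text)  # opaque full-IRI passthrough
    ref = CurieRef.parse(text)
    if ref.prefix not in default_table() and ref.prefix.isalpha():
        # OBO-style CURIEs (UBERON:0001419) live under the obo namespace
        # as PREFIX_local IRIs
        return CurieRef("obo", f"{ref.prefix}_{ref.local_id}")
    return ref


_SUBCLASS_SPELLINGS = {
    "rdfs:subClassOf",
    "subClassOf",
    "http://www.w3.org/2000/01/rdf-schema#subClassOf",
    "biolink:subclass_of",
    "https://w3id.org/biolink/vocab/subclass_of",
}
_PARTOF_SPELLINGS = {
    "BFO:0000050",
    "bfo:0000050",
    "obo:BFO_0000050",
    "http://purl.obolibrary.org/obo/BFO_0000050",
    "biolink:part_of",
    "https://w3id.org/biolink/vocab/part_of",
}


def kgx_to_anatomy_edges(rows: Iterable[KgxEdgeRow]) -> tuple[list[AnatomyEdge], int]:
    """Classify KGX rows into subClassOf / partOf anatomy edges.

    The ``relation`` column, when present, decides part-of detection;
    otherwise the ``predicate`` spelling does.  Rows under any other
    relation (develops_from etc.) and self-loops are ignored and
    counted.  Returns ``(edges, ignored_count)``.
    """
    edges: list[AnatomyEdge] = []
    ignored = 0
    for row in rows:
        spelling = row.relation if row.relation else row.predicate
        if spelling in _PARTOF_SPELLINGS:
            relation = "partOf"
        elif spelling in _SUBCLASS_SPELLINGS or row.predicate in _SUBCLASS_SPELLINGS:
            relation = "subClassOf"
        else:
            ignored += 1
            continue
        if row.subject == row.object:
            ignored += 1
            continue
        edges.append(AnatomyEdge(row.subject, relation, row.object))
    return edges, ignored


# ---------------------------------------------------------------------------
# deterministic Turtle emission

def _escape(text: str) -> str:
    return (text.replace("\\", "\\\\").replace('"', '\\"')
                .replace("\n", "\\n").replace("\r", "\\r"))


def _term(value, table: NamespaceTable) -> str:
    if isinstance(value, CurieRef):
        ref = value if value.prefix in table else None
        if ref is not None:
            return f"{ref.prefix}:{ref.local_id}"
        return f"<{value.local_id}>" if value.prefix == "_iri" else f"<{value}>"
    if isinstance(value, str) and (value.startswith("http://") or value.startswith("https://")):
        ref = table.try_compact(value)
        if ref is not None:
            return f"{ref.prefix}:{ref.local_id}"
        return f"<{value}>"
    if isinstance(value, float):
        return repr(value) if value != int(value) else f"{value:.1f}"
    return f'"{_escape(str(value))}"'


def _used_prefix(value, table: NamespaceTable, prefixes: set[str]) -> None:
    if isinstance(value, CurieRef) and value.prefix in table:
        prefixes.add(value.prefix)
    elif isinstance(value, str) and (value.startswith("http://") or value.startswith("https://")):
        ref = table.try_compact(value)
        if ref is not None:
            prefixes.add(ref.prefix)


def _emit_turtle(triples: list[tuple], table: NamespaceTable) -> str:
    prefixes: set[str] = set()
    rendered = []
    for s, p, o in triples:
        for value in (s, p, o):
            _used_prefix(value, table, prefixes)
        rendered.append((_term(s, table), _term(p, table), _term(o, table)))
    rendered.sort()
    lines = [f"@prefix {p}: <{table.iri(p)}> ." for p in sorted(prefixes)]
    lines.append("")
    seen = set()
    for s, p, o in rendered:
        statement = f"{s} {p} {o} ."
        if statement not in seen:
            seen.add(statement)
            lines.append(statement)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# writing record collections

@dataclass
class GdaCollection:
    """The gene-disease named graph: scored associations plus disease labels."""

    associations: list[GeneDiseaseAssociation] = field(default_factory=list)
    diseases: list[Disease] = field(default_factory=list)


def _bioresource_triples(records: Iterable[Bioresource], d: GraphDialect):
    for r in records:
        yield (r.resource_id, _RDF_TYPE, d.iri("type"))
        if r.label:
            yield (r.resource_id, d.iri("label"), r.label)
        if r.resource_kind:
            yield (r.resource_id, d.iri("resource_kind"), r.resource_kind)
        for gene in sorted(r.gene_links):
            yield (r.resource_id, d.iri("gene"), gene)


def _gene_triples(records: Iterable[GeneRecord], d: GraphDialect):
    for g in records:
        yield (g.primary_id, _RDF_TYPE, d.iri("type"))
        yield (g.primary_id, d.iri("taxon"), g.taxon)
        if g.label:
            yield (g.primary_id, d.iri("label"), g.label)
        if g.ncbi_id is not None:
            yield (g.primary_id, d.iri("xref_ncbi"), g.ncbi_id)
        if g.ensembl_id is not None:
            yield (g.primary_id, d.iri("xref_ensembl"), g.ensembl_id)
        for acc in sorted(g.uniprot_accessions):
            yield (g.primary_id, d.iri("xref_uniprot"), acc)


def _uniprot_triples(records: Iterable[UniProtLink], d: GraphDialect):
    for link in records:
        yield (link.ncbi_gene, d.iri("xref_uniprot"), link.uniprot)


def _cluster_triples(records: Iterable[OrthologyCluster], d: GraphDialect):
    for c in records:
        yield (c.cluster_id, _RDF_TYPE, d.iri("type"))
        for gene, taxon in sorted(c.members):
            yield (c.cluster_id, d.iri("member"), gene)
            yield (gene, d.iri("taxon"), taxon)
        for child in sorted(c.children):
            yield (c.cluster_id, d.iri("child"), child)


def _gda_triples(collection: GdaCollection, d: GraphDialect):
    for g in collection.associations:
        if not (0.0 <= g.score <= 1.0):
            raise InvalidRecordError(f"GDA {g.gda_id} score {g.score} outside [0, 1]")
        yield (g.gda_id, _RDF_TYPE, d.iri("type"))
        yield (g.gda_id, d.iri("refers_to"), g.gene)
        yield (g.gda_id, d.iri("refers_to"), g.disease)
        yield (g.gda_id, d.iri("score"), float(g.score))
    for disease in collection.diseases:
        yield (disease.cui, _RDF_TYPE, d.iri("disease_type"))
        if disease.label:
            yield (disease.cui, d.iri("label"), disease.label)


def _call_node(index: int) -> CurieRef:
    return CurieRef("bgee", f"call{index:06d}")


def _call_sort_key(c: ExpressionCall):
    return (str(c.gene), str(c.anatomical_entity), c.confidence, c.sex,
            str(c.dev_stage or ""), c.strain or "",
            -1.0 if c.expression_score is None else c.expression_score)


def _expression_triples(records: Iterable[ExpressionCall], d: GraphDialect):
    for i, c in enumerate(sorted(records, key=_call_sort_key)):
        node = _call_node(i)
        yield (node, _RDF_TYPE, d.iri("type"))
        yield (node, d.iri("gene"), c.gene)
        yield (node, d.iri("anatomical_entity"), c.anatomical_entity)
        yield (node, d.iri("confidence"), c.confidence)
        yield (node, d.iri("sex"), c.sex)
        if c.dev_stage is not None:
            yield (node, d.iri("dev_stage"), c.dev_stage)
        if c.strain is not None:
            yield (node, d.iri("strain"), c.strain)
        if c.expression_score is not None:
            yield (node, d.iri("score"), float(c.expression_score))


def write_named_graph(records, dialect: GraphDialect,
                      table: Optional[NamespaceTable] = None) -> str:
    """Serialize a typed record collection as sorted Turtle text."""
    table = table or default_table()
    kind = dialect.graph_kind
    if kind == "anatomy_broader":
        partof, subclassof = split_serialize(records, table, dialect.iri("broader"))
        return partof + "\n" + subclassof
    makers = {
        "bioresource": _bioresource_triples,
        "mgi_mapping": _gene_triples,
        "uniprot_mapping": _uniprot_triples,
        "orthology": _cluster_triples,
        "gda": _gda_triples,
        "expression": _expression_triples,
    }
    return _emit_turtle(list(makers[kind](records, dialect)), table)


# ---------------------------------------------------------------------------
# reading record collections

def _parse_turtle(text: str) -> rdflib.Graph:
    g = rdflib.Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises several exception types
        raise ParseFailureError(f"Turtle parse failure: {exc}") from exc
    return g


def _compact(term, table: NamespaceTable) -> CurieRef:
    iri = str(term)
    ref = table.try_compact(iri)
    return ref if ref is not None else CurieRef("_iri", iri)


@dataclass
class ReadResult:
    """A typed collection plus warnings about unresolvable references."""

    records: object
    warnings: list[str] = field(default_factory=list)


def read_named_graph(stream: Union[str, io.TextIOBase], dialect: GraphDialect,
                     table: Optional[NamespaceTable] = None) -> ReadResult:
    """Parse a named-graph Turtle serialization into its typed collection.

    Unknown predicates are ignored; nodes referenced but not declared in
    the document surface in the warnings list.
    """
    table = table or default_table()
    if not isinstance(stream, str):
        stream = stream.read()
    graph = _parse_turtle(stream)
    kind = dialect.graph_kind
    readers = {
        "bioresource": _read_bioresources,
        "mgi_mapping": _read_genes,
        "uniprot_mapping": _read_uniprot_links,
        "orthology": _read_clusters,
        "gda": _read_gda,
        "expression": _read_calls,
        "anatomy_broader": _read_broader,
    }
    return readers[kind](graph, dialect, table)


def _objects(graph, subject, predicate_iri):
    return list(graph.objects(subject, URIRef(predicate_iri)))


def _first_literal(graph, subject, predicate_iri) -> str:
    for obj in _objects(graph, subject, predicate_iri):
        return str(obj)
    return ""


def _read_bioresources(graph, d, table) -> ReadResult:
    records = []
    for node in sorted(graph.subjects(URIRef(_RDF_TYPE), URIRef(d.iri("type")))):
        records.append(Bioresource(
            resource_id=_compact(node, table),
            label=_first_literal(graph, node, d.iri("label")),
            resource_kind=_first_literal(graph, node, d.iri("resource_kind")),
            gene_links=frozenset(_compact(o, table) for o in _objects(graph, node, d.iri("gene"))),
        ))
    return ReadResult(records)


def _read_genes(graph, d, table) -> ReadResult:
    records = []
    warnings = []
    for node in sorted(graph.subjects(URIRef(_RDF_TYPE), URIRef(d.iri("type")))):
        taxa = _objects(graph, node, d.iri("taxon"))
        if not taxa:
            warnings.append(f"gene {node} lacks a taxon")
            continue
        ncbi = _objects(graph, node, d.iri("xref_ncbi"))
        ensembl = _objects(graph, node, d.iri("xref_ensembl"))
        records.append(GeneRecord(
            primary_id=_compact(node, table),
            taxon=_compact(taxa[0], table),
            label=_first_literal(graph, node, d.iri("label")),
            ncbi_id=_compact(ncbi[0], table) if ncbi else None,
            ensembl_id=_compact(ensembl[0], table) if ensembl else None,
            uniprot_accessions=frozenset(
                _compact(o, table) for o in _objects(graph, node, d.iri("xref_uniprot"))),
        ))
    return ReadResult(records, warnings)


def _read_uniprot_links(graph, d, table) -> ReadResult:
    records = []
    for s, _, o in graph.triples((None, URIRef(d.iri("xref_uniprot")), None)):
        records.append(UniProtLink(_compact(s, table), _compact(o, table)))
    records.sort(key=lambda r: (str(r.ncbi_gene), str(r.uniprot)))
    return ReadResult(records)


def _read_clusters(graph, d, table) -> ReadResult:
    records = []
    warnings = []
    taxon_of = {}
    for s, _, o in graph.triples((None, URIRef(d.iri("taxon")), None)):
        taxon_of[_compact(s, table)] = _compact(o, table)
    for node in sorted(graph.subjects(URIRef(_RDF_TYPE), URIRef(d.iri("type")))):
        members = set()
        for obj in _objects(graph, node, d.iri("member")):
            gene = _compact(obj, table)
            taxon = taxon_of.get(gene)
            if taxon is None:
                warnings.append(f"cluster member {gene} has no taxon statement")
                continue
            members.add((gene, taxon))
        records.append(OrthologyCluster(
            cluster_id=_compact(node, table),
            members=frozenset(members),
            children=frozenset(_compact(o, table) for o in _objects(graph, node, d.iri("child"))),
        ))
    declared = {c.cluster_id for c in records}
    for c in records:
        for child in sorted(c.children):
            if child not in declared:
                warnings.append(f"cluster {c.cluster_id} references undeclared child {child}")
    return ReadResult(records, warnings)


def _read_gda(graph, d, table) -> ReadResult:
    associations = []
    warnings = []
    disease_class = URIRef(d.iri("disease_type"))
    disease_nodes = set(graph.subjects(URIRef(_RDF_TYPE), disease_class))
    for node in sorted(graph.subjects(URIRef(_RDF_TYPE), URIRef(d.iri("type")))):
        refs = [_compact(o, table) for o in _objects(graph, node, d.iri("refers_to"))]
        scores = _objects(graph, node, d.iri("score"))
        if not scores:
            warnings.append(f"association {node} lacks a score")
            continue
        try:
            score = float(scores[0])
        except (ValueError, TypeError) as exc:
            raise ParseFailureError(f"non-numeric score on association node {node}") from exc
        disease_refs = [r for r in refs if r.prefix == "umls"]
        gene_refs = [r for r in refs if r.prefix != "umls"]
        if not disease_refs or not gene_refs:
            warnings.append(f"association {node} lacks a gene or disease reference")
            continue
        associations.append(GeneDiseaseAssociation(
            gda_id=_compact(node, table),
            gene=gene_refs[0],
            disease=disease_refs[0],
            score=score,
        ))
    diseases = [Disease(cui=_compact(n, table), label=_first_literal(graph, n, d.iri("label")))
                for n in sorted(disease_nodes)]
    return ReadResult(GdaCollection(associations, diseases), warnings)


def _read_calls(graph, d, table) -> ReadResult:
    records = []
    for node in sorted(graph.subjects(URIRef(_RDF_TYPE), URIRef(d.iri("type")))):
        genes = _objects(graph, node, d.iri("gene"))
        anats = _objects(graph, node, d.iri("anatomical_entity"))
        if not genes or not anats:
            continue
        stage = _objects(graph, node, d.iri("dev_stage"))
        strain = _first_literal(graph, node, d.iri("strain"))
        score = _objects(graph, node, d.iri("score"))
        records.append(ExpressionCall(
            gene=_compact(genes[0], table),
            anatomical_entity=_compact(anats[0], table),
            confidence=_first_literal(graph, node, d.iri("confidence")) or "high",
            sex=_first_literal(graph, node, d.iri("sex")) or "any",
            dev_stage=_compact(stage[0], table) if stage else None,
            strain=strain or None,
            expression_score=float(score[0]) if score else None,
        ))
    records.sort(key=_call_sort_key)
    return ReadResult(records)


def _read_broader(graph, d, table) -> ReadResult:
    # a single document cannot distinguish the two source tags; edges land
    # in from_subclassof unless read through read_kg's split files.
    edges = set()
    for s, _, o in graph.triples((None, URIRef(d.iri("broader")), None)):
        edges.add((_compact(s, table), _compact(o, table)))
    return ReadResult(BroaderGraph(from_subclassof=edges))


# ---------------------------------------------------------------------------
# directory-level KG persistence

_KIND_FILENAMES = {
    "bioresource": "bioresource.ttl",
    "mgi_mapping": "gene_mapping.ttl",
    "uniprot_mapping": "uniprot_mapping.ttl",
    "orthology": "orthology.ttl",
    "gda": "gda.ttl",
    "expression": "expression.ttl",
}


def write_kg(kg: KnowledgeGraph, out_dir: Union[str, Path],
             dialects: Optional[dict[str, GraphDialect]] = None,
             table: Optional[NamespaceTable] = None) -> list[Path]:
    """Write one Turtle file per graph kind; anatomy as its two split files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = table or default_table()
    dialects = dialects or {}
    written = []
    collections = {
        "bioresource": kg.bioresources,
        "mgi_mapping": kg.genes,
        "uniprot_mapping": kg.uniprot_links,
        "orthology": kg.clusters,
        "gda": GdaCollection(kg.gdas, kg.diseases),
        "expression": kg.calls,
    }
    for kind, filename in _KIND_FILENAMES.items():
        dialect = dialects.get(kind, default_dialect(kind))
        path = out_dir / filename
        path.write_text(write_named_graph(collections[kind], dialect, table), encoding="utf-8")
        written.append(path)
    anatomy_dialect = dialects.get("anatomy_broader", default_dialect("anatomy_broader"))
    partof, subclassof = split_serialize(kg.anatomy, table, anatomy_dialect.iri("broader"))
    for filename, text in ((PARTOF_FILENAME, partof), (SUBCLASS_FILENAME, subclassof)):
        path = out_dir / filename
        path.write_text(text, encoding="utf-8")
        written.append(path)
    return written


def read_kg(in_dir: Union[str, Path],
            dialects: Optional[dict[str, GraphDialect]] = None,
            table: Optional[NamespaceTable] = None) -> KnowledgeGraph:
    """Load a knowledge graph from a directory written by :func:`write_kg`.

    Missing files yield empty collections, so graph shards load cleanly.
    """
    in_dir = Path(in_dir)
    table = table or default_table()
    dialects = dialects or {}

    def _read(kind):
        path = in_dir / _KIND_FILENAMES[kind]
        if not path.exists():
            return None
        dialect = dialects.get(kind, default_dialect(kind))
        return read_named_graph(path.read_text(encoding="utf-8"), dialect, table).records

    gda = _read("gda") or GdaCollection()
    anatomy = BroaderGraph()
    anatomy_dialect = dialects.get("anatomy_broader", default_dialect("anatomy_broader"))
    partof_path = in_dir / PARTOF_FILENAME
    subclass_path = in_dir / SUBCLASS_FILENAME
    if partof_path.exists():
        parsed = read_named_graph(partof_path.read_text(encoding="utf-8"), anatomy_dialect, table)
        anatomy.from_partof |= parsed.records.from_subclassof
    if subclass_path.exists():
        parsed = read_named_graph(subclass_path.read_text(encoding="utf-8"), anatomy_dialect, table)
        anatomy.from_subclassof |= parsed.records.from_subclassof
    return KnowledgeGraph(
        bioresources=_read("bioresource") or [],
        genes=_read("mgi_mapping") or [],
        uniprot_links=_read("uniprot_mapping") or [],
        clusters=_read("orthology") or [],
        gdas=gda.associations,
        calls=_read("expression") or [],
        diseases=gda.diseases,
        anatomy=anatomy,
    )


# ---------------------------------------------------------------------------
# config

def load_config(path: Union[str, Path]) -> tuple[NamespaceTable, dict[str, GraphDialect]]:
    """Load namespace extensions and dialect predicate overrides from YAML.

    Schema::

        namespaces:
          myprefix: "http://example.org/ns/"
        dialects:
          expression:
            confidence: "http://example.org/ns/confidenceLevel"
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    table = default_table()
    table.update(data.get("namespaces", {}))
    dialects = {}
    for kind, overrides in (data.get("dialects") or {}).items():
        dialects[kind] = default_dialect(kind, overrides)
    return table, dialects
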