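"""Flattening a mixed subClassOf / part-of anatomy hierarchy.

Cross-species anatomy ontologies link terms through a mixture of
``rdfs:subClassOf`` and ``BFO:0000050`` (part of) relations nested to
unknown depth, which makes transitive retrieval ("all parts and kinds
of skin of body") awkward to express directly over the OWL
serialization.  The approach implemented here rewrites both relations
into a single directed narrower->broader predicate, after which
reflexive-transitive descendant queries become plain graph reachability
(or a one-line SPARQL property path).

The flattened graph keeps the provenance of every edge (which of the
two source relations produced it) so the two derived Turtle files can
be written separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import networkx as nx

from .namespaces import CurieRef, NamespaceTable, default_table

__all__ = [
    "AnatomyEdge",
    "BroaderGraph",
    "BROADER_PREDICATE",
    "PARTOF_FILENAME",
    "SUBCLASS_FILENAME",
    "to_broader",
    "split_serialize",
    "descendants",
    "min_broader_path",
    "check_acyclic",
]

#: Default IRI of the flattened predicate (SKOS "has broader concept").
BROADER_PREDICATE = "http://www.w3.org/2004/02/skos/core#broader"

PARTOF_FILENAME = "subject_broader_object_from_BFO_0000050.ttl"
SUBCLASS_FILENAME = "subject_broader_object_from_subClassOf.ttl"

Relation = Literal["subClassOf", "partOf"]


@dataclass(frozen=True)
class AnatomyEdge:
    """One narrower -> broader ontology edge before flattening."""

    narrower: CurieRef
    relation: Relation
    broader_term: CurieRef

    def __post_init__(self):
        if self.relation not in ("subClassOf", "partOf"):
            raise ValueError(f"relation must be subClassOf or partOf, got {self.relation!r}")
        if self.narrower == self.broader_term:
            raise ValueError(f"self-loop edge on {self.narrower}")


@dataclass
class BroaderGraph:
    """Directed narrower->broader edges tagged by source relation.

    Closure semantics treat an edge present under both tags as a single
    logical edge; the tags matter only for split serialization.
    """

    from_partof: set[tuple[CurieRef, CurieRef]] = field(default_factory=set)
    from_subclassof: set[tuple[CurieRef, CurieRef]] = field(default_factory=set)

    def logical_edges(self) -> set[tuple[CurieRef, CurieRef]]:
        return self.from_partof | self.from_subclassof

    def terms(self) -> set[CurieRef]:
        nodes: set[CurieRef] = set()
        for n, b in self.logical_edges():
            nodes.add(n)
            nodes.add(b)
        return nodes

    def union(self, other: "BroaderGraph") -> "BroaderGraph":
        return BroaderGraph(
            from_partof=self.from_partof | other.from_partof,
            from_subclassof=self.from_subclassof | other.from_subclassof,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BroaderGraph):
            return NotImplemented
        return (self.from_partof == other.from_partof
                and self.from_subclassof == other.from_subclassof)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms())
        g.add_edges_from(self.logical_edges())
        return g


def to_broader(edges: Iterable[AnatomyEdge]) -> BroaderGraph:
    """Flatten subClassOf/partOf edges into one broader-edge set.

    Every input edge yields exactly one narrower->broader edge tagged by
    its source relation; duplicates within a tag collapse.
    """
    g = BroaderGraph()
    for edge in edges:
        pair = (edge.narrower, edge.broader_term)
        if edge.relation == "partOf":
            g.from_partof.add(pair)
        else:
            g.from_subclassof.add(pair)
    return g


def _serialize_edges(edges: set[tuple[CurieRef, CurieRef]],
                     table: NamespaceTable,
                     predicate_iri: str) -> str:
    # rdflib's turtle serializer does not guarantee statement order, so
    # triples are written directly, sorted by expanded subject IRI.
    used_prefixes = {"skos"} if predicate_iri == BROADER_PREDICATE else set()
    rows = []
    for narrower, broader in edges:
        rows.append((table.expand(narrower), table.expand(broader), narrower, broader))
        used_prefixes.add(narrower.prefix)
        used_prefixes.add(broader.prefix)
    rows.sort()
    pred = "skos:broader" if predicate_iri == BROADER_PREDICATE else f"<{predicate_iri}>"
    lines = [f"@prefix {p}: <{table.iri(p)}> ." for p in sorted(used_prefixes)]
    lines.append("")
    for _, _, narrower, broader in rows:
        lines.append(f"{narrower.prefix}:{narrower.local_id} {pred} {broader.prefix}:{broader.local_id} .")
    return "\n".join(lines) + "\n"


def split_serialize(g: BroaderGraph,
                    table: Optional[NamespaceTable] = None,
                    predicate_iri: str = BROADER_PREDICATE) -> tuple[str, str]:
    """Serialize the two tagged edge subsets as separate Turtle texts.

    Returns ``(partof_ttl, subclassof_ttl)`` — the part-of-derived edges
    first, matching the two derived ontology files this method ships.
    """
    table = table or default_table()
    return (
        _serialize_edges(g.from_partof, table, predicate_iri),
        _serialize_edges(g.from_subclassof, table, predicate_iri),
    )


def descendants(g: BroaderGraph, root: CurieRef, reflexive: bool = True) -> set[CurieRef]:
    """All terms with a directed broader path to ``root``.

    Reflexive by default: the root itself is part of its own expansion,
    so a query term always matches its own expression calls.  Cycles,
    if present, are tolerated (fixed-point reachability).
    """
    incoming: dict[CurieRef, set[CurieRef]] = {}
    for narrower, broader in g.logical_edges():
        incoming.setdefault(broader, set()).add(narrower)
    seen: set[CurieRef] = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in incoming.get(node, ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    if not reflexive:
        seen.discard(root)
    return seen


def min_broader_path(g: BroaderGraph, from_term: CurieRef, to_term: CurieRef) -> Optional[int]:
    """Length of the shortest directed broader path, or None if unreachable."""
    if from_term == to_term:
        return 0
    outgoing: dict[CurieRef, set[CurieRef]] = {}
    for narrower, broader in g.logical_edges():
        outgoing.setdefault(narrower, set()).add(broader)
    frontier = {from_term}
    seen = {from_term}
    dist = 0
    while frontier:
        dist += 1
        nxt: set[CurieRef] = set()
        for node in frontier:
            for parent in outgoing.get(node, ()):
                if parent == to_term:
                    return dist
                if parent not in seen:
                    seen.add(parent)
                    nxt.add(parent)
        frontier = nxt
    return None


@dataclass
class CycleReport:
    cycles: list[list[CurieRef]] = field(default_factory=list)

    @property
    def is_acyclic(self) -> bool:
        return not self.cycles


def check_acyclic(g: BroaderGraph) -> CycleReport:
    """Report directed cycles in the logical edge set (empty iff a DAG)."""
    digraph = g.to_networkx()
    report = CycleReport()
    try:
        cycle_edges = nx.find_cycle(digraph, orientation="original")
    except nx.NetworkXNoCycle:
        return report
    report.cycles.append([edge[0] for edge in cycle_edges])
    return report
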