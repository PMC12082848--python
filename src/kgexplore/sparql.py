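"""SPARQL rendering, embedded-engine verification, remote execution.

:func:`render` turns a :class:`QuerySpec` + :class:`PlanSpec` into the
corresponding SPARQL 1.1 document: four pattern blocks (bioresource/ID
mapping, orthology, gene-disease, expression) arranged under the chosen
subquery nesting, a ``SERVICE`` clause around the expression block in
federated mode, and a one-or-more/zero-or-more ``broader`` property
path when the anatomical closure is requested.  Only constructs common
embedded engines support are emitted (subqueries, property paths,
``FILTER``, ``UNION``).

:func:`verify_local` executes a centralized rendering with rdflib's
SPARQL engine over the fully serialized knowledge graph — the
independent engine-level check that the rendered text and the native
pipeline agree.  :func:`run_remote` speaks the SPARQL HTTP protocol to
a live endpoint; elapsed time is reported, never asserted.
"""

from __future__ import annotations

import json
import re
import socket
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Optional

import rdflib

from .io_rdf import GraphDialect, default_dialect, write_named_graph, GdaCollection
from .namespaces import CurieRef, NamespaceTable, default_table
from .pipeline import (ExplorationResult, PlanConfigError, PlanSpec, QuerySpec,
                       ResultRow)
from .records import KnowledgeGraph

__all__ = [
    "RenderedQuery",
    "EngineFailureError",
    "EndpointError",
    "QueryTimeoutError",
    "render",
    "verify_local",
    "run_remote",
]


class EngineFailureError(RuntimeError):
    """The embedded SPARQL engine failed to parse or evaluate a query."""


class EndpointError(RuntimeError):
    """A remote endpoint returned an HTTP error or was unreachable."""


class QueryTimeoutError(RuntimeError):
    """A remote query exceeded the configured timeout."""

    def __init__(self, timeout_s: float):
        super().__init__(f"query timed out after {timeout_s} s")
        self.timeout_s = timeout_s


@dataclass(frozen=True)
class RenderedQuery:
    text: str
    mode: str
    nesting: str
    uses_property_path: bool
    qspec: QuerySpec


_LOCAL_OK = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_-]*$")


def _term(ref: CurieRef, table: NamespaceTable) -> str:
    if ref.prefix in table and _LOCAL_OK.match(ref.local_id):
        return f"{ref.prefix}:{ref.local_id}"
    return f"<{table.expand(ref)}>"


def _pred(iri: str, table: NamespaceTable) -> str:
    ref = table.try_compact(iri)
    if ref is not None and _LOCAL_OK.match(ref.local_id):
        return f"{ref.prefix}:{ref.local_id}"
    return f"<{iri}>"


def _indent(lines: list[str], depth: int) -> list[str]:
    pad = "  " * depth
    return [pad + line if line else line for line in lines]


def _subpart1(d: dict[str, GraphDialect], t: NamespaceTable) -> list[str]:
    bio, gene = d["bioresource"], d["mgi_mapping"]
    return [
        "# query subpart 1: bioresource and gene ID mapping",
        f"?resource a {_pred(bio.iri('type'), t)} .",
        f"?resource {_pred(bio.iri('gene'), t)} ?mgi .",
        f"?mgi {_pred(gene.iri('xref_ncbi'), t)} ?ncbi .",
        f"?mgi {_pred(gene.iri('xref_ensembl'), t)} ?ensMouse .",
    ]


def _subpart2(d: dict[str, GraphDialect], t: NamespaceTable) -> list[str]:
    orth, gene, uni = d["orthology"], d["mgi_mapping"], d["uniprot_mapping"]
    member = _pred(orth.iri("member"), t)
    child = _pred(orth.iri("child"), t)
    taxon = _pred(orth.iri("taxon"), t)
    return [
        "# query subpart 2: orthology (nested cluster member closure)",
        f"?cluster a {_pred(orth.iri('type'), t)} .",
        f"?cluster {child}* ?subM .",
        f"?cluster {child}* ?subH .",
        "{",
        f"  ?subM {member} ?ensMouse .",
        "} UNION {",
        f"  ?subM {member} ?upMouse .",
        f"  ?mgi {_pred(gene.iri('xref_uniprot'), t)} ?upMouse .",
        "} UNION {",
        f"  ?subM {member} ?upMouse2 .",
        f"  ?ncbi {_pred(uni.iri('xref_uniprot'), t)} ?upMouse2 .",
        "}",
        f"?subH {member} ?humanEns .",
        f"?humanEns {taxon} {_term(CurieRef('taxon', '9606'), t)} .",
        f"?humanEns {_pred(gene.iri('xref_ncbi'), t)} ?humanNcbi .",
    ]


def _subpart3(qspec: QuerySpec, d: dict[str, GraphDialect], t: NamespaceTable) -> list[str]:
    gda = d["gda"]
    refers = _pred(gda.iri("refers_to"), t)
    threshold = repr(float(qspec.gda_threshold))
    return [
        "# query subpart 3: gene-disease association",
        f"?gdaNode a {_pred(gda.iri('type'), t)} .",
        f"?gdaNode {refers} ?humanNcbi .",
        f"?gdaNode {refers} {_term(qspec.disease, t)} .",
        f"?gdaNode {_pred(gda.iri('score'), t)} ?gdaScore .",
        f"FILTER(?gdaScore >= {threshold})",
    ]


def _subpart4(qspec: QuerySpec, d: dict[str, GraphDialect], t: NamespaceTable) -> list[str]:
    expr, anat = d["expression"], d["anatomy_broader"]
    lines = [
        "# query subpart 4: expression",
        f"?call a {_pred(expr.iri('type'), t)} .",
        f"?call {_pred(expr.iri('gene'), t)} ?humanEns .",
        f"?call {_pred(expr.iri('anatomical_entity'), t)} ?anat .",
        f'?call {_pred(expr.iri("confidence"), t)} "{qspec.confidence}" .',
        f'?call {_pred(expr.iri("sex"), t)} "{qspec.sex}" .',
    ]
    if qspec.dev_stage is not None:
        lines.append(f"?call {_pred(expr.iri('dev_stage'), t)} {_term(qspec.dev_stage, t)} .")
    if qspec.strain is not None:
        lines.append(f'?call {_pred(expr.iri("strain"), t)} "{qspec.strain}" .')
    if qspec.use_closure:
        # reflexive transitive search up the flattened broader hierarchy
        lines.append(f"?anat {_pred(anat.iri('broader'), t)}* {_term(qspec.anatomical_entity, t)} .")
    else:
        lines.append(f"FILTER(?anat = {_term(qspec.anatomical_entity, t)})")
    return lines


def _select(projection: str, body: list[str]) -> list[str]:
    return ["{", f"  SELECT DISTINCT {projection} WHERE {{"] + \
        _indent(body, 2) + ["  }", "}"]


def render(qspec: QuerySpec, plan: PlanSpec,
           table: Optional[NamespaceTable] = None,
           dialects: Optional[dict[str, GraphDialect]] = None) -> RenderedQuery:
    """Render the exploration as a SPARQL 1.1 document.

    Subquery nesting mirrors the plan: ``flat`` places all four pattern
    blocks in one group; each further level materializes one more inner
    block (innermost first: subpart 1, then 2, then 3), the expression
    block always outermost.  Deterministic: equal inputs render
    byte-identical text.
    """
    if plan.mode == "federated" and not plan.expression_endpoint:
        raise PlanConfigError("federated mode requires expression_endpoint")
    t = table or default_table()
    d = dialects or {}
    d = {kind: d.get(kind, default_dialect(kind)) for kind in
         ("bioresource", "mgi_mapping", "uniprot_mapping", "orthology",
          "gda", "expression", "anatomy_broader")}

    sp1, sp2 = _subpart1(d, t), _subpart2(d, t)
    sp3, sp4 = _subpart3(qspec, d, t), _subpart4(qspec, d, t)

    if plan.nesting == "flat":
        upstream = sp1 + sp2 + sp3
    elif plan.nesting == "one_subquery":
        upstream = _select("?resource ?mgi ?humanEns", sp1 + sp2 + sp3)
    elif plan.nesting == "two_subqueries":
        inner = _select("?resource ?mgi ?ncbi ?ensMouse", sp1)
        upstream = _select("?resource ?mgi ?humanEns", inner + sp2 + sp3)
    else:  # three_subqueries
        inner1 = _select("?resource ?mgi ?ncbi ?ensMouse", sp1)
        inner2 = _select("?resource ?mgi ?humanNcbi ?humanEns", inner1 + sp2)
        upstream = _select("?resource ?mgi ?humanEns", inner2 + sp3)

    if plan.mode == "federated":
        expression_block = [f"SERVICE <{plan.expression_endpoint}> {{"] + \
            _indent(sp4, 1) + ["}"]
    else:
        expression_block = sp4

    lines = [f"PREFIX {prefix}: <{iri}>" for prefix, iri in t]
    lines.append("")
    lines.append("SELECT DISTINCT ?resource ?mgi ?humanEns ?anat WHERE {")
    lines.extend(_indent(upstream + expression_block, 1))
    lines.append("}")
    if qspec.limit is not None or qspec.offset is not None:
        lines.append("ORDER BY ?resource ?humanEns ?anat ?mgi")
        if qspec.offset is not None:
            lines.append(f"OFFSET {qspec.offset}")
        if qspec.limit is not None:
            lines.append(f"LIMIT {qspec.limit}")
    return RenderedQuery(
        text="\n".join(lines) + "\n",
        mode=plan.mode,
        nesting=plan.nesting,
        uses_property_path=qspec.use_closure,
        qspec=qspec,
    )


# ---------------------------------------------------------------------------
# embedded verification

def _merged_graph(kg: KnowledgeGraph,
                  dialects: Optional[dict[str, GraphDialect]] = None,
                  table: Optional[NamespaceTable] = None) -> rdflib.Graph:
    table = table or default_table()
    dialects = dialects or {}
    graph = rdflib.Graph()
    collections = {
        "bioresource": kg.bioresources,
        "mgi_mapping": kg.genes,
        "uniprot_mapping": kg.uniprot_links,
        "orthology": kg.clusters,
        "gda": GdaCollection(kg.gdas, kg.diseases),
        "expression": kg.calls,
        "anatomy_broader": kg.anatomy,
    }
    for kind, records in collections.items():
        dialect = dialects.get(kind, default_dialect(kind))
        graph.parse(data=write_named_graph(records, dialect, table), format="turtle")
    return graph


def _row_from_solution(solution, qspec: QuerySpec, table: NamespaceTable) -> ResultRow:
    def compact(term) -> CurieRef:
        ref = table.try_compact(str(term))
        return ref if ref is not None else CurieRef("_iri", str(term))

    return ResultRow(
        bioresource=compact(solution["resource"]),
        mouse_gene=compact(solution["mgi"]),
        human_gene=compact(solution["humanEns"]),
        disease=qspec.disease,
        anatomical_entity=compact(solution["anat"]),
        confidence=qspec.confidence,
    )


def verify_local(kg: KnowledgeGraph, rendered: RenderedQuery,
                 dialects: Optional[dict[str, GraphDialect]] = None,
                 table: Optional[NamespaceTable] = None) -> ExplorationResult:
    """Execute a centralized rendering over the serialized KG with rdflib.

    The graph is serialized through the io layer and re-parsed, so the
    engine sees exactly what a triple store loading the Turtle files
    would see.  Any LIMIT/OFFSET in the query has already been applied
    by the engine and is not re-applied here.
    """
    if rendered.mode != "centralized":
        raise ValueError("verify_local evaluates centralized renderings only")
    table = table or default_table()
    graph = _merged_graph(kg, dialects, table)
    try:
        result = graph.query(rendered.text)
    except Exception as exc:
        raise EngineFailureError(f"embedded engine failure: {exc}") from exc
    rows = [_row_from_solution(sol.asdict(), rendered.qspec, table) for sol in result]
    return ExplorationResult.from_rows(rows)


# ---------------------------------------------------------------------------
# remote execution

def run_remote(rendered: RenderedQuery, endpoint: str,
               timeout_s: float = 600.0) -> tuple[list[dict], float]:
    """POST a query to a SPARQL endpoint; returns (binding rows, elapsed s).

    The default timeout matches routine endpoint limits (600 s); pass
    3600 for a long-transaction cap.  Elapsed wall-clock time is
    reported for inspection, never asserted against.
    """
    payload = urllib.parse.urlencode({"query": rendered.text}).encode("ascii")
    request = urllib.request.Request(
        endpoint,
        data=payload,
        headers={
            "Content-Type": "application/x-www-form-urlencoded",
            "Accept": "application/sparql-results+json",
        },
    )
    start = time.monotonic()
    try:
        with urllib.request.urlopen(request, timeout=timeout_s) as response:
            body = response.read()
    except socket.timeout as exc:
        raise QueryTimeoutError(timeout_s) from exc
    except urllib.error.HTTPError as exc:
        raise EndpointError(f"endpoint returned HTTP {exc.code}") from exc
    except urllib.error.URLError as exc:
        if isinstance(exc.reason, (socket.timeout, TimeoutError)):
            raise QueryTimeoutError(timeout_s) from exc
        raise EndpointError(f"endpoint unreachable: {exc.reason}") from exc
    elapsed = time.monotonic() - start
    try:
        parsed = json.loads(body)
        bindings = parsed["results"]["bindings"]
    except (ValueError, KeyError) as exc:
        raise EndpointError(f"malformed SPARQL JSON response: {exc}") from exc
    rows = [{name: b[name]["value"] for name in b} for b in bindings]
    return rows, elapsed
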