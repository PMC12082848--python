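"""CURIE <-> IRI namespace handling.

The default table carries the namespaces used across the integrated
bioresource / orthology / gene-disease / expression graphs, plus the
generic RDF vocabularies needed for serialization.  Additional prefixes
can be registered at runtime or loaded from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "CurieRef",
    "NamespaceTable",
    "UnknownNamespaceError",
    "DEFAULT_NAMESPACES",
    "default_table",
]


class UnknownNamespaceError(KeyError):
    """Raised when a CURIE prefix is not in the namespace table."""

    def __init__(self, prefix: str):
        super().__init__(prefix)
        self.prefix = prefix

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"unknown namespace prefix: {self.prefix!r}"


@dataclass(frozen=True, order=True)
class CurieRef:
    """A compact identifier ``prefix:local_id`` resolved against a table."""

    prefix: str
    local_id: str

    @classmethod
    def parse(cls, curie: str) -> "CurieRef":
        """Parse ``prefix:local`` text; the first colon splits the parts."""
        if ":" not in curie:
            raise ValueError(f"not a CURIE (no colon): {curie!r}")
        prefix, local = curie.split(":", 1)
        return cls(prefix, local)

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:
        return self.curie


#: Prefix -> IRI mappings for the integrated knowledge graphs.
DEFAULT_NAMESPACES: Mapping[str, str] = {
    "bgee": "http://bgee.org/#",
    "brso": "http://purl.jp/bio/10/brso/",
    "ensembl": "http://rdf.ebi.ac.uk/resource/ensembl/",
    "gda": "http://rdf.disgenet.org/resource/gda/",
    "genex": "http://purl.org/genex#",
    "lscr": "http://purl.org/lscr#",
    "ncbigene": "https://www.ncbi.nlm.nih.gov/gene/",
    "obo": "http://purl.obolibrary.org/obo/",
    "oma": "http://omabrowser.org/ontology/oma#",
    "omagenome": "https://omabrowser.org/oma/genome/",
    "omahog": "https://omabrowser.org/oma/hog/resolve/",
    "omainfo": "https://omabrowser.org/oma/info/",
    "orth": "http://purl.org/net/orth#",
    "rbrc": "http://purl.org/rbrc/resource/",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "riken": "http://metadb.riken.jp/db/rikenbrc_mouse/",
    "sio": "http://semanticscience.org/resource/",
    "taxon": "http://purl.uniprot.org/taxonomy/",
    "umls": "http://linkedlifedata.com/resource/umls/id/",
    "uniprot": "http://purl.uniprot.org/uniprot/",
    # generic vocabularies needed for serialization and closure queries
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "biolink": "https://w3id.org/biolink/vocab/",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "mgi": "http://identifiers.org/mgi/",
}


class NamespaceTable:
    """Registry of prefix -> IRI bindings with expand/compact helpers.

    Compaction picks the longest matching registered IRI so that nested
    namespaces (e.g. ``obo`` under a broader base) resolve predictably.
    """

    def __init__(self, bindings: Mapping[str, str] | None = None):
        self._by_prefix: dict[str, str] = dict(bindings or {})

    # -- registry -----------------------------------------------------
    def register(self, prefix: str, iri: str) -> None:
        self._by_prefix[prefix] = iri

    def update(self, bindings: Mapping[str, str]) -> None:
        self._by_prefix.update(bindings)

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._by_prefix

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._by_prefix.items()))

    def iri(self, prefix: str) -> str:
        try:
            return self._by_prefix[prefix]
        except KeyError:
            raise UnknownNamespaceError(prefix) from None

    # -- conversions --------------------------------------------------
    def expand(self, ref: CurieRef | str) -> str:
        """Expand a CURIE to its full IRI."""
        if isinstance(ref, str):
            ref = CurieRef.parse(ref)
        return self.iri(ref.prefix) + ref.local_id

    def compact(self, iri: str) -> CurieRef:
        """Compact a full IRI to a CURIE using the longest-prefix match."""
        best: tuple[str, str] | None = None
        for prefix, base in self._by_prefix.items():
            if iri.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            raise UnknownNamespaceError(iri)
        prefix, base = best
        return CurieRef(prefix, iri[len(base):])

    def try_compact(self, iri: str) -> CurieRef | None:
        try:
            return self.compact(iri)
        except UnknownNamespaceError:
            return None


def default_table() -> NamespaceTable:
    """A fresh namespace table seeded with the default bindings."""
    return NamespaceTable(DEFAULT_NAMESPACES)
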