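import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgexplore.namespaces import (DEFAULT_NAMESPACES, CurieRef,
                                  UnknownNamespaceError, default_table)

TABLE = default_table()


@pytest.mark.parametrize("curie, iri", [
    ("obo:UBERON_0000451", "http://purl.obolibrary.org/obo/UBERON_0000451"),
    ("rdfs:label", "http://www.w3.org/2000/01/rdf-schema#label"),
    ("umls:C0002395", "http://linkedlifedata.com/resource/umls/id/C0002395"),
    ("ensembl:ENSG00000142192", "http://rdf.ebi.ac.uk/resource/ensembl/ENSG00000142192"),
    ("skos:broader", "http://www.w3.org/2004/02/skos/core#broader"),
])
def test_expand_known_curies(curie, iri):
    assert TABLE.expand(curie) == iri


def test_expand_unknown_prefix_names_offender():
    with pytest.raises(UnknownNamespaceError) as exc:
        TABLE.expand(CurieRef("nosuchprefix", "X1"))
    assert exc.value.prefix == "nosuchprefix"


@settings(derandomize=True, max_examples=100)
@given(
    prefix=st.sampled_from(sorted(DEFAULT_NAMESPACES)),
    local=st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_", min_size=1, max_size=20),
)
def test_compact_expand_roundtrip(prefix, local):
    """compact(expand(c)) == c for every CURIE with a registered prefix."""
    ref = CurieRef(prefix, local)
    assert TABLE.compact(TABLE.expand(ref)) == ref


def test_compact_prefers_longest_prefix_match():
    table = default_table()
    table.register("obobase", "http://purl.obolibrary.org/")
    ref = table.compact("http://purl.obolibrary.org/obo/UBERON_0002097")
    assert ref == CurieRef("obo", "UBERON_0002097")


def test_runtime_registration_and_parse():
    table = default_table()
    table.register("ex", "http://example.org/")
    assert table.expand("ex:thing") == "http://example.org/thing"
    assert CurieRef.parse("umls:C0002395") == CurieRef("umls", "C0002395")
    with pytest.raises(ValueError):
        CurieRef.parse("nocolon")
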