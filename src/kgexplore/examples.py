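"""Small packaged worked examples.

Two hand-transcribed fixtures used throughout the tests and docs:

* :func:`app_alzheimer_example` — a one-row exploration: the RIKEN
  knock-in mouse RBRC06344 carries a mutation in the App gene, whose
  human ortholog APP (ENSG00000142192) is associated with Alzheimer's
  disease (UMLS CUI C0002395) and expressed with high confidence in the
  prefrontal cortex (UBERON:0000451).

* :func:`skin_hierarchy_fragment` — a fragment of the anatomy
  hierarchy around "skin of body" (UBERON:0002097), mixing part-of and
  subClassOf edges, flattened to broader edges.  The edge set is a
  synthetic transcription: relations between terms are plausible, not
  authoritative ontology releases.
"""

from __future__ import annotations

from .anatomy import AnatomyEdge, BroaderGraph, to_broader
from .namespaces import CurieRef
from .pipeline import QuerySpec
from .records import (HUMAN_TAXON, MOUSE_TAXON, Bioresource, Disease,
                      ExpressionCall, GeneDiseaseAssociation, GeneRecord,
                      KnowledgeGraph, OrthologyCluster, UniProtLink)

__all__ = [
    "app_alzheimer_example",
    "app_alzheimer_queryspec",
    "skin_minimal_edges",
    "skin_hierarchy_fragment",
    "SKIN_FRAGMENT_TERMS",
    "SKIN_OF_BODY",
    "SKIN_OF_LIMB",
    "ZONE_OF_SKIN",
]

SKIN_OF_BODY = CurieRef("obo", "UBERON_0002097")
ZONE_OF_SKIN = CurieRef("obo", "UBERON_0000014")
SKIN_OF_LIMB = CurieRef("obo", "UBERON_0001419")

ALZHEIMER = CurieRef("umls", "C0002395")
PREFRONTAL_CORTEX = CurieRef("obo", "UBERON_0000451")


def app_alzheimer_example() -> KnowledgeGraph:
    """The single-result worked example around RBRC06344 / App / APP."""
    app_mouse = GeneRecord(
        primary_id=CurieRef("mgi", "88059"),
        taxon=MOUSE_TAXON,
        label="App",
        ncbi_id=CurieRef("ncbigene", "11820"),
        ensembl_id=CurieRef("ensembl", "ENSMUSG00000022892"),
        uniprot_accessions=frozenset({CurieRef("uniprot", "P12023")}),
    )
    app_human = GeneRecord(
        primary_id=CurieRef("ensembl", "ENSG00000142192"),
        taxon=HUMAN_TAXON,
        label="APP",
        ncbi_id=CurieRef("ncbigene", "351"),
        ensembl_id=CurieRef("ensembl", "ENSG00000142192"),
        uniprot_accessions=frozenset({CurieRef("uniprot", "P05067")}),
    )
    return KnowledgeGraph(
        bioresources=[Bioresource(
            resource_id=CurieRef("rbrc", "RBRC06344"),
            label="App knock-in mouse",
            resource_kind="knock-in mouse",
            gene_links=frozenset({app_mouse.primary_id}),
        )],
        genes=[app_mouse, app_human],
        uniprot_links=[
            UniProtLink(app_mouse.ncbi_id, CurieRef("uniprot", "P12023")),
            UniProtLink(app_human.ncbi_id, CurieRef("uniprot", "P05067")),
        ],
        clusters=[OrthologyCluster(
            cluster_id=CurieRef("omahog", "APPEXAMPLE"),
            members=frozenset({
                (app_mouse.ensembl_id, MOUSE_TAXON),
                (app_human.primary_id, HUMAN_TAXON),
            }),
        )],
        gdas=[GeneDiseaseAssociation(
            gda_id=CurieRef("gda", "APPEXAMPLEGDA"),
            gene=app_human.ncbi_id,
            disease=ALZHEIMER,
            score=0.7,
        )],
        calls=[ExpressionCall(
            gene=app_human.primary_id,
            anatomical_entity=PREFRONTAL_CORTEX,
            confidence="high",
            sex="any",
        )],
        diseases=[Disease(ALZHEIMER, "Alzheimer's Disease")],
    )


def app_alzheimer_queryspec(**kwargs) -> QuerySpec:
    return QuerySpec(disease=ALZHEIMER, anatomical_entity=PREFRONTAL_CORTEX, **kwargs)


def skin_minimal_edges() -> BroaderGraph:
    """Two edges: zone of skin part-of skin of body; skin of limb is-a zone.

    The shortest broader path from skin of limb to skin of body on this
    graph has length 2.
    """
    return to_broader([
        AnatomyEdge(ZONE_OF_SKIN, "partOf", SKIN_OF_BODY),
        AnatomyEdge(SKIN_OF_LIMB, "subClassOf", ZONE_OF_SKIN),
    ])


#: The 12 anatomy terms of the skin fragment (including the root).
SKIN_FRAGMENT_TERMS = tuple(CurieRef("obo", local) for local in (
    "UBERON_0000014",  # zone of skin
    "UBERON_0001003",  # skin epidermis
    "UBERON_0001416",  # skin of abdomen
    "UBERON_0001419",  # skin of limb
    "UBERON_0001511",  # skin of leg
    "UBERON_0001554",  # skin of hip
    "UBERON_0002073",  # hair follicle
    "UBERON_0002097",  # skin of body
    "UBERON_0003531",  # forelimb skin
    "UBERON_0003532",  # hindlimb skin
    "UBERON_0004262",  # upper leg skin
    "UBERON_0004263",  # upper arm skin
))


def skin_hierarchy_fragment() -> BroaderGraph:
    """A 12-term mixed part-of / subClassOf fragment rooted at skin of body."""
    u = {ref.local_id[-7:]: ref for ref in SKIN_FRAGMENT_TERMS}
    return to_broader([
        AnatomyEdge(u["0000014"], "partOf", u["0002097"]),      # zone of skin
        AnatomyEdge(u["0001003"], "partOf", u["0002097"]),      # skin epidermis
        AnatomyEdge(u["0002073"], "partOf", u["0002097"]),      # hair follicle
        AnatomyEdge(u["0001416"], "subClassOf", u["0000014"]),  # skin of abdomen
        AnatomyEdge(u["0001419"], "subClassOf", u["0000014"]),  # skin of limb
        AnatomyEdge(u["0001554"], "subClassOf", u["0000014"]),  # skin of hip
        AnatomyEdge(u["0003531"], "subClassOf", u["0001419"]),  # forelimb skin
        AnatomyEdge(u["0003532"], "subClassOf", u["0001419"]),  # hindlimb skin
        AnatomyEdge(u["0001511"], "subClassOf", u["0003532"]),  # skin of leg
        AnatomyEdge(u["0004262"], "subClassOf", u["0001511"]),  # upper leg skin
        AnatomyEdge(u["0004263"], "subClassOf", u["0003531"]),  # upper arm skin
    ])
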