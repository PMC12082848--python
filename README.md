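# kgexplore

Finding the right model organism for a disease study means joining
knowledge that lives in separate databases: a bioresource centre's
catalogue of genetically modified mouse strains, gene identifier
mappings (MGI ↔ NCBI Gene ↔ Ensembl ↔ UniProtKB), mouse–human
orthology (hierarchical orthologous groups, HOGs), scored human
gene–disease associations, and anatomically annotated gene expression
calls. `kgexplore` implements that multi-graph exploration as a typed,
testable pipeline, together with the SPARQL machinery a production RDF
deployment of the same data would use.

The core query answers: *which bioresources (mouse strains) carry a
gene whose human ortholog is associated with disease D (association
score ≥ τ) and is expressed, with a given confidence and sex
annotation, in anatomical entity A?* Formally, the result set is

```
{ (r, g_m, g_h, D, a) :  r  —links→ g_m,
                         (g_m, g_h) share an orthology-cluster closure,
                         score(g_h, D) ≥ τ,
                         call(g_h, a, confidence, sex) exists,
                         a = A  or  a broader* A }
```

where `broader*` is the reflexive–transitive closure of a single
narrower→broader relation obtained by flattening the anatomy
ontology's mixed `rdfs:subClassOf` and `BFO:0000050` (part-of) edges.
That flattening is the package's second ingredient: anatomy ontologies
nest the two relations to unknown depth, which defeats plain SPARQL
property paths over the OWL serialization; rewriting both into one
`skos:broader` predicate makes transitive anatomical search a
single-atom property path (and, here, plain graph reachability).

The pipeline decomposes into four query subparts — (1) bioresource/ID
mapping, (2) orthology, (3) gene–disease, (4) expression — which can
be materialized under different subquery nesting plans and in
centralized or federated (remote expression endpoint) mode. Every
arrangement returns the same canonical result; the per-plan trace
records how many bindings cross each materialization boundary, the
quantity that dominates federated transfer cost.

## Worked example

The packaged fixture transcribes a one-row exploration: the knock-in
mouse strain RBRC06344 carries a mutation in *App*; the human ortholog
*APP* (ENSG00000142192) is associated with Alzheimer's disease (UMLS
CUI C0002395, score 0.7 ≥ 0.5) and expressed with high confidence in
the prefrontal cortex (UBERON:0000451):

```python
from kgexplore import explore
from kgexplore.examples import app_alzheimer_example, app_alzheimer_queryspec

kg = app_alzheimer_example()
result = explore(app_alzheimer_queryspec(), kg)
for row in result:
    print(row.bioresource, row.mouse_gene, row.human_gene,
          row.disease, row.anatomical_entity)
print("resources:", result.distinct_bioresources(),
      "genes:", result.distinct_human_genes())
```

prints

```
rbrc:RBRC06344 mgi:88059 ensembl:ENSG00000142192 umls:C0002395 obo:UBERON_0000451
resources: 1 genes: 1
```

— one result row, i.e. one candidate strain and one disease gene.
Flattening the two skin relations (*zone of skin* part-of *skin of
body*; *skin of limb* subClassOf *zone of skin*) and asking for the
shortest broader path from skin of limb to skin of body:

```python
from kgexplore import min_broader_path
from kgexplore.examples import skin_minimal_edges, SKIN_OF_LIMB, SKIN_OF_BODY
print(min_broader_path(skin_minimal_edges(), SKIN_OF_LIMB, SKIN_OF_BODY))
```

prints `2` — the term is two broader steps below the query term, so
only a transitive search finds its expression calls. On a synthetic
knowledge graph the same toggle looks like this:

```python
from kgexplore.synth import SynthParams, generate, focal_queryspec
kg, gt = generate(SynthParams(seed=0))
off = explore(focal_queryspec(gt), kg)
on = explore(focal_queryspec(gt, use_closure=True), kg)
print(len(off), off.distinct_bioresources(), off.distinct_human_genes())
print(len(on), on.distinct_bioresources(), on.distinct_human_genes())
```

```
2 2 1
10 10 5
```

— with the closure off, genes whose calls sit on proper descendants of
the query term are invisible; the closure recovers them.

## Command line

```
kgexplore synth-kg --seed 0 --out-dir kg/            # Turtle files + ground truth
kgexplore explore --kg kg/ --disease umls:CSYN0000 \
    --anatomy obo:SYNANAT0001 --closure --out rows.tsv --trace trace.json
kgexplore convert-uberon --kgx uberon_kgx_tsv_edge.tsv --out-dir broader/
kgexplore anatomy-descendants --term UBERON:0002097 --kgx uberon_kgx_tsv_edge.tsv
kgexplore render-query --disease umls:C0002395 --anatomy UBERON:0000451 \
    --plan one_subquery --mode centralized -o query.rq
kgexplore run-query --endpoint https://example.org/sparql --query query.rq
```

`convert-uberon` writes the two derived ontology files
(`subject_broader_object_from_BFO_0000050.ttl`,
`subject_broader_object_from_subClassOf.ttl`), keeping the provenance
of every flattened edge.

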