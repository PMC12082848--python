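# Methods

## The exploration model

`kgexplore` treats disease-model-mouse discovery as a conjunctive
query over six record collections plus an anatomy graph, held in a
`KnowledgeGraph` container and serializable as one RDF named graph per
kind (Turtle). A result row is a 5-tuple *(bioresource, mouse gene,
human gene, disease, anatomical entity)* plus the confidence level the
query demanded. The evaluation is staged as four query subparts:

1. **Bioresource / ID mapping.** Each bioresource links to mouse genes
   by their MGI primary ID; a link survives only if the gene record
   resolves NCBI *and* Ensembl cross-references, because the
   downstream joins key on those ID spaces. UniProt accessions are
   attached from the gene record and from the separate NCBI→UniProt
   link table.
2. **Orthology.** Clusters are hierarchical orthologous groups: a
   cluster's *effective member set* is its own members plus all
   members of transitively nested child clusters. A mouse and a human
   gene are orthologous when some cluster's effective member set
   contains both. Mouse genes are matched into membership through
   their Ensembl ID or any UniProt accession (union of both routes);
   human members resolve to gene records through any registered ID and
   must carry the human taxon.
3. **Gene–disease.** A binding survives if its human gene has an
   association to the query disease with score ≥ the threshold,
   **inclusive** — a score of exactly 0.5 passes the default 0.5
   threshold ("0.5 or more" semantics).
4. **Expression.** A binding joins each call of its human gene whose
   confidence and sex annotations equal the requested values and whose
   anatomical entity either equals the query term (closure off) or
   lies in the term's reflexive descendant closure (closure on).
   Developmental-stage and strain constraints are applied only when
   set; unconstrained means no predicate at all, not "equals null".

Sex filtering is annotation equality: requesting "any" selects calls
annotated `any`, it is not a wildcard over `male`/`female`. Confidence
is a two-value enumeration `{high, low}`; source vocabularies with
finer grading are expected to be mapped onto these at read time via a
dialect override.

Rows are deduplicated (many-to-many ortholog pairs yield one row per
pair) and canonically ordered by the expanded IRIs of (bioresource,
human gene, anatomical entity, mouse gene). The ordering is a package
decision — some total order is required for deterministic paging and
cross-plan comparison. LIMIT/OFFSET paging is applied after ordering,
so concatenated pages reconstruct the unpaged result exactly.

### Nesting plans and traces

`execute_plan` evaluates the same composition under four arrangements
(`flat`, `one_subquery`, `two_subqueries`, `three_subqueries`),
materializing progressively more inner stage outputs (innermost first:
subpart 1, then 2, then 3; the expression subpart is always
outermost). All plans return the identical canonical result — that
invariance is asserted by the test suite — and differ only in the
`StageTrace`, which records the binding count at each materialized
boundary. The `subpart3` boundary counts *distinct human genes*
entering the expression subpart: in a federated deployment this is the
binding volume shipped to the remote expression endpoint, the quantity
worth minimizing. Federated pipeline evaluation is simulated: the
expression subpart is evaluated against a separately supplied
expression-graph shard standing in for the remote endpoint; real
network federation lives in the SPARQL layer.

## Anatomy flattening and closure

`to_broader` rewrites each `subClassOf` or `partOf` edge into one
directed narrower→broader edge, tagged with its source relation; the
two tagged subsets serialize to separate Turtle files (part-of-derived
first), so provenance survives the flattening. The broader predicate
defaults to `skos:broader` — the conventional IRI for a
narrower→broader concept link — and is overridable.

Closure semantics: `descendants(g, root)` is reflexive by default (a
query term matches its own calls) and computed by breadth-first
reverse reachability, so cycles — which a healthy ontology export
should not contain, but `check_acyclic` reports if present — cannot
cause non-termination. An edge present under both source tags counts
once in closure. `min_broader_path` is plain BFS shortest path.

KGX edge TSVs are the expected ontology input: `subject`, `predicate`,
`object` columns (tab-delimited, header-bearing); a `relation` column,
when present, is authoritative for part-of detection since KGX exports
vary in whether `predicate` carries the Biolink predicate or the OBO
relation. Rows under any other relation (e.g. develops-from) are
ignored and counted, as are blank-field rows. OBO-style CURIEs
(`UBERON:0001419`) are normalized into the `obo` namespace
(`obo:UBERON_0001419`).

## Serialization dialects

Each graph kind has a `GraphDialect` mapping field roles to predicate
IRIs. Defaults use vocabularies the source databases are known to
publish (`lscr` cross-references, `orth` homology and
`orth:OrthologsCluster`, `sio` association/score, `genex` expression
roles, `obo:RO_0002162` for taxon) and mint predicates under the same
namespaces where the production vocabulary is release-dependent
(`brso:gene` for bioresource→gene, `orth:hasSubCluster` for cluster
nesting — a distinct predicate keeps parsing unambiguous where real
exports overload the member relation). Every predicate is overridable
per dialect from a YAML config, which also extends the namespace
table. Turtle output is emitted sorted by (subject, predicate, object)
so equal collections serialize byte-identically; floats use shortest
`repr`, which round-trips exactly through decimal literals.

Gene records serialize fully (including UniProt xrefs) in the gene
mapping graph, while the UniProt mapping graph carries NCBI→UniProt
link rows as its own collection — slightly redundant, but each named
graph round-trips its own typed collection exactly.

## SPARQL generation and verification

`render` emits SPARQL 1.1 restricted to constructs common embedded
engines evaluate (subqueries, property paths, `FILTER`, `UNION`): the
four subpart pattern blocks under the chosen nesting, a single
`SERVICE <endpoint>` clause around the expression block in federated
mode, and `?anat skos:broader* <term>` (zero-or-more, hence reflexive,
matching the native closure) when closure is requested. `ORDER BY`
plus `LIMIT`/`OFFSET` are emitted only when paging is set. Rendering
is deterministic.

`verify_local` serializes the whole KG through the io layer, re-parses
it into rdflib, and executes the rendered centralized text — an
engine-level, independent check that the query documents mean what the
native pipeline computes. Federated (`SERVICE`-bearing) text is
validated structurally only; embedded engines' federation support is
unreliable, and live execution belongs to `run_remote`, which speaks
the SPARQL HTTP protocol with a default 600 s timeout (3600 s
available for long transactions) and reports — never asserts —
elapsed time.

One known asymmetry: the rendered query matches genes into orthology
clusters and expression calls via Ensembl identifiers (with a UniProt
`UNION` route for cluster membership), while the native pipeline
resolves any registered cross-reference. On graphs whose calls
reference genes by some other ID the rendered query is stricter; the
synthetic generator and the packaged fixtures use Ensembl references,
where the two agree exactly.

## Synthetic data

`generate(SynthParams)` emulates the joint structure of the six
graphs, with defaults chosen as a plausible desk-scale study: 30
bioresources each linking 1–3 of 40 mouse genes, 100 human genes, 3
diseases; 80 % ortholog coverage with every fifth cluster nested two
levels; 90 % of mouse genes fully ID-mapped (the rest exercise the
stage-1 drop rule); uniform association scores; a depth-4,
branching-3 anatomy DAG whose tree edges are part-of with probability
0.4 and which gains extra part-of parents for ~15 % of nodes —
multi-parent mixed hierarchies being exactly the structure the
flattening exists for; Poisson(3) expression calls per human gene with
70 % high confidence and 80 % `any` sex.

For the focal disease, `round(0.14 × n_human_genes)` genes (14 at the
default size) are planted with scores drawn in [0.5, 1]; non-planted
genes receive only sub-0.5 decoy associations. Planted genes
alternate between a guaranteed high-confidence call on the focal
anatomy term and one on a proper descendant only, so closure-on and
closure-off results differ by construction. `GroundTruth` records
flat tables (links, mappings, pairs, scores, calls, anatomy edges) and
`expected_result` derives the expected rows from those tables alone —
never from the KG objects or pipeline code — so recovery tests are
exact set equality, not approximation.

What the generator does not model: realistic expression-score
distributions (scores are placeholders), per-call data-source
annotations, non-mouse resource types, and real accession identifiers
(all IDs are in reserved `SYN…` ranges). Passing tests therefore
demonstrate the correctness of the joins, closures and query
generation on graphs with this structure — not robustness to the
vocabulary drift, scale or noise of production database releases.

## Numerical and edge-case choices

- Association scores compare with `>=` (inclusive threshold).
- Score literals are written as decimal text from shortest float
  `repr`; read-back is exact.
- Duplicate anatomy edges deduplicate within a source tag; records
  equal on all fields deduplicate on merge, while records sharing an
  ID but differing in any field raise a merge conflict naming the ID.
- Validation never raises; it returns a list of named issues, with
  referential-integrity checks only in strict mode so partial shards
  remain loadable.
- The brute-force oracle is guarded to ≤10⁴ records per collection.
- Problem sizes in the test and acceptance suites (default generator
  parameters; 20 seeds for plan invariance and recovery, 10 for
  engine equivalence, 100 random DAGs ≤200 nodes for the closure
  oracle) keep every suite comfortably fast while exercising nesting,
  multi-parent anatomy and both closure modes.

## Known limitations

- The predicate vocabularies of the production mapping graphs are only
  partially documented publicly; the defaults here are explicit,
  configurable assumptions.
- Query cost estimation and automatic plan selection are out of scope;
  plans are user-chosen, and traces are descriptive.
- `read_named_graph` on a single broader file cannot know the source
  tag; tags are recovered only through the two split files.
- The embedded engine check covers centralized renderings; federated
  text is structurally validated and exercised against a loopback HTTP
  endpoint in the tests, not against live endpoints.
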