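# rdfacets

Faceted exploratory search over RDF triple stores built from heterogeneous
tabular biological databases.

Biological data — SNP catalogues, gene annotation, pathway membership,
viral-integration-site tables — mostly ships as delimited tables whose
columns mean very different things. `rdfacets` turns any such table into an
RDF store with a machine-readable structure description, and then supports
the kind of exploration biologists actually do over it: free-text entry
points, conjunctive/disjunctive filtering by facet (column) values, raw
SPARQL (including federated `SERVICE` queries passed through unmodified),
and — the analytical core — statistical ranking and filtering of facet
values to surface what is unusually frequent or rare in the current result.

## Data model

A table with namespace *N* becomes triples: row *i* is the subject `N:i`,
column *j* the predicate `N:P_j`, and each non-empty cell a literal object.
The collection is described in RDFS: every database is an `rdfs:Class`
typed `rdx:Database`, nesting (e.g. dbSNP inside NCBI) is
`rdfs:subClassOf`, each predicate is tied to its database by `rdfs:domain`,
and display names, display order, hidden/indexed flags, datatypes and
entity tags (gene, protein, SNP, pathway, publication) are statements about
the predicate. A facet that is meaningless on its own — a genomic
coordinate without its chromosome — declares a prerequisite
(`rdfs:seeAlso`), and its stored values carry the prerequisite as a colon
prefix: `chr5:1253`.

## Search and facet statistics

Every search state compiles into a single SPARQL *key query* whose
solutions are exactly the matching row subjects. Free text goes through a
subject-keyed inverted index; of the matches, only the best 300 (default)
that score at least 25% of the top score are retained. Facet values and
their frequencies in the current result come from one aggregate query that
concatenates predicate and value with a reserved separator, groups, and
counts.

For a facet with values *n₁…n_N*, whole-database counts *c₁…c_N* and
in-result counts *c′₁…c′_N*, values can be

- ranked by frequency,
- banded: *average* values lie in \[μ−Mσ, μ+Mσ\] of the frequency
  distribution, *extreme* values strictly beyond μ±M̄σ,
- color-graded by z = (f−μ)/σ (yellow above the mean, green below,
  brightness ∝ |z|),
- tested for over/under-representation with the exact binomial: with
  p_i = c_i/Σc_j and n′ = Σc′_j,
  α_i = P(X = c′_i | Bin(n′, p_i)), β_i = P(X > c′_i), γ_i = P(X < c′_i).
  Ranking ascending in α and keeping values with α ≤ λ·P_M (P_M the
  smallest α) zooms in on what matters to the query rather than what is
  merely common.

## Worked example

The bundled generator emulates a hepatitis-B-virus integration-site
database from paired tumor/normal liver samples: one row per integration
(sample, tissue, nearest gene, region class, chromosome + coordinate, HBV
genome region), with planted recurrent genes — a gene is *recurrent* when
integrations affect it in at least 4 distinct samples.

```console
$ rdfacets fixture --seed 7 --out fx
{"rows": 109, "out": "fx"}
$ rdfacets convert --table fx/integrations.tsv --config fx/structure.yaml \
    --database hbv_integrations --out conv
{"database": "hbv_integrations", "rows": 109, "triples": 763, ...}
$ rdfacets index --store conv/data.nt --config fx/structure.yaml --out idx
{"literals": 654, "subjects": 109}
$ rdfacets facets --store conv/data.nt --config fx/structure.yaml \
    --select tissue=tumor --facet gene --band upper --mbar 1.0 --out facets.json
{"facet": "https://rdfacets.io/data/hbv/gene", "values": 5}
```

109 integrations convert to 763 triples (7 cells per row). Restricting to
tumor tissue and asking for the upper extreme band of the gene facet
returns exactly the five planted recurrent genes:

| gene | count | z | hue | brightness | α |
|---|---|---|---|---|---|
| GENE_T1 | 8 | 4.64 | above_mean | 1.00 | 0.1119 |
| GENE_T2 | 6 | 3.19 | above_mean | 1.00 | 0.1366 |
| GENE_T3 | 5 | 2.46 | above_mean | 0.82 | 0.1535 |
| GENE_T4 | 4 | 1.73 | above_mean | 0.58 | 0.1758 |
| GENE_T5 | 4 | 1.73 | above_mean | 0.58 | 0.1758 |

`count` is the gene's integration count among the 84 tumor rows; its
deviation from the mean gene frequency (z) drives the color grade, and α is
the exact binomial probability of seeing exactly that count given the
gene's whole-database share. The same genes are isolated by the
significance filter (`--rank alpha --lam 1.8`), and a raw SPARQL
conjunction query (tumor ∧ normal on the same gene, or the same sample and
chromosome) recovers the planted shared genes and co-located breakpoint
pairs.

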