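# Methods

## Tabular-to-RDF model

A delimited table is treated as a collection of row objects: row *i* of a
database with namespace *N* becomes the subject `N + str(i)` (1-based, in
file order), column *j* the predicate `N + local_name_j`, and each
non-empty cell one `(subject, predicate, literal)` statement. Consequences
of this model that the engine relies on:

- the number of data triples equals the number of non-empty,
  datatype-valid cells, exactly;
- a facet value's frequency is the number of rows holding that value, so
  facet counting is a plain group-by over `(predicate, value)` pairs;
- every predicate is single-valued per subject (one cell per row/column),
  so a conjunctive ("all") selection of two different values of one facet
  is necessarily empty. Multi-valued cells are not split; a future
  in-cell-delimiter convention would change this.

Empty cells produce no triple. Cells that fail their column's datatype
(integer/decimal lexical forms per XSD) are skipped, recorded per cell in
the conversion report, and conversion continues.

**Dependent facets.** A column may declare a prerequisite column
(chromosome for a coordinate). The stored literal is
`prerequisite_value + ":" + value`, applied along the dependency chain
root-first (A→B→C with cells a, b, c stores `c:b:a` for A). Splitting on
the *first* colon recovers prerequisite and raw value; colons inside the
prerequisite itself are not escaped — this is a documented convention, not
a reversible encoding for arbitrary values. Prefixed literals are stored
as plain strings even when the raw column is numeric, because the prefixed
lexical form is not a valid numeric literal; the raw cell is still
datatype-validated first. An empty prerequisite on a row with a non-empty
dependent value emits the value un-prefixed and logs a warning.

**Schema description.** Databases are `rdfs:Class`es typed
`rdx:Database`; collections (groupings with no rows of their own, e.g.
NCBI) are classes without namespaces; nesting is `rdfs:subClassOf`;
predicates attach to their database via `rdfs:domain`. Per-column display
name, display order, hidden, indexed, datatype, source column and optional
entity type are statements about the predicate in the small project
vocabulary `https://rdfacets.io/vocab#`. The dependency is emitted as one
`rdfs:seeAlso` statement in the direction dependent → prerequisite only:
a fixed direction is needed to know which value becomes the prefix. The
schema graph is self-describing — parsing it back recovers an equivalent
structure — and is written to a separate artifact from the data triples so
that unconstrained "browse" queries over a data store never pick up
schema statements.

## Free-text index

Literals of columns marked `indexed` are tokenized (lowercase, split on
non-alphanumeric runs, no stemming; the tokenizer is replaceable) into an
inverted index keyed by row subject; each subject also stores its complete
literals. Scoring is a tf·idf sum over matched query tokens with
idf = ln(1 + N/df). The tested contract is ordering and retention, not
absolute scores: hits sort by descending score with subject-IRI
tie-breaks; at most `search_limit` (default **300**) hits are kept, and of
those, hits scoring below `score_ratio` (default **0.25**) of the top
score are dropped. The cap is applied before the ratio cutoff. A boolean
reports whether more hits existed. The 1–5 star rating shown alongside
scores is presentation only: the score quantized into fifths of the top
score.

## Key query and facet counting

Any combination of free text, raw SPARQL and facet selections compiles to
one SPARQL `SELECT DISTINCT ?subject` query. Free text is resolved through
the index first and embedded as a `VALUES ?subject {…}` block (the
displayed/audited template form shows the unresolved text clause with its
`Search_Limit`). Raw SPARQL must project `?subject` — checked by parsing,
before execution — and is embedded as a subquery with its `PREFIX`
declarations hoisted; `SERVICE` clauses inside it pass through unmodified.
Within a facet, `any` compiles to one triple pattern plus a value-
disjunction `FILTER IN`, `all` to one triple pattern per value; across
facets, selections always combine conjunctively. Literal comparison is
SPARQL `=` on literals built with the column's declared datatype: exact
string equality for strings, value equality for numerics. There are no
numeric range filters.

Facet counts come from one aggregate query that binds
`CONCAT(STR(?p), sep, STR(?v))`, groups and counts, with the key query as
a subquery. The separator (default `⟂|⟂`, configurable) must not occur in
any stored predicate or value; this is checked once per store with an
`ASK` and a collision raises an error instructing reconfiguration.
Whole-database baseline counts per facet value are computed once per
database (restricting subjects to the database namespace) and cached.
Hidden facets are excluded from counts unless explicitly requested.
Two views exist: the *display* view lists only values present in the
result (c′ > 0), as a facet widget would; the *full* view adds baseline
values absent from the result (c′ = 0), which under-representation
analysis needs.

Remote SPARQL 1.1 endpoints are supported by pointing the store at an
endpoint URL (rdflib's SPARQL protocol client); all generated queries are
standard SPARQL 1.1, and results are identical to local execution on the
same graph. Every generated query is logged as a JSON line for
auditability.

## Facet value statistics

Let c₁…c_N be one facet's whole-database counts and c′₁…c′_N the counts in
the current result; μ and σ are the mean and **population** standard
deviation (ddof = 0, used consistently in tests and oracles) of the chosen
counts.

- *Average band*: values with frequency in the **closed** interval
  \[μ−Mσ, μ+Mσ\]; closed so that the σ = 0 case retains everything for any
  M. Monotone: smaller M never grows the set.
- *Extreme bands*: **strictly** above μ+M̄σ / below μ−M̄σ; strict so that
  σ = 0 yields empty tails. Monotone: larger M̄ never grows the set.
- *Color grade*: hue `above_mean` (yellow) iff (f−μ)/σ > 0 else
  `below_mean` (green); brightness = min(1, |z|/Z_cap) with Z_cap = 3 —
  deviations beyond 3σ render at full brightness (presentation choice);
  σ = 0 grades flat at brightness 0.
- *Binomial significance*: p_i = c_i/Σc_j (counts, not labels — the only
  consistent reading), n′ = Σc′_j, and under Bin(n′, p_i):
  α_i = P(X = c′_i), β_i = P(X > c′_i), γ_i = P(X < c′_i), with strict
  inequalities, so α+β+γ = 1 identically. Probabilities are evaluated via
  `scipy.stats.binom` (log-gamma space internally), verified against an
  exact rational-arithmetic oracle for n′ ≤ 30 and against an independent
  `lgamma` evaluation at n′ = 10⁴ (agreement ≤ 1e-9 relative). Ranking by
  β or γ surfaces over- and under-represented values respectively; no
  multiple-testing correction is applied across facet values.
- *Significance filter*: with P_M the smallest (top-ranked) α among the
  values under consideration, keep values with α **≤** λ·P_M, λ ≥ 1.
  Inclusive so that λ = 1 retains exactly the best value and its exact
  ties. Crucially, α is always computed against the **whole-database**
  baseline (the full view), even when the filter is then applied to the
  present-in-result values only; computing p_i from the result's own
  values would erase the signal the statistic exists to find.

## Synthetic integration fixture

The generator emulates a viral-integration-site table from a paired
tumor/normal liver-tissue sequencing study: per integration, sample id
(88 samples by default), tissue, nearest gene, region class
(exon/intron/promoter/intergenic at 0.28/0.34/0.16/0.22), chromosome +
coordinate (uniform within approximate hg19 chromosome lengths; coordinate
declared dependent on chromosome to exercise colon-prefixing), and HBV
genome region (X/core/enhancer/other at 0.24/0.15/0.10/0.51, reflecting
the known clustering of breakpoints near the X, core and enhancer
regions).

Planted ground truth (defaults): five tumor-recurrent genes at 8/6/5/4/4
distinct samples (recurrence ≥ 4 distinct samples), one normal-recurrent
gene at 4 samples, three genes shared between tumor and normal (in
different samples), and two samples with a tumor and a normal breakpoint
on the same chromosome. Background integrations (52 tumor, 16 normal) use
tissue-specific gene pools at ≤ 2 occurrences per gene, so recurrence,
sharing and co-location are separable by construction — a fixture
convention, not a biological claim. Chromosomes of non-planted rows are
drawn avoiding accidental same-sample tumor/normal chromosome overlap.
Row counts are fixed by the plan (84 tumor / 25 normal); the seed
randomizes assignments only, so tables are byte-identical per seed.

The default plan was chosen analytically so that the exploration
operations have clean margins: background at ≤ 2 and planted at ≥ 4
integrations puts the tumor gene-facet upper-band threshold μ+σ ≈ 3
between the two groups (M̄ = 1), and the exact binomial α of the planted
tumor genes (≤ 0.176) is separated from the best background value
(≥ 0.257), so λ = 1.8 isolates exactly the planted set. In normal tissue,
λ = 10 leaves two genes — the planted recurrent one plus the one
background gene with both its occurrences in the query — mirroring the
"crop by significance" exploration pattern.

What the fixture does *not* emulate: real integration-site hotspots,
per-chromosome gene density, sequencing noise, or the actual counts of any
published cohort. Passing tests demonstrate that the mechanics — bands,
grades, binomial ranking, conjunction queries — recover planted structure
exactly; they say nothing about recovering structure from noisy real data
where the planted/background separation does not hold.

## Problem sizes and numerical conventions

- Oracle-equivalence checks run 200 randomized query specs over 50 seeded
  tables of up to 120 rows × 8 columns with ≤ 10% empty cells; conversion
  exactness checks every cell individually. In these checks the text-hit
  cap is raised to 1000 so the subject-set oracle is exact (retention is
  verified separately, including a 350-candidate corpus returning exactly
  300 with the more-results flag).
- The planted-enrichment recovery property uses 15 categories with
  baselines 150–300 and 300 multinomial draws at 3× enrichment — sizes at
  which the ascending-α ranking has adequate power for a ≥ 95%-of-seeds
  assertion.
- Ties everywhere break lexicographically by label/subject IRI, making
  every ordering deterministic.
- Canonical N-Triples output (sorted statement lines) makes serialized
  stores byte-reproducible.

## Known limitations

- Facet selection values are compared against the *stored* form; users of
  dependent facets select `chr5:1253`, not `1253`.
- The text index is rebuilt explicitly (`rdfacets index`); there is no
  incremental update.
- Numeric literal equality in filters follows SPARQL value semantics, so
  `05` and `5` match in an integer column even though their lexical forms
  differ.
- Entity-type tags are attached to display records for a front end to
  render links; resolving them against external databases is out of
  scope, as is any web UI or cross-database entity linking.
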