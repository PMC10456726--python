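# Methods

## Scope and model

`samplemeta` standardizes per-sample tabular metadata against
controlled vocabularies so downstream queries reduce to string
equality. The core assumptions are:

* one vocabulary per controlled category; main-term sets are pairwise
  disjoint across categories (*orthogonality*), so a standardized
  value identifies its category without further context;
* each concept has one canonical surface (*main term*) and zero or
  more synonyms mapped many-to-one onto it (*non-redundancy*);
* vocabularies are expandable at submission time: an unmatched value
  explicitly confirmed by the submitter becomes a new main term and
  the matching model for that category is refitted.

Synonyms are deliberately **not** required to be orthogonal across
categories: natural-language synonyms such as unit abbreviations are
unavoidable and only main terms carry identity.

## String normalization

All stored and compared strings are lowercased with whitespace runs
collapsed to single spaces. Punctuation is preserved because it is
meaningful in strain names (`balb/c`) and compound units
(`hours/day`). This is the entire normalization — equality on
standardized output is byte equality of normalized strings.

## Trigram tf-idf matching

Surfaces (main terms and synonyms alike — synonyms are first-class
rows so "mouse" can match at cosine 1.0 and then map to its main
term) are embedded over the union of their character trigrams:
length-3 sliding windows over the full string, spaces included, no
boundary padding. Surfaces shorter than three characters contribute
themselves as a single gram, otherwise units like `g` would be
unrepresentable. Weights are raw term frequency times the smoothed
inverse document frequency `ln((1+D)/(1+df)) + 1` (never zero, no
division by zero on refit), followed by L2 normalization; queries are
coerced into the fitted space with unknown grams dropped. Fitting is
delegated to scikit-learn's `TfidfVectorizer` with a custom analyzer,
which implements exactly this weighting; query vectorization is a
direct reimplementation of the same formula over the fitted
components (and is cross-checked against the fitted rows in tests).

Decision thresholds: exact main/synonym hits short-circuit at
similarity 1.0 and are always applied; cosine ≥ 0.80
(`accept_threshold`) is applied automatically; ≥ 0.20
(`propose_threshold`) becomes a proposal requiring confirmation;
below that the value is unmatched. Both thresholds are keyword
arguments; the defaults are package choices balancing typo tolerance
against false automation, and the proposal mechanism covers both an
aggressive and a conservative reading of "automatic" curation.

Ranking ties break deterministically: higher similarity, then shorter
surface, then lexicographic surface order. Similarities are quantized
at 1e-12 before ranking so the sparse-matrix path and the pure-Python
brute-force oracle order candidates identically despite last-bit
floating-point differences; reported similarities are unquantized.

`BruteForceMatcher` is an independent oracle — dictionaries and
`math` only, no shared code with the fitted model beyond the gram
extractor — used in tests and in the acceptance script to certify the
indexed path (agreement on top-1 term, and similarity within 1e-9, on
1,000 mixed queries against a 500-term vocabulary).

## The three-pass pipeline

1. **Automatic pass.** Per delimited value of each controlled cell:
   exact lookup, synonym lookup, then nearest-neighbor matching with
   the thresholds above. Numeric cells must parse as plain decimal or
   scientific notation (comma decimals are rejected to keep CSV
   semantics unambiguous); freetext cells pass through verbatim and
   are never split on the delimiter, since comments may legitimately
   contain semicolons.
2. **Substring pass.** Unresolved values are matched where the query
   is a substring of a surface or vice versa, ranked by length ratio.
   Substring hits only ever become proposals — containment is too
   weak a signal to auto-apply.
3. **New-term pass.** Every remaining value must be covered by a
   confirmation: a chosen proposal (recorded as `nn_confirmed` or
   `substring` depending on the proposal's source) or adoption as a
   new main term (`new_term`), which enforces orthogonality and
   refits the affected models. Rejecting a proposal simply leaves the
   value for adoption; nothing errors on rejection.

Multi-value cells use `";"` as the delimiter, each value curated
independently and rejoined in input order without padding.

The pipeline is all-or-nothing with respect to the vocabulary store:
it works on a deep copy and returns it, so a failed submission never
pollutes the caller's vocabularies. After success, every non-empty
controlled value in the output is a main term of the returned store
(checked by `verify_guarantee`, re-checked by the service on study
ingest), and re-running the pipeline on its own output is the
identity with every controlled value resolving as `exact`.

Models are keyed by vocabulary version (an integer bumped on every
mutation); any skew between store and model versions makes both the
pipeline and the service refuse with a retrain-required error rather
than silently matching against a stale space.

## Vocabulary construction from ontology dumps

Two dump dialects cover the shapes the large public ontologies come
in: pipe-delimited node/name tables for ranked taxonomies (scientific
name becomes the node name, every other name class a synonym; a
self-parented node is the root), and TSVs of descriptors with
dot-separated tree numbers, where parentage drops the last dot
segment (`A01` is a parent of `A01.1` but not of `A011`) and a node
with k headings has up to k parents. OBO/XML sources are expected to
be pre-converted to the tree-number dialect; keeping the parsing
surface to two dialects still exercises every extraction rule.

Extraction is subtree selection (roots by node id or heading prefix;
a bare-letter root such as `A` selects all headings whose first
segment extends it with digits) followed by a **closed** set of
exclusion rules: `drop_rank`, `drop_descendants_of_name_containing`
(case-insensitive on normalized names; the matching node is removed
*with* its subtree, since a flagged grouping node is not a useful
term itself), `drop_rank_name_containing`,
`drop_rank_name_matching_digits`, and `subtract_reference`, the
build-time orthogonality mechanism for categories derived from
overlapping sources. Each rule computes its drop set from the full
graph and the union is subtracted, so rule application is conjunctive
and order-independent by construction. The slash rule for unranked
nodes inspects names only, not synonyms. During packaging, node
synonyms that collide with a main term of the same vocabulary are
dropped (main terms are the identity anchors) and a synonym claimed
by two main terms keeps its first assignment in sorted order.

## Synthetic data

Nothing in the package downloads ontologies; term counts of the real
public sources are version-dependent and out of scope. The fixture
generators emulate their structure instead:

* **Vocabularies** — pronounceable CV-syllable terms prefixed by
  their category name, which makes generated stores orthogonal by
  construction; synonyms are abbreviations or reworded variants at a
  configurable rate (default 0.3). Default sizes used in tests and
  the acceptance script: 500 terms for matcher benchmarks, 15–25
  terms per category for pipeline property suites over 50 seeded
  submissions of 6–8 samples — sizes at which the brute-force oracle
  stays exact and fast while exercising every code path.
* **Typos** — compositions of substitute/delete/insert/transpose
  edits, certified to sit at exactly the requested Levenshtein
  distance by an internal DP check (and cross-checked with `edlib` in
  tests).
* **Taxonomy dump** — a 19-node tree in which every exclusion rule
  removes at least one node and five clean species survive; the
  survivor set was derived by hand and frozen as the oracle.
* **Worked example** — the lung/ozone study: matrix of 4 mouse lung
  samples with colloquial spellings, a store covering every value
  except `allergen exposure`, `ozone` and `hours/day`, and the
  hand-written expected output. Cell magnitudes are synthetic
  placeholders; only the category structure, the species synonym
  mapping and the three missing terms mirror the real study. The
  fixture's unit vocabularies (`massUnit`, `ageUnit`, `timeUnit`,
  `drugDoseUnit`) are deliberately disjoint term sets — real unit
  ontology subtrees overlap, and a deployment would resolve that with
  `subtract_reference` at build time, which the fixture sidesteps by
  construction. The `sex` vocabulary is {male, female, hermaphrodite}.

What passing tests on these fixtures does **not** show: robustness to
the scale (10^5–10^6 terms), the heavy synonym skew, or the
multilingual noise of real ontology dumps, nor the behavior of the
thresholds on real submitter typo distributions — those would need
the full downloads that are explicitly out of scope.

## Interfaces

The submission worksheet is RFC 4180 CSV with a required, first
`sampleLabel` column (a per-sample identifier the source material
leaves implicit; it is this package's addition). Unknown headers are
a hard error rather than implicit comments — the `comment` category
is the explicit escape hatch. Unit categories can only be selected
together with their magnitude partner. Vocabularies persist as
three-column TSVs plus a JSON manifest; trigram models serialize to a
single JSON file carrying the vocabulary versions they were fitted
on.

The service layer is an in-process object mirroring the HTTP surface
(categories, terms with prefix/pagination, match, standardize with a
409-style needs-confirmation payload, study submission with ingest
re-validation, string-equality sample queries) plus a stdlib WSGI
adapter; persistence sits behind a small storage protocol with
in-memory and one-JSON-file-per-study backends. Vocabulary mutations
through the service are serialized behind a lock. Authentication,
graph-shaped metadata storage and hierarchical ontology queries are
out of scope.

## Known limitations

* Trigram cosine is a lexical measure: it cannot distinguish
  semantically different but lexically close terms, and very short
  queries carry almost no signal (hence the substring pass and the
  confirmation step).
* Orthogonality is enforced per store; merging two independently
  grown stores may require re-running reference subtraction.
* The delimiter convention gives a list of values no defined
  relationship semantics (a two-species cell does not say co-culture);
  richer relations would need a graph data model.
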