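# samplemeta

Controlled-vocabulary standardization of tabular sample metadata, built
for metabolomics repositories and core facilities that want submitted
studies to be queryable by plain string equality.

## The problem

Meta-analysis across -omics studies fails at the metadata layer: if one
submitter writes "mouse", another "mice" and a third "M. musculus",
aggregating their samples requires natural-language guessing instead of
a one-line query like `species == "mus musculus"`. `samplemeta`
standardizes sample-metadata worksheets (rows = samples, columns =
metadata categories such as `species`, `organ`, `drugName`) so that
every controlled cell ends up as a *main term* from a curated,
per-category vocabulary — while magnitudes (mass, age, dose) pass
through as validated numbers and freetext escape hatches (`comment`,
`inclusion`, `exclusion`) stay untouched.

Three design rules make the result machine-usable:

* **Orthogonality** — no string is a main term of two different
  categories, so a standardized value identifies its category.
* **Non-redundancy** — each concept has exactly one main term; all
  other surfaces ("mouse", "mice", "house mouse") are synonyms mapped
  many-to-one onto it.
* **Expandability** — genuinely new terms are adopted into the
  vocabulary at submission time (after explicit confirmation) and the
  matching models are retrained, so the system improves with use.

## The matcher

Freetext is resolved by a character-trigram tf-idf nearest-neighbor
model. Every vocabulary surface *s* is embedded over the set of
length-3 sliding windows of all surfaces (spaces included; `mus
musculus` → `mus`, `us␣`, `s␣m`, `␣mu`, `usc`, …), weighted by

    w(g, s) = tf(g, s) · ( ln((1 + D) / (1 + df(g))) + 1 )

where `tf` is the gram count within the surface, `df` the number of
surfaces containing the gram and `D` the number of surfaces, followed
by L2 normalization. Queries are coerced into this space and ranked by
cosine similarity; the winning surface's main term is the match.
Standardization runs in three passes:

1. exact / synonym lookup, then nearest-neighbor matching (cosine
   ≥ 0.80 is applied automatically; ≥ 0.20 becomes a proposal);
2. substring rescue for abbreviations and truncations (proposals only);
3. confirmed adoption of new terms, with orthogonality enforced and
   models refitted.

After a successful run **every** non-empty controlled value is a main
term of the (possibly expanded) store, and a second run is the
identity.

Initial vocabularies are built from ontology dumps by subtree
extraction plus a closed set of exclusion rules (drop a rank, drop
subtrees under matching names, drop rank-restricted name patterns,
subtract a reference set); two dump dialects are supported (ranked
taxonomy node/name tables and heading-organised descriptor TSVs).

## Worked example

A lung/ozone exposure study: adult mice of both sexes sensitized to an
allergen, exposed to ozone (represented as a drug), lungs profiled
hours later. The submitter writes "mouse", "mg", "weeks", "BALB/c".

```python
from samplemeta.fixtures import worked_example
from samplemeta.standardizer import standardize, ConfirmationRequired

ex = worked_example()
try:
    standardize(ex.matrix, ex.store)
except ConfirmationRequired as e:
    for p in e.pending[:3]:
        print("pending:", p.category, repr(p.original))

res = standardize(ex.matrix, ex.store, confirmations=ex.confirmations)
print("new terms:", sorted(res.report.new_terms))
```

prints

```
pending: drugName 'ozone'
pending: drugDoseUnit 'hours/day'
pending: zeroTimeEvent 'allergen exposure'
new terms: [('drugDoseUnit', 'hours/day'), ('drugName', 'ozone'), ('zeroTimeEvent', 'allergen exposure')]
```

Everything else resolves automatically — the three listed strings are
the only values absent from the initial vocabularies, and after
confirmation they are adopted into their categories. The standardized
matrix comes back with `mouse`/`mice`/`house mouse` all as
`mus musculus`, `mg` as `milligram`, `weeks` as `week`:

```
sampleLabel,organ,species,sex,age,ageUnit,strain,mass,massUnit,drugName,drugDoseMagnitude,drugDoseUnit,zeroTimeEvent,time,timeUnit
s1,lung,mus musculus,male,8,week,balb/c,23.5,milligram,ozone,0.8,hours/day,allergen exposure,24,hour
s2,lung,mus musculus,female,8,week,balb/c,21.0,milligram,ozone,0.8,hours/day,allergen exposure,24,hour
...
```

The same flow is available from the shell:

```sh
samplemeta schema -s organ -s species -s sex --out template.csv
samplemeta standardize --in submission.csv --vocab-dir vocabs/ \
    --out standardized.csv --report report.json
# exit code 2 => standardized.pending.json lists values needing confirmation
samplemeta standardize --in submission.csv --vocab-dir vocabs/ \
    --confirm confirmations.json --out standardized.csv
```

and programmatically through `samplemeta.service.MetadataService`
(vocabulary queries, matching, standardization, study storage and
string-equality sample retrieval), with a stdlib WSGI adapter for HTTP
deployment.

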