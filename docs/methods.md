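# Methods

## The corpus profile

`phenocurate` models the restricted slice of the GA4GH Phenopacket Schema v2
that literature-curated rare-disease collections actually use. One phenopacket
represents one published individual and carries:

- a **subject** with the identifier used in the source publication (the
  literal `individual` when the publication names none), administrative sex,
  and optional ages at last encounter and at death;
- **phenotypic features**: HPO terms, each observed (default) or explicitly
  excluded, with an optional age of onset. Exclusion is a positive assertion
  of absence and is distinct from a term simply not being mentioned;
- exactly one **disease** (OMIM or Mondo term) with an optional onset — the
  schema itself allows several diseases, so the one-disease constraint is
  enforced as a validation rule (`R0`) rather than a type invariant;
- **interpretations** whose diagnosis must refer to a disease in the disease
  list, each carrying genomic interpretations that link the subject to a
  variant descriptor (gene symbol, HGNC id, transcript-anchored HGVS
  expressions or a free-text label for structural events, GENO allelic
  state, causality status, ACMG class);
- **metadata**: creation provenance, a resource declaration for every
  ontology prefix in use, and at least one PubMed external reference.

The phenopacket id is `PMID_<pmid>_<sanitized individual id>`; sanitization
replaces each maximal run of non-alphanumeric characters with one underscore
so ids stay file-name- and cross-reference-safe. Ids are deterministic and
distinct for distinct (PMID, sanitized id) pairs, which is exactly the
uniqueness the corpus needs because individual ids must be unique within a
publication.

Ages are pure ISO 8601 durations (`P[nY][nM][nW][nD]`; no time-of-day).
Because a case report states "onset at 4 years" without any calendar
reference, duration arithmetic uses fixed conventions — 1 year = 365.25 days,
1 month = 30.44 days, 1 week = 7 days — rather than calendar arithmetic. The
free-text age parser accepts the forms common in curation tables ("4 years",
"6 mo", "newborn" → `P0D`); fractional values fold into the next smaller
unit ("1.5 years" → `P1Y6M`). Non-age time elements (gestational ages,
ranges, timestamps) are out of profile and round-trip opaquely.

## JSON dialect and round-trip guarantees

Files are the lowerCamelCase protobuf JSON mapping used by published
phenopacket repositories: omitted defaults (no `"excluded": false`, no empty
lists, never `null`), ages nested as `{"age": {"iso8601duration": ...}}`,
variant descriptors under
`interpretations[].diagnosis.genomicInterpretations[].variantInterpretation`.
Every parsed object keeps unconsumed keys in an `extras` slot that is written
back verbatim, so:

- read ∘ write is the identity on the domain model;
- write ∘ read canonicalizes (structural JSON equality with the input,
  stable key order) and is idempotent thereafter.

A corpus is a directory tree of `*.json` files read recursively in sorted
order; unparseable files are isolated into a load report instead of aborting.
Duplicate ids are deliberately representable (the container does not enforce
uniqueness) so that the validator can report them.

## Validation rules and severities

Severities follow the curation conventions the corpus is built on: rules that
make a record wrong (diagnosis not in the disease list, malformed or
unprovenanced identifiers, wrong term namespaces, observed+excluded
contradictions, undeclared resources, subject mismatches, more than one
disease) are ERRORs; findings that need a curator's judgement (duplicate
annotations, onset after the last examination, a possibly republished patient
— same individual id and variant set under two PMIDs) are WARNINGs, because
cross-publication deduplication is explicitly a human decision. Term
existence can be checked against a supplied id→label subset (the bundled HPO
subset or a synthetic pool); absence is a WARNING since the full ontology is
never required at run time. Issue lists are sorted, so reports are invariant
under record ordering.

`seed_violations` mutation-tests the engine: it injects `k` violations drawn
uniformly over the injectable rule types, each on a distinct (rule, record)
slot, and returns the ground-truth (code, phenopacket) list. Injections may
produce collateral findings (a bogus term prefix also trips the undeclared-
resource rule); the detection-completeness property only requires every
injected code to be reported at its injected record, which the suite checks
across 20 seeds.

## Tabular ingestion

A curation table has one row per patient and one column per data item. Column
semantics are declared, not guessed: every column must carry a mapping
(`IGNORE` to drop), so silent data loss is impossible. The observed/excluded/
missing cell vocabulary defaults to `+ yes y observed present true 1` /
`- no n excluded absent false 0` / blank `NA n/a ? unknown none .`
(case-insensitive, overridable per column) — chosen to cover the dominant
conventions in published supplementary tables. Cells matching `\d+/\d+` in
phenotype columns are rejected as aggregate-style data, implementing the
individual-level inclusion rule at cell granularity. Row processing is
row-local: a bad cell rejects its row and the rest of the table still
ingests, and permuting rows permutes outputs without changing any packet.
Everything ingest emits is built through the same constructor the library
exposes, so ingest output validates with zero ERRORs by construction.

## The synthetic-corpus generator

The generator emulates the shape of a published corpus of 4916 phenopackets
across 277 Mendelian diseases so that round-trip, validation and analytics
behaviour can be exercised at realistic scale without downloads. Default
conditions:

- **cohort sizes**: discretized log-normal with median 7 and mean 17.7,
  clamped to [1, 463] — matching the reported skew where a few diseases have
  cohorts of hundreds while half have at most 7;
- **genes**: 236 for 277 diseases — 16 genes with two diseases, 7 with four
  and 1 with five (the published collection reports 16 genes with two and 8
  with more than two);
- **alleles**: pathogenic alleles are mostly private, so each disease gets
  roughly 0.35–0.8 alleles per curated individual and individuals cycle
  through the allele list; realized distinct-variant counts land near the
  reported ~0.58 alleles per individual;
- **publications**: 1–4 per disease, individuals split round-robin across
  them, ids `individual_1..n` per publication;
- **phenotypes**: a per-disease signature of 25–40 terms drawn from a pool of
  3000 synthetic HPO ids; each individual samples 4–12 signature terms
  without replacement, 10% of them as exclusions, half of the observed ones
  with an onset no later than the age at last encounter.

All synthetic identifiers live in reserved fake ranges (`HP:9xxxxxx`,
`OMIM:9xxxxx`, `HGNC:9xxxx`, 9-digit PMIDs starting 9000…) so they can never
collide with, or be mistaken for, real ones. Ground truth is bookkept from
the *realized* draw, not the requested distributions, so
`summarize(generate(cfg)) == truth` is an exact equality for every
configuration; the suite checks it over 40+ randomized configurations. The
generator is deterministic: one seed, byte-identical files.

What the generator does **not** emulate: disease-specific feature frequency
structure (signature terms are sampled uniformly), variant pathogenicity
classes beyond CAUSATIVE/heterozygous defaults, families or repeat
encounters, and curation noise other than the explicit seeded mutations.
Green tests therefore demonstrate the machinery (round-trips, rule recall,
statistic conservation), not fidelity of any biological co-occurrence
pattern.

`corpus_to_tables` inverts ingestion for generated corpora — one table per
(disease, publication) with `+`/`-`/blank HPO columns — and the suite checks
that generate → tables → ingest preserves every summary statistic exactly.
Per-feature onsets are the one thing tables drop (a `+` cell has no onset
slot); no summary statistic depends on them.

## Analytics conventions

- Cohort = phenopackets sharing a disease term id; mean individuals/disease
  is `n_phenopackets / n_diseases` (full precision internally, one decimal
  in display); median is the standard middle/mean-of-middles.
- Distinct-variant identity is the string pair (gene symbol, first HGVS
  expression) after whitespace normalization — no allele normalization, no
  cross-gene deduplication. Published pipelines may normalize differently;
  this choice is documented precisely so the distinct-variant count is
  interpretable.
- The distinct-HPO count includes terms used only as exclusions: an excluded
  annotation is still an annotation.
- Publications are distinct numeric PMIDs from metadata external references,
  falling back to the id prefix for records without references.
- The empty corpus yields the all-zero summary (mean and median reported
  as 0).

## Problem sizes and numerical notes

The test suite runs on desk-scale corpora (8–12 diseases, 36–110 records);
the acceptance script additionally draws one full paper-scale corpus
(277 diseases, ≈4900 records, ≈1 s to generate and summarize). Equalities on
summaries are exact (integer counts, identical float expressions); the only
tolerance in the suite is 1e-9 on the mean×diseases=packets conservation
law. Total-day values are rounded to 1e-6 days to keep duration comparisons
stable. Ties in sorting (issues, files, table groups) break on full string
keys, so every artifact is deterministic.
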