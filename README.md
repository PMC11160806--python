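# phenocurate

Tools for building, validating and summarizing corpora of **GA4GH
phenopackets** curated from published rare-disease case reports.

Rare-disease diagnostics and genotype–phenotype research need case-level,
computable phenotype data: for each published patient, the observed (and
explicitly excluded) Human Phenotype Ontology terms, the disease diagnosis
(OMIM/Mondo), the causal variant, ages of onset and last examination, and the
provenance of it all (a PubMed id). The GA4GH Phenopacket Schema is the ISO
standard for exactly this record, and repository-scale collections of such
records — one JSON file per patient, grouped by disease — are what software
like phenotype-driven variant prioritizers are tested against.

`phenocurate` is aimed at curators and bioinformaticians who assemble or
consume such collections. It provides:

- a typed **data model** of the corpus profile of the schema (subject,
  observed/excluded features with onset ages, one disease per record, genomic
  interpretations, PMID-anchored metadata), with the corpus identifier
  convention `PMID_<pmid>_<individual>` (e.g. `PMID_24126608_BAB3022`) and
  ISO 8601 age durations (1 year = 365.25 d, 1 month = 30.44 d);
- lossless **JSON I/O** in the lowerCamelCase protobuf dialect used by
  published phenopacket repositories;
- a **validation engine** with stable machine-readable rule codes
  (`R0`–`R8` per record — diagnosis/disease cross-reference, identifier and
  provenance checks, term-prefix checks, observed-vs-excluded contradictions,
  undeclared ontology resources, onset-after-encounter; `C1`–`C3` per corpus —
  duplicate individuals, duplicate ids, possibly republished patients), plus
  a seeded mutation harness to measure the engine's own recall;
- a **tabular ingest** workflow that turns publication tables (patients in
  rows, one column per data item) into validated phenopackets through
  declarative column mappings, rejecting aggregate-style cells such as
  `7/12`;
- **corpus analytics**: counts of individuals, diseases, genes, distinct
  alleles, publications and distinct HPO terms, cohort-size distribution,
  and gene–disease multiplicity;
- a seeded **synthetic-corpus generator** with exact ground truth, so every
  workflow above can be tested end to end without downloading anything.

## Worked example

```python
from phenocurate import summarize, validate_corpus
from phenocurate.synthetic_corpus import GeneratorConfig, generate_corpus

cfg = GeneratorConfig(seed=11, n_diseases=8, cohort_sizes=[3, 5, 2, 8, 1, 6, 4, 7],
                      hpo_pool_size=80, signature_size_range=(10, 18),
                      features_per_individual=(2, 6),
                      multi_disease_genes=[("SYNG001", 2)])
corpus, truth = generate_corpus(cfg)
summary = summarize(corpus)
print(summary.table())
report = validate_corpus(corpus)
print(f"validation: {report.n_errors} errors, {report.n_warnings} warnings")
print("summary == generator ground truth:", summary == truth)
```

prints

```
phenopackets                36
diseases                    8
genes                       7
distinct variants           23
publications                17
distinct HPO terms          55
mean individuals/disease    4.5
median individuals/disease  4.5
smallest cohort             1
largest cohort              8
genes with two diseases     1
genes with >2 diseases      0

validation: 0 errors, 1 warnings
summary == generator ground truth: True
```

The eight cohorts (3+5+2+8+1+6+4+7 = 36 individuals) come from 17 synthetic
publications; 7 genes cover 8 diseases because one gene (`SYNG001`) was
configured to carry two. The summary computed from the emitted records equals
the generator's bookkept ground truth exactly, and a freshly generated corpus
always validates with zero errors (the single warning here flags two records
that look like the same patient republished under different PMIDs — the
C3 caution, which is informational by design).

The same functionality is available from the shell:

```
phenocurate generate --seed 11 --n-diseases 8 --out corpus/ --tables
phenocurate validate corpus/            # exit 0 iff no ERROR-level findings
phenocurate summarize corpus/ --json summary.json
phenocurate ingest corpus/tables/OMIM_900001_PMID_900000001.csv \
    --mapping corpus/tables/OMIM_900001_PMID_900000001.mapping.yaml \
    --out ingested/
```

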