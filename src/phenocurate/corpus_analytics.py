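"""Corpus-level descriptive statistics.

Summarizes a phenopacket corpus the way a curation project reports itself:
how many individuals, diseases, genes, distinct pathogenic alleles,
publications, and distinct HPO terms it contains; the cohort-size
distribution over diseases; and how many genes are associated with two or
with more than two diseases.

Counting conventions (they matter when comparing against published numbers):

* a *cohort* is the set of phenopackets sharing one disease term id;
* the distinct-variant key is ``(gene symbol, first HGVS expression)`` after
  whitespace normalization — string-level identity, no allele normalization;
* the distinct-HPO count includes terms used only as excluded annotations,
  since an exclusion is an annotation;
* publications are distinct numeric PMIDs drawn from metadata external
  references (falling back to the phenopacket id prefix).
"""

from __future__ import annotations

import json
import statistics
from collections import Counter
from dataclasses import dataclass, field

from .json_io import Corpus
from .model import PHENOPACKET_ID_RE, Phenopacket

__all__ = ["CorpusSummary", "summarize", "cohort_size_distribution",
           "gene_disease_multiplicity"]


@dataclass
class CorpusSummary:
    n_phenopackets: int = 0
    n_diseases: int = 0
    n_genes: int = 0
    n_distinct_variants: int = 0
    n_publications: int = 0
    n_distinct_hpo_terms: int = 0
    mean_individuals_per_disease: float = 0.0
    median_individuals_per_disease: float = 0.0
    min_cohort: int = 0
    max_cohort: int = 0
    genes_with_two_diseases: int = 0
    genes_with_more_than_two_diseases: int = 0
    cohort_size_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cohort_size_histogram"}
        d["cohort_size_histogram"] = {str(k): v for k, v in
                                      sorted(self.cohort_size_histogram.items())}
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def table(self) -> str:
        """Human-readable two-column rendering; the mean is shown to 1 dp."""
        rows = [
            ("phenopackets", self.n_phenopackets),
            ("diseases", self.n_diseases),
            ("genes", self.n_genes),
            ("distinct variants", self.n_distinct_variants),
            ("publications", self.n_publications),
            ("distinct HPO terms", self.n_distinct_hpo_terms),
            ("mean individuals/disease", f"{self.mean_individuals_per_disease:.1f}"),
            ("median individuals/disease", f"{self.median_individuals_per_disease:g}"),
            ("smallest cohort", self.min_cohort),
            ("largest cohort", self.max_cohort),
            ("genes with two diseases", self.genes_with_two_diseases),
            ("genes with >2 diseases", self.genes_with_more_than_two_diseases),
        ]
        width = max(len(name) for name, _ in rows)
        return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)

    def histogram_tsv(self) -> str:
        lines = ["cohort_size\tn_diseases"]
        for size, n in sorted(self.cohort_size_histogram.items()):
            lines.append(f"{size}\t{n}")
        return "\n".join(lines) + "\n"


def _pmids_of(pp: Phenopacket) -> set[str]:
    pmids = set(pp.meta_data.pmids())
    if not pmids:
        m = PHENOPACKET_ID_RE.match(pp.id)
        if m:
            pmids.add(m.group(1))
    return pmids


def _variant_keys_of(pp: Phenopacket) -> set[tuple[str, str]]:
    keys = set()
    for itp in pp.interpretations:
        for gi in itp.genomic_interpretations:
            v = gi.variant
            expr = v.hgvs_expressions[0] if v.hgvs_expressions else (v.label or "")
            keys.add((v.gene_symbol, " ".join(expr.split())))
    return keys


def cohort_size_distribution(corpus: Corpus) -> dict[int, int]:
    """Cohort size -> number of diseases with exactly that many phenopackets."""
    per_disease: Counter[str] = Counter()
    for pp in corpus.phenopackets():
        for disease in pp.diseases[:1]:
            per_disease[disease.term.id] += 1
    histogram: Counter[int] = Counter(per_disease.values())
    return dict(sorted(histogram.items()))


def gene_disease_multiplicity(corpus: Corpus) -> dict[str, set[str]]:
    """Gene symbol -> set of disease term ids it is interpreted as causing.

    Phenopackets without interpretations contribute nothing here (they still
    count toward cohort sizes).
    """
    genes: dict[str, set[str]] = {}
    for pp in corpus.phenopackets():
        for itp in pp.interpretations:
            for gi in itp.genomic_interpretations:
                genes.setdefault(gi.variant.gene_symbol, set()).add(itp.diagnosis_term.id)
    return genes


def summarize(corpus: Corpus) -> CorpusSummary:
    """Compute the full :class:`CorpusSummary` for a corpus.

    Statistics are permutation-invariant over records and need no prior
    validation — they are computed over whatever parsed.  An empty corpus
    yields the all-zero summary.
    """
    n = len(corpus.records)
    per_disease: Counter[str] = Counter()
    hpo_ids: set[str] = set()
    variant_keys: set[tuple[str, str]] = set()
    pmids: set[str] = set()
    for pp in corpus.phenopackets():
        for disease in pp.diseases[:1]:
            per_disease[disease.term.id] += 1
        for f in pp.phenotypic_features:
            hpo_ids.add(f.term.id)
        variant_keys |= _variant_keys_of(pp)
        pmids |= _pmids_of(pp)
    genes = gene_disease_multiplicity(corpus)
    sizes = sorted(per_disease.values())
    n_diseases = len(sizes)
    return CorpusSummary(
        n_phenopackets=n,
        n_diseases=n_diseases,
        n_genes=len(genes),
        n_distinct_variants=len(variant_keys),
        n_publications=len(pmids),
        n_distinct_hpo_terms=len(hpo_ids),
        mean_individuals_per_disease=(n / n_diseases) if n_diseases else 0.0,
        median_individuals_per_disease=float(statistics.median(sizes)) if sizes else 0.0,
        min_cohort=sizes[0] if sizes else 0,
        max_cohort=sizes[-1] if sizes else 0,
        genes_with_two_diseases=sum(1 for ds in genes.values() if len(ds) == 2),
        genes_with_more_than_two_diseases=sum(1 for ds in genes.values() if len(ds) > 2),
        cohort_size_histogram=dict(Counter(sizes)),
    )
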