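"""Seeded generator of realistic multi-disease phenopacket corpora.

The generator produces corpora with the shape of a literature-curated
rare-disease collection: a few hundred Mendelian diseases, each with a gene,
a set of pathogenic alleles, one or more source publications, and a cohort
of individuals annotated with observed/excluded HPO terms.  Everything is
drawn from reserved synthetic identifier ranges (``OMIM:9xxxxx``,
``HP:9xxxxxx``, 9-digit PMIDs starting with 9) so that synthetic records can
never be mistaken for, or collide with, real ones.

Ground truth is computed from the *realized* draws, not from the requested
distributions, so parameter-recovery tests against
:func:`phenocurate.corpus_analytics.summarize` are exact rather than
statistical.  The same seed always yields a byte-identical corpus.

Default configuration
---------------------
Defaults emulate the shape of a published corpus of 4916 phenopackets for
277 diseases: cohort sizes follow a discretized log-normal with median 7 and
mean ≈ 17.7, clamped to [1, 463]; 236 genes of which 16 carry two diseases
and 8 carry more than two; roughly ten alleles and two publications per
disease; and per-disease HPO signatures drawn from a pool large enough to
realize a few thousand distinct terms.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .corpus_analytics import CorpusSummary, summarize
from .errors import ConfigurationError
from .json_io import Corpus
from .model import (
    AgeDuration,
    DiseaseDiagnosis,
    GenomicInterpretation,
    Individual,
    Interpretation,
    OntologyTerm,
    PhenotypicFeature,
    Sex,
    VariantDescriptor,
    build_phenopacket,
)

__all__ = ["GeneratorConfig", "generate_corpus", "corpus_to_tables", "TableBundle"]

_CREATED = "2024-05-29T12:00:00Z"  # fixed so identical seeds give identical bytes


def _default_multi_disease_genes() -> list[tuple[str, int]]:
    # 16 genes with two diseases and 8 with more than two (seven with four,
    # one with five): with 212 single-disease genes this realizes 236 genes
    # and 277 diseases.
    out = [(f"SYNG{i:03d}", 2) for i in range(1, 17)]
    out += [(f"SYNG{i:03d}", 4) for i in range(17, 24)]
    out += [("SYNG024", 5)]
    return out


@dataclass
class GeneratorConfig:
    """Configuration of one synthetic corpus draw.

    ``cohort_sizes`` is either an explicit list (length ``n_diseases``) or
    None, in which case sizes are drawn from a log-normal with the given
    median and mean, rounded and clamped to ``cohort_size_range``.
    """

    seed: int = 0
    n_diseases: int = 277
    cohort_sizes: Sequence[int] | None = None
    cohort_size_median: float = 7.0
    cohort_size_mean: float = 17.7
    cohort_size_range: tuple[int, int] = (1, 463)
    hpo_pool_size: int = 3000
    signature_size_range: tuple[int, int] = (25, 40)
    features_per_individual: tuple[int, int] = (4, 12)
    excluded_fraction: float = 0.1
    variants_per_disease: tuple[int, int] = (1, 463)
    variant_load_range: tuple[float, float] = (0.35, 0.8)
    multi_disease_genes: list[tuple[str, int]] = field(
        default_factory=_default_multi_disease_genes)
    pmids_per_disease: tuple[int, int] = (1, 4)
    onset_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_diseases < 1:
            raise ConfigurationError("n_diseases must be positive")
        if self.cohort_sizes is not None:
            if len(self.cohort_sizes) != self.n_diseases:
                raise ConfigurationError(
                    f"cohort_sizes has {len(self.cohort_sizes)} entries for "
                    f"{self.n_diseases} diseases")
            if any(s < 1 for s in self.cohort_sizes):
                raise ConfigurationError("every cohort needs at least one individual")
        if not 0.0 <= self.excluded_fraction <= 1.0:
            raise ConfigurationError("excluded_fraction must be in [0, 1]")
        if not 0.0 <= self.onset_fraction <= 1.0:
            raise ConfigurationError("onset_fraction must be in [0, 1]")
        if sum(n for _, n in self.multi_disease_genes) > self.n_diseases:
            raise ConfigurationError(
                "multi-disease genes claim more diseases than n_diseases")
        for name, count in self.multi_disease_genes:
            if count < 2:
                raise ConfigurationError(
                    f"multi-disease gene {name} must carry >= 2 diseases")
        if self.hpo_pool_size < self.signature_size_range[1]:
            raise ConfigurationError("hpo_pool_size smaller than a disease signature")
        if self.features_per_individual[0] < 1:
            raise ConfigurationError("individuals need at least one feature")


def _draw_cohort_sizes(cfg: GeneratorConfig, rng: random.Random) -> list[int]:
    if cfg.cohort_sizes is not None:
        return [int(s) for s in cfg.cohort_sizes]
    mu = math.log(cfg.cohort_size_median)
    ratio = cfg.cohort_size_mean / cfg.cohort_size_median
    sigma = math.sqrt(2.0 * math.log(ratio)) if ratio > 1 else 0.0
    lo, hi = cfg.cohort_size_range
    sizes = []
    for _ in range(cfg.n_diseases):
        s = int(round(rng.lognormvariate(mu, sigma)))
        sizes.append(min(max(s, lo), hi))
    return sizes


def _gene_plan(cfg: GeneratorConfig) -> list[str]:
    """Gene symbol for each of the n_diseases diseases, multi-disease genes first."""
    plan: list[str] = []
    for gene, count in cfg.multi_disease_genes:
        plan.extend([gene] * count)
    next_single = 1
    taken = {g for g, _ in cfg.multi_disease_genes}
    while len(plan) < cfg.n_diseases:
        name = f"SYNGS{next_single:04d}"
        next_single += 1
        if name in taken:
            continue
        plan.append(name)
    return plan


def generate_corpus(cfg: GeneratorConfig) -> tuple[Corpus, CorpusSummary]:
    """Draw one synthetic corpus and its exact ground-truth summary.

    The ground truth is bookkept from the realized draw (cohort sizes, the
    variants, PMIDs and HPO terms actually emitted), so
    ``summarize(corpus) == truth`` holds exactly for every configuration.
    """
    rng = random.Random(cfg.seed)
    sizes = _draw_cohort_sizes(cfg, rng)
    genes = _gene_plan(cfg)

    pool = [
        OntologyTerm(id=f"HP:9{k:06d}", label=f"Synthetic phenotype {k}")
        for k in range(1, cfg.hpo_pool_size + 1)
    ]
    heterozygous = OntologyTerm(id="GENO:0000135", label="heterozygous")

    # realized-draw bookkeeping for the exact ground truth
    truth_hpo: set[str] = set()
    truth_variants: set[tuple[str, str]] = set()
    truth_pmids: set[str] = set()
    gene_diseases: dict[str, set[str]] = {}

    packets = []
    pmid_counter = 0
    for d in range(cfg.n_diseases):
        disease_term = OntologyTerm(
            id=f"OMIM:9{d + 1:05d}", label=f"Synthetic disease {d + 1}")
        gene = genes[d]
        hgnc = f"HGNC:9{d + 1:04d}"
        transcript = f"NM_9{d + 1:05d}.1"
        # pathogenic alleles are mostly private, so the allele count scales
        # with the cohort: roughly variant_load alleles per curated individual
        load = rng.uniform(*cfg.variant_load_range)
        lo_v, hi_v = cfg.variants_per_disease
        n_variants = min(max(int(round(sizes[d] * load)), lo_v), hi_v, max(sizes[d], lo_v))
        alleles = [
            f"{transcript}:c.{100 * (v + 1) + rng.randrange(99)}A>G"
            for v in range(n_variants)
        ]
        signature = rng.sample(pool, rng.randint(*cfg.signature_size_range))

        n_pmids = rng.randint(*cfg.pmids_per_disease)
        pmids = []
        for _ in range(n_pmids):
            pmid_counter += 1
            pmids.append(str(900000000 + pmid_counter))

        # split the cohort across this disease's publications
        cohort = sizes[d]
        counts = [0] * n_pmids
        for i in range(cohort):
            counts[i % n_pmids] += 1
        gene_diseases.setdefault(gene, set()).add(disease_term.id)

        allele_cursor = 0  # alleles are mostly private: cycle rather than resample
        for p, (pmid, n_individuals) in enumerate(zip(pmids, counts)):
            if n_individuals == 0:
                continue
            truth_pmids.add(pmid)
            for i in range(1, n_individuals + 1):
                subject_id = f"individual_{i}"
                encounter_years = rng.randint(1, 70)
                subject = Individual(
                    id=subject_id,
                    sex=rng.choice((Sex.MALE, Sex.FEMALE)),
                    age_at_last_encounter=AgeDuration(years=encounter_years),
                )
                n_features = rng.randint(*cfg.features_per_individual)
                n_features = min(n_features, len(signature))
                terms = rng.sample(signature, n_features)
                features = []
                for term in terms:
                    excluded = rng.random() < cfg.excluded_fraction
                    onset = None
                    if not excluded and rng.random() < cfg.onset_fraction:
                        onset = AgeDuration(years=rng.randint(0, encounter_years))
                    features.append(PhenotypicFeature(
                        term=term, excluded=excluded, onset=onset))
                    truth_hpo.add(term.id)
                allele = alleles[allele_cursor % len(alleles)]
                allele_cursor += 1
                truth_variants.add((gene, allele))
                variant = VariantDescriptor(
                    id=f"{gene}-{allele}",
                    gene_symbol=gene,
                    hgnc_id=hgnc,
                    hgvs_expressions=[allele],
                    allelic_state=heterozygous,
                )
                interpretation = Interpretation(
                    id=f"{subject_id}-diagnosis",
                    diagnosis_term=disease_term,
                    genomic_interpretations=[GenomicInterpretation(
                        subject_id=subject_id, variant=variant)],
                )
                disease = DiseaseDiagnosis(
                    term=disease_term,
                    onset=(AgeDuration(years=rng.randint(0, encounter_years))
                           if rng.random() < cfg.onset_fraction else None),
                )
                packets.append(build_phenopacket(
                    subject, features, disease, interpretation, pmid,
                    created=_CREATED, created_by="phenocurate-synthetic",
                ))

    n = len(packets)
    import statistics as _stats
    from collections import Counter as _Counter
    truth = CorpusSummary(
        n_phenopackets=n,
        n_diseases=cfg.n_diseases,
        n_genes=len(gene_diseases),
        n_distinct_variants=len(truth_variants),
        n_publications=len(truth_pmids),
        n_distinct_hpo_terms=len(truth_hpo),
        mean_individuals_per_disease=n / cfg.n_diseases,
        median_individuals_per_disease=float(_stats.median(sizes)),
        min_cohort=min(sizes),
        max_cohort=max(sizes),
        genes_with_two_diseases=sum(1 for ds in gene_diseases.values() if len(ds) == 2),
        genes_with_more_than_two_diseases=sum(
            1 for ds in gene_diseases.values() if len(ds) > 2),
        cohort_size_histogram=dict(_Counter(sizes)),
    )
    return Corpus.from_phenopackets(packets), truth


@dataclass
class TableBundle:
    """One publication-style table (patients in rows) plus its mapping config."""

    pmid: str
    disease: DiseaseDiagnosis
    frame: pd.DataFrame
    mapping_config: dict


def corpus_to_tables(corpus: Corpus) -> list[TableBundle]:
    """Render a generated corpus back into curation tables, one per
    (disease, publication) group — the inverse of the ingest workflow.

    HPO columns are keyed by term id with ``+``/``-``/blank cells; sex, age
    at last encounter, and the variant ride along as dedicated columns.
    Ingesting each bundle's frame under its mapping config reproduces the
    corpus summary statistics.
    """
    groups: dict[tuple[str, str], list] = {}
    for pp in corpus.phenopackets():
        disease = pp.diseases[0]
        pmid = pp.meta_data.pmids()[0]
        groups.setdefault((disease.term.id, pmid), []).append(pp)

    bundles = []
    for (disease_id, pmid), members in sorted(groups.items()):
        disease = members[0].diseases[0]
        term_labels: dict[str, str] = {}
        for pp in members:
            for f in pp.phenotypic_features:
                term_labels.setdefault(f.term.id, f.term.label)
        hpo_columns = sorted(term_labels)
        gene = None
        hgnc = None
        for pp in members:
            for itp in pp.interpretations:
                for gi in itp.genomic_interpretations:
                    gene = gi.variant.gene_symbol
                    hgnc = gi.variant.hgnc_id
        rows = []
        for pp in members:
            status = {f.term.id: ("-" if f.excluded else "+")
                      for f in pp.phenotypic_features}
            variant_cell = ""
            for itp in pp.interpretations:
                for gi in itp.genomic_interpretations:
                    if gi.variant.hgvs_expressions:
                        variant_cell = gi.variant.hgvs_expressions[0]
                    elif gi.variant.label:
                        variant_cell = gi.variant.label
            age = pp.subject.age_at_last_encounter
            row = {
                "individual_id": pp.subject.id,
                "sex": pp.subject.sex.value,
                "age_last_encounter": age.iso8601 if age else "",
                "variant": variant_cell,
            }
            row.update({t: status.get(t, "") for t in hpo_columns})
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["individual_id", "sex",
                                            "age_last_encounter", "variant",
                                            *hpo_columns])
        columns_cfg: dict = {
            "individual_id": {"kind": "identifier"},
            "sex": {"kind": "sex"},
            "age_last_encounter": {"kind": "age", "field": "last_encounter"},
            "variant": {"kind": "variant", "gene": gene or "UNKNOWN",
                        **({"hgnc": hgnc} if hgnc else {})},
        }
        for t in hpo_columns:
            columns_cfg[t] = {"kind": "hpo_simple",
                              "term": {"id": t, "label": term_labels[t]}}
        bundles.append(TableBundle(
            pmid=pmid,
            disease=disease,
            frame=frame,
            mapping_config={
                "pmid": pmid,
                "disease": {"id": disease.term.id, "label": disease.term.label},
                "columns": columns_cfg,
            },
        ))
    return bundles
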