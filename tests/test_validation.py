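"""The validation rule engine: per-record rules, corpus rules, seeded mutations."""

import copy

import pytest

from phenocurate.errors import CapacityError
from phenocurate.json_io import Corpus
from phenocurate.model import (
    AgeDuration,
    ExternalReference,
    OntologyTerm,
    PhenotypicFeature,
)
from phenocurate.validation import (
    Severity,
    seed_violations,
    validate_corpus,
    validate_phenopacket,
)
from phenocurate.synthetic_corpus import generate_corpus

from conftest import make_marfan_phenopacket, small_config


class TestPhenopacketRules:
    def test_clean_marfan_passes(self, marfan_phenopacket):
        report = validate_phenopacket(marfan_phenopacket)
        assert report.passed
        assert report.issues == []

    def test_r1_interpretation_diagnosis_not_in_disease_list(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.interpretations[0].diagnosis_term = OntologyTerm(
            id="OMIM:129600", label="Some other disease")
        report = validate_phenopacket(pp)
        assert [i.code for i in report.errors()] == ["R1_DISEASE_MISMATCH"]

    def test_r2_id_without_pmid_prefix(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.id = "case_A"
        assert validate_phenopacket(pp).by_code("R2_ID_PMID")

    def test_r2_pmid_missing_from_external_references(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.meta_data.external_references = [ExternalReference(id="PMID:99999999")]
        issues = validate_phenopacket(pp).by_code("R2_ID_PMID")
        assert issues and issues[0].level is Severity.ERROR

    def test_r3_non_hp_feature_and_non_disease_prefix(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.phenotypic_features[0].term = OntologyTerm(id="MP:0001262", label="mouse term")
        pp.diseases[0].term = OntologyTerm(id="DOID:14323", label="wrong terminology")
        pp.interpretations[0].diagnosis_term = pp.diseases[0].term
        codes = [i.code for i in validate_phenopacket(pp).errors()]
        assert codes.count("R3_TERM_PREFIX") == 2

    def test_r4_observed_and_excluded_contradiction(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        scoliosis = OntologyTerm(id="HP:0002650", label="Scoliosis")
        pp.phenotypic_features.append(PhenotypicFeature(term=scoliosis))  # also excluded
        report = validate_phenopacket(pp)
        assert [i.code for i in report.errors()] == ["R4_OBSERVED_AND_EXCLUDED"]

    def test_r5_duplicate_same_status_is_warning_only(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.phenotypic_features.append(copy.deepcopy(pp.phenotypic_features[1]))
        report = validate_phenopacket(pp)
        assert report.passed
        assert [i.code for i in report.issues] == ["R5_DUPLICATE_FEATURE"]

    def test_r6_undeclared_prefix(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.meta_data.resources = [r for r in pp.meta_data.resources
                                  if r.namespace_prefix != "GENO"]
        issues = validate_phenopacket(pp).by_code("R6_UNDECLARED_PREFIX")
        assert issues and "GENO" in issues[0].message

    def test_r7_onset_after_last_encounter(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.phenotypic_features[0].onset = AgeDuration(years=40)  # encounter is P27Y
        report = validate_phenopacket(pp)
        assert report.passed  # a warning, not an error
        assert report.by_code("R7_ONSET_AFTER_ENCOUNTER")

    def test_r8_genomic_interpretation_subject_mismatch(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.interpretations[0].genomic_interpretations[0].subject_id = "B"
        assert [i.code for i in validate_phenopacket(pp).errors()] == \
            ["R8_SUBJECT_MISMATCH"]

    def test_r0_multiple_diseases_violate_corpus_profile(self, marfan_phenopacket):
        pp = copy.deepcopy(marfan_phenopacket)
        pp.diseases.append(copy.deepcopy(pp.diseases[0]))
        pp.diseases[1].term = OntologyTerm(id="OMIM:129600", label="Second disease")
        assert validate_phenopacket(pp).by_code("R0_DISEASE_COUNT")

    def test_known_term_subset_check_is_warning(self, marfan_phenopacket):
        subset = {"HP:0001083": "Ectopia lentis"}  # everything else unknown
        report = validate_phenopacket(marfan_phenopacket, known_terms=subset)
        assert report.passed
        assert len(report.by_code("TERM_NOT_IN_SUBSET")) == 3


class TestCorpusRules:
    def test_empty_corpus_passes_vacuously(self):
        report = validate_corpus(Corpus())
        assert report.passed and report.issues == []

    def test_c1_duplicate_individual_within_publication(self, marfan_phenopacket):
        twin = copy.deepcopy(marfan_phenopacket)
        twin.id = marfan_phenopacket.id + "_again"
        corpus = Corpus.from_phenopackets([marfan_phenopacket, twin])
        issues = validate_corpus(corpus).by_code("C1_DUPLICATE_INDIVIDUAL")
        assert len(issues) == 1
        assert issues[0].level is Severity.ERROR

    def test_c2_duplicate_phenopacket_id(self, marfan_phenopacket):
        corpus = Corpus.from_phenopackets(
            [marfan_phenopacket, copy.deepcopy(marfan_phenopacket)])
        assert validate_corpus(corpus).by_code("C2_DUPLICATE_PHENOPACKET_ID")

    def test_c3_same_patient_same_variants_different_pmids(self, marfan_phenopacket):
        republished = copy.deepcopy(marfan_phenopacket)
        republished.id = "PMID_300000002_A"
        republished.meta_data.external_references = [
            ExternalReference(id="PMID:300000002")]
        corpus = Corpus.from_phenopackets([marfan_phenopacket, republished])
        report = validate_corpus(corpus)
        assert report.passed  # caution, not an error
        assert report.by_code("C3_POSSIBLE_REPUBLICATION")

    def test_issue_list_invariant_under_record_order(self, small_corpus):
        corpus, _ = small_corpus
        mutated, _ = seed_violations(corpus, k=6, seed=3)
        forward = validate_corpus(mutated)
        reversed_corpus = Corpus(records=list(reversed(mutated.records)))
        assert validate_corpus(reversed_corpus).issues == forward.issues

    def test_generated_corpora_have_zero_errors(self, small_corpus):
        corpus, _ = small_corpus
        assert validate_corpus(corpus).n_errors == 0


class TestSeedViolations:
    def test_k_zero_rejected(self, small_corpus):
        with pytest.raises(CapacityError):
            seed_violations(small_corpus[0], k=0, seed=1)

    def test_single_record_hosts_one_violation(self, marfan_phenopacket):
        corpus = Corpus.from_phenopackets([marfan_phenopacket])
        mutated, injected = seed_violations(corpus, k=1, seed=4)
        assert len(injected) == 1
        assert injected[0].detected_in(validate_corpus(mutated))

    def test_determinism_same_seed_same_mutations(self, small_corpus):
        corpus, _ = small_corpus
        a = seed_violations(corpus, k=10, seed=21)[1]
        b = seed_violations(corpus, k=10, seed=21)[1]
        assert a == b

    def test_input_corpus_untouched(self, small_corpus):
        corpus, _ = small_corpus
        before = validate_corpus(corpus).n_errors
        seed_violations(corpus, k=8, seed=2)
        assert validate_corpus(corpus).n_errors == before == 0

    def test_capacity_error_when_corpus_too_small(self, marfan_phenopacket):
        corpus = Corpus.from_phenopackets([marfan_phenopacket])
        with pytest.raises(CapacityError):
            seed_violations(corpus, k=50, seed=1)

    def test_all_injected_violations_detected(self, small_corpus):
        corpus, _ = small_corpus
        mutated, injected = seed_violations(corpus, k=25, seed=7)
        report = validate_corpus(mutated)
        assert len(injected) == 25
        for violation in injected:
            assert violation.detected_in(report), violation
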