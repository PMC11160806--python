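"""JSON serialization: protobuf-dialect reading, canonical writing, round-trips."""

import json

import pytest

from phenocurate.errors import PhenocurateError, SchemaError
from phenocurate.json_io import (
    Corpus,
    phenopacket_to_dict,
    read_corpus,
    read_phenopacket,
    write_corpus,
    write_phenopacket,
)
from phenocurate.corpus_analytics import summarize
from phenocurate.synthetic_corpus import GeneratorConfig, generate_corpus

from conftest import small_config


class TestReadPhenopacket:
    def test_marfan_document(self, marfan_json_text):
        pp = read_phenopacket(marfan_json_text)
        assert pp.id == "PMID_300000001_A"
        assert len(pp.diseases) == 1
        assert pp.diseases[0].term.id == "OMIM:154700"
        assert len(pp.interpretations) == 1
        gi = pp.interpretations[0].genomic_interpretations[0]
        assert gi.variant.gene_symbol == "FBN1"
        assert gi.variant.hgvs_expressions == ["NM_000138.4:c.4082G>A"]
        excluded = [f for f in pp.phenotypic_features if f.excluded]
        assert [f.term.id for f in excluded] == ["HP:0002650"]
        assert pp.phenotypic_features[0].onset.iso8601 == "P4Y"

    def test_minimal_document_yields_empty_lists(self):
        pp = read_phenopacket('{"id": "PMID_1_x", "subject": {"id": "x"}, "metaData": {}}')
        assert pp.phenotypic_features == []
        assert pp.diseases == []
        assert pp.interpretations == []

    def test_malformed_json_reports_position(self):
        with pytest.raises(SchemaError) as excinfo:
            read_phenopacket('{"id": "x", ')
        assert "line" in str(excinfo.value)

    @pytest.mark.parametrize("doc,missing", [
        ('{"subject": {"id": "x"}}', "id"),
        ('{"id": "x"}', "subject"),
        ('{"id": "x", "subject": {}}', "id"),
    ])
    def test_missing_required_field_named(self, doc, missing):
        with pytest.raises(SchemaError) as excinfo:
            read_phenopacket(doc)
        assert missing in str(excinfo.value)


class TestWritePhenopacket:
    def test_excluded_feature_emitted_observed_omitted(self, marfan_phenopacket):
        data = phenopacket_to_dict(marfan_phenopacket)
        flags = {f["type"]["id"]: f.get("excluded") for f in data["phenotypicFeatures"]}
        assert flags["HP:0002650"] is True
        assert flags["HP:0001083"] is None  # protobuf dialect: defaults omitted

    def test_onset_nested_as_age_element(self, marfan_phenopacket):
        data = phenopacket_to_dict(marfan_phenopacket)
        assert data["phenotypicFeatures"][0]["onset"] == {
            "age": {"iso8601duration": "P4Y"}}

    def test_no_nulls_anywhere(self, marfan_phenopacket):
        text = write_phenopacket(marfan_phenopacket)
        assert "null" not in text

    def test_write_is_utf8_file(self, tmp_path, marfan_phenopacket):
        path = tmp_path / "pp.json"
        write_phenopacket(marfan_phenopacket, path)
        assert json.loads(path.read_text(encoding="utf-8"))["id"] == marfan_phenopacket.id


class TestRoundTrip:
    def test_read_write_identity_on_generated_corpus(self):
        corpus, _ = generate_corpus(small_config(seed=5))
        assert len(corpus) >= 30
        for pp in corpus.phenopackets():
            text = write_phenopacket(pp)
            again = write_phenopacket(read_phenopacket(text))
            assert again == text

    def test_write_read_canonicalizes_idempotently(self, marfan_json_text):
        once = write_phenopacket(read_phenopacket(marfan_json_text))
        twice = write_phenopacket(read_phenopacket(once))
        assert once == twice
        # structural equality with the input, ignoring key order
        assert json.loads(once) == json.loads(marfan_json_text)

    def test_unknown_fields_survive_round_trip(self, marfan_json_text):
        data = json.loads(marfan_json_text)
        data["measurements"] = [{"assay": {"id": "LOINC:26515-7", "label": "Platelets"}}]
        data["subject"]["karyotypicSex"] = "XX"
        out = json.loads(write_phenopacket(read_phenopacket(json.dumps(data))))
        assert out["measurements"] == data["measurements"]
        assert out["subject"]["karyotypicSex"] == "XX"


class TestCorpusIO:
    def test_read_counts_json_files(self, tmp_path, small_corpus):
        corpus, _ = small_corpus
        write_corpus(corpus, tmp_path)
        loaded = read_corpus(tmp_path)
        assert len(loaded) == len(corpus)
        assert not loaded.load_failures
        index = loaded.index_by_disease
        assert sum(len(v) for v in index.values()) == len(corpus)

    def test_malformed_file_isolated_in_load_report(self, tmp_path, marfan_phenopacket):
        write_phenopacket(marfan_phenopacket, tmp_path / "good1.json")
        other = read_phenopacket(write_phenopacket(marfan_phenopacket))
        other.id = "PMID_300000001_B"
        other.subject.id = "B"
        write_phenopacket(other, tmp_path / "good2.json")
        (tmp_path / "broken.json").write_text("{not json", encoding="utf-8")
        corpus = read_corpus(tmp_path)
        assert len(corpus) == 2
        assert len(corpus.load_failures) == 1
        assert corpus.load_failures[0].path.name == "broken.json"

    def test_empty_directory_is_empty_corpus(self, tmp_path):
        corpus = read_corpus(tmp_path)
        assert len(corpus) == 0

    def test_missing_directory_raises(self, tmp_path):
        with pytest.raises(PhenocurateError):
            read_corpus(tmp_path / "nope")

    def test_summary_stable_across_disk_round_trip(self, tmp_path, small_corpus):
        corpus, truth = small_corpus
        write_corpus(corpus, tmp_path)
        assert summarize(read_corpus(tmp_path)) == truth
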