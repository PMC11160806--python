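"""Tabular ingestion: column mappings, cell vocabularies, row-local errors."""

import pytest

from phenocurate.errors import CellParseError, ConfigurationError, IngestError
from phenocurate.hpo import HPO_SUBSET
from phenocurate.model import DiseaseDiagnosis, OntologyTerm, Sex
from phenocurate.corpus_analytics import summarize
from phenocurate.json_io import Corpus
from phenocurate.synthetic_corpus import corpus_to_tables, generate_corpus
from phenocurate.tabular_ingest import (
    ColumnMapping,
    MappingKind,
    ingest,
    load_template,
    mappings_from_config,
    parse_cell,
)

from conftest import MARFAN, small_config

SCOLIOSIS = OntologyTerm(id="HP:0002650", label=HPO_SUBSET["HP:0002650"])
PES_PLANUS = OntologyTerm(id="HP:0001763", label=HPO_SUBSET["HP:0001763"])

TOY_CSV = """patient,Sex,Age,Scoliosis,Pes planus,Variant
P1,M,P10Y,+,-,c.100A>G
P2,F,33 years,-,+,c.200C>T
,U,,?,+,c.100A>G
"""


def toy_mappings():
    return [
        ColumnMapping("patient", MappingKind.IDENTIFIER),
        ColumnMapping("Sex", MappingKind.SEX),
        ColumnMapping("Age", MappingKind.AGE, {"field": "last_encounter"}),
        ColumnMapping("Scoliosis", MappingKind.HPO_SIMPLE, {"term": SCOLIOSIS}),
        ColumnMapping("Pes planus", MappingKind.HPO_SIMPLE, {"term": PES_PLANUS}),
        ColumnMapping("Variant", MappingKind.VARIANT,
                      {"gene": "FBN1", "transcript": "NM_000138.4",
                       "hgnc": "HGNC:3603"}),
    ]


@pytest.fixture
def toy_template(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(TOY_CSV, encoding="utf-8")
    return load_template(path, toy_mappings(), pmid="55555555",
                         disease=DiseaseDiagnosis(term=MARFAN))


class TestLoadTemplate:
    def test_rows_counted(self, toy_template):
        assert len(toy_template.rows) == 3

    def test_unmapped_column_is_named_in_the_error(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(TOY_CSV, encoding="utf-8")
        mappings = [m for m in toy_mappings() if m.column_name != "Scoliosis"]
        with pytest.raises(ConfigurationError, match="Scoliosis"):
            load_template(path, mappings, pmid="55555555",
                          disease=DiseaseDiagnosis(term=MARFAN))

    def test_duplicate_row_identifiers_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("patient,Scoliosis\nP1,+\nP1,-\n", encoding="utf-8")
        mappings = [ColumnMapping("patient", MappingKind.IDENTIFIER),
                    ColumnMapping("Scoliosis", MappingKind.HPO_SIMPLE,
                                  {"term": SCOLIOSIS})]
        with pytest.raises(IngestError, match="P1"):
            load_template(path, mappings, pmid="55555555",
                          disease=DiseaseDiagnosis(term=MARFAN))

    def test_csv_and_xlsx_encodings_agree(self, tmp_path, toy_template):
        import pandas as pd
        xlsx = tmp_path / "cohort.xlsx"
        pd.read_csv(tmp_path / "cohort.csv", dtype=str,
                    keep_default_na=False).to_excel(xlsx, index=False)
        from_xlsx = load_template(xlsx, toy_mappings(), pmid="55555555",
                                  disease=DiseaseDiagnosis(term=MARFAN))
        assert from_xlsx.rows == toy_template.rows

    def test_ignore_columns_are_dropped(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("patient,Notes,Scoliosis\nP1,long prose,+\n", encoding="utf-8")
        template = load_template(
            path,
            [ColumnMapping("patient", MappingKind.IDENTIFIER),
             ColumnMapping("Notes", MappingKind.IGNORE),
             ColumnMapping("Scoliosis", MappingKind.HPO_SIMPLE, {"term": SCOLIOSIS})],
            pmid="55555555", disease=DiseaseDiagnosis(term=MARFAN))
        assert "Notes" not in template.rows[0]


class TestParseCell:
    simple = ColumnMapping("Scoliosis", MappingKind.HPO_SIMPLE, {"term": SCOLIOSIS})

    @pytest.mark.parametrize("token", ["+", "yes", "Y", "observed", "Present"])
    def test_observed_vocabulary(self, token):
        (feature,) = parse_cell(token, self.simple)
        assert feature.term.id == "HP:0002650" and not feature.excluded

    @pytest.mark.parametrize("token", ["-", "no", "N", "excluded", "absent"])
    def test_excluded_vocabulary(self, token):
        (feature,) = parse_cell(token, self.simple)
        assert feature.excluded

    @pytest.mark.parametrize("token", ["", "NA", "n/a", "?", "unknown"])
    def test_missing_vocabulary_emits_nothing(self, token):
        assert parse_cell(token, self.simple) == []

    def test_unrecognized_token_carries_coordinates(self):
        with pytest.raises(CellParseError) as excinfo:
            parse_cell("severe", self.simple, row="P1")
        assert excinfo.value.column == "Scoliosis"
        assert excinfo.value.row == "P1"

    def test_aggregate_cell_rejected(self):
        # "7/12 patients" style summaries violate the individual-level rule
        with pytest.raises(CellParseError) as excinfo:
            parse_cell("7/12", self.simple, row="cohort")
        assert excinfo.value.aggregate

    def test_option_mapping_emits_term_sets(self):
        mapping = ColumnMapping("Spine", MappingKind.HPO_OPTION, {
            "options": {"scoliosis+flat feet": [SCOLIOSIS, PES_PLANUS]}})
        features = parse_cell("Scoliosis+Flat Feet", mapping)
        assert [f.term.id for f in features] == ["HP:0002650", "HP:0001763"]

    def test_option_value_absent_from_map(self):
        mapping = ColumnMapping("Spine", MappingKind.HPO_OPTION,
                                {"options": {"mild": [SCOLIOSIS]}})
        with pytest.raises(CellParseError):
            parse_cell("severe", mapping)

    def test_variant_cell_anchored_on_transcript(self):
        mapping = ColumnMapping("Variant", MappingKind.VARIANT,
                                {"gene": "FBN1", "transcript": "NM_000138.4"})
        descriptor = parse_cell("c.100A>G", mapping)
        assert descriptor.hgvs_expressions == ["NM_000138.4:c.100A>G"]

    def test_variant_without_transcript_kept_as_label(self):
        mapping = ColumnMapping("Variant", MappingKind.VARIANT, {"gene": "FBN1"})
        descriptor = parse_cell("del exon 2-5", mapping)
        assert descriptor.label == "del exon 2-5"
        assert descriptor.hgvs_expressions == []

    def test_age_cell_routed_to_parser(self):
        mapping = ColumnMapping("Age", MappingKind.AGE)
        assert parse_cell("4 years", mapping).iso8601 == "P4Y"
        assert parse_cell("", mapping) is None


class TestIngest:
    def test_one_phenopacket_per_row_with_derived_ids(self, toy_template):
        packets, report = ingest(toy_template)
        assert report.n_succeeded == 3 and not report.row_errors
        assert packets[0].id == "PMID_55555555_P1"
        assert packets[1].subject.sex is Sex.FEMALE

    def test_blank_identifier_becomes_individual(self, toy_template):
        packets, _ = ingest(toy_template)
        assert packets[2].id.endswith("_individual")

    def test_everything_ingested_validates_clean(self, toy_template):
        _, report = ingest(toy_template)
        assert report.validation.n_errors == 0

    def test_bad_row_rejected_others_processed(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("patient,Scoliosis\nP1,+\nP2,7/12\nP3,-\n", encoding="utf-8")
        template = load_template(
            path,
            [ColumnMapping("patient", MappingKind.IDENTIFIER),
             ColumnMapping("Scoliosis", MappingKind.HPO_SIMPLE, {"term": SCOLIOSIS})],
            pmid="55555555", disease=DiseaseDiagnosis(term=MARFAN))
        packets, report = ingest(template)
        assert [pp.subject.id for pp in packets] == ["P1", "P3"]
        assert len(report.row_errors) == 1 and report.row_errors[0][0] == "P2"

    def test_row_permutation_only_permutes_outputs(self, toy_template):
        import copy
        packets, _ = ingest(toy_template)
        shuffled = copy.deepcopy(toy_template)
        shuffled.rows = list(reversed(shuffled.rows))
        shuffled_packets, _ = ingest(shuffled)
        from phenocurate.json_io import write_phenopacket
        assert sorted(write_phenopacket(pp) for pp in packets) == \
            sorted(write_phenopacket(pp) for pp in shuffled_packets)

    def test_table_round_trip_preserves_summary(self, tmp_path):
        corpus, truth = generate_corpus(small_config(seed=17))
        packets = []
        for i, bundle in enumerate(corpus_to_tables(corpus)):
            path = tmp_path / f"table_{i}.csv"
            bundle.frame.to_csv(path, index=False)
            mappings, pmid, disease = mappings_from_config(bundle.mapping_config)
            template = load_template(path, mappings, pmid=pmid, disease=disease)
            got, report = ingest(template)
            assert not report.row_errors
            packets.extend(got)
        assert summarize(Corpus.from_phenopackets(packets)) == truth
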