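import pytest

from phenocurate.model import (
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
from phenocurate.synthetic_corpus import GeneratorConfig, generate_corpus

MARFAN = OntologyTerm(id="OMIM:154700", label="Marfan syndrome")
HETEROZYGOUS = OntologyTerm(id="GENO:0000135", label="heterozygous")
MARFAN_PMID = "300000001"  # synthetic provenance anchor for the worked example


def make_marfan_phenopacket(diagnosis: OntologyTerm = MARFAN):
    """A Marfan-syndrome case: FBN1 variant interpreted as causal, classic
    connective-tissue features, one excluded feature, onset ages."""
    subject = Individual(
        id="A", sex=Sex.FEMALE,
        age_at_last_encounter=AgeDuration(years=27),
    )
    features = [
        PhenotypicFeature(term=OntologyTerm(id="HP:0001083", label="Ectopia lentis"),
                          onset=AgeDuration(years=4)),
        PhenotypicFeature(term=OntologyTerm(id="HP:0002616", label="Aortic root aneurysm")),
        PhenotypicFeature(term=OntologyTerm(id="HP:0001166", label="Arachnodactyly")),
        PhenotypicFeature(term=OntologyTerm(id="HP:0002650", label="Scoliosis"),
                          excluded=True),
    ]
    variant = VariantDescriptor(
        id="FBN1-NM_000138.4:c.4082G>A",
        gene_symbol="FBN1",
        hgnc_id="HGNC:3603",
        hgvs_expressions=["NM_000138.4:c.4082G>A"],
        allelic_state=HETEROZYGOUS,
    )
    interpretation = Interpretation(
        id="A-diagnosis",
        diagnosis_term=diagnosis,
        genomic_interpretations=[GenomicInterpretation(subject_id="A", variant=variant)],
    )
    disease = DiseaseDiagnosis(term=MARFAN, onset=AgeDuration(years=4))
    return build_phenopacket(subject, features, disease, interpretation, MARFAN_PMID,
                             created="2024-01-01T00:00:00Z", created_by="tests")


@pytest.fixture
def marfan_phenopacket():
    return make_marfan_phenopacket()


# A hand-written lowerCamelCase document, independent of this package's writer.
MARFAN_JSON = """
{
  "id": "PMID_300000001_A",
  "subject": {
    "id": "A",
    "timeAtLastEncounter": {"age": {"iso8601duration": "P27Y"}},
    "sex": "FEMALE"
  },
  "phenotypicFeatures": [
    {"type": {"id": "HP:0001083", "label": "Ectopia lentis"},
     "onset": {"age": {"iso8601duration": "P4Y"}}},
    {"type": {"id": "HP:0002616", "label": "Aortic root aneurysm"}},
    {"type": {"id": "HP:0002650", "label": "Scoliosis"}, "excluded": true}
  ],
  "interpretations": [
    {
      "id": "A-diagnosis",
      "progressStatus": "SOLVED",
      "diagnosis": {
        "disease": {"id": "OMIM:154700", "label": "Marfan syndrome"},
        "genomicInterpretations": [
          {
            "subjectOrBiosampleId": "A",
            "interpretationStatus": "CAUSATIVE",
            "variantInterpretation": {
              "variationDescriptor": {
                "id": "FBN1-NM_000138.4:c.4082G>A",
                "geneContext": {"valueId": "HGNC:3603", "symbol": "FBN1"},
                "expressions": [
                  {"syntax": "hgvs.c", "value": "NM_000138.4:c.4082G>A"}
                ],
                "allelicState": {"id": "GENO:0000135", "label": "heterozygous"}
              }
            }
          }
        ]
      }
    }
  ],
  "diseases": [
    {"term": {"id": "OMIM:154700", "label": "Marfan syndrome"},
     "onset": {"age": {"iso8601duration": "P4Y"}}}
  ],
  "metaData": {
    "created": "2024-01-01T00:00:00Z",
    "createdBy": "tests",
    "resources": [
      {"id": "hp", "name": "human phenotype ontology",
       "url": "http://purl.obolibrary.org/obo/hp.owl", "version": "2024-01-01",
       "namespacePrefix": "HP", "iriPrefix": "http://purl.obolibrary.org/obo/HP_"},
      {"id": "omim", "name": "An Online Catalog of Human Genes and Genetic Disorders",
       "url": "https://www.omim.org", "version": "2024-01-01",
       "namespacePrefix": "OMIM", "iriPrefix": "https://www.omim.org/entry/"},
      {"id": "geno", "name": "Genotype Ontology",
       "url": "http://purl.obolibrary.org/obo/geno.owl", "version": "2023-10-08",
       "namespacePrefix": "GENO", "iriPrefix": "http://purl.obolibrary.org/obo/GENO_"},
      {"id": "hgnc", "name": "HUGO Gene Nomenclature Committee",
       "url": "https://www.genenames.org", "version": "2024-01-01",
       "namespacePrefix": "HGNC",
       "iriPrefix": "https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/"}
    ],
    "phenopacketSchemaVersion": "2.0.0",
    "externalReferences": [{"id": "PMID:300000001"}]
  }
}
"""


@pytest.fixture
def marfan_json_text():
    return MARFAN_JSON


def small_config(seed: int = 11) -> GeneratorConfig:
    """A desk-scale generator configuration used across the suite."""
    return GeneratorConfig(
        seed=seed, n_diseases=8,
        cohort_sizes=[3, 5, 2, 8, 1, 6, 4, 7],
        hpo_pool_size=80, signature_size_range=(10, 18),
        features_per_individual=(2, 6),
        multi_disease_genes=[("SYNG001", 2)],
    )


@pytest.fixture
def small_corpus():
    return generate_corpus(small_config())
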