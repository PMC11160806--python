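"""Read and write phenopackets as protobuf-dialect JSON.

The on-disk format is the lowerCamelCase JSON mapping of the Phenopacket
Schema v2 used by literature-curated phenopacket repositories: one JSON
document per phenopacket, one file per document, files grouped in per-cohort
sub-directories.  Protobuf conventions apply — absent optionals and default
values (``false``, empty lists) are omitted, never written as ``null``.

Fields outside the corpus profile (biosamples, measurements, medical
actions, non-age time elements, ...) are preserved verbatim in per-object
``extras`` slots so that read -> write is lossless and write -> read is
canonicalizing and idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

from .errors import PhenocurateError, SchemaError
from .model import (
    AcmgClassification,
    AgeDuration,
    DiseaseDiagnosis,
    ExternalReference,
    GenomicInterpretation,
    Individual,
    Interpretation,
    InterpretationStatus,
    MetaData,
    OntologyTerm,
    PhenotypicFeature,
    Phenopacket,
    Resource,
    Sex,
    VariantDescriptor,
)

__all__ = [
    "Corpus",
    "CorpusRecord",
    "LoadFailure",
    "read_phenopacket",
    "write_phenopacket",
    "phenopacket_to_dict",
    "phenopacket_from_dict",
    "read_corpus",
    "write_corpus",
]


# ---------------------------------------------------------------------------
# helpers

def _age_element(age: AgeDuration | None) -> dict | None:
    """TimeElement carrying an Age, the only variant in the corpus profile."""
    if age is None:
        return None
    return {"age": {"iso8601duration": age.iso8601}}


def _parse_time_element(elem: Any) -> tuple[AgeDuration | None, Any]:
    """Return (age, passthrough).  Non-age TimeElement variants are preserved
    opaquely in the enclosing object's extras rather than parsed."""
    if isinstance(elem, dict) and set(elem) == {"age"} and isinstance(elem["age"], dict) \
            and set(elem["age"]) == {"iso8601duration"}:
        return AgeDuration.from_iso8601(elem["age"]["iso8601duration"]), None
    return None, elem


def _term_from(obj: Any, where: str) -> OntologyTerm:
    if not isinstance(obj, dict) or "id" not in obj:
        raise SchemaError(f"missing ontology term id at {where}", field=where)
    return OntologyTerm(id=obj["id"], label=obj.get("label", ""))


def _term_to(term: OntologyTerm) -> dict:
    return {"id": term.id, "label": term.label}


def _take(data: dict, consumed: set[str]) -> dict:
    """Unconsumed keys, preserved for lossless round-trips."""
    return {k: v for k, v in data.items() if k not in consumed}


# ---------------------------------------------------------------------------
# per-element parsers (lowerCamelCase JSON -> model)

def _individual_from(data: dict) -> Individual:
    if "id" not in data:
        raise SchemaError("subject is missing its id", field="subject.id")
    consumed = {"id", "sex", "timeAtLastEncounter", "vitalStatus"}
    extras: dict[str, Any] = {}
    age_last = None
    if "timeAtLastEncounter" in data:
        age_last, passthrough = _parse_time_element(data["timeAtLastEncounter"])
        if passthrough is not None:
            extras["timeAtLastEncounter"] = passthrough
    age_death = None
    vital = data.get("vitalStatus")
    if vital is not None:
        if (isinstance(vital, dict) and set(vital) <= {"status", "timeOfDeath"}
                and "timeOfDeath" in vital):
            age_death, passthrough = _parse_time_element(vital["timeOfDeath"])
            if passthrough is not None:
                extras["vitalStatus"] = vital
        else:
            extras["vitalStatus"] = vital
    try:
        sex = Sex(data.get("sex", "UNKNOWN_SEX"))
    except ValueError as exc:
        raise SchemaError(f"unknown sex value {data['sex']!r}", field="subject.sex") from exc
    extras.update(_take(data, consumed))
    return Individual(
        id=data["id"], sex=sex,
        age_at_last_encounter=age_last, age_at_death=age_death, extras=extras,
    )


def _individual_to(ind: Individual) -> dict:
    out: dict[str, Any] = {"id": ind.id}
    if ind.age_at_last_encounter is not None:
        out["timeAtLastEncounter"] = _age_element(ind.age_at_last_encounter)
    if ind.age_at_death is not None and "vitalStatus" not in ind.extras:
        out["vitalStatus"] = {
            "status": "DECEASED",
            "timeOfDeath": _age_element(ind.age_at_death),
        }
    if ind.sex is not Sex.UNKNOWN_SEX:
        out["sex"] = ind.sex.value
    out.update(ind.extras)
    return out


def _feature_from(data: dict) -> PhenotypicFeature:
    term = _term_from(data.get("type"), "phenotypicFeature.type")
    consumed = {"type", "excluded", "onset"}
    extras: dict[str, Any] = {}
    onset = None
    if "onset" in data:
        onset, passthrough = _parse_time_element(data["onset"])
        if passthrough is not None:
            extras["onset"] = passthrough
    extras.update(_take(data, consumed))
    return PhenotypicFeature(
        term=term, excluded=bool(data.get("excluded", False)), onset=onset, extras=extras,
    )


def _feature_to(f: PhenotypicFeature) -> dict:
    out: dict[str, Any] = {"type": _term_to(f.term)}
    if f.excluded:
        out["excluded"] = True
    if f.onset is not None:
        out["onset"] = _age_element(f.onset)
    out.update(f.extras)
    return out


def _disease_from(data: dict) -> DiseaseDiagnosis:
    term = _term_from(data.get("term"), "disease.term")
    consumed = {"term", "onset"}
    extras: dict[str, Any] = {}
    onset = None
    if "onset" in data:
        onset, passthrough = _parse_time_element(data["onset"])
        if passthrough is not None:
            extras["onset"] = passthrough
    extras.update(_take(data, consumed))
    return DiseaseDiagnosis(term=term, onset=onset, extras=extras)


def _disease_to(d: DiseaseDiagnosis) -> dict:
    out: dict[str, Any] = {"term": _term_to(d.term)}
    if d.onset is not None:
        out["onset"] = _age_element(d.onset)
    out.update(d.extras)
    return out


_HGVS_SYNTAX = {"c": "hgvs.c", "n": "hgvs.n", "g": "hgvs.g", "m": "hgvs.m", "p": "hgvs.p"}


def _variant_from(data: dict) -> VariantDescriptor:
    consumed = {"id", "geneContext", "expressions", "label", "allelicState"}
    gene = data.get("geneContext", {})
    expressions = [e.get("value", "") for e in data.get("expressions", []) if e.get("value")]
    allelic = None
    if "allelicState" in data:
        allelic = _term_from(data["allelicState"], "variationDescriptor.allelicState")
    return VariantDescriptor(
        id=data.get("id", ""),
        gene_symbol=gene.get("symbol", ""),
        hgnc_id=gene.get("valueId"),
        hgvs_expressions=expressions,
        label=data.get("label"),
        allelic_state=allelic,
        extras=_take(data, consumed),
    )


def _variant_to(v: VariantDescriptor) -> dict:
    out: dict[str, Any] = {"id": v.id}
    if v.label:
        out["label"] = v.label
    gene: dict[str, Any] = {}
    if v.hgnc_id:
        gene["valueId"] = v.hgnc_id
    gene["symbol"] = v.gene_symbol
    out["geneContext"] = gene
    if v.hgvs_expressions:
        expressions = []
        for expr in v.hgvs_expressions:
            kind = ""
            if ":" in expr:
                local = expr.split(":", 1)[1]
                kind = local.split(".", 1)[0] if "." in local else ""
            expressions.append({"syntax": _HGVS_SYNTAX.get(kind, "hgvs"), "value": expr})
        out["expressions"] = expressions
    if v.allelic_state is not None:
        out["allelicState"] = _term_to(v.allelic_state)
    out.update(v.extras)
    return out


def _genomic_interpretation_from(data: dict) -> GenomicInterpretation:
    consumed = {"subjectOrBiosampleId", "interpretationStatus", "variantInterpretation"}
    vi = data.get("variantInterpretation", {})
    descriptor = vi.get("variationDescriptor")
    if descriptor is None:
        raise SchemaError(
            "genomic interpretation lacks a variationDescriptor",
            field="genomicInterpretation.variantInterpretation",
        )
    extras = _take(data, consumed)
    vi_extras = _take(vi, {"acmgPathogenicityClassification", "variationDescriptor"})
    if vi_extras:
        extras["variantInterpretation"] = vi_extras
    try:
        status = InterpretationStatus(data.get("interpretationStatus", "UNKNOWN_STATUS"))
    except ValueError:
        status = InterpretationStatus.UNKNOWN
    try:
        acmg = AcmgClassification(vi.get("acmgPathogenicityClassification", "NOT_PROVIDED"))
    except ValueError:
        acmg = AcmgClassification.NOT_PROVIDED
    return GenomicInterpretation(
        subject_id=data.get("subjectOrBiosampleId", ""),
        status=status,
        acmg_classification=acmg,
        variant=_variant_from(descriptor),
        extras=extras,
    )


def _genomic_interpretation_to(gi: GenomicInterpretation) -> dict:
    vi: dict[str, Any] = {}
    if gi.acmg_classification is not AcmgClassification.NOT_PROVIDED:
        vi["acmgPathogenicityClassification"] = gi.acmg_classification.value
    vi["variationDescriptor"] = _variant_to(gi.variant)
    extras = dict(gi.extras)
    vi.update(extras.pop("variantInterpretation", {}))
    out: dict[str, Any] = {"subjectOrBiosampleId": gi.subject_id}
    if gi.status is not InterpretationStatus.UNKNOWN:
        out["interpretationStatus"] = gi.status.value
    out["variantInterpretation"] = vi
    out.update(extras)
    return out


def _interpretation_from(data: dict) -> Interpretation:
    consumed = {"id", "progressStatus", "diagnosis"}
    diagnosis = data.get("diagnosis", {})
    term = _term_from(diagnosis.get("disease"), "interpretation.diagnosis.disease")
    extras = _take(data, consumed)
    diag_extras = _take(diagnosis, {"disease", "genomicInterpretations"})
    if diag_extras:
        extras["diagnosis"] = diag_extras
    return Interpretation(
        id=data.get("id", ""),
        progress_status=data.get("progressStatus", "SOLVED"),
        diagnosis_term=term,
        genomic_interpretations=[
            _genomic_interpretation_from(gi)
            for gi in diagnosis.get("genomicInterpretations", [])
        ],
        extras=extras,
    )


def _interpretation_to(itp: Interpretation) -> dict:
    extras = dict(itp.extras)
    diagnosis: dict[str, Any] = {"disease": _term_to(itp.diagnosis_term)}
    if itp.genomic_interpretations:
        diagnosis["genomicInterpretations"] = [
            _genomic_interpretation_to(gi) for gi in itp.genomic_interpretations
        ]
    diagnosis.update(extras.pop("diagnosis", {}))
    out: dict[str, Any] = {
        "id": itp.id,
        "progressStatus": itp.progress_status,
        "diagnosis": diagnosis,
    }
    out.update(extras)
    return out


def _metadata_from(data: dict) -> MetaData:
    consumed = {"created", "createdBy", "resources", "phenopacketSchemaVersion",
                "externalReferences"}
    resources = [
        Resource(
            id=r.get("id", ""), name=r.get("name", ""),
            namespace_prefix=r.get("namespacePrefix", ""),
            url=r.get("url", ""), version=r.get("version", "unknown"),
            iri_prefix=r.get("iriPrefix", ""),
        )
        for r in data.get("resources", [])
    ]
    refs = [
        ExternalReference(id=r.get("id", ""), description=r.get("description"))
        for r in data.get("externalReferences", [])
    ]
    return MetaData(
        created=data.get("created", ""),
        created_by=data.get("createdBy", ""),
        schema_version=data.get("phenopacketSchemaVersion", "2.0.0"),
        resources=resources,
        external_references=refs,
        extras=_take(data, consumed),
    )


def _metadata_to(md: MetaData) -> dict:
    out: dict[str, Any] = {}
    if md.created:
        out["created"] = md.created
    if md.created_by:
        out["createdBy"] = md.created_by
    if md.resources:
        out["resources"] = [
            {
                "id": r.id, "name": r.name, "url": r.url, "version": r.version,
                "namespacePrefix": r.namespace_prefix, "iriPrefix": r.iri_prefix,
            }
            for r in md.resources
        ]
    out["phenopacketSchemaVersion"] = md.schema_version
    if md.external_references:
        out["externalReferences"] = [
            ({"id": r.id, "description": r.description} if r.description
             else {"id": r.id})
            for r in md.external_references
        ]
    out.update(md.extras)
    return out


# ---------------------------------------------------------------------------
# public API

def phenopacket_from_dict(data: dict) -> Phenopacket:
    if not isinstance(data, dict):
        raise SchemaError("phenopacket document must be a JSON object")
    for required in ("id", "subject"):
        if required not in data:
            raise SchemaError(f"phenopacket is missing required field {required!r}",
                              field=required)
    consumed = {"id", "subject", "phenotypicFeatures", "diseases", "interpretations",
                "metaData"}
    return Phenopacket(
        id=data["id"],
        subject=_individual_from(data["subject"]),
        phenotypic_features=[_feature_from(f) for f in data.get("phenotypicFeatures", [])],
        diseases=[_disease_from(d) for d in data.get("diseases", [])],
        interpretations=[_interpretation_from(i) for i in data.get("interpretations", [])],
        meta_data=_metadata_from(data.get("metaData", {})),
        extras=_take(data, consumed),
    )


def phenopacket_to_dict(pp: Phenopacket) -> dict:
    out: dict[str, Any] = {"id": pp.id, "subject": _individual_to(pp.subject)}
    if pp.phenotypic_features:
        out["phenotypicFeatures"] = [_feature_to(f) for f in pp.phenotypic_features]
    if pp.interpretations:
        out["interpretations"] = [_interpretation_to(i) for i in pp.interpretations]
    if pp.diseases:
        out["diseases"] = [_disease_to(d) for d in pp.diseases]
    out.update(pp.extras)
    out["metaData"] = _metadata_to(pp.meta_data)
    return out


def read_phenopacket(source: str | Path) -> Phenopacket:
    """Load a phenopacket from a JSON file path or a JSON text string."""
    if isinstance(source, Path) or (isinstance(source, str) and
                                    not source.lstrip().startswith("{")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    return phenopacket_from_dict(data)


def write_phenopacket(pp: Phenopacket, path: str | Path | None = None) -> str:
    """Serialize to canonical JSON text; write to ``path`` when given.

    Key order is structural (id, subject, features, interpretations, diseases,
    metadata) and therefore stable; output is UTF-8 with 2-space indentation.
    """
    text = json.dumps(phenopacket_to_dict(pp), indent=2, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


@dataclass
class CorpusRecord:
    phenopacket: Phenopacket
    source_path: Path | None = None


@dataclass
class LoadFailure:
    path: Path
    error: str


@dataclass
class Corpus:
    """A collection of phenopackets grouped by disease.

    Id uniqueness and other cross-record constraints are checked by
    :func:`phenocurate.validation.validate_corpus`, not at construction, so
    that defective collections can be loaded and reported.
    """

    records: list[CorpusRecord] = field(default_factory=list)
    load_failures: list[LoadFailure] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def phenopackets(self) -> Iterator[Phenopacket]:
        for rec in self.records:
            yield rec.phenopacket

    @property
    def index_by_disease(self) -> dict[str, list[str]]:
        """Disease term id -> list of phenopacket ids (first disease of each)."""
        index: dict[str, list[str]] = {}
        for pp in self.phenopackets():
            for disease in pp.diseases[:1]:
                index.setdefault(disease.term.id, []).append(pp.id)
        return index

    @classmethod
    def from_phenopackets(cls, packets: Iterator[Phenopacket] | list[Phenopacket]) -> "Corpus":
        return cls(records=[CorpusRecord(phenopacket=pp) for pp in packets])


def read_corpus(root: str | Path) -> Corpus:
    """Recursively load every ``*.json`` file under ``root``.

    Files that fail to parse are collected into ``corpus.load_failures``
    rather than aborting the load.  An empty directory yields an empty corpus.
    """
    root = Path(root)
    if not root.is_dir():
        raise PhenocurateError(f"not a directory: {root}")
    corpus = Corpus()
    for path in sorted(root.rglob("*.json")):
        try:
            pp = read_phenopacket(path)
        except PhenocurateError as exc:
            corpus.load_failures.append(LoadFailure(path=path, error=str(exc)))
            continue
        corpus.records.append(CorpusRecord(phenopacket=pp, source_path=path))
    return corpus


def write_corpus(corpus: Corpus, root: str | Path,
                 cohort_of: "dict[str, str] | None" = None) -> list[Path]:
    """Write one JSON file per record under ``root``.

    Records are grouped into per-disease sub-directories named after the
    disease label (sanitized); ``cohort_of`` may override the directory name
    per phenopacket id.  The file stem is the phenopacket id.
    """
    from .model import sanitize_identifier

    root = Path(root)
    written = []
    for rec in corpus.records:
        pp = rec.phenopacket
        if cohort_of and pp.id in cohort_of:
            sub = cohort_of[pp.id]
        elif pp.diseases:
            sub = sanitize_identifier(pp.diseases[0].term.label) or "unassigned"
        else:
            sub = "unassigned"
        directory = root / sub
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / f"{pp.id}.json"
        write_phenopacket(pp, path)
        written.append(path)
    return written
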