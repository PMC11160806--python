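"""Domain model for the corpus profile of the GA4GH Phenopacket Schema (v2).

Only the subset of the schema used by literature-curated rare-disease case
reports is modelled: a subject, observed/excluded HPO phenotypic features
with optional onset ages, a single disease diagnosis (OMIM/Mondo), genomic
interpretations carrying the causal variant, and provenance metadata anchored
on a PubMed identifier.  Ages are pure ISO 8601 durations (no time-of-day,
no calendar reference date), because published case reports state ages, not
dates.

Serialization to/from the lowerCamelCase protobuf JSON dialect lives in
:mod:`phenocurate.json_io`; structural validation rules live in
:mod:`phenocurate.validation`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Any

from .errors import (
    AgeParseError,
    CrossReferenceError,
    MalformedIdentifierError,
    MissingIdentifierError,
)

__all__ = [
    "OntologyTerm",
    "AgeDuration",
    "Sex",
    "Individual",
    "PhenotypicFeature",
    "DiseaseDiagnosis",
    "VariantDescriptor",
    "InterpretationStatus",
    "AcmgClassification",
    "GenomicInterpretation",
    "Interpretation",
    "Resource",
    "ExternalReference",
    "MetaData",
    "Phenopacket",
    "make_phenopacket_id",
    "parse_age",
    "build_phenopacket",
    "KNOWN_RESOURCES",
]

# Fixed day-length conventions for duration arithmetic.  Ages in case reports
# are durations without a reference date, so calendar arithmetic is neither
# possible nor meaningful.
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44
DAYS_PER_WEEK = 7.0

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")


@dataclass(frozen=True)
class OntologyTerm:
    """A CURIE-identified ontology concept, e.g. ``HP:0002650`` / ``Scoliosis``."""

    id: str
    label: str

    def __post_init__(self) -> None:
        if not _CURIE_RE.match(self.id):
            raise MalformedIdentifierError(f"not a CURIE: {self.id!r}")
        if not self.label:
            raise MissingIdentifierError(f"term {self.id} has an empty label")

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


_ISO_DURATION_RE = re.compile(
    r"^P(?:(?P<years>\d+)Y)?(?:(?P<months>\d+)M)?"
    r"(?:(?P<weeks>\d+)W)?(?:(?P<days>\d+)D)?$"
)

# free-text unit words accepted by parse_age, mapped to component names
_UNIT_WORDS = {
    "y": "years", "yr": "years", "yrs": "years", "year": "years", "years": "years",
    "m": "months", "mo": "months", "mos": "months", "month": "months", "months": "months",
    "w": "weeks", "wk": "weeks", "wks": "weeks", "week": "weeks", "weeks": "weeks",
    "d": "days", "day": "days", "days": "days",
}
_FREETEXT_ZERO = {"newborn", "neonatal", "birth", "at birth", "congenital", "congenital onset"}
_FREETEXT_TOKEN_RE = re.compile(r"(\d+(?:\.\d+)?)\s*([a-z]+)\.?")


@total_ordering
@dataclass(frozen=True)
class AgeDuration:
    """An age expressed as an ISO 8601 duration ``P[nY][nM][nW][nD]``.

    Durations are compared through :attr:`total_days`, computed with the
    fixed conventions 1 year = 365.25 days, 1 month = 30.44 days,
    1 week = 7 days.
    """

    years: int = 0
    months: int = 0
    weeks: int = 0
    days: int = 0

    def __post_init__(self) -> None:
        for name in ("years", "months", "weeks", "days"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise AgeParseError(str(v), f"negative or non-integer {name} component")

    @property
    def iso8601(self) -> str:
        """Canonical ISO 8601 serialization; the zero duration is ``P0D``."""
        parts = []
        if self.years:
            parts.append(f"{self.years}Y")
        if self.months:
            parts.append(f"{self.months}M")
        if self.weeks:
            parts.append(f"{self.weeks}W")
        if self.days:
            parts.append(f"{self.days}D")
        return "P" + ("".join(parts) or "0D")

    @property
    def total_days(self) -> float:
        return round(
            self.years * DAYS_PER_YEAR
            + self.months * DAYS_PER_MONTH
            + self.weeks * DAYS_PER_WEEK
            + self.days,
            6,
        )

    def __lt__(self, other: "AgeDuration") -> bool:
        return self.total_days < other.total_days

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.iso8601

    @classmethod
    def from_iso8601(cls, text: str) -> "AgeDuration":
        m = _ISO_DURATION_RE.match(text.strip())
        if not m or text.strip() == "P":
            if "T" in text:
                raise AgeParseError(text, "time-of-day components are not permitted")
            raise AgeParseError(text)
        return cls(**{k: int(v) if v else 0 for k, v in m.groupdict().items()})


def parse_age(text: str) -> AgeDuration:
    """Parse an age string into an :class:`AgeDuration`.

    Accepts ISO 8601 durations (``"P4Y"``, ``"P3Y2M"``) and common free-text
    forms found in curation tables (``"4 years"``, ``"6 mo"``, ``"3 years
    2 months"``, ``"newborn"``).  Fractional free-text values are folded into
    the next-smaller unit (``"1.5 years"`` -> ``P1Y6M``).
    """
    if not isinstance(text, str) or not text.strip():
        raise AgeParseError(str(text), "empty age string")
    stripped = text.strip()
    if stripped[0] in "Pp":
        return AgeDuration.from_iso8601(stripped.upper())
    lowered = stripped.lower()
    if lowered in _FREETEXT_ZERO:
        return AgeDuration()
    components = {"years": 0, "months": 0, "weeks": 0, "days": 0.0}
    consumed = 0
    for num, word in _FREETEXT_TOKEN_RE.findall(lowered):
        unit = _UNIT_WORDS.get(word)
        if unit is None:
            raise AgeParseError(text, f"unknown age unit {word!r}")
        components[unit] += float(num)
        consumed += 1
    if consumed == 0:
        raise AgeParseError(text)
    # fold fractional parts downward: years -> months -> days; weeks -> days
    years = int(components["years"])
    months_f = components["months"] + (components["years"] - years) * 12
    months = int(months_f)
    weeks = int(components["weeks"])
    days_f = (
        components["days"]
        + (months_f - months) * DAYS_PER_MONTH
        + (components["weeks"] - weeks) * DAYS_PER_WEEK
    )
    return AgeDuration(years=years, months=months, weeks=weeks, days=round(days_f))


class Sex(str, Enum):
    """Phenopacket Schema v2 administrative sex value set."""

    UNKNOWN_SEX = "UNKNOWN_SEX"
    FEMALE = "FEMALE"
    MALE = "MALE"
    OTHER_SEX = "OTHER_SEX"


@dataclass
class Individual:
    """The subject of a phenopacket, identified as in the source publication."""

    id: str
    sex: Sex = Sex.UNKNOWN_SEX
    age_at_last_encounter: AgeDuration | None = None
    age_at_death: AgeDuration | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise MissingIdentifierError("individual id must be non-empty")
        if isinstance(self.sex, str) and not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)


@dataclass
class PhenotypicFeature:
    """An HPO term annotated as observed (default) or explicitly excluded."""

    term: OntologyTerm
    excluded: bool = False
    onset: AgeDuration | None = None
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass
class DiseaseDiagnosis:
    """A disease (OMIM or Mondo term) with optional age of onset."""

    term: OntologyTerm
    onset: AgeDuration | None = None
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass
class VariantDescriptor:
    """A variant stated relative to a reference transcript (HGVS) or, for
    structural/chromosomal events without HGVS, as a free-text label."""

    id: str
    gene_symbol: str
    hgvs_expressions: list[str] = field(default_factory=list)
    hgnc_id: str | None = None
    label: str | None = None
    allelic_state: OntologyTerm | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise MissingIdentifierError("variant descriptor needs a gene symbol")
        if not self.hgvs_expressions and not self.label:
            raise MissingIdentifierError(
                f"variant {self.id!r} needs an HGVS expression or a free-text label"
            )


class InterpretationStatus(str, Enum):
    UNKNOWN = "UNKNOWN_STATUS"
    CANDIDATE = "CANDIDATE"
    CAUSATIVE = "CAUSATIVE"


class AcmgClassification(str, Enum):
    NOT_PROVIDED = "NOT_PROVIDED"
    BENIGN = "BENIGN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    UNCERTAIN_SIGNIFICANCE = "UNCERTAIN_SIGNIFICANCE"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    PATHOGENIC = "PATHOGENIC"
    # alias matching common curation shorthand
    VUS = "UNCERTAIN_SIGNIFICANCE"


@dataclass
class GenomicInterpretation:
    """Links the subject to a variant with a causality status and ACMG class."""

    subject_id: str
    variant: VariantDescriptor
    status: InterpretationStatus = InterpretationStatus.CAUSATIVE
    acmg_classification: AcmgClassification = AcmgClassification.NOT_PROVIDED
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass
class Interpretation:
    """A diagnosis with its supporting genomic interpretations.

    The diagnosis term must refer to a disease in the enclosing phenopacket's
    disease list; that agreement is a validation rule, not a construction
    constraint, so that non-conforming files can still be loaded and reported.
    """

    id: str
    diagnosis_term: OntologyTerm
    genomic_interpretations: list[GenomicInterpretation] = field(default_factory=list)
    progress_status: str = "SOLVED"
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class Resource:
    """An ontology/terminology declared in metadata."""

    id: str
    name: str
    namespace_prefix: str
    url: str = ""
    version: str = "unknown"
    iri_prefix: str = ""


@dataclass
class ExternalReference:
    id: str  # CURIE, PMID prefix for corpus records
    description: str | None = None


@dataclass
class MetaData:
    created: str = ""
    created_by: str = ""
    schema_version: str = "2.0.0"
    resources: list[Resource] = field(default_factory=list)
    external_references: list[ExternalReference] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def pmids(self) -> list[str]:
        """Numeric PubMed ids cited in external references, in order."""
        out = []
        for ref in self.external_references:
            if ref.id.upper().startswith("PMID:"):
                out.append(ref.id.split(":", 1)[1])
        return out


@dataclass
class Phenopacket:
    """One individual's structured case record."""

    id: str
    subject: Individual
    phenotypic_features: list[PhenotypicFeature] = field(default_factory=list)
    diseases: list[DiseaseDiagnosis] = field(default_factory=list)
    interpretations: list[Interpretation] = field(default_factory=list)
    meta_data: MetaData = field(default_factory=MetaData)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise MissingIdentifierError("phenopacket id must be non-empty")


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9]+")
PHENOPACKET_ID_RE = re.compile(r"^PMID_(\d+)_(\S+)$")


def sanitize_identifier(individual_id: str) -> str:
    """Collapse each maximal run of non-alphanumeric characters to ``_``.

    Keeps identifiers safe for file names and cross-references; leading and
    trailing separators are dropped.
    """
    out = _SANITIZE_RE.sub("_", individual_id.strip()).strip("_")
    return out


def make_phenopacket_id(pmid: str, individual_id: str) -> str:
    """Build the corpus phenopacket id ``PMID_<pmid>_<individual>``.

    The individual id is taken from the source publication; curators substitute
    the literal ``"individual"`` when the publication names none.

    >>> make_phenopacket_id("24126608", "BAB3022")
    'PMID_24126608_BAB3022'
    """
    if not isinstance(pmid, str) or not pmid.isdigit():
        raise MalformedIdentifierError(f"PMID must be all digits, got {pmid!r}")
    if not individual_id or not individual_id.strip():
        raise MissingIdentifierError("individual id must be non-empty")
    sanitized = sanitize_identifier(individual_id)
    if not sanitized:
        raise MissingIdentifierError(
            f"individual id {individual_id!r} has no alphanumeric characters"
        )
    return f"PMID_{pmid}_{sanitized}"


# Registry of resource declarations for the ontology prefixes the corpus
# profile uses.  Versions are overridable at build time.
KNOWN_RESOURCES: dict[str, Resource] = {
    "HP": Resource(
        id="hp", name="human phenotype ontology", namespace_prefix="HP",
        url="http://purl.obolibrary.org/obo/hp.owl",
        iri_prefix="http://purl.obolibrary.org/obo/HP_",
    ),
    "OMIM": Resource(
        id="omim", name="An Online Catalog of Human Genes and Genetic Disorders",
        namespace_prefix="OMIM", url="https://www.omim.org",
        iri_prefix="https://www.omim.org/entry/",
    ),
    "MONDO": Resource(
        id="mondo", name="Mondo Disease Ontology", namespace_prefix="MONDO",
        url="http://purl.obolibrary.org/obo/mondo.obo",
        iri_prefix="http://purl.obolibrary.org/obo/MONDO_",
    ),
    "GENO": Resource(
        id="geno", name="Genotype Ontology", namespace_prefix="GENO",
        url="http://purl.obolibrary.org/obo/geno.owl",
        iri_prefix="http://purl.obolibrary.org/obo/GENO_",
    ),
    "HGNC": Resource(
        id="hgnc", name="HUGO Gene Nomenclature Committee", namespace_prefix="HGNC",
        url="https://www.genenames.org",
        iri_prefix="https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/",
    ),
}


def _used_prefixes(features: list[PhenotypicFeature], disease: DiseaseDiagnosis,
                   interpretation: Interpretation | None) -> list[str]:
    prefixes: list[str] = []

    def add(p: str) -> None:
        if p not in prefixes:
            prefixes.append(p)

    for f in features:
        add(f.term.prefix)
    add(disease.term.prefix)
    if interpretation is not None:
        add(interpretation.diagnosis_term.prefix)
        for gi in interpretation.genomic_interpretations:
            if gi.variant.allelic_state is not None:
                add(gi.variant.allelic_state.prefix)
            if gi.variant.hgnc_id:
                add(gi.variant.hgnc_id.split(":", 1)[0])
    return prefixes


def build_phenopacket(
    subject: Individual,
    features: list[PhenotypicFeature],
    disease: DiseaseDiagnosis,
    interpretation: Interpretation | None,
    pmid: str,
    *,
    created: str = "",
    created_by: str = "phenocurate",
    citation: str | None = None,
    resource_versions: dict[str, str] | None = None,
) -> Phenopacket:
    """Assemble a corpus-profile phenopacket from validated parts.

    The phenopacket id is derived from the PMID and the subject id, metadata
    declares every ontology prefix in use plus the PMID provenance reference,
    and the interpretation (if any) must carry the same diagnosis term as the
    single disease — otherwise construction is refused.
    """
    if interpretation is not None and interpretation.diagnosis_term.id != disease.term.id:
        raise CrossReferenceError(
            f"interpretation diagnosis {interpretation.diagnosis_term.id} does not "
            f"match the disease {disease.term.id}"
        )
    pp_id = make_phenopacket_id(pmid, subject.id)
    versions = resource_versions or {}
    resources = []
    for prefix in _used_prefixes(features, disease, interpretation):
        base = KNOWN_RESOURCES.get(prefix)
        if base is None:
            base = Resource(id=prefix.lower(), name=prefix, namespace_prefix=prefix)
        if prefix in versions:
            base = Resource(
                id=base.id, name=base.name, namespace_prefix=base.namespace_prefix,
                url=base.url, version=versions[prefix], iri_prefix=base.iri_prefix,
            )
        resources.append(base)
    meta = MetaData(
        created=created,
        created_by=created_by,
        resources=resources,
        external_references=[ExternalReference(id=f"PMID:{pmid}", description=citation)],
    )
    return Phenopacket(
        id=pp_id,
        subject=subject,
        phenotypic_features=list(features),
        diseases=[disease],
        interpretations=[interpretation] if interpretation is not None else [],
        meta_data=meta,
    )
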