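"""Convert publication-style tables into phenopackets.

Case-report papers typically present a cohort as a table with one row per
patient and one column per data item (identifier, sex, ages, genetic variant,
phenotypic features).  This module turns such tables — CSV or XLSX with a
single header row — into corpus-profile phenopackets through declarative
per-column mappings.

Column kinds
------------
``IDENTIFIER``       the patient id column; a blank cell becomes the literal
                     ``"individual"``
``SEX``              male/female/other/unknown vocabulary
``AGE``              ISO 8601 or free-text age; ``field`` parameter routes it
                     to the encounter age, the disease onset, or the age of
                     death
``HPO_SIMPLE``       one HPO term per column; "+"-style cells mean observed,
                     "-"-style excluded, blank/NA means not reported
``HPO_OPTION``       a categorical cell mapped to a set of HPO terms
``VARIANT``          an HGVS cell, anchored on the mapping's transcript
``DISEASE_CONSTANT`` a column restating the cohort's disease; ignored per cell
``IGNORE``           dropped

Cells matching ``\\d+/\\d+`` in phenotype columns ("7/12") are rejected as
aggregate-style data: the corpus includes only individual-level reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import pandas as pd

from .errors import CellParseError, ConfigurationError, IngestError, PhenocurateError
from .model import (
    AgeDuration,
    DiseaseDiagnosis,
    GenomicInterpretation,
    Individual,
    Interpretation,
    OntologyTerm,
    PhenotypicFeature,
    Phenopacket,
    Sex,
    VariantDescriptor,
    build_phenopacket,
    make_phenopacket_id,
    parse_age,
)
from .validation import ValidationReport, validate_phenopacket

__all__ = [
    "MappingKind",
    "ColumnMapping",
    "IngestTemplate",
    "IngestReport",
    "load_template",
    "parse_cell",
    "ingest",
    "mappings_from_config",
]


class MappingKind(str, Enum):
    HPO_SIMPLE = "HPO_SIMPLE"
    HPO_OPTION = "HPO_OPTION"
    AGE = "AGE"
    SEX = "SEX"
    VARIANT = "VARIANT"
    DISEASE_CONSTANT = "DISEASE_CONSTANT"
    IDENTIFIER = "IDENTIFIER"
    IGNORE = "IGNORE"


# default observed/excluded/missing vocabulary; overridable per mapping
OBSERVED_TOKENS = frozenset({"+", "yes", "y", "observed", "present", "true", "1"})
EXCLUDED_TOKENS = frozenset({"-", "no", "n", "excluded", "absent", "false", "0"})
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "?", "unknown", "none", "."})

_SEX_TOKENS = {
    "m": Sex.MALE, "male": Sex.MALE,
    "f": Sex.FEMALE, "female": Sex.FEMALE,
    "o": Sex.OTHER_SEX, "other": Sex.OTHER_SEX, "other_sex": Sex.OTHER_SEX,
    "u": Sex.UNKNOWN_SEX, "unknown": Sex.UNKNOWN_SEX, "unknown_sex": Sex.UNKNOWN_SEX,
}

_AGGREGATE_RE = re.compile(r"^\d+\s*/\s*\d+$")


@dataclass
class ColumnMapping:
    """How one table column is interpreted.

    ``parameters`` is kind-specific: HPO_SIMPLE needs ``term`` (an
    :class:`OntologyTerm`); HPO_OPTION needs ``options`` (cell value ->
    list of terms); AGE takes ``field`` in {"last_encounter", "disease_onset",
    "death"}; VARIANT takes ``gene``, optional ``transcript`` and ``hgnc``.
    """

    column_name: str
    kind: MappingKind
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.kind, str) and not isinstance(self.kind, MappingKind):
            self.kind = MappingKind(self.kind.upper())
        if self.kind is MappingKind.HPO_SIMPLE and "term" not in self.parameters:
            raise ConfigurationError(
                f"HPO_SIMPLE mapping for {self.column_name!r} needs a 'term' parameter")
        if self.kind is MappingKind.HPO_OPTION and "options" not in self.parameters:
            raise ConfigurationError(
                f"HPO_OPTION mapping for {self.column_name!r} needs an 'options' parameter")
        if self.kind is MappingKind.VARIANT and not self.parameters.get("gene"):
            raise ConfigurationError(
                f"VARIANT mapping for {self.column_name!r} needs a 'gene' parameter")


@dataclass
class IngestTemplate:
    """A loaded table plus everything needed to build its phenopackets."""

    pmid: str
    disease: DiseaseDiagnosis
    rows: list[dict[str, str]]
    mappings: list[ColumnMapping]

    def __post_init__(self) -> None:
        if not self.pmid.isdigit():
            raise ConfigurationError(f"template PMID must be digits-only, got {self.pmid!r}")

    def mapping_for(self, column: str) -> ColumnMapping:
        for m in self.mappings:
            if m.column_name == column:
                return m
        raise ConfigurationError(f"no mapping for column {column!r}")


def _normalize_cells(df: pd.DataFrame) -> list[dict[str, str]]:
    df = df.astype("string").fillna("")
    return [
        {str(col): str(row[col]).strip() for col in df.columns}
        for _, row in df.iterrows()
    ]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_template(path: str | Path, mappings: list[ColumnMapping], *,
                  pmid: str, disease: DiseaseDiagnosis) -> IngestTemplate:
    """Read a single-header-row CSV/XLSX table into an :class:`IngestTemplate`.

    Every column must carry a mapping (IGNORE to drop); unmapped columns are a
    configuration error so that silent data loss is impossible.  Row
    identifiers must be unique after blank cells are substituted with
    ``"individual"``.
    """
    df = _read_table(path)
    by_name = {m.column_name: m for m in mappings}
    unmapped = [c for c in df.columns if str(c) not in by_name]
    if unmapped:
        raise ConfigurationError(
            "columns without a mapping: " + ", ".join(repr(str(c)) for c in unmapped))
    id_columns = [m for m in mappings if m.kind is MappingKind.IDENTIFIER]
    if len(id_columns) != 1:
        raise ConfigurationError(
            f"exactly one IDENTIFIER column is required, found {len(id_columns)}")
    rows = _normalize_cells(df)
    keep = [m.column_name for m in mappings if m.kind is not MappingKind.IGNORE]
    rows = [{c: r[c] for c in r if c in keep} for r in rows]
    ids = [(r.get(id_columns[0].column_name, "") or "individual") for r in rows]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise IngestError(f"duplicate row identifiers: {', '.join(dupes)}")
    return IngestTemplate(
        pmid=pmid, disease=disease, rows=rows,
        mappings=[m for m in mappings if m.kind is not MappingKind.IGNORE],
    )


def parse_cell(value: str, mapping: ColumnMapping, *,
               row: object = None):
    """Interpret one cell under its column mapping.

    Returns a list of :class:`PhenotypicFeature` for the HPO kinds, an
    :class:`AgeDuration` or None for AGE, a :class:`Sex` for SEX, a
    :class:`VariantDescriptor` or None for VARIANT, and None for
    IDENTIFIER / DISEASE_CONSTANT / IGNORE (handled at row level).
    """
    col = mapping.column_name
    raw = (value or "").strip()
    token = raw.lower()
    kind = mapping.kind

    if kind in (MappingKind.HPO_SIMPLE, MappingKind.HPO_OPTION):
        if _AGGREGATE_RE.match(raw):
            raise CellParseError(
                f"cell {raw!r} looks like aggregate data (n/N); the corpus accepts "
                f"individual-level observations only",
                row=row, column=col, aggregate=True,
            )

    if kind is MappingKind.HPO_SIMPLE:
        observed = frozenset(mapping.parameters.get("observed_tokens", OBSERVED_TOKENS))
        excluded = frozenset(mapping.parameters.get("excluded_tokens", EXCLUDED_TOKENS))
        missing = frozenset(mapping.parameters.get("missing_tokens", MISSING_TOKENS))
        term: OntologyTerm = mapping.parameters["term"]
        if token in missing:
            return []
        if token in observed:
            return [PhenotypicFeature(term=term)]
        if token in excluded:
            return [PhenotypicFeature(term=term, excluded=True)]
        raise CellParseError(f"unrecognized observed/excluded token {raw!r}",
                             row=row, column=col)

    if kind is MappingKind.HPO_OPTION:
        if token in MISSING_TOKENS:
            return []
        options: dict[str, list[OntologyTerm]] = mapping.parameters["options"]
        lookup = {str(k).strip().lower(): v for k, v in options.items()}
        if token not in lookup:
            raise CellParseError(
                f"value {raw!r} is not in the option map "
                f"({', '.join(sorted(map(repr, options)))})",
                row=row, column=col)
        targets = lookup[token]
        return [PhenotypicFeature(term=t) for t in targets]

    if kind is MappingKind.AGE:
        if token in MISSING_TOKENS:
            return None
        try:
            return parse_age(raw)
        except PhenocurateError as exc:
            raise CellParseError(str(exc), row=row, column=col) from exc

    if kind is MappingKind.SEX:
        if token in MISSING_TOKENS:
            return Sex.UNKNOWN_SEX
        if token not in _SEX_TOKENS:
            raise CellParseError(f"unrecognized sex token {raw!r}", row=row, column=col)
        return _SEX_TOKENS[token]

    if kind is MappingKind.VARIANT:
        if token in MISSING_TOKENS:
            return None
        transcript = mapping.parameters.get("transcript")
        expr = raw if ":" in raw else (f"{transcript}:{raw}" if transcript else None)
        gene = mapping.parameters["gene"]
        if expr is None:
            # no transcript anchor: keep the verbatim cell as a free-text label
            return VariantDescriptor(id=f"{gene}-{raw}", gene_symbol=gene, label=raw,
                                     hgnc_id=mapping.parameters.get("hgnc"))
        return VariantDescriptor(
            id=f"{gene}-{expr}", gene_symbol=gene, hgvs_expressions=[" ".join(expr.split())],
            hgnc_id=mapping.parameters.get("hgnc"),
        )

    return None  # IDENTIFIER / DISEASE_CONSTANT / IGNORE are row-level concerns


@dataclass
class IngestReport:
    n_rows: int = 0
    n_succeeded: int = 0
    row_errors: list[tuple[str, str]] = field(default_factory=list)  # (row id, error)
    warnings: list[str] = field(default_factory=list)
    validation: ValidationReport = field(default_factory=ValidationReport)


def _ingest_row(template: IngestTemplate, row: dict[str, str], *,
                created_by: str) -> Phenopacket:
    id_mapping = next(m for m in template.mappings if m.kind is MappingKind.IDENTIFIER)
    row_id = row.get(id_mapping.column_name, "").strip() or "individual"

    sex = Sex.UNKNOWN_SEX
    age_last = age_death = disease_onset = None
    features: list[PhenotypicFeature] = []
    variants: list[VariantDescriptor] = []
    for m in template.mappings:
        if m.kind in (MappingKind.IDENTIFIER, MappingKind.DISEASE_CONSTANT,
                      MappingKind.IGNORE):
            continue
        parsed = parse_cell(row.get(m.column_name, ""), m, row=row_id)
        if m.kind in (MappingKind.HPO_SIMPLE, MappingKind.HPO_OPTION):
            features.extend(parsed)
        elif m.kind is MappingKind.AGE and parsed is not None:
            target = m.parameters.get("field", "last_encounter")
            if target == "disease_onset":
                disease_onset = parsed
            elif target == "death":
                age_death = parsed
            else:
                age_last = parsed
        elif m.kind is MappingKind.SEX:
            sex = parsed
        elif m.kind is MappingKind.VARIANT and parsed is not None:
            variants.append(parsed)

    subject = Individual(id=row_id, sex=sex, age_at_last_encounter=age_last,
                         age_at_death=age_death)
    disease = DiseaseDiagnosis(term=template.disease.term,
                               onset=disease_onset or template.disease.onset)
    interpretation = None
    if variants:
        interpretation = Interpretation(
            id=f"{row_id}-diagnosis",
            diagnosis_term=disease.term,
            genomic_interpretations=[
                GenomicInterpretation(subject_id=row_id, variant=v) for v in variants
            ],
        )
    return build_phenopacket(subject, features, disease, interpretation,
                             template.pmid, created_by=created_by)


def ingest(template: IngestTemplate, *,
           created_by: str = "phenocurate") -> tuple[list[Phenopacket], IngestReport]:
    """Build one phenopacket per table row.

    Row processing is row-local: a cell-parse error rejects that row (recorded
    in the report) and the remaining rows are still processed.  Every emitted
    phenopacket is validated; the per-packet reports are aggregated into the
    ingest report.
    """
    report = IngestReport(n_rows=len(template.rows))
    packets: list[Phenopacket] = []
    for row in template.rows:
        id_mapping = next(m for m in template.mappings
                          if m.kind is MappingKind.IDENTIFIER)
        row_id = row.get(id_mapping.column_name, "").strip() or "individual"
        try:
            pp = _ingest_row(template, row, created_by=created_by)
        except PhenocurateError as exc:
            report.row_errors.append((row_id, str(exc)))
            continue
        packets.append(pp)
        report.n_succeeded += 1
        report.validation.extend(validate_phenopacket(pp))
    return packets, report


# ---------------------------------------------------------------------------
# mapping configuration documents (YAML/JSON)

def _term_from_config(obj: Any) -> OntologyTerm:
    if isinstance(obj, dict):
        return OntologyTerm(id=obj["id"], label=obj.get("label", obj["id"]))
    raise ConfigurationError(f"expected a term object with id/label, got {obj!r}")


def mappings_from_config(config: dict) -> tuple[list[ColumnMapping], str | None,
                                                DiseaseDiagnosis | None]:
    """Build column mappings (plus optional pmid/disease) from a config dict.

    The document shape is ``{pmid, disease: {id,label}, columns: {name:
    {kind, ...params}}}``; see the CLI documentation for a worked example.
    """
    columns = config.get("columns")
    if not isinstance(columns, dict):
        raise ConfigurationError("mapping config needs a 'columns' table")
    mappings = []
    for name, spec in columns.items():
        if isinstance(spec, str):
            spec = {"kind": spec}
        kind = MappingKind(str(spec.get("kind", "")).upper())
        params: dict[str, Any] = {k: v for k, v in spec.items() if k != "kind"}
        if kind is MappingKind.HPO_SIMPLE:
            params["term"] = _term_from_config(spec["term"])
        if kind is MappingKind.HPO_OPTION:
            params["options"] = {
                value: [_term_from_config(t) for t in terms]
                for value, terms in spec["options"].items()
            }
        mappings.append(ColumnMapping(column_name=str(name), kind=kind, parameters=params))
    pmid = str(config["pmid"]) if "pmid" in config else None
    disease = None
    if "disease" in config:
        disease = DiseaseDiagnosis(term=_term_from_config(config["disease"]))
    return mappings, pmid, disease
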