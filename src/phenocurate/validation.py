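"""Structural and curation-rule validation for phenopackets and corpora.

The rule engine never raises on bad content: every finding is returned as a
:class:`ValidationIssue` with an ``ERROR`` or ``WARNING`` severity, a stable
machine-readable code, and a location of the form
``<phenopacket id>/<element path>``.  A report *passes* iff it contains no
ERROR-level issue.

Per-phenopacket rules
---------------------
========  ========  ==========================================================
code      severity  meaning
========  ========  ==========================================================
R0        ERROR     corpus profile: record must carry exactly one disease
R1        ERROR     interpretation diagnosis not in the disease list
R2        ERROR     id not of the form ``PMID_<digits>_<individual>`` or the
                    PMID missing from metadata external references
R3        ERROR     feature term not HP-prefixed / disease term not OMIM or
                    MONDO
R4        ERROR     same HP term both observed and excluded
R5        WARNING   duplicate HP term with identical excluded status
R6        ERROR     ontology prefix in use but undeclared in metadata resources
R7        WARNING   feature onset later than age at last encounter
R8        ERROR     genomic-interpretation subject id differs from subject id
TERM      WARNING   HP term absent from the supplied known-term subset
========  ========  ==========================================================

Corpus-level rules
------------------
========  ========  ==========================================================
C1        ERROR     duplicate (PMID, individual id) pair — ids must be
                    distinct for all individuals described in any publication
C2        ERROR     duplicate phenopacket id
C3        WARNING   same individual id and identical variant set under two
                    different PMIDs — possible republished patient
========  ========  ==========================================================

:func:`seed_violations` injects known violations into a clean corpus for
mutation-testing the engine itself (the detection-completeness property).
"""

from __future__ import annotations

import copy
import random
import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import CapacityError
from .json_io import Corpus, CorpusRecord
from .model import (
    AgeDuration,
    ExternalReference,
    OntologyTerm,
    PhenotypicFeature,
    Phenopacket,
    PHENOPACKET_ID_RE,
)

__all__ = [
    "Severity",
    "ValidationIssue",
    "ValidationReport",
    "InjectedViolation",
    "RULE_CODES",
    "validate_phenopacket",
    "validate_corpus",
    "seed_violations",
]


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


RULE_CODES = (
    "R0_DISEASE_COUNT",
    "R1_DISEASE_MISMATCH",
    "R2_ID_PMID",
    "R3_TERM_PREFIX",
    "R4_OBSERVED_AND_EXCLUDED",
    "R5_DUPLICATE_FEATURE",
    "R6_UNDECLARED_PREFIX",
    "R7_ONSET_AFTER_ENCOUNTER",
    "R8_SUBJECT_MISMATCH",
    "TERM_NOT_IN_SUBSET",
    "C1_DUPLICATE_INDIVIDUAL",
    "C2_DUPLICATE_PHENOPACKET_ID",
    "C3_POSSIBLE_REPUBLICATION",
)


@dataclass(frozen=True)
class ValidationIssue:
    level: Severity
    code: str
    message: str
    location: str

    def __post_init__(self) -> None:
        assert self.code in RULE_CODES, f"unregistered rule code {self.code}"
        assert self.location, "issue location must be non-empty"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.level is Severity.ERROR)

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.level is Severity.WARNING)

    @property
    def passed(self) -> bool:
        return self.n_errors == 0

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level is Severity.ERROR]

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def sort(self) -> None:
        self.issues.sort(key=lambda i: (i.location, i.code, i.message))

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "n_errors": self.n_errors,
            "n_warnings": self.n_warnings,
            "issues": [
                {"level": i.level.value, "code": i.code,
                 "message": i.message, "location": i.location}
                for i in self.issues
            ],
        }

    def to_tsv(self) -> str:
        lines = ["level\tcode\tlocation\tmessage"]
        for i in self.issues:
            lines.append(f"{i.level.value}\t{i.code}\t{i.location}\t{i.message}")
        return "\n".join(lines) + "\n"


def _issue(level: Severity, code: str, message: str, location: str) -> ValidationIssue:
    return ValidationIssue(level=level, code=code, message=message, location=location)


def validate_phenopacket(pp: Phenopacket,
                         known_terms: dict[str, str] | None = None) -> ValidationReport:
    """Apply the per-phenopacket rules R0–R8 (and the optional known-term check).

    ``known_terms`` is an id -> label mapping (e.g. the bundled HPO subset or a
    synthetic pool); when given, HP terms outside it are flagged as WARNINGs.
    All findings are collected and returned; nothing is raised.
    """
    report = ValidationReport()
    loc = pp.id

    # R0 — corpus profile: exactly one disease
    if len(pp.diseases) != 1:
        report.issues.append(_issue(
            Severity.ERROR, "R0_DISEASE_COUNT",
            f"corpus records must have exactly one disease, found {len(pp.diseases)}",
            f"{loc}/diseases",
        ))

    # R1 — interpretation diagnosis must be in the disease list
    disease_ids = {d.term.id for d in pp.diseases}
    for k, itp in enumerate(pp.interpretations):
        if itp.diagnosis_term.id not in disease_ids:
            report.issues.append(_issue(
                Severity.ERROR, "R1_DISEASE_MISMATCH",
                f"interpretation diagnosis {itp.diagnosis_term.id} matches no disease "
                f"in the disease list {sorted(disease_ids)}",
                f"{loc}/interpretations[{k}]",
            ))

    # R2 — id format and PMID provenance
    m = PHENOPACKET_ID_RE.match(pp.id)
    if not m:
        report.issues.append(_issue(
            Severity.ERROR, "R2_ID_PMID",
            f"phenopacket id {pp.id!r} does not match PMID_<digits>_<individual>",
            f"{loc}/id",
        ))
    else:
        pmid = m.group(1)
        if pmid not in pp.meta_data.pmids():
            report.issues.append(_issue(
                Severity.ERROR, "R2_ID_PMID",
                f"PMID:{pmid} from the phenopacket id is not among the metadata "
                f"external references",
                f"{loc}/metaData/externalReferences",
            ))

    # R3 — term prefixes
    for k, f in enumerate(pp.phenotypic_features):
        if f.term.prefix != "HP":
            report.issues.append(_issue(
                Severity.ERROR, "R3_TERM_PREFIX",
                f"phenotypic feature term {f.term.id} is not an HP term",
                f"{loc}/phenotypicFeatures[{k}]",
            ))
        elif known_terms is not None and f.term.id not in known_terms:
            report.issues.append(_issue(
                Severity.WARNING, "TERM_NOT_IN_SUBSET",
                f"HP term {f.term.id} is absent from the supplied term subset",
                f"{loc}/phenotypicFeatures[{k}]",
            ))
    for k, d in enumerate(pp.diseases):
        if d.term.prefix not in ("OMIM", "MONDO"):
            report.issues.append(_issue(
                Severity.ERROR, "R3_TERM_PREFIX",
                f"disease term {d.term.id} is neither OMIM nor MONDO",
                f"{loc}/diseases[{k}]",
            ))

    # R4/R5 — contradictory or duplicated feature annotations
    seen: dict[tuple[str, bool], int] = {}
    statuses: dict[str, set[bool]] = {}
    for f in pp.phenotypic_features:
        seen[(f.term.id, f.excluded)] = seen.get((f.term.id, f.excluded), 0) + 1
        statuses.setdefault(f.term.id, set()).add(f.excluded)
    for term_id, flags in sorted(statuses.items()):
        if len(flags) == 2:
            report.issues.append(_issue(
                Severity.ERROR, "R4_OBSERVED_AND_EXCLUDED",
                f"HP term {term_id} is annotated both observed and excluded",
                f"{loc}/phenotypicFeatures",
            ))
    for (term_id, excluded), n in sorted(seen.items()):
        if n > 1:
            report.issues.append(_issue(
                Severity.WARNING, "R5_DUPLICATE_FEATURE",
                f"HP term {term_id} appears {n} times with excluded={excluded}",
                f"{loc}/phenotypicFeatures",
            ))

    # R6 — every prefix in use must be declared in metadata resources
    declared = {r.namespace_prefix for r in pp.meta_data.resources}
    used: set[str] = set()
    for f in pp.phenotypic_features:
        used.add(f.term.prefix)
    for d in pp.diseases:
        used.add(d.term.prefix)
    for itp in pp.interpretations:
        used.add(itp.diagnosis_term.prefix)
        for gi in itp.genomic_interpretations:
            if gi.variant.allelic_state is not None:
                used.add(gi.variant.allelic_state.prefix)
            if gi.variant.hgnc_id and ":" in gi.variant.hgnc_id:
                used.add(gi.variant.hgnc_id.split(":", 1)[0])
    for prefix in sorted(used - declared):
        report.issues.append(_issue(
            Severity.ERROR, "R6_UNDECLARED_PREFIX",
            f"ontology prefix {prefix} is used but not declared in metadata resources",
            f"{loc}/metaData/resources",
        ))

    # R7 — onsets after the last encounter
    encounter = pp.subject.age_at_last_encounter
    if encounter is not None:
        for k, f in enumerate(pp.phenotypic_features):
            if f.onset is not None and f.onset.total_days > encounter.total_days:
                report.issues.append(_issue(
                    Severity.WARNING, "R7_ONSET_AFTER_ENCOUNTER",
                    f"feature {f.term.id} onset {f.onset.iso8601} is later than the "
                    f"age at last encounter {encounter.iso8601}",
                    f"{loc}/phenotypicFeatures[{k}]",
                ))

    # R8 — genomic interpretations must refer to the subject
    for k, itp in enumerate(pp.interpretations):
        for j, gi in enumerate(itp.genomic_interpretations):
            if gi.subject_id != pp.subject.id:
                report.issues.append(_issue(
                    Severity.ERROR, "R8_SUBJECT_MISMATCH",
                    f"genomic interpretation subject {gi.subject_id!r} is not the "
                    f"phenopacket subject {pp.subject.id!r}",
                    f"{loc}/interpretations[{k}]/genomicInterpretations[{j}]",
                ))

    report.sort()
    return report


def _record_pmid(pp: Phenopacket) -> str | None:
    """PMID of a record: from the id when well-formed, else from metadata."""
    m = PHENOPACKET_ID_RE.match(pp.id)
    if m:
        return m.group(1)
    pmids = pp.meta_data.pmids()
    return pmids[0] if pmids else None


def _variant_keys(pp: Phenopacket) -> frozenset[tuple[str, str]]:
    keys = set()
    for itp in pp.interpretations:
        for gi in itp.genomic_interpretations:
            v = gi.variant
            expr = v.hgvs_expressions[0] if v.hgvs_expressions else (v.label or "")
            keys.add((v.gene_symbol, " ".join(expr.split())))
    return frozenset(keys)


def validate_corpus(corpus: Corpus,
                    known_terms: dict[str, str] | None = None) -> ValidationReport:
    """Per-record rules on every phenopacket, then the corpus rules C1–C3.

    The resulting issue list is sorted and therefore invariant under record
    ordering.
    """
    report = ValidationReport()
    for rec in corpus.records:
        report.extend(validate_phenopacket(rec.phenopacket, known_terms=known_terms))

    # C1 — (PMID, individual id) must be unique
    by_pub: dict[tuple[str, str], list[str]] = {}
    for pp in corpus.phenopackets():
        pmid = _record_pmid(pp)
        if pmid is not None:
            by_pub.setdefault((pmid, pp.subject.id), []).append(pp.id)
    for (pmid, ind_id), pp_ids in sorted(by_pub.items()):
        if len(pp_ids) > 1:
            for dup in sorted(pp_ids)[1:]:
                report.issues.append(_issue(
                    Severity.ERROR, "C1_DUPLICATE_INDIVIDUAL",
                    f"individual id {ind_id!r} appears more than once for PMID:{pmid}",
                    f"{dup}/subject/id",
                ))

    # C2 — phenopacket ids must be unique
    id_counts: dict[str, int] = {}
    for pp in corpus.phenopackets():
        id_counts[pp.id] = id_counts.get(pp.id, 0) + 1
    for pp_id, n in sorted(id_counts.items()):
        if n > 1:
            for _ in range(n - 1):
                report.issues.append(_issue(
                    Severity.ERROR, "C2_DUPLICATE_PHENOPACKET_ID",
                    f"phenopacket id {pp_id!r} appears {n} times in the corpus",
                    f"{pp_id}/id",
                ))

    # C3 — same individual id + same variant set under different PMIDs
    by_patient: dict[tuple[str, frozenset], dict[str, list[str]]] = {}
    for pp in corpus.phenopackets():
        variants = _variant_keys(pp)
        if not variants:
            continue
        pmid = _record_pmid(pp) or ""
        by_patient.setdefault((pp.subject.id, variants), {}).setdefault(pmid, []).append(pp.id)
    for (ind_id, _variants), pmid_map in sorted(by_patient.items()):
        if len(pmid_map) > 1:
            ordered = sorted(pp_id for ids in pmid_map.values() for pp_id in ids)
            for dup in ordered[1:]:
                report.issues.append(_issue(
                    Severity.WARNING, "C3_POSSIBLE_REPUBLICATION",
                    f"individual id {ind_id!r} with an identical variant set appears "
                    f"under {len(pmid_map)} different PMIDs — possibly the same "
                    f"patient republished",
                    f"{dup}/subject/id",
                ))

    report.sort()
    return report


# ---------------------------------------------------------------------------
# seeded violation injection (mutation testing of the rule engine)

@dataclass(frozen=True)
class InjectedViolation:
    """Ground truth for one seeded mutation: the rule code and the phenopacket
    where the engine must report it."""

    code: str
    phenopacket_id: str

    def detected_in(self, report: ValidationReport) -> bool:
        return any(
            i.code == self.code and i.location.split("/", 1)[0] == self.phenopacket_id
            for i in report.issues
        )


_INJECTABLE = (
    "R1_DISEASE_MISMATCH", "R2_ID_PMID", "R3_TERM_PREFIX",
    "R4_OBSERVED_AND_EXCLUDED", "R5_DUPLICATE_FEATURE", "R6_UNDECLARED_PREFIX",
    "R7_ONSET_AFTER_ENCOUNTER", "R8_SUBJECT_MISMATCH",
    "C1_DUPLICATE_INDIVIDUAL", "C2_DUPLICATE_PHENOPACKET_ID",
    "C3_POSSIBLE_REPUBLICATION",
)


def _suitable(code: str, pp: Phenopacket) -> bool:
    if code in ("R1_DISEASE_MISMATCH", "R8_SUBJECT_MISMATCH"):
        return bool(pp.interpretations)
    if code == "R2_ID_PMID":
        return bool(pp.meta_data.external_references)
    if code in ("R3_TERM_PREFIX", "R4_OBSERVED_AND_EXCLUDED", "R5_DUPLICATE_FEATURE"):
        return bool(pp.phenotypic_features)
    if code == "R6_UNDECLARED_PREFIX":
        return bool(pp.meta_data.resources)
    if code == "R7_ONSET_AFTER_ENCOUNTER":
        return bool(pp.phenotypic_features) and pp.subject.age_at_last_encounter is not None
    if code == "C3_POSSIBLE_REPUBLICATION":
        return bool(_variant_keys(pp)) and _record_pmid(pp) is not None
    if code == "C1_DUPLICATE_INDIVIDUAL":
        return _record_pmid(pp) is not None
    return True  # C2


def _inject(code: str, corpus: Corpus, rec: CorpusRecord,
            rng: random.Random) -> InjectedViolation:
    pp = rec.phenopacket
    if code == "R1_DISEASE_MISMATCH":
        itp = pp.interpretations[0]
        itp.diagnosis_term = OntologyTerm(id="OMIM:999999", label="Mismatched disease")
        return InjectedViolation(code, pp.id)
    if code == "R2_ID_PMID":
        pp.meta_data.external_references = []
        return InjectedViolation(code, pp.id)
    if code == "R3_TERM_PREFIX":
        f = pp.phenotypic_features[0]
        f.term = OntologyTerm(id="XX:0000001", label=f.term.label)
        return InjectedViolation(code, pp.id)
    if code == "R4_OBSERVED_AND_EXCLUDED":
        f = pp.phenotypic_features[0]
        pp.phenotypic_features.append(
            PhenotypicFeature(term=f.term, excluded=not f.excluded))
        return InjectedViolation(code, pp.id)
    if code == "R5_DUPLICATE_FEATURE":
        f = pp.phenotypic_features[0]
        pp.phenotypic_features.append(
            PhenotypicFeature(term=f.term, excluded=f.excluded))
        return InjectedViolation(code, pp.id)
    if code == "R6_UNDECLARED_PREFIX":
        declared = {r.namespace_prefix for r in pp.meta_data.resources}
        # drop a declared-and-used resource so the gap is observable
        used = set()
        for f in pp.phenotypic_features:
            used.add(f.term.prefix)
        for d in pp.diseases:
            used.add(d.term.prefix)
        droppable = sorted(declared & used) or sorted(declared)
        victim = droppable[rng.randrange(len(droppable))]
        pp.meta_data.resources = [
            r for r in pp.meta_data.resources if r.namespace_prefix != victim
        ]
        if victim not in used:  # ensure the prefix really is in use
            pp.phenotypic_features.append(PhenotypicFeature(
                term=OntologyTerm(id=f"{victim}:1", label="injected")))
        return InjectedViolation(code, pp.id)
    if code == "R7_ONSET_AFTER_ENCOUNTER":
        encounter = pp.subject.age_at_last_encounter
        f = pp.phenotypic_features[0]
        f.onset = AgeDuration(years=encounter.years + 10, months=encounter.months,
                              weeks=encounter.weeks, days=encounter.days)
        return InjectedViolation(code, pp.id)
    if code == "R8_SUBJECT_MISMATCH":
        gi = pp.interpretations[0].genomic_interpretations
        if gi:
            gi[0].subject_id = pp.subject.id + "_other"
        else:  # no genomic interpretation to corrupt: fall back to R1-style? no —
            # suitability guaranteed interpretations exist; an empty list means
            # nothing to mutate, so create a mismatching placeholder is not
            # possible without a variant.  Treated as unsuitable upstream.
            raise CapacityError("record has no genomic interpretation to corrupt")
        return InjectedViolation(code, pp.id)
    if code == "C1_DUPLICATE_INDIVIDUAL":
        dup = copy.deepcopy(pp)
        dup.id = pp.id + "_dup"
        corpus.records.append(CorpusRecord(phenopacket=dup))
        return InjectedViolation(code, dup.id)
    if code == "C2_DUPLICATE_PHENOPACKET_ID":
        dup = copy.deepcopy(pp)
        corpus.records.append(CorpusRecord(phenopacket=dup))
        return InjectedViolation(code, dup.id)
    if code == "C3_POSSIBLE_REPUBLICATION":
        dup = copy.deepcopy(pp)
        new_pmid = str(999000000 + rng.randrange(1, 999999))
        from .model import make_phenopacket_id
        dup.id = make_phenopacket_id(new_pmid, pp.subject.id)
        dup.meta_data.external_references = [ExternalReference(id=f"PMID:{new_pmid}")]
        corpus.records.append(CorpusRecord(phenopacket=dup))
        return InjectedViolation(code, dup.id)
    raise AssertionError(f"unknown injectable code {code}")


def seed_violations(corpus: Corpus, k: int,
                    seed: int) -> tuple[Corpus, list[InjectedViolation]]:
    """Inject ``k`` rule violations into a copy of a clean corpus.

    Violations are drawn uniformly over the injectable rule types, each hosted
    on a distinct (rule, record) slot; the returned ground-truth list states
    which code must be detected in which phenopacket.  The input corpus is
    never modified.  Deterministic in ``seed``.
    """
    if k < 1:
        raise CapacityError("k must be >= 1")
    mutated = copy.deepcopy(corpus)
    rng = random.Random(seed)
    used_slots: set[tuple[str, str]] = set()
    injected: list[InjectedViolation] = []
    base_records = list(mutated.records)  # only mutate originals, not injected copies
    for _ in range(k):
        codes = list(_INJECTABLE)
        rng.shuffle(codes)
        placed = False
        for code in codes:
            hosts = [rec for rec in base_records
                     if _suitable(code, rec.phenopacket)
                     and (code, rec.phenopacket.id) not in used_slots
                     and _has_mutable_part(code, rec.phenopacket)]
            if not hosts:
                continue
            rec = hosts[rng.randrange(len(hosts))]
            injected.append(_inject(code, mutated, rec, rng))
            used_slots.add((code, rec.phenopacket.id))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"corpus of {len(base_records)} records cannot host {k} distinct "
                f"violations (placed {len(injected)})"
            )
    return mutated, injected


def _has_mutable_part(code: str, pp: Phenopacket) -> bool:
    if code == "R8_SUBJECT_MISMATCH":
        return any(itp.genomic_interpretations for itp in pp.interpretations)
    return True
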