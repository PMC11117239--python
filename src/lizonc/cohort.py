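"""Case-record schema, controlled vocabularies and harmonization rules.

A cohort is a collection of individual lizard neoplasia case records drawn
from two kinds of sources: published case reports ("literature") and a
multi-institution clinical oncology registry ("escra", the Exotic Species
Cancer Research Alliance).  Records are heavily incomplete — unknown sex,
life stage, metastasis status and treatment are the norm, not the
exception — so "unknown" is a first-class level of every categorical
field rather than missing data to be dropped.

The module defines

* the :class:`CaseRecord` schema and its enumerated vocabularies,
* harmonization rules: malignancy classification from the reported
  histologic behavior, treatment categorization from raw modality tokens,
  and binary outcome coding for the boosting analysis,
* delimited-text (CSV) input/output with validation.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

UNKNOWN = "unknown"

#: Tokens that normalize to the unknown level (case-insensitive).
UNKNOWN_TOKENS = frozenset({"", "na", "n/a", "nan", "none given", "unknown", "unk"})


class Source(str, enum.Enum):
    literature = "literature"
    escra = "escra"


class LifeStage(str, enum.Enum):
    adult = "adult"
    juvenile = "juvenile"
    unknown = "unknown"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Malignancy(str, enum.Enum):
    benign = "benign"
    malignant = "malignant"
    undetermined = "undetermined"


class Metastasis(str, enum.Enum):
    present = "present"
    absent = "absent"
    unknown = "unknown"


class TreatmentCategory(str, enum.Enum):
    """Union of the literature-review and registry treatment categories."""

    surgery_only = "surgery_only"
    chemotherapy_only = "chemotherapy_only"
    radiation_only = "radiation_only"
    surgery_and_chemotherapy = "surgery_and_chemotherapy"
    surgery_and_radiation = "surgery_and_radiation"
    surgery_radiation_and_chemotherapy = "surgery_radiation_and_chemotherapy"
    supportive_care = "supportive_care"
    unknown_treatment = "unknown_treatment"
    no_treatment = "no_treatment"


class Outcome(str, enum.Enum):
    died_neoplasia = "died_neoplasia"
    died_other = "died_other"
    died_unknown_cause = "died_unknown_cause"
    alive = "alive"
    unknown = "unknown"


#: Treatment categories that count as treatment actually pursued.
PURSUED_TREATMENTS = frozenset(
    t for t in TreatmentCategory
    if t not in (TreatmentCategory.no_treatment, TreatmentCategory.unknown_treatment)
)

#: CSV column order; also the mandatory header of a cohort file.
SCHEMA_FIELDS = (
    "record_id",
    "source",
    "species_common",
    "species_scientific",
    "age_months",
    "life_stage",
    "sex",
    "diagnosis",
    "malignancy",
    "metastasis",
    "tumor_location",
    "treatment",
    "outcome",
    "survival_months",
)

#: The eight categorical predictors entering the boosting model.  Species is
#: keyed on the scientific name (common names collide across sources).
MODEL_VARIABLES = (
    "species_scientific",
    "sex",
    "life_stage",
    "diagnosis",
    "malignancy",
    "metastasis",
    "tumor_location",
    "treatment",
)


class SchemaError(ValueError):
    """Input file does not conform to the case-record schema."""


class UnmappedModalityError(ValueError):
    """A raw treatment token has no entry in the modality synonym table."""


@dataclass(frozen=True)
class CaseRecord:
    """One lizard's harmonized covariates, outcome and survival time.

    ``age_months`` and ``survival_months`` are ``None`` when unknown;
    categorical fields carry their explicit ``unknown`` level instead.
    """

    record_id: str
    source: Source
    species_common: str
    species_scientific: str
    age_months: float | None
    life_stage: LifeStage
    sex: Sex
    diagnosis: str
    malignancy: Malignancy
    metastasis: Metastasis
    tumor_location: str
    treatment: TreatmentCategory
    outcome: Outcome
    survival_months: float | None

    def __post_init__(self) -> None:
        if self.age_months is not None and self.age_months < 0:
            raise ValueError(f"{self.record_id}: age_months must be >= 0")
        if self.survival_months is not None and self.survival_months < 0:
            raise ValueError(f"{self.record_id}: survival_months must be >= 0")


@dataclass(frozen=True)
class OutcomeCoding:
    """Binary outcome for one record: y=1 non-neoplastic, y=0 death due to
    the neoplasm; ``included`` is False for records left out of modeling."""

    y: int | None
    included: bool


@dataclass(frozen=True)
class ValidationIssue:
    record_id: str | None
    field: str
    message: str
    severity: str  # "warning" | "error"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    vocabulary_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.record_id, i.field, i.severity, i.message) for i in self.issues],
            columns=["record_id", "field", "severity", "message"],
        )


class Cohort:
    """Ordered, id-unique collection of :class:`CaseRecord` objects."""

    def __init__(self, records: Iterable[CaseRecord]):
        self.records: list[CaseRecord] = list(records)
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate record_id values: {dupes}")
        self.validation: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CaseRecord:
        return self.records[i]

    def subset(self, source: Source | str) -> "Cohort":
        source = Source(source)
        return Cohort(r for r in self.records if r.source == source)

    def values(self, field_name: str) -> list:
        """Raw per-record values of one schema field, in record order."""
        if field_name not in SCHEMA_FIELDS:
            raise KeyError(f"unknown schema field {field_name!r}")
        return [getattr(r, field_name) for r in self.records]

    def categorical_values(self, field_name: str) -> list[str]:
        """String level labels of a field, enums unwrapped."""
        out = []
        for v in self.values(field_name):
            out.append(v.value if isinstance(v, enum.Enum) else str(v))
        return out

    @property
    def vocabularies(self) -> dict[str, list[str]]:
        """Observed levels per categorical field, lexicographically sorted."""
        vocab = {}
        for f in MODEL_VARIABLES + ("outcome", "source", "species_common"):
            vocab[f] = sorted(set(self.categorical_values(f)))
        return vocab

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {}
            for f in SCHEMA_FIELDS:
                v = getattr(r, f)
                row[f] = v.value if isinstance(v, enum.Enum) else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(SCHEMA_FIELDS))


# ---------------------------------------------------------------------------
# Harmonization rules
# ---------------------------------------------------------------------------

#: Diagnoses defined as malignant by category, matched as case-insensitive
#: substrings.  Lymphosarcoma is the older synonym for lymphoma still used
#: in registry submissions.
DEFAULT_MALIGNANT_SYNONYMS = ("lymphoma", "leukemia", "leukaemia", "lymphosarcoma")


class ReportedBehavior(str, enum.Enum):
    benign = "benign"
    malignant = "malignant"
    ambiguous = "ambiguous"


def classify_malignancy(
    diagnosis: str,
    reported_behavior: ReportedBehavior | str,
    metastasis_observed: bool = False,
    local_invasion_with_destruction: bool = False,
    malignant_synonyms: Sequence[str] = DEFAULT_MALIGNANT_SYNONYMS,
) -> Malignancy:
    """Classify a tumor as benign / malignant / undetermined.

    Round-cell neoplasms (lymphoma, leukemia) are categorically malignant
    regardless of reported behavior.  An unambiguous reported behavior
    passes through.  Ambiguous reports are malignant only with observed
    metastatic disease or local invasion with tissue destruction; otherwise
    the tumor is classified as undetermined.
    """
    if not diagnosis:
        raise ValueError("diagnosis must be non-empty")
    behavior = ReportedBehavior(reported_behavior)
    low = diagnosis.lower()
    if any(s.lower() in low for s in malignant_synonyms):
        return Malignancy.malignant
    if behavior is ReportedBehavior.benign:
        return Malignancy.benign
    if behavior is ReportedBehavior.malignant:
        return Malignancy.malignant
    if metastasis_observed or local_invasion_with_destruction:
        return Malignancy.malignant
    return Malignancy.undetermined


# Raw modality token -> modality class.  Classes combine into categories.
_SURGERY = "surgery"
_CHEMO = "chemo"
_RADIATION = "radiation"
_SUPPORTIVE = "supportive"
_SAMPLING = "sampling"
_NONE = "none"
_UNKNOWN = "unknown"

#: Modality synonym table shared by both sources; entries that only exist
#: in the registry's submission form are marked escra-only.
MODALITY_SYNONYMS: dict[str, tuple[str, str | None]] = {
    # token: (modality class, restricted-to-source or None)
    "surgery": (_SURGERY, None),
    "surgical excision": (_SURGERY, None),
    "excision": (_SURGERY, None),
    "complete excision": (_SURGERY, None),
    "marginal excision": (_SURGERY, None),
    "amputation": (_SURGERY, None),
    "cryosurgery": (_SURGERY, "escra"),
    "cryotherapy": (_SURGERY, "escra"),
    "chemotherapy": (_CHEMO, None),
    "electrochemotherapy": (_CHEMO, "escra"),
    "steroid therapy": (_CHEMO, "escra"),
    "steroids": (_CHEMO, "escra"),
    "nsaid": (_CHEMO, "escra"),
    "nsaids": (_CHEMO, "escra"),
    "radiation": (_RADIATION, None),
    "radiation therapy": (_RADIATION, None),
    "external beam": (_RADIATION, None),
    "strontium": (_RADIATION, None),
    "photoradiation": (_RADIATION, "escra"),
    "phototherapy": (_RADIATION, "escra"),
    "supportive care": (_SUPPORTIVE, "escra"),
    "antibiotics": (_SUPPORTIVE, "escra"),
    "topical antibiotics": (_SUPPORTIVE, "escra"),
    "systemic antibiotics": (_SUPPORTIVE, "escra"),
    "fine needle aspirate": (_SAMPLING, None),
    "fine needle aspirates": (_SAMPLING, None),
    "fna": (_SAMPLING, None),
    "incision biopsy": (_SAMPLING, None),
    "incisional biopsy": (_SAMPLING, None),
    "biopsy": (_SAMPLING, None),
    "no treatment": (_NONE, None),
    "none": (_NONE, None),
    "unknown": (_UNKNOWN, None),
}


def categorize_treatment(
    raw_modalities: Iterable[str], source: Source | str
) -> TreatmentCategory:
    """Map a set of raw treatment modality tokens to a treatment category.

    Diagnostic sampling alone (fine needle aspirates, incision biopsies) is
    not a treatment and maps to ``no_treatment``.  Supportive care counts
    only when no definitive modality (surgery / chemotherapy / radiation)
    was also given.  Unrecognized tokens raise
    :class:`UnmappedModalityError` naming the offending token.
    """
    source = Source(source)
    classes: set[str] = set()
    for raw in raw_modalities:
        token = raw.strip().lower()
        entry = MODALITY_SYNONYMS.get(token)
        if entry is None:
            raise UnmappedModalityError(f"unmapped modality: {raw!r}")
        cls, restricted = entry
        if restricted is not None and source.value != restricted:
            # Tokens outside the source's category list still classify by
            # their modality class; the restriction records provenance only.
            pass
        classes.add(cls)

    definitive = classes & {_SURGERY, _CHEMO, _RADIATION}
    if definitive == {_SURGERY, _CHEMO, _RADIATION}:
        return TreatmentCategory.surgery_radiation_and_chemotherapy
    if definitive == {_SURGERY, _CHEMO}:
        return TreatmentCategory.surgery_and_chemotherapy
    if definitive == {_SURGERY, _RADIATION}:
        return TreatmentCategory.surgery_and_radiation
    if definitive == {_SURGERY}:
        return TreatmentCategory.surgery_only
    if definitive == {_CHEMO}:
        return TreatmentCategory.chemotherapy_only
    if definitive == {_RADIATION}:
        return TreatmentCategory.radiation_only
    if _SUPPORTIVE in classes:
        return TreatmentCategory.supportive_care
    if _UNKNOWN in classes:
        return TreatmentCategory.unknown_treatment
    # Only sampling / explicit no-treatment tokens (or nothing) remain.
    return TreatmentCategory.no_treatment


def encode_outcome(
    outcome: Outcome | str,
    unknown_death: str = "non_neoplastic",
    positive_is_non_neoplastic: bool = True,
) -> OutcomeCoding:
    """Binary outcome coding for the boosting analysis.

    Default convention: y=1 for non-neoplastic outcomes (alive, or death
    from a cause other than the neoplasm) and y=0 for death or euthanasia
    due to the neoplasm, so positive modeled effects read as association
    with the favorable outcome.  ``positive_is_non_neoplastic=False``
    flips the coding.  Records with entirely unknown outcome are excluded;
    deaths of unknown cause are grouped with the non-neoplastic class by
    default (``unknown_death="non_neoplastic"``) or excluded
    (``unknown_death="exclude"``).
    """
    outcome = Outcome(outcome)
    if unknown_death not in ("non_neoplastic", "exclude"):
        raise ValueError("unknown_death must be 'non_neoplastic' or 'exclude'")
    if outcome is Outcome.unknown:
        return OutcomeCoding(y=None, included=False)
    if outcome is Outcome.died_unknown_cause and unknown_death == "exclude":
        return OutcomeCoding(y=None, included=False)
    non_neoplastic = outcome is not Outcome.died_neoplasia
    y = int(non_neoplastic) if positive_is_non_neoplastic else int(not non_neoplastic)
    return OutcomeCoding(y=y, included=True)


def encode_outcomes(
    cohort: Cohort,
    unknown_death: str = "non_neoplastic",
    positive_is_non_neoplastic: bool = True,
) -> tuple["pd.Series", list[int]]:
    """Vector of y values for the included records of a cohort.

    Returns ``(y, index)`` where ``index`` holds the positions of included
    records within the cohort's record order.
    """
    ys, idx = [], []
    for i, r in enumerate(cohort):
        coding = encode_outcome(r.outcome, unknown_death, positive_is_non_neoplastic)
        if coding.included:
            ys.append(coding.y)
            idx.append(i)
    return pd.Series(ys, dtype=float), idx


def subset_by_indices(cohort: Cohort, indices: Sequence[int]) -> Cohort:
    return Cohort(cohort.records[i] for i in indices)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _norm_token(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return UNKNOWN
    s = str(v).strip()
    return UNKNOWN if s.lower() in UNKNOWN_TOKENS else s


def _parse_number(v, field_name: str, record_id: str) -> float | None:
    s = _norm_token(v)
    if s == UNKNOWN:
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"{record_id}: non-numeric {field_name} value {v!r}")


_ENUM_FIELDS = {
    "source": Source,
    "life_stage": LifeStage,
    "sex": Sex,
    "malignancy": Malignancy,
    "metastasis": Metastasis,
    "treatment": TreatmentCategory,
    "outcome": Outcome,
}

# Field-specific spellings of the unknown level.
_ENUM_UNKNOWN = {
    "malignancy": Malignancy.undetermined,
    "treatment": TreatmentCategory.unknown_treatment,
}


def _parse_enum(v, field_name: str, record_id: str):
    enum_cls = _ENUM_FIELDS[field_name]
    s = _norm_token(v)
    if s == UNKNOWN:
        if field_name == "source":
            raise SchemaError(f"{record_id}: source may not be unknown")
        if field_name in _ENUM_UNKNOWN:
            return _ENUM_UNKNOWN[field_name]
        return enum_cls(UNKNOWN)
    try:
        return enum_cls(s.lower())
    except ValueError:
        raise SchemaError(
            f"{record_id}: invalid {field_name} value {v!r}; "
            f"expected one of {[e.value for e in enum_cls]}"
        )


def record_from_mapping(row: dict) -> CaseRecord:
    rid = _norm_token(row.get("record_id"))
    if rid == UNKNOWN:
        raise SchemaError("record with empty record_id")
    return CaseRecord(
        record_id=rid,
        source=_parse_enum(row.get("source"), "source", rid),
        species_common=_norm_token(row.get("species_common")),
        species_scientific=_norm_token(row.get("species_scientific")),
        age_months=_parse_number(row.get("age_months"), "age_months", rid),
        life_stage=_parse_enum(row.get("life_stage"), "life_stage", rid),
        sex=_parse_enum(row.get("sex"), "sex", rid),
        diagnosis=_norm_token(row.get("diagnosis")),
        malignancy=_parse_enum(row.get("malignancy"), "malignancy", rid),
        metastasis=_parse_enum(row.get("metastasis"), "metastasis", rid),
        tumor_location=_norm_token(row.get("tumor_location")),
        treatment=_parse_enum(row.get("treatment"), "treatment", rid),
        outcome=_parse_enum(row.get("outcome"), "outcome", rid),
        survival_months=_parse_number(row.get("survival_months"), "survival_months", rid),
    )


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (header = schema field names; empty cells unknown).

    The returned cohort carries a :class:`ValidationReport` on its
    ``validation`` attribute.  Missing mandatory columns and duplicate
    record ids raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    records = [record_from_mapping(row) for row in df.to_dict("records")]
    cohort = Cohort(records)
    cohort.validation = validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; unknown numbers become empty cells."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)


def read_cohort_string(text: str) -> Cohort:
    return read_cohort(io.StringIO(text))


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check per-record invariants; never mutates the cohort.

    A juvenile life stage with a recorded age of 3 months or more is a
    warning (the classification window is under 3 months of age), as is a
    death of unknown cause, which the default outcome coding groups with
    the non-neoplastic class.
    """
    report = ValidationReport()
    for r in cohort:
        if (
            r.life_stage is LifeStage.juvenile
            and r.age_months is not None
            and r.age_months >= 3
        ):
            report.issues.append(ValidationIssue(
                r.record_id, "life_stage",
                f"juvenile with age {r.age_months} months (window is < 3 months)",
                "warning",
            ))
        if r.outcome is Outcome.died_unknown_cause:
            report.issues.append(ValidationIssue(
                r.record_id, "outcome",
                "death of unknown cause; coded as non-neoplastic by default",
                "warning",
            ))
        if r.outcome is Outcome.alive and r.survival_months is None:
            report.issues.append(ValidationIssue(
                r.record_id, "survival_months",
                "alive record without a censoring time; excluded from survival curves",
                "warning",
            ))
    report.vocabulary_sizes = {f: len(v) for f, v in cohort.vocabularies.items()}
    return report
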