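"""Shared domain types: patient cases, the treatment catalogue, and advice.

These types are the vocabulary of every other module: :class:`PatientCase`
carries one value for each decision point, :class:`TreatmentOption` entries
form the catalogue of treatments under audit, and :class:`TreatmentAdvice`
assigns each catalogue option one of the three advice categories
(recommended / for consideration / not recommended).
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class PTStage(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"


class PNStage(str, enum.Enum):
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"


class NodesExamined(str, enum.Enum):
    """Number of examined regional lymph nodes, dichotomized at 10."""

    LT10 = "LT10"
    GE10 = "GE10"


class Differentiation(str, enum.Enum):
    WELL_MODERATE = "WELL_MODERATE"
    POOR_UNDIFF = "POOR_UNDIFF"


class MsiStatus(str, enum.Enum):
    MSS = "MSS"
    MSI = "MSI"


class ResectionMargin(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    POSITIVE = "POSITIVE"


class Stage(str, enum.Enum):
    """AJCC-style tumor stage group."""

    I = "I"
    II = "II"
    III = "III"


class AdviceCategory(str, enum.Enum):
    """Advice category for one treatment option."""

    R = "R"  # recommended
    C = "C"  # for consideration
    NR = "NR"  # not recommended


class AdviceSource(str, enum.Enum):
    GUIDELINE = "GUIDELINE"
    ADVISOR = "ADVISOR"


CATEGORIES: tuple[AdviceCategory, ...] = (
    AdviceCategory.R,
    AdviceCategory.C,
    AdviceCategory.NR,
)


@dataclass(frozen=True)
class TreatmentOption:
    """One entry of the treatment catalogue."""

    code: str
    label: str
    is_chemotherapy: bool


Catalogue = tuple[TreatmentOption, ...]


def default_catalogue() -> Catalogue:
    """The default 6-option catalogue (one non-chemotherapy option)."""
    return (
        TreatmentOption("OBSERVATION", "Observation (no adjuvant treatment)", False),
        TreatmentOption("CAPE_MONO", "Capecitabine monotherapy", True),
        TreatmentOption("FU_LV_MONO", "5-FU/leucovorin monotherapy", True),
        TreatmentOption("CAPOX", "Capecitabine + oxaliplatin", True),
        TreatmentOption("FOLFOX", "5-FU/leucovorin + oxaliplatin", True),
        TreatmentOption("OTHER_SYSTEMIC", "Other systemic therapy", True),
    )


def validate_catalogue(catalogue: Sequence[TreatmentOption]) -> Catalogue:
    if not catalogue:
        raise ValueError("catalogue must not be empty")
    codes = [o.code for o in catalogue]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate option codes in catalogue: {codes}")
    return tuple(catalogue)


def load_catalogue(path: str | Path) -> Catalogue:
    """Load a catalogue from a JSON list of {code, label, is_chemotherapy}."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise FormatError(f"{path}: catalogue file must be a JSON list")
    options = []
    for entry in raw:
        try:
            options.append(
                TreatmentOption(
                    code=str(entry["code"]),
                    label=str(entry.get("label", entry["code"])),
                    is_chemotherapy=bool(entry["is_chemotherapy"]),
                )
            )
        except (TypeError, KeyError) as exc:
            raise FormatError(f"{path}: malformed catalogue entry {entry!r}") from exc
    return validate_catalogue(options)


def save_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    payload = [
        {"code": o.code, "label": o.label, "is_chemotherapy": o.is_chemotherapy}
        for o in catalogue
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


class FormatError(ValueError):
    """An input file does not conform to its documented dialect."""


@dataclass(frozen=True)
class PatientCase:
    """One synthetic patient: a value for every decision point.

    All fields are mandatory; enum fields accept only their listed values.
    """

    case_id: str
    age: int
    functional_status: int
    pt_stage: PTStage
    pn_stage: PNStage
    nodes_examined: NodesExamined
    differentiation: Differentiation
    vascular_invasion: bool
    obstruction_or_perforation: bool
    msi_status: MsiStatus
    oxaliplatin_contraindicated: bool
    serious_liver_disease: bool
    serious_kidney_disease: bool
    resection_margin: ResectionMargin
    perineural_invasion: bool

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not isinstance(self.age, int) or self.age <= 0:
            raise ValueError(f"age must be a positive integer, got {self.age!r}")
        if self.functional_status not in range(6):
            raise ValueError(
                f"functional_status must be in 0..5, got {self.functional_status!r}"
            )
        for name, typ in _ENUM_FIELDS.items():
            value = getattr(self, name)
            if not isinstance(value, typ):
                raise ValueError(f"{name} must be a {typ.__name__}, got {value!r}")
        for name in _BOOL_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, bool):
                raise ValueError(f"{name} must be a boolean, got {value!r}")


_ENUM_FIELDS: dict[str, type] = {
    "pt_stage": PTStage,
    "pn_stage": PNStage,
    "nodes_examined": NodesExamined,
    "differentiation": Differentiation,
    "msi_status": MsiStatus,
    "resection_margin": ResectionMargin,
}

_BOOL_FIELDS: tuple[str, ...] = (
    "vascular_invasion",
    "obstruction_or_perforation",
    "oxaliplatin_contraindicated",
    "serious_liver_disease",
    "serious_kidney_disease",
    "perineural_invasion",
)

#: All decision-point field names, in canonical (CSV column) order.
CASE_FIELDS: tuple[str, ...] = tuple(
    f.name for f in dc_fields(PatientCase) if f.name != "case_id"
)

#: Finite value domains, for ruleset validation and enumeration.
#: ``age`` is continuous and deliberately absent.
FIELD_DOMAINS: dict[str, tuple[object, ...]] = {
    "functional_status": tuple(range(6)),
    **{name: tuple(typ) for name, typ in _ENUM_FIELDS.items()},
    **{name: (False, True) for name in _BOOL_FIELDS},
}


def value_to_str(value: object) -> str:
    if isinstance(value, enum.Enum):
        return str(value.value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def value_from_str(field: str, text: str) -> object:
    """Parse one CSV cell back into the field's Python value."""
    text = text.strip()
    if field in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[field](text)
        except ValueError as exc:
            raise FormatError(f"invalid value {text!r} for field {field}") from exc
    if field in _BOOL_FIELDS:
        lowered = text.lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no"):
            return False
        raise FormatError(f"invalid boolean {text!r} for field {field}")
    if field in ("age", "functional_status"):
        try:
            return int(text)
        except ValueError as exc:
            raise FormatError(f"invalid integer {text!r} for field {field}") from exc
    raise FormatError(f"unknown case field {field!r}")


def case_to_row(case: PatientCase) -> dict[str, str]:
    row = {"case_id": case.case_id}
    for name in CASE_FIELDS:
        row[name] = value_to_str(getattr(case, name))
    return row


def case_from_row(row: Mapping[str, str]) -> PatientCase:
    missing = [c for c in ("case_id", *CASE_FIELDS) if c not in row]
    if missing:
        raise FormatError(f"case row missing columns: {missing}")
    kwargs = {name: value_from_str(name, row[name]) for name in CASE_FIELDS}
    return PatientCase(case_id=str(row["case_id"]), **kwargs)


def write_cases_csv(cases: Iterable[PatientCase], path: str | Path) -> None:
    """Write cases as CSV, one row per case, header row first."""
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=["case_id", *CASE_FIELDS])
        writer.writeheader()
        for case in cases:
            writer.writerow(case_to_row(case))


def read_cases_csv(path: str | Path) -> list[PatientCase]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        cases = [case_from_row(row) for row in reader]
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate case_id values")
    return cases


@dataclass(frozen=True)
class TreatmentAdvice:
    """A total assignment of advice categories over a catalogue.

    Stored as an ordered tuple of (option code, category) pairs so advice
    values are hashable (used as path signatures during case deduplication).
    Build instances with :meth:`of`, which orders by the catalogue and
    coerces unmentioned options to NR.
    """

    items: tuple[tuple[str, AdviceCategory], ...]
    source: AdviceSource = AdviceSource.GUIDELINE

    @classmethod
    def of(
        cls,
        categories: Mapping[str, AdviceCategory | str],
        catalogue: Catalogue,
        source: AdviceSource = AdviceSource.GUIDELINE,
    ) -> "TreatmentAdvice":
        codes = {o.code for o in catalogue}
        unknown = set(categories) - codes
        if unknown:
            raise FormatError(f"unknown option codes in advice: {sorted(unknown)}")
        items = tuple(
            (o.code, AdviceCategory(categories.get(o.code, AdviceCategory.NR)))
            for o in catalogue
        )
        return cls(items=items, source=source)

    @property
    def categories(self) -> dict[str, AdviceCategory]:
        return dict(self.items)

    def __getitem__(self, code: str) -> AdviceCategory:
        for c, cat in self.items:
            if c == code:
                return cat
        raise KeyError(code)

    def __iter__(self) -> Iterator[tuple[str, AdviceCategory]]:
        return iter(self.items)

    def is_total_over(self, catalogue: Catalogue) -> bool:
        return tuple(c for c, _ in self.items) == tuple(o.code for o in catalogue)

    def with_source(self, source: AdviceSource) -> "TreatmentAdvice":
        return TreatmentAdvice(items=self.items, source=source)
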