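"""Patient and cohort data model for BI-RADS structured mammography reports.

A screening case is described by general patient data (age, personal and
family cancer history) plus the radiologist-annotated mammogram findings in
the BI-RADS lexicon: mass (shape, margins, density), calcifications (type,
shape, distribution), asymmetries and architectural distortion, overall
breast tissue density, and the assigned BI-RADS category.  An optional
biopsy-confirmed outcome label (``cancer`` / ``non-cancer``) supports
training and evaluation; screening-mode records carry no label.

All categorical values are validated against controlled vocabularies and
canonicalized on read (case-insensitive, with a small alias table for
spellings that vary across the BI-RADS literature, e.g. "popcorn" for coarse
calcifications and "homogeneous" for equal-density masses).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping, Optional

__all__ = [
    "PatientRecord",
    "Cohort",
    "ValidationError",
    "CohortParseError",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "read_patient_json",
    "COLUMNS",
    "VOCABULARIES",
]


class ValidationError(ValueError):
    """A record field violates its controlled vocabulary or an invariant."""


class CohortParseError(ValueError):
    """A cohort file is malformed or contains invalid rows."""


# Controlled vocabularies (canonical spellings).
PERSONAL_HISTORY = ("yes", "no", "NA")
FAMILY_HISTORY = ("none", "minor", "major", "NA")
MASS_SHAPE = ("none", "oval", "round", "lobulated", "irregular")
MASS_MARGINS = (
    "none",
    "circumscribed",
    "obscured",
    "micro-lobulated",
    "indistinct",
    "spiculated",
)
MASS_DENSITY = ("none", "equal density", "low density", "high density")
CALC_TYPE = ("none", "primary", "associated")
CALC_SHAPE = (
    "none",
    "skin",
    "vascular",
    "coarse",
    "large rod-like",
    "round",
    "rim",
    "dystrophic",
    "milk of calcium",
    "suture",
    "amorphous",
    "coarse heterogeneous",
    "fine pleomorphic",
    "fine linear",
    "fine linear branching",
)
CALC_DISTRIBUTION = ("none", "diffuse", "regional", "grouped", "linear", "segmental")
ASYMMETRY_TYPE = ("none", "missing", "focal", "developing")
DISTORTION_TYPE = ("none", "primary", "associated")
BREAST_DENSITY = (
    "missing",
    "fatty",
    "scattered fibroglandular",
    "heterogeneously dense",
    "extremely dense",
)
BIRADS = ("0", "1", "2", "3", "4A", "4B", "4C", "5", "6")
LABEL = ("cancer", "non-cancer")

#: alias -> canonical value (keys lower-case); covers spelling variants used
#: interchangeably in the BI-RADS literature.
ALIASES = {
    'coarse or "popcorn-like"': "coarse",
    "coarse or popcorn-like": "coarse",
    "popcorn": "coarse",
    "popcorn-like": "coarse",
    "homogeneous": "equal density",
    "isodense": "equal density",
    "scattered areas of fibro glandular": "scattered fibroglandular",
    "scattered areas of fibroglandular": "scattered fibroglandular",
    "scattered fibro glandular": "scattered fibroglandular",
    "4.a": "4A",
    "4.b": "4B",
    "4.c": "4C",
    "n/a": "NA",
    "microlobulated": "micro-lobulated",
    "large rodlike": "large rod-like",
    "non cancer": "non-cancer",
    "noncancer": "non-cancer",
}

VOCABULARIES: dict[str, tuple[str, ...]] = {
    "personal_history": PERSONAL_HISTORY,
    "family_history": FAMILY_HISTORY,
    "mass_shape": MASS_SHAPE,
    "mass_margins": MASS_MARGINS,
    "mass_density": MASS_DENSITY,
    "calc_type": CALC_TYPE,
    "calc_shape": CALC_SHAPE,
    "calc_distribution": CALC_DISTRIBUTION,
    "asymmetry_type": ASYMMETRY_TYPE,
    "distortion_type": DISTORTION_TYPE,
    "breast_density": BREAST_DENSITY,
    "birads": BIRADS,
    "label": LABEL,
}

FLAG_FIELDS = ("mass_present", "calc_present", "asymmetry_present", "distortion_present")

#: finding-group flag -> its dependent sub-fields (forced to "none" when absent)
FINDING_GROUPS = {
    "mass_present": ("mass_shape", "mass_margins", "mass_density"),
    "calc_present": ("calc_type", "calc_shape", "calc_distribution"),
    "asymmetry_present": ("asymmetry_type",),
    "distortion_present": ("distortion_type",),
}

#: documented CSV column order (also the JSON field names)
COLUMNS = (
    "patient_id",
    "age",
    "personal_history",
    "family_history",
    "mass_present",
    "mass_shape",
    "mass_margins",
    "mass_density",
    "calc_present",
    "calc_type",
    "calc_shape",
    "calc_distribution",
    "asymmetry_present",
    "asymmetry_type",
    "distortion_present",
    "distortion_type",
    "breast_density",
    "birads",
    "label",
)

MANDATORY = tuple(c for c in COLUMNS if c != "label")

_TRUE = {"true", "yes", "present", "1", "y"}
_FALSE = {"false", "no", "absent", "0", "n"}
# values treated as "unspecified" for sub-fields of an absent finding group
_EMPTYISH = {"", "-", "na", "n/a", "none", "missing"}

# case-insensitive lookup tables, canonical values included as their own keys
_LOOKUP: dict[str, dict[str, str]] = {}
for _field, _vocab in VOCABULARIES.items():
    table = {v.lower(): v for v in _vocab}
    for alias, canon in ALIASES.items():
        if canon in _vocab:
            table[alias.lower()] = canon
    _LOOKUP[_field] = table


@dataclass(frozen=True)
class PatientRecord:
    """One screening case in canonical form."""

    patient_id: str
    age: float
    personal_history: str
    family_history: str
    mass_present: bool
    mass_shape: str
    mass_margins: str
    mass_density: str
    calc_present: bool
    calc_type: str
    calc_shape: str
    calc_distribution: str
    asymmetry_present: bool
    asymmetry_type: str
    distortion_present: bool
    distortion_type: str
    breast_density: str
    birads: str
    label: Optional[str] = None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """An ordered collection of patient records with unique ids."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]


def _canon_category(field: str, value: Any) -> str:
    key = str(value).strip().lower()
    try:
        return _LOOKUP[field][key]
    except KeyError:
        raise ValidationError(
            f"field {field!r}: value {value!r} not in vocabulary {VOCABULARIES[field]}"
        ) from None


def _canon_flag(field: str, value: Any) -> bool:
    if isinstance(value, bool):
        return value
    key = str(value).strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise ValidationError(
        f"field {field!r}: value {value!r} is not a recognized present/absent flag"
    )


def validate_record(raw: Mapping[str, Any]) -> PatientRecord:
    """Validate and canonicalize a raw field mapping into a :class:`PatientRecord`.

    Raises :class:`ValidationError` naming the offending field for vocabulary
    violations, missing mandatory fields, out-of-range ages, or sub-fields
    inconsistent with an absent finding group.  Idempotent: validating the
    dict of an already-validated record reproduces it exactly.
    """
    missing = [f for f in MANDATORY if f not in raw or raw[f] is None]
    if missing:
        raise ValidationError(f"missing mandatory field(s): {missing}")

    out: dict[str, Any] = {"patient_id": str(raw["patient_id"])}

    try:
        age = float(raw["age"])
    except (TypeError, ValueError):
        raise ValidationError(f"field 'age': {raw['age']!r} is not a number") from None
    if not 0 < age < 130:
        raise ValidationError(f"field 'age': {age} outside (0, 130)")
    out["age"] = age

    for field in FLAG_FIELDS:
        out[field] = _canon_flag(field, raw[field])

    for field in ("personal_history", "family_history", "breast_density", "birads"):
        out[field] = _canon_category(field, raw[field])

    # finding sub-fields: forced to "none" when the group is absent; a concrete
    # non-none value on an absent group is an inconsistency, not silently dropped
    for flag, subfields in FINDING_GROUPS.items():
        present = out[flag]
        for field in subfields:
            value = raw[field]
            if present:
                out[field] = _canon_category(field, value)
            else:
                if str(value).strip().lower() in _EMPTYISH:
                    out[field] = "none"
                else:
                    canon = _canon_category(field, value)
                    if canon != "none":
                        raise ValidationError(
                            f"field {field!r}: value {canon!r} inconsistent with "
                            f"{flag}=absent"
                        )
                    out[field] = "none"

    label = raw.get("label")
    if label is None or str(label).strip() == "":
        out["label"] = None
    else:
        out["label"] = _canon_category("label", label)

    return PatientRecord(**out)


def _record_to_row(record: PatientRecord) -> dict[str, str]:
    row = {}
    for col in COLUMNS:
        value = getattr(record, col)
        if isinstance(value, bool):
            row[col] = "true" if value else "false"
        elif value is None:
            row[col] = ""
        else:
            row[col] = str(value)
    return row


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_cohort(path: str | Path, fmt: Optional[str] = None) -> Cohort:
    """Read a cohort from a CSV (documented header) or JSON file.

    Every row is validated via :func:`validate_record`; failures are collected
    and reported together with their row numbers.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in MANDATORY if c not in header]
            if missing:
                raise CohortParseError(f"{path}: missing column(s) {missing}")
            rows = list(reader)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"{path}: invalid JSON ({exc})") from exc
        if isinstance(doc, dict) and "records" in doc:
            rows = doc["records"]
        elif isinstance(doc, list):
            rows = doc
        else:
            raise CohortParseError(f"{path}: expected a record list or a 'records' key")
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")

    records, errors = [], []
    for i, row in enumerate(rows, start=1):
        try:
            records.append(validate_record(row))
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise CohortParseError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return Cohort(records=records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path, fmt: Optional[str] = None) -> Path:
    """Write a cohort to CSV or JSON; round-trips losslessly through
    :func:`read_cohort`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(COLUMNS))
            writer.writeheader()
            for record in cohort:
                writer.writerow(_record_to_row(record))
    elif fmt == "json":
        doc = {"provenance": cohort.provenance, "records": [r.to_dict() for r in cohort]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    return path


def read_patient_json(path: str | Path) -> PatientRecord:
    """Read and validate a single-patient JSON document."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CohortParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, Mapping):
        raise CohortParseError(f"{path}: expected a JSON object of record fields")
    return validate_record(doc)
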