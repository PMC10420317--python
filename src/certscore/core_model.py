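"""Subject-level data model, unit handling, and CSV/report I/O.

A cohort is an ordered collection of :class:`SubjectRecord` objects, one per
participant, carrying demographics, anthropometrics, blood pressure,
biochemistry and the four plasma ceramide concentrations (in µmol/L) that the
scoring and statistics modules consume.  CSV input uses one comma-separated
header row; units are fixed by the schema, never declared per file.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "SubjectRecord",
    "CohortFrame",
    "SchemaError",
    "ParseError",
    "read_cohort_csv",
    "write_report",
    "read_report",
    "convert_glucose",
    "GLUCOSE_MG_PER_MMOL",
    "NUMERIC_FIELDS",
    "BOOLEAN_FIELDS",
]

#: Molar mass based conversion: mg/dL of glucose per mmol/L (180.16 g/mol / 10).
GLUCOSE_MG_PER_MMOL = 18.016

#: Rounded bracket factor some clinical sources quote (1 mg/dL = 0.06 mmol/L).
GLUCOSE_ROUNDED_FACTOR = 0.06


class Group(str, enum.Enum):
    """Study group labels: normal weight, obese without / with metabolic syndrome."""

    NW = "NW"
    OB_METS_NEG = "OB-MetS-"
    OB_METS_POS = "OB-MetS+"
    UNASSIGNED = "UNASSIGNED"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class SchemaError(ValueError):
    """A mandatory column is missing or the schema mapping is inconsistent."""


class ParseError(ValueError):
    """A cell could not be parsed into its declared type."""


# canonical column -> (unit, mandatory)
_FIELD_SPEC: dict[str, tuple[str, bool]] = {
    "id": ("", True),
    "group": ("", False),
    "sex": ("", True),
    "age": ("years", True),
    "smoking": ("bool", False),
    "bmi": ("kg/m^2", False),
    "wc": ("cm", False),
    "sbp": ("mmHg", False),
    "dbp": ("mmHg", False),
    "glucose": ("mg/dL", False),
    "insulin": ("uIU/mL", False),
    "tc": ("mg/dL", False),
    "hdl": ("mg/dL", False),
    "ldl": ("mg/dL", False),
    "tg": ("mg/dL", False),
    "crp": ("mg/dL", False),
    "cer16": ("umol/L", True),
    "cer18": ("umol/L", True),
    "cer241": ("umol/L", True),
    "cer240": ("umol/L", True),
    "treated_htn": ("bool", False),
    "diabetes": ("bool", False),
}

NUMERIC_FIELDS: tuple[str, ...] = (
    "age",
    "bmi",
    "wc",
    "sbp",
    "dbp",
    "glucose",
    "insulin",
    "tc",
    "hdl",
    "ldl",
    "tg",
    "crp",
    "cer16",
    "cer18",
    "cer241",
    "cer240",
)

BOOLEAN_FIELDS: tuple[str, ...] = ("smoking", "treated_htn", "diabetes")

#: Fields that must be strictly positive when present (concentrations,
#: pressures, anthropometrics, age).  CRP may legitimately be zero (below
#: the assay detection limit).
_STRICTLY_POSITIVE = (
    "age",
    "bmi",
    "wc",
    "sbp",
    "dbp",
    "glucose",
    "insulin",
    "tc",
    "hdl",
    "ldl",
    "tg",
    "cer16",
    "cer18",
    "cer241",
    "cer240",
)


@dataclass
class SubjectRecord:
    """One participant's demographics, clinical measurements and ceramide panel.

    All concentrations use the units of the schema: glucose/lipids/CRP in
    mg/dL, insulin in µIU/mL (identical to mU/L), ceramides in µmol/L,
    pressures in mmHg.  Optional analytes may be ``None``; operations whose
    required input is ``None`` raise rather than impute.
    """

    id: str
    sex: Sex
    age: float
    group: Group = Group.UNASSIGNED
    smoking: bool | None = None
    bmi: float | None = None
    wc: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    glucose: float | None = None
    insulin: float | None = None
    tc: float | None = None
    hdl: float | None = None
    ldl: float | None = None
    tg: float | None = None
    crp: float | None = None
    cer16: float | None = None
    cer18: float | None = None
    cer241: float | None = None
    cer240: float | None = None
    treated_htn: bool | None = None
    diabetes: bool | None = None

    def __post_init__(self) -> None:
        if isinstance(self.sex, str):
            self.sex = Sex(self.sex)
        if isinstance(self.group, str):
            self.group = Group(self.group)
        for name in _STRICTLY_POSITIVE:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(
                    f"subject {self.id!r}: field {name!r} must be strictly "
                    f"positive, got {value!r}"
                )
        if self.crp is not None and self.crp < 0:
            raise ValueError(f"subject {self.id!r}: crp must be non-negative")

    def require(self, *names: str) -> None:
        """Raise ``ValueError`` naming the first missing field among *names*."""
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"subject {self.id!r}: required field {name!r} is missing")

    def as_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, enum.Enum):
                value = value.value
            out[f.name] = value
        return out


@dataclass
class CohortFrame:
    """Ordered collection of subjects with a provenance note.

    ``provenance`` records where the cohort came from (a file path or a
    simulation seed) so analysis reports are self-describing.
    """

    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    @property
    def groups(self) -> list[Group]:
        return sorted({s.group for s in self.subjects}, key=lambda g: g.value)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to a :class:`pandas.DataFrame` (enums as their string values)."""
        df = pd.DataFrame([s.as_dict() for s in self.subjects])
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortFrame":
        subjects = []
        for _, row in df.iterrows():
            kwargs: dict[str, Any] = {}
            for f in fields(SubjectRecord):
                if f.name not in df.columns:
                    continue
                value = row[f.name]
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    value = None
                kwargs[f.name] = value
            subjects.append(SubjectRecord(**kwargs))
        return cls(subjects=subjects, provenance=provenance)


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(raw: Any, row_id: str, column: str) -> bool | None:
    if raw is None:
        return None
    if isinstance(raw, bool):
        return raw
    if isinstance(raw, (int, float)):
        if float(raw) in (0.0, 1.0):
            return bool(raw)
        raise ParseError(f"row {row_id!r}: non-boolean value {raw!r} in column {column!r}")
    text = str(raw).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"row {row_id!r}: non-boolean value {raw!r} in column {column!r}")


def _parse_float(raw: Any, row_id: str, column: str) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    if isinstance(raw, str) and raw.strip() == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row_id!r}: non-numeric value {raw!r} in numeric column {column!r}"
        ) from exc


def read_cohort_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> CohortFrame:
    """Read a subject-level cohort from a comma-separated UTF-8 file.

    Parameters
    ----------
    path:
        CSV file with one header row naming columns.
    schema:
        Optional mapping from canonical field names (``"wc"``, ``"cer16"``,
        ...) to the column names used in the file.  Fields not mentioned keep
        their canonical name.

    Raises
    ------
    SchemaError
        if a mandatory column (id, sex, age, the four ceramides) is absent.
    ParseError
        if a numeric cell fails to parse; the message names the row id.
    """
    path = Path(path)
    schema = dict(schema or {})
    rename = {schema.get(name, name): name for name in _FIELD_SPEC}
    raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    raw = raw.rename(columns=rename)
    for name, (_, mandatory) in _FIELD_SPEC.items():
        if mandatory and name not in raw.columns:
            raise SchemaError(f"mandatory column {name!r} missing from {path.name}")

    subjects: list[SubjectRecord] = []
    for _, row in raw.iterrows():
        row_id = str(row["id"]).strip()
        kwargs: dict[str, Any] = {"id": row_id}
        group_raw = row.get("group")
        if group_raw is None or (isinstance(group_raw, float) and math.isnan(group_raw)):
            kwargs["group"] = Group.UNASSIGNED
        else:
            try:
                kwargs["group"] = Group(str(group_raw).strip())
            except ValueError as exc:
                raise ParseError(f"row {row_id!r}: unknown group label {group_raw!r}") from exc
        sex_raw = str(row["sex"]).strip().upper()
        try:
            kwargs["sex"] = Sex(sex_raw)
        except ValueError as exc:
            raise ParseError(f"row {row_id!r}: unknown sex label {sex_raw!r}") from exc
        for name in NUMERIC_FIELDS:
            if name in raw.columns:
                kwargs[name] = _parse_float(row[name], row_id, name)
        for name in BOOLEAN_FIELDS:
            if name in raw.columns:
                kwargs[name] = _parse_bool(row[name], row_id, name)
        subjects.append(SubjectRecord(**kwargs))
    return CohortFrame(subjects=subjects, provenance=str(path))


def write_cohort_csv(cohort: CohortFrame, path: str | Path) -> Path:
    """Write a cohort back to CSV with canonical column names."""
    path = Path(path)
    cohort.to_dataframe().to_csv(path, index=False)
    return path


def write_report(report: Any, path: str | Path) -> Path:
    """Serialize an analysis report (or any mapping) to JSON.

    Floats are stored at full ``repr`` precision so that re-reading the file
    reproduces every numeric field bit-exactly.
    """
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    try:
        path.write_text(json.dumps(payload, indent=2, allow_nan=True), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def read_report(path: str | Path) -> dict[str, Any]:
    """Read back a report written by :func:`write_report` as a plain dict."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


def convert_glucose(mg_per_dl: float, rounded: bool = False) -> float:
    """Convert a glucose concentration from mg/dL to mmol/L.

    The exact molar factor 1/18.016 is used by default.  ``rounded=True``
    selects the coarser bracket factor 0.06 mmol/L per mg/dL that some
    clinical reports quote, for replication studies; it introduces roughly
    8% bias and is never the default.
    """
    if mg_per_dl < 0:
        raise ValueError(f"glucose concentration must be non-negative, got {mg_per_dl}")
    if rounded:
        return mg_per_dl * GLUCOSE_ROUNDED_FACTOR
    return mg_per_dl / GLUCOSE_MG_PER_MMOL


def iter_complete(cohort: CohortFrame, names: Iterable[str]) -> Iterator[SubjectRecord]:
    """Yield the subjects of *cohort* with all fields in *names* present."""
    names = tuple(names)
    for s in cohort:
        if all(getattr(s, n) is not None for n in names):
            yield s
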