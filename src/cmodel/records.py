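"""Per-woman delivery records: data model, CSV I/O and input validation.

The CSV dialect is RFC-4180 with a mandatory header row.  Missing values are
explicit (empty cell or a configurable sentinel, default ``""`` and ``"NA"``);
no imputation happens anywhere in the package.  Malformed cells degrade to
missing with a logged warning — parsing is total and never drops a row.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields as _dc_fields
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

from .errors import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Onset",
    "Presentation",
    "PreeclampsiaLevel",
    "DeliveryMode",
    "WomanRecord",
    "FacilityDataset",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "DEFAULT_MISSING_TOKENS",
    "FIELD_ORDER",
]


class Onset(str, Enum):
    SPONTANEOUS = "spontaneous"
    INDUCED = "induced"
    PRELABOUR_CS = "prelabour_cs"


class Presentation(str, Enum):
    CEPHALIC = "cephalic"
    BREECH = "breech"
    TRANSVERSE_OBLIQUE = "transverse_oblique"
    OTHER = "other"


class PreeclampsiaLevel(str, Enum):
    NONE = "none"
    PREECLAMPSIA = "preeclampsia"
    ECLAMPSIA = "eclampsia"


class DeliveryMode(str, Enum):
    VAGINAL = "vaginal"
    CAESAREAN = "caesarean"


@dataclass
class WomanRecord:
    """One delivery.  Every clinical field is optional; ``None`` means missing."""

    record_id: str
    facility_id: str
    country_id: Optional[str] = None
    maternal_age: Optional[int] = None
    parity: Optional[int] = None
    previous_cs: Optional[int] = None
    onset_of_labour: Optional[Onset] = None
    gestational_age: Optional[int] = None
    presentation: Optional[Presentation] = None
    multiple_pregnancy: Optional[bool] = None
    organ_dysfunction_or_icu: Optional[bool] = None
    placenta_praevia: Optional[bool] = None
    abruptio_placentae: Optional[bool] = None
    chronic_hypertension: Optional[bool] = None
    renal_disease: Optional[bool] = None
    hiv: Optional[bool] = None
    preeclampsia_level: Optional[PreeclampsiaLevel] = None
    mode_of_delivery: Optional[DeliveryMode] = None
    livebirth: Optional[bool] = None
    intrapartum_stillbirth: Optional[bool] = None
    neonatal_death_day1: Optional[bool] = None
    maternal_death: Optional[bool] = None
    maternal_near_miss: Optional[bool] = None


# Canonical column order for CSV output; also the default column names.
FIELD_ORDER: tuple[str, ...] = tuple(f.name for f in _dc_fields(WomanRecord))

# Fields whose presence/absence is tracked in the dataset manifest.
_OPTIONAL_FIELDS: tuple[str, ...] = tuple(
    f for f in FIELD_ORDER if f not in ("record_id", "facility_id")
)

DEFAULT_MISSING_TOKENS = ("", "na")

# Extensible synonym tables; lookups are case-insensitive with ' ' and '-'
# normalised to '_'.
ENUM_SYNONYMS: dict[type, dict[str, Enum]] = {
    Onset: {
        "spontaneous": Onset.SPONTANEOUS,
        "spont": Onset.SPONTANEOUS,
        "induced": Onset.INDUCED,
        "induction": Onset.INDUCED,
        "prelabour_cs": Onset.PRELABOUR_CS,
        "prelabor_cs": Onset.PRELABOUR_CS,
        "cs_before_labour": Onset.PRELABOUR_CS,
        "cs_before_labor": Onset.PRELABOUR_CS,
    },
    Presentation: {
        "cephalic": Presentation.CEPHALIC,
        "vertex": Presentation.CEPHALIC,
        "breech": Presentation.BREECH,
        "transverse_oblique": Presentation.TRANSVERSE_OBLIQUE,
        "transverse": Presentation.TRANSVERSE_OBLIQUE,
        "oblique": Presentation.TRANSVERSE_OBLIQUE,
        "transverse_lie": Presentation.TRANSVERSE_OBLIQUE,
        "other": Presentation.OTHER,
    },
    PreeclampsiaLevel: {
        "none": PreeclampsiaLevel.NONE,
        "no": PreeclampsiaLevel.NONE,
        "preeclampsia": PreeclampsiaLevel.PREECLAMPSIA,
        "pre_eclampsia": PreeclampsiaLevel.PREECLAMPSIA,
        "eclampsia": PreeclampsiaLevel.ECLAMPSIA,
    },
    DeliveryMode: {
        "vaginal": DeliveryMode.VAGINAL,
        "vag": DeliveryMode.VAGINAL,
        "caesarean": DeliveryMode.CAESAREAN,
        "cesarean": DeliveryMode.CAESAREAN,
        "caesarean_section": DeliveryMode.CAESAREAN,
        "cs": DeliveryMode.CAESAREAN,
        "c_section": DeliveryMode.CAESAREAN,
        "csection": DeliveryMode.CAESAREAN,
    },
}

_TRUE_TOKENS = {"true", "t", "yes", "y", "1"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0"}

_ENUM_FIELDS = {
    "onset_of_labour": Onset,
    "presentation": Presentation,
    "preeclampsia_level": PreeclampsiaLevel,
    "mode_of_delivery": DeliveryMode,
}
_BOOL_FIELDS = (
    "multiple_pregnancy",
    "organ_dysfunction_or_icu",
    "placenta_praevia",
    "abruptio_placentae",
    "chronic_hypertension",
    "renal_disease",
    "hiv",
    "livebirth",
    "intrapartum_stillbirth",
    "neonatal_death_day1",
    "maternal_death",
    "maternal_near_miss",
)
_INT_FIELDS = ("maternal_age", "parity", "previous_cs", "gestational_age")

# Plausibility windows; values outside degrade to missing with a warning.
_INT_BOUNDS = {
    "maternal_age": (10, 60),
    "gestational_age": (22, 44),
    "parity": (0, 30),
    "previous_cs": (0, 20),
}


@dataclass
class FacilityDataset:
    """An ordered collection of :class:`WomanRecord` with provenance."""

    records: list[WomanRecord]
    provenance: str = ""
    parse_warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[WomanRecord]:
        return iter(self.records)

    @property
    def column_manifest(self) -> frozenset[str]:
        """Optional fields that are non-missing for at least one record."""
        present: set[str] = set()
        for rec in self.records:
            for name in _OPTIONAL_FIELDS:
                if name not in present and getattr(rec, name) is not None:
                    present.add(name)
        return frozenset(present)

    @property
    def n_parse_warnings(self) -> int:
        return len(self.parse_warnings)

    def subset(self, records: Sequence[WomanRecord], note: str = "") -> "FacilityDataset":
        return FacilityDataset(
            records=list(records),
            provenance=f"{self.provenance}{'|' if self.provenance else ''}{note}",
        )


def _normalise_token(raw: str) -> str:
    return raw.strip().lower().replace("-", "_").replace(" ", "_")


def _parse_cell(name: str, raw: str, missing_tokens: frozenset[str], warnings: list[str]):
    token = raw.strip()
    if token.lower() in missing_tokens:
        return None
    if name in _ENUM_FIELDS:
        enum_cls = _ENUM_FIELDS[name]
        value = ENUM_SYNONYMS[enum_cls].get(_normalise_token(token))
        if value is None:
            warnings.append(f"{name}: unrecognised value {raw!r}")
        return value
    if name in _BOOL_FIELDS:
        norm = token.lower()
        if norm in _TRUE_TOKENS:
            return True
        if norm in _FALSE_TOKENS:
            return False
        warnings.append(f"{name}: unrecognised boolean {raw!r}")
        return None
    if name in _INT_FIELDS:
        try:
            value = float(token)
        except ValueError:
            warnings.append(f"{name}: not a number {raw!r}")
            return None
        if value != int(value):
            warnings.append(f"{name}: non-integer value {raw!r}")
            return None
        value = int(value)
        # previous_cs may arrive as a 0/1 flag; a count ≥ 0 is also fine and
        # both normalise to a count, so only the bounds are enforced here.
        lo, hi = _INT_BOUNDS[name]
        if not lo <= value <= hi:
            warnings.append(f"{name}: out-of-range value {raw!r}")
            return None
        return value
    return token  # identifier fields pass through verbatim


def read_dataset(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    *,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> FacilityDataset:
    """Read a delivery CSV into a :class:`FacilityDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Mapping from source column names to ``WomanRecord`` field names.
        Defaults to the identity mapping over the canonical field names;
        unmapped fields become missing.
    missing_tokens:
        Case-insensitive cell values interpreted as missing.
    """
    path = Path(path)
    missing = frozenset(t.lower() for t in missing_tokens)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, no header row")
        if schema is None:
            column_to_field = {c: c for c in header if c in FIELD_ORDER}
        else:
            absent = [c for c in schema if c not in header]
            if absent:
                raise SchemaError(
                    f"{path}: mapped column(s) absent from header: {', '.join(sorted(absent))}"
                )
            column_to_field = dict(schema)

        records: list[WomanRecord] = []
        warnings: list[str] = []
        for i, row in enumerate(reader):
            kwargs: dict = {}
            row_warnings: list[str] = []
            for column, field_name in column_to_field.items():
                raw = row.get(column)
                if raw is None:
                    continue
                kwargs[field_name] = _parse_cell(field_name, raw, missing, row_warnings)
            kwargs.setdefault("record_id", str(i))
            kwargs.setdefault("facility_id", "unknown")
            if kwargs["record_id"] is None:
                kwargs["record_id"] = str(i)
            if kwargs["facility_id"] is None:
                kwargs["facility_id"] = "unknown"
            records.append(WomanRecord(**kwargs))
            warnings.extend(f"row {i} ({kwargs['record_id']}): {w}" for w in row_warnings)

    if warnings:
        logger.warning("%s: %d cell(s) degraded to missing while parsing", path, len(warnings))
    return FacilityDataset(records=records, provenance=str(path), parse_warnings=warnings)


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    return str(value)


def write_dataset(ds: FacilityDataset, path: str | Path) -> None:
    """Write a dataset using the canonical column names (RFC-4180, UTF-8)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(FIELD_ORDER)
        for rec in ds.records:
            writer.writerow([_format_cell(getattr(rec, name)) for name in FIELD_ORDER])


@dataclass
class ValidationReport:
    """Counts of record-level invariant violations; reporting only."""

    n_records: int
    violations: dict[str, dict]

    def to_dict(self) -> dict:
        return {"n_records": self.n_records, "violations": self.violations}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @property
    def total_violations(self) -> int:
        return sum(v["count"] for v in self.violations.values())


_MAX_EXAMPLES = 10


def validate_dataset(ds: FacilityDataset) -> ValidationReport:
    """Check record-level invariants and report violation counts.

    The dataset is never modified; each invariant lists at most ten example
    record ids.
    """
    checks = {
        "previous_cs_implies_parity": lambda r: (
            r.previous_cs is not None
            and r.previous_cs > 0
            and r.parity is not None
            and r.parity == 0
        ),
        "prelabour_cs_implies_caesarean": lambda r: (
            r.onset_of_labour is Onset.PRELABOUR_CS
            and r.mode_of_delivery is not None
            and r.mode_of_delivery is not DeliveryMode.CAESAREAN
        ),
        "stillbirth_implies_not_livebirth": lambda r: (
            r.intrapartum_stillbirth is True and r.livebirth is True
        ),
    }
    violations: dict[str, dict] = {}
    for name, predicate in checks.items():
        count = 0
        examples: list[str] = []
        for rec in ds.records:
            if predicate(rec):
                count += 1
                if len(examples) < _MAX_EXAMPLES:
                    examples.append(rec.record_id)
        violations[name] = {"count": count, "examples": examples}

    seen: set[str] = set()
    dup_count = 0
    dup_examples: list[str] = []
    for rec in ds.records:
        if rec.record_id in seen:
            dup_count += 1
            if len(dup_examples) < _MAX_EXAMPLES:
                dup_examples.append(rec.record_id)
        seen.add(rec.record_id)
    violations["unique_record_id"] = {"count": dup_count, "examples": dup_examples}

    return ValidationReport(n_records=len(ds), violations=violations)
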