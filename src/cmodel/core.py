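"""Covariate encoding and the four published caesarean-section scoring models.

Each model version is a fixed logistic score: ``logit = β + Σ xi·βi`` over the
covariates the version includes, and ``P(CS) = e^logit / (1 + e^logit)``.  The
versions nest by data availability: v1.0 uses the six obstetric covariates,
v1.1 adds a maternal-age indicator, v1.2 adds organ dysfunction/ICU admission,
and v1.3 adds six complication covariates (and drops the preterm indicator).

Coefficients are shipped verbatim at full printed precision and are never
re-estimated here (see :mod:`cmodel.refpop` for the fitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Union

from .errors import IncompleteRecordError, NoModelError
from .records import (
    FacilityDataset,
    Onset,
    PreeclampsiaLevel,
    Presentation,
    WomanRecord,
)

__all__ = [
    "ModelVersion",
    "CovariateVector",
    "MODEL_VERSIONS",
    "VERSION_ORDER",
    "COVARIATE_FIELDS",
    "DEFAULT_AGE_CUTOFF",
    "encode",
    "logit",
    "probability",
    "best_version",
    "predict_dataset",
    "PredictionResult",
    "Exclusion",
    "resolve_version",
]

#: Maternal age (completed years) at or above which the age indicator x7 is 1.
#: The published table gives only a 0/1 rule for age, so the cutoff is an
#: assumption of this implementation (advanced maternal age, ≥ 35 years);
#: every public entry point lets callers override it.
DEFAULT_AGE_CUTOFF = 35

#: Record field that each covariate index is derived from.
COVARIATE_FIELDS: Mapping[int, str] = MappingProxyType(
    {
        1: "parity",
        2: "previous_cs",
        3: "multiple_pregnancy",
        4: "onset_of_labour",
        5: "presentation",
        6: "gestational_age",
        7: "maternal_age",
        8: "organ_dysfunction_or_icu",
        9: "placenta_praevia",
        10: "abruptio_placentae",
        11: "chronic_hypertension",
        12: "preeclampsia_level",
        13: "renal_disease",
        14: "hiv",
    }
)


@dataclass(frozen=True)
class ModelVersion:
    """Intercept and per-covariate coefficients for one published version."""

    id: str
    intercept: float
    coefficients: Mapping[int, float]

    @property
    def covariates(self) -> tuple[int, ...]:
        return tuple(sorted(self.coefficients))

    @property
    def required_fields(self) -> frozenset[str]:
        return frozenset(COVARIATE_FIELDS[i] for i in self.coefficients)


def _mv(vid: str, intercept: float, coeffs: dict[int, float]) -> ModelVersion:
    return ModelVersion(id=vid, intercept=intercept, coefficients=MappingProxyType(coeffs))


VERSION_ORDER: tuple[str, ...] = ("v1.0", "v1.1", "v1.2", "v1.3")

MODEL_VERSIONS: Mapping[str, ModelVersion] = MappingProxyType(
    {
        "v1.0": _mv(
            "v1.0",
            -3.392134,
            {
                1: -0.559968,
                2: 2.842534,
                3: 1.694844,
                4: 2.747953,
                5: 2.922391,
                6: 0.368073,
            },
        ),
        "v1.1": _mv(
            "v1.1",
            -3.992549,
            {
                1: -0.760441,
                2: 2.873179,
                3: 1.722743,
                4: 2.708164,
                5: 2.911992,
                6: 0.364223,
                7: 0.734265,
            },
        ),
        "v1.2": _mv(
            "v1.2",
            -3.989357,
            {
                1: -0.76173,
                2: 2.87813,
                3: 1.721366,
                4: 2.686502,
                5: 2.9241,
                6: 0.285275,
                7: 0.728236,
                8: 1.499462,
            },
        ),
        "v1.3": _mv(
            "v1.3",
            -4.015252,
            {
                1: -0.77531,
                2: 2.922222,
                3: 1.834027,
                4: 2.634921,
                5: 2.985162,
                7: 0.71104,
                8: 0.661417,
                9: 3.796513,
                10: 2.741255,
                11: 0.561991,
                12: 0.98718,
                13: 1.301346,
                14: 1.310211,
            },
        ),
    }
)


def resolve_version(version: Union[str, ModelVersion]) -> ModelVersion:
    if isinstance(version, ModelVersion):
        return version
    try:
        return MODEL_VERSIONS[version]
    except KeyError:
        raise KeyError(
            f"unknown model version {version!r}; expected one of {', '.join(VERSION_ORDER)}"
        ) from None


@dataclass(frozen=True)
class CovariateVector:
    """Encoded x1…x14 for one woman, with a mask of missing indices.

    All covariates are 0/1 indicators except x5 (presentation: 0 cephalic,
    1 breech, 2 transverse/oblique or other) and x12 (0 none, 1 pre-eclampsia,
    2 eclampsia).
    """

    values: Mapping[int, int]
    missing: frozenset[int] = field(default_factory=frozenset)

    def __getitem__(self, index: int) -> int:
        return self.values[index]

    def is_complete_for(self, version: ModelVersion) -> bool:
        return not (set(version.coefficients) & self.missing)


def encode(record: WomanRecord, age_cutoff: int = DEFAULT_AGE_CUTOFF) -> CovariateVector:
    """Encode a record into the covariate vector x1…x14.

    x1 = 1 iff parity ≥ 1 (multiparous); x2 = 1 iff previous CS ≥ 1;
    x4 = 1 for provider-initiated childbirth (induced or prelabour CS);
    x5 maps cephalic/breech/transverse-or-other to 0/1/2; x6 = 1 iff
    gestational age ≤ 36 completed weeks; x7 = 1 iff maternal age ≥
    ``age_cutoff``; x12 maps none/pre-eclampsia/eclampsia to 0/1/2.
    Missing source fields set the index in the mask and the value to 0.
    """
    values: dict[int, int] = {}
    missing: set[int] = set()

    def put(index: int, value: Optional[int]) -> None:
        if value is None:
            missing.add(index)
            values[index] = 0
        else:
            values[index] = value

    put(1, None if record.parity is None else int(record.parity >= 1))
    put(2, None if record.previous_cs is None else int(record.previous_cs >= 1))
    put(3, None if record.multiple_pregnancy is None else int(record.multiple_pregnancy))
    put(
        4,
        None
        if record.onset_of_labour is None
        else int(record.onset_of_labour in (Onset.INDUCED, Onset.PRELABOUR_CS)),
    )
    if record.presentation is None:
        put(5, None)
    elif record.presentation is Presentation.CEPHALIC:
        put(5, 0)
    elif record.presentation is Presentation.BREECH:
        put(5, 1)
    else:  # transverse/oblique lie or other presentation
        put(5, 2)
    put(6, None if record.gestational_age is None else int(record.gestational_age <= 36))
    put(7, None if record.maternal_age is None else int(record.maternal_age >= age_cutoff))
    put(
        8,
        None
        if record.organ_dysfunction_or_icu is None
        else int(record.organ_dysfunction_or_icu),
    )
    put(9, None if record.placenta_praevia is None else int(record.placenta_praevia))
    put(10, None if record.abruptio_placentae is None else int(record.abruptio_placentae))
    put(11, None if record.chronic_hypertension is None else int(record.chronic_hypertension))
    if record.preeclampsia_level is None:
        put(12, None)
    else:
        put(
            12,
            {
                PreeclampsiaLevel.NONE: 0,
                PreeclampsiaLevel.PREECLAMPSIA: 1,
                PreeclampsiaLevel.ECLAMPSIA: 2,
            }[record.preeclampsia_level],
        )
    put(13, None if record.renal_disease is None else int(record.renal_disease))
    put(14, None if record.hiv is None else int(record.hiv))

    return CovariateVector(values=MappingProxyType(values), missing=frozenset(missing))


def logit(cov: CovariateVector, version: Union[str, ModelVersion]) -> float:
    """Linear score: intercept plus dot product over the version's covariates.

    Summation runs in ascending covariate index so results are bit-stable.
    """
    mv = resolve_version(version)
    required_missing = set(mv.coefficients) & cov.missing
    if required_missing:
        raise IncompleteRecordError(required_missing)
    total = mv.intercept
    for index in mv.covariates:
        total += cov.values[index] * mv.coefficients[index]
    return total


def probability(cov: CovariateVector, version: Union[str, ModelVersion]) -> float:
    """Probability of caesarean section: logistic transform of the logit."""
    value = logit(cov, version)
    if value >= 0:
        return 1.0 / (1.0 + math.exp(-value))
    expv = math.exp(value)
    return expv / (1.0 + expv)


def best_version(manifest: Iterable[str]) -> str:
    """Highest-numbered version whose covariates are all derivable.

    The version with the largest number of variables gives the best estimate;
    availability is judged from the dataset's column manifest.
    """
    available = set(manifest)
    base_missing = MODEL_VERSIONS["v1.0"].required_fields - available
    if base_missing:
        raise NoModelError(base_missing)
    for vid in reversed(VERSION_ORDER):
        if MODEL_VERSIONS[vid].required_fields <= available:
            return vid
    raise NoModelError(())  # unreachable: v1.0 checked above


@dataclass(frozen=True)
class Exclusion:
    record_id: str
    reason: str


@dataclass(frozen=True)
class PredictionResult:
    version: str
    records: list[WomanRecord]
    probabilities: list[float]
    exclusions: list[Exclusion]

    @property
    def n_total(self) -> int:
        return len(self.records) + len(self.exclusions)


def predict_dataset(
    ds: FacilityDataset,
    version: Union[str, ModelVersion],
    age_cutoff: int = DEFAULT_AGE_CUTOFF,
) -> PredictionResult:
    """Score every record complete under ``version``; log the rest.

    The record count is preserved: n = predicted + excluded.
    """
    mv = resolve_version(version)
    kept: list[WomanRecord] = []
    probs: list[float] = []
    exclusions: list[Exclusion] = []
    for rec in ds.records:
        cov = encode(rec, age_cutoff=age_cutoff)
        required_missing = sorted(set(mv.coefficients) & cov.missing)
        if required_missing:
            fields = ", ".join(COVARIATE_FIELDS[i] for i in required_missing)
            exclusions.append(Exclusion(rec.record_id, f"missing: {fields}"))
            continue
        kept.append(rec)
        probs.append(probability(cov, mv))
    if not kept:
        raise IncompleteRecordError(set(mv.coefficients))
    return PredictionResult(
        version=mv.id, records=kept, probabilities=probs, exclusions=exclusions
    )
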