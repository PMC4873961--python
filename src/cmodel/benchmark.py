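"""Observed-vs-expected CS rate comparison and the standardised CS ratio.

The expected rate is the mean model probability over the scored records; the
standardised caesarean section ratio (SCR) is observed/expected, and the
uncertainty range is a relative band (default ±20%) around the expected rate.
Records that cannot be scored are excluded from both the observed and the
expected side so the two populations always match.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Union

from . import core
from .errors import CModelError
from .records import DeliveryMode, FacilityDataset
from .robson import RobsonGroup, classify

__all__ = ["BenchmarkReport", "benchmark", "benchmark_by_group", "DEFAULT_RANGE"]

#: Relative half-width of the uncertainty range around the expected rate.
DEFAULT_RANGE = 0.20

#: Robson-group reports with fewer predictable records than this are flagged
#: low_n instead of being reported.
LOW_N_THRESHOLD = 20


@dataclass(frozen=True)
class BenchmarkReport:
    n_total: int
    n_predicted: int
    n_excluded: int
    version: str
    observed_rate: float      # percent
    expected_rate: float      # percent
    uncertainty_low: float    # percent
    uncertainty_high: float   # percent
    deviation: float          # percentage points, observed − expected
    scr: float                # standardised CS ratio, dimensionless
    flag: str                 # within_range | above_range | below_range

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_total": self.n_total,
            "n_predicted": self.n_predicted,
            "n_excluded": self.n_excluded,
            "version": self.version,
            "observed_rate": self.observed_rate,
            "expected_rate": self.expected_rate,
            "uncertainty_low": self.uncertainty_low,
            "uncertainty_high": self.uncertainty_high,
            "deviation": self.deviation,
            "scr": self.scr,
            "flag": self.flag,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _resolve(ds: FacilityDataset, version: Union[str, core.ModelVersion]) -> core.ModelVersion:
    if version == "auto":
        return core.MODEL_VERSIONS[core.best_version(ds.column_manifest)]
    return core.resolve_version(version)


def benchmark(
    ds: FacilityDataset,
    version: Union[str, core.ModelVersion] = "auto",
    age_cutoff: int = core.DEFAULT_AGE_CUTOFF,
    range_multiplier: float = DEFAULT_RANGE,
) -> BenchmarkReport:
    """Compare a dataset's observed CS rate with its model-expected rate.

    Observed and expected are computed over the identical record subset:
    records excluded from prediction (incomplete covariates or missing mode
    of delivery) are excluded from the observed rate too, and counted.
    """
    mv = _resolve(ds, version)
    prediction = core.predict_dataset(ds, mv, age_cutoff=age_cutoff)

    records, probs = [], []
    n_no_mode = 0
    for rec, p in zip(prediction.records, prediction.probabilities):
        if rec.mode_of_delivery is None:
            n_no_mode += 1
            continue
        records.append(rec)
        probs.append(p)
    if not records:
        raise CModelError("no records with a recorded mode of delivery to benchmark")

    n = len(records)
    observed_cs = sum(r.mode_of_delivery is DeliveryMode.CAESAREAN for r in records)
    observed = 100.0 * observed_cs / n
    expected = 100.0 * math.fsum(probs) / n
    if expected == 0.0:
        raise CModelError("expected rate is zero; standardised CS ratio undefined")
    low = (1.0 - range_multiplier) * expected
    high = (1.0 + range_multiplier) * expected
    if observed < low:
        flag = "below_range"
    elif observed > high:
        flag = "above_range"
    else:
        flag = "within_range"

    return BenchmarkReport(
        n_total=len(ds),
        n_predicted=n,
        n_excluded=len(ds) - n,
        version=mv.id,
        observed_rate=observed,
        expected_rate=expected,
        uncertainty_low=low,
        uncertainty_high=high,
        deviation=observed - expected,
        scr=observed / expected,
        flag=flag,
    )


@dataclass(frozen=True)
class GroupBenchmark:
    group: RobsonGroup
    n_predictable: int
    low_n: bool
    report: Optional[BenchmarkReport]


def benchmark_by_group(
    ds: FacilityDataset,
    version: Union[str, core.ModelVersion] = "auto",
    age_cutoff: int = core.DEFAULT_AGE_CUTOFF,
    range_multiplier: float = DEFAULT_RANGE,
    low_n_threshold: int = LOW_N_THRESHOLD,
) -> dict[RobsonGroup, GroupBenchmark]:
    """Benchmark within each Robson group; small groups are flagged, not rated."""
    mv = _resolve(ds, version)
    by_group: dict[RobsonGroup, list] = {}
    for rec in ds.records:
        group = classify(rec)
        if group is RobsonGroup.UNCLASSIFIABLE:
            continue
        by_group.setdefault(group, []).append(rec)

    out: dict[RobsonGroup, GroupBenchmark] = {}
    for group, recs in sorted(by_group.items()):
        sub = ds.subset(recs, note=f"robson_group_{int(group)}")
        n_predictable = sum(
            1
            for rec in recs
            if rec.mode_of_delivery is not None
            and core.encode(rec, age_cutoff=age_cutoff).is_complete_for(mv)
        )
        if n_predictable < low_n_threshold:
            out[group] = GroupBenchmark(group, n_predictable, low_n=True, report=None)
            continue
        report = benchmark(sub, mv, age_cutoff=age_cutoff, range_multiplier=range_multiplier)
        out[group] = GroupBenchmark(group, n_predictable, low_n=False, report=report)
    return out
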