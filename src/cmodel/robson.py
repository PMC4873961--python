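"""Robson ten-group classification and the group-wise CS-rate table.

The ten groups partition deliveries by plurality, lie/presentation, parity,
previous uterine scar, gestational age and onset of labour.  The decision
cascade runs in the fixed precedence 8 → 9 → 6/7 → 10 → 5 → 1–4, which makes
the groups mutually exclusive and exhaustive given complete inputs; a record
missing a field required at the decision node actually reached degrades to
``UNCLASSIFIABLE``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum

from .errors import EmptyTableError
from .records import DeliveryMode, FacilityDataset, Onset, Presentation, WomanRecord

__all__ = ["RobsonGroup", "RobsonRow", "RobsonTable", "classify", "robson_report"]


class RobsonGroup(IntEnum):
    UNCLASSIFIABLE = 0
    G1 = 1
    G2 = 2
    G3 = 3
    G4 = 4
    G5 = 5
    G6 = 6
    G7 = 7
    G8 = 8
    G9 = 9
    G10 = 10


def classify(record: WomanRecord) -> RobsonGroup:
    """Assign a delivery to its Robson group.

    Precedence: multiple pregnancy (8); transverse/oblique or other lie (9);
    breech by parity (6 nulliparous / 7 multiparous); single cephalic ≤ 36
    weeks (10); previous uterine scar at term (5); then parity × onset
    (1–4), where provider-initiated = induced or prelabour caesarean.
    "Multiparous" means parity ≥ 1 and "previous uterine scar" means
    previous caesarean count ≥ 1; week 36+6 counts as 36 completed weeks.
    """
    if record.multiple_pregnancy is None:
        return RobsonGroup.UNCLASSIFIABLE
    if record.multiple_pregnancy:
        return RobsonGroup.G8

    if record.presentation is None:
        return RobsonGroup.UNCLASSIFIABLE
    if record.presentation in (Presentation.TRANSVERSE_OBLIQUE, Presentation.OTHER):
        return RobsonGroup.G9
    if record.presentation is Presentation.BREECH:
        if record.parity is None:
            return RobsonGroup.UNCLASSIFIABLE
        return RobsonGroup.G6 if record.parity == 0 else RobsonGroup.G7

    # single cephalic from here on
    if record.gestational_age is None:
        return RobsonGroup.UNCLASSIFIABLE
    if record.gestational_age <= 36:
        return RobsonGroup.G10
    if record.previous_cs is None:
        return RobsonGroup.UNCLASSIFIABLE
    if record.previous_cs >= 1:
        return RobsonGroup.G5
    if record.parity is None or record.onset_of_labour is None:
        return RobsonGroup.UNCLASSIFIABLE
    provider_initiated = record.onset_of_labour in (Onset.INDUCED, Onset.PRELABOUR_CS)
    if record.parity == 0:
        return RobsonGroup.G2 if provider_initiated else RobsonGroup.G1
    return RobsonGroup.G4 if provider_initiated else RobsonGroup.G3


@dataclass(frozen=True)
class RobsonRow:
    group: RobsonGroup
    cs_count: int
    group_size: int
    cs_rate: float        # percent, full precision
    relative_size: float  # percent of all classified births
    contribution: float   # CS in group / all classified births, percent


@dataclass(frozen=True)
class RobsonTable:
    rows: dict[RobsonGroup, RobsonRow]
    total_classified: int
    total_cs: int
    overall_cs_rate: float
    unclassifiable_count: int
    excluded_no_mode: int

    def to_dict(self) -> dict:
        return {
            "groups": {
                str(int(g)): {
                    "cs_count": row.cs_count,
                    "group_size": row.group_size,
                    "cs_rate": round(row.cs_rate, 1),
                    "relative_size": round(row.relative_size, 1),
                    "contribution": round(row.contribution, 1),
                }
                for g, row in sorted(self.rows.items())
            },
            "overall": {
                "cs_count": self.total_cs,
                "group_size": self.total_classified,
                "cs_rate": round(self.overall_cs_rate, 1),
            },
            "unclassifiable_count": self.unclassifiable_count,
            "excluded_no_mode": self.excluded_no_mode,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def render_text(self) -> str:
        lines = [
            f"{'Group':>5}  {'CS/group':>14}  {'CS rate %':>9}  "
            f"{'Rel. size %':>11}  {'CS/all %':>8}"
        ]
        for g, row in sorted(self.rows.items()):
            lines.append(
                f"{int(g):>5}  {row.cs_count:>6}/{row.group_size:<7}  "
                f"{row.cs_rate:>9.1f}  {row.relative_size:>11.1f}  "
                f"{row.contribution:>8.1f}"
            )
        lines.append(
            f"{'All':>5}  {self.total_cs:>6}/{self.total_classified:<7}  "
            f"{self.overall_cs_rate:>9.1f}  {100.0:>11.1f}  "
            f"{self.overall_cs_rate:>8.1f}"
        )
        if self.unclassifiable_count:
            lines.append(f"Unclassifiable records: {self.unclassifiable_count}")
        if self.excluded_no_mode:
            lines.append(f"Excluded (missing mode of delivery): {self.excluded_no_mode}")
        return "\n".join(lines)


def robson_report(ds: FacilityDataset) -> RobsonTable:
    """Tabulate group sizes, CS counts and rates over the classified records.

    Records lacking ``mode_of_delivery`` are excluded from the table and
    counted; rates are stored at full precision and rounded only for display.
    """
    sizes: dict[RobsonGroup, int] = {RobsonGroup(i): 0 for i in range(1, 11)}
    cs: dict[RobsonGroup, int] = {RobsonGroup(i): 0 for i in range(1, 11)}
    unclassifiable = 0
    excluded_no_mode = 0
    for rec in ds.records:
        group = classify(rec)
        if group is RobsonGroup.UNCLASSIFIABLE:
            unclassifiable += 1
            continue
        if rec.mode_of_delivery is None:
            excluded_no_mode += 1
            continue
        sizes[group] += 1
        if rec.mode_of_delivery is DeliveryMode.CAESAREAN:
            cs[group] += 1

    total = sum(sizes.values())
    if total == 0:
        raise EmptyTableError("no classifiable records with a recorded mode of delivery")
    total_cs = sum(cs.values())

    rows = {
        g: RobsonRow(
            group=g,
            cs_count=cs[g],
            group_size=sizes[g],
            cs_rate=100.0 * cs[g] / sizes[g] if sizes[g] else 0.0,
            relative_size=100.0 * sizes[g] / total,
            contribution=100.0 * cs[g] / total,
        )
        for g in sizes
    }
    return RobsonTable(
        rows=rows,
        total_classified=total,
        total_cs=total_cs,
        overall_cs_rate=100.0 * total_cs / total,
        unclassifiable_count=unclassifiable,
        excluded_no_mode=excluded_no_mode,
    )
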