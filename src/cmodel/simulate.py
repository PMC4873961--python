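"""Synthetic multi-facility obstetric datasets with known truth.

Covariates are drawn independently per configured prevalence, except for two
consistency constraints: a previous caesarean is only drawn for multiparous
women, and a prelabour-caesarean onset is only assigned when the drawn mode
of delivery is caesarean.  The CS outcome is Bernoulli with probability given
by one of the shipped model versions (plus an optional per-facility normal
shift on the logit scale), so recovery and calibration tests have an exact
truth to target.  Default prevalences are tuned so the Robson group mix is
broadly realistic for a low-intervention multi-facility population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np

from . import core
from .errors import ConfigError
from .records import (
    DeliveryMode,
    FacilityDataset,
    Onset,
    PreeclampsiaLevel,
    Presentation,
    WomanRecord,
)

__all__ = ["SimulationConfig", "DEFAULT_PREVALENCES", "simulate", "make_fixture"]

DEFAULT_PREVALENCES: Mapping[str, float] = {
    "multiparous": 0.615,
    "previous_cs_given_multiparous": 0.135,
    "provider_initiated": 0.17,
    "breech": 0.027,
    "transverse_oblique": 0.004,
    "multiple_pregnancy": 0.009,
    "preterm": 0.045,
    "age_over_cutoff": 0.09,
    "organ_dysfunction": 0.005,
    "placenta_praevia": 0.005,
    "abruptio_placentae": 0.005,
    "chronic_hypertension": 0.015,
    "preeclampsia": 0.02,
    "eclampsia": 0.004,
    "renal_disease": 0.004,
    "hiv": 0.01,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_facilities: int = 5
    n_per_facility: Union[int, tuple[int, int]] = 1000
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    truth_version: str = "v1.0"
    truth_coefficients: Optional[core.ModelVersion] = None
    facility_effect_sd: float = 0.0
    age_cutoff: int = core.DEFAULT_AGE_CUTOFF
    intrapartum_mortality_per_1000: float = 3.0
    maternal_mortality_per_100k: float = 23.6
    near_miss_per_1000: float = 2.6
    seed: int = 0

    def validated(self) -> "SimulationConfig":
        if self.n_facilities < 1:
            raise ConfigError("n_facilities must be ≥ 1")
        unknown = set(self.covariate_prevalences) - set(DEFAULT_PREVALENCES)
        if unknown:
            raise ConfigError(f"unknown prevalence key(s): {', '.join(sorted(unknown))}")
        prev = {**DEFAULT_PREVALENCES, **self.covariate_prevalences}
        for key, value in prev.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"prevalence {key} = {value} outside [0, 1]")
        if prev["breech"] + prev["transverse_oblique"] > 1.0:
            raise ConfigError("breech + transverse_oblique prevalences exceed 1")
        if prev["preeclampsia"] + prev["eclampsia"] > 1.0:
            raise ConfigError("preeclampsia + eclampsia prevalences exceed 1")
        if self.truth_version not in core.MODEL_VERSIONS:
            raise ConfigError(f"unknown truth version {self.truth_version!r}")
        if self.facility_effect_sd < 0:
            raise ConfigError("facility_effect_sd must be ≥ 0")
        return replace(self, covariate_prevalences=prev)


def simulate(config: SimulationConfig) -> FacilityDataset:
    """Generate a multi-facility dataset, reproducible from the seed."""
    cfg = config.validated()
    prev = cfg.covariate_prevalences
    rng = np.random.default_rng(cfg.seed)
    mv = cfg.truth_coefficients or core.MODEL_VERSIONS[cfg.truth_version]

    records: list[WomanRecord] = []
    rid = 0
    for f in range(cfg.n_facilities):
        if isinstance(cfg.n_per_facility, int):
            n = cfg.n_per_facility
        else:
            lo, hi = cfg.n_per_facility
            n = int(rng.integers(lo, hi + 1))
        facility_effect = (
            float(rng.normal(0.0, cfg.facility_effect_sd)) if cfg.facility_effect_sd else 0.0
        )

        multip = rng.random(n) < prev["multiparous"]
        parity = np.where(multip, 1 + rng.poisson(1.0, n), 0)
        prevcs = (multip & (rng.random(n) < prev["previous_cs_given_multiparous"])).astype(int)
        u = rng.random(n)
        p_t, p_b = prev["transverse_oblique"], prev["breech"]
        transverse = u < p_t
        breech = (u >= p_t) & (u < p_t + p_b)
        # half of the non-cephalic lies are recorded as "other" to exercise
        # the synonym path; both encode identically
        other = transverse & (rng.random(n) < 0.5)
        multiple = rng.random(n) < prev["multiple_pregnancy"]
        preterm = rng.random(n) < prev["preterm"]
        ga = np.where(preterm, rng.integers(28, 37, n), rng.integers(37, 42, n))
        provider = rng.random(n) < prev["provider_initiated"]
        older = rng.random(n) < prev["age_over_cutoff"]
        age = np.where(
            older,
            cfg.age_cutoff + rng.integers(0, 10, n),
            rng.integers(18, cfg.age_cutoff, n),
        )
        organ = rng.random(n) < prev["organ_dysfunction"]
        praevia = rng.random(n) < prev["placenta_praevia"]
        abruptio = rng.random(n) < prev["abruptio_placentae"]
        chtn = rng.random(n) < prev["chronic_hypertension"]
        renal = rng.random(n) < prev["renal_disease"]
        hiv = rng.random(n) < prev["hiv"]
        upe = rng.random(n)
        eclampsia = upe < prev["eclampsia"]
        preeclampsia = (upe >= prev["eclampsia"]) & (
            upe < prev["eclampsia"] + prev["preeclampsia"]
        )

        x = {
            1: multip.astype(float),
            2: prevcs.astype(float),
            3: multiple.astype(float),
            4: provider.astype(float),
            5: np.where(transverse, 2.0, np.where(breech, 1.0, 0.0)),
            6: (ga <= 36).astype(float),
            7: older.astype(float),
            8: organ.astype(float),
            9: praevia.astype(float),
            10: abruptio.astype(float),
            11: chtn.astype(float),
            12: np.where(eclampsia, 2.0, np.where(preeclampsia, 1.0, 0.0)),
            13: renal.astype(float),
            14: hiv.astype(float),
        }
        eta = np.full(n, mv.intercept + facility_effect)
        for index in mv.covariates:
            eta += x[index] * mv.coefficients[index]
        p_cs = 1.0 / (1.0 + np.exp(-eta))
        caesarean = rng.random(n) < p_cs
        # provider-initiated caesareans are sometimes recorded as prelabour CS
        prelabour = provider & caesarean & (rng.random(n) < 0.3)

        ip_death = rng.random(n) < cfg.intrapartum_mortality_per_1000 / 1000.0
        stillbirth = ip_death & (rng.random(n) < 0.5)
        neonatal_death = ip_death & ~stillbirth
        mat_death = rng.random(n) < cfg.maternal_mortality_per_100k / 100_000.0
        near_miss = rng.random(n) < cfg.near_miss_per_1000 / 1000.0

        fid = f"F{f + 1:03d}"
        for i in range(n):
            if transverse[i]:
                pres = Presentation.OTHER if other[i] else Presentation.TRANSVERSE_OBLIQUE
            elif breech[i]:
                pres = Presentation.BREECH
            else:
                pres = Presentation.CEPHALIC
            if eclampsia[i]:
                pe = PreeclampsiaLevel.ECLAMPSIA
            elif preeclampsia[i]:
                pe = PreeclampsiaLevel.PREECLAMPSIA
            else:
                pe = PreeclampsiaLevel.NONE
            if prelabour[i]:
                onset = Onset.PRELABOUR_CS
            elif provider[i]:
                onset = Onset.INDUCED
            else:
                onset = Onset.SPONTANEOUS
            records.append(
                WomanRecord(
                    record_id=f"R{rid:07d}",
                    facility_id=fid,
                    country_id="SIM",
                    maternal_age=int(age[i]),
                    parity=int(parity[i]),
                    previous_cs=int(prevcs[i]),
                    onset_of_labour=onset,
                    gestational_age=int(ga[i]),
                    presentation=pres,
                    multiple_pregnancy=bool(multiple[i]),
                    organ_dysfunction_or_icu=bool(organ[i]),
                    placenta_praevia=bool(praevia[i]),
                    abruptio_placentae=bool(abruptio[i]),
                    chronic_hypertension=bool(chtn[i]),
                    renal_disease=bool(renal[i]),
                    hiv=bool(hiv[i]),
                    preeclampsia_level=pe,
                    mode_of_delivery=(
                        DeliveryMode.CAESAREAN if caesarean[i] else DeliveryMode.VAGINAL
                    ),
                    livebirth=not bool(stillbirth[i]),
                    intrapartum_stillbirth=bool(stillbirth[i]),
                    neonatal_death_day1=bool(neonatal_death[i]),
                    maternal_death=bool(mat_death[i]),
                    maternal_near_miss=bool(near_miss[i]),
                )
            )
            rid += 1

    return FacilityDataset(records=records, provenance=f"simulate(seed={cfg.seed})")


# ---------------------------------------------------------------------------
# Named fixtures

# Per-group (cs_count, group_size) for the reference-population table the
# reporting module must reproduce exactly.
REFERENCE_TABLE_COUNTS: Mapping[int, tuple[int, int]] = {
    1: (1182, 12069),
    2: (1446, 3620),
    3: (503, 16538),
    4: (624, 2631),
    5: (2194, 2948),
    6: (391, 498),
    7: (471, 638),
    8: (222, 385),
    9: (140, 158),
    10: (432, 1718),
}
_N_UNCLASSIFIABLE = 1434  # reference population minus classified births
_N_UNCLASSIFIABLE_CS = 24  # 7629 CS among all women vs 7605 among classified
_REFERENCE_OUTCOMES = {
    "non_livebirths": 276,       # 42,637 women − 42,361 livebirths
    "intrapartum_stillbirths": 64,
    "neonatal_deaths_day1": 63,  # stillbirths + day-1 deaths = 127
    "maternal_deaths": 10,
    "near_misses": 111,
}


def _group_template(group: int) -> dict:
    base = dict(
        maternal_age=27,
        parity=0,
        previous_cs=0,
        onset_of_labour=Onset.SPONTANEOUS,
        gestational_age=39,
        presentation=Presentation.CEPHALIC,
        multiple_pregnancy=False,
        organ_dysfunction_or_icu=False,
        placenta_praevia=False,
        abruptio_placentae=False,
        chronic_hypertension=False,
        renal_disease=False,
        hiv=False,
        preeclampsia_level=PreeclampsiaLevel.NONE,
    )
    if group == 2:
        base["onset_of_labour"] = Onset.INDUCED
    elif group == 3:
        base["parity"] = 2
    elif group == 4:
        base.update(parity=2, onset_of_labour=Onset.INDUCED)
    elif group == 5:
        base.update(parity=2, previous_cs=1)
    elif group == 6:
        base["presentation"] = Presentation.BREECH
    elif group == 7:
        base.update(parity=2, presentation=Presentation.BREECH)
    elif group == 8:
        base["multiple_pregnancy"] = True
    elif group == 9:
        base["presentation"] = Presentation.TRANSVERSE_OBLIQUE
    elif group == 10:
        base["gestational_age"] = 34
    return base


def _tiny_fixture() -> FacilityDataset:
    records = []
    for g in range(1, 11):
        records.append(
            WomanRecord(
                record_id=f"T{g:02d}",
                facility_id="F001",
                mode_of_delivery=DeliveryMode.CAESAREAN if g >= 5 else DeliveryMode.VAGINAL,
                livebirth=True,
                **_group_template(g),
            )
        )
    # two unclassifiable records: missing gestational age / missing plurality
    u1 = _group_template(1)
    u1["gestational_age"] = None
    records.append(
        WomanRecord(
            record_id="T11",
            facility_id="F001",
            mode_of_delivery=DeliveryMode.VAGINAL,
            livebirth=True,
            **u1,
        )
    )
    u2 = _group_template(1)
    u2["multiple_pregnancy"] = None
    records.append(
        WomanRecord(
            record_id="T12",
            facility_id="F001",
            mode_of_delivery=DeliveryMode.VAGINAL,
            livebirth=True,
            **u2,
        )
    )
    return FacilityDataset(records=records, provenance="fixture:tiny")


def _table_fixture() -> FacilityDataset:
    """Reconstruct the printed per-group margins of the reference table.

    One aggregated facility; outcome flags are spread over the records so the
    facility-level indicators reproduce the published outcome rates.
    """
    records: list[WomanRecord] = []
    rid = 0
    for group, (n_cs, n_group) in REFERENCE_TABLE_COUNTS.items():
        template = _group_template(group)
        for i in range(n_group):
            records.append(
                WomanRecord(
                    record_id=f"A{rid:06d}",
                    facility_id="F001",
                    mode_of_delivery=(
                        DeliveryMode.CAESAREAN if i < n_cs else DeliveryMode.VAGINAL
                    ),
                    **template,
                )
            )
            rid += 1
    unclass = _group_template(1)
    unclass["gestational_age"] = None
    for i in range(_N_UNCLASSIFIABLE):
        records.append(
            WomanRecord(
                record_id=f"A{rid:06d}",
                facility_id="F001",
                mode_of_delivery=(
                    DeliveryMode.CAESAREAN
                    if i < _N_UNCLASSIFIABLE_CS
                    else DeliveryMode.VAGINAL
                ),
                **unclass,
            )
        )
        rid += 1

    oc = _REFERENCE_OUTCOMES
    n_still = oc["intrapartum_stillbirths"]
    n_nonlive = oc["non_livebirths"]
    for i, rec in enumerate(records):
        rec.livebirth = i >= n_nonlive
        rec.intrapartum_stillbirth = i < n_still
        rec.neonatal_death_day1 = n_nonlive <= i < n_nonlive + oc["neonatal_deaths_day1"]
        rec.maternal_death = i < oc["maternal_deaths"]
        rec.maternal_near_miss = (
            oc["maternal_deaths"] <= i < oc["maternal_deaths"] + oc["near_misses"]
        )
    return FacilityDataset(records=records, provenance="fixture:reference_table")


def _heterogeneous_fixture() -> FacilityDataset:
    """20 facilities spanning low→high CS rates and perinatal mortality.

    Facility k (0-based) has a CS rate of (5 + 2k)% and k day-one neonatal
    deaths per 100 women, guaranteeing facilities strictly on both sides of
    both medians.
    """
    records: list[WomanRecord] = []
    rid = 0
    template = _group_template(1)
    for k in range(20):
        n_cs = 5 + 2 * k
        for i in range(100):
            records.append(
                WomanRecord(
                    record_id=f"H{rid:05d}",
                    facility_id=f"F{k + 1:03d}",
                    mode_of_delivery=(
                        DeliveryMode.CAESAREAN if i < n_cs else DeliveryMode.VAGINAL
                    ),
                    livebirth=True,
                    intrapartum_stillbirth=False,
                    neonatal_death_day1=i < k,
                    maternal_death=False,
                    maternal_near_miss=False,
                    **template,
                )
            )
            rid += 1
    return FacilityDataset(records=records, provenance="fixture:heterogeneous_facilities")


_FIXTURES = {
    "tiny": _tiny_fixture,
    "reference_table": _table_fixture,
    "heterogeneous_facilities": _heterogeneous_fixture,
}
_FIXTURE_ALIASES = {"table2_like": "reference_table"}


def make_fixture(name: str) -> FacilityDataset:
    """Build a named deterministic dataset: ``tiny``, ``reference_table`` or
    ``heterogeneous_facilities``."""
    name = _FIXTURE_ALIASES.get(name, name)
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of {', '.join(sorted(_FIXTURES))}"
        ) from None
    return builder()
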