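"""Reference-population construction and a from-scratch logistic fitter.

Facilities are summarised by CS rate and intrapartum-related perinatal
mortality (intrapartum stillbirths plus neonatal deaths on the first day,
per 1000 livebirths); the reference population is the set of facilities
strictly below the across-facility median on both indicators, and is split
90/10 into a building and an internal-validation subset.

The fitter is plain maximum-likelihood logistic regression via iteratively
reweighted least squares.  It deliberately has no random intercept: the
acceptance surface here is coefficient recovery against fixed published
values, not variance components.  A facility-level cluster bootstrap is
available for standard errors when clustering matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import core
from .errors import CModelError, RankError, SeparationError
from .records import DeliveryMode, FacilityDataset

__all__ = [
    "FacilityIndicators",
    "FittedModel",
    "facility_indicators",
    "select_reference",
    "SelectionResult",
    "split_reference",
    "fit_logistic",
    "design_matrix",
]


@dataclass(frozen=True)
class FacilityIndicators:
    facility_id: str
    n_women: int
    n_livebirths: int
    cs_rate: Optional[float]                        # percent
    intrapartum_perinatal_mortality: Optional[float]  # per 1000 livebirths
    maternal_mortality: Optional[float]             # per 100,000 livebirths
    near_miss_rate: Optional[float]                 # per 1000 livebirths
    severe_maternal_outcome_rate: Optional[float]   # per 1000 livebirths
    undefined: bool = False                         # zero livebirths

    def to_dict(self) -> dict:
        return {
            "facility_id": self.facility_id,
            "n_women": self.n_women,
            "n_livebirths": self.n_livebirths,
            "cs_rate": self.cs_rate,
            "intrapartum_perinatal_mortality": self.intrapartum_perinatal_mortality,
            "maternal_mortality": self.maternal_mortality,
            "near_miss_rate": self.near_miss_rate,
            "severe_maternal_outcome_rate": self.severe_maternal_outcome_rate,
            "undefined": self.undefined,
        }


def facility_indicators(ds: FacilityDataset) -> list[FacilityIndicators]:
    """Per-facility outcome indicators, ordered by facility id.

    CS rate is a percent of records with a recorded mode of delivery;
    intrapartum-related perinatal mortality counts intrapartum stillbirths
    plus neonatal deaths on day one per 1000 livebirths; maternal mortality
    is per 100,000 livebirths; near-miss and severe maternal outcome
    (near-miss plus maternal deaths) per 1000 livebirths.  A facility with
    zero livebirths has its livebirth-denominated rates undefined and is
    flagged.
    """
    groups: dict[str, list] = {}
    for rec in ds.records:
        groups.setdefault(rec.facility_id, []).append(rec)

    out: list[FacilityIndicators] = []
    for fid in sorted(groups):
        recs = groups[fid]
        n_women = len(recs)
        n_live = sum(r.livebirth is True for r in recs)
        n_mode = sum(r.mode_of_delivery is not None for r in recs)
        n_cs = sum(r.mode_of_delivery is DeliveryMode.CAESAREAN for r in recs)
        cs_rate = 100.0 * n_cs / n_mode if n_mode else None

        if n_live == 0:
            out.append(
                FacilityIndicators(
                    facility_id=fid,
                    n_women=n_women,
                    n_livebirths=0,
                    cs_rate=cs_rate,
                    intrapartum_perinatal_mortality=None,
                    maternal_mortality=None,
                    near_miss_rate=None,
                    severe_maternal_outcome_rate=None,
                    undefined=True,
                )
            )
            continue

        n_ip_deaths = sum(r.intrapartum_stillbirth is True for r in recs) + sum(
            r.neonatal_death_day1 is True for r in recs
        )
        n_mat_deaths = sum(r.maternal_death is True for r in recs)
        n_near_miss = sum(r.maternal_near_miss is True for r in recs)
        out.append(
            FacilityIndicators(
                facility_id=fid,
                n_women=n_women,
                n_livebirths=n_live,
                cs_rate=cs_rate,
                intrapartum_perinatal_mortality=1000.0 * n_ip_deaths / n_live,
                maternal_mortality=100_000.0 * n_mat_deaths / n_live,
                near_miss_rate=1000.0 * n_near_miss / n_live,
                severe_maternal_outcome_rate=1000.0 * (n_near_miss + n_mat_deaths) / n_live,
            )
        )
    return out


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    cs_rate_threshold: float
    mortality_threshold: float
    n_considered: int


def select_reference(indicators: Sequence[FacilityIndicators]) -> SelectionResult:
    """Facilities strictly below the median on both quality indicators.

    The median over an even number of facilities is the midpoint of the two
    central order statistics; "below" is strict, so with all facilities
    identical nothing is selected.  Facilities with undefined indicators are
    excluded from both the threshold computation and the selection.
    """
    usable = [
        ind
        for ind in indicators
        if not ind.undefined
        and ind.cs_rate is not None
        and ind.intrapartum_perinatal_mortality is not None
    ]
    if len(usable) < 2:
        raise CModelError("need at least two facilities with defined indicators")
    cs_threshold = float(np.median([ind.cs_rate for ind in usable]))
    mort_threshold = float(
        np.median([ind.intrapartum_perinatal_mortality for ind in usable])
    )
    selected = tuple(
        sorted(
            ind.facility_id
            for ind in usable
            if ind.cs_rate < cs_threshold
            and ind.intrapartum_perinatal_mortality < mort_threshold
        )
    )
    return SelectionResult(
        selected=selected,
        cs_rate_threshold=cs_threshold,
        mortality_threshold=mort_threshold,
        n_considered=len(usable),
    )


def split_reference(
    ds: FacilityDataset, fraction: float = 0.9, seed: int = 0
) -> tuple[FacilityDataset, FacilityDataset]:
    """Record-level simple random split into (building, validation) subsets.

    The first subset gets ⌈fraction·n⌉ records; the split is deterministic
    given the seed, disjoint, and covers every record exactly once.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(ds)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n1 = math.ceil(fraction * n)
    idx1 = np.sort(perm[:n1])
    idx2 = np.sort(perm[n1:])
    a1 = ds.subset([ds.records[i] for i in idx1], note=f"split_a1(seed={seed})")
    a2 = ds.subset([ds.records[i] for i in idx2], note=f"split_a2(seed={seed})")
    return a1, a2


@dataclass(frozen=True)
class FittedModel:
    coefficients: np.ndarray   # intercept first when add_intercept=True
    standard_errors: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    names: tuple[str, ...]
    cluster_se: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "coefficients": [float(b) for b in self.coefficients],
            "standard_errors": [float(s) for s in self.standard_errors],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n": self.n,
        }
        if self.cluster_se is not None:
            d["cluster_se"] = [float(s) for s in self.cluster_se]
        return d


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: Sequence[Sequence[float]],
    y: Sequence[int],
    *,
    add_intercept: bool = True,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    clusters: Optional[Sequence] = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FittedModel:
    """Maximum-likelihood logistic regression via IRLS.

    Converges when the maximum absolute score drops below ``score_tol`` or
    the relative log-likelihood change drops below ``ll_tol``; standard
    errors come from the inverse observed information.  Diverging
    coefficients (max |β| > 50) raise :class:`SeparationError`; a singular
    or constant design raises :class:`RankError`.  Non-convergence within
    ``max_iter`` is reported on the result, never silent.  With ``clusters``
    given, facility-level bootstrap standard errors are added.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        # allow (p, n) input only when unambiguous
        raise ValueError("X rows must match len(y)")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("y must be 0/1")

    n_obs, p_raw = X.shape
    if p_raw and np.any(np.ptp(X, axis=0) == 0.0):
        raise RankError("a covariate is constant across records")
    if add_intercept:
        X = np.column_stack([np.ones(n_obs), X])
    p = X.shape[1]
    if n_obs <= p:
        raise RankError(f"n = {n_obs} must exceed the {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise RankError("design matrix is rank deficient")

    if names is None:
        base = [f"x{i + 1}" for i in range(p_raw)]
        names = (["intercept"] + base) if add_intercept else base
    names = tuple(names)

    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankError("information matrix is singular") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0:
            raise SeparationError(
                "coefficient diverged (|beta| > 50); data are likely separable"
            )
        ll_new = _loglik(X, y, beta)
        if abs(ll_new - ll) < ll_tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    # quasi-separation can satisfy the likelihood tolerance while the
    # coefficients drift to implausible magnitudes; treat a perfectly
    # classifying fit with huge coefficients as separation too
    if np.max(np.abs(beta)) > 15.0 and np.all(np.abs(y - mu) < 1e-4):
        raise SeparationError(
            "data are perfectly separated; coefficients are unbounded"
        )
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankError("observed information is singular at the optimum") from exc
    se = np.sqrt(np.diag(cov))

    cluster_se = None
    if clusters is not None:
        cluster_se = _cluster_bootstrap_se(
            X, y, np.asarray(clusters), n_bootstrap=n_bootstrap, seed=seed
        )

    return FittedModel(
        coefficients=beta,
        standard_errors=se,
        loglik=_loglik(X, y, beta),
        converged=converged,
        n_iter=it,
        n=n_obs,
        names=names,
        cluster_se=cluster_se,
    )


def _cluster_bootstrap_se(
    X: np.ndarray, y: np.ndarray, clusters: np.ndarray, n_bootstrap: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    unique = np.unique(clusters)
    index_of = {c: np.flatnonzero(clusters == c) for c in unique}
    draws = []
    for _ in range(n_bootstrap):
        chosen = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([index_of[c] for c in chosen])
        try:
            fit = fit_logistic(X[idx, 1:] if X.shape[1] > 1 else X[idx, :0],
                               y[idx], add_intercept=True)
        except (RankError, SeparationError):
            continue
        draws.append(fit.coefficients)
    if len(draws) < 2:
        raise CModelError("cluster bootstrap produced fewer than two usable fits")
    return np.std(np.vstack(draws), axis=0, ddof=1)


def design_matrix(
    ds: FacilityDataset,
    version: Union[str, core.ModelVersion],
    age_cutoff: int = core.DEFAULT_AGE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], list[str]]:
    """Encoded covariate matrix and 0/1 CS outcome for refitting.

    Returns ``(X, y, column_names, excluded_record_ids)``; rows are records
    complete under the version with a recorded mode of delivery, columns
    follow ascending covariate index (no intercept column).
    """
    mv = core.resolve_version(version)
    idx = mv.covariates
    rows: list[list[int]] = []
    ys: list[int] = []
    excluded: list[str] = []
    for rec in ds.records:
        if rec.mode_of_delivery is None:
            excluded.append(rec.record_id)
            continue
        cov = core.encode(rec, age_cutoff=age_cutoff)
        if not cov.is_complete_for(mv):
            excluded.append(rec.record_id)
            continue
        rows.append([cov.values[i] for i in idx])
        ys.append(int(rec.mode_of_delivery is DeliveryMode.CAESAREAN))
    if not rows:
        raise CModelError("no usable records for the design matrix")
    return (
        np.asarray(rows, dtype=float),
        np.asarray(ys, dtype=float),
        tuple(f"x{i}" for i in idx),
        excluded,
    )
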