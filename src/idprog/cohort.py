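"""Cohort data model and derivation of likelihood-ready observations.

A :class:`CohortRecord` holds one subject's raw observational data: baseline
covariates, the intermittent visit history with measured GFR, renal
replacement therapy dates, death and administrative censoring.  The disease
stage of interest (default: CKD stage 5, GFR < 15 mL/min/1.73 m^2) is never
observed directly — only bracketed between the last visit above the
threshold and the first diagnosis (first visit below threshold, dialysis
start, or preemptive transplantation, whichever comes first).

:func:`derive_id_observation` turns a record into the likelihood-ready
:class:`IDObservation`: the illness interval (L, R], the death/censoring
time, and the covariate vector.  Death follow-up is censored at
nonpreemptive kidney transplantation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: covariate order used throughout the package
COVARIATES = ("sex", "age0", "log_pcr0", "mgfr0")

#: GFR threshold (mL/min/1.73 m^2) defining the disease stage of interest
DEFAULT_GFR_THRESHOLD = 15.0


class InconsistentRecordError(ValueError):
    """Raised when a record violates basic chronology (e.g. visit after death)."""


@dataclass
class CohortRecord:
    """One subject's visit history, event dates and baseline covariates.

    Times are in years since inclusion (t = 0).  ``visit_times`` excludes the
    inclusion measure itself: eligibility requires GFR above the threshold at
    t = 0, so inclusion always counts as a healthy observation.
    """

    subject_id: str
    visit_times: Sequence[float] = field(default_factory=list)
    visit_gfr: Sequence[float] = field(default_factory=list)
    dialysis_time: Optional[float] = None
    preemptive_transplant_time: Optional[float] = None
    nonpreemptive_transplant_time: Optional[float] = None
    death_time: Optional[float] = None
    admin_censor_time: float = np.inf
    sex: float = 0.0  # female = 1
    age0: float = np.nan  # years
    log_pcr0: float = np.nan  # log(mg/mmol)
    mgfr0: float = np.nan  # mL/min/1.73 m^2

    def __post_init__(self) -> None:
        self.visit_times = [float(t) for t in self.visit_times]
        self.visit_gfr = [float(g) for g in self.visit_gfr]
        if len(self.visit_times) != len(self.visit_gfr):
            raise ValueError(
                f"{self.subject_id}: visit_times and visit_gfr length mismatch"
            )

    @property
    def covariate_vector(self) -> np.ndarray:
        return np.array([self.sex, self.age0, self.log_pcr0, self.mgfr0])


@dataclass
class IDObservation:
    """Likelihood-ready observation for the illness-death model.

    ``L`` is the last time the subject was known healthy (in state 0); ``R``
    is the first time known ill (in state 1), ``None`` if illness was never
    observed.  ``death_obs_time`` is the exact death time when ``died`` is 1,
    otherwise the censoring time for death (nonpreemptive transplantation or
    end of vital-status follow-up).  ``illness_exact`` marks observations
    whose illness onset time is known exactly (only produced by simulation
    scenarios; visit data can never yield it).
    """

    subject_id: str
    L: float
    R: Optional[float]
    death_obs_time: float
    died: int
    death_censored_at_transplant: int
    followup_end: float
    z: np.ndarray
    diagnosed_by: Optional[str] = None  # 'gfr' | 'dialysis' | 'preemptive'
    illness_exact: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.L < 0:
            raise ValueError(f"{self.subject_id}: L must be >= 0")
        if self.R is not None:
            if self.illness_exact:
                if self.R < self.L:
                    raise ValueError(f"{self.subject_id}: R < L")
            elif not self.L < self.R:
                raise ValueError(f"{self.subject_id}: requires L < R, got "
                                 f"L={self.L}, R={self.R}")
            if self.death_obs_time < self.R - 1e-12:
                raise ValueError(f"{self.subject_id}: death_obs_time < R")
        if self.death_obs_time < self.L - 1e-12:
            raise ValueError(f"{self.subject_id}: death_obs_time < L")
        if self.died and self.death_censored_at_transplant:
            raise ValueError(
                f"{self.subject_id}: died and censored-at-transplant both set"
            )

    @property
    def observed_ill(self) -> bool:
        return self.R is not None


@dataclass
class SurvObservation:
    """Single-event observation for the standard survival models M1-M3."""

    subject_id: str
    time: float
    event: int
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not self.time > 0:
            raise ValueError(f"{self.subject_id}: follow-up time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.subject_id}: event must be 0/1")


def derive_id_observation(
    record: CohortRecord, threshold: float = DEFAULT_GFR_THRESHOLD
) -> IDObservation:
    """Derive the interval-censored illness-death observation from a record.

    Diagnosis time R is the earliest of the first visit with GFR below
    ``threshold``, dialysis initiation, and preemptive transplantation.
    L is the last visit time with GFR >= threshold before R; inclusion
    (t = 0) counts as a healthy observation, so L is always defined.
    Death follow-up is censored at nonpreemptive transplantation.  A death
    date equal to a diagnosing visit date is processed diagnosis-first.
    """
    sid = record.subject_id
    times = np.asarray(record.visit_times, dtype=float)
    gfr = np.asarray(record.visit_gfr, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise InconsistentRecordError(f"{sid}: visit_times not strictly increasing")
    if times.size and times[0] < 0:
        raise InconsistentRecordError(f"{sid}: negative visit time")

    death = record.death_time
    admin = record.admin_censor_time
    transplant = record.nonpreemptive_transplant_time
    if death is not None and death > admin + 1e-12:
        raise InconsistentRecordError(f"{sid}: death after administrative censoring")
    if death is not None and times.size and np.any(times > death + 1e-12):
        if np.any((times > death + 1e-12) & (gfr < threshold)):
            raise InconsistentRecordError(f"{sid}: sub-threshold visit after death")
        raise InconsistentRecordError(f"{sid}: visit after death")

    # death observation / censoring for death (transplant censors death)
    if death is not None and (transplant is None or death <= transplant):
        died, censored_tx, death_obs = 1, 0, float(death)
    elif transplant is not None and transplant <= admin:
        died, censored_tx, death_obs = 0, 1, float(transplant)
    else:
        died, censored_tx, death_obs = 0, 0, float(admin)
    followup_end = death_obs

    # diagnosis candidates, restricted to the follow-up window (a death-day
    # visit ties diagnosis-first, hence the tolerance)
    candidates = []
    below = (gfr < threshold) & (times <= followup_end + 1e-12)
    if np.any(below):
        candidates.append((float(times[below][0]), "gfr"))
    if record.dialysis_time is not None and record.dialysis_time <= followup_end + 1e-12:
        candidates.append((float(record.dialysis_time), "dialysis"))
    if (
        record.preemptive_transplant_time is not None
        and record.preemptive_transplant_time <= followup_end + 1e-12
    ):
        candidates.append((float(record.preemptive_transplant_time), "preemptive"))

    R: Optional[float] = None
    diagnosed_by: Optional[str] = None
    if candidates:
        R, diagnosed_by = min(candidates, key=lambda c: c[0])
        if R <= 0:
            raise InconsistentRecordError(
                f"{sid}: diagnosis at or before inclusion (baseline GFR must be "
                f">= {threshold})"
            )
        if diagnosed_by == "preemptive":
            # diagnosis by preemptive transplant also ends death follow-up
            if died and death_obs > R:
                died, death_obs = 0, R
            death_obs = min(death_obs, R)
            censored_tx = 1 if not died else censored_tx
            followup_end = death_obs

    healthy = times[
        (gfr >= threshold)
        & (times < (R if R is not None else np.inf))
        & (times <= followup_end + 1e-12)
    ]
    L = float(healthy[-1]) if healthy.size else 0.0

    return IDObservation(
        subject_id=sid,
        L=L,
        R=R,
        death_obs_time=death_obs,
        died=died,
        death_censored_at_transplant=censored_tx,
        followup_end=followup_end,
        z=record.covariate_vector,
        diagnosed_by=diagnosed_by,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SUBJECT_COLUMNS = {
    "subject_id", "sex", "age0", "log_pcr0", "mgfr0",
    "dialysis_time", "preemptive_transplant_time",
    "nonpreemptive_transplant_time", "death_time", "admin_censor_time",
}
_VISIT_COLUMNS = {"subject_id", "time", "gfr"}


def read_cohort(subjects_path, visits_path=None) -> list[CohortRecord]:
    """Read a cohort from a subject-level CSV plus an optional long visits CSV.

    The subject table has one row per subject with the baseline covariates and
    event times (empty cells for events that did not occur); the visit table
    is long format with columns ``subject_id, time, gfr``.  Rows with missing
    baseline covariates are dropped with a logged count, matching the
    complete-case analysis set.
    """
    subjects = pd.read_csv(subjects_path)
    unknown = set(subjects.columns) - _SUBJECT_COLUMNS
    if unknown:
        raise ValueError(f"unknown subject columns: {sorted(unknown)}")
    missing = _SUBJECT_COLUMNS - set(subjects.columns)
    if {"subject_id", "admin_censor_time"} & missing:
        raise ValueError(f"required subject columns absent: {sorted(missing)}")

    if len(subjects) == 0:
        logger.warning("empty cohort file %s", subjects_path)
        return []

    complete = subjects.dropna(subset=[c for c in COVARIATES if c in subjects])
    n_dropped = len(subjects) - len(complete)
    if n_dropped:
        logger.info("dropped %d subjects with missing baseline covariates", n_dropped)

    visits_by_id: dict[str, pd.DataFrame] = {}
    if visits_path is not None:
        visits = pd.read_csv(visits_path)
        unknown = set(visits.columns) - _VISIT_COLUMNS
        if unknown:
            raise ValueError(f"unknown visit columns: {sorted(unknown)}")
        visits["subject_id"] = visits["subject_id"].astype(str)
        visits_by_id = {k: v.sort_values("time") for k, v in visits.groupby("subject_id")}

    records = []
    for i, row in complete.iterrows():
        sid = str(row["subject_id"])
        v = visits_by_id.get(sid)
        try:
            records.append(
                CohortRecord(
                    subject_id=sid,
                    visit_times=[] if v is None else v["time"].tolist(),
                    visit_gfr=[] if v is None else v["gfr"].tolist(),
                    dialysis_time=_opt(row.get("dialysis_time")),
                    preemptive_transplant_time=_opt(row.get("preemptive_transplant_time")),
                    nonpreemptive_transplant_time=_opt(row.get("nonpreemptive_transplant_time")),
                    death_time=_opt(row.get("death_time")),
                    admin_censor_time=float(row["admin_censor_time"]),
                    sex=float(row["sex"]),
                    age0=float(row["age0"]),
                    log_pcr0=float(row["log_pcr0"]),
                    mgfr0=float(row["mgfr0"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable subject row {i} ({sid}): {exc}") from exc
    return records


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def derived_to_frame(observations: Iterable[IDObservation]) -> pd.DataFrame:
    """Canonical derived-observation table (one row per subject)."""
    rows = []
    for o in observations:
        rows.append({
            "subject_id": o.subject_id,
            "L": o.L,
            "R": o.R if o.R is not None else np.nan,
            "death_obs_time": o.death_obs_time,
            "died": o.died,
            "death_censored_at_transplant": o.death_censored_at_transplant,
            "followup_end": o.followup_end,
            "diagnosed_by": o.diagnosed_by or "",
            "illness_exact": int(o.illness_exact),
            **dict(zip(COVARIATES, o.z)),
        })
    return pd.DataFrame(rows)


def write_derived(observations: Iterable[IDObservation], path) -> None:
    derived_to_frame(observations).to_csv(path, index=False, float_format="%.10g")


def read_derived(path) -> list[IDObservation]:
    """Read the pre-derived interval schema written by :func:`write_derived`."""
    df = pd.read_csv(path)
    obs = []
    for _, row in df.iterrows():
        obs.append(
            IDObservation(
                subject_id=str(row["subject_id"]),
                L=float(row["L"]),
                R=None if pd.isna(row["R"]) else float(row["R"]),
                death_obs_time=float(row["death_obs_time"]),
                died=int(row["died"]),
                death_censored_at_transplant=int(row["death_censored_at_transplant"]),
                followup_end=float(row["followup_end"]),
                z=np.array([row[c] for c in COVARIATES], dtype=float),
                diagnosed_by=(None if pd.isna(row.get("diagnosed_by"))
                              else str(row["diagnosed_by"]) or None),
                illness_exact=bool(int(row.get("illness_exact", 0))),
            )
        )
    return obs


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n: int
    n_diagnosed: int
    n_died_without_diagnosis: int
    n_died_after_diagnosis: int
    n_alive_never_diagnosed: int
    undiagnosed_death_gaps: list[float]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary_frame(self) -> pd.DataFrame:
        gaps = np.asarray(self.undiagnosed_death_gaps)
        rows = [
            ("n", self.n, ""),
            ("CKD stage diagnosis", self.n_diagnosed,
             f"{100 * self.n_diagnosed / max(self.n, 1):.1f}%"),
            ("death without diagnosis", self.n_died_without_diagnosis,
             f"{100 * self.n_died_without_diagnosis / max(self.n, 1):.1f}%"),
            ("death after diagnosis", self.n_died_after_diagnosis,
             f"{100 * self.n_died_after_diagnosis / max(self.n, 1):.1f}%"),
            ("gap last-healthy-visit to death (mean y)",
             float(gaps.mean()) if gaps.size else np.nan, ""),
        ]
        return pd.DataFrame(rows, columns=["characteristic", "value", "pct"])


def validate_cohort(
    records: Iterable[CohortRecord], threshold: float = DEFAULT_GFR_THRESHOLD
) -> ValidationReport:
    """Report-only validation: invariant violations plus descriptive counts."""
    violations: list[str] = []
    n = n_diag = n_death_nodiag = n_death_diag = 0
    gaps: list[float] = []
    for rec in records:
        n += 1
        times = np.asarray(rec.visit_times)
        if times.size and np.any(np.diff(times) <= 0):
            violations.append(f"{rec.subject_id}: visit_times not strictly increasing")
            continue
        if times.size and times[0] < 0:
            violations.append(f"{rec.subject_id}: negative visit time")
            continue
        if not np.isfinite(rec.mgfr0) or rec.mgfr0 < threshold:
            violations.append(f"{rec.subject_id}: baseline mGFR below threshold")
            continue
        if any(not np.isfinite(v) for v in (rec.sex, rec.age0, rec.log_pcr0)):
            violations.append(f"{rec.subject_id}: missing baseline covariate")
            continue
        try:
            obs = derive_id_observation(rec, threshold)
        except (InconsistentRecordError, ValueError) as exc:
            violations.append(str(exc))
            continue
        if obs.observed_ill:
            n_diag += 1
            n_death_diag += obs.died
        elif obs.died:
            n_death_nodiag += 1
            gaps.append(obs.death_obs_time - obs.L)
    return ValidationReport(
        n=n,
        n_diagnosed=n_diag,
        n_died_without_diagnosis=n_death_nodiag,
        n_died_after_diagnosis=n_death_diag,
        n_alive_never_diagnosed=n - n_diag - n_death_nodiag - len(violations),
        undiagnosed_death_gaps=gaps,
        violations=violations,
    )
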