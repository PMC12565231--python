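"""Cohort records and standard life tables.

The unit of observation is one adult parasitoid female followed from
emergence (age 0, in days) to death, together with her host-exposure
events (hosts offered, adult daughters and sons that later emerged).
A cohort is the set of females sharing a rearing line and trial
environment; from it we build the classic discrete life-table columns

    lx  proportion of the cohort alive at the start of age x
    px  probability of surviving through [x, x+1)
    qx  probability of dying in [x, x+1)
    dx  fraction of the original cohort dying in [x, x+1)
    Tx  cumulative survivorship from age x onward (female-days)
    ex  remaining life expectancy at age x, Tx / lx
    mx  daughters produced per living female per day at age x

Ages are integer days with closed-open intervals [x, x+1); a female with
age_at_death = d is alive at the start of ages 0 .. d-1 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExposureEvent",
    "IndividualRecord",
    "CohortSchedule",
    "LifeTable",
    "CohortError",
    "ALL_FEMALE",
    "build_cohort_schedule",
    "compute_life_table",
    "life_table_from_lx_mx",
    "median_survival_age",
    "offspring_sex_ratio",
]


class CohortError(ValueError):
    """Invalid cohort data (empty cohort, mixed labels, bad ages ...)."""


#: Sentinel returned by :func:`offspring_sex_ratio` when no sons emerged,
#: so the daughters-per-son ratio is not a number.
ALL_FEMALE = "all-female"


@dataclass(frozen=True)
class ExposureEvent:
    """One host-exposure of a female: hosts offered and adult offspring reared.

    Offspring are attributed to the maternal age on the exposure day,
    even though they are counted at their own adult emergence.
    """

    maternal_age: int
    hosts_exposed: int
    daughters: int
    sons: int

    def __post_init__(self) -> None:
        if min(self.maternal_age, self.hosts_exposed, self.daughters, self.sons) < 0:
            raise CohortError("exposure counts and ages must be non-negative")
        if self.daughters + self.sons > self.hosts_exposed:
            raise CohortError(
                f"offspring ({self.daughters + self.sons}) exceed hosts exposed "
                f"({self.hosts_exposed}) at maternal age {self.maternal_age}"
            )


@dataclass(frozen=True)
class IndividualRecord:
    """One female's lifespan and reproduction — the unit of resampling."""

    female_id: str
    cohort_id: str
    age_at_death: int
    exposures: tuple[ExposureEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.age_at_death < 1:
            raise CohortError(
                f"female {self.female_id}: age_at_death must be >= 1 day"
            )
        ages = [e.maternal_age for e in self.exposures]
        if any(a >= self.age_at_death for a in ages):
            raise CohortError(
                f"female {self.female_id}: exposure at or past age_at_death"
            )
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CohortError(
                f"female {self.female_id}: exposure ages must be strictly increasing"
            )

    @property
    def daughters(self) -> int:
        return sum(e.daughters for e in self.exposures)

    @property
    def sons(self) -> int:
        return sum(e.sons for e in self.exposures)


@dataclass
class CohortSchedule:
    """Per-age tallies for one cohort: survivors and offspring by maternal age.

    Ages run 0 .. xmax-1 where xmax is the largest age at death, so the
    last row still has at least one survivor; at age xmax the cohort is
    extinct (implied, not stored).
    """

    cohort_id: str
    ages: np.ndarray
    n_alive: np.ndarray
    daughters_at_age: np.ndarray
    sons_at_age: np.ndarray

    @property
    def n0(self) -> int:
        return int(self.n_alive[0])

    def validate(self) -> None:
        if self.n_alive[0] <= 0:
            raise CohortError("empty cohort schedule")
        if np.any(np.diff(self.n_alive) > 0):
            raise CohortError("n_alive must be non-increasing")
        dead = self.n_alive == 0
        if np.any(self.daughters_at_age[dead] > 0) or np.any(self.sons_at_age[dead] > 0):
            raise CohortError("offspring recorded at ages with no survivors")


@dataclass
class LifeTable:
    """Standard discrete life table for one cohort (see module docstring).

    ``extinct`` records whether the cohort was followed to the death of
    its last member (true for these trials — no censoring), which makes
    survivorship implicitly 0 one age past the table's last row.
    """

    ages: np.ndarray
    lx: np.ndarray
    px: np.ndarray
    qx: np.ndarray
    dx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    mx: np.ndarray
    cohort_id: str = ""
    extinct: bool = True

    def to_frame(self, precision: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.ages,
                "lx": self.lx,
                "px": self.px,
                "qx": self.qx,
                "dx": self.dx,
                "Tx": self.Tx,
                "ex": self.ex,
                "mx": self.mx,
            }
        )
        if precision is not None:
            cols = df.columns.drop("x")
            df[cols] = df[cols].round(precision)
        return df

    def validate(self, atol: float = 1e-9) -> None:
        """Check the defining identities; raises CohortError on violation."""
        lx, px, qx, dx, Tx, ex = self.lx, self.px, self.qx, self.dx, self.Tx, self.ex
        if abs(lx[0] - 1.0) > atol:
            raise CohortError("lx[0] must be 1")
        if np.any(np.diff(lx) > atol):
            raise CohortError("lx must be non-increasing")
        alive = lx > 0
        if np.max(np.abs(px[alive] + qx[alive] - 1.0)) > atol:
            raise CohortError("px + qx must equal 1 where lx > 0")
        lx_next = np.append(lx[1:], 0.0 if self.extinct else lx[-1])
        if np.max(np.abs(dx - (lx - lx_next))) > atol:
            raise CohortError("dx must equal lx[x] - lx[x+1]")
        if np.max(np.abs(Tx - np.cumsum(lx[::-1])[::-1])) > atol:
            raise CohortError("Tx must be the tail-cumulative sum of lx")
        if np.max(np.abs(ex[alive] * lx[alive] - Tx[alive])) > atol:
            raise CohortError("ex must equal Tx/lx")
        if np.any(self.mx < 0):
            raise CohortError("mx must be non-negative")


def build_cohort_schedule(records: Sequence[IndividualRecord]) -> CohortSchedule:
    """Tally a cohort of individual records into per-age counts.

    n_alive[x] counts females with age_at_death > x; daughters_at_age[x]
    sums daughters over exposures performed at maternal age x.
    """
    records = list(records)
    if not records:
        raise CohortError("empty cohort")
    cohort_ids = {rec.cohort_id for rec in records}
    if len(cohort_ids) > 1:
        raise CohortError(f"mixed cohort_ids in one cohort: {sorted(cohort_ids)}")
    deaths = np.array([rec.age_at_death for rec in records], dtype=np.int64)
    xmax = int(deaths.max())
    ages = np.arange(xmax, dtype=np.int64)
    n_alive = (deaths[:, None] > ages).sum(axis=0)
    daughters = np.zeros(xmax, dtype=np.int64)
    sons = np.zeros(xmax, dtype=np.int64)
    for rec in records:
        for e in rec.exposures:
            daughters[e.maternal_age] += e.daughters
            sons[e.maternal_age] += e.sons
    sched = CohortSchedule(
        cohort_id=cohort_ids.pop(),
        ages=ages,
        n_alive=n_alive.astype(np.int64),
        daughters_at_age=daughters,
        sons_at_age=sons,
    )
    sched.validate()
    return sched


def compute_life_table(schedule: CohortSchedule) -> LifeTable:
    """Derive the life-table columns from a cohort schedule."""
    if schedule.n_alive[0] <= 0:
        raise CohortError("empty cohort")
    n0 = float(schedule.n_alive[0])
    lx = schedule.n_alive / n0
    lx_next = np.append(lx[1:], 0.0)
    dx = lx - lx_next
    with np.errstate(divide="ignore", invalid="ignore"):
        px = np.where(lx > 0, lx_next / np.where(lx > 0, lx, 1.0), 0.0)
    qx = 1.0 - px
    Tx = np.cumsum(lx[::-1])[::-1]
    ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    mx = np.where(
        schedule.n_alive > 0,
        schedule.daughters_at_age / np.maximum(schedule.n_alive, 1),
        0.0,
    )
    return LifeTable(
        ages=schedule.ages.copy(),
        lx=lx,
        px=px,
        qx=qx,
        dx=dx,
        Tx=Tx,
        ex=ex,
        mx=mx,
        cohort_id=schedule.cohort_id,
        extinct=True,
    )


def life_table_from_lx_mx(
    lx: Iterable[float],
    mx: Iterable[float],
    cohort_id: str = "",
    extinct: bool = True,
) -> LifeTable:
    """Build a LifeTable from survivorship and fecundity schedules alone.

    Convenience for analytic schedules (e.g. the closed-form truth of a
    synthetic cohort) where per-female counts do not exist; the remaining
    columns follow from lx under the same conventions as
    :func:`compute_life_table`.
    """
    lx = np.asarray(list(lx), dtype=float)
    mx = np.asarray(list(mx), dtype=float)
    if lx.shape != mx.shape:
        raise CohortError("lx and mx must have the same length")
    if lx[0] <= 0:
        raise CohortError("lx[0] must be positive")
    lx = lx / lx[0]
    lx_next = np.append(lx[1:], 0.0 if extinct else lx[-1])
    dx = lx - lx_next
    with np.errstate(divide="ignore", invalid="ignore"):
        px = np.where(lx > 0, lx_next / np.where(lx > 0, lx, 1.0), 0.0)
    qx = 1.0 - px
    Tx = np.cumsum(lx[::-1])[::-1]
    ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(
        ages=np.arange(lx.size, dtype=np.int64),
        lx=lx,
        px=px,
        qx=qx,
        dx=dx,
        Tx=Tx,
        ex=ex,
        mx=np.maximum(mx, 0.0),
        cohort_id=cohort_id,
        extinct=extinct,
    )


def median_survival_age(lt: LifeTable) -> int | None:
    """Age at which survivorship first falls to 50% (l50), in whole days.

    Returns the smallest age x with lx[x] <= 0.5. For an extinct cohort
    whose tabulated lx never reaches 0.5 the answer is the age just past
    the last row (where lx is implicitly 0). For a censored (non-extinct)
    table that stays above 0.5 the median is not reached and None is
    returned.
    """
    below = np.flatnonzero(lt.lx <= 0.5)
    if below.size:
        return int(lt.ages[below[0]])
    if lt.extinct:
        return int(lt.ages[-1] + 1)
    return None


def offspring_sex_ratio(records: Iterable[IndividualRecord]) -> float | str:
    """Lifetime daughters-per-son ratio pooled over a set of females.

    Returns :data:`ALL_FEMALE` when daughters emerged but no sons did;
    raises CohortError when there are no offspring at all.
    """
    daughters = sons = 0
    for rec in records:
        daughters += rec.daughters
        sons += rec.sons
    if daughters + sons == 0:
        raise CohortError("no offspring")
    if sons == 0:
        return ALL_FEMALE
    return daughters / sons
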