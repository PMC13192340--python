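"""Synthetic life tables and cohorts with known ground truth.

Life tables come from a Gompertz-Makeham hazard h(a) = A + B*exp(c*a) whose
cumulative hazard has a closed form, so every nqx is exact.  Cohorts are
simulated against a PopMort table with piecewise-constant annual hazards
(one rate per year of age per calendar year), which mirrors the PopMort
semantics exactly -- a zero-excess-hazard cohort therefore has relative
survival 1 up to Monte Carlo error.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from popmortgen.life_table import AbridgedLifeTable, AgeGroupRow
from popmortgen.popmort_engine import PopMortTable
from popmortgen.relative_survival import CohortRecord

__all__ = [
    "SyntheticParams",
    "make_life_table",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass
class SyntheticParams:
    """Parameters for synthetic life tables and cohort simulation."""

    makeham_a: float = 0.0005
    gompertz_b: float = 3e-5
    gompertz_c: float = 0.09
    seed: int = 0
    cohort_n: int = 1000
    excess_hazard: float = 0.0
    entry_year_range: tuple[int, int] = (2010, 2015)
    entry_age_range: tuple[int, int] = (40, 75)
    follow_up_years: int = 5

    def __post_init__(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b < 0:
            raise ValueError("hazard components must be >= 0")
        if self.gompertz_c <= 0:
            raise ValueError("gompertz_c must be > 0")
        if self.excess_hazard < 0:
            raise ValueError("excess_hazard must be >= 0")
        if self.cohort_n < 1:
            raise ValueError("cohort_n must be >= 1")
        if self.follow_up_years < 1:
            raise ValueError("follow_up_years must be >= 1")

    def hazard(self, age: float) -> float:
        return self.makeham_a + self.gompertz_b * math.exp(self.gompertz_c * age)

    def cumulative_hazard(self, a0: float, a1: float) -> float:
        """Integral of the hazard over [a0, a1], closed form."""
        a, b, c = self.makeham_a, self.gompertz_b, self.gompertz_c
        return a * (a1 - a0) + (b / c) * (math.exp(c * a1) - math.exp(c * a0))


DEFAULT_GROUPS: tuple[tuple[int, int], ...] = ((0, 5),) + tuple(
    (s, 5) for s in range(5, 95, 5)
)


def make_life_table(
    params: SyntheticParams,
    period: tuple[int, int],
    sex: int,
    groups: Sequence[tuple[int, int]] = DEFAULT_GROUPS,
    label: str = "synthetic",
    sex_scale: float | None = None,
) -> AbridgedLifeTable:
    """Build an abridged life table from the Gompertz-Makeham hazard.

    nqx for group [x, x+n) is 1 - exp(-H(x, x+n)) with the cumulative
    hazard H in closed form.  Deterministic; the seed is not used.
    ``sex_scale`` multiplies the hazard (default: 1.0 for males, 0.85 for
    females, so the two sexes differ).
    """
    if sex_scale is None:
        sex_scale = 1.0 if sex == 1 else 0.85
    rows = []
    for age_start, width in groups:
        h = sex_scale * params.cumulative_hazard(age_start, age_start + width)
        nqx = 1.0 - math.exp(-h)
        if nqx >= 1.0:
            raise ValueError(
                f"hazard parameters give nqx >= 1 in closed group "
                f"[{age_start}, {age_start + width})"
            )
        rows.append(AgeGroupRow(age_start=age_start, width_n=width, nqx=nqx))
    return AbridgedLifeTable(
        label=label,
        period_start=period[0],
        period_end=period[1],
        sex=sex,
        rows=tuple(rows),
    )


def simulate_cohort(
    popmort: PopMortTable,
    params: SyntheticParams,
) -> list[CohortRecord]:
    """Simulate a patient cohort against a PopMort table.

    Entry year, age and sex are uniform over the configured ranges.  Death
    times come from the piecewise-constant total hazard
    rate(year + t, age + t) + excess_hazard, with year and age advancing at
    whole years; follow-up is censored at ``follow_up_years``.  Reproducible
    for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.cohort_n
    y0, y1 = params.entry_year_range
    a0, a1 = params.entry_age_range

    min_year, max_age, rates, _ = popmort.lookup_arrays()
    n_years = rates.shape[0]
    max_year = min_year + n_years - 1

    entry_year = rng.integers(y0, y1 + 1, size=n)
    entry_age = rng.integers(a0, a1 + 1, size=n)
    sex = rng.integers(1, 3, size=n)

    horizon = params.follow_up_years
    if entry_year.max() + horizon - 1 > max_year:
        raise ValueError(
            f"popmort coverage ends at {max_year} but simulation reaches "
            f"{entry_year.max() + horizon - 1}; extend the popmort years"
        )

    time = np.full(n, float(horizon))
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)

    for step in range(horizon):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        year_i = entry_year[idx] + step - min_year
        age_i = np.minimum(entry_age[idx] + step, max_age)
        hazard = rates[year_i, sex[idx] - 1, age_i] + params.excess_hazard
        # exponential waiting time within this one-year step
        u = rng.random(idx.size)
        with np.errstate(divide="ignore"):
            wait = np.where(hazard > 0, -np.log(u) / np.where(hazard > 0, hazard, 1.0), np.inf)
        died = wait < 1.0
        died_idx = idx[died]
        time[died_idx] = step + wait[died]
        event[died_idx] = 1
        alive[died_idx] = False

    return [
        CohortRecord(
            id=i,
            sex=int(sex[i]),
            entry_year=int(entry_year[i]),
            entry_age=int(entry_age[i]),
            time_years=float(time[i]),
            event=int(event[i]),
        )
        for i in range(n)
    ]


COHORT_HEADER = ["id", "sex", "entry_year", "entry_age", "time_years", "event"]


def write_cohort(cohort: Sequence[CohortRecord], destination: str | Path | IO[str]) -> int:
    """Write a cohort as delimiter-separated text; returns the record count."""

    def _write(stream: IO[str]) -> int:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(COHORT_HEADER)
        for rec in cohort:
            writer.writerow(
                [rec.id, rec.sex, rec.entry_year, rec.entry_age, repr(rec.time_years), rec.event]
            )
        return len(cohort)

    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="") as fh:
            return _write(fh)
    return _write(destination)


def read_cohort(source: str | Path | IO[str]) -> list[CohortRecord]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError("cohort file is empty")
    reader = csv.DictReader(lines)
    records = []
    for row in reader:
        records.append(
            CohortRecord(
                id=row["id"],
                sex=int(row["sex"]),
                entry_year=int(row["entry_year"]),
                entry_age=int(row["entry_age"]),
                time_years=float(row["time_years"]),
                event=int(row["event"]),
            )
        )
    return records
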