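"""Core PopMort computation.

Inverts age-group death probabilities (nqx) to central mortality rates via
separation factors, converts rates to annual survival probabilities with
prob = exp(-rate), expands groups to single years of age 0-100, maps each
life-table period to its central calendar year, and assembles the long
(year, sex, age, rate, prob) table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from popmortgen.life_table import (
    AbridgedLifeTable,
    LifeTableError,
    merge_infant_rows,
    separation_factor,
)

__all__ = [
    "SingleAgeRecord",
    "PopMortTable",
    "nqx_to_rate",
    "rate_to_nqx",
    "rate_to_prob",
    "expand_to_single_ages",
    "period_to_midyear",
    "assign_years",
    "build_popmort",
]

DEFAULT_MAX_AGE = 100


def nqx_to_rate(nqx: float, width_n: float, f: float) -> float:
    """Central death rate nMx from the death probability nqx.

    rate = nqx / (n - f * nqx), the algebraic inverse of :func:`rate_to_nqx`.
    """
    if not 0.0 <= nqx < 1.0:
        raise ValueError(f"nqx must lie in [0, 1), got {nqx}")
    if width_n < 1:
        raise ValueError(f"width_n must be >= 1, got {width_n}")
    if f <= 0:
        raise ValueError(f"separation factor must be > 0, got {f}")
    denom = width_n - f * nqx
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator {denom} for nqx={nqx}, n={width_n}, f={f}"
        )
    return nqx / denom


def rate_to_nqx(rate: float, width_n: float, f: float) -> float:
    """Death probability nqx from the central rate: n*M / (1 + f*M)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return (width_n * rate) / (1.0 + f * rate)


def rate_to_prob(rate: float) -> float:
    """Annual survival probability exp(-rate)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return math.exp(-rate)


@dataclass(frozen=True)
class SingleAgeRecord:
    """Mortality rate and annual survival probability at one year of age."""

    age: int
    rate: float
    prob: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if not math.isclose(self.prob, math.exp(-self.rate), rel_tol=1e-12):
            raise ValueError(
                f"prob {self.prob} inconsistent with exp(-rate) = "
                f"{math.exp(-self.rate)} at age {self.age}"
            )


def expand_to_single_ages(
    lt: AbridgedLifeTable,
    max_age: int = DEFAULT_MAX_AGE,
    sep_overrides: Mapping[tuple[int, int], float] | None = None,
) -> list[SingleAgeRecord]:
    """Expand an abridged table to one record per single year of age.

    Every age within a closed group carries that group's rate and prob
    (piecewise-constant smoothing).  Ages past the last closed group --
    including any open terminal row, whose nqx of 1 cannot be inverted --
    reuse the last closed group's values up to ``max_age`` inclusive.
    """
    lt = merge_infant_rows(lt)
    closed = lt.closed_rows
    if not closed:
        raise LifeTableError("life table has no closed age groups")
    if max_age + 1 < lt.last_closed_end:
        raise LifeTableError(
            f"max_age {max_age} is below the last closed group "
            f"(ends at {lt.last_closed_end - 1})"
        )
    records: list[SingleAgeRecord] = []
    for row in closed:
        f = separation_factor(row.age_start, row.width_n, sep_overrides)
        rate = nqx_to_rate(row.nqx, row.width_n, f)
        prob = rate_to_prob(rate)
        for age in range(row.age_start, row.age_start + row.width_n):
            if age > max_age:
                break
            records.append(SingleAgeRecord(age=age, rate=rate, prob=prob))
    # terminal extension: carry the last closed group's values to max_age
    last = records[-1]
    for age in range(records[-1].age + 1, max_age + 1):
        records.append(SingleAgeRecord(age=age, rate=last.rate, prob=last.prob))
    assert len(records) == max_age + 1
    return records


def period_to_midyear(period_start: int, period_end: int) -> int:
    """Central calendar year of a life-table period (floor of the mean)."""
    if period_start > period_end:
        raise ValueError(f"period_start {period_start} > period_end {period_end}")
    return (period_start + period_end) // 2


def assign_years(
    available: Iterable[int] | Mapping[int, object],
    start_year: int,
    end_year: int,
) -> dict[int, int]:
    """Map each calendar year in [start_year, end_year] to a source midyear.

    Nearest midyear wins; ties break toward the earlier midyear.  Years past
    the latest midyear carry it forward; years before the earliest use the
    earliest (backfill).
    """
    midyears = sorted(set(available))
    if not midyears:
        raise ValueError("no life-table midyears available")
    if start_year > end_year:
        raise ValueError(f"start_year {start_year} > end_year {end_year}")
    mapping: dict[int, int] = {}
    for year in range(start_year, end_year + 1):
        best = min(midyears, key=lambda m: (abs(year - m), m))
        mapping[year] = best
    return mapping


@dataclass
class PopMortTable:
    """Long PopMort table: one row per (year, sex, age) triple.

    ``frame`` has columns year, sex, age, rate, prob sorted by (year, sex,
    age).  ``provenance`` records which source midyear fed each calendar
    year.
    """

    frame: pd.DataFrame
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = ["year", "sex", "age", "rate", "prob"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"PopMort frame missing columns: {missing}")
        f = self.frame
        years = np.sort(f["year"].unique())
        expected_n = len(years) * 2 * (f["age"].max() + 1)
        if f.duplicated(subset=["year", "sex", "age"]).any():
            dup = f[f.duplicated(subset=["year", "sex", "age"])].iloc[0]
            raise ValueError(
                f"duplicate record for (year={dup['year']}, sex={dup['sex']}, "
                f"age={dup['age']})"
            )
        ages = np.arange(0, f["age"].max() + 1)
        for year in years:
            for sex in (1, 2):
                got = f[(f["year"] == year) & (f["sex"] == sex)]["age"].to_numpy()
                if len(got) != len(ages) or not np.array_equal(np.sort(got), ages):
                    missing_ages = sorted(set(ages) - set(got))
                    raise ValueError(
                        f"incomplete coverage for (year={year}, sex={sex}): "
                        f"missing ages {missing_ages[:5]}"
                    )
        if len(f) != expected_n:
            raise ValueError(f"expected {expected_n} records, got {len(f)}")

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    @property
    def max_age(self) -> int:
        return int(self.frame["age"].max())

    def lookup_arrays(self) -> tuple[int, int, np.ndarray, np.ndarray]:
        """Dense (year, sex, age)-indexed rate and prob arrays for fast lookup.

        Returns (min_year, max_age, rates, probs) with rates shaped
        (n_years, 2, max_age + 1).
        """
        f = self.frame.sort_values(["year", "sex", "age"])
        years = self.years
        n_ages = self.max_age + 1
        shape = (len(years), 2, n_ages)
        rates = f["rate"].to_numpy(dtype=float).reshape(shape)
        probs = f["prob"].to_numpy(dtype=float).reshape(shape)
        return years[0], self.max_age, rates, probs

    def prob_at(self, year: int, sex: int, age: int) -> float:
        sel = self.frame[
            (self.frame["year"] == year)
            & (self.frame["sex"] == sex)
            & (self.frame["age"] == age)
        ]
        if sel.empty:
            raise KeyError(f"no PopMort record for (year={year}, sex={sex}, age={age})")
        return float(sel["prob"].iloc[0])


def build_popmort(
    tables: Sequence[AbridgedLifeTable],
    start_year: int,
    end_year: int,
    max_age: int = DEFAULT_MAX_AGE,
    sep_overrides: Mapping[tuple[int, int], float] | None = None,
) -> PopMortTable:
    """Assemble the full PopMort table from abridged life tables.

    Each table is normalised, inverted to single-age rates/probs and keyed
    by its period midyear; calendar years in [start_year, end_year] are then
    served by the nearest midyear.  Both sexes must be present for every
    midyear used.  Deterministic: identical inputs give identical output.
    """
    if start_year > end_year:
        raise ValueError(f"start_year {start_year} > end_year {end_year}")
    by_midyear: dict[int, dict[int, AbridgedLifeTable]] = {}
    for lt in tables:
        midyear = period_to_midyear(lt.period_start, lt.period_end)
        slot = by_midyear.setdefault(midyear, {})
        if lt.sex in slot:
            raise ValueError(
                f"duplicate life table for sex {lt.sex} at midyear {midyear}"
            )
        slot[lt.sex] = lt
    if not by_midyear:
        raise ValueError("no life tables supplied")

    year_map = assign_years(by_midyear.keys(), start_year, end_year)
    used_midyears = sorted(set(year_map.values()))
    for midyear in used_midyears:
        for sex in (1, 2):
            if sex not in by_midyear[midyear]:
                lt_any = next(iter(by_midyear[midyear].values()))
                raise ValueError(
                    f"missing sex {sex} life table for period "
                    f"{lt_any.period_start}-{lt_any.period_end} (midyear {midyear})"
                )

    expanded: dict[tuple[int, int], list[SingleAgeRecord]] = {}
    for midyear in used_midyears:
        for sex in (1, 2):
            expanded[(midyear, sex)] = expand_to_single_ages(
                by_midyear[midyear][sex], max_age=max_age, sep_overrides=sep_overrides
            )

    rows = []
    provenance: dict[int, str] = {}
    for year in range(start_year, end_year + 1):
        midyear = year_map[year]
        lt = by_midyear[midyear][1]
        label = lt.label or f"{lt.period_start}-{lt.period_end}"
        provenance[year] = f"{label} (midyear {midyear})"
        for sex in (1, 2):
            for rec in expanded[(midyear, sex)]:
                rows.append((year, sex, rec.age, rec.rate, rec.prob))

    frame = pd.DataFrame(rows, columns=["year", "sex", "age", "rate", "prob"])
    frame = frame.sort_values(["year", "sex", "age"], ignore_index=True)
    return PopMortTable(frame=frame, provenance=provenance)
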