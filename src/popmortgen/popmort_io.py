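"""Read/write PopMort tables as delimiter-separated text.

The default column headers (_year, sex, _age, rate, prob) follow the
convention expected by common relative-survival software; both headers and
delimiter are configurable through :class:`PopMortFileSpec`.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import pandas as pd

from popmortgen.popmort_engine import PopMortTable

__all__ = ["PopMortFileSpec", "write_popmort", "read_popmort"]

DEFAULT_COLUMNS = {
    "year": "_year",
    "sex": "sex",
    "age": "_age",
    "rate": "rate",
    "prob": "prob",
}

ROLES = ("year", "sex", "age", "rate", "prob")

# tolerance for prob vs exp(-rate) after a text round trip
_CONSISTENCY_TOL = 1e-9


@dataclass
class PopMortFileSpec:
    """Column naming, delimiter and float formatting for PopMort files."""

    column_names: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    delimiter: str = ","
    float_precision: int | None = None  # None = shortest round-trip repr

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.column_names]
        if missing:
            raise ValueError(f"column_names missing roles: {missing}")
        headers = [self.column_names[r] for r in ROLES]
        if len(set(headers)) != len(headers):
            raise ValueError(f"column headers must be distinct, got {headers}")

    def format_float(self, x: float) -> str:
        if self.float_precision is None:
            return repr(x)
        return f"{x:.{self.float_precision}g}"


def write_popmort(
    table: PopMortTable,
    destination: str | Path | IO[str],
    spec: PopMortFileSpec | None = None,
) -> int:
    """Write a PopMort table; returns the number of data rows written.

    Rows are sorted by (year, sex, age); floats use the shortest
    round-trip representation unless the spec fixes a precision.
    """
    spec = spec or PopMortFileSpec()
    table.validate()
    frame = table.frame.sort_values(["year", "sex", "age"])

    def _write(stream: IO[str]) -> int:
        writer = csv.writer(stream, delimiter=spec.delimiter, lineterminator="\n")
        writer.writerow([spec.column_names[r] for r in ROLES])
        n = 0
        for year, sex, age, rate, prob in frame.itertuples(index=False):
            writer.writerow(
                [
                    int(year),
                    int(sex),
                    int(age),
                    spec.format_float(float(rate)),
                    spec.format_float(float(prob)),
                ]
            )
            n += 1
        return n

    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="") as fh:
            return _write(fh)
    return _write(destination)


def read_popmort(
    source: str | Path | IO[str],
    spec: PopMortFileSpec | None = None,
) -> PopMortTable:
    """Read a PopMort file written by :func:`write_popmort` (or matching spec).

    Validates structural completeness and that prob = exp(-rate) within a
    small tolerance that absorbs text round-tripping; inconsistent rows are
    reported with their (year, sex, age) keys.
    """
    spec = spec or PopMortFileSpec()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    frame = pd.read_csv(
        io.StringIO(text),
        sep=spec.delimiter,
        dtype={spec.column_names["year"]: int, spec.column_names["sex"]: int,
               spec.column_names["age"]: int},
        float_precision="round_trip",
    )
    rename = {v: k for k, v in spec.column_names.items()}
    missing = [h for h in spec.column_names.values() if h not in frame.columns]
    if missing:
        raise ValueError(f"popmort file missing columns: {missing}")
    frame = frame.rename(columns=rename)[list(ROLES)]

    bad = frame[
        (frame["prob"] - (-frame["rate"]).apply(math.exp)).abs() > _CONSISTENCY_TOL
    ]
    if not bad.empty:
        offenders = [
            (int(r.year), int(r.sex), int(r.age)) for r in bad.head(10).itertuples()
        ]
        raise ValueError(
            f"prob != exp(-rate) beyond {_CONSISTENCY_TOL} for "
            f"{len(bad)} record(s), e.g. {offenders}"
        )
    frame = frame.sort_values(["year", "sex", "age"], ignore_index=True)
    return PopMortTable(frame=frame)  # __post_init__ validates completeness
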