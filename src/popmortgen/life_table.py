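"""Abridged life tables: domain types, parsing, and separation factors.

An abridged life table gives, per sex and reference period, the probability
of dying (nqx) within each age group.  Supported group labels are ``a-b``
(hyphen or en dash), ``a+`` for the open terminal group, and bare integers
(interval width inferred from the following row).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

__all__ = [
    "AgeGroupRow",
    "AbridgedLifeTable",
    "LifeTableError",
    "LifeTableParseError",
    "merge_infant_rows",
    "parse_life_table",
    "separation_factor",
]

SEX_MALE = 1
SEX_FEMALE = 2
VALID_SEXES = (SEX_MALE, SEX_FEMALE)


class LifeTableError(ValueError):
    """A life table violates a structural invariant."""


class LifeTableParseError(LifeTableError):
    """A source row or cell could not be interpreted.

    Carries ``row`` (1-based data-row index) and ``column`` when known, so
    callers can point users at the offending cell.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column!r}")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)
        self.row = row
        self.column = column


@dataclass(frozen=True)
class AgeGroupRow:
    """One age group of an abridged life table.

    ``width_n == 0`` denotes the open terminal group (e.g. "85+").
    """

    age_start: int
    width_n: int
    nqx: float

    def __post_init__(self) -> None:
        if self.age_start < 0:
            raise LifeTableError(f"age_start must be >= 0, got {self.age_start}")
        if self.width_n < 0:
            raise LifeTableError(f"width_n must be >= 0, got {self.width_n}")
        if not 0.0 <= self.nqx <= 1.0:
            raise LifeTableError(
                f"nqx must lie in [0, 1], got {self.nqx} for age {self.age_start}"
            )
        if self.nqx == 1.0 and self.width_n != 0:
            raise LifeTableError(
                f"nqx = 1 is only permitted for the open terminal group "
                f"(age {self.age_start} has width {self.width_n})"
            )

    @property
    def is_open(self) -> bool:
        return self.width_n == 0


@dataclass(frozen=True)
class AbridgedLifeTable:
    """An abridged life table for one sex over one reference period."""

    label: str
    period_start: int
    period_end: int
    sex: int
    rows: tuple[AgeGroupRow, ...]

    def __post_init__(self) -> None:
        if self.period_start > self.period_end:
            raise LifeTableError(
                f"period_start {self.period_start} > period_end {self.period_end}"
            )
        if self.sex not in VALID_SEXES:
            raise LifeTableError(f"sex must be 1 (male) or 2 (female), got {self.sex}")
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise LifeTableError("life table has no rows")
        if rows[0].age_start != 0:
            raise LifeTableError(
                f"first age group must start at 0, got {rows[0].age_start}"
            )
        for i, (cur, nxt) in enumerate(zip(rows, rows[1:])):
            if cur.is_open:
                raise LifeTableError(
                    f"open terminal group at age {cur.age_start} must be the last row"
                )
            if nxt.age_start != cur.age_start + cur.width_n:
                raise LifeTableError(
                    f"age groups not contiguous at row {i + 1}: "
                    f"group [{cur.age_start}, {cur.age_start + cur.width_n}) "
                    f"followed by age_start {nxt.age_start}"
                )

    @property
    def closed_rows(self) -> tuple[AgeGroupRow, ...]:
        return tuple(r for r in self.rows if not r.is_open)

    @property
    def last_closed_end(self) -> int:
        last = self.closed_rows[-1]
        return last.age_start + last.width_n


def separation_factor(
    age_start: int,
    width_n: int,
    overrides: Mapping[tuple[int, int], float] | None = None,
) -> float:
    """Separation factor nfx for a closed age group.

    1/2 for the combined 0-4 group, width/2 otherwise (5/2 for the usual
    5-year groups).  ``overrides`` maps (age_start, width_n) to a custom
    factor and wins when present.
    """
    if width_n < 1:
        raise LifeTableError(
            "separation factor is undefined for the open terminal group "
            f"(age {age_start}+)"
        )
    if overrides is not None and (age_start, width_n) in overrides:
        return float(overrides[(age_start, width_n)])
    if age_start == 0 and width_n == 5:
        return 0.5
    return width_n / 2.0


def merge_infant_rows(lt: AbridgedLifeTable) -> AbridgedLifeTable:
    """Collapse split infant rows (0 / 1-4) into a single 0-4 group.

    q(0-4) = 1 - (1 - q0) * (1 - 4q1).  Idempotent: a table whose first row
    already spans 0-4 is returned unchanged.
    """
    first = lt.rows[0]
    if first.age_start == 0 and first.width_n == 5:
        return lt
    if len(lt.rows) < 2:
        raise LifeTableError("cannot merge infant rows: table has a single row")
    second = lt.rows[1]
    if not (first.age_start == 0 and first.width_n == 1 and second.age_start == 1 and second.width_n == 4):
        raise LifeTableError(
            "expected leading rows (0, width 1) and (1, width 4) or a combined "
            f"(0, width 5); got (age {first.age_start}, width {first.width_n}) "
            f"then (age {second.age_start}, width {second.width_n})"
        )
    merged_q = 1.0 - (1.0 - first.nqx) * (1.0 - second.nqx)
    merged = AgeGroupRow(age_start=0, width_n=5, nqx=merged_q)
    return replace(lt, rows=(merged,) + lt.rows[2:])


# --- parsing ---------------------------------------------------------------

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")
_OPEN_RE = re.compile(r"^\s*(\d+)\s*\+\s*$")
_BARE_RE = re.compile(r"^\s*(\d+)\s*$")


def parse_age_group_label(label: str) -> tuple[int, int | None]:
    """Parse an age-group label into (age_start, width_n).

    Returns ``width_n = None`` for a bare integer label; the caller infers
    the width from the next row's start.  ``width_n = 0`` marks an open
    group ("85+").
    """
    m = _RANGE_RE.match(label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise LifeTableParseError(f"age group {label!r} has end < start")
        # "0-4" spans ages 0..4 inclusive -> width 5
        return lo, hi - lo + 1
    m = _OPEN_RE.match(label)
    if m:
        return int(m.group(1)), 0
    m = _BARE_RE.match(label)
    if m:
        return int(m.group(1)), None
    raise LifeTableParseError(f"unparseable age-group label {label!r}")


@dataclass
class LifeTableSchema:
    """Column mapping for :func:`parse_life_table`.

    Either ``nqx_columns`` maps sex codes to per-sex nqx column headers, or
    ``nqx_column`` plus ``sex_column`` (with optional ``sex_map`` for
    textual codes) describe a long-format source.
    """

    age_column: str = "age_group"
    nqx_columns: Mapping[int, str] | None = None
    nqx_column: str | None = None
    sex_column: str | None = None
    sex_map: Mapping[str, int] = field(default_factory=dict)
    period_start: int | None = None
    period_end: int | None = None
    label: str = ""
    delimiter: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "LifeTableSchema":
        d = dict(d)
        if "nqx_columns" in d and d["nqx_columns"] is not None:
            d["nqx_columns"] = {int(k): v for k, v in dict(d["nqx_columns"]).items()}
        period = d.pop("period", None)
        if period is not None:
            d.setdefault("period_start", int(period[0]))
            d.setdefault("period_end", int(period[1]))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise LifeTableParseError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**d)


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_rows(source, delimiter: str | None) -> tuple[list[str], list[list[str]]]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError(f"unsupported source type {type(source).__name__}")
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:2048])
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = [r for r in reader if any(cell.strip() for cell in r)]
    if not rows:
        raise LifeTableParseError("source is empty")
    header = [h.strip() for h in rows[0]]
    return header, rows[1:]


def _parse_nqx(cell: str, row_idx: int, column: str) -> float:
    try:
        q = float(cell)
    except ValueError:
        raise LifeTableParseError(
            f"nqx value {cell!r} is not a number", row=row_idx, column=column
        ) from None
    if not 0.0 <= q <= 1.0:
        raise LifeTableParseError(
            f"nqx value {q} outside [0, 1]", row=row_idx, column=column
        )
    return q


def _build_rows(
    parsed: Sequence[tuple[int, int | None, float]],
) -> tuple[AgeGroupRow, ...]:
    """Resolve inferred widths (bare-integer labels) against the next row."""
    out: list[AgeGroupRow] = []
    for i, (start, width, q) in enumerate(parsed):
        if width is None:
            if i + 1 < len(parsed):
                width = parsed[i + 1][0] - start
                if width < 1:
                    raise LifeTableParseError(
                        f"cannot infer width for age group starting at {start}",
                        row=i + 1,
                    )
            else:
                width = 0  # trailing bare label: treat as open group
        out.append(AgeGroupRow(age_start=start, width_n=width, nqx=q))
    return tuple(out)


def parse_life_table(
    source: str | Path | IO[str],
    schema: LifeTableSchema | Mapping,
) -> list[AbridgedLifeTable]:
    """Parse a delimiter-separated abridged life table.

    Returns one :class:`AbridgedLifeTable` per (sex, period) found.  The
    source is either wide (one nqx column per sex, via ``nqx_columns``) or
    long (a single nqx column plus a sex column).
    """
    if not isinstance(schema, LifeTableSchema):
        schema = LifeTableSchema.from_dict(schema)
    if schema.period_start is None or schema.period_end is None:
        raise LifeTableParseError("schema must supply period_start and period_end")
    header, data = _read_rows(source, schema.delimiter)
    col_index = {name: i for i, name in enumerate(header)}

    def col(name: str) -> int:
        if name not in col_index:
            raise LifeTableParseError(f"missing column", column=name)
        return col_index[name]

    age_i = col(schema.age_column)

    tables: list[AbridgedLifeTable] = []
    if schema.nqx_columns:
        for sex, nqx_col in sorted(schema.nqx_columns.items()):
            nqx_i = col(nqx_col)
            parsed = []
            for r, cells in enumerate(data, start=1):
                start, width = parse_age_group_label(cells[age_i])
                q = _parse_nqx(cells[nqx_i], r, nqx_col)
                parsed.append((start, width, q))
            tables.append(
                AbridgedLifeTable(
                    label=schema.label,
                    period_start=schema.period_start,
                    period_end=schema.period_end,
                    sex=int(sex),
                    rows=_build_rows(parsed),
                )
            )
    elif schema.nqx_column and schema.sex_column:
        nqx_i = col(schema.nqx_column)
        sex_i = col(schema.sex_column)
        by_sex: dict[int, list[tuple[int, int | None, float]]] = {}
        for r, cells in enumerate(data, start=1):
            raw_sex = cells[sex_i].strip()
            if raw_sex in schema.sex_map:
                sex = int(schema.sex_map[raw_sex])
            else:
                try:
                    sex = int(raw_sex)
                except ValueError:
                    raise LifeTableParseError(
                        f"unrecognised sex code {raw_sex!r}",
                        row=r,
                        column=schema.sex_column,
                    ) from None
            if sex not in VALID_SEXES:
                raise LifeTableParseError(
                    f"sex code {sex} is not 1 or 2", row=r, column=schema.sex_column
                )
            start, width = parse_age_group_label(cells[age_i])
            q = _parse_nqx(cells[nqx_i], r, schema.nqx_column)
            by_sex.setdefault(sex, []).append((start, width, q))
        for sex in sorted(by_sex):
            tables.append(
                AbridgedLifeTable(
                    label=schema.label,
                    period_start=schema.period_start,
                    period_end=schema.period_end,
                    sex=sex,
                    rows=_build_rows(by_sex[sex]),
                )
            )
    else:
        raise LifeTableParseError(
            "schema must define either nqx_columns (per-sex) or "
            "nqx_column + sex_column"
        )
    return tables


def parse_life_table_xlsx(
    path: str | Path,
    schema: LifeTableSchema | Mapping,
    sheet: str | int = 0,
) -> list[AbridgedLifeTable]:
    """Thin adapter: read one sheet of an xlsx workbook and parse it.

    Requires openpyxl (installed with the ``xlsx`` extra).
    """
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if isinstance(sheet, str) else wb.worksheets[sheet]
    buf = io.StringIO()
    writer = csv.writer(buf)
    for row in ws.iter_rows(values_only=True):
        writer.writerow(["" if v is None else v for v in row])
    wb.close()
    buf.seek(0)
    if not isinstance(schema, LifeTableSchema):
        schema = LifeTableSchema.from_dict(schema)
    schema.delimiter = ","
    return parse_life_table(buf, schema)


def serialise_life_table(lt: AbridgedLifeTable, delimiter: str = ",") -> str:
    """Render a life table back to delimiter-separated text (round-trips nqx)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(["age_group", "nqx"])
    for row in lt.rows:
        if row.is_open:
            label = f"{row.age_start}+"
        else:
            label = f"{row.age_start}-{row.age_start + row.width_n - 1}"
        writer.writerow([label, repr(row.nqx)])
    return buf.getvalue()
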