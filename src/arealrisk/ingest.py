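"""Line-list ingestion: from event records to analysis panels.

Converts a CSV line-list of events (notification date, 5-digit DIVIPOLA
municipality code, age, sex) plus a census population table and a quarterly
covariate table into one :class:`~arealrisk.panel.PanelData` per age group.
Validation failures are collected into reject/drop reports rather than
silently discarded, so record counts are conserved end to end: panel cells +
exclusions (rejects, under-5 ages, out-of-window dates, zero-population
areas) always add back up to the input row count.

Conventions: municipality codes are matched as zero-padded 5-character
strings; quarters are indexed t = 4*(year - origin_year) + ceil(month/3), so
with the default origin 2018 the window 2018Q1..2020Q4 maps to t = 1..12;
population offsets are constant over quarters at the census value; covariate
gaps are forward-filled within an area and then zero-filled, with every
filled cell listed in the gap report.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .panel import AGE_GROUPS, AgeGroup, PanelData

__all__ = [
    "LineListRecord",
    "ConfigurationError",
    "ReconciliationError",
    "DEFAULT_SCHEMA",
    "parse_line_list",
    "assign_age_group",
    "assign_quarter",
    "build_panel",
    "build_all_panels",
    "IngestReport",
]


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


class ReconciliationError(ValueError):
    """Records reference areas absent from the population table."""


class LineListRecord(NamedTuple):
    notification_date: dt.date
    municipality_code: str
    age: int
    sex: str


DEFAULT_SCHEMA = {
    "date": "notification_date",
    "municipality": "municipality_code",
    "age": "age",
    "sex": "sex",
}


def _normalize_code(raw: str) -> str | None:
    code = str(raw).strip()
    if code.isdigit() and 1 <= len(code) <= 5:
        return code.zfill(5)
    return None


def parse_line_list(
    path: str | Path, schema: dict[str, str] | None = None
) -> tuple[list[LineListRecord], pd.DataFrame]:
    """Parse a line-list CSV into validated records plus a rejects report.

    ``schema`` maps the logical names {date, municipality, age, sex} to the
    file's column names.  Returns ``(records, rejects)`` where ``rejects``
    has one row per failed input row with its 0-based row index and reason.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise OSError(f"line-list file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise OSError(f"could not read line-list {path}: {exc}") from exc
    missing = [col for col in schema.values() if col not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"line-list {path} lacks configured columns {missing}; has {list(raw.columns)}"
        )
    records: list[LineListRecord] = []
    rejects: list[tuple[int, str]] = []
    dates = pd.to_datetime(raw[schema["date"]], format="ISO8601", errors="coerce")
    ages = pd.to_numeric(raw[schema["age"]], errors="coerce")
    for i in range(len(raw)):
        code = _normalize_code(raw[schema["municipality"]].iat[i])
        if code is None:
            rejects.append((i, "invalid municipality code"))
            continue
        if pd.isna(dates.iat[i]):
            rejects.append((i, "unparseable date"))
            continue
        age = ages.iat[i]
        if pd.isna(age) or age != int(age) or age < 0:
            rejects.append((i, "invalid age"))
            continue
        records.append(
            LineListRecord(
                notification_date=dates.iat[i].date(),
                municipality_code=code,
                age=int(age),
                sex=str(raw[schema["sex"]].iat[i]),
            )
        )
    rejects_df = pd.DataFrame(rejects, columns=["row", "reason"])
    return records, rejects_df


def assign_age_group(age: int) -> AgeGroup | None:
    """Map an age in years to its analysis bracket; None below the first
    bracket (under-5s are excluded from the analysis)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for group in AGE_GROUPS:
        if group.contains(age):
            return group
    return None


def assign_quarter(date: dt.date, origin_year: int = 2018, n_quarters: int = 12) -> int:
    """1-based quarter index t = 4*(year - origin_year) + ceil(month/3).

    Raises a ``ValueError`` naming the date if it falls outside the window
    covered by ``n_quarters``.
    """
    t = 4 * (date.year - origin_year) + (date.month + 2) // 3
    if not 1 <= t <= n_quarters:
        raise ValueError(
            f"date {date.isoformat()} outside the {n_quarters}-quarter window "
            f"starting {origin_year}-01-01"
        )
    return t


@dataclass
class IngestReport:
    """What was excluded on the way from records to a panel, and why."""

    age_group: AgeGroup
    n_records_in_group: int = 0
    n_out_of_window: int = 0
    n_in_dropped_areas: int = 0
    dropped_areas: list[str] = field(default_factory=list)
    covariate_gaps: list[tuple[str, int]] = field(default_factory=list)

    def drop_frame(self) -> pd.DataFrame:
        rows = [(code, "zero population in age group") for code in self.dropped_areas]
        return pd.DataFrame(rows, columns=["municipality_code", "reason"])


def _prepare_population(population: pd.DataFrame, label: str) -> pd.Series:
    required = {"municipality_code", "age_group", "population"}
    missing = required - set(population.columns)
    if missing:
        raise ConfigurationError(f"population table lacks columns {sorted(missing)}")
    sub = population[population["age_group"].astype(str) == label].copy()
    sub["municipality_code"] = sub["municipality_code"].map(
        lambda c: str(c).strip().zfill(5)
    )
    return sub.set_index("municipality_code")["population"].astype(float)


def _covariate_matrix(
    covariate: pd.DataFrame,
    area_ids: list[str],
    n_quarters: int,
    report: IngestReport,
) -> np.ndarray:
    cols = set(covariate.columns)
    if {"municipality_code", "quarter_index", "value"} <= cols:
        df = covariate.copy()
    elif {"municipality_code", "year", "quarter", "value"} <= cols:
        df = covariate.copy()
        origin = int(df["year"].astype(int).min())
        df["quarter_index"] = 4 * (df["year"].astype(int) - origin) + df[
            "quarter"
        ].astype(int)
    else:
        raise ConfigurationError(
            "covariate table needs columns (municipality_code, quarter_index, value)"
            " or (municipality_code, year, quarter, value)"
        )
    df["municipality_code"] = df["municipality_code"].map(
        lambda c: str(c).strip().zfill(5)
    )
    wide = (
        df.pivot_table(
            index="municipality_code",
            columns="quarter_index",
            values="value",
            aggfunc="mean",
        )
        .reindex(index=area_ids, columns=range(1, n_quarters + 1))
    )
    gaps = wide.isna()
    if gaps.any().any():
        for code, row in gaps.iterrows():
            for t in row.index[row]:
                report.covariate_gaps.append((str(code), int(t)))
    wide = wide.ffill(axis=1).fillna(0.0)
    return wide.to_numpy(dtype=float)


def build_panel(
    records: Iterable[LineListRecord],
    population: pd.DataFrame,
    covariate: pd.DataFrame,
    age_group: AgeGroup,
    origin_year: int = 2018,
    n_quarters: int = 12,
) -> tuple[PanelData, IngestReport]:
    """Aggregate one age group's records onto the area x quarter grid.

    Areas are the population table's municipalities for this group; areas
    with zero census population are dropped (listed in the report), and a
    record whose municipality is absent from the population table raises a
    :class:`ReconciliationError` listing the offending codes.
    """
    report = IngestReport(age_group=age_group)
    pop = _prepare_population(population, age_group.label)
    grouped = [
        r for r in records if assign_age_group(r.age) == age_group
    ]
    unknown = sorted(
        {r.municipality_code for r in grouped} - set(pop.index)
    )
    if unknown:
        raise ReconciliationError(
            f"municipalities in records but not in population table: {unknown}"
        )
    area_ids = sorted(pop.index[pop > 0])
    report.dropped_areas = sorted(pop.index[pop <= 0])
    index = {code: i for i, code in enumerate(area_ids)}
    n = len(area_ids)
    counts = np.zeros((n, n_quarters), dtype=int)
    for r in grouped:
        try:
            t = assign_quarter(r.notification_date, origin_year, n_quarters)
        except ValueError:
            report.n_out_of_window += 1
            continue
        i = index.get(r.municipality_code)
        if i is None:  # area dropped for zero population
            report.n_in_dropped_areas += 1
            continue
        counts[i, t - 1] += 1
    report.n_records_in_group = int(counts.sum())
    offset = np.tile(pop.loc[area_ids].to_numpy()[:, None], (1, n_quarters))
    cov = _covariate_matrix(covariate, area_ids, n_quarters, report)
    panel = PanelData(
        area_ids=list(area_ids),
        age_group=age_group,
        counts=counts,
        offset=offset,
        covariate=cov,
    )
    return panel, report


def build_all_panels(
    records: Iterable[LineListRecord],
    population: pd.DataFrame,
    covariate: pd.DataFrame,
    origin_year: int = 2018,
    n_quarters: int = 12,
) -> dict[str, tuple[PanelData, IngestReport]]:
    """Build the six age-group panels from one record set."""
    records = list(records)
    return {
        g.label: build_panel(
            records, population, covariate, g, origin_year, n_quarters
        )
        for g in AGE_GROUPS
    }
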