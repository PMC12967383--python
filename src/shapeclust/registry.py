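"""Long-format registry incidence tables: loading, exclusions, panels, trends.

Input is the long export dialect of a population cancer registry's
statistics application: one row per sex x cancer-site x 10-year age band x
calendar year, with the case count and the incidence rate per 100,000
person-years.  Rates are used as provided; the package never recomputes
them from cases, because the export carries no population denominators.

Certain seldom-metastasizing neoplasms (basal cell carcinomas, in-situ and
borderline/non-invasive categories) are excluded before analysis.  The
exclusion vocabulary is configuration (a YAML list, matched exactly but
case-insensitively), not code: export label spellings vary by registry.

Trend statistics: percentage change between two years and the extreme
yearly percentage changes within a window.  The denominator uses the
absolute value of the starting point so the convention extends to
standardized series, which cross zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateKeyError,
    EmptyPanelError,
    SchemaError,
    WindowError,
    ZeroBaselineError,
)
from .measures import SeriesPanel, TimeSeries

__all__ = [
    "RegistryConfig",
    "RegistryTable",
    "DEFAULT_EXCLUSIONS",
    "AGE_GROUPS",
    "load_registry_csv",
    "apply_exclusions",
    "build_panel",
    "top_sites",
    "pct_change",
    "yearly_extremes",
    "YearlyExtremes",
]

log = logging.getLogger(__name__)

AGE_GROUPS = ("30-39", "40-49", "50-59", "60-69", "70-79")
SEXES = ("female", "male")

#: default site categories removed before analysis (rarely metastasizing
#: neoplasms); matched case-insensitively, overridable via config
DEFAULT_EXCLUSIONS = (
    "basal cell carcinoma of the skin",
    "basal cell carcinoma of the genitals",
    "borderline tumor of the ovary",
    "carcinoma in situ of the breast",
    "non-invasive neoplasm of the cervix uteri",
    "non-invasive neoplasm of the vagina and vulva",
)

REQUIRED_FIELDS = ("sex", "site", "age_group", "year", "cases", "rate")


@dataclass
class RegistryConfig:
    """Column mapping and exclusion list for a registry export dialect."""

    columns: dict[str, str] = field(
        default_factory=lambda: {f: f for f in REQUIRED_FIELDS}
    )
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    year_span: tuple[int, int] = (1963, 2023)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegistryConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        if "columns" in raw:
            kwargs["columns"] = {
                **{f: f for f in REQUIRED_FIELDS},
                **raw["columns"],
            }
        if "exclusions" in raw:
            kwargs["exclusions"] = tuple(raw["exclusions"])
        if "year_span" in raw:
            kwargs["year_span"] = tuple(raw["year_span"])
        return cls(**kwargs)


@dataclass
class RegistryTable:
    """Validated long-format incidence table (canonical column names)."""

    df: pd.DataFrame
    year_span: tuple[int, int] = (1963, 2023)

    def __len__(self) -> int:
        return len(self.df)


def load_registry_csv(
    path: str | Path, config: RegistryConfig | None = None
) -> RegistryTable:
    """Read and validate a long-format registry CSV.

    Raises :class:`SchemaError` for missing columns,
    :class:`DuplicateKeyError` for repeated (sex, site, age_group, year)
    keys, and ``ValueError`` with row numbers for malformed cells.
    """
    config = config or RegistryConfig()
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in config.columns.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing!r} in {path}")
    rename = {v: k for k, v in config.columns.items()}
    df = df.rename(columns=rename)[list(REQUIRED_FIELDS)].copy()

    problems = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            year = int(row["year"])
            cases = int(row["cases"])
            rate = float(row["rate"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric year/cases/rate")
            continue
        if cases < 0:
            problems.append(f"line {line}: negative case count {cases}")
        if rate < 0:
            problems.append(f"line {line}: negative rate {rate}")
        lo, hi = config.year_span
        if not lo <= year <= hi:
            problems.append(
                f"line {line}: year {year} outside declared span {lo}-{hi}"
            )
    if problems:
        raise ValueError("malformed registry rows:\n" + "\n".join(problems))

    df["year"] = df["year"].astype(int)
    df["cases"] = df["cases"].astype(int)
    df["rate"] = df["rate"].astype(float)

    key_cols = ["sex", "site", "age_group", "year"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise DuplicateKeyError(f"duplicated key {tuple(first)!r}")
    return RegistryTable(df=df, year_span=config.year_span)


def apply_exclusions(
    table: RegistryTable, exclusions: Sequence[str] = DEFAULT_EXCLUSIONS
) -> RegistryTable:
    """Drop rows whose site is on the exclusion list (case-insensitive
    exact match).  Idempotent; the removed-row count is logged."""
    excl = {e.strip().casefold() for e in exclusions}
    mask = table.df["site"].str.strip().str.casefold().isin(excl)
    removed = int(mask.sum())
    if removed:
        log.info("apply_exclusions: removed %d rows", removed)
    return RegistryTable(df=table.df.loc[~mask].copy(), year_span=table.year_span)


def top_sites(
    table: RegistryTable, sex: str, age_group: str, year: int, n: int = 10
) -> list[str]:
    """Sites ranked by case count (descending) in one subgroup-year; ties
    broken alphabetically.  Returns at most n sites."""
    df = table.df
    sub = df[(df["sex"] == sex) & (df["age_group"] == age_group) & (df["year"] == year)]
    counts = sub.groupby("site")["cases"].sum()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [site for site, _ in ranked[:n]]


def build_panel(
    table: RegistryTable,
    sex: str,
    age_group: str,
    site_selection: Sequence[str] | int | None = None,
) -> SeriesPanel:
    """Assemble one sex x age-group panel of complete-coverage series.

    ``site_selection`` may be an explicit site list, an integer n (top-n
    sites by cases in the final year of the span, the default notion of
    "most common"), or None (all sites).  Sites missing any year on the
    span are dropped with a warning -- there is no imputation.
    """
    lo, hi = table.year_span
    axis = np.arange(lo, hi + 1)
    df = table.df
    sub = df[(df["sex"] == sex) & (df["age_group"] == age_group)]

    if isinstance(site_selection, int):
        wanted = top_sites(table, sex, age_group, hi, site_selection)
    elif site_selection is None:
        wanted = sorted(sub["site"].unique())
    else:
        wanted = list(site_selection)

    members = []
    for site in wanted:
        rows = sub[sub["site"] == site].sort_values("year")
        if not np.array_equal(rows["year"].to_numpy(), axis):
            warnings.warn(
                f"site {site!r} does not cover the full span {lo}-{hi} in "
                f"{sex}/{age_group}; dropped (no imputation)",
                stacklevel=2,
            )
            continue
        members.append(
            TimeSeries(site=site, years=axis, values=rows["rate"].to_numpy())
        )
    if not members:
        raise EmptyPanelError(
            f"no site with complete {lo}-{hi} coverage for {sex}/{age_group}"
        )
    return SeriesPanel(members=members, sex=sex, age_group=age_group)


def _value_at(series: TimeSeries, year: int) -> float:
    idx = np.flatnonzero(series.years == year)
    if idx.size == 0:
        raise WindowError(f"year {year} not on the axis of {series.site!r}")
    return float(series.values[idx[0]])


def pct_change(series: TimeSeries, year_from: int, year_to: int) -> float:
    """Percentage change 100 * (v_to - v_from) / |v_from| between two years.

    The absolute-value denominator keeps the sign meaningful for
    standardized series, whose values cross zero.
    """
    v_from = _value_at(series, year_from)
    v_to = _value_at(series, year_to)
    if v_from == 0:
        raise ZeroBaselineError(
            f"{series.site!r}: value at {year_from} is zero; % change undefined"
        )
    return 100.0 * (v_to - v_from) / abs(v_from)


class YearlyExtremes(NamedTuple):
    """Extreme consecutive-year percentage changes in a window.

    ``max_increase`` and ``min_change`` are signed; ``max_decrease`` is the
    magnitude of the largest drop (0 if the series never drops)."""

    max_increase: float
    max_decrease: float
    min_change: float


def yearly_extremes(
    series: TimeSeries, year_from: int, year_to: int
) -> YearlyExtremes:
    """Largest yearly rise and fall of 100*(v_{i+1}-v_i)/|v_i| in a window.

    Year-steps starting from a zero value are skipped with a warning.
    """
    if year_to <= year_from:
        raise WindowError(f"window [{year_from}, {year_to}] must have length >= 2")
    lo = _value_at(series, year_from)  # validates endpoints on axis
    hi = _value_at(series, year_to)
    del lo, hi
    sel = (series.years >= year_from) & (series.years <= year_to)
    vals = series.values[sel]
    changes = []
    for i in range(len(vals) - 1):
        if vals[i] == 0:
            warnings.warn(
                f"{series.site!r}: zero value at year "
                f"{int(series.years[sel][i])}; year-step skipped",
                stacklevel=2,
            )
            continue
        changes.append(100.0 * (vals[i + 1] - vals[i]) / abs(vals[i]))
    if not changes:
        raise WindowError("no computable year-steps in window")
    mx, mn = max(changes), min(changes)
    return YearlyExtremes(
        max_increase=mx, max_decrease=max(0.0, -mn), min_change=mn
    )


def panel_to_frame(panel: SeriesPanel) -> pd.DataFrame:
    """Panel as a long DataFrame (site, year, value), for CSV export."""
    rows = []
    for ts in panel:
        for y, v in zip(ts.years, ts.values):
            rows.append({"site": ts.site, "year": int(y), "value": float(v)})
    return pd.DataFrame(rows)
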