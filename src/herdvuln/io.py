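"""Reading, writing and validating per-nation indicator tables.

The canonical input is a UTF-8 CSV with one row per nation: seven metadata
columns (``nation_id,name,region,income_group,developed_status,food_deficit,
population``) followed by raw indicator columns in their native units, each
declared in a :class:`~herdvuln.config.CategoryConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CategoryConfig
from .errors import ConfigError, ParseError, SchemaError

log = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "nation_id",
    "name",
    "region",
    "income_group",
    "developed_status",
    "food_deficit",
    "population",
]

#: the seven World Bank regions used for grouping
REGIONS = [
    "East Asia and Pacific",
    "Europe and Central Asia",
    "Latin America and Caribbean",
    "Middle East and North Africa",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
]

INCOME_GROUPS = ["low", "lower middle", "upper middle", "high"]

DEVELOPED_STATUS = ["least developed", "developing", "developed"]


@dataclass
class IndicatorTable:
    """A validated nation table: metadata plus raw indicator values.

    ``data`` holds one row per nation with the metadata columns followed by
    the indicator columns declared in ``config``.
    """

    data: pd.DataFrame
    config: CategoryConfig

    def __post_init__(self) -> None:
        missing_meta = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing_meta:
            raise SchemaError(f"missing mandatory metadata column(s): {missing_meta}")
        extra = [
            c for c in self.data.columns
            if c not in METADATA_COLUMNS and c not in self.config.indicator_names
        ]
        if extra:
            raise ConfigError(
                f"indicator column(s) not declared in the category config: {extra}"
            )
        ids = self.data["nation_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise SchemaError(f"duplicate nation_id values: {dupes}")
        if (pd.to_numeric(self.data["population"], errors="coerce") < 0).any():
            raise SchemaError("population must be non-negative")
        for col, vocab in [
            ("region", REGIONS),
            ("income_group", INCOME_GROUPS),
            ("developed_status", DEVELOPED_STATUS),
        ]:
            bad = set(self.data[col].dropna()) - set(vocab)
            if bad:
                raise SchemaError(f"{col} values outside vocabulary: {sorted(bad)}")

    @property
    def indicator_names(self) -> list[str]:
        return [c for c in self.config.indicator_names if c in self.data.columns]

    @property
    def indicators(self) -> pd.DataFrame:
        """Indicator values indexed by nation_id."""
        return self.data.set_index("nation_id")[self.indicator_names]

    @property
    def meta(self) -> pd.DataFrame:
        return self.data.set_index("nation_id")[METADATA_COLUMNS[1:]]

    @property
    def n_nations(self) -> int:
        return len(self.data)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path


def read_indicator_csv(path: str | Path, config: CategoryConfig) -> IndicatorTable:
    """Read and validate a nation indicator CSV against a category config.

    Missing indicator cells stay as NaN (flagged by :func:`validate_table`),
    never silently dropped. Non-numeric indicator cells raise
    :class:`~herdvuln.errors.ParseError` naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"nation_id": str, "name": str})
    missing_meta = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise SchemaError(
            f"{path.name}: missing mandatory metadata column(s): {missing_meta}"
        )
    undeclared = [
        c for c in raw.columns
        if c not in METADATA_COLUMNS and c not in config.indicator_names
    ]
    if undeclared:
        raise ConfigError(
            f"{path.name}: indicator column(s) absent from config: {undeclared}"
        )
    for col in config.indicator_names:
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path.name}: non-numeric value {raw[col].iloc[row]!r} in "
                f"column {col!r}, row {row + 2} (nation "
                f"{raw['nation_id'].iloc[row]!r})"
            )
        raw[col] = coerced
    raw["food_deficit"] = _parse_bool(raw["food_deficit"], path.name)
    raw["population"] = pd.to_numeric(raw["population"], errors="raise")
    return IndicatorTable(raw, config)


def _parse_bool(col: pd.Series, where: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise ParseError(f"{where}: food_deficit value {bad!r} is not boolean")
    return out.astype(bool)


@dataclass
class ValidationReport:
    """Report-only completeness screen; the caller decides exclusions."""

    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    sparse_indicators: list[str] = field(default_factory=list)  # < 2 observed
    zero_range_indicators: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.missing_cells or self.sparse_indicators or self.zero_range_indicators
        )

    @property
    def nations_with_missing(self) -> list[str]:
        return sorted({n for n, _ in self.missing_cells})


def validate_table(table: IndicatorTable) -> ValidationReport:
    """List missing (nation, indicator) cells and degenerate indicators.

    Degenerate means fewer than two observed values or zero range across
    nations (which would make min-max scaling undefined). The table is not
    mutated.
    """
    report = ValidationReport()
    ind = table.indicators
    for col in ind.columns:
        vals = ind[col]
        for nation in vals.index[vals.isna()]:
            report.missing_cells.append((str(nation), col))
        observed = vals.dropna()
        if len(observed) < 2:
            report.sparse_indicators.append(col)
        elif float(observed.max()) == float(observed.min()):
            report.zero_range_indicators.append(col)
    return report


def apply_missing_policy(table: IndicatorTable) -> IndicatorTable:
    """Apply the configured missing-data policy and return a new table.

    ``exclude`` drops nations with any missing indicator (listwise, the
    default); ``impute-median`` fills each missing cell with the indicator's
    cohort median.
    """
    report = validate_table(table)
    if not report.missing_cells:
        return table
    data = table.data.copy()
    if table.config.missing_policy == "exclude":
        drop = set(report.nations_with_missing)
        log.info("excluding %d nation(s) with missing indicators: %s",
                 len(drop), sorted(drop))
        data = data[~data["nation_id"].isin(drop)].reset_index(drop=True)
    else:
        for col in table.indicator_names:
            med = data[col].median()
            n_fill = int(data[col].isna().sum())
            if n_fill:
                log.info("imputing %d cell(s) of %s with median %.4g",
                         n_fill, col, med)
                data[col] = data[col].fillna(med)
    return IndicatorTable(data, table.config)


RESULT_COLUMNS = [
    "nation_id", "model", "variant", "S", "E", "AC", "v_raw", "v", "rank",
]


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write vulnerability results as CSV, one row per nation x variant.

    Rows are ordered deterministically by (model, variant, rank, nation_id);
    columns follow :data:`RESULT_COLUMNS`.
    """
    if results.empty:
        raise ValueError("results collection is empty")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"results missing column(s): {missing}")
    path = Path(path)
    out = results[RESULT_COLUMNS].sort_values(
        ["model", "variant", "rank", "nation_id"]
    )
    out.to_csv(path, index=False)
    return path


def write_long_export(results: pd.DataFrame, path: str | Path) -> Path:
    """Long-format export keyed by nation_id, joinable to country boundaries."""
    long = results.melt(
        id_vars=["nation_id", "model", "variant"],
        value_vars=["S", "E", "AC", "v"],
        var_name="measure",
        value_name="score",
    ).sort_values(["nation_id", "model", "variant", "measure"])
    path = Path(path)
    long.to_csv(path, index=False)
    return path
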