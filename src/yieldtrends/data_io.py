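"""Reading, validating and writing long-format yield panels.

A panel is a delimited text file with one row per geographical unit and
year.  Column names are mapped through a :class:`Dialect`; presets ship for
FAOSTAT-like exports (``Area``/``Year``/``Value``) and AGRESTE-like exports
(``departement``/``annee``/``rendement``).  Yields are tonnes per hectare;
FAOSTAT's native hg/ha can be converted with ``scale=1e-4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "Dialect",
    "DIALECTS",
    "YieldPanel",
    "YieldSeries",
    "read_panel",
    "write_table",
]


class ConfigurationError(ValueError):
    """The file cannot be interpreted with the given dialect."""


class DataError(ValueError):
    """The file content violates a panel invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping (and unit scale) for a panel file."""

    unit: str = "unit"
    year: str = "year"
    value: str = "yield"
    #: multiplicative conversion applied to the value column; 1e-4 turns
    #: FAOSTAT's hg/ha into t/ha.
    scale: float = 1.0


DIALECTS: Mapping[str, Dialect] = {
    "generic": Dialect(),
    "faostat": Dialect(unit="Area", year="Year", value="Value"),
    "agreste": Dialect(unit="departement", year="annee", value="rendement"),
}


@dataclass
class YieldSeries:
    """One geographical unit's yearly yield observations.

    ``years`` are strictly increasing calendar years with no internal gaps
    (absent years are stored as NaN observations).  The internal model time
    index is ``t_index = years - years[0] + 1`` so that T = 1 at the first
    year of the series; calendar years are metadata only.
    """

    unit_id: str
    years: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.yields.shape:
            raise DataError(f"{self.unit_id}: years and yields must be equal-length 1-d arrays")
        if self.years.size == 0:
            raise DataError(f"{self.unit_id}: empty series")
        if np.any(np.diff(self.years) <= 0):
            raise DataError(f"{self.unit_id}: years must be strictly increasing")
        bad = np.isfinite(self.yields) & (self.yields <= 0)
        if np.any(bad):
            raise DataError(
                f"{self.unit_id}: non-positive yields at years {self.years[bad].tolist()}"
            )
        inf = np.isinf(self.yields)
        if np.any(inf):
            raise DataError(f"{self.unit_id}: non-finite yields at years {self.years[inf].tolist()}")

    @property
    def t_index(self) -> np.ndarray:
        """Model time index, T = 1 at the first year of the series."""
        return self.years - self.years[0] + 1

    @property
    def n_obs(self) -> int:
        """Number of non-missing observations."""
        return int(np.isfinite(self.yields).sum())

    def __len__(self) -> int:
        return self.years.size

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(t_index, yields) restricted to non-missing observations."""
        mask = np.isfinite(self.yields)
        return self.t_index[mask], self.yields[mask]

    def truncate(self, last_year: int) -> "YieldSeries":
        """The sub-series of all years ≤ ``last_year`` (same time origin)."""
        keep = self.years <= last_year
        if not keep.any():
            raise DataError(f"{self.unit_id}: no data at or before {last_year}")
        return YieldSeries(self.unit_id, self.years[keep], self.yields[keep])

    def t_of_year(self, year: int) -> int:
        """Model index T of a calendar year (extrapolation allowed)."""
        return int(year - self.years[0] + 1)


@dataclass
class YieldPanel:
    """A collection of :class:`YieldSeries` keyed by unit id."""

    series: dict[str, YieldSeries]
    label: str = "panel"

    def __post_init__(self) -> None:
        if not self.series:
            raise DataError("panel contains no series")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series.values())

    def unit_ids(self) -> list[str]:
        return list(self.series)

    def to_frame(self, dialect: Dialect | str = "generic") -> pd.DataFrame:
        d = _resolve_dialect(dialect)
        rows = []
        for s in self:
            for year, value in zip(s.years, s.yields):
                rows.append({d.unit: s.unit_id, d.year: int(year), d.value: value})
        return pd.DataFrame(rows)


def _resolve_dialect(dialect: Dialect | str | None) -> Dialect:
    if dialect is None:
        return DIALECTS["generic"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    return dialect


def read_panel(
    path,
    dialect: Dialect | str | None = None,
    *,
    label: str | None = None,
    delimiter: str | None = None,
) -> YieldPanel:
    """Read a long-format yield panel from a delimited text file.

    Rows with non-numeric or non-positive yield become missing observations.
    Years absent between a unit's first and last observed year are filled in
    as missing, so every series is gap-free on the calendar axis.  Duplicate
    (unit, year) rows are a :class:`DataError`.
    """
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing_cols = [c for c in (d.unit, d.year, d.value) if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"columns {missing_cols} not found in {path}; available: {list(df.columns)}"
        )
    df = df[[d.unit, d.year, d.value]].copy()
    df.columns = ["unit", "year", "value"]
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)

    dup = df.duplicated(["unit", "year"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["unit", "year"]].drop_duplicates().to_records(index=False)
        raise DataError(f"duplicate (unit, year) rows: {list(offending)}")

    values = pd.to_numeric(df["value"], errors="coerce") * d.scale
    values[values <= 0] = np.nan
    df["value"] = values

    series: dict[str, YieldSeries] = {}
    for unit, grp in df.groupby("unit", sort=True):
        grp = grp.sort_values("year")
        years = np.arange(grp["year"].iloc[0], grp["year"].iloc[-1] + 1)
        observed = grp.set_index("year")["value"].reindex(years)
        series[str(unit)] = YieldSeries(str(unit), years, observed.to_numpy())
    return YieldPanel(series, label=label or str(path))


def write_table(table: pd.DataFrame, path, *, decimals: int = 6) -> None:
    """Write a result table as CSV with fixed-precision floats."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table.to_csv(path, index=False, float_format=f"%.{decimals}f")
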