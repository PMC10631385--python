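"""Reading and writing mortality-rate surfaces.

Two on-disk formats are supported:

* the Human Mortality Database (HMD) ``Mx_1x1`` plain-text layout — header
  lines followed by whitespace-separated columns ``Year Age Female Male
  Total``, with ``.`` marking unavailable cells and the open age group coded
  ``110+``;
* a simple CSV dialect with an ``age`` column and one column per calendar
  year, cells holding central death rates (empty cell = missing).

Internally a surface stores *log* central death rates with years as rows and
ages as columns.  Rates that are zero or missing cannot be log-transformed and
are masked rather than imputed; downstream smoothing interpolates across
masked cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MortalitySurface", "read_hmd_mx", "read_csv_surface", "write_csv_surface"]

_HMD_SEX_COLUMNS = ("Female", "Male", "Total")


class SurfaceParseError(ValueError):
    """Raised when an input file cannot be parsed as a mortality surface."""


@dataclass
class MortalitySurface:
    """Observed log central death rates on an age x year grid.

    Attributes
    ----------
    population_id:
        Short label, e.g. ``"JPN_male"``.
    ages:
        Strictly increasing integer age grid (columns).
    years:
        Consecutive integer calendar years (rows).
    log_rates:
        ``(T, J)`` array of natural-log central death rates; masked entries
        hold ``nan``.
    missing_mask:
        ``(T, J)`` boolean array, ``True`` where the cell is unusable.
    """

    population_id: str
    ages: np.ndarray
    years: np.ndarray
    log_rates: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.log_rates)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        T, J = len(self.years), len(self.ages)
        if self.log_rates.shape != (T, J):
            raise ValueError(
                f"log_rates shape {self.log_rates.shape} does not match "
                f"{T} years x {J} ages"
            )
        if self.missing_mask.shape != (T, J):
            raise ValueError("missing_mask shape does not match log_rates")
        if len(np.unique(self.ages)) != J or np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be unique and strictly increasing")
        if T > 1 and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive integers")
        unmasked = self.log_rates[~self.missing_mask]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValueError("non-missing log rates must be finite")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_ages(self) -> int:
        return len(self.ages)


def _log_with_mask(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of rates; zero/negative/NaN cells are masked."""
    rates = np.asarray(rates, dtype=float)
    mask = ~np.isfinite(rates) | (rates <= 0.0)
    log_rates = np.full(rates.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rates[~mask] = np.log(rates[~mask])
    return log_rates, mask


def read_hmd_mx(
    path,
    population_id: str,
    sex_column: str = "Total",
    max_age: int = 100,
) -> MortalitySurface:
    """Read one sex column from an HMD ``Mx_1x1`` file.

    Ages above ``max_age`` are dropped (the HMD open age group ``110+`` is
    treated as age 110 before truncation).  Cells coded ``.`` or equal to
    zero are masked.
    """
    sex_column = sex_column.capitalize()
    if sex_column not in _HMD_SEX_COLUMNS:
        raise ValueError(f"sex_column must be one of {_HMD_SEX_COLUMNS}")

    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()

    header_idx = None
    for k, line in enumerate(lines):
        tokens = line.split()
        if tokens[:2] == ["Year", "Age"]:
            if not all(c in tokens for c in _HMD_SEX_COLUMNS):
                raise SurfaceParseError(
                    f"line {k + 1}: column header lacks Female/Male/Total"
                )
            header_idx = k
            columns = tokens
            break
    if header_idx is None:
        raise SurfaceParseError("no 'Year Age ...' column header found")

    records: list[tuple[int, int, str]] = []
    col = columns.index(sex_column)
    for k, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != len(columns):
            raise SurfaceParseError(f"line {k}: expected {len(columns)} fields")
        try:
            year = int(tokens[0])
        except ValueError as exc:
            raise SurfaceParseError(f"line {k}: non-numeric year {tokens[0]!r}") from exc
        age_tok = tokens[1]
        age = int(age_tok[:-1]) if age_tok.endswith("+") else int(age_tok)
        records.append((year, age, tokens[col]))

    if not records:
        raise SurfaceParseError("file contains no data rows")

    years = np.array(sorted({r[0] for r in records}))
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError("years in file are not consecutive")
    ages = np.array(sorted({r[1] for r in records if r[1] <= max_age}))

    year_pos = {y: i for i, y in enumerate(years)}
    age_pos = {a: j for j, a in enumerate(ages)}
    rates = np.full((len(years), len(ages)), np.nan)
    for year, age, tok in records:
        if age > max_age:
            continue
        if tok != ".":
            rates[year_pos[year], age_pos[age]] = float(tok)

    log_rates, mask = _log_with_mask(rates)
    return MortalitySurface(population_id, ages, years, log_rates, mask)


def read_csv_surface(path, population_id: str) -> MortalitySurface:
    """Read the package CSV dialect: column ``age``, one column per year."""
    df = pd.read_csv(path)
    if df.columns[0] != "age":
        raise SurfaceParseError("first CSV column must be named 'age'")
    year_cols = list(df.columns[1:])
    if not year_cols:
        raise ValueError("CSV has no year columns")
    try:
        years = np.array([int(c) for c in year_cols])
    except ValueError as exc:
        raise SurfaceParseError("year column names must be integers") from exc
    ages = df["age"].to_numpy()
    if len(np.unique(ages)) != len(ages):
        raise ValueError("duplicate age rows in CSV")
    order = np.argsort(ages)
    # rates are stored ages-as-rows on disk; transpose to years-as-rows
    rates = df[year_cols].to_numpy(dtype=float)[order].T
    log_rates, mask = _log_with_mask(rates)
    return MortalitySurface(population_id, ages[order], years, log_rates, mask)


def write_csv_surface(surface: MortalitySurface, path) -> None:
    """Write a surface in the package CSV dialect (rates, not log rates).

    Masked cells become empty fields; values survive a round trip through
    :func:`read_csv_surface` to 10 significant digits.
    """
    surface.validate()
    rates = np.exp(surface.log_rates)
    rates[surface.missing_mask] = np.nan
    df = pd.DataFrame(
        rates.T, index=pd.Index(surface.ages, name="age"), columns=surface.years
    )
    buf = io.StringIO()
    df.to_csv(buf, float_format="%.10g", na_rep="")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
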