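"""Reading, validation and standardization of annual ecosystem tables.

The pipeline consumes a single table of annual averages: one row per year,
one column per named ecosystem component (climate indices, physiochemical
pressures, production, population and stock-productivity series).  All
modeling happens on the standardized scale (each column rescaled to mean 0,
standard deviation 1), so this module also keeps the original per-column
moments, which are needed later to convert physical-unit temperature
perturbations into model units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = frozenset(
    {
        "climate",
        "physiochemical",
        "primary_production",
        "population_estimate",
        "stock_productivity",
    }
)

YEAR_COLUMN = "year"


@dataclass(frozen=True)
class VariableDescriptor:
    """Metadata for one ecosystem component (one table column).

    Parameters
    ----------
    name
        Unique column name.
    category
        One of ``climate``, ``physiochemical``, ``primary_production``,
        ``population_estimate``, ``stock_productivity``.
    sst_region_flag
        True for the regional sea-surface-temperature series (the press-
        perturbation targets).  Implies ``category == "climate"``.
    predicted_flag
        True for the components whose one-step-ahead predictions are scored
        in the model comparison.  Always False for climate and
        physiochemical drivers (those are inputs, not prediction targets).
    """

    name: str
    category: str
    sst_region_flag: bool = False
    predicted_flag: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for variable {self.name!r};"
                f" expected one of {sorted(CATEGORIES)}"
            )
        if self.sst_region_flag and self.category != "climate":
            raise ValueError(
                f"sst_region_flag requires category='climate' (variable {self.name!r})"
            )
        if self.predicted_flag and self.category in ("climate", "physiochemical"):
            raise ValueError(
                f"climate/physiochemical variable {self.name!r} cannot be a "
                "prediction target"
            )


@dataclass(frozen=True)
class EcosystemTable:
    """Years × variables matrix with explicit missingness and metadata.

    ``data`` is a float DataFrame indexed by year (strictly increasing
    integers); missing entries are NaN and are never silently imputed.
    """

    data: pd.DataFrame
    descriptors: tuple[VariableDescriptor, ...]

    def __post_init__(self) -> None:
        years = np.asarray(self.data.index)
        if len(years) < 3:
            raise ValueError("need at least 3 years")
        if not np.issubdtype(years.dtype, np.integer):
            raise ValueError("year index must be integer")
        if np.any(np.diff(years) <= 0):
            raise ValueError("non-monotone years")
        names = list(self.data.columns)
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable name")
        desc_names = [d.name for d in self.descriptors]
        if sorted(desc_names) != sorted(names):
            raise ValueError(
                "descriptors do not match table columns: "
                f"{sorted(desc_names)} vs {sorted(names)}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data.index)

    @property
    def n_years(self) -> int:
        return len(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Years × variables float matrix, NaN where missing."""
        return self.data.to_numpy(dtype=float)

    def descriptor(self, name: str) -> VariableDescriptor:
        for d in self.descriptors:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def predicted_variables(self) -> list[str]:
        return [d.name for d in self.descriptors if d.predicted_flag]

    @property
    def sst_variables(self) -> list[str]:
        return [d.name for d in self.descriptors if d.sst_region_flag]

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def with_data(self, data: pd.DataFrame) -> "EcosystemTable":
        return replace(self, data=data)


@dataclass(frozen=True)
class StandardizationParams:
    """Original-unit mean and standard deviation per column.

    Applying :func:`standardize` then :func:`inverse_standardize` with the
    returned params is the identity (to numerical tolerance).
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"standard deviation must be positive ({name!r}: {s})")
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd cover different variables")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": dict(self.mean),
            "sd": dict(self.sd),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(mean=payload["mean"], sd=payload["sd"])


def _default_descriptors(names: Iterable[str]) -> tuple[VariableDescriptor, ...]:
    # Without a schema every column is treated as a predictable population
    # estimate; callers doing real analyses should pass explicit descriptors.
    return tuple(
        VariableDescriptor(name=n, category="population_estimate", predicted_flag=True)
        for n in names
    )


def _validate_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.columns[0] != YEAR_COLUMN:
        raise ValueError(f"{source}: first column must be {YEAR_COLUMN!r}, got {df.columns[0]!r}")
    var_names = list(df.columns[1:])
    if len(set(var_names)) != len(var_names):
        dupes = sorted({n for n in var_names if var_names.count(n) > 1})
        raise ValueError(f"{source}: duplicate variable name {dupes}")
    years = df[YEAR_COLUMN]
    try:
        years = years.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: non-integer year column") from exc
    if np.any(np.diff(years.to_numpy()) <= 0):
        raise ValueError(f"{source}: non-monotone years")
    body = df[var_names]
    for col in var_names:
        try:
            pd.to_numeric(body[col])
        except (TypeError, ValueError) as exc:
            bad = body[col][pd.to_numeric(body[col], errors="coerce").isna() & body[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{source}: non-numeric cell in column {col!r}, row {row}"
            ) from exc
    out = body.apply(pd.to_numeric).astype(float)
    out.index = pd.Index(years.to_numpy(), name=YEAR_COLUMN)
    return out


def read_table(
    path: str | Path,
    schema: Sequence[VariableDescriptor] | None = None,
) -> EcosystemTable:
    """Read an annual ecosystem table from CSV.

    The file must have a ``year`` first column and one named column per
    variable.  Blank cells become explicit missing entries.  When a
    ``schema`` is given, the file's variable set must match it exactly
    (unknown columns are rejected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    body = _validate_frame(df, str(path))
    return _attach_schema(body, schema, str(path))


def read_table_xlsx(
    path: str | Path,
    schema: Sequence[VariableDescriptor] | None = None,
    sheet: int | str = 0,
) -> EcosystemTable:
    """Read a single-sheet XLSX table laid out like the CSV format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_excel(path, sheet_name=sheet)
    body = _validate_frame(df, str(path))
    return _attach_schema(body, schema, str(path))


def _attach_schema(
    body: pd.DataFrame,
    schema: Sequence[VariableDescriptor] | None,
    source: str,
) -> EcosystemTable:
    if schema is None:
        descriptors = _default_descriptors(body.columns)
    else:
        by_name = {d.name: d for d in schema}
        unknown = [c for c in body.columns if c not in by_name]
        if unknown:
            raise ValueError(f"{source}: unknown columns {unknown} not in schema")
        missing = [n for n in by_name if n not in body.columns]
        if missing:
            raise ValueError(f"{source}: schema variables {missing} absent from file")
        descriptors = tuple(by_name[c] for c in body.columns)
    return EcosystemTable(data=body, descriptors=descriptors)


def write_table(table: EcosystemTable, path: str | Path) -> None:
    """Write the table as CSV with a ``year`` first column."""
    out = table.data.copy()
    out.insert(0, YEAR_COLUMN, table.years)
    out.to_csv(path, index=False)


def schema_to_json(
    descriptors: Sequence[VariableDescriptor], path: str | Path
) -> None:
    """Serialize variable descriptors (categories and flags) as JSON."""
    payload = [
        {
            "name": d.name,
            "category": d.category,
            "sst_region_flag": d.sst_region_flag,
            "predicted_flag": d.predicted_flag,
        }
        for d in descriptors
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def schema_from_json(path: str | Path) -> tuple[VariableDescriptor, ...]:
    payload = json.loads(Path(path).read_text())
    return tuple(VariableDescriptor(**d) for d in payload)


def standardize(table: EcosystemTable) -> tuple[EcosystemTable, StandardizationParams]:
    """Rescale every column to mean 0, sd 1 over its non-missing entries.

    Uses the sample standard deviation (n−1 denominator).  Missing entries
    are excluded from the moments and stay missing in the output.  The
    returned params hold each column's original mean and sd.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    out = table.data.copy()
    for col in table.columns:
        x = table.data[col]
        n_obs = int(x.notna().sum())
        if n_obs < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        m = float(x.mean())
        s = float(x.std(ddof=1))
        if not s > 0:
            raise ValueError(f"cannot standardize constant column {col!r}")
        means[col] = m
        sds[col] = s
        out[col] = (x - m) / s
    params = StandardizationParams(mean=means, sd=sds)
    return table.with_data(out), params


def inverse_standardize(
    table: EcosystemTable, params: StandardizationParams
) -> EcosystemTable:
    """Map standardized values back to original units: v ↦ v·sd + mean."""
    missing = [c for c in table.columns if c not in params.mean]
    if missing:
        raise ValueError(f"no standardization params for columns {missing}")
    out = table.data.copy()
    for col in table.columns:
        out[col] = table.data[col] * params.sd[col] + params.mean[col]
    return table.with_data(out)
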