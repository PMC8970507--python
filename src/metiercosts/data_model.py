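"""Tabular data layouts, validation and I/O.

Four flat CSV layouts are supported, mirroring the concepts of the EU Data
Collection Framework (DCF) and the Fishery Dependent Information (FDI)
dissemination:

``trips``
    one row per fishing trip of an individual vessel (vessel id, year,
    fleet segment, métier, hours at sea, fishing days, engine kW, landings
    weight and value);
``vessel_costs``
    one row per vessel-year with the annual variable costs (fuel cost,
    fuel consumption, labour cost, other variable costs);
``segment_costs``
    official aggregate variable costs in long form, one row per
    (year, fleet segment, variable name);
``transversal``
    effort and landings value per (year, fleet segment, métier).

Headers are matched case-insensitively and can be renamed through a
column-mapping config.  Validation is total: every input row is either
accepted or listed in the rejection log with a reason.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ValidationReport",
    "InputTables",
    "COST_VARIABLES",
    "read_trips",
    "read_vessel_costs",
    "read_segment_costs",
    "read_transversal",
    "read_tables",
    "write_report",
]

#: canonical names of the variable-cost series handled by the pipeline
COST_VARIABLES = ("fuel_cost", "fuel_consumption", "labour_cost", "other_variable")

#: accepted spellings of the variable_name key in the segment-costs layout
_SEGMENT_VARIABLE_ALIASES = {
    "fuel_costs": "fuel_cost",
    "fuel_cost": "fuel_cost",
    "fuel_consumption": "fuel_consumption",
    "labour_costs": "labour_cost",
    "labour_cost": "labour_cost",
    "labor_costs": "labour_cost",
    "labor_cost": "labour_cost",
    "other": "other_variable",
    "other_variable": "other_variable",
    "other_variable_costs": "other_variable",
}

TRIP_COLUMNS = {
    "required": [
        "vessel_id",
        "year",
        "fleet_segment",
        "metier",
        "hours_at_sea",
        "fishing_days",
        "kw",
    ],
    "optional": ["landings_weight", "landings_value"],
}
VESSEL_COST_COLUMNS = {
    "required": ["vessel_id", "year", "fuel_cost", "fuel_consumption", "labour_cost"],
    "optional": ["other_variable_costs"],
}
SEGMENT_COST_COLUMNS = {
    "required": ["year", "fleet_segment", "variable_name", "value"],
    "optional": [],
}
TRANSVERSAL_COLUMNS = {
    "required": ["year", "fleet_segment", "metier", "effort_hours", "landings_value"],
    "optional": ["effort_dayskw"],
}


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class ValidationError(ValueError):
    """An input table violates a structural invariant (e.g. duplicate keys)."""


@dataclass
class ValidationReport:
    """Accounting of accepted and rejected rows for one table."""

    table: str
    n_read: int = 0
    n_accepted: int = 0
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        return (
            f"{self.table}: read {self.n_read}, accepted {self.n_accepted}, "
            f"rejected {self.n_rejected}"
        )


@dataclass
class InputTables:
    """The four validated input tables plus their validation reports."""

    trips: pd.DataFrame
    vessel_costs: pd.DataFrame
    segment_costs: pd.DataFrame
    transversal: pd.DataFrame
    reports: dict[str, ValidationReport] = field(default_factory=dict)


def _normalise_columns(
    df: pd.DataFrame,
    spec: Mapping[str, list[str]],
    table: str,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Lower-case headers, apply the user column mapping, check required ones."""
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        renames = {str(src).strip().lower(): dst for src, dst in column_map.items()}
        df = df.rename(columns=renames)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table}: missing required column(s): {', '.join(sorted(missing))}"
        )
    keep = [c for c in spec["required"] + spec["optional"] if c in df.columns]
    return df[keep]


def _coerce_numeric(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _reject(mask: pd.Series, reason: str, log: list[tuple[int, str]]) -> pd.Series:
    for idx in mask[mask].index:
        log.append((int(idx), reason))
    return ~mask


def read_trips(
    source, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate the trip-level activity table.

    Rows with a negative effort or landings figure are rejected; a missing
    ``landings_value`` is kept as NaN so the row still serves the fuel-side
    analyses (each analysis drops its own missing values).
    """
    raw = pd.read_csv(source)
    df = _normalise_columns(raw, TRIP_COLUMNS, "trips", column_map)
    df = _coerce_numeric(
        df, ["year", "hours_at_sea", "fishing_days", "kw", "landings_weight", "landings_value"]
    )
    report = ValidationReport("trips", n_read=len(df))
    log: list[tuple[int, str]] = []
    ok = pd.Series(True, index=df.index)
    ok &= _reject(df["vessel_id"].isna(), "missing vessel_id", log)
    ok &= _reject(df["year"].isna(), "missing or non-numeric year", log)
    ok &= _reject(df["metier"].isna(), "missing metier", log)
    ok &= _reject(df["fleet_segment"].isna(), "missing fleet_segment", log)
    ok &= _reject(df["hours_at_sea"].isna() | (df["hours_at_sea"] < 0), "hours_at_sea missing or negative", log)
    ok &= _reject(df["fishing_days"].isna() | (df["fishing_days"] < 0), "fishing_days missing or negative", log)
    ok &= _reject(df["kw"].isna() | (df["kw"] <= 0), "kw missing or non-positive", log)
    for col in ("landings_weight", "landings_value"):
        if col in df.columns:
            ok &= _reject(df[col] < 0, f"{col} negative", log)
    out = df[ok].copy()
    out["year"] = out["year"].astype(int)
    out["vessel_id"] = out["vessel_id"].astype(str)

    # a vessel must sit in exactly one fleet segment within a year
    seg_counts = out.groupby(["vessel_id", "year"])["fleet_segment"].nunique()
    bad_keys = set(seg_counts[seg_counts > 1].index)
    if bad_keys:
        mask = out.set_index(["vessel_id", "year"]).index.isin(bad_keys)
        mask = pd.Series(mask, index=out.index)
        _reject(mask, "fleet_segment not constant within vessel-year", log)
        out = out[~mask]

    report.n_accepted = len(out)
    report.rejections = pd.DataFrame(log, columns=["row", "reason"])
    return out.reset_index(drop=True), report


def read_vessel_costs(
    source, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate annual per-vessel variable costs.

    Duplicate (vessel_id, year) keys raise :class:`ValidationError` — the
    layout admits at most one record per vessel-year.
    """
    raw = pd.read_csv(source)
    df = _normalise_columns(raw, VESSEL_COST_COLUMNS, "vessel_costs", column_map)
    df = _coerce_numeric(
        df, ["year", "fuel_cost", "fuel_consumption", "labour_cost", "other_variable_costs"]
    )
    report = ValidationReport("vessel_costs", n_read=len(df))
    log: list[tuple[int, str]] = []
    ok = pd.Series(True, index=df.index)
    ok &= _reject(df["vessel_id"].isna(), "missing vessel_id", log)
    ok &= _reject(df["year"].isna(), "missing or non-numeric year", log)
    for col in ("fuel_cost", "fuel_consumption", "labour_cost", "other_variable_costs"):
        if col in df.columns:
            ok &= _reject(df[col] < 0, f"{col} negative", log)
    out = df[ok].copy()
    out["year"] = out["year"].astype(int)
    out["vessel_id"] = out["vessel_id"].astype(str)
    dup = out.duplicated(subset=["vessel_id", "year"], keep=False)
    if dup.any():
        keys = out.loc[dup, ["vessel_id", "year"]].drop_duplicates()
        pairs = ", ".join(f"({r.vessel_id}, {r.year})" for r in keys.itertuples())
        raise ValidationError(f"vessel_costs: duplicate vessel-year record(s): {pairs}")
    report.n_accepted = len(out)
    report.rejections = pd.DataFrame(log, columns=["row", "reason"])
    return out.reset_index(drop=True), report


def read_segment_costs(
    source, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read official aggregate variable costs by fleet segment and year."""
    raw = pd.read_csv(source)
    df = _normalise_columns(raw, SEGMENT_COST_COLUMNS, "segment_costs", column_map)
    df = _coerce_numeric(df, ["year", "value"])
    report = ValidationReport("segment_costs", n_read=len(df))
    log: list[tuple[int, str]] = []
    ok = pd.Series(True, index=df.index)
    ok &= _reject(df["year"].isna(), "missing or non-numeric year", log)
    ok &= _reject(df["fleet_segment"].isna(), "missing fleet_segment", log)
    variable = (
        df["variable_name"].astype(str).str.strip().str.lower().map(_SEGMENT_VARIABLE_ALIASES)
    )
    ok &= _reject(variable.isna(), "unknown variable_name", log)
    ok &= _reject(df["value"].isna() | (df["value"] < 0), "value missing or negative", log)
    out = df[ok].copy()
    out["variable_name"] = variable[ok]
    out["year"] = out["year"].astype(int)
    dup = out.duplicated(subset=["year", "fleet_segment", "variable_name"], keep=False)
    if dup.any():
        raise ValidationError(
            "segment_costs: duplicate (year, fleet_segment, variable_name) key(s)"
        )
    report.n_accepted = len(out)
    report.rejections = pd.DataFrame(log, columns=["row", "reason"])
    return out.reset_index(drop=True), report


def read_transversal(
    source, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read FDI-style effort/landings by fleet segment × métier × year."""
    raw = pd.read_csv(source)
    df = _normalise_columns(raw, TRANSVERSAL_COLUMNS, "transversal", column_map)
    df = _coerce_numeric(df, ["year", "effort_hours", "effort_dayskw", "landings_value"])
    report = ValidationReport("transversal", n_read=len(df))
    log: list[tuple[int, str]] = []
    ok = pd.Series(True, index=df.index)
    ok &= _reject(df["year"].isna(), "missing or non-numeric year", log)
    ok &= _reject(df["fleet_segment"].isna(), "missing fleet_segment", log)
    ok &= _reject(df["metier"].isna(), "missing metier", log)
    ok &= _reject(
        df["effort_hours"].isna() | (df["effort_hours"] < 0),
        "effort_hours missing or negative",
        log,
    )
    ok &= _reject(
        df["landings_value"].isna() | (df["landings_value"] < 0),
        "landings_value missing or negative",
        log,
    )
    out = df[ok].copy()
    out["year"] = out["year"].astype(int)
    dup = out.duplicated(subset=["year", "fleet_segment", "metier"], keep=False)
    if dup.any():
        raise ValidationError("transversal: duplicate (year, fleet_segment, metier) key(s)")
    report.n_accepted = len(out)
    report.rejections = pd.DataFrame(log, columns=["row", "reason"])
    return out.reset_index(drop=True), report


def read_tables(
    trips_path,
    vessel_costs_path,
    segment_costs_path,
    transversal_path,
    column_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> InputTables:
    """Read and validate all four input tables.

    ``column_maps`` may hold one source→canonical rename mapping per table
    (keys ``trips``, ``vessel_costs``, ``segment_costs``, ``transversal``).
    """
    column_maps = column_maps or {}
    trips, r1 = read_trips(trips_path, column_maps.get("trips"))
    costs, r2 = read_vessel_costs(vessel_costs_path, column_maps.get("vessel_costs"))
    seg, r3 = read_segment_costs(segment_costs_path, column_maps.get("segment_costs"))
    trans, r4 = read_transversal(transversal_path, column_maps.get("transversal"))
    return InputTables(
        trips=trips,
        vessel_costs=costs,
        segment_costs=seg,
        transversal=trans,
        reports={r.table: r for r in (r1, r2, r3, r4)},
    )


# deterministic sort keys per result table name
_SORT_KEYS = {
    "regressions": ["fleet_segment", "metier", "cost_variable", "transversal"],
    "glm_terms": ["fleet_segment", "cost_variable", "equation", "term"],
    "model_selection": ["fleet_segment", "cost_variable"],
    "disaggregated_costs": ["year", "fleet_segment", "metier", "cost_variable"],
    "consistency_check": ["year", "fleet_segment", "cost_variable"],
    "coverage": ["fleet_segment", "metier"],
    "observations": ["fleet_segment", "vessel_id", "year"],
}


def write_report(results: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table to ``<out_dir>/<name>.csv``.

    Column order follows each DataFrame; rows are sorted on the table's
    natural key so re-running with identical inputs yields byte-identical
    files.  Empty tables produce headers-only CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        df = results[name]
        keys = [k for k in _SORT_KEYS.get(name, []) if k in df.columns]
        if keys and len(df):
            df = df.sort_values(keys, kind="mergesort")
        path = out / f"{name}.csv"
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\n")
        path.write_text(buf.getvalue())
        written.append(path)
    return written
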