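"""Phase 2: disaggregate official segment costs to métier level and reconcile.

The coefficients fitted on individual vessel data are applied to the
publicly available transversal table (effort and landings value by fleet
segment × métier × year).  With métier intercepts the métier's cost is
``α_m + slope_m · X_m``; with the proportional model it is ``α · X_m``.
Summing the métier estimates within a segment-year and comparing against
the official segment total gives the consistency check: the signed relative
difference per row and the mean absolute relative difference overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import EQ3, ModelSelection

__all__ = [
    "TRANSVERSAL_SOURCES",
    "ConsistencyReport",
    "disaggregate",
    "consistency_check",
]

logger = logging.getLogger(__name__)

#: which transversal-table column feeds each model regressor
TRANSVERSAL_SOURCES = {
    "effort_hours": "effort_hours",
    "effort_dayskw": "effort_dayskw",
    "revenue": "landings_value",
    # net-revenue regressors are observable only on sampled vessels; at the
    # aggregate level the landings value is the closest available carrier
    "revenue_minus_fuel": "landings_value",
    "revenue_minus_variable": "landings_value",
}

DISAGGREGATED_COLUMNS = [
    "year",
    "fleet_segment",
    "metier",
    "cost_variable",
    "estimated_value",
    "equation_used",
    "transversal_value",
]


def disaggregate(
    selection: ModelSelection,
    transversal: pd.DataFrame,
    fallback: str = "pooled",
    pooled_slopes: dict[tuple[str, str], float] | None = None,
    scale_intercepts_by_vessel_count: bool = False,
    vessel_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Estimate métier-level costs for one fleet segment and cost type.

    Parameters
    ----------
    selection
        A selected model (``chosen_equation`` must not be ``"none"``).
    transversal
        FDI-style rows for the segment (year, fleet_segment, metier,
        effort_hours, effort_dayskw, landings_value); other segments'
        rows are ignored.
    fallback
        Policy for métiers present in the transversal table but absent from
        the fitted model: ``"pooled"`` applies the segment's pooled
        zero-intercept slope (requires ``pooled_slopes``); ``"skip"`` leaves
        them unallocated, which is what drives part of the reconciliation
        gap when only the dominant métiers were modelled.
    pooled_slopes
        ``(fleet_segment, cost_variable) → slope`` from the exploratory
        ``ALL`` regressions, used by the pooled fallback.
    scale_intercepts_by_vessel_count
        Multiply each métier intercept by the number of active vessels in
        the métier-year (off by default: the intercepts are applied once per
        métier, as estimated).  Requires ``vessel_counts`` with columns
        (year, fleet_segment, metier, n_vessels).
    """
    if not selection.selected:
        raise ValueError("no equation was selected; nothing to disaggregate")
    if fallback not in ("pooled", "skip"):
        raise ValueError(f"unknown fallback policy: {fallback!r}")
    if scale_intercepts_by_vessel_count and vessel_counts is None:
        raise ValueError("vessel_counts table required to scale intercepts")

    fit = selection.fit
    source = TRANSVERSAL_SOURCES[selection.chosen_transversal]
    seg = selection.fleet_segment
    rows = transversal[transversal["fleet_segment"] == seg]
    if source not in rows.columns or rows[source].isna().any():
        raise ValueError(
            f"transversal column {source!r} missing or incomplete for segment {seg}"
        )
    intercepts = fit.intercepts()
    slopes = fit.slopes()
    counts = None
    if scale_intercepts_by_vessel_count:
        counts = vessel_counts.set_index(["year", "fleet_segment", "metier"])["n_vessels"]

    out = []
    for r in rows.itertuples():
        x = float(getattr(r, source))
        metier = r.metier
        if selection.chosen_equation == EQ3:
            est = slopes[next(iter(slopes))] * x if slopes else float(fit.params.iloc[0]) * x
            eq_used = EQ3
        elif metier in slopes:
            a = intercepts[metier]
            if counts is not None:
                a *= float(counts.get((r.year, seg, metier), 1.0))
            est = a + slopes[metier] * x
            eq_used = selection.chosen_equation
        elif fallback == "pooled":
            key = (seg, selection.cost_variable)
            if pooled_slopes is None or key not in pooled_slopes:
                raise ValueError(
                    f"pooled fallback requested but no pooled slope for {key}"
                )
            est = pooled_slopes[key] * x
            eq_used = "pooled"
            logger.info("métier %s not in model; pooled slope applied", metier)
        else:
            logger.info("métier %s not in model; skipped", metier)
            continue
        out.append(
            {
                "year": int(r.year),
                "fleet_segment": seg,
                "metier": metier,
                "cost_variable": selection.cost_variable,
                "estimated_value": est,
                "equation_used": eq_used,
                "transversal_value": x,
            }
        )
    return pd.DataFrame(out, columns=DISAGGREGATED_COLUMNS)


@dataclass
class ConsistencyReport:
    """Reconciliation of métier-level estimates against official totals."""

    table: pd.DataFrame  # per (year, fleet_segment, cost_variable)
    overall_abs_relative_difference: float  # percent

    def __str__(self) -> str:  # pragma: no cover - convenience
        return (
            f"consistency check over {len(self.table)} segment-year rows: "
            f"overall |relative difference| = "
            f"{self.overall_abs_relative_difference:.1f}%"
        )


def consistency_check(
    disaggregated: pd.DataFrame, segment_costs: pd.DataFrame
) -> ConsistencyReport:
    """Compare summed métier estimates with the official segment costs.

    For each (year, fleet_segment, cost_variable) the signed relative
    difference ``(Σ_m estimate_m − official) / official`` is reported; the
    overall statistic is the mean of the absolute relative differences, in
    percent.  Rows whose official value is zero are flagged and excluded
    from the overall mean.
    """
    sums = (
        disaggregated.groupby(["year", "fleet_segment", "cost_variable"], sort=True)[
            "estimated_value"
        ]
        .sum()
        .rename("sum_costs_by_metier")
        .reset_index()
    )
    official = segment_costs.rename(
        columns={"variable_name": "cost_variable", "value": "costs_by_fleet_segment"}
    )[["year", "fleet_segment", "cost_variable", "costs_by_fleet_segment"]]
    merged = sums.merge(official, on=["year", "fleet_segment", "cost_variable"], how="left")
    missing = merged["costs_by_fleet_segment"].isna()
    if missing.any():
        keys = merged.loc[missing, ["year", "fleet_segment", "cost_variable"]]
        raise ValueError(
            "no official segment cost for: "
            + "; ".join(f"{r.year}/{r.fleet_segment}/{r.cost_variable}" for r in keys.itertuples())
        )
    zero = merged["costs_by_fleet_segment"] == 0
    if zero.any():
        logger.warning(
            "%d row(s) with official value 0 excluded from the overall statistic",
            int(zero.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["relative_difference"] = (
            merged["sum_costs_by_metier"] - merged["costs_by_fleet_segment"]
        ) / merged["costs_by_fleet_segment"]
    merged.loc[zero, "relative_difference"] = np.nan
    merged["flagged_zero_official"] = zero
    usable = merged.loc[~zero, "relative_difference"]
    overall = float(usable.abs().mean() * 100.0) if len(usable) else float("nan")
    return ConsistencyReport(table=merged, overall_abs_relative_difference=overall)
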