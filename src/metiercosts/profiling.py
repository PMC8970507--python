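"""Phase-1 preprocessing: prevalent-métier profiling of individual vessels.

Variable costs are collected once per vessel-year while fishing activity is
recorded per trip and métier.  To obtain métier-resolved cost observations
each vessel-year is attributed to its *prevalent métier* — the métier
accounting for the largest share of its activity — and every cost and
transversal total is scaled by that métier's activity share (a vessel whose
prevalent métier covers 75% of its activity contributes 75% of its fuel
bill, labour cost, effort and revenue).  Activity attributable to the other,
less relevant métiers is discarded.

Within each fleet segment only the métiers that jointly cover a configurable
share of the observed vessels (80% by default) are retained for model
fitting, to avoid spurious relationships driven by a handful of vessels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_METRICS",
    "assign_prevalent_metier",
    "build_observations",
    "filter_by_coverage",
]

logger = logging.getLogger(__name__)

#: usable measures of fishing activity for prevalence
ACTIVITY_METRICS = ("hours_at_sea", "fishing_days", "trip_count")

#: columns of the MetierObservation table
OBSERVATION_COLUMNS = [
    "vessel_id",
    "year",
    "fleet_segment",
    "prevalent_metier",
    "activity_share",
    "hours_at_sea",
    "effort_dayskw",
    "revenue",
    "fuel_cost_adj",
    "fuel_consumption_adj",
    "labour_cost_adj",
    "other_variable_adj",
]


@dataclass
class CoverageRow:
    fleet_segment: str
    metier: str
    n_observations: int
    cumulative_share: float
    retained: bool


def assign_prevalent_metier(
    trips: pd.DataFrame, activity_metric: str = "hours_at_sea"
) -> tuple[str, float]:
    """Prevalent métier and activity share for one vessel-year's trips.

    Parameters
    ----------
    trips
        Trip rows of a single vessel-year (``metier`` plus the activity
        columns).
    activity_metric
        ``hours_at_sea``, ``fishing_days`` or ``trip_count``.

    Returns
    -------
    (metier, share)
        The métier with the largest summed activity and its fraction of the
        vessel-year total.  Exact ties go to the lexicographically smaller
        métier code (logged).
    """
    if activity_metric not in ACTIVITY_METRICS:
        raise ValueError(f"unknown activity metric: {activity_metric!r}")
    if len(trips) == 0:
        raise ValueError("no trips for vessel-year")
    if activity_metric == "trip_count":
        totals = trips.groupby("metier").size().astype(float)
    else:
        totals = trips.groupby("metier")[activity_metric].sum()
    grand_total = float(totals.sum())
    if grand_total <= 0:
        raise ValueError("no measurable activity in vessel-year trips")
    top = totals[totals == totals.max()]
    if len(top) > 1:
        logger.info(
            "prevalence tie between %s; choosing lexicographically smallest",
            ", ".join(sorted(top.index)),
        )
    metier = sorted(top.index)[0]
    return metier, float(totals[metier]) / grand_total


def build_observations(
    trips: pd.DataFrame,
    vessel_costs: pd.DataFrame,
    activity_metric: str = "hours_at_sea",
) -> pd.DataFrame:
    """Build the métier-resolved observation table (one row per vessel-year).

    Each vessel-year present in both tables yields one observation carrying
    its prevalent métier, the activity share of that métier, and the raw
    costs *and* transversal totals (hours, days×kW, revenue) multiplied by
    the share.  The proportional adjustment is applied to the transversal
    totals as well as the costs so the regressions relate like with like
    (logged).

    Vessel-years with cost records but no trips are excluded with a warning.
    """
    logger.info(
        "proportional adjustment by activity share applied to costs and to "
        "transversal totals (hours, days-kW, revenue)"
    )
    if "landings_value" not in trips.columns:
        trips = trips.assign(landings_value=np.nan)
    cost_keys = set(zip(vessel_costs["vessel_id"], vessel_costs["year"]))
    rows = []
    for (vessel, year), vtrips in trips.groupby(["vessel_id", "year"], sort=True):
        if (vessel, year) not in cost_keys:
            continue
        metier, share = assign_prevalent_metier(vtrips, activity_metric)
        dayskw = float((vtrips["fishing_days"] * vtrips["kw"]).sum())
        # revenue is only known when every trip's landings value is; a
        # partial sum would bias the labour-side analyses downwards
        revenue = (
            float(vtrips["landings_value"].sum())
            if vtrips["landings_value"].notna().all()
            else np.nan
        )
        rows.append(
            {
                "vessel_id": vessel,
                "year": year,
                "fleet_segment": vtrips["fleet_segment"].iloc[0],
                "prevalent_metier": metier,
                "activity_share": share,
                "hours_at_sea": float(vtrips["hours_at_sea"].sum()) * share,
                "effort_dayskw": dayskw * share,
                "revenue": revenue * share,
            }
        )
    obs = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS[:8])

    trip_keys = set(zip(trips["vessel_id"], trips["year"]))
    orphans = cost_keys - trip_keys
    if orphans:
        logger.warning(
            "%d vessel-year cost record(s) have no trips and were excluded", len(orphans)
        )

    costs = vessel_costs.set_index(["vessel_id", "year"])
    if "other_variable_costs" not in costs.columns:
        costs["other_variable_costs"] = np.nan
    if len(obs) == 0:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    idx = pd.MultiIndex.from_frame(obs[["vessel_id", "year"]])
    share = obs["activity_share"].to_numpy()
    for src, dst in [
        ("fuel_cost", "fuel_cost_adj"),
        ("fuel_consumption", "fuel_consumption_adj"),
        ("labour_cost", "labour_cost_adj"),
        ("other_variable_costs", "other_variable_adj"),
    ]:
        obs[dst] = costs[src].reindex(idx).to_numpy() * share
    return obs[OBSERVATION_COLUMNS]


def _prefix_pass(counts: pd.Series, threshold: float) -> list[str]:
    """One application of the smallest-prefix rule on ranked counts."""
    total = counts.sum()
    kept, cum = [], 0
    for metier, n in counts.items():
        kept.append(metier)
        cum += int(n)
        if cum / total >= threshold:
            break
    return kept


def _prefix_fixpoint(counts: pd.Series, threshold: float) -> set[str]:
    """Iterate the prefix rule until the retained métier set is stable."""
    current = counts
    while True:
        kept = _prefix_pass(current, threshold)
        if len(kept) == len(current):
            return set(kept)
        current = current.loc[kept]


def filter_by_coverage(
    observations: pd.DataFrame,
    threshold: float = 0.8,
    per_segment: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain, per fleet segment, the métiers covering ``threshold`` of observations.

    Métiers are ranked by descending observation count (vessels whose
    prevalent métier it is); the smallest prefix whose cumulative count
    share reaches the segment's threshold is retained and all observations
    of other métiers are dropped.  Count ties rank lexicographically for
    determinism.  The prefix rule is applied repeatedly until the retained
    set is stable, which makes the filter idempotent (a second application
    is the identity); on typical fleet data the first pass is already the
    fixpoint.

    Returns
    -------
    (retained, coverage)
        The filtered observation table and a coverage table with one row per
        (fleet_segment, metier) recording counts, cumulative share (over the
        segment's original observations) and the retained flag.
    """
    per_segment = per_segment or {}
    for name, thr in [("threshold", threshold), *per_segment.items()]:
        if not (0 < thr <= 1):
            raise ValueError(f"coverage threshold out of (0, 1]: {name}={thr}")
    cov_rows: list[CoverageRow] = []
    keep_keys: set[tuple[str, str]] = set()
    for segment, seg_obs in observations.groupby("fleet_segment", sort=True):
        thr = per_segment.get(segment, threshold)
        counts = (
            seg_obs.groupby("prevalent_metier")
            .size()
            .sort_index()
            .sort_values(ascending=False, kind="mergesort")
        )
        total = int(counts.sum())
        if total == 0:
            logger.warning("fleet segment %s has no observations", segment)
            continue
        retained_metiers = _prefix_fixpoint(counts, thr)
        keep_keys.update((segment, m) for m in retained_metiers)
        cum = 0
        for metier, n in counts.items():
            cum += int(n)
            cov_rows.append(
                CoverageRow(segment, metier, int(n), cum / total, metier in retained_metiers)
            )
    coverage = pd.DataFrame(
        [vars(r) for r in cov_rows],
        columns=["fleet_segment", "metier", "n_observations", "cumulative_share", "retained"],
    )
    if len(observations) == 0:
        return observations.copy(), coverage
    mask = [
        (seg, met) in keep_keys
        for seg, met in zip(observations["fleet_segment"], observations["prevalent_metier"])
    ]
    return observations[mask].reset_index(drop=True), coverage
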