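"""End-to-end pipeline: observations → exploratory analysis → GLM selection
→ disaggregation → consistency check.

The pipeline is stateless between stages: the exploratory table and the
selected models are sufficient inputs for the disaggregation, so each stage
can also be run on its own from the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import disaggregation as dis
from . import glm as glm_mod
from . import profiling, regression

__all__ = ["PipelineConfig", "PipelineResults", "run_pipeline"]

logger = logging.getLogger(__name__)

#: candidate transversal regressors per cost variable, in preference order
DEFAULT_TRANSVERSALS: dict[str, list[str]] = {
    "fuel_cost": ["effort_hours"],
    "fuel_consumption": ["effort_hours"],
    "labour_cost": ["revenue", "revenue_minus_variable", "revenue_minus_fuel", "effort_hours"],
}


@dataclass
class PipelineConfig:
    """Tunable knobs of the whole pipeline (see the methods note)."""

    activity_metric: str = "hours_at_sea"
    coverage_threshold: float = 0.8
    coverage_per_segment: dict[str, float] = field(default_factory=dict)
    min_n: int = 30
    alpha: float = 0.05
    effort: str = "effort_hours"
    cost_variables: tuple[str, ...] = ("fuel_cost", "fuel_consumption", "labour_cost")
    transversals: Mapping[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSVERSALS)
    )
    fallback: str = "pooled"
    scale_intercepts_by_vessel_count: bool = False
    joint_metier_test: bool = False

    def validate(self) -> None:
        if self.activity_metric not in profiling.ACTIVITY_METRICS:
            raise ValueError(f"unknown activity_metric: {self.activity_metric!r}")
        for name, thr in [
            ("coverage_threshold", self.coverage_threshold),
            *self.coverage_per_segment.items(),
        ]:
            if not (0 < thr <= 1):
                raise ValueError(f"coverage threshold out of (0, 1]: {name}={thr}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha out of (0, 1): {self.alpha}")
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")
        if self.fallback not in ("pooled", "skip"):
            raise ValueError(f"unknown fallback policy: {self.fallback!r}")


@dataclass
class PipelineResults:
    """All intermediate and final tables of one pipeline run."""

    observations: pd.DataFrame
    coverage: pd.DataFrame
    regressions: pd.DataFrame
    selections: list[glm_mod.ModelSelection]
    glm_terms: pd.DataFrame
    model_selection: pd.DataFrame
    disaggregated: pd.DataFrame
    consistency: dis.ConsistencyReport | None

    def tables(self) -> dict[str, pd.DataFrame]:
        """Result tables keyed by their output file name."""
        out = {
            "observations": self.observations,
            "coverage": self.coverage,
            "regressions": self.regressions,
            "glm_terms": self.glm_terms,
            "model_selection": self.model_selection,
            "disaggregated_costs": self.disaggregated,
        }
        if self.consistency is not None:
            out["consistency_check"] = self.consistency.table
        return out


def _selection_tables(
    selections: list[glm_mod.ModelSelection],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    term_rows, sel_rows = [], []
    for sel in selections:
        sel_rows.append(
            {
                "fleet_segment": sel.fleet_segment,
                "cost_variable": sel.cost_variable,
                "chosen_equation": sel.chosen_equation,
                "chosen_transversal": sel.chosen_transversal or "",
                "explained_deviance": sel.fit.explained_deviance if sel.fit else float("nan"),
                "aic": sel.fit.aic if sel.fit else float("nan"),
                "n": sel.fit.nobs if sel.fit else 0,
                "rationale": " | ".join(sel.rationale),
            }
        )
        if sel.fit is None:
            continue
        terms = sel.fit.terms()
        terms.insert(0, "fleet_segment", sel.fleet_segment)
        terms.insert(1, "cost_variable", sel.cost_variable)
        terms.insert(2, "equation", sel.chosen_equation)
        term_rows.append(terms)
    glm_terms = (
        pd.concat(term_rows, ignore_index=True)
        if term_rows
        else pd.DataFrame(
            columns=[
                "fleet_segment",
                "cost_variable",
                "equation",
                "term",
                "coefficient",
                "standard_error",
                "p_value",
            ]
        )
    )
    model_selection = pd.DataFrame(
        sel_rows,
        columns=[
            "fleet_segment",
            "cost_variable",
            "chosen_equation",
            "chosen_transversal",
            "explained_deviance",
            "aic",
            "n",
            "rationale",
        ],
    )
    return glm_terms, model_selection


def _pooled_slopes(
    regressions: pd.DataFrame, selections: list[glm_mod.ModelSelection]
) -> dict[tuple[str, str], float]:
    """Segment-pooled zero-intercept slopes for the fallback policy,
    matching each selection's chosen transversal."""
    out: dict[tuple[str, str], float] = {}
    for sel in selections:
        if not sel.selected:
            continue
        rows = regressions[
            (regressions["fleet_segment"] == sel.fleet_segment)
            & (regressions["cost_variable"] == sel.cost_variable)
            & (regressions["transversal"] == sel.chosen_transversal)
            & (regressions["metier"] == "ALL")
            & (regressions["suppressed_reason"] == "")
        ]
        if len(rows):
            out[(sel.fleet_segment, sel.cost_variable)] = float(rows["slope"].iloc[0])
    return out


def run_pipeline(
    trips: pd.DataFrame,
    vessel_costs: pd.DataFrame,
    segment_costs: pd.DataFrame | None,
    transversal: pd.DataFrame | None,
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Run phases 1 and 2 on validated input tables.

    ``segment_costs`` and ``transversal`` may be omitted to run phase 1
    only (no disaggregation or consistency check).
    """
    config = config or PipelineConfig()
    config.validate()

    obs = profiling.build_observations(trips, vessel_costs, config.activity_metric)
    logger.info("built %d vessel-year observations", len(obs))
    obs, coverage = profiling.filter_by_coverage(
        obs, config.coverage_threshold, config.coverage_per_segment
    )
    logger.info("retained %d observations after coverage filter", len(obs))

    catalogue = regression.default_catalogue(config.effort)
    catalogue = [r for r in catalogue if r.cost_variable in config.cost_variables]
    regressions = regression.run_ea(obs, catalogue, config.min_n)

    selections: list[glm_mod.ModelSelection] = []
    for segment, seg_obs in obs.groupby("fleet_segment", sort=True):
        for cost in config.cost_variables:
            candidates = list(config.transversals.get(cost, [config.effort]))
            try:
                sel = glm_mod.select_model(
                    seg_obs,
                    cost,
                    candidates,
                    alpha=config.alpha,
                    joint_metier_test=config.joint_metier_test,
                )
            except ValueError as exc:
                logger.warning("selection failed for %s/%s: %s", segment, cost, exc)
                sel = glm_mod.ModelSelection(
                    fleet_segment=segment,
                    cost_variable=cost,
                    chosen_equation="none",
                    rationale=[str(exc)],
                )
            selections.append(sel)
    glm_terms, model_selection = _selection_tables(selections)

    disaggregated = pd.DataFrame(columns=dis.DISAGGREGATED_COLUMNS)
    consistency = None
    if transversal is not None:
        pooled = _pooled_slopes(regressions, selections)
        pieces = []
        for sel in selections:
            if not sel.selected:
                continue
            try:
                pieces.append(
                    dis.disaggregate(
                        sel,
                        transversal,
                        fallback=config.fallback,
                        pooled_slopes=pooled,
                        scale_intercepts_by_vessel_count=config.scale_intercepts_by_vessel_count,
                    )
                )
            except ValueError as exc:
                logger.warning(
                    "disaggregation failed for %s/%s: %s",
                    sel.fleet_segment,
                    sel.cost_variable,
                    exc,
                )
        if pieces:
            disaggregated = pd.concat(pieces, ignore_index=True)
        if segment_costs is not None and len(disaggregated):
            consistency = dis.consistency_check(disaggregated, segment_costs)
            logger.info("%s", consistency)

    return PipelineResults(
        observations=obs,
        coverage=coverage,
        regressions=regressions,
        selections=selections,
        glm_terms=glm_terms,
        model_selection=model_selection,
        disaggregated=disaggregated,
        consistency=consistency,
    )
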