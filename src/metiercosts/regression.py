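"""Exploratory analysis: correlations and zero-intercept regressions.

For every fleet segment and retained métier (plus the pooled ``ALL`` group)
the strength of the link between a variable cost and a transversal variable
is summarised by the Pearson correlation coefficient and by a linear
regression through the origin.  The null intercept mirrors the way the
fitted slope is later used for disaggregation: a métier with zero effort
must be attributed zero cost.

The default relationship catalogue covers fuel costs and fuel consumption
against effort, and labour costs against revenue, revenue net of variable
costs, revenue net of fuel costs, and effort.  Labour costs track revenue
closely wherever crews are paid a share of the catch value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "Relationship",
    "DEFAULT_CATALOGUE",
    "ZeroInterceptFit",
    "pearson",
    "fit_zero_intercept",
    "run_ea",
]

#: transversal columns a relationship may reference, and how each is built
#: from the observation table
_TRANSVERSAL_BUILDERS = {
    "effort_hours": lambda df: df["hours_at_sea"],
    "effort_dayskw": lambda df: df["effort_dayskw"],
    "revenue": lambda df: df["revenue"],
    "revenue_minus_fuel": lambda df: df["revenue"] - df["fuel_cost_adj"],
    # composition of "total variable costs" is configurable; the default
    # subtracts fuel, labour and other variable costs
    "revenue_minus_variable": lambda df: df["revenue"]
    - df["fuel_cost_adj"]
    - df["labour_cost_adj"]
    - df["other_variable_adj"].fillna(0.0),
}

_COST_COLUMNS = {
    "fuel_cost": "fuel_cost_adj",
    "fuel_consumption": "fuel_consumption_adj",
    "labour_cost": "labour_cost_adj",
    "other_variable": "other_variable_adj",
}


@dataclass(frozen=True)
class Relationship:
    """A (cost variable, transversal variable) pair under study."""

    cost_variable: str
    transversal: str

    def __post_init__(self) -> None:
        if self.cost_variable not in _COST_COLUMNS:
            raise ValueError(f"unknown cost variable: {self.cost_variable!r}")
        if self.transversal not in _TRANSVERSAL_BUILDERS:
            raise ValueError(f"unknown transversal: {self.transversal!r}")

    def frame(self, observations: pd.DataFrame) -> pd.DataFrame:
        """Aligned (x, y) pairs for this relationship, NaN rows dropped."""
        x = _TRANSVERSAL_BUILDERS[self.transversal](observations)
        y = observations[_COST_COLUMNS[self.cost_variable]]
        out = pd.DataFrame({"x": x, "y": y})
        return out.dropna()


def default_catalogue(effort: str = "effort_hours") -> list[Relationship]:
    """The standard cost~transversal pairs, with a chosen effort metric."""
    return [
        Relationship("fuel_cost", effort),
        Relationship("fuel_consumption", effort),
        Relationship("labour_cost", "revenue"),
        Relationship("labour_cost", "revenue_minus_variable"),
        Relationship("labour_cost", "revenue_minus_fuel"),
        Relationship("labour_cost", effort),
    ]


DEFAULT_CATALOGUE = default_catalogue()


@dataclass
class ZeroInterceptFit:
    """A regression through the origin of cost on a transversal variable."""

    n: int
    slope: float
    slope_se: float
    p_value: float
    pearson_r: float

    @property
    def significant(self) -> bool:
        """True when the slope differs from zero at the 5% level (strict)."""
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)


def fit_zero_intercept(x: np.ndarray, y: np.ndarray) -> ZeroInterceptFit:
    """Least-squares line through the origin.

    Fits ``y = slope * x`` with ``slope = Σxy / Σx²``; the slope's standard
    error uses the residual variance on n−1 degrees of freedom and the
    p-value comes from the t distribution with n−1 df.  When the fit is
    exact (zero residual sum of squares) a nonzero slope is reported with
    p-value 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two (x, y) pairs")
    if not np.any(x != 0):
        raise ValueError("all-zero regressor: slope through origin undefined")
    res = sm.OLS(y, x[:, None]).fit()
    slope = float(res.params[0])
    se = float(res.bse[0])
    if se == 0.0:
        p = 0.0 if slope != 0.0 else 1.0
    else:
        p = float(res.pvalues[0])
    return ZeroInterceptFit(
        n=len(x), slope=slope, slope_se=se, p_value=p, pearson_r=pearson(x, y)
    )


def run_ea(
    observations: pd.DataFrame,
    catalogue: list[Relationship] | None = None,
    min_n: int = 30,
) -> pd.DataFrame:
    """Exploratory-analysis table over segments, métiers and relationships.

    For every fleet segment and relationship one row is emitted per métier
    with at least ``min_n`` usable observations, plus an ``ALL`` row pooling
    the segment's (coverage-retained) métiers.  Groups below ``min_n`` are
    suppressed with reason ``insufficient observations``; degenerate groups
    (zero-variance regressor) are reported as missing with a reason.

    Returns a DataFrame with columns fleet_segment, metier, cost_variable,
    transversal, n, pearson_r, slope, slope_se, p_value, significant,
    suppressed_reason.
    """
    if catalogue is None:
        catalogue = DEFAULT_CATALOGUE
    rows = []
    for segment, seg_obs in observations.groupby("fleet_segment", sort=True):
        metier_groups = [(m, g) for m, g in seg_obs.groupby("prevalent_metier", sort=True)]
        for rel in catalogue:
            for metier, group in metier_groups + [("ALL", seg_obs)]:
                xy = rel.frame(group)
                row = {
                    "fleet_segment": segment,
                    "metier": metier,
                    "cost_variable": rel.cost_variable,
                    "transversal": rel.transversal,
                    "n": len(xy),
                    "pearson_r": np.nan,
                    "slope": np.nan,
                    "slope_se": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                    "suppressed_reason": "",
                }
                if len(xy) < min_n:
                    row["suppressed_reason"] = "insufficient observations"
                else:
                    try:
                        fit = fit_zero_intercept(xy["x"].to_numpy(), xy["y"].to_numpy())
                    except ValueError as exc:
                        row["suppressed_reason"] = str(exc)
                    else:
                        row.update(
                            pearson_r=fit.pearson_r,
                            slope=fit.slope,
                            slope_se=fit.slope_se,
                            p_value=fit.p_value,
                            significant=fit.significant,
                        )
                rows.append(row)
    columns = [
        "fleet_segment",
        "metier",
        "cost_variable",
        "transversal",
        "n",
        "pearson_r",
        "slope",
        "slope_se",
        "p_value",
        "significant",
        "suppressed_reason",
    ]
    return pd.DataFrame(rows, columns=columns)
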