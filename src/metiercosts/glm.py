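"""Gaussian GLMs testing the métier effect on variable costs.

Within a fleet segment, an annual variable cost ``VC`` of a vessel is
modelled against its (prevalent) métier ``m`` and a transversal variable
``x`` (effort or revenue) with three nested candidate mean structures:

- métier intercepts and a common slope:   ``VC = α_m + β·x``
- métier intercepts and métier slopes:    ``VC = α_m + (β + γ_m)·x``
- a single proportional slope:            ``VC = α·x``

All are Gaussian-family, identity-link fits with *no* global intercept: the
métier factor is cell-means coded, so each métier receives its own
coefficient and the coefficients can be applied directly in the
disaggregation step.  The métier-slope model codes the interaction as slope
deviations ``γ_m`` relative to the first métier (``γ`` of the reference
métier is zero), giving 2·M columns for M métiers.

:class:`CostGLM` is the model object (data + design); :meth:`CostGLM.fit`
returns a :class:`CostGLMResults` carrying coefficients, standard errors,
p-values, explained deviance and AIC, with a ``summary()`` table.
:func:`select_model` walks the decision flow that picks the equation used
for disaggregation — or concludes that none is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regression import Relationship, fit_zero_intercept

__all__ = [
    "EQ1",
    "EQ2",
    "EQ3",
    "CostGLM",
    "CostGLMResults",
    "ModelSelection",
    "metier_significant",
    "select_model",
]

EQ1 = "EQ1"  # métier intercepts + common transversal slope
EQ2 = "EQ2"  # métier intercepts + métier-specific transversal slopes
EQ3 = "EQ3"  # single slope through the origin

_EQUATIONS = (EQ1, EQ2, EQ3)


class CostGLM:
    """Gaussian GLM of an adjusted variable cost within one fleet segment.

    Parameters
    ----------
    observations
        Métier-resolved observation table (one row per vessel-year) for a
        single fleet segment; NaN rows for the chosen variables are dropped.
    cost_variable
        One of ``fuel_cost``, ``fuel_consumption``, ``labour_cost``,
        ``other_variable``.
    transversal
        Transversal regressor: ``effort_hours``, ``effort_dayskw``,
        ``revenue``, ``revenue_minus_fuel`` or ``revenue_minus_variable``.
    equation
        ``EQ1``, ``EQ2`` or ``EQ3``.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        cost_variable: str,
        transversal: str,
        equation: str,
    ) -> None:
        if equation not in _EQUATIONS:
            raise ValueError(f"unknown equation: {equation!r}")
        self.cost_variable = cost_variable
        self.transversal = transversal
        self.equation = equation
        rel = Relationship(cost_variable, transversal)
        xy = rel.frame(observations)
        metier = observations.loc[xy.index, "prevalent_metier"]
        self._data = pd.DataFrame(
            {"metier": metier.to_numpy(), "x": xy["x"].to_numpy(), "y": xy["y"].to_numpy()}
        )
        segments = observations.loc[xy.index, "fleet_segment"].unique()
        if len(segments) > 1:
            raise ValueError("observations span multiple fleet segments")
        self.fleet_segment = segments[0] if len(segments) else ""
        self.metiers = sorted(self._data["metier"].unique())
        self.nobs = len(self._data)
        if self.nobs < 2:
            raise ValueError("need at least two observations")
        if equation in (EQ1, EQ2) and len(self.metiers) < 2:
            raise ValueError(f"{equation} needs at least two métiers")
        self._check_cells()
        self.exog_names, self.exog = self._design()
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            raise ValueError(
                f"rank-deficient design for {equation} "
                f"({rank} < {self.exog.shape[1]} columns)"
            )

    def _check_cells(self) -> None:
        need = 2 if self.equation == EQ2 else 1
        counts = self._data.groupby("metier").size()
        thin = counts[counts < need]
        if len(thin):
            raise ValueError(
                f"métier(s) with too few observations for {self.equation}: "
                + ", ".join(f"{m} (n={n})" for m, n in thin.items())
            )

    def _design(self) -> tuple[list[str], np.ndarray]:
        d = self._data
        x = d["x"].to_numpy(float)
        if self.equation == EQ3:
            return [f"slope[{self.transversal}]"], x[:, None]
        cols, names = [], []
        for m in self.metiers:
            cols.append((d["metier"] == m).to_numpy(float))
            names.append(f"alpha[{m}]")
        cols.append(x)
        names.append(f"beta[{self.transversal}]")
        if self.equation == EQ2:
            for m in self.metiers[1:]:
                cols.append((d["metier"] == m).to_numpy(float) * x)
                names.append(f"gamma[{m}]")
        return names, np.column_stack(cols)

    def fit(self) -> "CostGLMResults":
        """Fit by iteratively reweighted least squares (Gaussian, identity).

        p-values use the t distribution, consistent with a least-squares fit
        whose error variance is estimated from the residuals.
        """
        glm = sm.GLM(self._data["y"].to_numpy(float), self.exog, family=sm.families.Gaussian())
        with warnings.catch_warnings():
            # exact fits trip statsmodels' perfect-prediction warning; the
            # degenerate p-values are repaired in CostGLMResults
            warnings.simplefilter("ignore")
            res = glm.fit(use_t=True)
        return CostGLMResults(self, res)


class CostGLMResults:
    """Fitted coefficients and diagnostics of a :class:`CostGLM`."""

    def __init__(self, model: CostGLM, res) -> None:
        self.model = model
        self._res = res
        names = model.exog_names
        with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
            # statsmodels evaluates aic/pvalues lazily; exact fits (zero
            # residual deviance) make their intermediate ratios degenerate
            warnings.simplefilter("ignore")
            self.params = pd.Series(res.params, index=names)
            self.bse = pd.Series(res.bse, index=names)
            self.deviance = float(res.deviance)
            self.null_deviance = float(res.null_deviance)
            self.aic = float(res.aic)
            self.pvalues = pd.Series(res.pvalues, index=names)
        self.nobs = model.nobs
        if not np.isfinite(self.aic):
            # a perfect fit dominates every imperfect one
            self.aic = -np.inf
        # An (numerically) exact fit has vanishing standard errors and the
        # t statistics degenerate to 0/0: declare coefficients that are
        # nonzero on the scale of the response unambiguous and the rest
        # uninformative, instead of trusting ratios of rounding noise.
        y = model._data["y"].to_numpy(float)
        y_scale = max(1.0, float(np.abs(y).max()))
        if self.deviance <= 1e-16 * model.nobs * y_scale**2:
            x_scale = np.maximum(1.0, np.abs(model.exog).max(axis=0))
            material = np.abs(self.params.to_numpy()) * x_scale > 1e-6 * y_scale
            self.pvalues[:] = np.where(material, 0.0, 1.0)

    @property
    def explained_deviance(self) -> float:
        """Percent of the null deviance explained by the model."""
        if self.null_deviance == 0:
            return 100.0 if self.deviance == 0 else 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    # -- term groups -------------------------------------------------
    def _group(self, prefix: str) -> pd.Series:
        return self.pvalues[[n for n in self.params.index if n.startswith(prefix)]]

    @property
    def metier_pvalues(self) -> pd.Series:
        return self._group("alpha[")

    @property
    def slope_pvalue(self) -> float:
        s = self._group("beta[") if self.model.equation != EQ3 else self._group("slope[")
        return float(s.iloc[0])

    @property
    def interaction_pvalues(self) -> pd.Series:
        return self._group("gamma[")

    # -- coefficients on the disaggregation scale --------------------
    def intercepts(self) -> dict[str, float]:
        """Per-métier intercepts α_m (empty for the proportional model)."""
        if self.model.equation == EQ3:
            return {}
        return {
            m: float(self.params[f"alpha[{m}]"]) for m in self.model.metiers
        }

    def slopes(self) -> dict[str, float]:
        """Per-métier effective slope on the transversal variable."""
        if self.model.equation == EQ3:
            a = float(self.params.iloc[0])
            return {m: a for m in self.model.metiers}
        beta = float(self._group_params("beta[").iloc[0])
        if self.model.equation == EQ1:
            return {m: beta for m in self.model.metiers}
        out = {}
        for m in self.model.metiers:
            gname = f"gamma[{m}]"
            out[m] = beta + (float(self.params[gname]) if gname in self.params else 0.0)
        return out

    def _group_params(self, prefix: str) -> pd.Series:
        return self.params[[n for n in self.params.index if n.startswith(prefix)]]

    def terms(self) -> pd.DataFrame:
        """Long-form coefficient table (term, coefficient, se, p-value)."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "coefficient": self.params.to_numpy(),
                "standard_error": self.bse.to_numpy(),
                "p_value": self.pvalues.to_numpy(),
            }
        )

    def summary(self) -> str:
        """Plain-text summary in the style of a GLM coefficient table."""
        lines = [
            f"Gaussian GLM ({self.model.equation}) — {self.model.cost_variable} ~ "
            f"métier/{self.model.transversal}",
            f"fleet segment: {self.model.fleet_segment}   n = {self.nobs}",
            "-" * 64,
            f"{'term':<28}{'coef':>12}{'std err':>12}{'P>|t|':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"{self.pvalues[name]:>10.3g}"
            )
        lines.append("-" * 64)
        lines.append(
            f"explained deviance: {self.explained_deviance:.1f}%   AIC: {self.aic:.1f}"
        )
        return "\n".join(lines)


def metier_significant(results: CostGLMResults, alpha: float = 0.05) -> bool:
    """Whether the métier factor matters: any métier coefficient with p < alpha.

    The permissive any-level rule is the default; pass the results to
    :func:`metier_jointly_significant` for a joint F-test instead.
    """
    if results.model.equation == EQ3:
        raise ValueError("the proportional model has no métier term")
    p = results.metier_pvalues
    return bool((p < alpha).any())


def metier_jointly_significant(results: CostGLMResults, alpha: float = 0.05) -> bool:
    """Joint Wald F-test that all métier intercepts are zero."""
    if results.model.equation == EQ3:
        raise ValueError("the proportional model has no métier term")
    names = list(results.metier_pvalues.index)
    k = len(results.params)
    contrast = np.zeros((len(names), k))
    for i, n in enumerate(names):
        contrast[i, list(results.params.index).index(n)] = 1.0
    test = results._res.f_test(contrast)
    return bool(float(test.pvalue) < alpha)


@dataclass
class ModelSelection:
    """Outcome of the equation-selection decision flow for one cost type."""

    fleet_segment: str
    cost_variable: str
    chosen_equation: str  # EQ1 / EQ2 / EQ3 / "none"
    chosen_transversal: str | None = None
    fit: CostGLMResults | None = None
    rationale: list[str] = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return self.chosen_equation != "none"


def _significant(p: float, alpha: float) -> bool:
    return bool(np.isfinite(p) and p < alpha)


def _flow_for_transversal(
    observations: pd.DataFrame,
    cost_variable: str,
    transversal: str,
    alpha: float,
    joint_metier_test: bool,
    trail: list[str],
) -> tuple[str, CostGLMResults | None]:
    """Walk the nested-model decision flow for one candidate transversal."""
    sig = metier_jointly_significant if joint_metier_test else metier_significant

    # gate: is there any linear relationship at all, pooled over métiers?
    xy = Relationship(cost_variable, transversal).frame(observations)
    try:
        gate = fit_zero_intercept(xy["x"].to_numpy(), xy["y"].to_numpy())
    except ValueError as exc:
        trail.append(f"{transversal}: exploratory gate failed ({exc})")
        return "none", None
    if not _significant(gate.p_value, alpha):
        trail.append(
            f"{transversal}: no significant pooled relationship "
            f"(p = {gate.p_value:.3g}); disaggregation not meaningful"
        )
        return "none", None
    trail.append(
        f"{transversal}: pooled zero-intercept slope significant (p = {gate.p_value:.3g})"
    )

    n_metiers = observations["prevalent_metier"].nunique()
    if n_metiers >= 2:
        # métier-specific slopes: métier, slope and interaction all needed
        try:
            eq2 = CostGLM(observations, cost_variable, transversal, EQ2).fit()
        except ValueError as exc:
            trail.append(f"{transversal}: métier-slope model not fittable ({exc})")
            eq2 = None
        if eq2 is not None:
            ok = (
                sig(eq2, alpha)
                and _significant(eq2.slope_pvalue, alpha)
                and bool((eq2.interaction_pvalues < alpha).any())
            )
            trail.append(
                f"{transversal}: métier+slope+interaction "
                f"{'all significant → métier-specific slopes' if ok else 'not all significant'}"
            )
            if ok:
                return EQ2, eq2

        try:
            eq1 = CostGLM(observations, cost_variable, transversal, EQ1).fit()
        except ValueError as exc:
            trail.append(f"{transversal}: métier-intercept model not fittable ({exc})")
            eq1 = None
        if eq1 is not None:
            ok = sig(eq1, alpha) and _significant(eq1.slope_pvalue, alpha)
            trail.append(
                f"{transversal}: métier and slope "
                f"{'significant → métier intercepts' if ok else 'not both significant'}"
            )
            if ok:
                return EQ1, eq1
    else:
        trail.append(f"{transversal}: single métier; métier effect untestable")

    eq3 = CostGLM(observations, cost_variable, transversal, EQ3).fit()
    if _significant(eq3.slope_pvalue, alpha):
        trail.append(f"{transversal}: proportional slope significant")
        return EQ3, eq3
    trail.append(f"{transversal}: proportional slope not significant")
    return "none", None


def select_model(
    observations: pd.DataFrame,
    cost_variable: str,
    transversals: list[str],
    alpha: float = 0.05,
    joint_metier_test: bool = False,
) -> ModelSelection:
    """Choose the disaggregation equation for one segment and cost type.

    The decision flow prefers, in order, métier-specific slopes, métier
    intercepts with a common slope, and a single proportional slope, each
    subject to its terms being significant at ``alpha`` (strict); absent any
    significant relationship the outcome is ``"none"`` and the cost cannot
    be disaggregated defensibly.  When several candidate transversals
    qualify, the qualifying fit with the lowest AIC wins.

    ``observations`` must belong to a single fleet segment.
    """
    if len(observations) == 0:
        raise ValueError("no observations")
    segments = observations["fleet_segment"].unique()
    if len(segments) != 1:
        raise ValueError("select_model expects a single fleet segment")
    trail: list[str] = []
    candidates: list[tuple[str, str, CostGLMResults]] = []
    for transversal in transversals:
        eq, fit = _flow_for_transversal(
            observations, cost_variable, transversal, alpha, joint_metier_test, trail
        )
        if eq != "none":
            candidates.append((transversal, eq, fit))
    if not candidates:
        return ModelSelection(
            fleet_segment=segments[0],
            cost_variable=cost_variable,
            chosen_equation="none",
            rationale=trail,
        )
    if len(candidates) > 1:
        trail.append(
            "several transversals qualify; choosing lowest AIC: "
            + ", ".join(f"{t} ({f.aic:.1f})" for t, _, f in candidates)
        )
    transversal, eq, fit = min(candidates, key=lambda c: c[2].aic)
    return ModelSelection(
        fleet_segment=segments[0],
        cost_variable=cost_variable,
        chosen_equation=eq,
        chosen_transversal=transversal,
        fit=fit,
        rationale=trail,
    )
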