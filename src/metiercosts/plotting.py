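"""Diagnostic plots: scatter/fit panels and reconciliation bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .regression import Relationship

__all__ = ["plot_regressions", "plot_consistency"]


def plot_regressions(
    observations: pd.DataFrame,
    regressions: pd.DataFrame,
    out_dir,
) -> list[Path]:
    """One scatter-plus-fitted-line panel per (segment, relationship).

    Points are the métier-adjusted vessel-year observations; the lines are
    the fitted zero-intercept regressions, one per métier plus the pooled
    fit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    fitted = regressions[regressions["suppressed_reason"] == ""]
    keys = fitted[["fleet_segment", "cost_variable", "transversal"]].drop_duplicates()
    for key in keys.itertuples(index=False):
        seg_obs = observations[observations["fleet_segment"] == key.fleet_segment]
        rel = Relationship(key.cost_variable, key.transversal)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for metier, group in seg_obs.groupby("prevalent_metier"):
            xy = rel.frame(group)
            ax.scatter(xy["x"], xy["y"], s=12, alpha=0.6, label=metier)
        rows = fitted[
            (fitted["fleet_segment"] == key.fleet_segment)
            & (fitted["cost_variable"] == key.cost_variable)
            & (fitted["transversal"] == key.transversal)
        ]
        xmax = rel.frame(seg_obs)["x"].max()
        for r in rows.itertuples():
            style = "k-" if r.metier == "ALL" else "--"
            ax.plot([0, xmax], [0, r.slope * xmax], style, lw=1.2)
        ax.set_xlabel(key.transversal)
        ax.set_ylabel(key.cost_variable)
        ax.set_title(f"{key.fleet_segment}: {key.cost_variable} vs {key.transversal}")
        ax.legend(fontsize=7)
        path = out / f"ea_{key.fleet_segment}_{key.cost_variable}_{key.transversal}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_consistency(consistency_table: pd.DataFrame, out_dir) -> list[Path]:
    """Bar chart per cost variable: official vs summed métier estimates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cost, sub in consistency_table.groupby("cost_variable"):
        sub = sub.sort_values(["fleet_segment", "year"])
        labels = [f"{r.fleet_segment}\n{r.year}" for r in sub.itertuples()]
        x = range(len(sub))
        fig, ax = plt.subplots(figsize=(1.2 * len(sub) + 2, 4.5))
        ax.bar([i - 0.2 for i in x], sub["costs_by_fleet_segment"], width=0.4, label="official")
        ax.bar([i + 0.2 for i in x], sub["sum_costs_by_metier"], width=0.4, label="sum by métier")
        ax.set_xticks(list(x))
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_ylabel(cost)
        ax.set_title(f"Consistency check: {cost}")
        ax.legend()
        path = out / f"consistency_{cost}.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
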