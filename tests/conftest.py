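import numpy as np
import pandas as pd
import pytest

from metiercosts import FleetScenario, generate


def make_trips(rows):
    """Trip table from (vessel, year, segment, metier, hours, days, kw, weight, value)."""
    return pd.DataFrame(
        rows,
        columns=[
            "vessel_id",
            "year",
            "fleet_segment",
            "metier",
            "hours_at_sea",
            "fishing_days",
            "kw",
            "landings_weight",
            "landings_value",
        ],
    )


def make_costs(rows):
    """Vessel-cost table from (vessel, year, fuel, consumption, labour, other)."""
    return pd.DataFrame(
        rows,
        columns=[
            "vessel_id",
            "year",
            "fuel_cost",
            "fuel_consumption",
            "labour_cost",
            "other_variable_costs",
        ],
    )


def make_observations(metiers, x, y, cost="fuel_cost_adj", segment="SEG"):
    """Observation table with one cost column set to y and x as hours."""
    n = len(x)
    df = pd.DataFrame(
        {
            "vessel_id": [f"V{i}" for i in range(n)],
            "year": 2015,
            "fleet_segment": segment,
            "prevalent_metier": metiers,
            "activity_share": 1.0,
            "hours_at_sea": np.asarray(x, float),
            "effort_dayskw": np.nan,
            "revenue": np.nan,
            "fuel_cost_adj": np.nan,
            "fuel_consumption_adj": np.nan,
            "labour_cost_adj": np.nan,
            "other_variable_adj": np.nan,
        }
    )
    df[cost] = np.asarray(y, float)
    return df


@pytest.fixture(scope="session")
def eq1_fleet():
    """A noisy fleet with métier-specific fuel intercepts and a common slope."""
    return generate(FleetScenario.eq1(seed=7))


@pytest.fixture(scope="session")
def default_fleet():
    """The four-segment fleet mirroring the case-study scale."""
    return generate(FleetScenario.default(seed=11))
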