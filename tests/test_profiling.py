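import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metiercosts import assign_prevalent_metier, build_observations, filter_by_coverage
from tests.conftest import make_costs, make_trips


def trips_for(metier_hours, vessel="V1", year=2015):
    rows = [
        (vessel, year, "SEG", m, h, max(1, h / 10), 200, 0.0, 100.0 * h)
        for m, h in metier_hours
    ]
    return make_trips(rows)


class TestPrevalentMetier:
    def test_single_metier_share_one(self):
        m, share = assign_prevalent_metier(trips_for([("OTB_DES", 40.0)]))
        assert (m, share) == ("OTB_DES", 1.0)

    def test_argmax_and_ratio(self):
        m, share = assign_prevalent_metier(trips_for([("OTB_DES", 75.0), ("OTB_MDD", 25.0)]))
        assert m == "OTB_DES"
        assert share == pytest.approx(0.75)

    def test_exact_tie_goes_to_lexicographically_smaller(self, caplog):
        with caplog.at_level("INFO"):
            m, share = assign_prevalent_metier(
                trips_for([("OTB_MDD", 50.0), ("OTB_DES", 50.0)])
            )
        assert m == "OTB_DES"
        assert share == pytest.approx(0.5)
        assert any("tie" in r.message for r in caplog.records)

    def test_no_activity_is_an_error(self):
        with pytest.raises(ValueError, match="activity"):
            assign_prevalent_metier(trips_for([("OTB_DES", 0.0)]))

    def test_alternative_metrics(self):
        trips = trips_for([("A", 10.0), ("A", 10.0), ("B", 30.0)])
        assert assign_prevalent_metier(trips, "hours_at_sea")[0] == "B"
        assert assign_prevalent_metier(trips, "trip_count")[0] == "A"


class TestBuildObservations:
    def test_costs_scaled_by_activity_share(self):
        """A 75% prevalent métier keeps 75% of every cost type."""
        trips = trips_for([("OTB_DES", 75.0), ("OTB_MDD", 25.0)])
        costs = make_costs([("V1", 2015, 10_000.0, 12_000.0, 20_000.0, 1_000.0)])
        obs = build_observations(trips, costs)
        row = obs.iloc[0]
        assert row["activity_share"] == pytest.approx(0.75)
        assert row["fuel_cost_adj"] == pytest.approx(7_500.0)
        assert row["labour_cost_adj"] == pytest.approx(15_000.0)
        assert row["hours_at_sea"] == pytest.approx(100.0 * 0.75)
        assert row["revenue"] == pytest.approx(10_000.0 * 0.75)

    def test_full_share_is_identity(self):
        trips = trips_for([("OTB_DES", 40.0)])
        costs = make_costs([("V1", 2015, 500.0, 600.0, 700.0, 0.0)])
        obs = build_observations(trips, costs)
        assert obs.iloc[0]["fuel_cost_adj"] == 500.0
        assert obs.iloc[0]["labour_cost_adj"] == 700.0

    def test_hand_computed_fixture_four_vessels_two_years(self):
        rows, cost_rows, expected = [], [], {}
        for i, share_hours in enumerate([(80, 20), (60, 40), (90, 10), (50, 50)]):
            vessel = f"V{i}"
            for year in (2015, 2016):
                rows += [
                    (vessel, year, "SEG", "A", float(share_hours[0]), 1, 100, 0, 100.0),
                    (vessel, year, "SEG", "B", float(share_hours[1]), 1, 100, 0, 100.0),
                ]
                fuel = 1000.0 * (i + 1)
                cost_rows.append((vessel, year, fuel, 0.0, 0.0, 0.0))
                top = max(share_hours)
                prev = "A" if share_hours[0] >= share_hours[1] else "B"
                expected[(vessel, year)] = fuel * top / sum(share_hours)
        obs = build_observations(make_trips(rows), make_costs(cost_rows))
        assert len(obs) == 8
        for r in obs.itertuples():
            assert r.fuel_cost_adj == pytest.approx(expected[(r.vessel_id, r.year)])

    def test_costs_without_trips_excluded(self, caplog):
        trips = trips_for([("OTB_DES", 40.0)])
        costs = make_costs(
            [("V1", 2015, 1.0, 1.0, 1.0, 0.0), ("GHOST", 2015, 9.0, 9.0, 9.0, 0.0)]
        )
        with caplog.at_level("WARNING"):
            obs = build_observations(trips, costs)
        assert obs["vessel_id"].tolist() == ["V1"]
        assert any("no trips" in r.message for r in caplog.records)

    def test_missing_trip_value_blanks_revenue_only(self):
        trips = trips_for([("OTB_DES", 30.0), ("OTB_DES", 10.0)])
        trips.loc[1, "landings_value"] = np.nan
        costs = make_costs([("V1", 2015, 100.0, 0.0, 50.0, 0.0)])
        obs = build_observations(trips, costs)
        assert np.isnan(obs.iloc[0]["revenue"])
        assert obs.iloc[0]["fuel_cost_adj"] == 100.0

    def test_adjusted_costs_never_exceed_raw(self, eq1_fleet):
        obs = build_observations(eq1_fleet.trips, eq1_fleet.vessel_costs)
        raw = eq1_fleet.vessel_costs.set_index(["vessel_id", "year"])["fuel_cost"]
        for r in obs.itertuples():
            assert r.fuel_cost_adj <= raw.loc[(r.vessel_id, r.year)] + 1e-9


def obs_with_counts(counts, segment="SEG"):
    rows = []
    i = 0
    for metier, n in counts.items():
        for _ in range(n):
            rows.append((f"V{i}", 2015, segment, metier))
            i += 1
    df = pd.DataFrame(rows, columns=["vessel_id", "year", "fleet_segment", "prevalent_metier"])
    for col in (
        "activity_share",
        "hours_at_sea",
        "effort_dayskw",
        "revenue",
        "fuel_cost_adj",
        "fuel_consumption_adj",
        "labour_cost_adj",
        "other_variable_adj",
    ):
        df[col] = 1.0
    return df


class TestCoverageFilter:
    def test_prefix_rule(self):
        obs = obs_with_counts({"m1": 50, "m2": 30, "m3": 15, "m4": 4, "m5": 1})
        kept, cov = filter_by_coverage(obs, 0.8)
        assert set(kept["prevalent_metier"]) == {"m1", "m2"}
        assert cov.set_index("metier")["retained"].to_dict() == {
            "m1": True,
            "m2": True,
            "m3": False,
            "m4": False,
            "m5": False,
        }

    def test_threshold_one_keeps_everything(self):
        obs = obs_with_counts({"m1": 5, "m2": 3, "m3": 1})
        kept, _ = filter_by_coverage(obs, 1.0)
        assert set(kept["prevalent_metier"]) == {"m1", "m2", "m3"}

    @staticmethod
    def brute_force(counts, threshold):
        """Independent oracle: smallest descending-count prefix reaching the
        threshold, re-applied until stable."""
        current = dict(counts)
        while True:
            ordered = sorted(current, key=lambda m: (-current[m], m))
            total = sum(current.values())
            for k in range(1, len(ordered) + 1):
                if sum(current[m] for m in ordered[:k]) / total >= threshold:
                    break
            kept = {m: current[m] for m in ordered[:k]}
            if len(kept) == len(current):
                return set(kept)
            current = kept

    def test_matches_brute_force_prefix(self):
        # the dominant-two pattern of a mixed trawler segment: the third
        # métier survives the first pass but not the stable rule
        counts = {"m1": 55, "m2": 53, "m3": 26, "m4": 4, "m5": 3}
        obs = obs_with_counts(counts)
        kept, _ = filter_by_coverage(obs, 0.8)
        assert set(kept["prevalent_metier"]) == self.brute_force(counts, 0.8) == {"m1", "m2"}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.sampled_from([f"m{i}" for i in range(6)]),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=6,
        ),
        threshold=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_matches_brute_force_everywhere(self, counts, threshold):
        obs = obs_with_counts(counts)
        kept, _ = filter_by_coverage(obs, threshold)
        assert set(kept["prevalent_metier"]) == self.brute_force(counts, threshold)

    def test_per_segment_override(self):
        obs = pd.concat(
            [
                obs_with_counts({"a": 50, "b": 40, "c": 10}, segment="S1"),
                obs_with_counts({"a": 50, "b": 40, "c": 10}, segment="S2"),
            ],
            ignore_index=True,
        )
        kept, _ = filter_by_coverage(obs, 0.8, per_segment={"S2": 0.95})
        s1 = set(kept.loc[kept["fleet_segment"] == "S1", "prevalent_metier"])
        s2 = set(kept.loc[kept["fleet_segment"] == "S2", "prevalent_metier"])
        assert s1 == {"a", "b"}
        assert s2 == {"a", "b", "c"}

    def test_retained_count_equals_sum_of_retained_metiers(self):
        obs = obs_with_counts({"m1": 7, "m2": 5, "m3": 2})
        kept, cov = filter_by_coverage(obs, 0.7)
        assert len(kept) == cov.loc[cov["retained"], "n_observations"].sum()

    def test_bad_threshold_rejected(self):
        obs = obs_with_counts({"m1": 3})
        with pytest.raises(ValueError, match="threshold"):
            filter_by_coverage(obs, 1.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.sampled_from([f"m{i}" for i in range(6)]),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=6,
        ),
        threshold=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_idempotent(self, counts, threshold):
        """Filtering an already-filtered table changes nothing."""
        obs = obs_with_counts(counts)
        once, _ = filter_by_coverage(obs, threshold)
        twice, _ = filter_by_coverage(once, threshold)
        assert sorted(twice["vessel_id"]) == sorted(once["vessel_id"])
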