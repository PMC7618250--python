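"""Design rules, data-quality filters and density series."""

import numpy as np
import pandas as pd
import pytest

import flocknet as fn
from flocknet.config import ExperimentDesign, FlockNetError
from flocknet.flocks import FlockEvent


class TestFeederRoles:
    FEEDERS = {f"S{i}": (f"S{i}a", f"S{i}b") for i in range(1, 7)}

    def test_half_of_sites_majority_high(self):
        counts = {f: (900 if f.endswith("a") else 100) for pair in self.FEEDERS.values() for f in pair}
        roles = fn.assign_feeder_roles(counts, self.FEEDERS, control_sites=[], seed=3)
        majority_high = sum(roles[f"S{i}a"] == "high" for i in range(1, 7))
        assert majority_high == 3
        for site, (f1, f2) in self.FEEDERS.items():
            assert {roles[f1], roles[f2]} == {"low", "high"}

    def test_majority_feeder_gets_high_at_chosen_sites(self):
        counts = {"S1a": 100, "S1b": 900}
        feeders = {"S1": ("S1a", "S1b")}
        for seed in range(10):
            roles = fn.assign_feeder_roles(counts, feeders, control_sites=[], seed=seed)
            majority_role = roles["S1b"]
            assert {roles["S1a"], roles["S1b"]} == {"low", "high"}
            # whichever arm was drawn, the rule maps the majority feeder
            assert majority_role in ("low", "high")

    def test_control_sites_untouched(self):
        feeders = {"S1": ("S1a", "S1b"), "C1": ("C1a", "C1b")}
        roles = fn.assign_feeder_roles({"S1a": 5, "S1b": 9}, feeders, control_sites=["C1"], seed=0)
        assert roles["C1a"] == roles["C1b"] == "control"

    def test_deterministic(self):
        counts = {f: (900 if f.endswith("a") else 100) for pair in self.FEEDERS.values() for f in pair}
        r1 = fn.assign_feeder_roles(counts, self.FEEDERS, [], seed=11)
        r2 = fn.assign_feeder_roles(counts, self.FEEDERS, [], seed=11)
        assert r1 == r2


class TestBirdTreatments:
    def test_twenty_percent_of_twenty(self):
        pre = {"S1": {f"b{i}": 150 for i in range(20)}}
        tr = fn.assign_bird_treatments(pre, min_records=100, low_fraction=0.2, seed=0)
        assert sum(v == "low" for v in tr.values()) == 4

    def test_just_under_threshold_never_low(self):
        pre = {"S1": {"edge": 99, **{f"b{i}": 200 for i in range(10)}}}
        for seed in range(20):
            tr = fn.assign_bird_treatments(pre, min_records=100, seed=seed)
            assert tr[("S1", "edge")] == "high"

    def test_deterministic(self):
        pre = {"S1": {f"b{i}": 150 for i in range(25)}}
        assert fn.assign_bird_treatments(pre, seed=9) == fn.assign_bird_treatments(pre, seed=9)

    def test_no_eligible_birds_raises(self):
        with pytest.raises(FlockNetError, match="S1"):
            fn.assign_bird_treatments({"S1": {"b0": 10}}, min_records=100)


def make_design(days_pre=2, days_exp=2):
    d = ExperimentDesign(
        feeders={"S1": ("S1a", "S1b")},
        roles={"S1a": "low", "S1b": "high"},
        days_pre=days_pre,
        days_exp=days_exp,
    )
    return d


def visits_frame(rows):
    df = pd.DataFrame(rows, columns=["time", "tag", "feeder", "site", "access", "day"])
    return df


class TestFilterFailedDays:
    def test_single_silent_feeder_drops_day(self):
        design = make_design()
        rows = [(100.0 + i, "b1", "S1a", "S1", 1, 0) for i in range(5)]
        rows += [(90_000.0 + i, "b1", "S1a", "S1", 1, 1) for i in range(3)]
        rows += [(90_500.0 + i, "b2", "S1b", "S1", 1, 1) for i in range(3)]
        kept, log = fn.filter_failed_days(visits_frame(rows), design)
        assert set(kept["day"]) == {1}
        reasons = dict(zip(log["day"], log["reason"]))
        assert reasons[0] == "failed-day"

    def test_planted_failure_fraction_recovered(self):
        """Silencing a fraction of feeder-days is reported as that fraction."""
        rng = np.random.default_rng(0)
        n_days = 50
        design = make_design(days_pre=25, days_exp=25)
        rows = []
        failed = set()
        for day in range(n_days):
            fail_here = rng.random() < 0.22
            if fail_here:
                failed.add(day)
            for feeder in ("S1a", "S1b"):
                if fail_here and feeder == "S1a":
                    continue
                rows.append((day * 86_400.0 + 30_000, "b1", feeder, "S1", 1, day))
        kept, log = fn.filter_failed_days(visits_frame(rows), design)
        assert set(log["day"]) == failed
        assert log.attrs["exclusion_fraction"] == pytest.approx(len(failed) / n_days)


class TestSiteDensity:
    def test_proportions_and_counts(self):
        design = make_design()
        rows = [(i + 0.0, f"b{i % 3}", "S1a", "S1", 1, 0) for i in range(90)]
        rows += [(i + 200.0, "b9", "S1b", "S1", 1, 0) for i in range(10)]
        events = [
            FlockEvent("S1a", 0, 50, frozenset({"b0", "b1"}), 4),
            FlockEvent("S1a", 60, 80, frozenset({"b0", "b1", "b2"}), 5),
            FlockEvent("S1a", 85, 90, frozenset({"b0", "b1", "b2", "b3"}), 5),
            FlockEvent("S1b", 200, 210, frozenset({"b9"}), 10),
        ]
        df = fn.site_density_series(visits_frame(rows), events, design)
        a = df[df.feeder == "S1a"].iloc[0]
        b = df[df.feeder == "S1b"].iloc[0]
        assert a.proportion_of_recordings == pytest.approx(0.9)
        assert b.proportion_of_recordings == pytest.approx(0.1)
        assert a.proportion_of_recordings + b.proportion_of_recordings == 1.0
        assert a.n_individuals == 3 and b.n_individuals == 1
        assert a.mean_flock_size == pytest.approx(3.0)  # sizes 2, 3, 4


class TestIndividualDensity:
    def _design(self):
        d = make_design(days_pre=1, days_exp=1)
        d.treatments = {("S1", "b1"): "low", ("S1", "b2"): "high"}
        return d

    def test_prop_assigned_and_thresholds(self):
        design = self._design()
        rows = []
        # b1 (low): 100 reads pre, 100 during of which 80 at low feeder
        for i in range(100):
            rows.append((i * 1.0, "b1", "S1a", "S1", 1, 0))
        for i in range(80):
            rows.append((86_400.0 + i, "b1", "S1a", "S1", 1, 1))
        for i in range(20):
            rows.append((86_400.0 + 200 + i, "b1", "S1b", "S1", 0, 1))
        # b2 (high): 100 pre but only 99 during -> excluded
        for i in range(100):
            rows.append((i * 1.0 + 0.5, "b2", "S1b", "S1", 1, 0))
        for i in range(99):
            rows.append((86_400.0 + i + 0.5, "b2", "S1b", "S1", 1, 1))
        df = fn.individual_density_series(visits_frame(rows), [], design, min_records=100)
        assert set(df["tag"]) == {"b1"}
        during = df[(df.tag == "b1") & (df.period == "during")].iloc[0]
        assert during.prop_assigned_visits == pytest.approx(0.8)

    def test_mean_flock_size(self):
        design = self._design()
        rows = [(i * 1.0, "b1", "S1a", "S1", 1, 0) for i in range(100)]
        rows += [(86_400.0 + i, "b1", "S1a", "S1", 1, 1) for i in range(100)]
        events = [
            FlockEvent("S1a", 10, 20, frozenset({"b1", "x", "y"}), 5),
            FlockEvent("S1a", 100, 120, frozenset({"b1", "x", "y", "z", "w"}), 5),
        ]
        df = fn.individual_density_series(visits_frame(rows), events, design, min_records=100)
        pre = df[(df.tag == "b1") & (df.period == "pre")].iloc[0]
        assert pre.mean_flock_size == pytest.approx(4.0)  # flocks of 3 and 5

    def test_full_compliance_assigned_proportion_is_one(self):
        """With c = 1 every access-granted during-period read of an assigned
        bird is at its assigned feeder."""
        cfg = fn.SimConfig(
            n_sites=1, birds_per_site=14, days_pre=2, days_exp=4, flock_rate=1.0, compliance=1.0, seed=5
        )
        pop, design, visits, _ = fn.simulate_experiment(cfg, min_records=5)
        granted = visits[visits["access"] == 1]
        df = fn.individual_density_series(granted, [], design, min_records=5)
        during = df[df.period == "during"]
        assert len(during) > 0
        assert np.allclose(during["prop_assigned_visits"], 1.0)
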