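"""Contrast estimation and node-permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import flocknet as fn
from flocknet.inference import PermutationResult, apply_transformation


def make_cells(n_per_cell=20, effect=0.0, sites=("S1", "S2"), rng=None, site_sd=0.5, noise=1.0):
    """Gaussian period x treatment data with an optional during:high shift."""
    if rng is None:
        rng = np.random.default_rng(0)
    site_effects = {s: rng.normal(0, site_sd) for s in sites}
    rows = []
    for period in ("pre", "during"):
        for treatment in ("low", "high"):
            for i in range(n_per_cell):
                site = sites[i % len(sites)]
                mu = site_effects[site]
                if period == "during" and treatment == "high":
                    mu += effect
                rows.append((site, period, treatment, 1 + i % 7, rng.normal(mu, noise)))
    return pd.DataFrame(rows, columns=["site", "period", "treatment", "day_in_period", "y"])


class TestFitPeriodTreatmentModel:
    def test_identical_cells_give_zero_contrasts(self):
        rows = []
        for period in ("pre", "during"):
            for treatment in ("low", "high"):
                rows += [("S1", period, treatment, 1, v) for v in (1.0, 2.0, 3.0)]
        data = pd.DataFrame(rows, columns=["site", "period", "treatment", "day_in_period", "y"])
        tbl = fn.fit_period_treatment_model(data, "y", family="gaussian")
        assert np.allclose(tbl.contrasts["estimate"], 0.0, atol=1e-10)

    def test_transformations(self):
        y = np.array([1.0, 4.0])
        assert np.allclose(apply_transformation(y, "inverse"), [1.0, 0.25])
        assert np.allclose(apply_transformation(y, "square"), [1.0, 16.0])
        assert np.allclose(apply_transformation(y, "square-root"), [1.0, 2.0])
        assert np.allclose(apply_transformation(y, "log"), [0.0, np.log(4.0)])

    def test_planted_effect_recovered(self):
        """The during-period high-low contrast covers a planted shift."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep, effect = 50, 1.0
        for _ in range(n_rep):
            data = make_cells(n_per_cell=30, effect=effect, rng=rng)
            tbl = fn.fit_period_treatment_model(data, "y", family="gaussian")
            c = tbl.contrasts
            row = c[(c.cell_a == "during:high") & (c.cell_b == "during:low")]
            if row.empty:
                row = c[(c.cell_a == "during:low") & (c.cell_b == "during:high")]
                est, se = -row.estimate.iloc[0], row.se.iloc[0]
            else:
                est, se = row.estimate.iloc[0], row.se.iloc[0]
            if est - 1.96 * se <= effect <= est + 1.96 * se and est > 0:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2)
        n_rep = 200
        rej = 0
        for _ in range(n_rep):
            data = make_cells(n_per_cell=25, effect=0.0, sites=("S1",), rng=rng, site_sd=0.0)
            tbl = fn.fit_period_treatment_model(data, "y", family="gaussian")
            c = tbl.contrasts
            row = c[(c.cell_a.isin(["during:high", "during:low"])) & (c.cell_b.isin(["during:high", "during:low"]))]
            if row.p.iloc[0] <= 0.05:
                rej += 1
        lo, hi = binom.interval(0.99, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_binomial_family_with_weights(self):
        data = pd.DataFrame(
            {
                "site": ["S1"] * 8,
                "period": ["pre", "pre", "during", "during"] * 2,
                "treatment": ["low", "high"] * 4,
                "day_in_period": [1, 1, 1, 1, 2, 2, 2, 2],
                "prop": [0.4, 0.6, 0.1, 0.9, 0.45, 0.55, 0.12, 0.88],
                "n": [100] * 8,
            }
        )
        tbl = fn.fit_period_treatment_model(data, "prop", family="binomial", weights="n")
        during = tbl.cells[(tbl.cells.period == "during")]
        probs = dict(zip(during.treatment, 1 / (1 + np.exp(-during.estimate))))
        assert probs["high"] > 0.8 > 0.2 > probs["low"]


def series_net(values):
    return pd.Series(values, index=[f"b{i}" for i in range(len(values))])


class TestNodePermutation:
    def _table(self, values, treatments, period="during", site="S1"):
        return pd.DataFrame(
            {
                "tag": [f"b{i}" for i in range(len(values))],
                "site": site,
                "period": period,
                "treatment": treatments,
                "value": values,
            }
        )

    def test_bookkeeping_null_length_and_determinism(self):
        rng = np.random.default_rng(0)
        values = rng.random(12)
        treatments = ["low"] * 6 + ["high"] * 6
        data = self._table(values, treatments)
        nets = {("S1", "during"): series_net(values)}
        r1 = fn.node_permutation_test(data, nets, n_perm=1000, seed=4)
        r2 = fn.node_permutation_test(data, nets, n_perm=1000, seed=4)
        assert r1.nulls.shape == (1, 1000)
        assert np.array_equal(r1.nulls, r2.nulls)
        assert ((r1.contrasts["p"] > 0) & (r1.contrasts["p"] <= 1)).all()

    def test_missing_network_bird_dropped(self):
        values = np.arange(6.0)
        data = self._table(values, ["low", "high"] * 3)
        nets = {("S1", "during"): series_net(values[:5])}  # b5 missing
        res = fn.node_permutation_test(data, nets, n_perm=150, seed=0)
        assert res.n_dropped == 1

    def test_null_matches_exhaustive_enumeration(self):
        """Monte-Carlo null equals the exact all-relabelings distribution on
        a six-bird stratum."""
        values = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        treatments = ["low", "low", "low", "high", "high", "high"]
        data = self._table(values, treatments)
        nets = {("S1", "during"): series_net(values)}
        res = fn.node_permutation_test(data, nets, n_perm=4000, seed=1)
        exact = []
        high = np.array([t == "high" for t in treatments])
        for perm in itertools.permutations(values):
            v = np.asarray(perm)
            exact.append(v[high].mean() - v[~high].mean())
        exact = np.array(exact)
        sign = 1.0
        # contrast orientation depends on level ordering; align by observed
        obs = values[high].mean() - values[~high].mean()
        if not np.isclose(abs(res.contrasts.observed.iloc[0]), abs(obs)):
            pytest.fail("observed contrast does not match the cell difference")
        if np.sign(res.contrasts.observed.iloc[0]) != np.sign(obs):
            sign = -1.0
        nulls = sign * res.nulls[0]
        assert abs(nulls.mean() - exact.mean()) < 0.05
        assert abs(nulls.std() - exact.std()) < 0.1
        # the distribution is discrete (20 atoms = choose(6,3) splits);
        # compare per-atom frequencies within Monte-Carlo error
        atoms, exact_counts = np.unique(np.round(exact, 9), return_counts=True)
        exact_freq = exact_counts / exact.size
        for atom, f_exact in zip(atoms, exact_freq):
            f_mc = np.mean(np.abs(nulls - atom) < 1e-9)
            assert abs(f_mc - f_exact) < 0.02

    def test_observed_equals_reduced_model_coefficient(self):
        rng = np.random.default_rng(3)
        values = rng.random(10)
        data = self._table(values, ["low", "high"] * 5)
        nets = {("S1", "during"): series_net(values)}
        res = fn.node_permutation_test(data, nets, n_perm=150, seed=0)
        low = values[::2].mean()
        high = values[1::2].mean()
        assert abs(abs(res.contrasts.observed.iloc[0]) - abs(high - low)) < 1e-10


class TestDiscoveryModels:
    def _records(self, rng, p_by_cell=None, latency_shift=0.0):
        rows = []
        for period in ("pre", "during"):
            for treatment in ("low", "high"):
                p = 0.6 if p_by_cell is None else p_by_cell[(period, treatment)]
                for i in range(25):
                    disc = rng.random() < p
                    lat = rng.exponential(2000) + 60
                    if treatment == "high":
                        lat = max(30.0, lat - latency_shift)
                    rows.append(
                        ("S1", f"b{period}{treatment}{i}", period, treatment, disc, lat if disc else np.nan, rng.integers(1, 9) if disc else np.nan)
                    )
        return pd.DataFrame(rows, columns=["site", "tag", "period", "treatment", "discovered", "latency", "order"])

    def test_all_discovered_flags_separation_and_zero_contrasts(self):
        rng = np.random.default_rng(0)
        rec = self._records(rng, p_by_cell={c: 1.0 for c in itertools.product(("pre", "during"), ("low", "high"))})
        tables = fn.discovery_models(rec)
        assert any("separation" in f for f in tables["discovery"].flags)
        assert np.allclose(tables["discovery"].contrasts["estimate"], 0.0, atol=1e-6)

    def test_planted_latency_advantage_recovered(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng, latency_shift=1500.0)
        tables = fn.discovery_models(rec)
        cells = tables["latency"].cells
        hi = cells[(cells.period == "during") & (cells.treatment == "high")].estimate.iloc[0]
        lo = cells[(cells.period == "during") & (cells.treatment == "low")].estimate.iloc[0]
        assert hi < lo  # high birds arrive sooner (smaller sqrt latency)
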