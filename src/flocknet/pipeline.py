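"""End-to-end pipeline: simulate -> detect -> networks -> metrics ->
assortment -> permutation inference -> patch discovery.

Given a :class:`~flocknet.io.RunConfig`, the driver either simulates a
colony or loads a visit log, applies the design rules (feeder roles from
pre-period majorities, 20% low-density assignment among eligible birds),
filters failed days, detects flocking events, builds daily and
site-period SRI networks, computes density and network metrics, runs the
assortment and node-permutation analyses and scores simulated patch
discovery trials.  All artifacts are CSVs with schema sidecars plus a
JSON manifest; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assortment import assortment_null, daily_assortment
from .config import (
    PERIOD_DURING,
    PERIOD_PRE,
    TREATMENT_CONTROL,
    ExperimentDesign,
    FlockNetError,
    SimConfig,
)
from .density import (
    assign_bird_treatments,
    assign_feeder_roles,
    filter_failed_days,
    individual_density_series,
    site_density_series,
)
from .discovery import DiscoveryTrial, score_discovery, select_trial_birds
from .flocks import detect_events
from .inference import discovery_models, node_permutation_test
from .io import (
    RunConfig,
    events_to_frame,
    write_design,
    write_events_csv,
    write_manifest,
    write_table,
    write_visit_log,
)
from .network import daily_networks, global_metrics, node_metrics, site_period_network
from .simulate import Population, feeder_names, simulate_discovery_trial, simulate_population, simulate_visits, site_names

logger = logging.getLogger(__name__)

NODE_METRIC_NAMES = [
    "weighted_degree",
    "average_association_strength",
    "weighted_clustering",
    "weighted_eigenvector",
]


def build_design(config: SimConfig, n_control_sites: int = 0) -> ExperimentDesign:
    """Site/feeder layout with empty roles and treatments (pre-period)."""
    feeders = {s: feeder_names(s) for s in site_names(config)}
    return ExperimentDesign(feeders=feeders, days_pre=config.days_pre, days_exp=config.days_exp)


def simulate_experiment(
    config: SimConfig,
    n_control_sites: int = 0,
    min_records: int | None = None,
) -> tuple[Population, ExperimentDesign, pd.DataFrame, pd.DataFrame]:
    """Full two-phase simulation mirroring the field protocol.

    The pre-period is simulated first with open feeders; feeder roles and
    bird treatments are then assigned from the observed pre-period counts
    (majority-feeder rule, 20% of eligible birds to low density), and the
    experimental period is simulated under the finished design.  Returns
    (population, design, visits, planted truth).
    """
    if n_control_sites >= config.n_sites:
        raise FlockNetError("need at least one experimental site")
    if min_records is None:
        min_records = config.eligibility_min_reads
    pop = simulate_population(config)
    design = build_design(config)
    sites = site_names(config)
    control = sites[config.n_sites - n_control_sites :]

    pre_visits, pre_truth = simulate_visits(pop, config, design, days=range(config.days_pre))
    pre_counts = pre_visits.groupby("feeder").size().to_dict()
    design.roles = assign_feeder_roles(pre_counts, design.feeders, control, seed=config.seed + 1)
    per_site = {
        site: pre_visits[pre_visits["site"] == site].groupby("tag").size().to_dict()
        for site in sites
        if site not in set(control)
    }
    design.treatments = assign_bird_treatments(
        per_site, min_records=min_records, low_fraction=config.low_fraction, seed=config.seed + 2
    )
    for site in control:
        for tag in pop.site_tags(site):
            design.treatments[(site, tag)] = TREATMENT_CONTROL
    design.validate()

    during_visits, during_truth = simulate_visits(
        pop, config, design, days=range(config.days_pre, config.n_days)
    )
    visits = pd.concat([pre_visits, during_visits], ignore_index=True)
    visits = visits.sort_values(["site", "feeder", "time"], kind="mergesort").reset_index(drop=True)
    truth = pd.concat([pre_truth, during_truth], ignore_index=True)
    return pop, design, visits, truth


def _treatment_labels(design: ExperimentDesign, site: str) -> dict[str, str]:
    return {tag: tr for (s, tag), tr in design.treatments.items() if s == site}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "seed": config.seed,
        "exclusions": {},
        "stages": [],
    }

    try:
        # --- simulate (or load) ------------------------------------------
        sim = SimConfig(**{**config.sim, "seed": config.seed})
        pop, design, visits, truth = simulate_experiment(
            sim, n_control_sites=config.control_sites, min_records=config.min_records
        )
        write_visit_log(visits, out / "visits.csv")
        write_table(truth, out / "planted_events.csv")
        write_design(design, out / "design_roles.csv", out / "design_treatments.csv")
        manifest["stages"].append("simulate")

        # --- failed-day filter + detection -------------------------------
        visits_kept, fail_log = filter_failed_days(visits, design)
        write_table(fail_log, out / "excluded_days.csv")
        manifest["exclusions"]["failed_days"] = {
            "n": int(len(fail_log)),
            "fraction": fail_log.attrs.get("exclusion_fraction", 0.0),
            "rule": "site-day with a silent feeder",
        }
        events = detect_events(
            visits_kept, tau=config.tau, k_max=config.k_max, method=config.detector, window=config.window
        )
        write_events_csv(events, out / "events.csv")
        manifest["stages"].append("detect")

        # --- density metrics ---------------------------------------------
        site_density = site_density_series(visits_kept, events, design)
        write_table(site_density, out / "site_density.csv")
        indiv_density = individual_density_series(
            visits_kept, events, design, min_records=config.min_records
        )
        write_table(indiv_density, out / "individual_density.csv")
        n_recorded_pairs = len(visits_kept[["site", "tag"]].drop_duplicates())
        n_retained_pairs = len(indiv_density[["site", "tag"]].drop_duplicates())
        manifest["exclusions"]["individual_min_records"] = {
            "n": int(n_recorded_pairs - n_retained_pairs),
            "rule": f"fewer than {config.min_records} reads in either period at the site",
        }
        manifest["stages"].append("metrics")

        # --- daily feeder networks + global metrics ----------------------
        daily, drop_log = daily_networks(events)
        write_table(drop_log, out / "excluded_networks.csv")
        manifest["exclusions"]["sparse_networks"] = {
            "n": int(len(drop_log)),
            "rule": "fewer than three connected individuals",
        }
        g_rows = []
        for day, feeder, net in daily:
            gm = global_metrics(net)
            if gm is None:
                continue
            site = design.site_of_feeder(feeder)
            g_rows.append(
                (
                    site,
                    feeder,
                    design.roles.get(feeder, ""),
                    day,
                    design.period_of_day(day),
                    design.day_in_period(day),
                    gm.n_nodes,
                    gm.network_density,
                    gm.average_edge_weight,
                    gm.global_clustering,
                )
            )
        global_df = pd.DataFrame(
            g_rows,
            columns=[
                "site",
                "feeder",
                "treatment",
                "day",
                "period",
                "day_in_period",
                "n_nodes",
                "network_density",
                "average_edge_weight",
                "global_clustering",
            ],
        )
        write_table(global_df, out / "global_metrics.csv")
        manifest["stages"].append("networks")

        # --- site-period networks, node metrics, assortment --------------
        node_rows = []
        assort_rows = []
        nets: dict[tuple[str, str], pd.Series] = {}
        metric_series: dict[str, dict[tuple[str, str], pd.Series]] = {m: {} for m in NODE_METRIC_NAMES}
        for site in design.sites:
            labels = _treatment_labels(design, site)
            for period, days in (
                (PERIOD_PRE, range(design.days_pre)),
                (PERIOD_DURING, range(design.days_pre, design.n_days)),
            ):
                sp = site_period_network(events, design.feeders[site], days, scope=f"{site}/{period}")
                if sp is None:
                    continue
                net, gbi = sp
                nm = node_metrics(net, gbi)
                for m in NODE_METRIC_NAMES:
                    metric_series[m][(site, period)] = nm[m]
                for tag, row in nm.iterrows():
                    node_rows.append(
                        (site, period, tag, design.treatments.get((site, tag), ""), *row.tolist())
                    )
                edge_df = net.edge_list()
                write_table(edge_df, out / f"network_{site}_{period}.csv")
                if site in design.experimental_sites and len(set(labels.get(t) for t in net.nodes if t in labels)) >= 2:
                    res = assortment_null(net, labels, n_perm=config.n_perm, seed=config.seed + 7)
                    assort_rows.append(
                        (site, period, res.r, res.se, res.null_low, res.null_high, res.p, res.n_perm)
                    )
        node_df = pd.DataFrame(
            node_rows,
            columns=["site", "period", "tag", "treatment"] + NODE_METRIC_NAMES + ["mean_flock_size"],
        )
        write_table(node_df, out / "node_metrics.csv")
        assort_df = pd.DataFrame(
            assort_rows, columns=["site", "period", "r", "se", "null_low", "null_high", "p", "n_perm"]
        )
        write_table(assort_df, out / "assortment.csv")
        daily_exp = [
            (day, feeder, net)
            for day, feeder, net in daily
            if design.site_of_feeder(feeder) in design.experimental_sites
        ]
        daily_labels: dict[str, str] = {}
        for site in design.experimental_sites:
            daily_labels.update(_treatment_labels(design, site))
        daily_df, daily_skip = daily_assortment(
            daily_exp, daily_labels, n_perm=config.n_perm, seed=config.seed + 8
        )
        write_table(daily_df, out / "assortment_daily.csv")
        manifest["exclusions"]["assortment_days"] = {
            "n": int(len(daily_skip)),
            "rule": "fewer than two individuals of each treatment",
        }
        manifest["stages"].append("assort")

        # --- node-permutation inference ----------------------------------
        analysis = node_df[
            node_df["treatment"].isin(["low", "high"])
            & node_df["tag"].isin(indiv_density["tag"])
        ].rename(columns={})
        perm_rows = []
        for metric in NODE_METRIC_NAMES:
            tbl = analysis[["tag", "site", "period", "treatment", metric]].rename(
                columns={metric: "value"}
            ).dropna(subset=["value"])
            if tbl.empty or tbl["treatment"].nunique() < 2:
                continue
            res = node_permutation_test(
                tbl, metric_series[metric], n_perm=config.n_perm, seed=config.seed + 9
            )
            for row in res.contrasts.itertuples():
                perm_rows.append(
                    (metric, row.cell_a, row.cell_b, row.observed, row.null_low, row.null_high, row.p, bool(row.significant))
                )
        perm_df = pd.DataFrame(
            perm_rows,
            columns=["metric", "cell_a", "cell_b", "observed", "null_low", "null_high", "p", "significant"],
        )
        write_table(perm_df, out / "node_permutation.csv")
        manifest["stages"].append("permtest")

        # --- patch discovery ---------------------------------------------
        discovery_records = []
        trial_days = {PERIOD_PRE: design.days_pre - 1, PERIOD_DURING: design.n_days - 1}
        for site in design.sites:
            for period, day in trial_days.items():
                key = (site, period)
                trial = DiscoveryTrial(
                    site=site,
                    period=period,
                    day=day,
                    novel_feeders=(f"{site}-novel1", f"{site}-novel2"),
                )
                days = range(design.days_pre, design.n_days)
                eligible = select_trial_birds(
                    visits, trial, design.feeders[site], days, min_records=config.min_records
                )
                if not eligible:
                    continue
                sp = site_period_network(
                    events,
                    design.feeders[site],
                    range(design.days_pre) if period == PERIOD_PRE else days,
                    scope=f"{site}/{period}",
                )
                if sp is None:
                    continue
                net, _ = sp
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=config.seed + 11, spawn_key=(design.sites.index(site), day))
                )
                arrivals = simulate_discovery_trial(
                    net.nodes, net.weights, sim, trial_length=config.trial_length, rng=rng
                )
                reads = pd.DataFrame(
                    {
                        "time": [trial.start + t for t in arrivals.values()],
                        "tag": list(arrivals.keys()),
                        "feeder": [
                            trial.novel_feeders[int(rng.integers(2))] for _ in arrivals
                        ],
                    }
                )
                scored = score_discovery(reads, trial, eligible)
                scored["treatment"] = [design.treatments.get((site, t), "") for t in scored["tag"]]
                discovery_records.append(scored)
        if discovery_records:
            disc_df = pd.concat(discovery_records, ignore_index=True)
            write_table(disc_df, out / "discovery.csv")
            exp = disc_df[disc_df["treatment"].isin(["low", "high"])]
            if len(exp) and exp["treatment"].nunique() >= 2:
                tables = discovery_models(exp)
                rows = []
                for name, tbl in tables.items():
                    for c in tbl.contrasts.itertuples():
                        rows.append((name, tbl.family, tbl.transformation, c.cell_a, c.cell_b, c.estimate, c.se, c.p, c.p_adj))
                write_table(
                    pd.DataFrame(
                        rows,
                        columns=["response", "family", "transformation", "cell_a", "cell_b", "estimate", "se", "p", "p_adj"],
                    ),
                    out / "discovery_contrasts.csv",
                )
        manifest["stages"].append("discovery")
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "simulate"
        manifest["error"] = str(exc)
        write_manifest(out / "manifest.json", manifest)
        raise
    write_manifest(out / "manifest.json", manifest)
    return out
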