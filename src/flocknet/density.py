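"""Experimental design rules and local-density measures.

Implements the feeder-role assignment (at half of the experimental sites
the pre-period majority feeder becomes the high-density feeder, at the
other half the low-density feeder), the 20%-of-eligible-birds low-density
assignment (eligible = recorded at least ``min_records`` times in the
pre-period), the failed-day filter (days on which one feeder of a site
recorded nothing are excluded), and the site- and individual-level
density series: daily proportion of recordings per feeder, daily number
of distinct birds, daily mean flock size, per-bird proportion of visits
to the assigned feeder and per-bird mean flock size.

"Recordings" are raw antenna reads; denied-access reads count, since all
perched birds are recorded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    ROLE_CONTROL,
    ROLE_HIGH,
    ROLE_LOW,
    TREATMENT_HIGH,
    TREATMENT_LOW,
    ExperimentDesign,
    FlockNetError,
)
from .flocks import FlockEvent

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECORDS = 100
DEFAULT_LOW_FRACTION = 0.20


def assign_feeder_roles(
    pre_counts: dict[str, int],
    feeders: dict[str, tuple[str, str]],
    control_sites: list[str],
    seed: int = 0,
) -> dict[str, str]:
    """Assign low/high roles from pre-period visit counts.

    A uniformly random half of the experimental sites have their majority
    feeder assigned high density; the remainder majority -> low.  Control
    sites get two control feeders.  Tied counts break by feeder identifier
    order (logged).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    exp_sites = sorted(s for s in feeders if s not in set(control_sites))
    n_high = len(exp_sites) // 2
    majority_high = set(rng.choice(exp_sites, size=n_high, replace=False)) if exp_sites else set()
    roles: dict[str, str] = {}
    for site in sorted(feeders):
        f1, f2 = sorted(feeders[site])
        if site in set(control_sites):
            roles[f1] = roles[f2] = ROLE_CONTROL
            continue
        c1, c2 = pre_counts.get(f1, 0), pre_counts.get(f2, 0)
        if c1 == c2:
            logger.info("site %s: tied pre-period counts, tie broken by feeder id order", site)
            majority = f1
        else:
            majority = f1 if c1 > c2 else f2
        minority = f2 if majority == f1 else f1
        if site in majority_high:
            roles[majority], roles[minority] = ROLE_HIGH, ROLE_LOW
        else:
            roles[majority], roles[minority] = ROLE_LOW, ROLE_HIGH
    return roles


def assign_bird_treatments(
    pre_visits: dict[str, dict[str, int]],
    min_records: int = DEFAULT_MIN_RECORDS,
    low_fraction: float = DEFAULT_LOW_FRACTION,
    seed: int = 0,
) -> dict[tuple[str, str], str]:
    """Sample the low-density birds per site from the eligible set.

    ``pre_visits`` maps site -> {tag: pre-period read count}.  Eligible
    birds have at least ``min_records`` reads at the site;
    ``round(low_fraction * n_eligible)`` of them (minimum 1) are sampled
    without replacement into the low-density treatment, every other
    recorded bird retains access at the high-density feeder.  Returns
    ``(site, tag) -> treatment``.
    """
    treatments: dict[tuple[str, str], str] = {}
    for site_index, site in enumerate(sorted(pre_visits)):
        counts = pre_visits[site]
        eligible = sorted(t for t, c in counts.items() if c >= min_records)
        if not eligible:
            raise FlockNetError(f"site {site!r}: no birds with >= {min_records} pre-period reads")
        n_low = max(1, round(low_fraction * len(eligible)))
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(site_index,)))
        low = set(rng.choice(eligible, size=n_low, replace=False))
        for tag in sorted(counts):
            treatments[(site, tag)] = TREATMENT_LOW if tag in low else TREATMENT_HIGH
    return treatments


def filter_failed_days(visits: pd.DataFrame, design: ExperimentDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop site-days on which a feeder recorded nothing.

    A site-day with exactly one silent feeder is excluded as a recording
    failure; a site-day with both feeders silent is excluded as no-data.
    Returns the retained visits and an exclusion log whose attrs carry the
    overall exclusion fraction.
    """
    all_days = range(design.n_days)
    rows = []
    keep_keys = set()
    for site, pair in design.feeders.items():
        f1, f2 = pair
        site_visits = visits[visits["site"] == site]
        per = site_visits.groupby(["day", "feeder"]).size().unstack(fill_value=0)
        for day in all_days:
            c1 = int(per.at[day, f1]) if day in per.index and f1 in per.columns else 0
            c2 = int(per.at[day, f2]) if day in per.index and f2 in per.columns else 0
            if c1 > 0 and c2 > 0:
                keep_keys.add((site, day))
            elif c1 == 0 and c2 == 0:
                rows.append((site, day, "no-data"))
            else:
                rows.append((site, day, "failed-day"))
    log = pd.DataFrame(rows, columns=["site", "day", "reason"])
    n_total = design.n_days * len(design.feeders)
    log.attrs["exclusion_fraction"] = len(log) / n_total if n_total else 0.0
    kept = visits[[(s, d) in keep_keys for s, d in zip(visits["site"], visits["day"])]]
    return kept.reset_index(drop=True), log


def site_density_series(
    visits: pd.DataFrame,
    events: list[FlockEvent],
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Daily per-feeder density measures on (already filtered) visits.

    Columns: site, feeder, role/treatment, day, period, day_in_period,
    n_reads, proportion_of_recordings (the two feeders of a site-day sum
    to 1), n_individuals, mean_flock_size.
    """
    ev_by_fd: dict[tuple[str, int], list[int]] = {}
    for e in events:
        ev_by_fd.setdefault((e.feeder, e.day), []).append(e.size)
    rows = []
    for (site, day), grp in visits.groupby(["site", "day"]):
        site_reads = len(grp)
        assert site_reads > 0, "filtered site-days cannot be empty"
        for feeder in design.feeders[site]:
            sub = grp[grp["feeder"] == feeder]
            sizes = ev_by_fd.get((feeder, int(day)), [])
            rows.append(
                (
                    site,
                    feeder,
                    design.roles.get(feeder, ""),
                    int(day),
                    design.period_of_day(int(day)),
                    design.day_in_period(int(day)),
                    len(sub),
                    len(sub) / site_reads,
                    sub["tag"].nunique(),
                    float(np.mean(sizes)) if sizes else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "feeder",
            "treatment",
            "day",
            "period",
            "day_in_period",
            "n_reads",
            "proportion_of_recordings",
            "n_individuals",
            "mean_flock_size",
        ],
    )


def individual_density_series(
    visits: pd.DataFrame,
    events: list[FlockEvent],
    design: ExperimentDesign,
    min_records: int = DEFAULT_MIN_RECORDS,
) -> pd.DataFrame:
    """Per bird-site-period visiting and flock-size measures.

    Only birds recorded at least ``min_records`` times in *both* periods at
    a site are retained (birds seen at several sites are handled per
    site).  For assigned birds, ``prop_assigned_visits`` is the fraction
    of the bird's reads at its two site feeders made at the feeder it was
    assigned to.
    """
    ev_by_feeder: dict[str, list[FlockEvent]] = {}
    for e in events:
        ev_by_feeder.setdefault(e.feeder, []).append(e)
    visits = visits.copy()
    visits["period"] = [design.period_of_day(d) for d in visits["day"]]
    rows = []
    for site in design.sites:
        pair = design.feeders[site]
        site_v = visits[(visits["site"] == site) & visits["feeder"].isin(pair)]
        counts = site_v.groupby(["tag", "period"]).size().unstack(fill_value=0)
        for required in ("pre", "during"):
            if required not in counts.columns:
                counts[required] = 0
        kept_tags = counts.index[(counts["pre"] >= min_records) & (counts["during"] >= min_records)]
        site_events = [e for f in pair for e in ev_by_feeder.get(f, [])]
        for tag in kept_tags:
            treatment = design.treatments.get((site, tag), "")
            assigned = design.assigned_feeder(site, tag)
            bird_v = site_v[site_v["tag"] == tag]
            for period in ("pre", "during"):
                pv = bird_v[bird_v["period"] == period]
                n = len(pv)
                prop = float((pv["feeder"] == assigned).sum() / n) if assigned and n else np.nan
                sizes = [
                    e.size
                    for e in site_events
                    if tag in e.members and design.period_of_day(e.day) == period
                ]
                rows.append(
                    (
                        site,
                        tag,
                        treatment,
                        period,
                        n,
                        prop,
                        float(np.mean(sizes)) if sizes else np.nan,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["site", "tag", "treatment", "period", "n_reads", "prop_assigned_visits", "mean_flock_size"],
    )
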