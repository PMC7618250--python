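"""Synthetic colony generator.

Produces PIT-tag visit logs with the statistical structure the downstream
analysis assumes: bursty fission-fusion flock visits at two feeders per
site, a pre-experimental and an experimental period, partial compliance of
density-restricted birds, and (optionally) socially transmitted discovery
of novel feeders.  A sidecar table of the planted flock events is returned
alongside the visit stream so detectors can be benchmarked against truth.

Random streams are split per ``(site, day, feeder)`` from the master seed,
so any subset of the study can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    PERIOD_DURING,
    ROLE_CONTROL,
    ROLE_HIGH,
    ROLE_LOW,
    SECONDS_PER_DAY,
    TREATMENT_LOW,
    ConfigError,
    ExperimentDesign,
    FlockNetError,
    SimConfig,
)

VISIT_COLUMNS = ["time", "tag", "feeder", "site", "access", "day"]
TRUTH_COLUMNS = ["site", "feeder", "day", "center", "start", "end", "n_members", "members"]


@dataclass
class Population:
    """Birds, their site membership, pair bonds and pairwise preferences.

    ``preference`` is a symmetric nonnegative matrix with zero diagonal;
    bonded pairs carry strictly larger weights than the non-bonded,
    within-site baseline, and cross-site entries are zero.
    """

    tags: list[str]
    site_of: dict[str, str]
    pair_bonds: set[frozenset]
    preference: np.ndarray

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.tags)}

    def index(self, tag: str) -> int:
        return self._index[tag]

    def site_tags(self, site: str) -> list[str]:
        return [t for t in self.tags if self.site_of[t] == site]


def site_names(config: SimConfig) -> list[str]:
    return [f"S{i + 1}" for i in range(config.n_sites)]


def feeder_names(site: str) -> tuple[str, str]:
    return (f"{site}a", f"{site}b")


def _rng_for(seed: int, site_index: int, day: int, feeder_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(site_index, day, feeder_index))
    return np.random.default_rng(ss)


def simulate_population(config: SimConfig) -> Population:
    """Create birds, bonded pairs and the pairwise preference matrix.

    Each site receives ``birds_per_site`` birds and
    ``floor(pair_fraction * birds_per_site / 2)`` bonded pairs.  Non-bonded
    within-site preferences are drawn uniformly from [0.05, 0.30); bonded
    pairs from [0.8, 1.0), so bonds always exceed the baseline.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(999,)))
    tags: list[str] = []
    site_of: dict[str, str] = {}
    bonds: set[frozenset] = set()
    for site in site_names(config):
        site_tags = [f"{site}:B{i:03d}" for i in range(config.birds_per_site)]
        tags.extend(site_tags)
        for t in site_tags:
            site_of[t] = site
    n = len(tags)
    pref = np.zeros((n, n))
    index = {t: i for i, t in enumerate(tags)}
    for site in site_names(config):
        members = [t for t in tags if site_of[t] == site]
        idx = np.array([index[t] for t in members])
        k = len(members)
        base = rng.uniform(0.05, 0.30, size=(k, k))
        base = np.triu(base, 1)
        block = base + base.T
        pref[np.ix_(idx, idx)] = block
        # bonded pairs: sample disjoint pairs from a shuffled order
        n_pairs = math.floor(config.pair_fraction * config.birds_per_site / 2)
        order = rng.permutation(k)
        for p in range(n_pairs):
            a, b = members[order[2 * p]], members[order[2 * p + 1]]
            bonds.add(frozenset((a, b)))
            w = rng.uniform(0.8, 1.0)
            pref[index[a], index[b]] = pref[index[b], index[a]] = w
    np.fill_diagonal(pref, 0.0)
    return Population(tags=tags, site_of=site_of, pair_bonds=bonds, preference=pref)


def _access_allowed(design: ExperimentDesign, site: str, tag: str, feeder: str, period: str) -> bool:
    if period != PERIOD_DURING or design.is_control_site(site):
        return True
    role = design.roles.get(feeder)
    treatment = design.treatments.get((site, tag))
    if role == ROLE_LOW:
        return treatment == TREATMENT_LOW
    if role == ROLE_HIGH:
        return treatment != TREATMENT_LOW
    return True


def simulate_visits(
    pop: Population,
    config: SimConfig,
    design: ExperimentDesign,
    days: range | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the antenna read stream and the planted flock events.

    Flocks arrive at each feeder as a Poisson process (rate ``flock_rate``
    per feeder-hour) within the daily recording window.  Each flock is
    seeded with one bird from the pool of birds choosing that feeder and
    recruits further members with probability increasing in the pairwise
    preference; sizes follow a truncated Poisson around
    ``flock_size_mean``.  Each member emits ``1 + Poisson(reads_per_member)``
    reads at ``Normal(centre, read_jitter)`` times clipped to the event.

    During the experimental period, a low-assigned bird picks its assigned
    feeder with probability ``compliance`` and otherwise the high feeder,
    where its visit is recorded with the access flag down; all other birds
    use the high feeder (and would be denied at the low feeder).

    Returns
    -------
    visits, truth:
        ``visits`` has columns ``time, tag, feeder, site, access, day``
        sorted by (site, feeder, time); ``truth`` lists the planted events.
    """
    design.validate()
    if design.n_days < config.n_days:
        raise ConfigError("design periods must cover days_pre + days_exp")
    sites = site_names(config)
    for site in sites:
        if site not in design.feeders:
            raise FlockNetError(f"design is missing site {site!r} present in the population")
    if days is None:
        days = range(config.n_days)

    win_lo, win_hi = config.day_window
    hours = (win_hi - win_lo) / 3600.0
    sigma = config.read_jitter
    rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for si, site in enumerate(sites):
        feeders = design.feeders[site]
        tags = pop.site_tags(site)
        idx = np.array([pop.index(t) for t in tags])
        pref = pop.preference[np.ix_(idx, idx)]
        low_mask = np.array(
            [design.treatments.get((site, t)) == TREATMENT_LOW for t in tags]
        )
        control = design.is_control_site(site)
        for day in days:
            period = design.period_of_day(day)
            day_base = day * SECONDS_PER_DAY
            for fi, feeder in enumerate(feeders):
                rng = _rng_for(config.seed, si, day, fi)
                n_events = rng.poisson(config.flock_rate * hours)
                if n_events == 0:
                    continue
                centers = np.sort(rng.uniform(win_lo, win_hi, size=n_events))
                role = design.roles.get(feeder)
                for center in centers:
                    # pool of birds whose choice, for this event, is this feeder
                    n_tags = len(tags)
                    if period == PERIOD_DURING and not control:
                        follows = rng.random(n_tags) < config.compliance
                        if role == ROLE_LOW:
                            policy_here = low_mask & follows
                        else:
                            policy_here = ~low_mask | (low_mask & ~follows)
                        exploring = rng.random(n_tags) < config.explore_prob
                        explore_here = rng.integers(0, 2, size=n_tags) == fi
                        here = np.where(exploring, explore_here, policy_here)
                    else:
                        here = rng.integers(0, 2, size=n_tags) == fi
                    present = rng.random(n_tags) < config.attendance
                    pool = np.flatnonzero(here & present)
                    if pool.size == 0:
                        continue
                    seed_pos = rng.integers(pool.size)
                    seed_bird = pool[seed_pos]
                    size = min(1 + rng.poisson(max(config.flock_size_mean - 1, 0.0)), pool.size)
                    members = [seed_bird]
                    if size > 1:
                        others = np.delete(pool, seed_pos)
                        raw = 1.0 / (1.0 + np.exp(-config.preference_scale * pref[seed_bird, others]))
                        p = raw / raw.sum()
                        members.extend(rng.choice(others, size=size - 1, replace=False, p=p))
                    ev_lo = max(day_base + win_lo, day_base + center - 3 * sigma)
                    ev_hi = min(day_base + win_hi, day_base + center + 3 * sigma)
                    read_times: list[float] = []
                    for b in members:
                        tag = tags[b]
                        n_reads = 1 + rng.poisson(config.reads_per_member)
                        times = rng.normal(day_base + center, sigma, size=n_reads)
                        times = np.clip(times, ev_lo, ev_hi)
                        allowed = _access_allowed(design, site, tag, feeder, period)
                        for t in times:
                            rows.append((float(t), tag, feeder, site, int(allowed), day))
                        read_times.extend(times)
                    truth_rows.append(
                        (
                            site,
                            feeder,
                            day,
                            float(day_base + center),
                            float(min(read_times)),
                            float(max(read_times)),
                            len(members),
                            ";".join(sorted(tags[b] for b in members)),
                        )
                    )

    visits = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    visits = visits.sort_values(["site", "feeder", "time"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["site", "feeder", "start"], kind="mergesort").reset_index(drop=True)
    return visits, truth


def simulate_discovery_trial(
    nodes: list[str],
    weights: np.ndarray,
    config: SimConfig,
    trial_length: float,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Socially transmitted discovery of a novel feeder on a weighted network.

    In one-minute steps, each naive bird becomes informed with per-minute
    hazard ``discovery_base * (1 + social_effect * z_i)``, where ``z_i`` is
    the summed association weight to already-informed birds.  When
    ``social_effect > 0`` one uniformly chosen bird is seeded informed at a
    random step in the first tenth of the trial, so transmission has a
    source.  Returns arrival time (s from trial start) per informed bird.
    """
    if trial_length <= 0:
        raise FlockNetError("trial_length must be > 0 seconds")
    if len(nodes) == 0:
        raise FlockNetError("network node set must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(nodes)
    steps = int(trial_length // 60)
    informed = np.zeros(n, dtype=bool)
    arrival: dict[str, float] = {}
    seed_step = -1
    seed_bird = -1
    if config.social_effect > 0:
        seed_bird = int(rng.integers(n))
        seed_step = int(rng.integers(max(1, steps // 10)))
    for step in range(steps):
        if step == seed_step:
            informed[seed_bird] = True
            arrival[nodes[seed_bird]] = (step + 1) * 60.0
        z = weights @ informed
        hazard = config.discovery_base * (1.0 + config.social_effect * z)
        p = 1.0 - np.exp(-hazard)
        draws = rng.random(n)
        newly = (~informed) & (draws < p)
        for i in np.flatnonzero(newly):
            arrival[nodes[i]] = (step + 1) * 60.0
        informed |= newly
    return arrival
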