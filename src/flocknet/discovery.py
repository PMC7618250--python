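"""Novel-feeder (patch) discovery scoring.

A discovery trial deploys novel feeders near a site's two selective
feeders for one day.  Eligible birds are those read at the selective
feeders on the trial day that were also recorded at least ``min_records``
times across the density-manipulation period.  A bird discovers when it
has at least one read at any of the trial's novel feeders (whichever of
the two it reaches first); latency is seconds from trial start to first
arrival, and the order of arrival groups birds arriving within 10 minutes
of each other as discovering at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SECONDS_PER_DAY, FlockNetError

TIE_WINDOW = 600.0  # s; arrivals within 10 min share a discovery rank
DEFAULT_MIN_RECORDS = 100


@dataclass(frozen=True)
class DiscoveryTrial:
    """One day of novel feeders at a site."""

    site: str
    period: str
    day: int
    novel_feeders: tuple[str, ...]

    @property
    def start(self) -> float:
        """Trial start: first second of the trial day (feeders are deployed
        before sunrise)."""
        return float(self.day * SECONDS_PER_DAY)


def select_trial_birds(
    visits: pd.DataFrame,
    trial: DiscoveryTrial,
    selective_feeders: tuple[str, str],
    manipulation_days: range,
    min_records: int = DEFAULT_MIN_RECORDS,
) -> list[str]:
    """Birds eligible for a trial's analysis.

    Eligible = read at the site's selective feeders on the trial day AND
    recorded at least ``min_records`` times at those feeders across the
    density-manipulation period.
    """
    at_sel = visits[visits["feeder"].isin(selective_feeders)]
    on_day = set(at_sel.loc[at_sel["day"] == trial.day, "tag"])
    manip = at_sel[at_sel["day"].isin(manipulation_days)]
    counts = manip.groupby("tag").size()
    enough = set(counts.index[counts >= min_records])
    return sorted(on_day & enough)


def order_with_ties(times: np.ndarray, tie_window: float = TIE_WINDOW) -> np.ndarray:
    """Tie-grouped discovery ranks for sorted arrival times.

    Greedy grouping anchored at each group's first arrival: an arrival
    joins the current group iff it is within ``tie_window`` of the group's
    anchor, otherwise it starts the next group.  All members of group g
    receive rank g (starting at 1).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.array([], dtype=int)
    if np.any(np.diff(times) < 0):
        raise FlockNetError("arrival times must be sorted ascending")
    ranks = np.empty(times.size, dtype=int)
    rank = 1
    anchor = times[0]
    for i, t in enumerate(times):
        if t - anchor > tie_window:
            rank += 1
            anchor = t
        ranks[i] = rank
    return ranks


def score_discovery(
    novel_reads: pd.DataFrame,
    trial: DiscoveryTrial,
    eligible: list[str],
    tie_window: float = TIE_WINDOW,
) -> pd.DataFrame:
    """Score one trial: discovered flag, latency and tie-grouped order.

    ``novel_reads`` holds time-sorted reads at the trial's novel feeders.
    A bird reaching both novel feeders yields one record at its earliest
    arrival.  Reads before the trial start indicate a clock
    misconfiguration and raise.
    """
    reads = novel_reads[novel_reads["feeder"].isin(trial.novel_feeders)]
    if len(reads) and (reads["time"] < trial.start).any():
        raise FlockNetError("novel-feeder reads precede the trial start (clock misconfiguration)")
    first = reads.groupby("tag")["time"].min()
    discoverers = [t for t in eligible if t in first.index]
    arrivals = np.array(sorted(first[t] - trial.start for t in discoverers))
    order_of = {}
    if arrivals.size:
        ranks = order_with_ties(arrivals, tie_window)
        # map arrival time -> rank (ties share times rarely; map per bird)
        sorted_birds = sorted(discoverers, key=lambda t: first[t])
        for bird, rank in zip(sorted_birds, ranks):
            order_of[bird] = int(rank)
    rows = []
    for tag in eligible:
        if tag in order_of:
            latency = float(first[tag] - trial.start)
            rows.append((tag, trial.site, trial.period, True, latency, latency, order_of[tag]))
        else:
            rows.append((tag, trial.site, trial.period, False, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["tag", "site", "period", "discovered", "first_arrival", "latency", "order"],
    )
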