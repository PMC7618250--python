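"""Core configuration and experiment-design types.

Time is modelled internally as seconds from the start of the study; calendar
days are derived by integer division with :data:`SECONDS_PER_DAY`.  This keeps
the pipeline free of timezone/DST ambiguity; ISO 8601 timestamps only appear
at the file boundary (see :mod:`flocknet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SECONDS_PER_DAY = 86_400

PERIOD_PRE = "pre"
PERIOD_DURING = "during"

ROLE_LOW = "low"
ROLE_HIGH = "high"
ROLE_CONTROL = "control"

TREATMENT_LOW = "low"
TREATMENT_HIGH = "high"
TREATMENT_CONTROL = "control"
TREATMENT_UNASSIGNED = "unassigned"


class FlockNetError(Exception):
    """Base class for all package errors."""


class ConfigError(FlockNetError):
    """Invalid configuration value; the message names the offending field."""


class UndefinedMetric(FlockNetError):
    """A metric is undefined on this input (e.g. assortativity with one label)."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic colony generator.

    Defaults mirror the experimental design the pipeline analyses: a
    two-week pre-period followed by a six-week manipulation, feeders active
    during daylight, and 20% of eligible birds assigned to the low-density
    treatment.

    Parameters
    ----------
    n_sites:
        Number of experimental sites (two feeders each).
    birds_per_site:
        PIT-tagged birds resident at each site.
    days_pre, days_exp:
        Length of the pre-experimental and experimental periods in days.
    day_window:
        (start, end) seconds within each day during which feeders record
        (default 07:00-17:00).
    flock_rate:
        Poisson rate of flock arrivals per feeder-hour.
    flock_size_mean:
        Target mean flock size (truncated-Poisson around this value).
    pair_fraction:
        Fraction of birds per site in bonded pairs.
    preference_scale:
        Positive scale applied to pairwise preferences when recruiting flock
        members; larger values make bonded birds co-occur more.
    reads_per_member:
        Mean number of extra antenna reads each flock member emits (each
        member emits ``1 + Poisson(reads_per_member)`` reads).
    read_jitter:
        Standard deviation (s) of read times around the flock centre.
    low_fraction:
        Fraction of eligible birds assigned to the low-density treatment.
    eligibility_min_reads:
        Pre-period read count required before a bird can be assigned.
    compliance:
        Probability that a low-assigned bird's feeder choice follows its
        assignment during the experiment (otherwise it visits the high
        feeder and is recorded but denied access).
    explore_prob:
        Probability that, for a given flock, a bird ignores its policy and
        samples one of the two site feeders uniformly.  This keeps a trickle
        of (recorded, possibly denied) visits by restricted birds at the
        "wrong" feeder, as selective feeders record every perched bird.
    attendance:
        Probability that a bird is present in the feeder area (and hence a
        candidate member) when a given flock forms.  Wild birds forage away
        from the feeders much of the day, so no bird joins anywhere near
        every flock at its feeder.
    discovery_base:
        Baseline per-minute hazard of discovering a novel feeder.
    social_effect:
        Multiplier of the social transmission term in the discovery hazard.
    seed:
        Master seed; all random streams derive from it.
    """

    n_sites: int = 2
    birds_per_site: int = 25
    days_pre: int = 14
    days_exp: int = 42
    day_window: tuple[int, int] = (7 * 3600, 17 * 3600)
    flock_rate: float = 2.0
    flock_size_mean: float = 5.0
    pair_fraction: float = 0.4
    preference_scale: float = 3.0
    reads_per_member: float = 8.0
    read_jitter: float = 60.0
    low_fraction: float = 0.20
    eligibility_min_reads: int = 100
    compliance: float = 0.6
    explore_prob: float = 0.1
    attendance: float = 0.5
    discovery_base: float = 0.005
    social_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "n_sites",
            "birds_per_site",
            "flock_size_mean",
            "preference_scale",
            "read_jitter",
        )
        if self.flock_rate < 0:  # zero is the valid degenerate "no flocks" case
            raise ConfigError(f"flock_rate must be >= 0, got {self.flock_rate}")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("days_pre", "days_exp"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("pair_fraction", "low_fraction", "compliance", "explore_prob", "attendance"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("reads_per_member", "discovery_base", "social_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = self.day_window
        if not 0 <= lo < hi <= SECONDS_PER_DAY:
            raise ConfigError(f"day_window must satisfy 0 <= start < end <= 86400, got {self.day_window}")
        if self.eligibility_min_reads < 0:
            raise ConfigError("eligibility_min_reads must be >= 0")

    @property
    def n_days(self) -> int:
        return self.days_pre + self.days_exp


@dataclass
class ExperimentDesign:
    """Sites, feeder roles, period boundaries and per-bird treatments.

    ``feeders`` maps each site to its two feeder identifiers.  ``roles`` maps
    each feeder to ``low``/``high``/``control``; experimental sites carry
    exactly one low and one high feeder, control sites two control feeders.
    ``treatments`` maps ``(site, tag)`` to the treatment the bird was
    assigned at that site (birds seen at several sites are handled per site).
    """

    feeders: dict[str, tuple[str, str]]
    roles: dict[str, str] = field(default_factory=dict)
    treatments: dict[tuple[str, str], str] = field(default_factory=dict)
    days_pre: int = 14
    days_exp: int = 42

    def validate(self) -> None:
        if self.days_pre < 1 or self.days_exp < 1:
            raise ConfigError("days_pre and days_exp must be >= 1")
        for site, pair in self.feeders.items():
            if len(pair) != 2 or len(set(pair)) != 2:
                raise ConfigError(f"site {site!r} must have exactly two distinct feeders")
            if self.roles:
                site_roles = sorted(self.roles.get(f, "?") for f in pair)
                if site_roles not in (["high", "low"], ["control", "control"]):
                    raise ConfigError(
                        f"site {site!r} feeder roles must be one low + one high "
                        f"or two control, got {site_roles}"
                    )

    # -- lookups -----------------------------------------------------------
    @property
    def sites(self) -> list[str]:
        return sorted(self.feeders)

    @property
    def experimental_sites(self) -> list[str]:
        return [s for s in self.sites if not self.is_control_site(s)]

    @property
    def control_sites(self) -> list[str]:
        return [s for s in self.sites if self.is_control_site(s)]

    def is_control_site(self, site: str) -> bool:
        f1, f2 = self.feeders[site]
        return self.roles.get(f1) == ROLE_CONTROL and self.roles.get(f2) == ROLE_CONTROL

    def site_of_feeder(self, feeder: str) -> str:
        for site, pair in self.feeders.items():
            if feeder in pair:
                return site
        raise KeyError(f"unknown feeder {feeder!r}")

    def feeder_with_role(self, site: str, role: str) -> str:
        for f in self.feeders[site]:
            if self.roles.get(f) == role:
                return f
        raise KeyError(f"site {site!r} has no feeder with role {role!r}")

    def assigned_feeder(self, site: str, tag: str) -> str | None:
        """Feeder the bird may access during the experiment, or None."""
        treatment = self.treatments.get((site, tag), TREATMENT_UNASSIGNED)
        if treatment == TREATMENT_LOW:
            return self.feeder_with_role(site, ROLE_LOW)
        if treatment in (TREATMENT_HIGH, TREATMENT_UNASSIGNED) and not self.is_control_site(site):
            return self.feeder_with_role(site, ROLE_HIGH)
        return None

    # -- periods -----------------------------------------------------------
    def period_of_day(self, day: int) -> str:
        """Period label for an absolute study day (0-based)."""
        return PERIOD_PRE if day < self.days_pre else PERIOD_DURING

    def day_in_period(self, day: int) -> int:
        """1-based experimental day within its period."""
        return day + 1 if day < self.days_pre else day - self.days_pre + 1

    @property
    def n_days(self) -> int:
        return self.days_pre + self.days_exp
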