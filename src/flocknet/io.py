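"""Visit-log dialect, CSV artifacts, run configuration and manifests.

The visit-log dialect is a CSV with header ``timestamp, tag_id,
feeder_id, site_id, access``: ISO 8601 timestamps at second resolution,
string identifiers and a 0/1 access flag, time-sorted within feeder.
Internally time is seconds from the study origin (midnight of the first
day); ISO 8601 only exists at the file boundary.

Every tabular artifact is written with a JSON sidecar declaring its
columns, and each pipeline run writes a manifest listing inputs, seeds,
versions and every exclusion applied with its rule.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SECONDS_PER_DAY, ConfigError, FlockNetError
from .flocks import FlockEvent, GroupByIndividual

VISIT_LOG_COLUMNS = ["timestamp", "tag_id", "feeder_id", "site_id", "access"]
DEFAULT_ORIGIN = datetime(2021, 1, 11)  # midnight starting the study


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    ``seed`` is mandatory: every stochastic stage derives its stream from
    it.  ``sim`` holds synthetic-colony parameter overrides; a run can
    instead start from an existing ``visit_log`` path.
    """

    seed: int
    out_dir: str = "flocknet-run"
    visit_log: str | None = None
    sim: dict = dataclasses.field(default_factory=dict)
    control_sites: int = 0
    tau: float = 600.0
    window: float = 300.0
    k_max: int = 10
    detector: str = "gmm"
    min_records: int = 100
    low_fraction: float = 0.20
    n_perm: int = 1000
    trial_length: float = 36_000.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a YAML mapping")
        if "seed" not in raw:
            raise ConfigError("run config must set an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def read_visit_log(
    path: str | Path, origin: datetime | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read and validate a visit-log CSV.

    Malformed rows (unparseable timestamp, access outside {0, 1}, missing
    values) are rejected with their line numbers collected in the returned
    counts dict; a missing column is fatal.  Returns the internal visit
    table (time, tag, feeder, site, access, day) and
    ``{"total": ..., "kept": ..., "rejected": ..., "rejected_lines": [...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise FlockNetError(f"visit log not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in VISIT_LOG_COLUMNS:
        if col not in raw.columns:
            raise FlockNetError(f"visit log is missing required column {col!r}")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    access_ok = raw["access"].isin(["0", "1"])
    ids_ok = (raw["tag_id"] != "") & (raw["feeder_id"] != "") & (raw["site_id"] != "")
    good = ts.notna() & access_ok & ids_ok
    rejected_lines = [int(i) + 2 for i in raw.index[~good]]  # +2: header + 1-based
    kept = raw[good].copy()
    ts = ts[good]
    if origin is None:
        origin = (
            ts.min().normalize().to_pydatetime() if len(ts) else DEFAULT_ORIGIN
        )
    time_s = (ts - pd.Timestamp(origin)).dt.total_seconds()
    visits = pd.DataFrame(
        {
            "time": time_s.to_numpy(),
            "tag": kept["tag_id"].to_numpy(),
            "feeder": kept["feeder_id"].to_numpy(),
            "site": kept["site_id"].to_numpy(),
            "access": kept["access"].astype(int).to_numpy(),
        }
    )
    visits["day"] = (visits["time"] // SECONDS_PER_DAY).astype(int)
    counts = {
        "total": int(len(raw)),
        "kept": int(len(visits)),
        "rejected": int(len(raw) - len(visits)),
        "rejected_lines": rejected_lines,
    }
    return visits, counts


def write_visit_log(visits: pd.DataFrame, path: str | Path, origin: datetime = DEFAULT_ORIGIN) -> None:
    """Write the internal visit table in the visit-log CSV dialect."""
    out = pd.DataFrame(
        {
            "timestamp": [
                (origin + timedelta(seconds=float(t))).strftime("%Y-%m-%dT%H:%M:%S")
                for t in visits["time"]
            ],
            "tag_id": visits["tag"],
            "feeder_id": visits["feeder"],
            "site_id": visits["site"],
            "access": visits["access"].astype(int),
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    _write_schema(path, VISIT_LOG_COLUMNS)


def events_to_frame(events: list[FlockEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": range(len(events)),
            "feeder": [e.feeder for e in events],
            "day": [e.day for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "n_members": [e.size for e in events],
            "n_reads": [e.n_reads for e in events],
            "members": [";".join(sorted(e.members)) for e in events],
        }
    )


def frame_to_events(frame: pd.DataFrame) -> list[FlockEvent]:
    return [
        FlockEvent(
            feeder=row.feeder,
            start=float(row.start),
            end=float(row.end),
            members=frozenset(str(row.members).split(";")),
            n_reads=int(row.n_reads),
        )
        for row in frame.itertuples()
    ]


def write_events_csv(events: list[FlockEvent], path: str | Path) -> None:
    frame = events_to_frame(events)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    _write_schema(path, list(frame.columns))


def read_events_csv(path: str | Path) -> list[FlockEvent]:
    return frame_to_events(pd.read_csv(path))


def write_gbi_csv(gbi: GroupByIndividual, path: str | Path) -> None:
    """Dense GBI matrix: metadata columns then one 0/1 column per tag."""
    frame = pd.concat(
        [gbi.meta.reset_index(drop=True), pd.DataFrame(gbi.matrix, columns=gbi.tags)], axis=1
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    _write_schema(path, list(frame.columns))


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    _write_schema(path, list(frame.columns))


def _write_schema(path: str | Path, columns: list[str]) -> None:
    sidecar = Path(str(path) + ".schema.json")
    sidecar.write_text(json.dumps({"columns": [str(c) for c in columns]}, indent=1))


def write_design(design, roles_path: str | Path, treatments_path: str | Path) -> None:
    """Persist an experiment design as the two design CSVs."""
    roles = pd.DataFrame(
        [(site, f, design.roles.get(f, "")) for site, pair in sorted(design.feeders.items()) for f in pair],
        columns=["site", "feeder", "role"],
    )
    write_table(roles, roles_path)
    tr = pd.DataFrame(
        [(tag, site, t) for (site, tag), t in sorted(design.treatments.items())],
        columns=["tag", "site", "treatment"],
    )
    write_table(tr, treatments_path)


def read_design(
    roles_path: str | Path,
    treatments_path: str | Path,
    days_pre: int,
    days_exp: int,
):
    """Load an experiment design from the two design CSVs."""
    from .config import ExperimentDesign

    roles_df = pd.read_csv(roles_path)
    feeders: dict[str, tuple[str, str]] = {}
    roles: dict[str, str] = {}
    for site, grp in roles_df.groupby("site"):
        pair = tuple(sorted(grp["feeder"]))
        if len(pair) != 2:
            raise FlockNetError(f"site {site!r} must list exactly two feeders")
        feeders[str(site)] = pair  # type: ignore[assignment]
        for row in grp.itertuples():
            roles[str(row.feeder)] = str(row.role)
    tr_df = pd.read_csv(treatments_path)
    treatments = {
        (str(row.site), str(row.tag)): str(row.treatment) for row in tr_df.itertuples()
    }
    design = ExperimentDesign(
        feeders=feeders, roles=roles, treatments=treatments, days_pre=days_pre, days_exp=days_exp
    )
    design.validate()
    return design


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
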