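"""Flock event detection from feeder read streams.

A raw antenna stream at one feeder is first cut into segments at silence
gaps longer than ``tau`` seconds.  Within each segment, read times are
modelled as a univariate Gaussian mixture fitted by EM for K = 1..K_max
components; K is selected by BIC, reads are labelled by maximum posterior
responsibility, and temporal contiguity is enforced by majority relabeling
so each label occupies one contiguous block of the time-ordered reads.
Each block becomes one non-overlapping flocking event whose member set is
the distinct tags of its reads; events stack into a binary
group-by-individual (GBI) matrix, the sampling unit for associations.

A fixed-window fallback detector (tumbling windows of ``window`` seconds)
is provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SECONDS_PER_DAY, FlockNetError

DEFAULT_TAU = 600.0
DEFAULT_WINDOW = 300.0
DEFAULT_K_MAX = 10
# Component-variance floor. Besides preventing singular components on
# duplicate timestamps, the floor encodes the shortest plausible flocking
# event: a gathering lasting about a minute spreads its reads with an SD of
# roughly 15 s. A near-zero floor lets EM lock a handful of almost-coincident
# reads into a spurious narrow component that beats BIC's penalty and
# over-splits genuine events.
VARIANCE_FLOOR = 225.0  # s^2 (15 s SD)
EM_MAX_ITER = 500
EM_TOL = 1e-6


@dataclass
class ReadSegment:
    """A maximal run of reads at one feeder with inter-read gaps <= tau."""

    feeder: str
    times: np.ndarray
    tags: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tags = np.asarray(self.tags, dtype=object)
        if self.times.size != self.tags.size:
            raise FlockNetError("times and tags must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise FlockNetError("segment read times must be nondecreasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FlockEvent:
    """A non-overlapping gathering at one feeder.

    The interval is the closed [min, max] of the member reads; ``day`` is
    derived from the start time.
    """

    feeder: str
    start: float
    end: float
    members: frozenset
    n_reads: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FlockNetError("event start must be <= end")
        if not self.members:
            raise FlockNetError("event member set must be nonempty")

    @property
    def day(self) -> int:
        return int(self.start // SECONDS_PER_DAY)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GroupByIndividual:
    """Binary events-by-individuals membership matrix.

    Rows are events in chronological order; columns are the sorted union of
    tags.  ``meta`` carries one row of event metadata (feeder, day, start,
    end) per matrix row.
    """

    matrix: np.ndarray
    tags: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tags(self) -> int:
        return self.matrix.shape[1]

    def subset_events(self, mask: np.ndarray) -> "GroupByIndividual":
        meta = self.meta.loc[mask].reset_index(drop=True) if len(self.meta) else self.meta
        return GroupByIndividual(self.matrix[mask], list(self.tags), meta)


def segment_reads(times, tags, feeder: str = "", tau: float = DEFAULT_TAU) -> list[ReadSegment]:
    """Split a time-ordered read stream at silence gaps longer than tau.

    Segments are maximal runs with inter-read gaps <= tau; their
    concatenation reproduces the input.  Unsorted input is an error (no
    silent sorting).
    """
    if tau <= 0:
        raise FlockNetError("tau must be > 0")
    times = np.asarray(times, dtype=float)
    tags = np.asarray(tags, dtype=object)
    if times.size == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise FlockNetError("reads must be sorted by time before segmentation")
    breaks = np.flatnonzero(np.diff(times) > tau) + 1
    pieces_t = np.split(times, breaks)
    pieces_g = np.split(tags, breaks)
    return [ReadSegment(feeder, t, g) for t, g in zip(pieces_t, pieces_g)]


# ---------------------------------------------------------------------------
# univariate Gaussian mixture, EM with deterministic seeding
# ---------------------------------------------------------------------------


def _em_1d(x: np.ndarray, k: int) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Fit a k-component univariate Gaussian mixture; returns (loglik, w, mu, var).

    Means are seeded at evenly spaced quantiles of the sorted times (a
    deterministic k-means-style initialisation); variances share the pooled
    variance and are floored at VARIANCE_FLOOR throughout.
    """
    n = x.size
    q = (np.arange(k) + 0.5) / k
    mu = np.quantile(x, q)
    var = np.full(k, max(np.var(x), VARIANCE_FLOOR))
    w = np.full(k, 1.0 / k)
    loglik = -np.inf
    for _ in range(EM_MAX_ITER):
        # E step: log responsibilities
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        log_w = np.log(w)
        joint = log_pdf + log_w[None, :]
        m = joint.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        new_loglik = float(log_norm.sum())
        resp = np.exp(joint - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VARIANCE_FLOOR)
        if abs(new_loglik - loglik) < EM_TOL:
            loglik = new_loglik
            break
        loglik = new_loglik
    return loglik, w, mu, var


def _posterior_labels(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    log_pdf = (
        -0.5 * np.log(2 * np.pi * var)[None, :]
        - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    )
    joint = log_pdf + np.log(w)[None, :]
    # ties broken toward the earlier-mean component: scan components in
    # order of increasing mean and take the first argmax
    order = np.argsort(mu, kind="mergesort")
    joint_ord = joint[:, order]
    best = np.argmax(joint_ord, axis=1)  # np.argmax returns the first maximum
    return order[best]


def _enforce_contiguity(labels: np.ndarray) -> np.ndarray:
    """Majority-relabel runs interleaved inside another label's span.

    Repeatedly, any label occupying more than one run keeps only its
    longest run; shorter runs adopt the label of their longer neighbour
    run.  Terminates because the run count strictly decreases.
    """
    labels = labels.copy()
    while True:
        # runs as (start, end_exclusive, label)
        runs: list[list[int]] = []
        for i, lab in enumerate(labels):
            if runs and runs[-1][2] == lab:
                runs[-1][1] = i + 1
            else:
                runs.append([i, i + 1, lab])
        counts: dict[int, int] = {}
        for r in runs:
            counts[r[2]] = counts.get(r[2], 0) + 1
        split = [lab for lab, c in counts.items() if c > 1]
        if not split:
            return labels
        # fix the most fragmented label first: keep its longest run
        lab = split[0]
        own = [r for r in runs if r[2] == lab]
        own.sort(key=lambda r: (r[1] - r[0]), reverse=True)
        for r in own[1:]:
            i = runs.index(r)
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            neighbours = [x for x in (left, right) if x is not None]
            best = max(neighbours, key=lambda r2: r2[1] - r2[0])
            labels[r[0] : r[1]] = best[2]


def fit_event_mixture(segment: ReadSegment, k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """Label each read of a segment with its flocking event.

    Fits univariate Gaussian mixtures for K = 1..min(k_max, n_reads),
    selects K by minimum BIC, labels reads by maximum posterior
    responsibility and enforces temporal contiguity.  Returns integer
    labels, renumbered 0..K'-1 in time order.
    """
    if k_max < 1:
        raise FlockNetError("k_max must be >= 1")
    n = len(segment)
    if n == 0:
        raise FlockNetError("segment must contain at least one read")
    if n == 1:
        return np.zeros(1, dtype=int)
    x = segment.times
    best_bic = np.inf
    best_labels = np.zeros(n, dtype=int)
    worse_in_a_row = 0
    for k in range(1, min(k_max, n) + 1):
        loglik, w, mu, var = _em_1d(x, k)
        n_params = 3 * k - 1
        bic = -2.0 * loglik + n_params * np.log(n)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best_labels = _posterior_labels(x, w, mu, var)
            worse_in_a_row = 0
        else:
            # BIC is in practice unimodal in K on these streams; stop after
            # two consecutive non-improvements instead of scanning to k_max
            worse_in_a_row += 1
            if worse_in_a_row >= 2:
                break
    labels = _enforce_contiguity(best_labels)
    # renumber blocks in time order
    out = np.empty(n, dtype=int)
    current = -1
    prev = None
    for i, lab in enumerate(labels):
        if lab != prev:
            current += 1
            prev = lab
        out[i] = current
    return out


def labels_to_events(segment: ReadSegment, labels: np.ndarray) -> list[FlockEvent]:
    """Turn contiguous per-read labels into disjoint flocking events."""
    labels = np.asarray(labels)
    if labels.size != len(segment):
        raise FlockNetError("labels must match segment length")
    if labels.size == 0:
        return []
    seen: set = set()
    prev = None
    for lab in labels:
        if lab != prev:
            if lab in seen:
                raise FlockNetError("labels must be contiguous in time")
            seen.add(lab)
            prev = lab
    events = []
    for lab in dict.fromkeys(labels.tolist()):  # insertion order
        mask = labels == lab
        t = segment.times[mask]
        members = frozenset(segment.tags[mask].tolist())
        events.append(
            FlockEvent(
                feeder=segment.feeder,
                start=float(t.min()),
                end=float(t.max()),
                members=members,
                n_reads=int(mask.sum()),
            )
        )
    return events


def fixed_window_events(times, tags, feeder: str = "", window: float = DEFAULT_WINDOW) -> list[FlockEvent]:
    """Fallback detector: tumbling windows of ``window`` seconds.

    Windows are aligned to the epoch (t // window); each non-empty window
    becomes one event.
    """
    if window <= 0:
        raise FlockNetError("window must be > 0")
    times = np.asarray(times, dtype=float)
    tags = np.asarray(tags, dtype=object)
    if times.size == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise FlockNetError("reads must be sorted by time")
    bins = (times // window).astype(np.int64)
    events = []
    for b in dict.fromkeys(bins.tolist()):
        mask = bins == b
        t = times[mask]
        events.append(
            FlockEvent(
                feeder=feeder,
                start=float(t.min()),
                end=float(t.max()),
                members=frozenset(tags[mask].tolist()),
                n_reads=int(mask.sum()),
            )
        )
    return events


def detect_events(
    visits: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    k_max: int = DEFAULT_K_MAX,
    method: str = "gmm",
    window: float = DEFAULT_WINDOW,
) -> list[FlockEvent]:
    """Detect flocking events per feeder across a visit table.

    ``visits`` needs columns ``time, tag, feeder``; denied-access reads
    still count (all perched birds are recorded).  ``method`` is ``gmm``
    (segment + mixture) or ``window`` (fixed tumbling windows).
    """
    events: list[FlockEvent] = []
    for feeder, grp in visits.groupby("feeder", sort=True):
        t = grp["time"].to_numpy()
        g = grp["tag"].to_numpy()
        if method == "window":
            events.extend(fixed_window_events(t, g, feeder=feeder, window=window))
            continue
        for seg in segment_reads(t, g, feeder=feeder, tau=tau):
            labels = fit_event_mixture(seg, k_max=k_max)
            events.extend(labels_to_events(seg, labels))
    events.sort(key=lambda e: (e.feeder, e.start))
    return events


def events_to_gbi(events: list[FlockEvent]) -> GroupByIndividual:
    """Stack events into a binary group-by-individual matrix.

    Rows follow chronological (start-time) order; columns are the sorted
    union of member tags.  The entry total equals the total number of
    (bird, event) memberships.
    """
    events = sorted(events, key=lambda e: (e.start, e.feeder))
    tags = sorted({t for e in events for t in e.members})
    index = {t: j for j, t in enumerate(tags)}
    mat = np.zeros((len(events), len(tags)), dtype=np.int8)
    meta_rows = []
    for i, e in enumerate(events):
        for t in e.members:
            mat[i, index[t]] = 1
        meta_rows.append((e.feeder, e.day, e.start, e.end, e.size, e.n_reads))
    meta = pd.DataFrame(meta_rows, columns=["feeder", "day", "start", "end", "n_members", "n_reads"])
    return GroupByIndividual(matrix=mat, tags=tags, meta=meta)
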