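"""Simple-ratio-index association networks and their metrics.

The simple ratio index (SRI) for a dyad is the proportion of flocking
events containing either bird in which both occur: ``w_ab = T / D`` with
``T`` the number of events containing both and ``D`` the number containing
at least one.  It ranges from 0 (never in the same flock) to 1 (always
foraging together).  Networks are undirected with weights in [0, 1] and a
zero diagonal.

Global metrics (per feeder-day network): unweighted network density,
average nonzero edge weight, and the unweighted global clustering
coefficient (3 x triangles / connected triples, via the binarized graph).
Node metrics (per site-period network): weighted degree (strength),
average association strength, the Barrat weighted clustering coefficient,
weighted eigenvector centrality (power iteration, scaled to max 1), and
the mean size of the flocks the bird was seen in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import FlockNetError
from .flocks import FlockEvent, GroupByIndividual, events_to_gbi

logger = logging.getLogger(__name__)

EIGEN_TOL = 1e-10
MIN_CONNECTED = 3  # feeder-day networks with fewer connected birds are dropped


@dataclass
class SocialNetwork:
    """Symmetric SRI-weighted association matrix over tagged birds."""

    nodes: list[str]
    weights: np.ndarray
    scope: str = ""
    unobserved: np.ndarray | None = None  # dyads never seen in any event
    together: np.ndarray | None = None  # SRI numerator counts (T)
    either: np.ndarray | None = None  # SRI denominator counts (D)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise FlockNetError("weight matrix shape must match node count")
        if not np.allclose(w, w.T):
            raise FlockNetError("weight matrix must be symmetric")
        if np.any(w < 0) or np.any(w > 1):
            raise FlockNetError("SRI weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_connected(self) -> int:
        """Number of birds with at least one nonzero edge."""
        return int(((self.weights > 0).sum(axis=1) > 0).sum())

    def to_networkx(self, binarize: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(ii, jj):
            if binarize:
                g.add_edge(self.nodes[i], self.nodes[j])
            else:
                g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        return g

    def edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        frame = pd.DataFrame(
            {
                "tag_a": [self.nodes[i] for i in ii],
                "tag_b": [self.nodes[j] for j in jj],
                "weight": self.weights[ii, jj],
            }
        )
        if self.together is not None and self.either is not None:
            frame["n_together"] = self.together[ii, jj]
            frame["n_either"] = self.either[ii, jj]
        return frame


@dataclass
class GlobalMetrics:
    network_density: float
    average_edge_weight: float  # NaN (flagged) when the network has no edges
    global_clustering: float
    n_nodes: int


def sri_network(gbi: GroupByIndividual, scope: str = "") -> SocialNetwork:
    """Build the SRI association network from a group-by-individual matrix.

    Dyads never observed in any event (denominator zero) get weight 0 and
    are flagged in ``unobserved``.
    """
    if gbi.n_tags < 1:
        raise FlockNetError("GBI must have at least one column")
    x = gbi.matrix.astype(np.int64)
    together = x.T @ x  # T_ab
    counts = x.sum(axis=0)
    either = counts[:, None] + counts[None, :] - together  # D_ab
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(either > 0, together / np.maximum(either, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    unobserved = either == 0
    np.fill_diagonal(unobserved, False)
    return SocialNetwork(
        nodes=list(gbi.tags),
        weights=w,
        scope=scope,
        unobserved=unobserved,
        together=together,
        either=either,
    )


def global_metrics(net: SocialNetwork) -> GlobalMetrics | None:
    """Density, mean nonzero edge weight and global clustering.

    Returns ``None`` (a filtered-out signal, distinct from an error) when
    fewer than :data:`MIN_CONNECTED` birds have any connection.
    """
    if net.n_connected() < MIN_CONNECTED:
        return None
    n = net.n_nodes
    upper = np.triu(net.weights, 1)
    edge_weights = upper[upper > 0]
    n_edges = edge_weights.size
    density = n_edges / (n * (n - 1) / 2)
    avg_w = float(edge_weights.mean()) if n_edges else float("nan")
    clustering = nx.transitivity(net.to_networkx(binarize=True))
    return GlobalMetrics(
        network_density=float(density),
        average_edge_weight=avg_w,
        global_clustering=float(clustering),
        n_nodes=n,
    )


def _eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    """Leading-eigenvector scores per connected component, scaled to max 1.

    Power iteration with tolerance EIGEN_TOL; isolated nodes (components of
    size < 2) get 0.  Nonnegativity fixes the eigenvector sign; invariant
    to uniform rescaling of the weights.
    """
    n = w.shape[0]
    scores = np.zeros(n)
    g = nx.from_numpy_array(w)
    for comp in nx.connected_components(g):
        idx = np.array(sorted(comp))
        if idx.size < 2:
            continue
        block = w[np.ix_(idx, idx)]
        v = np.full(idx.size, 1.0 / np.sqrt(idx.size))
        for _ in range(10_000):
            nv = block @ v
            norm = np.linalg.norm(nv)
            if norm == 0:
                break
            nv /= norm
            if np.linalg.norm(nv - v) < EIGEN_TOL:
                v = nv
                break
            v = nv
        v = np.abs(v)
        if v.max() > 0:
            scores[idx] = v / v.max()
    return scores


def _barrat_clustering(w: np.ndarray) -> np.ndarray:
    """Barrat weighted clustering: C_i = [1/(s_i (k_i - 1))] sum over
    triangles (i,j,h) of (w_ij + w_ih)/2 with a_ij a_ih a_jh = 1."""
    a = (w > 0).astype(float)
    s = w.sum(axis=1)
    k = a.sum(axis=1)
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        if k[i] < 2 or s[i] == 0:
            continue
        nbrs = np.flatnonzero(a[i])
        total = 0.0
        for p in range(len(nbrs)):
            for q in range(p + 1, len(nbrs)):
                j, h = nbrs[p], nbrs[q]
                if a[j, h]:
                    total += (w[i, j] + w[i, h]) / 2.0
        # each unordered neighbour pair stands for two ordered (j, h) terms
        c[i] = total * 2.0 / (s[i] * (k[i] - 1))
    return c


def node_metrics(net: SocialNetwork, gbi: GroupByIndividual | None = None) -> pd.DataFrame:
    """Per-bird network position metrics.

    Returns a DataFrame indexed by tag with columns ``weighted_degree``,
    ``average_association_strength`` (NaN for isolated birds),
    ``weighted_clustering``, ``weighted_eigenvector`` and, when a GBI is
    supplied, ``mean_flock_size`` over the events containing the bird.
    """
    w = net.weights
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_assoc = np.where(degree > 0, strength / np.maximum(degree, 1), np.nan)
    clustering = _barrat_clustering(w)
    eigen = _eigenvector_centrality(w)
    out = pd.DataFrame(
        {
            "weighted_degree": strength,
            "average_association_strength": avg_assoc,
            "weighted_clustering": clustering,
            "weighted_eigenvector": eigen,
        },
        index=pd.Index(net.nodes, name="tag"),
    )
    if gbi is not None:
        sizes = gbi.matrix.sum(axis=1)
        mfs = []
        for tag in net.nodes:
            if tag in gbi.tags:
                col = gbi.tags.index(tag)
                mask = gbi.matrix[:, col] > 0
                mfs.append(float(sizes[mask].mean()) if mask.any() else np.nan)
            else:
                mfs.append(np.nan)
        out["mean_flock_size"] = mfs
    return out


def daily_networks(
    events: list[FlockEvent],
    min_connected: int = MIN_CONNECTED,
) -> tuple[list[tuple[int, str, SocialNetwork]], pd.DataFrame]:
    """One SRI network per (day, feeder), dropping sparse days.

    Networks where fewer than ``min_connected`` birds have any connection
    are removed and logged, mirroring the day-exclusion filter applied to
    daily feeder networks.  Returns the retained ``(day, feeder, network)``
    triples and an exclusion log.
    """
    keyed: dict[tuple[int, str], list[FlockEvent]] = {}
    for e in events:
        keyed.setdefault((e.day, e.feeder), []).append(e)
    retained = []
    dropped = []
    for (day, feeder) in sorted(keyed):
        gbi = events_to_gbi(keyed[(day, feeder)])
        net = sri_network(gbi, scope=f"{feeder}/day{day}")
        if net.n_connected() < min_connected:
            dropped.append((day, feeder, net.n_connected(), "fewer than %d connected" % min_connected))
            logger.info("dropping network %s: %d connected birds", net.scope, net.n_connected())
            continue
        retained.append((day, feeder, net))
    log = pd.DataFrame(dropped, columns=["day", "feeder", "n_connected", "reason"])
    return retained, log


def site_period_network(
    events: list[FlockEvent],
    feeders: tuple[str, str],
    days: range,
    scope: str = "",
) -> tuple[SocialNetwork, GroupByIndividual] | None:
    """Pooled SRI network over both feeders of a site for a period."""
    sel = [e for e in events if e.feeder in feeders and e.day in days]
    if not sel:
        return None
    gbi = events_to_gbi(sel)
    return sri_network(gbi, scope=scope), gbi
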