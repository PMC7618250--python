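"""Newman weighted assortativity by treatment label, with jackknife SE and
a node-label permutation null.

The mixing matrix ``e_kl`` holds the fraction of total edge weight joining
label k to label l (both edge ends counted, so ``e`` is symmetric and sums
to 1).  The assortativity coefficient is

    r = (sum_k e_kk - sum_k a_k^2) / (1 - sum_k a_k^2),    a_k = sum_l e_kl.

r ranges from 1 (all edge weight within-type) through 0 (random mixing)
to -1 (all weight between types, in the balanced case).  The standard
error is Newman's edge jackknife; significance comes from shuffling the
labels over the nodes with the network held fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import UndefinedMetric
from .network import SocialNetwork

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000


@dataclass
class AssortmentResult:
    r: float
    se: float  # NaN when only one edge
    null_low: float
    null_high: float
    p: float
    n_perm: int


def _label_arrays(net: SocialNetwork, labels: dict[str, str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Codes per node, dropping (with a logged count) unlabeled birds."""
    keep = [i for i, t in enumerate(net.nodes) if t in labels]
    dropped = net.n_nodes - len(keep)
    if dropped:
        logger.info("dropping %d unlabeled birds from assortment", dropped)
    kept_nodes = [net.nodes[i] for i in keep]
    cats = sorted({labels[t] for t in kept_nodes})
    code = {c: k for k, c in enumerate(cats)}
    codes = np.array([code[labels[t]] for t in kept_nodes])
    w = net.weights[np.ix_(keep, keep)]
    return w, codes, cats


def _r_from_codes(w: np.ndarray, codes: np.ndarray, n_cats: int) -> float:
    total = w.sum()  # counts both edge ends (matrix is symmetric)
    if total == 0:
        raise UndefinedMetric("assortativity requires at least one nonzero edge")
    onehot = np.zeros((codes.size, n_cats))
    onehot[np.arange(codes.size), codes] = 1.0
    e = onehot.T @ w @ onehot / total
    a = e.sum(axis=1)
    denom = 1.0 - float(a @ a)
    if denom <= 0:
        raise UndefinedMetric("assortativity undefined: all nodes share one label")
    return float((np.trace(e) - a @ a) / denom)


def mixing_matrix(net: SocialNetwork, labels: dict[str, str]) -> pd.DataFrame:
    """Symmetric label-mixing matrix of edge-weight fractions (sums to 1)."""
    w, codes, cats = _label_arrays(net, labels)
    total = w.sum()
    if total == 0:
        raise UndefinedMetric("mixing matrix requires at least one nonzero edge")
    onehot = np.zeros((codes.size, len(cats)))
    onehot[np.arange(codes.size), codes] = 1.0
    e = onehot.T @ w @ onehot / total
    return pd.DataFrame(e, index=cats, columns=cats)


def assortativity(net: SocialNetwork, labels: dict[str, str]) -> float:
    """Newman's weighted assortativity coefficient for a discrete label."""
    w, codes, cats = _label_arrays(net, labels)
    return _r_from_codes(w, codes, len(cats))


def jackknife_se(net: SocialNetwork, labels: dict[str, str]) -> float:
    """Edge-jackknife standard error: sigma^2 = sum_e (r_(-e) - r)^2.

    Returns NaN (flagged undefined) when the network has a single edge.
    """
    w, codes, cats = _label_arrays(net, labels)
    r = _r_from_codes(w, codes, len(cats))
    ii, jj = np.nonzero(np.triu(w, 1))
    if ii.size < 2:
        return float("nan")
    var = 0.0
    for i, j in zip(ii, jj):
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.0
        try:
            r_minus = _r_from_codes(w2, codes, len(cats))
        except UndefinedMetric:
            continue
        var += (r_minus - r) ** 2
    return float(np.sqrt(var))


def assortment_null(
    net: SocialNetwork,
    labels: dict[str, str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> AssortmentResult:
    """Observed r against a node-label permutation null.

    Labels are shuffled over the nodes ``n_perm`` times with the network
    held fixed; the two-tailed p uses the +1 correction,
    ``p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null quantiles will be coarse", stacklevel=2)
    w, codes, cats = _label_arrays(net, labels)
    if len(cats) < 2:
        raise UndefinedMetric("permutation null requires at least two distinct labels")
    r_obs = _r_from_codes(w, codes, len(cats))
    rng = np.random.default_rng(seed)
    nulls = np.full(n_perm, np.nan)
    for b in range(n_perm):
        perm = rng.permutation(codes)
        try:
            nulls[b] = _r_from_codes(w, perm, len(cats))
        except UndefinedMetric:
            # a permutation can park one whole label class on isolated
            # nodes, leaving all edge weight within the other class; such
            # draws carry no information about mixing and are dropped
            continue
    valid = nulls[np.isfinite(nulls)]
    if valid.size == 0:
        raise UndefinedMetric("no label permutation yields a defined assortativity")
    p = (1.0 + np.sum(np.abs(valid) >= abs(r_obs))) / (valid.size + 1.0)
    lo, hi = np.quantile(valid, [0.025, 0.975])
    return AssortmentResult(
        r=r_obs,
        se=jackknife_se(net, labels),
        null_low=float(lo),
        null_high=float(hi),
        p=float(p),
        n_perm=n_perm,
    )


def daily_assortment(
    daily: list[tuple[int, str, SocialNetwork]],
    labels: dict[str, str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_per_label: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day assortment, skipping days with fewer than two birds of any
    treatment present; returns (results, skip log)."""
    rows = []
    skipped = []
    for k, (day, scope, net) in enumerate(daily):
        present = [labels[t] for t in net.nodes if t in labels]
        counts = pd.Series(present).value_counts()
        if len(counts) < 2 or (counts < min_per_label).any():
            skipped.append((day, scope, "fewer than %d of each treatment" % min_per_label))
            continue
        res = assortment_null(net, labels, n_perm=n_perm, seed=seed + k)
        rows.append((day, scope, res.r, res.se, res.null_low, res.null_high, res.p, res.n_perm))
    results = pd.DataFrame(
        rows, columns=["day", "scope", "r", "se", "null_low", "null_high", "p", "n_perm"]
    )
    log = pd.DataFrame(skipped, columns=["day", "scope", "reason"])
    return results, log
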