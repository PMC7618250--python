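"""Period x treatment contrast estimation and node-permutation inference.

Responses are modelled as ``response ~ period * treatment (+ day)`` with a
site-level grouping effect, delegated to standard routines: linear mixed
models (random site intercept) for gaussian responses and GLMs with
cluster-robust (by site) covariance for binomial/Poisson responses; with a
single site the fit falls back to the ordinary model.  Estimated cell
means and all pairwise differences between (period, treatment) cells are
returned with Wald tests (Holm-adjusted).

Significance for social-network position metrics comes from a node
permutation: individual identities are shuffled within each site-period
network (the network structure itself stays fixed), the metrics are
reattached to the shuffled identities, a reduced model is refitted, and
each pairwise-contrast coefficient is compared with its permutation null;
a coefficient outside the central 95% of the null is significant at 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FlockNetError

logger = logging.getLogger(__name__)

TRANSFORMATIONS = {
    "identity": lambda y: y,
    "inverse": lambda y: 1.0 / y,
    "square": lambda y: y**2,
    "square-root": np.sqrt,
    "log": np.log,
}

PERIOD_ORDER = ["pre", "during"]


def apply_transformation(y: np.ndarray, name: str) -> np.ndarray:
    if name not in TRANSFORMATIONS:
        raise FlockNetError(f"unknown transformation {name!r}; choose from {sorted(TRANSFORMATIONS)}")
    return TRANSFORMATIONS[name](np.asarray(y, dtype=float))


@dataclass
class ContrastTable:
    """Cell means and pairwise differences for period x treatment."""

    response: str
    family: str
    transformation: str
    cells: pd.DataFrame  # period, treatment, estimate, se
    contrasts: pd.DataFrame  # cell_a, cell_b, estimate, se, z, p, p_adj
    converged: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    """Observed contrast coefficients against node-permutation nulls."""

    contrasts: pd.DataFrame  # cell_a, cell_b, observed, null_low, null_high, p, significant
    nulls: np.ndarray  # (n_contrasts, n_perm)
    n_perm: int
    seed: int
    n_dropped: int = 0


def _levels(series: pd.Series, preferred_order: list[str]) -> list[str]:
    present = list(dict.fromkeys(series))
    ordered = [x for x in preferred_order if x in present]
    ordered += sorted(x for x in present if x not in ordered)
    return ordered


def _design_matrix(
    data: pd.DataFrame, include_day: bool
) -> tuple[np.ndarray, list[str], list[str], float]:
    periods = _levels(data["period"], PERIOD_ORDER)
    treatments = _levels(data["treatment"], [])
    n = len(data)
    cols = [np.ones(n)]
    for p in periods[1:]:
        cols.append((data["period"] == p).to_numpy(float))
    for t in treatments[1:]:
        cols.append((data["treatment"] == t).to_numpy(float))
    for p in periods[1:]:
        dp = (data["period"] == p).to_numpy(float)
        for t in treatments[1:]:
            cols.append(dp * (data["treatment"] == t).to_numpy(float))
    day_center = 0.0
    if include_day and "day_in_period" in data.columns:
        day = data["day_in_period"].to_numpy(float)
        day_center = float(day.mean())
        cols.append(day - day_center)
    return np.column_stack(cols), periods, treatments, day_center


def _cell_rows(periods: list[str], treatments: list[str], include_day: bool) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Design rows evaluating each (period, treatment) cell mean at mean day."""
    cells = [(p, t) for p in periods for t in treatments]
    k = 1 + (len(periods) - 1) + (len(treatments) - 1) + (len(periods) - 1) * (len(treatments) - 1)
    if include_day:
        k += 1
    rows = np.zeros((len(cells), k))
    for i, (p, t) in enumerate(cells):
        rows[i, 0] = 1.0
        col = 1
        for p2 in periods[1:]:
            rows[i, col] = 1.0 if p == p2 else 0.0
            col += 1
        for t2 in treatments[1:]:
            rows[i, col] = 1.0 if t == t2 else 0.0
            col += 1
        for p2 in periods[1:]:
            for t2 in treatments[1:]:
                rows[i, col] = 1.0 if (p == p2 and t == t2) else 0.0
                col += 1
        # centred day contributes 0 at its mean
    return cells, rows


def fit_period_treatment_model(
    data: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    transformation: str = "identity",
    weights: str | None = None,
    include_day: bool = True,
    group: str = "site",
) -> ContrastTable:
    """Fit ``response ~ period * treatment (+ day)`` with site grouping.

    ``family`` is gaussian, binomial or poisson.  For binomial proportions
    pass the trial count column as ``weights``.  The field-standard variable
    transformations (identity, inverse, square, square-root, log) are
    applied to the response before a gaussian fit.  Non-converged fits are
    flagged, never silent.
    """
    import statsmodels.api as sm

    data = data.dropna(subset=[response]).reset_index(drop=True)
    if len(data) == 0:
        raise FlockNetError("no rows to fit after dropping missing responses")
    include_day = include_day and "day_in_period" in data.columns
    x, periods, treatments, _ = _design_matrix(data, include_day)
    y = apply_transformation(data[response].to_numpy(), transformation if family == "gaussian" else "identity")
    groups = data[group] if group in data.columns else pd.Series(["g0"] * len(data))
    n_groups = groups.nunique()
    flags: list[str] = []
    converged = True

    k = x.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "gaussian":
                if n_groups >= 2:
                    model = sm.MixedLM(y, x, groups=groups)
                    res = model.fit(reml=True)
                    converged = bool(res.converged)
                else:
                    res = sm.OLS(y, x).fit()
            elif family in ("binomial", "poisson"):
                fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
                var_weights = data[weights].to_numpy(float) if weights else None
                model = sm.GLM(y, x, family=fam, var_weights=var_weights)
                if n_groups >= 2:
                    res = model.fit(cov_type="cluster", cov_kwds={"groups": groups.to_numpy()})
                else:
                    res = model.fit()
                converged = bool(getattr(res, "converged", True))
            else:
                raise FlockNetError(f"unknown family {family!r}")
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FlockNetError(f"model fit failed: {exc}") from exc
    if not converged:
        flags.append("non-converged")

    beta = np.asarray(res.params)[:k]
    cov = np.asarray(res.cov_params())[:k, :k]
    cells, rows = _cell_rows(periods, treatments, include_day)
    cell_est = rows @ beta
    with np.errstate(invalid="ignore"):  # NaN se under separation/singular fits
        cell_se = np.sqrt(np.einsum("ij,jk,ik->i", rows, cov, rows))
    cells_df = pd.DataFrame(
        {
            "period": [c[0] for c in cells],
            "treatment": [c[1] for c in cells],
            "estimate": cell_est,
            "se": cell_se,
        }
    )

    rows_out = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = rows[i] - rows[j]
            est = float(d @ beta)
            with np.errstate(invalid="ignore"):
                se = float(np.sqrt(d @ cov @ d))
            z = est / se if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            rows_out.append(("%s:%s" % cells[i], "%s:%s" % cells[j], est, se, z, p))
    contrasts = pd.DataFrame(rows_out, columns=["cell_a", "cell_b", "estimate", "se", "z", "p"])
    valid = contrasts["p"].notna()
    p_adj = np.full(len(contrasts), np.nan)
    if valid.any():
        from statsmodels.stats.multitest import multipletests

        p_adj[valid.to_numpy()] = multipletests(contrasts.loc[valid, "p"], method="holm")[1]
    contrasts["p_adj"] = p_adj
    return ContrastTable(
        response=response,
        family=family,
        transformation=transformation if family == "gaussian" else "identity",
        cells=cells_df,
        contrasts=contrasts,
        converged=converged,
        flags=flags,
    )


def _ols_contrast_map(data: pd.DataFrame, include_day: bool) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Linear map A with contrast coefficients = A @ y for the reduced OLS.

    The reduced model regresses the response on period * treatment (+ day)
    without random effects; every pairwise cell difference is linear in y,
    so the whole permutation null is a single matrix product.
    """
    x, periods, treatments, _ = _design_matrix(data, include_day)
    cells, rows = _cell_rows(periods, treatments, include_day)
    pinv = np.linalg.pinv(x)
    labels = []
    diff_rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            labels.append(("%s:%s" % cells[i], "%s:%s" % cells[j]))
            diff_rows.append(rows[i] - rows[j])
    a = np.asarray(diff_rows) @ pinv
    return a, labels


def node_permutation_test(
    data: pd.DataFrame,
    networks: dict[tuple[str, str], pd.Series],
    response: str = "value",
    n_perm: int = 1000,
    seed: int = 0,
    include_day: bool = False,
) -> PermutationResult:
    """Node-permutation significance for network-position contrasts.

    ``data`` holds one row per bird-site-period with columns ``tag, site,
    period, treatment`` and the response; ``networks`` maps each
    ``(site, period)`` to the metric over *all* nodes of that network
    (a Series indexed by tag).  Each permutation shuffles node identities
    within every site-period network — equivalently, permutes the metric
    vector over the network's nodes — reattaches values to the analysis
    birds and refits the reduced model.  Two-tailed p uses the +1
    correction; ``significant`` marks observed coefficients outside the
    central 95% of their null.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null quantiles will be coarse", stacklevel=2)
    keep = []
    n_dropped = 0
    for idx, row in data.iterrows():
        key = (row["site"], row["period"])
        if key in networks and row["tag"] in networks[key].index:
            keep.append(idx)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("node_permutation_test: dropped %d birds without a matching network", n_dropped)
    data = data.loc[keep].reset_index(drop=True)
    if len(data) == 0:
        raise FlockNetError("no birds with matching networks")

    a, labels = _ols_contrast_map(data, include_day)
    y_obs = data[response].to_numpy(float)
    observed = a @ y_obs

    # per stratum: pool of metric values over all network nodes, and the
    # positions of the analysis birds inside that pool
    strata = []
    for key, grp in data.groupby(["site", "period"], sort=True):
        pool = networks[key].to_numpy(float)
        pos_of = {t: i for i, t in enumerate(networks[key].index)}
        positions = np.array([pos_of[t] for t in grp["tag"]])
        strata.append((grp.index.to_numpy(), pool, positions))

    rng = np.random.default_rng(seed)
    y_perm = np.empty((len(data), n_perm))
    for b in range(n_perm):
        for rows_idx, pool, positions in strata:
            shuffled = rng.permutation(pool)
            y_perm[rows_idx, b] = shuffled[positions]
    nulls = a @ y_perm  # (n_contrasts, n_perm)

    lo = np.quantile(nulls, 0.025, axis=1)
    hi = np.quantile(nulls, 0.975, axis=1)
    p = (1.0 + (np.abs(nulls) >= np.abs(observed)[:, None]).sum(axis=1)) / (n_perm + 1.0)
    contrasts = pd.DataFrame(
        {
            "cell_a": [l[0] for l in labels],
            "cell_b": [l[1] for l in labels],
            "observed": observed,
            "null_low": lo,
            "null_high": hi,
            "p": p,
            "significant": (observed < lo) | (observed > hi),
        }
    )
    return PermutationResult(contrasts=contrasts, nulls=nulls, n_perm=n_perm, seed=seed, n_dropped=n_dropped)


def discovery_models(records: pd.DataFrame, include_day: bool = False) -> dict[str, ContrastTable]:
    """Fit the three discovery responses against period x treatment.

    Binomial fit for the discovered flag; gaussian fits for log order of
    arrival and square-root latency (discoverers only).  Cells in which
    every bird discovered (or none did) are flagged as separation.
    """
    out: dict[str, ContrastTable] = {}
    rec = records.copy()
    rec["discovered"] = rec["discovered"].astype(float)
    table = fit_period_treatment_model(
        rec, "discovered", family="binomial", include_day=include_day
    )
    for (p, t), grp in rec.groupby(["period", "treatment"]):
        m = grp["discovered"].mean()
        if m in (0.0, 1.0):
            table.flags.append(f"separation in cell {p}:{t}")
    out["discovery"] = table

    disc = rec[rec["discovered"] > 0]
    if len(disc) and disc["order"].notna().any():
        out["order"] = fit_period_treatment_model(
            disc, "order", family="gaussian", transformation="log", include_day=include_day
        )
    if len(disc) and disc["latency"].notna().any():
        out["latency"] = fit_period_treatment_model(
            disc, "latency", family="gaussian", transformation="square-root", include_day=include_day
        )
    return out
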