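"""Univariate Cox machinery and the 1-D data-driven grouping (DDg) search.

The DDg family scores candidate patient bipartitions by the Wald statistic of
a Cox proportional-hazards fit with a single binary covariate (high-risk vs
low-risk group membership). Because the 2-D searches evaluate tens of
thousands of candidate partitions per gene pair, the partial-likelihood
maximisation (Breslow tie handling) is implemented as a Newton iteration on
the scalar log hazard ratio, vectorised across candidate group columns.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

BETA_CAP = 20.0  # |beta| bound; hit only under (near-)complete separation
_P_FLOOR = 1e-300

DEFAULT_QUANTILE_GRID = np.round(np.arange(0.10, 0.9001, 0.05), 10)


@dataclass
class CoxFit:
    """Cox fit for a binary covariate: beta is the log hazard ratio HR vs LR."""

    beta: float
    se: float
    wald_stat: float
    p_value: float


@dataclass
class Cutoff1D:
    """A fitted 1-D expression cutoff with its risk direction and Cox fit."""

    feature_id: str
    cutoff: float
    direction: str  # high_is_HR | low_is_HR
    fit: CoxFit
    quantile: float


def breslow_newton(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Breslow partial-likelihood Newton solver.

    ``groups`` is an (n, m) boolean matrix: each column is one candidate
    binary covariate. Returns (beta, se) arrays of length m. Columns whose
    covariate carries no information at the optimum (observed information
    ~ 0) get se = inf, hence Wald p = 1.

    With the risk set taken as {j : t_j >= t_i} for every event i, summing the
    per-event terms reproduces Breslow's tie approximation exactly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    if groups.ndim == 1:
        groups = groups[:, None]
    n, m = groups.shape
    order = np.argsort(times, kind="stable")
    ts, ev, G = times[order], events[order], groups[order]
    ev_idx = np.flatnonzero(ev == 1)
    if ev_idx.size == 0:
        raise ValueError("no events: Cox fit undefined")
    first = np.searchsorted(ts, ts[ev_idx], side="left")
    risk_n = (n - first).astype(float)
    # suffix counts of group-1 membership: r1[i] = #{j >= i in group 1}
    suffix = np.cumsum(G[::-1].astype(float), axis=0)[::-1]
    r1 = suffix[first]  # (E, m)
    r0 = risk_n[:, None] - r1
    d1 = G[ev_idx].sum(axis=0).astype(float)  # events in group 1

    beta = np.zeros(m)
    info = np.zeros(m)
    active = np.ones(m, dtype=bool)
    for _ in range(60):
        e = np.exp(beta)
        denom = r0 + r1 * e
        mu = (r1 * e) / denom
        score = d1 - mu.sum(axis=0)
        info = (mu * (r0 / denom)).sum(axis=0)
        step = np.where(info > 1e-12, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        step = np.where(active, step, 0.0)
        beta = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        active = np.abs(step) > 1e-10
        if not active.any():
            break
    se = np.where(info > 1e-12, 1.0 / np.sqrt(np.maximum(info, 1e-12)), np.inf)
    return beta, se


def _wald(beta: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(np.isfinite(se), (beta / se) ** 2, 0.0)
    p = np.maximum(stats.chi2.sf(w, df=1), _P_FLOOR)
    return w, p


def fit_cox_binary(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> CoxFit:
    """Fit the Cox model for a single binary group covariate (Breslow ties).

    beta is the maximum partial-likelihood estimate, se comes from the
    observed information and the p-value from the chi-square(1) Wald test.
    Raises when either group is empty or there are no events: such a
    partition is inadmissible for risk-group comparison.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group).astype(bool)
    if not (len(times) == len(events) == len(group)):
        raise ValueError("times, events and group must have equal length")
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("no events: Cox fit undefined")
    beta, se = breslow_newton(times, events, group[:, None])
    w, p = _wald(beta, se)
    return CoxFit(float(beta[0]), float(se[0]), float(w[0]), float(p[0]))


def default_min_group(n: int) -> int:
    """Smallest admissible risk-group size: max(5, 10% of the cohort)."""
    return max(5, int(np.ceil(0.10 * n)))


def ddg_1d(
    times: np.ndarray,
    events: np.ndarray,
    expr_row: np.ndarray,
    quantile_grid: np.ndarray | None = None,
    min_group: int | None = None,
    feature_id: str = "",
) -> Cutoff1D:
    """1-D data-driven grouping: the expression cutoff minimising Wald p.

    Candidate cutoffs are empirical quantiles of the feature (default 10%-90%
    step 5%); cutting at c puts samples with value <= c on the low side. The
    high-risk side is whichever group shows elevated hazard (beta > 0); the
    returned p is the un-adjusted selection minimum over the grid.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(expr_row, dtype=float)
    n = len(x)
    if quantile_grid is None:
        quantile_grid = DEFAULT_QUANTILE_GRID
    if min_group is None:
        min_group = default_min_group(n)
    if min_group < 5:
        raise ValueError("min_group must be >= 5")
    cutoffs = np.quantile(x, quantile_grid)
    groups = x[:, None] > cutoffs[None, :]
    sizes = groups.sum(axis=0)
    admissible = (sizes >= min_group) & (sizes <= n - min_group)
    if events.sum() == 0 or not admissible.any():
        raise ValueError(
            f"no admissible cutoff for feature {feature_id!r} "
            f"(min_group={min_group})"
        )
    beta, se = breslow_newton(times, events, groups[:, admissible])
    _, p = _wald(beta, se)
    full_p = np.full(len(cutoffs), np.inf)
    full_p[admissible] = p
    full_beta = np.full(len(cutoffs), np.nan)
    full_beta[admissible] = beta
    full_se = np.full(len(cutoffs), np.nan)
    full_se[admissible] = se
    k = int(np.argmin(full_p))
    b = full_beta[k]
    direction = "high_is_HR" if b > 0 else "low_is_HR"
    fit = CoxFit(
        beta=float(abs(b)),
        se=float(full_se[k]),
        wald_stat=float((b / full_se[k]) ** 2) if np.isfinite(full_se[k]) else 0.0,
        p_value=float(full_p[k]),
    )
    return Cutoff1D(
        feature_id=feature_id,
        cutoff=float(cutoffs[k]),
        direction=direction,
        fit=fit,
        quantile=float(quantile_grid[k]),
    )
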