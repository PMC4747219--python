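"""Differential expression between risk subgroups and gene-set enrichment.

Per-feature Welch two-sample t-tests between voting-defined HR and LR
patients, FDR control via Storey q-values, cross-cohort intersection of the
significant sets, and hypergeometric enrichment against user-supplied gene
sets (sharing its tail kernel with the pair co-occurrence test).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .correlation_screen import hypergeom_tail
from .data_model import ExpressionMatrix


@dataclass
class DEGRecord:
    feature_id: str
    t_stat: float
    p_value: float
    q_value: float
    direction: str  # up_in_HR | down_in_HR


def storey_qvalues(p_values: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda (default 0.5).

    pi0 = #{p > lambda} / ((1 - lambda) m), clipped to (0, 1]; q-values are
    pi0 * m * p_(i) / i made monotone from the largest p downwards.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = (p > lambda_).sum() / ((1.0 - lambda_) * m)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def deg_test(
    expr: ExpressionMatrix,
    assignment: Sequence[int],
    q_threshold: float = 0.01,
) -> tuple[list[DEGRecord], set[str]]:
    """Welch t per feature between HR (1) and LR (0) samples.

    Returns all per-feature records plus the significant set (q < threshold).
    Direction is the sign of (mean_HR - mean_LR).
    """
    assignment = np.asarray(assignment, dtype=int)
    if len(assignment) != len(expr.sample_ids):
        raise ValueError("assignment length must match sample count")
    hr = assignment == 1
    lr = assignment == 0
    if hr.sum() < 3 or lr.sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    a = expr.values[:, hr]
    b = expr.values[:, lr]
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # constant-in-both-classes features yield nan; treat as null
    bad = ~np.isfinite(p)
    t[bad] = 0.0
    p[bad] = 1.0
    q = storey_qvalues(p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    records = [
        DEGRecord(
            feature_id=fid,
            t_stat=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            direction="up_in_HR" if diff[i] > 0 else "down_in_HR",
        )
        for i, fid in enumerate(expr.feature_ids)
    ]
    significant = {r.feature_id for r in records if r.q_value < q_threshold}
    return records, significant


def intersect_deg(sets: Sequence[Iterable[str]]) -> set[str]:
    """Features significant in every cohort."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    return set.intersection(*(set(s) for s in sets))


def updown_fraction(records: Sequence[DEGRecord]) -> tuple[float, int, int]:
    """Fraction (and counts) of records up-regulated in the HR subgroup."""
    if not records:
        raise ValueError("no records")
    n_up = sum(1 for r in records if r.direction == "up_in_HR")
    return n_up / len(records), n_up, len(records)


def geneset_enrichment(
    hits: Iterable[str], geneset: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p of |hits ∩ geneset| within the universe."""
    H, G, U = set(hits), set(geneset), set(universe)
    if not H <= U or not G <= U:
        raise ValueError("hits and geneset must be subsets of the universe")
    return hypergeom_tail(len(H & G), len(U), len(H), len(G))
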