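"""Kendall-tau screening of gene pairs within clinical subgroups.

A pair is "significantly correlated" in a subgroup when its two partners'
expression has Kendall tau-b with two-sided p below a raw threshold (default
0.05). Screens are run per cohort and intersected across cohorts; correlation
coefficient distributions of pair sets are compared with two-sample KS tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .data_model import CohortBundle, GenePairAnnotation


@dataclass
class CorrelationRecord:
    pair_id: str
    cohort: str
    subgroup: str
    tau: float
    p_value: float
    n: int
    feature_a: str = ""
    feature_b: str = ""


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with two-sided p.

    Exact enumeration for n < 10 without ties, tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    method = "exact" if (n < 10 and tie_free) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def select_representative(
    pair: GenePairAnnotation,
    candidate_feature_pairs: Sequence[tuple[str, str]],
    bundle: CohortBundle,
    subgroup: str | None,
) -> tuple[str, str]:
    """Pick the candidate feature pair with the strongest |tau| in the subgroup.

    Mirrors choosing, per gene pair, the single representative probe-set pair
    with the strongest (positive or negative) correlation. Ties break
    lexicographically on the feature-id pair.
    """
    if not candidate_feature_pairs:
        raise ValueError(f"pair {pair.pair_id!r}: no candidate feature pairs")
    samples = bundle.select_samples(subgroup)
    sub = bundle.expression.subset_samples(samples)
    best: tuple[float, tuple[str, str]] | None = None
    for fa, fb in sorted(candidate_feature_pairs):
        tau, _ = kendall_tau(sub.row(fa), sub.row(fb))
        key = abs(tau)
        if best is None or key > best[0] + 1e-15:
            best = (key, (fa, fb))
    assert best is not None
    return best[1]


def screen_pairs(
    bundle: CohortBundle,
    pairs: Sequence[GenePairAnnotation],
    subgroup: str | None = None,
    alpha: float = 0.05,
    feature_candidates: dict[str, Sequence[tuple[str, str]]] | None = None,
    positive_only: bool = False,
) -> tuple[list[CorrelationRecord], list[str]]:
    """Correlate each pair's partners within a subgroup.

    Returns one record per pair plus the companion list of pair ids passing
    p < alpha (and tau > 0 when ``positive_only``). When a pair has several
    candidate feature mappings, the representative pair is selected first.
    """
    samples = bundle.select_samples(subgroup)
    if len(samples) < 3:
        raise ValueError(
            f"subgroup {subgroup!r} selects {len(samples)} samples; need >= 3"
        )
    sub = bundle.expression.subset_samples(samples)
    records: list[CorrelationRecord] = []
    kept: list[str] = []
    for pair in pairs:
        if feature_candidates and pair.pair_id in feature_candidates:
            fa, fb = select_representative(
                pair, feature_candidates[pair.pair_id], bundle, subgroup
            )
        else:
            fa, fb = pair.gene_a, pair.gene_b
        tau, p = kendall_tau(sub.row(fa), sub.row(fb))
        rec = CorrelationRecord(
            pair_id=pair.pair_id,
            cohort=bundle.name,
            subgroup=subgroup or "all",
            tau=tau,
            p_value=p,
            n=len(samples),
            feature_a=fa,
            feature_b=fb,
        )
        records.append(rec)
        if p < alpha and (tau > 0 or not positive_only):
            kept.append(pair.pair_id)
    return records, kept


def intersect_screens(kept_by_cohort: Iterable[Sequence[str]]) -> set[str]:
    """Pairs significantly correlated in every cohort (raw per-cohort threshold)."""
    sets = [set(k) for k in kept_by_cohort]
    if len(sets) < 2:
        raise ValueError("need at least 2 cohorts to intersect")
    return set.intersection(*sets)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Shared kernel for the pair co-occurrence test and gene-set enrichment.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cooccurrence_hypergeom(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail probability of the observed overlap of two pair sets."""
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("setA and setB must be subsets of the universe")
    return hypergeom_tail(len(A & B), len(U), len(A), len(B))


class KSResult(NamedTuple):
    statistic: float
    p_value: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(values)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def _taus(records: Sequence) -> np.ndarray:
    return np.array(
        [r.tau if hasattr(r, "tau") else float(r) for r in records], dtype=float
    )


def compare_tau_distributions(
    records_a: Sequence, records_b: Sequence
) -> KSResult:
    """Two-sample two-sided KS test on tau values, with the two ECDFs.

    Accepts CorrelationRecord lists or raw tau sequences. The ECDFs are the
    cumulative-frequency curves used to visualise systematic correlation
    shifts between tissue classes.
    """
    a, b = _taus(records_a), _taus(records_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 records on each side")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), _ecdf(a), _ecdf(b)
    )
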