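"""Voting-based integration of per-pair risk assignments (WVG).

Each selected gene pair casts a binary high-risk/low-risk vote for every
patient via its fitted 2-D partition; votes are stacked in a matrix ordered
by training significance and combined by majority into the final patient
stratification. Despite the historical name "weighted voting grouping" the
combination rule is the predominant vote; a per-pair weight hook (default 1)
is exposed for extension.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .cox_ddg import CoxFit, fit_cox_binary
from .data_model import CohortBundle, DataModelError
from .rddg import PartitionModel, assign_risk


@dataclass
class VoteMatrix:
    """Binary votes (pairs x samples), rows ordered most-significant first."""

    sample_ids: list[str]
    pair_order: list[str]
    votes: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if not np.isin(self.votes, (0, 1)).all():
            raise ValueError("votes must be binary")
        if self.votes.shape != (len(self.pair_order), len(self.sample_ids)):
            raise ValueError("vote matrix shape mismatch")


def build_vote_matrix(
    models: Sequence[PartitionModel],
    bundle: CohortBundle,
    training_p: Mapping[str, float] | None = None,
) -> VoteMatrix:
    """Apply each pair's partition to the cohort and stack the votes.

    Rows are sorted by ascending training Wald p (``training_p`` maps pair id
    to the max-over-training-cohorts p; defaults to each model's own fit p),
    with the pair id as deterministic tie break. Expression rows are assumed
    standardized per cohort, matching how the models were fitted.
    """
    def key(m: PartitionModel) -> tuple[float, str]:
        if training_p is not None:
            return (training_p[m.pair_id], m.pair_id)
        return (m.fit.p_value if m.fit is not None else np.inf, m.pair_id)

    ordered = sorted(models, key=key)
    rows = []
    for m in ordered:
        for g in (m.gene_a, m.gene_b):
            if not g or not bundle.expression.has_feature(g):
                raise DataModelError(
                    f"pair {m.pair_id!r}: gene {g!r} missing from expression"
                )
        rows.append(
            assign_risk(m, bundle.expression.row(m.gene_a),
                        bundle.expression.row(m.gene_b))
        )
    return VoteMatrix(
        sample_ids=list(bundle.expression.sample_ids),
        pair_order=[m.pair_id for m in ordered],
        votes=np.vstack(rows),
    )


def vote(matrix: VoteMatrix) -> np.ndarray:
    """Majority vote per sample; exact ties go to the most significant pair."""
    if matrix.votes.shape[0] < 1:
        raise ValueError("vote matrix needs at least one row")
    w = matrix.weights if matrix.weights is not None else np.ones(
        matrix.votes.shape[0]
    )
    score1 = (w[:, None] * matrix.votes).sum(axis=0)
    score0 = w.sum() - score1
    out = np.where(score1 > score0, 1, 0)
    ties = score1 == score0
    out[ties] = matrix.votes[0, ties]
    return out


def evaluate_stratification(
    assignment: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[CoxFit, float]:
    """Cox Wald test HR-vs-LR plus prognostic accuracy.

    Accuracy is the fraction of samples whose risk label equals the observed
    full-follow-up event indicator (1 = recurrence observed).
    """
    assignment = np.asarray(assignment, dtype=int)
    events = np.asarray(events, dtype=int)
    if assignment.min() == assignment.max():
        raise ValueError("assignment puts all samples in one class")
    fit = fit_cox_binary(times, events, assignment)
    accuracy = float((assignment == events).mean())
    return fit, accuracy


def cohens_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Cohen's kappa for two binary assignments of the same samples."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.array_equal(a, b):
        return 1.0  # includes the degenerate all-one-class case (p_e = 1)
    return float(cohen_kappa_score(a, b))
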