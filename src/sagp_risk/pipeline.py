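"""End-to-end orchestration: screen -> fit -> select -> stratify -> DEG.

The pipeline mirrors the study workflow: correlation screening of
sense-antisense pairs within a clinical subgroup, cross-cohort intersection,
2-D (rotated) data-driven grouping per pair in each training cohort,
cross-cohort synergistic signature selection, voting-based patient
stratification, and differential expression between the resulting risk
subgroups with optional gene-set enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from . import correlation_screen as cs
from . import deg_enrichment as deg
from .cox_ddg import ddg_1d
from .data_model import (
    CohortBundle,
    DataModelError,
    read_clinical,
    read_expression,
    read_gene_pairs,
    standardize,
)
from .rddg import (
    PairGrid,
    PartitionModel,
    SignatureEntry,
    fit_pair_grid,
    select_signature,
    transfer_model,
)
from .wvg import build_vote_matrix, evaluate_stratification, vote


@dataclass
class PipelineParams:
    """Thresholds and search settings (defaults follow the study workflow)."""

    screen_subgroup: str = "grade=G3"
    survival_subgroup: str = "grade=G3"
    alpha_corr: float = 0.05
    alpha_pair: float = 0.05
    alpha_wvg: float = 0.01
    q_deg: float = 0.01
    mode: str = "RDDG2D"
    quantile_grid: np.ndarray | None = None
    min_group: int | None = None
    train_cohorts: list[str] | None = None
    positive_corr_only: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_corr", "alpha_pair", "alpha_wvg", "q_deg"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class CohortStratification:
    cohort: str
    sample_ids: list[str]
    assignment: np.ndarray
    wald_p: float
    accuracy: float
    n_hr: int
    n_lr: int


@dataclass
class StudyResult:
    screened_pairs: set[str]
    correlation_records: dict[str, list[cs.CorrelationRecord]]
    signature: list[SignatureEntry]
    stratifications: dict[str, CohortStratification]
    deg_sets: dict[str, set[str]]
    deg_common: set[str]
    deg_frac_up: float | None
    enrichment: dict[str, float]
    summary: dict


def _survival_view(
    bundle: CohortBundle, subgroup: str, features: Sequence[str]
) -> tuple[CohortBundle, np.ndarray, np.ndarray]:
    """Standardized sub-bundle of the survival samples of one cohort."""
    ids = bundle.select_samples(subgroup)
    if len(ids) < 10:
        raise DataModelError(
            f"cohort {bundle.name!r}: subgroup {subgroup!r} selects "
            f"{len(ids)} samples"
        )
    expr = standardize(bundle.expression.subset_samples(ids), features)
    clinical = [r for r in bundle.clinical if r.sample_id in set(ids)]
    sub = CohortBundle(expr, clinical, bundle.name)
    times, events, _ = sub.survival_arrays(ids)
    return sub, times, events


def run_study(
    bundles: Sequence[CohortBundle],
    pairs: Sequence,
    params: PipelineParams | None = None,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> StudyResult:
    """Run the full analysis on in-memory cohorts; deterministic."""
    params = params or PipelineParams()
    by_name = {b.name: b for b in bundles}
    train = params.train_cohorts or [b.name for b in bundles[:2]]
    if len(train) < 2:
        raise ValueError("need at least 2 training cohorts")
    for t in train:
        if t not in by_name:
            raise ValueError(f"unknown training cohort {t!r}")
    sagp_pairs = [p for p in pairs if p.class_tag == "SAGP"]
    pair_by_id = {p.pair_id: p for p in sagp_pairs}

    # 1. correlation screening per training cohort, intersected
    corr_records: dict[str, list[cs.CorrelationRecord]] = {}
    kept_by_cohort = []
    for t in train:
        recs, kept = cs.screen_pairs(
            by_name[t], sagp_pairs, params.screen_subgroup,
            alpha=params.alpha_corr, positive_only=params.positive_corr_only,
        )
        corr_records[t] = recs
        kept_by_cohort.append(kept)
    screened = cs.intersect_screens(kept_by_cohort)

    # 2. per-pair grids + partner 1-D fits in each training cohort
    grids: dict[str, dict[str, PairGrid]] = {}
    best1d: dict[str, dict[str, tuple[float, float]]] = {}
    feature_ids = sorted(
        {g for pid in screened for g in (pair_by_id[pid].gene_a, pair_by_id[pid].gene_b)}
    )
    views: dict[str, tuple[CohortBundle, np.ndarray, np.ndarray]] = {}
    for t in train:
        view, times, events = _survival_view(
            by_name[t], params.survival_subgroup, feature_ids
        )
        views[t] = (view, times, events)
        grids[t] = {}
        best1d[t] = {}
        for pid in sorted(screened):
            pair = pair_by_id[pid]
            x = view.expression.row(pair.gene_a)
            y = view.expression.row(pair.gene_b)
            grids[t][pid] = fit_pair_grid(
                times, events, x, y, params.mode,
                params.quantile_grid, params.min_group,
                pair_id=pid, gene_a=pair.gene_a, gene_b=pair.gene_b,
            )
            pa = ddg_1d(times, events, x, quantile_grid=params.quantile_grid,
                        min_group=params.min_group, feature_id=pair.gene_a)
            pb = ddg_1d(times, events, y, quantile_grid=params.quantile_grid,
                        min_group=params.min_group, feature_id=pair.gene_b)
            best1d[t][pid] = (pa.fit.p_value, pb.fit.p_value)

    # 3. cross-cohort synergistic signature
    signature = (
        select_signature(grids, best1d, alpha=params.alpha_pair)
        if screened else []
    )

    # 4. voting stratification in every cohort
    stratifications: dict[str, CohortStratification] = {}
    deg_sets: dict[str, set[str]] = {}
    deg_records: dict[str, list[deg.DEGRecord]] = {}
    if signature:
        training_p = {e.pair_id: e.max_p for e in signature}
        for b in bundles:
            if b.name in views:
                view, times, events = views[b.name]
            else:
                view, times, events = _survival_view(
                    b, params.survival_subgroup, feature_ids
                )
            models: list[PartitionModel] = []
            for e in signature:
                if b.name in e.models_by_cohort:
                    models.append(e.models_by_cohort[b.name])
                else:
                    ref = e.models_by_cohort[train[0]]
                    pair = pair_by_id[e.pair_id]
                    models.append(
                        transfer_model(
                            ref,
                            view.expression.row(pair.gene_a),
                            view.expression.row(pair.gene_b),
                        )
                    )
            matrix = build_vote_matrix(models, view, training_p=training_p)
            assignment = vote(matrix)
            fit, acc = evaluate_stratification(assignment, times, events)
            stratifications[b.name] = CohortStratification(
                cohort=b.name,
                sample_ids=matrix.sample_ids,
                assignment=assignment,
                wald_p=fit.p_value,
                accuracy=acc,
                n_hr=int(assignment.sum()),
                n_lr=int(len(assignment) - assignment.sum()),
            )
            # 5. differential expression between the voted subgroups
            full_ids = view.expression.sample_ids
            full_expr = b.expression.subset_samples(full_ids)
            records, significant = deg.deg_test(
                full_expr, assignment, q_threshold=params.q_deg
            )
            deg_records[b.name] = records
            deg_sets[b.name] = significant

    deg_common: set[str] = (
        deg.intersect_deg(list(deg_sets.values())) if len(deg_sets) >= 2 else set()
    )
    frac_up = None
    if deg_common and signature:
        ref_records = [
            r for r in deg_records[train[0]] if r.feature_id in deg_common
        ]
        frac_up, _, _ = deg.updown_fraction(ref_records)

    # 6. gene-set enrichment of the common DEGs
    enrichment: dict[str, float] = {}
    if gene_sets and deg_common:
        universe = set(bundles[0].expression.feature_ids)
        for name, genes in gene_sets.items():
            enrichment[name] = deg.geneset_enrichment(
                deg_common, set(genes) & universe, universe
            )

    summary = {
        "n_pairs_input": len(sagp_pairs),
        "n_pairs_screened": len(screened),
        "n_signature": len(signature),
        "signature_pairs": [e.pair_id for e in signature],
        "wvg": {
            c: {"wald_p": s.wald_p, "accuracy": s.accuracy,
                "n_hr": s.n_hr, "n_lr": s.n_lr,
                "significant": bool(s.wald_p < params.alpha_wvg)}
            for c, s in stratifications.items()
        },
        "n_deg_per_cohort": {c: len(s) for c, s in deg_sets.items()},
        "n_deg_common": len(deg_common),
        "deg_frac_up": frac_up,
        "enrichment_p": enrichment,
    }
    return StudyResult(
        screened_pairs=screened,
        correlation_records=corr_records,
        signature=signature,
        stratifications=stratifications,
        deg_sets=deg_sets,
        deg_common=deg_common,
        deg_frac_up=frac_up,
        enrichment=enrichment,
        summary=summary,
    )


def signature_table(signature: Sequence[SignatureEntry]) -> pd.DataFrame:
    """Tabular view of a selected signature (one row per pair)."""
    rows = []
    for e in signature:
        any_model = next(iter(e.models_by_cohort.values()))
        row = {
            "pair_id": e.pair_id,
            "gene_a": any_model.gene_a,
            "gene_b": any_model.gene_b,
            "design_id": e.design.design_id,
            "hr_quadrants": "+".join(sorted(e.design.hr_quadrants)),
            "sub_design": e.design.sub_design,
            "angle_index": e.angle_index,
            "angle_deg": e.angle_index * 5.625,
            "q1": e.q1,
            "q2": e.q2,
        }
        for cohort, p in e.p_by_cohort.items():
            row[f"p_{cohort}"] = p
            m = e.models_by_cohort[cohort]
            row[f"c1_{cohort}"] = m.c1
            row[f"c2_{cohort}"] = m.c2
        rows.append(row)
    return pd.DataFrame(rows)


def load_cohorts(data_dir: str | Path, cohorts: Sequence[str]) -> list[CohortBundle]:
    """Load ``<cohort>_expression.tsv`` / ``<cohort>_clinical.tsv`` bundles."""
    data_dir = Path(data_dir)
    bundles = []
    for name in cohorts:
        expr_path = data_dir / f"{name}_expression.tsv"
        clin_path = data_dir / f"{name}_clinical.tsv"
        for p in (expr_path, clin_path):
            if not p.exists():
                raise DataModelError(f"missing input file: {p}")
        bundles.append(
            CohortBundle(read_expression(expr_path), read_clinical(clin_path), name)
        )
    return bundles


def write_results(result: StudyResult, out_dir: str | Path) -> Path:
    """Write stage outputs and a machine-readable summary to a run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
    if result.signature:
        signature_table(result.signature).to_csv(
            out / "signature.tsv", sep="\t", index=False
        )
    for cohort, recs in result.correlation_records.items():
        pd.DataFrame(
            [
                {"pair_id": r.pair_id, "cohort": r.cohort, "subgroup": r.subgroup,
                 "tau": r.tau, "p_value": r.p_value, "n": r.n,
                 "feature_a": r.feature_a, "feature_b": r.feature_b}
                for r in recs
            ]
        ).to_csv(out / f"correlation_{cohort}.tsv", sep="\t", index=False)
    for cohort, s in result.stratifications.items():
        pd.DataFrame(
            {"sample_id": s.sample_ids, "risk_class": s.assignment}
        ).to_csv(out / f"assignment_{cohort}.tsv", sep="\t", index=False)
    if result.deg_common:
        pd.DataFrame({"feature_id": sorted(result.deg_common)}).to_csv(
            out / "deg_common.tsv", sep="\t", index=False
        )
    return out
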