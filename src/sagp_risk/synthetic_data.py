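"""Synthetic multi-cohort studies with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-pair bivariate expression with a target Kendall tau, higher in tumor
  than in normal samples (Gaussian copula: Pearson rho = sin(pi*tau/2) gives
  exact tau targeting for Gaussian pairs);
* proportional-hazards disease-free survival whose hazard depends on
  membership in a true 2-D expression sector (design, rotation, cutoffs),
  with independent uniform censoring;
* control pair classes: correlated pairs without survival structure, and
  co-localized gene-neighbour (NGN) pairs sharing an additive copy-number
  factor but with low residual correlation;
* an optional background transcriptome with a known fraction of genes
  differentially expressed between the true risk classes.

Everything is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .data_model import (
    ClinicalRecord,
    CohortBundle,
    ExpressionMatrix,
    GenePairAnnotation,
    GenomicInterval,
    write_clinical,
    write_expression,
    write_gene_pairs,
)
from .rddg import PartitionDesign, PartitionModel, assign_risk

_LOG2_BASELINE = 8.0  # centre of simulated log2 intensities


def _default_true_design() -> PartitionDesign:
    return PartitionDesign(1, frozenset({"Q1"}), "as_is")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts (defaults; see docs)."""

    n_samples: int = 250          # tumor samples per cohort
    n_normal: int = 60            # adjacent-normal samples per cohort
    n_cohorts: int = 2
    n_signal_pairs: int = 12
    n_null_pairs: int = 12
    n_ngn_pairs: int = 12
    tau_tumor: float = 0.5
    tau_normal: float = 0.1
    beta_true: float = 1.5        # log hazard ratio of the HR sector
    baseline_hazard: float = 0.06  # events / year in the LR sector
    censor_max: float = 12.0      # years of uniform censoring
    true_design: PartitionDesign = field(default_factory=_default_true_design)
    true_angle_index: int = 0
    true_cutoffs: tuple[float, float] = (0.0, 0.0)
    cnv_shared_sd: float = 1.0    # NGN shared copy-number factor sd
    flip_noise: float = 0.1       # per-pair sector-label discordance rate
    n_background: int = 300
    frac_deg: float = 0.2         # fraction of background genes that are DEGs
    deg_effect: float = 1.0       # mean log2 shift of true DEGs in HR class
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_normal", "n_cohorts", "n_signal_pairs",
                     "n_null_pairs", "n_ngn_pairs", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for t in (self.tau_tumor, self.tau_normal):
            if not -1 < t < 1:
                raise ValueError("|tau| must be < 1")
        if self.baseline_hazard <= 0 or self.censor_max <= 0:
            raise ValueError("baseline_hazard and censor_max must be positive")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")


@dataclass
class SyntheticTruth:
    """Generating parameters and per-sample truth for recovery tests."""

    true_model: PartitionModel
    risk_class: dict[str, np.ndarray]        # cohort -> tumor-sample labels
    pair_table: list[dict]                    # pair_id, class_tag, role, taus
    deg_truth: dict[str, str]                 # background DEG -> direction
    hr_fraction: float                        # P(HR sector) under the pair law
    config: SimulationConfig

    def signal_pair_ids(self) -> set[str]:
        return {r["pair_id"] for r in self.pair_table if r["role"] == "signal"}

    def null_pair_ids(self) -> set[str]:
        return {r["pair_id"] for r in self.pair_table if r["role"] == "null"}


def simulate_pair_expression(
    n: int,
    tau_target: float,
    shared_cnv_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    return_parts: bool = False,
):
    """Bivariate Gaussian pair with Kendall tau equal to ``tau_target``.

    Pearson rho = sin(pi * tau / 2) (copula inversion); an optional shared
    additive factor of sd ``shared_cnv_sd`` is added to both coordinates,
    modelling a common copy-number confounder.
    """
    if not -1 < tau_target < 1:
        raise ValueError(f"|tau_target| must be < 1, got {tau_target}")
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng() if rng is None else rng
    rho = np.sin(np.pi * tau_target / 2.0)
    z = rng.standard_normal((2, n))
    x = z[0]
    y = rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]
    shared = shared_cnv_sd * rng.standard_normal(n) if shared_cnv_sd > 0 else np.zeros(n)
    if return_parts:
        return x + shared, y + shared, shared
    return x + shared, y + shared


def survival_from_class(
    risk_class: np.ndarray,
    beta_true: float,
    baseline_hazard: float,
    censor_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential PH event times for a binary risk class, uniform censoring."""
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if censor_max <= 0:
        raise ValueError("censor_max must be positive")
    risk_class = np.asarray(risk_class, dtype=int)
    rate = baseline_hazard * np.exp(beta_true * risk_class)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, censor_max, size=len(risk_class))
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events


def simulate_survival(
    x: np.ndarray,
    y: np.ndarray,
    model: PartitionModel,
    beta_true: float,
    baseline_hazard: float,
    censor_max: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Survival outcomes whose hazard depends on the model's HR sector."""
    rng = np.random.default_rng() if rng is None else rng
    risk = assign_risk(model, x, y)
    return survival_from_class(risk, beta_true, baseline_hazard, censor_max, rng)


def _conditional_pair(
    target: np.ndarray,
    tau: float,
    model: PartitionModel,
    rng: np.random.Generator,
    max_rounds: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair coordinates whose sector membership matches ``target`` exactly.

    Rejection sampling per sample; because targets are drawn with the
    sector's own marginal probability, the accepted draws keep the pair's
    unconditional bivariate-normal law.
    """
    n = len(target)
    x = np.zeros(n)
    y = np.zeros(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(max_rounds):
        if not todo.any():
            break
        k = int(todo.sum())
        cx, cy = simulate_pair_expression(max(k, 10), tau, rng=rng)
        cx, cy = cx[:k], cy[:k]
        z = assign_risk(model, cx, cy)
        idx = np.flatnonzero(todo)
        ok = z == target[idx]
        x[idx[ok]] = cx[ok]
        y[idx[ok]] = cy[ok]
        todo[idx[ok]] = False
    if todo.any():
        raise RuntimeError("rejection sampling failed to converge")
    return x, y


def _hr_fraction(
    model: PartitionModel, tau: float, rng: np.random.Generator, n: int = 40000
) -> float:
    x, y = simulate_pair_expression(n, tau, rng=rng)
    return float(assign_risk(model, x, y).mean())


def _pair_annotations(cfg: SimulationConfig) -> list[GenePairAnnotation]:
    pairs = []
    idx = 0

    def block(i: int) -> int:
        return 10_000 + i * 20_000

    for prefix, count, tag in (
        ("SIG", cfg.n_signal_pairs, "SAGP"),
        ("NUL", cfg.n_null_pairs, "SAGP"),
        ("NGN", cfg.n_ngn_pairs, "NGN"),
    ):
        for k in range(count):
            base = block(idx)
            pid = f"{prefix}{k:03d}"
            ga, gb = f"{pid}_A", f"{pid}_B"
            if tag == "SAGP" and idx % 2 == 0:
                orientation = "divergent"  # head-to-head, 100 bp SA overlap
                ia = GenomicInterval("chr1", base + 1900, base + 4000, "+")
                ib = GenomicInterval("chr1", base, base + 2000, "-")
            elif tag == "SAGP":
                orientation = "convergent"  # tail-to-tail overlap
                ia = GenomicInterval("chr1", base, base + 2000, "+")
                ib = GenomicInterval("chr1", base + 1900, base + 4000, "-")
            else:
                orientation = "convergent"  # co-localized, no SA overlap
                ia = GenomicInterval("chr1", base, base + 2000, "+")
                ib = GenomicInterval("chr1", base + 7000, base + 9000, "-")
            pairs.append(
                GenePairAnnotation(pid, ga, gb, orientation, ia, ib, tag)
            )
            idx += 1
    return pairs


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[CohortBundle], list[GenePairAnnotation], SyntheticTruth]:
    """Generate ``n_cohorts`` cohorts with tumor + normal samples and truth.

    Tumor samples carry survival outcomes driven by a latent per-sample risk
    class (membership in the true 2-D sector); each signal pair's expression
    is tied to that class up to ``flip_noise`` discordance, so individual
    pairs are informative but imperfect. Null pairs are equally correlated
    but survival-independent; NGN pairs share a copy-number factor with low
    residual correlation. Normal samples use ``tau_normal`` for every pair.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mode = "DDG2D" if cfg.true_angle_index == 0 else "RDDG2D"
    true_model = PartitionModel(
        pair_id="__truth__",
        design=cfg.true_design,
        angle_index=cfg.true_angle_index,
        c1=cfg.true_cutoffs[0],
        c2=cfg.true_cutoffs[1],
        fit=None,
        mode=mode,
    )
    q = _hr_fraction(true_model, cfg.tau_tumor, rng)
    annotations = _pair_annotations(cfg)
    pair_roles = {
        p.pair_id: {"SIG": "signal", "NUL": "null", "NGN": "ngn"}[p.pair_id[:3]]
        for p in annotations
    }
    pair_table = [
        {
            "pair_id": p.pair_id,
            "class_tag": p.class_tag,
            "role": pair_roles[p.pair_id],
            "tau_tumor": cfg.tau_tumor if pair_roles[p.pair_id] != "ngn" else cfg.tau_normal,
            "tau_normal": cfg.tau_normal,
        }
        for p in annotations
    ]

    n_deg = int(round(cfg.frac_deg * cfg.n_background))
    deg_dirs = {}
    for g in range(n_deg):
        # up-shift in HR for ~70% of true DEGs, mirroring the up-dominance
        # the stratification is expected to reveal
        deg_dirs[f"BG{g:03d}"] = "up_in_HR" if rng.random() < 0.7 else "down_in_HR"

    bundles: list[CohortBundle] = []
    risk_by_cohort: dict[str, np.ndarray] = {}
    for c in range(cfg.n_cohorts):
        name = f"cohort{c + 1}"
        nt, nn = cfg.n_samples, cfg.n_normal
        z = (rng.random(nt) < q).astype(int)
        times, events = survival_from_class(
            z, cfg.beta_true, cfg.baseline_hazard, cfg.censor_max, rng
        )
        feature_ids: list[str] = []
        rows: list[np.ndarray] = []
        for pair in annotations:
            role = pair_roles[pair.pair_id]
            if role == "signal":
                flips = rng.random(nt) < cfg.flip_noise
                target = np.where(flips, 1 - z, z)
                xt, yt = _conditional_pair(target, cfg.tau_tumor, true_model, rng)
                xn, yn = simulate_pair_expression(max(nn, 10), cfg.tau_normal, rng=rng)
            elif role == "null":
                xt, yt = simulate_pair_expression(nt, cfg.tau_tumor, rng=rng)
                xn, yn = simulate_pair_expression(max(nn, 10), cfg.tau_normal, rng=rng)
            else:
                xt, yt = simulate_pair_expression(
                    nt, cfg.tau_normal, shared_cnv_sd=cfg.cnv_shared_sd, rng=rng
                )
                xn, yn = simulate_pair_expression(
                    max(nn, 10), cfg.tau_normal,
                    shared_cnv_sd=cfg.cnv_shared_sd, rng=rng,
                )
            xn, yn = xn[:nn], yn[:nn]
            feature_ids += [pair.gene_a, pair.gene_b]
            rows.append(np.concatenate([xt, xn]) + _LOG2_BASELINE)
            rows.append(np.concatenate([yt, yn]) + _LOG2_BASELINE)
        for g in range(cfg.n_background):
            fid = f"BG{g:03d}"
            noise = rng.standard_normal(nt + nn)
            row = noise + _LOG2_BASELINE
            if fid in deg_dirs:
                sign = 1.0 if deg_dirs[fid] == "up_in_HR" else -1.0
                row[:nt] += sign * cfg.deg_effect * z
            feature_ids.append(fid)
            rows.append(row)

        tumor_ids = [f"{name}_T{i:03d}" for i in range(nt)]
        normal_ids = [f"{name}_N{i:03d}" for i in range(nn)]
        expr = ExpressionMatrix(feature_ids, tumor_ids + normal_ids, np.vstack(rows))
        subtypes = np.where(rng.random(nt) < 0.5, "basal", "non_basal")
        clinical = [
            ClinicalRecord(tumor_ids[i], float(times[i]), int(events[i]),
                           grade="G3", subtype=str(subtypes[i]), cohort=name)
            for i in range(nt)
        ] + [
            ClinicalRecord(sid, 0.0, 0, grade="unknown",
                           subtype="normal_tissue", cohort=name)
            for sid in normal_ids
        ]
        bundles.append(CohortBundle(expr, clinical, name))
        risk_by_cohort[name] = z

    truth = SyntheticTruth(
        true_model=true_model,
        risk_class=risk_by_cohort,
        pair_table=pair_table,
        deg_truth=deg_dirs,
        hr_fraction=q,
        config=cfg,
    )
    return bundles, annotations, truth


def write_study(
    bundles: Sequence[CohortBundle],
    pairs: Sequence[GenePairAnnotation],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> Path:
    """Write a simulated study as the standard TSV formats plus truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_expression(b.expression, out / f"{b.name}_expression.tsv")
        write_clinical(b.clinical, out / f"{b.name}_clinical.tsv")
    write_gene_pairs(pairs, out / "gene_pairs.tsv")
    truth_payload = {
        "hr_fraction": truth.hr_fraction,
        "pair_table": truth.pair_table,
        "deg_truth": truth.deg_truth,
        "risk_class": {c: v.tolist() for c, v in truth.risk_class.items()},
        "true_model": {
            "design_id": truth.true_model.design.design_id,
            "hr_quadrants": sorted(truth.true_model.design.hr_quadrants),
            "sub_design": truth.true_model.design.sub_design,
            "angle_index": truth.true_model.angle_index,
            "c1": truth.true_model.c1,
            "c2": truth.true_model.c2,
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    return out
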