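"""2-D data-driven grouping (DDg) and its rotated extension (RDDg).

A gene pair's standardized expression places each patient on a plane. Two
cutoffs (c1, c2) on the (optionally rotated) axes split the plane into four
quadrants; a *design* assigns a non-trivial subset of quadrants to the
high-risk sector, and a *sub-design* fixes which sector is labelled HR. The
rotated variant additionally searches a grid of 16 axis rotations spanning
[0, 90) degrees (rotations beyond 90 only permute quadrants). The fitted
partition is the one minimising the Cox Wald p-value over the full search
grid; selection across cohorts requires a single shared configuration.

Quadrant numbering (after rotation by -theta):
    Q1 = (x' >  c1, y' >  c2)     Q2 = (x' >  c1, y' <= c2)
    Q3 = (x' <= c1, y' >  c2)     Q4 = (x' <= c1, y' <= c2)
so {Q1,Q2} and {Q1,Q3} are the two single-axis splits. The plain 2-D DDg
uses the 5 designs whose boundary needs both cutoffs (10 sub-designs); the
rotated search uses all 7 non-trivial bipartitions (14 sub-designs), where
rotation makes even the single-axis splits distinct from 1-D grouping.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cox_ddg import (
    CoxFit,
    Cutoff1D,
    DEFAULT_QUANTILE_GRID,
    _wald,
    breslow_newton,
    default_min_group,
)

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
N_ANGLES = 16
ANGLE_STEP_DEG = 90.0 / N_ANGLES  # 5.625 degrees

# canonical design table: id -> HR-sector quadrants (as_is orientation)
_DESIGN_TABLE: dict[int, frozenset[str]] = {
    1: frozenset({"Q1"}),
    2: frozenset({"Q2"}),
    3: frozenset({"Q3"}),
    4: frozenset({"Q4"}),
    5: frozenset({"Q1", "Q4"}),  # diagonal
    6: frozenset({"Q1", "Q2"}),  # single-axis: x' > c1
    7: frozenset({"Q1", "Q3"}),  # single-axis: y' > c2
}
_DDG2D_IDS = (1, 2, 3, 4, 5)
_RDDG2D_IDS = (1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class PartitionDesign:
    design_id: int
    hr_quadrants: frozenset[str]
    sub_design: str = "as_is"  # as_is | flipped

    def __post_init__(self) -> None:
        if not (0 < len(self.hr_quadrants) < 4):
            raise ValueError("HR sector must be a non-empty proper quadrant subset")
        if self.sub_design not in ("as_is", "flipped"):
            raise ValueError(f"unknown sub_design {self.sub_design!r}")

    @property
    def effective_hr(self) -> frozenset[str]:
        if self.sub_design == "flipped":
            return frozenset(QUADRANTS) - self.hr_quadrants
        return self.hr_quadrants


def enumerate_designs(mode: str) -> list[PartitionDesign]:
    """All sub-designs of a mode: 14 for RDDG2D, 10 for DDG2D."""
    ids = {"DDG2D": _DDG2D_IDS, "RDDG2D": _RDDG2D_IDS}.get(mode)
    if ids is None:
        raise ValueError(f"mode must be DDG2D or RDDG2D, got {mode!r}")
    out = []
    for did in ids:
        for sub in ("as_is", "flipped"):
            out.append(PartitionDesign(did, _DESIGN_TABLE[did], sub))
    return out


@dataclass
class PartitionModel:
    """A fitted 2-D risk partition for one gene pair in one cohort."""

    pair_id: str
    design: PartitionDesign
    angle_index: int
    c1: float
    c2: float
    fit: CoxFit | None
    mode: str
    q1: float | None = None  # quantile levels of the cutoffs (for transfer)
    q2: float | None = None
    gene_a: str = ""
    gene_b: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.angle_index < N_ANGLES:
            raise ValueError("angle_index must be in 0..15")
        if self.mode == "DDG2D" and self.angle_index != 0:
            raise ValueError("DDG2D models have angle_index 0")
        if self.mode == "DDG2D" and self.design.design_id not in _DDG2D_IDS:
            raise ValueError("DDG2D models use the two-cutoff designs only")

    @property
    def angle_deg(self) -> float:
        return self.angle_index * ANGLE_STEP_DEG


def rotate(
    x: np.ndarray, y: np.ndarray, angle_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate points by -theta (theta = angle_index * 5.625 deg) about the origin."""
    th = np.deg2rad(angle_index * ANGLE_STEP_DEG)
    c, s = np.cos(th), np.sin(th)
    return x * c + y * s, -x * s + y * c


def _quadrant_membership(
    xhi: np.ndarray, yhi: np.ndarray, hr: frozenset[str]
) -> np.ndarray:
    m = np.zeros(xhi.shape, dtype=bool)
    if "Q1" in hr:
        m |= xhi & yhi
    if "Q2" in hr:
        m |= xhi & ~yhi
    if "Q3" in hr:
        m |= ~xhi & yhi
    if "Q4" in hr:
        m |= ~xhi & ~yhi
    return m


def assign_risk(model: PartitionModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Binary risk labels (1 = high-risk sector) for standardized coordinates.

    Points exactly on a cutoff fall on the "<=" (low) side of that axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    xr, yr = rotate(x, y, model.angle_index)
    m = _quadrant_membership(xr > model.c1, yr > model.c2, model.design.effective_hr)
    return m.astype(int)


@dataclass
class PairGrid:
    """Full Wald-p / beta grids over (angle, design, c1, c2) for one pair.

    Arrays have shape (A, D, K, K) with A angle indices, D as_is designs and
    K cutoff quantiles; inadmissible configurations hold p = inf, beta = nan.
    """

    mode: str
    pair_id: str
    quantile_grid: np.ndarray
    design_ids: tuple[int, ...]
    angle_indices: tuple[int, ...]
    p: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    cut1: np.ndarray  # (A, K) cutoff values on rotated x'
    cut2: np.ndarray  # (A, K) cutoff values on rotated y'
    gene_a: str = ""
    gene_b: str = ""

    def model_at(
        self, a: int, d: int, i: int, j: int, flip_to_positive: bool = True
    ) -> PartitionModel:
        """Materialise the PartitionModel at grid indices (a, d, i, j)."""
        beta = float(self.beta[a, d, i, j])
        se = float(self.se[a, d, i, j])
        p = float(self.p[a, d, i, j])
        sub = "as_is"
        if flip_to_positive and beta < 0:
            sub, beta = "flipped", -beta
        did = self.design_ids[d]
        design = PartitionDesign(did, _DESIGN_TABLE[did], sub)
        wald = (beta / se) ** 2 if np.isfinite(se) and se > 0 else 0.0
        return PartitionModel(
            pair_id=self.pair_id,
            design=design,
            angle_index=self.angle_indices[a],
            c1=float(self.cut1[a, i]),
            c2=float(self.cut2[a, j]),
            fit=CoxFit(beta, se, wald, p),
            mode=self.mode,
            q1=float(self.quantile_grid[i]),
            q2=float(self.quantile_grid[j]),
            gene_a=self.gene_a,
            gene_b=self.gene_b,
        )


def fit_pair_grid(
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "RDDG2D",
    quantile_grid: np.ndarray | None = None,
    min_group: int | None = None,
    angle_indices: Sequence[int] | None = None,
    design_ids: Sequence[int] | None = None,
    pair_id: str = "",
    gene_a: str = "",
    gene_b: str = "",
) -> PairGrid:
    """Evaluate the Cox Wald fit at every (angle, design, cutoff, cutoff).

    Cutoff candidates are empirical quantiles of the *rotated* coordinates.
    Admissibility requires both risk groups to hold at least ``min_group``
    samples. The Newton solver is batched across all designs and cutoff pairs
    of one rotation angle.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(times) == len(events) == n == len(y)):
        raise ValueError("times, events, x, y must have equal length")
    if events.sum() == 0:
        raise ValueError("no events: grid fit undefined")
    if quantile_grid is None:
        quantile_grid = DEFAULT_QUANTILE_GRID
    quantile_grid = np.asarray(quantile_grid, dtype=float)
    if min_group is None:
        min_group = default_min_group(n)
    if design_ids is None:
        design_ids = {"DDG2D": _DDG2D_IDS, "RDDG2D": _RDDG2D_IDS}[mode]
    design_ids = tuple(design_ids)
    if angle_indices is None:
        angle_indices = (0,) if mode == "DDG2D" else tuple(range(N_ANGLES))
    angle_indices = tuple(angle_indices)

    A, D, K = len(angle_indices), len(design_ids), len(quantile_grid)
    p_grid = np.full((A, D, K, K), np.inf)
    b_grid = np.full((A, D, K, K), np.nan)
    se_grid = np.full((A, D, K, K), np.nan)
    cut1 = np.zeros((A, K))
    cut2 = np.zeros((A, K))

    for ai, aidx in enumerate(angle_indices):
        xr, yr = rotate(x, y, aidx)
        c1 = np.quantile(xr, quantile_grid)
        c2 = np.quantile(yr, quantile_grid)
        cut1[ai], cut2[ai] = c1, c2
        xhi = xr[:, None, None] > c1[None, :, None]  # (n, K, 1)
        yhi = yr[:, None, None] > c2[None, None, :]  # (n, 1, K)
        xhi, yhi = np.broadcast_arrays(xhi, yhi)
        members = np.empty((n, D, K, K), dtype=bool)
        for di, did in enumerate(design_ids):
            members[:, di] = _quadrant_membership(xhi, yhi, _DESIGN_TABLE[did])
        flat = members.reshape(n, D * K * K)
        sizes = flat.sum(axis=0)
        adm = (sizes >= min_group) & (sizes <= n - min_group)
        if adm.any():
            beta, se = breslow_newton(times, events, flat[:, adm])
            _, p = _wald(beta, se)
            pf = np.full(D * K * K, np.inf)
            bf = np.full(D * K * K, np.nan)
            sf = np.full(D * K * K, np.nan)
            pf[adm], bf[adm], sf[adm] = p, beta, se
            p_grid[ai] = pf.reshape(D, K, K)
            b_grid[ai] = bf.reshape(D, K, K)
            se_grid[ai] = sf.reshape(D, K, K)
    return PairGrid(
        mode=mode,
        pair_id=pair_id,
        quantile_grid=quantile_grid,
        design_ids=design_ids,
        angle_indices=angle_indices,
        p=p_grid,
        beta=b_grid,
        se=se_grid,
        cut1=cut1,
        cut2=cut2,
        gene_a=gene_a,
        gene_b=gene_b,
    )


def fit_pair(
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "RDDG2D",
    quantile_grid: np.ndarray | None = None,
    min_group: int | None = None,
    pair_id: str = "",
    gene_a: str = "",
    gene_b: str = "",
) -> PartitionModel:
    """Exhaustive grid search for the partition minimising the Wald p-value.

    The sub-design is chosen so the HR sector carries elevated hazard
    (beta > 0). Ties resolve deterministically: smallest angle index, then
    lowest design id, then lowest cutoff grid indices.
    """
    grid = fit_pair_grid(
        times, events, x, y, mode, quantile_grid, min_group,
        pair_id=pair_id, gene_a=gene_a, gene_b=gene_b,
    )
    if not np.isfinite(grid.p).any():
        raise ValueError(f"pair {pair_id!r}: no admissible partition")
    a, d, i, j = np.unravel_index(int(np.argmin(grid.p)), grid.p.shape)
    return grid.model_at(a, d, i, j)


def transfer_model(
    model: PartitionModel, x: np.ndarray, y: np.ndarray
) -> PartitionModel:
    """Re-anchor a fitted model's cutoffs on another cohort's coordinates.

    The configuration (design, sub-design, rotation angle, cutoff quantile
    levels) is held fixed; the cutoff *values* are recomputed as the stored
    quantiles of this cohort's rotated standardized coordinates, the
    cohort-relative reading of "the same gene expression cutoff values".
    """
    if model.q1 is None or model.q2 is None:
        raise ValueError("model lacks quantile levels; cannot transfer")
    xr, yr = rotate(np.asarray(x, float), np.asarray(y, float), model.angle_index)
    return replace(
        model,
        c1=float(np.quantile(xr, model.q1)),
        c2=float(np.quantile(yr, model.q2)),
        fit=None,
    )


@dataclass
class SignatureEntry:
    """A selected pair: one shared configuration, per-cohort fits."""

    pair_id: str
    design: PartitionDesign
    angle_index: int
    q1: float
    q2: float
    p_by_cohort: dict[str, float]
    models_by_cohort: dict[str, PartitionModel]
    max_p: float


def select_signature(
    grids_by_cohort: Mapping[str, Mapping[str, PairGrid]],
    cutoffs1d: Mapping[str, Mapping[str, tuple[float, float]]],
    alpha: float = 0.05,
) -> list[SignatureEntry]:
    """Cross-cohort, synergy-constrained signature selection.

    Training is performed in each cohort independently; the candidate
    configurations for a pair are the per-cohort optimal (design,
    sub-design, rotation angle, quantile-scale cutoffs). A pair enters the
    signature iff

    * synergy holds in every cohort: the pair's own best grid p is strictly
      below both partner genes' best 1-D DDg p there (``cutoffs1d`` maps
      cohort -> pair_id -> the two best 1-D p-values), and
    * some candidate configuration, applied unchanged in *every* training
      cohort, is survival significant at alpha / n_candidates (Bonferroni
      over the independently trained candidates — the only multiplicity
      control in the pipeline) with a consistent risk direction.

    Among qualifying candidates the one minimising the max-over-cohorts p
    is kept (deterministic grid-order tie break).
    """
    cohorts = list(grids_by_cohort)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 training cohorts")
    pair_sets = [set(grids_by_cohort[c]) for c in cohorts]
    shared = set.intersection(*pair_sets)
    if not shared:
        raise ValueError("training cohorts have disjoint pair sets")

    entries: list[SignatureEntry] = []
    for pid in sorted(shared):
        grids = [grids_by_cohort[c][pid] for c in cohorts]
        ref = grids[0]
        if any(
            g.p.shape != ref.p.shape
            or g.design_ids != ref.design_ids
            or g.angle_indices != ref.angle_indices
            for g in grids
        ):
            raise ValueError(f"pair {pid!r}: grids differ across cohorts")
        if not all(np.isfinite(g.p).any() for g in grids):
            continue
        # in-cohort synergy of the pair over its individual genes
        if any(
            float(np.nanmin(np.where(np.isfinite(g.p), g.p, np.nan)))
            >= min(cutoffs1d[c][pid])
            for c, g in zip(cohorts, grids)
        ):
            continue
        candidates = sorted(
            {
                np.unravel_index(int(np.argmin(g.p)), g.p.shape)
                for g in grids
            }
        )
        thr = alpha / len(candidates)
        best: tuple[float, tuple[int, int, int, int]] | None = None
        for cfg in candidates:
            ps = np.array([g.p[cfg] for g in grids])
            betas = np.array([g.beta[cfg] for g in grids])
            if not np.all(np.isfinite(ps)):
                continue
            if not (np.all(betas > 0) or np.all(betas < 0)):
                continue
            if not np.all(ps < thr):
                continue
            mx = float(ps.max())
            if best is None or mx < best[0]:
                best = (mx, cfg)
        if best is None:
            continue
        a, d, i, j = best[1]
        models = {
            c: grids[ci].model_at(a, d, i, j, flip_to_positive=True)
            for ci, c in enumerate(cohorts)
        }
        design = next(iter(models.values())).design
        entries.append(
            SignatureEntry(
                pair_id=pid,
                design=design,
                angle_index=ref.angle_indices[a],
                q1=float(ref.quantile_grid[i]),
                q2=float(ref.quantile_grid[j]),
                p_by_cohort={
                    c: float(grids[ci].p[a, d, i, j])
                    for ci, c in enumerate(cohorts)
                },
                models_by_cohort=models,
                max_p=best[0],
            )
        )
    entries.sort(key=lambda e: (e.max_p, e.pair_id))
    return entries
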