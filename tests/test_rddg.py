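from itertools import product

import numpy as np
import pytest

from sagp_risk.cox_ddg import ddg_1d, fit_cox_binary, default_min_group
from sagp_risk.rddg import (
    DEFAULT_QUANTILE_GRID,
    N_ANGLES,
    PairGrid,
    PartitionDesign,
    PartitionModel,
    assign_risk,
    enumerate_designs,
    fit_pair,
    fit_pair_grid,
    rotate,
    select_signature,
    transfer_model,
)
from sagp_risk.synthetic_data import (
    simulate_pair_expression,
    simulate_survival,
)


def brute_force_bipartitions():
    """All non-trivial unordered bipartitions of the 4 quadrants."""
    quads = ("Q1", "Q2", "Q3", "Q4")
    labelled = set()
    for bits in product((0, 1), repeat=4):
        side = frozenset(q for q, b in zip(quads, bits) if b)
        if 0 < len(side) < 4:
            labelled.add(side)
    assert len(labelled) == 14  # 2^4 - 2 trivial labelings
    unordered = set()
    for side in labelled:
        unordered.add(frozenset({side, frozenset(quads) - side}))
    return unordered


class TestDesignEnumeration:
    def test_rddg_counts(self):
        subs = enumerate_designs("RDDG2D")
        assert len(subs) == 14
        assert len({d.design_id for d in subs}) == 7

    def test_ddg_counts(self):
        subs = enumerate_designs("DDG2D")
        assert len(subs) == 10
        assert len({d.design_id for d in subs}) == 5

    def test_rddg_matches_brute_force_enumeration(self):
        oracle = brute_force_bipartitions()
        assert len(oracle) == 7
        ours = {
            frozenset(
                {d.hr_quadrants, frozenset(("Q1", "Q2", "Q3", "Q4")) - d.hr_quadrants}
            )
            for d in enumerate_designs("RDDG2D")
        }
        assert ours == oracle

    def test_ddg_excludes_single_axis_splits(self):
        hr_sets = {d.hr_quadrants for d in enumerate_designs("DDG2D")}
        assert frozenset({"Q1", "Q2"}) not in hr_sets  # x-only split
        assert frozenset({"Q1", "Q3"}) not in hr_sets  # y-only split

    def test_angle_grid_size(self):
        assert N_ANGLES == 16

    def test_design_invariants(self):
        with pytest.raises(ValueError):
            PartitionDesign(1, frozenset())
        with pytest.raises(ValueError):
            PartitionDesign(1, frozenset({"Q1", "Q2", "Q3", "Q4"}))


class TestAssignRisk:
    def test_quadrant_membership(self, q1_model):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        np.testing.assert_array_equal(assign_risk(q1_model, x, y), [1, 0, 0, 0])

    def test_boundary_points_fall_on_low_side(self, q1_model):
        assert assign_risk(q1_model, np.array([0.0]), np.array([1.0]))[0] == 0
        assert assign_risk(q1_model, np.array([1.0]), np.array([0.0]))[0] == 0

    def test_subdesign_flip_complements_labels(self, q1_model):
        from dataclasses import replace

        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 100))
        flipped = replace(
            q1_model,
            design=PartitionDesign(1, frozenset({"Q1"}), "flipped"),
        )
        np.testing.assert_array_equal(
            assign_risk(q1_model, x, y), 1 - assign_risk(flipped, x, y)
        )

    def test_rotating_data_matches_rotated_model(self, rng):
        """Labels of a rotated model on raw data equal labels of the
        unrotated model on counter-rotated data."""
        x, y = rng.normal(size=(2, 100))
        for k in (1, 5, 15):
            model_k = PartitionModel(
                "p", PartitionDesign(4, frozenset({"Q4"})), k,
                0.3, -0.2, None, "RDDG2D",
            )
            model_0 = PartitionModel(
                "p", PartitionDesign(4, frozenset({"Q4"})), 0,
                0.3, -0.2, None, "RDDG2D",
            )
            xr, yr = rotate(x, y, k)  # rotate the points by -theta
            np.testing.assert_array_equal(
                assign_risk(model_k, x, y), assign_risk(model_0, xr, yr)
            )


def _pair_fixture(rng, n=60, beta=1.5):
    model = PartitionModel(
        "p", PartitionDesign(1, frozenset({"Q1"})), 0, 0.0, 0.0, None, "DDG2D"
    )
    x, y = simulate_pair_expression(n, 0.5, rng=rng)
    times, events = simulate_survival(x, y, model, beta, 0.08, 12.0, rng)
    return times, events, x, y


class TestFitPair:
    def test_ddg2d_matches_exhaustive_loop(self, rng):
        times, events, x, y = _pair_fixture(rng)
        res = fit_pair(times, events, x, y, mode="DDG2D")
        n = len(x)
        mg = default_min_group(n)
        best = np.inf
        designs = {d.design_id: d for d in enumerate_designs("DDG2D")
                   if d.sub_design == "as_is"}
        for did, design in designs.items():
            for qi in DEFAULT_QUANTILE_GRID:
                for qj in DEFAULT_QUANTILE_GRID:
                    c1, c2 = np.quantile(x, qi), np.quantile(y, qj)
                    m = PartitionModel("p", design, 0, c1, c2, None, "DDG2D")
                    g = assign_risk(m, x, y)
                    if not mg <= g.sum() <= n - mg:
                        continue
                    best = min(
                        best, fit_cox_binary(times, events, g).p_value
                    )
        assert res.fit.p_value == pytest.approx(best, rel=1e-9)

    def test_rddg_restricted_to_zero_angle_equals_ddg(self, rng):
        times, events, x, y = _pair_fixture(rng)
        ddg = fit_pair(times, events, x, y, mode="DDG2D")
        grid = fit_pair_grid(
            times, events, x, y, mode="RDDG2D",
            angle_indices=(0,), design_ids=(1, 2, 3, 4, 5),
        )
        a, d, i, j = np.unravel_index(int(np.argmin(grid.p)), grid.p.shape)
        restricted = grid.model_at(a, d, i, j)
        assert restricted.fit.p_value == pytest.approx(ddg.fit.p_value, rel=1e-12)
        assert restricted.design == ddg.design
        assert (restricted.c1, restricted.c2) == (ddg.c1, ddg.c2)

    def test_rddg_never_worse_than_best_partner_1d(self, rng):
        """The RDDg grid embeds the 1-D splits (single-axis designs at 0)."""
        for _ in range(3):
            times, events, x, y = _pair_fixture(rng, n=80)
            pair = fit_pair(times, events, x, y, mode="RDDG2D")
            best1d = min(
                ddg_1d(times, events, x).fit.p_value,
                ddg_1d(times, events, y).fit.p_value,
            )
            assert pair.fit.p_value <= best1d * (1 + 1e-12)

    def test_hr_sector_has_positive_beta(self, rng):
        times, events, x, y = _pair_fixture(rng)
        res = fit_pair(times, events, x, y, mode="RDDG2D")
        assert res.fit.beta > 0

    def test_degenerate_input_rejected(self):
        times = np.arange(1.0, 21)
        events = np.ones(20, dtype=int)
        with pytest.raises(ValueError):
            fit_pair(times, events, np.ones(20), np.ones(20), mode="DDG2D")


def _toy_grid(p_vals, beta_vals, pair_id="p"):
    """1 angle x 1 design x 2x2 cutoff grid."""
    p = np.array(p_vals, dtype=float).reshape(1, 1, 2, 2)
    b = np.array(beta_vals, dtype=float).reshape(1, 1, 2, 2)
    return PairGrid(
        mode="RDDG2D", pair_id=pair_id,
        quantile_grid=np.array([0.25, 0.75]),
        design_ids=(1,), angle_indices=(0,),
        p=p, beta=b, se=np.ones_like(p),
        cut1=np.zeros((1, 2)), cut2=np.zeros((1, 2)),
        gene_a="gA", gene_b="gB",
    )


class TestSelectSignature:
    def _grids(self, p1, p2, b1=None, b2=None):
        ones = [1.0] * 4
        return {
            "c1": {"p": _toy_grid(p1, b1 or ones)},
            "c2": {"p": _toy_grid(p2, b2 or ones)},
        }

    def test_reproducible_candidate_selected(self):
        # both cohorts' optima at the same cell, significant everywhere
        grids = self._grids([0.001, 0.5, 0.5, 0.5], [0.002, 0.5, 0.5, 0.5])
        best1d = {"c1": {"p": (0.2, 0.3)}, "c2": {"p": (0.15, 0.4)}}
        sel = select_signature(grids, best1d, alpha=0.05)
        assert [e.pair_id for e in sel] == ["p"]
        assert sel[0].p_by_cohort == {"c1": 0.001, "c2": 0.002}

    def test_candidate_failing_in_other_cohort_rejected(self):
        grids = self._grids([0.001, 0.5, 0.5, 0.5], [0.30, 0.04, 0.5, 0.5])
        best1d = {"c1": {"p": (0.2, 0.3)}, "c2": {"p": (0.15, 0.4)}}
        # c1's optimum (cell 0) has p=0.30 in c2; c2's optimum (cell 1) has
        # p=0.5 in c1 -> no candidate reproduces
        assert select_signature(grids, best1d, alpha=0.05) == []

    def test_non_synergistic_pair_rejected(self):
        grids = self._grids([0.001, 0.5, 0.5, 0.5], [0.002, 0.5, 0.5, 0.5])
        best1d = {"c1": {"p": (0.0005, 0.3)}, "c2": {"p": (0.15, 0.4)}}
        assert select_signature(grids, best1d, alpha=0.05) == []

    def test_inconsistent_risk_direction_rejected(self):
        grids = self._grids(
            [0.001, 0.5, 0.5, 0.5], [0.002, 0.5, 0.5, 0.5],
            b1=[1.0] * 4, b2=[-1.0] * 4,
        )
        best1d = {"c1": {"p": (0.2, 0.3)}, "c2": {"p": (0.15, 0.4)}}
        assert select_signature(grids, best1d, alpha=0.05) == []

    def test_disjoint_pair_sets_rejected(self):
        grids = {
            "c1": {"pA": _toy_grid([0.1] * 4, [1.0] * 4, "pA")},
            "c2": {"pB": _toy_grid([0.1] * 4, [1.0] * 4, "pB")},
        }
        with pytest.raises(ValueError):
            select_signature(grids, {"c1": {}, "c2": {}})


class TestTransferModel:
    def test_cutoffs_recomputed_on_new_cohort(self, rng):
        times, events, x, y = _pair_fixture(rng, n=100)
        model = fit_pair(times, events, x, y, mode="RDDG2D")
        x2, y2 = simulate_pair_expression(150, 0.5, rng=rng)
        moved = transfer_model(model, x2, y2)
        xr, yr = rotate(x2, y2, model.angle_index)
        assert moved.c1 == pytest.approx(np.quantile(xr, model.q1))
        assert moved.c2 == pytest.approx(np.quantile(yr, model.q2))
        assert moved.design == model.design
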