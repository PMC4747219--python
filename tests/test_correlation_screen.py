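from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sagp_risk.correlation_screen import (
    compare_tau_distributions,
    cooccurrence_hypergeom,
    hypergeom_tail,
    kendall_tau,
    screen_pairs,
    select_representative,
)
from sagp_risk.data_model import (
    ClinicalRecord,
    CohortBundle,
    ExpressionMatrix,
    GenePairAnnotation,
    GenomicInterval,
)


def brute_force_tau(x, y):
    """Concordant/discordant pair counting (tau-a; valid for tie-free data)."""
    n = len(x)
    s = sum(
        np.sign((x[i] - x[j]) * (y[i] - y[j]))
        for i, j in combinations(range(n), 2)
    )
    return s / (n * (n - 1) / 2)


class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 1 / 3),  # 4 concordant, 2 discordant
            ([1, 2, 3], [3, 2, 1], -1.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_counting(self, rng):
        for _ in range(10):
            x = rng.permutation(8).astype(float)
            y = rng.permutation(8).astype(float)
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(brute_force_tau(x, y), abs=1e-12)

    def test_antisymmetric_under_reversal(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        tau_fwd, _ = kendall_tau(x, y)
        tau_rev, _ = kendall_tau(x, -y)
        assert tau_fwd == pytest.approx(-tau_rev, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float)
        y = np.sort(x)[::-1].copy()
        t1, _ = kendall_tau(x, y)
        t2, _ = kendall_tau(x**3, y)  # strictly increasing, injective
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_gaussian_pairs_follow_arcsine_law(self, rng):
        rho = 0.6
        z = rng.standard_normal((2, 2000))
        x = z[0]
        y = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(2 / np.pi * np.arcsin(rho), abs=0.03)

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [3, 4])
        with pytest.raises(ValueError):
            kendall_tau([1, 2, 3], [1, 2])


class TestHypergeometric:
    def test_known_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert cooccurrence_hypergeom(
            set("abcde"), set("abcd"), set("abcdefghij")
        ) == pytest.approx(5 / 210, rel=1e-9)

    def test_zero_overlap_gives_one(self):
        assert cooccurrence_hypergeom({"a"}, {"b"}, set("ab")) == pytest.approx(1.0)

    def test_full_universe_forces_one(self):
        u = set("abcdef")
        assert cooccurrence_hypergeom(u, set("abc"), u) == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_hypergeom({"z"}, {"a"}, {"a", "b"})

    def test_matches_exhaustive_enumeration(self):
        # P(X >= k) by enumerating every draw of size n from N
        from itertools import combinations as combs

        N, K, n = 9, 4, 5
        universe = list(range(N))
        marked = set(universe[:K])
        for k in range(0, min(K, n) + 1):
            total = hits = 0
            for draw in combs(universe, n):
                total += 1
                hits += len(marked & set(draw)) >= k
            assert hypergeom_tail(k, N, K, n) == pytest.approx(
                hits / total, rel=1e-9
            )


def _two_gene_bundle(x, y, name="c"):
    n = len(x)
    expr = ExpressionMatrix(
        ["gA", "gB"], [f"s{i}" for i in range(n)], np.vstack([x, y])
    )
    clinical = [
        ClinicalRecord(f"s{i}", 1.0, 0, grade="G3", cohort=name) for i in range(n)
    ]
    return CohortBundle(expr, clinical, name)


def _pair(pid="p1", ga="gA", gb="gB"):
    iv1 = GenomicInterval("chr1", 0, 100, "+")
    iv2 = GenomicInterval("chr1", 50, 150, "-")
    return GenePairAnnotation(pid, ga, gb, "divergent", iv1, iv2)


class TestScreening:
    def test_threshold_splits_records(self, rng):
        z = rng.standard_normal((2, 40))
        strong = _two_gene_bundle(z[0], 0.9 * z[0] + 0.1 * z[1])
        records, kept = screen_pairs(strong, [_pair()], "grade=G3")
        assert records[0].p_value < 0.05 and kept == ["p1"]
        weak = _two_gene_bundle(z[0], z[1])
        records, kept = screen_pairs(weak, [_pair()], "grade=G3")
        if records[0].p_value >= 0.05:
            assert kept == []

    def test_positive_only_filter(self, rng):
        x = rng.standard_normal(40)
        bundle = _two_gene_bundle(x, -x)
        _, kept = screen_pairs(bundle, [_pair()], None, positive_only=True)
        assert kept == []
        _, kept = screen_pairs(bundle, [_pair()], None, positive_only=False)
        assert kept == ["p1"]

    def test_small_subgroup_rejected(self, rng):
        x = rng.standard_normal(10)
        bundle = _two_gene_bundle(x, x)
        bundle.clinical = bundle.clinical[:2]
        with pytest.raises(ValueError):
            screen_pairs(
                CohortBundle(bundle.expression, bundle.clinical[:2], "c"),
                [_pair()],
                "grade=G3",
            )


class TestRepresentative:
    def _bundle(self):
        vals = np.array(
            [
                [1.0, 2, 3, 4, 5],       # base
                [1.1, 2.2, 2.9, 4.3, 5.2],  # tau ~ +1 with base
                [5.0, 4, 3, 2, 1],       # tau = -1 with base
                [2.0, 1, 4, 3, 5],       # weaker
            ]
        )
        expr = ExpressionMatrix(
            ["base", "pos", "neg", "weak"], [f"s{i}" for i in range(5)], vals
        )
        clinical = [ClinicalRecord(f"s{i}", 1.0, 0) for i in range(5)]
        return CohortBundle(expr, clinical, "c")

    def test_strongest_magnitude_wins_even_if_negative(self):
        bundle = self._bundle()
        chosen = select_representative(
            _pair(), [("base", "weak"), ("base", "neg")], bundle, None
        )
        assert chosen == ("base", "neg")

    def test_single_candidate_returned(self):
        bundle = self._bundle()
        assert select_representative(
            _pair(), [("base", "pos")], bundle, None
        ) == ("base", "pos")

    def test_tie_breaks_lexicographically(self):
        bundle = self._bundle()
        # both candidates have |tau| = 1
        chosen = select_representative(
            _pair(), [("base", "neg"), ("base", "pos")], bundle, None
        )
        assert chosen == ("base", "neg")

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_representative(_pair(), [], self._bundle(), None)


class TestKSComparison:
    def test_identical_multisets(self):
        taus = [0.1, 0.2, 0.3, 0.4]
        res = compare_tau_distributions(taus, taus)
        assert res.statistic == 0.0 and res.p_value >= 0.999

    def test_disjoint_supports(self):
        res = compare_tau_distributions([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert res.statistic == pytest.approx(1.0)

    def test_stepped_ecdf_value(self):
        res = compare_tau_distributions([0.1, 0.5, 0.9], [0.2, 0.6, 0.6])
        # manual ECDF sweep over the pooled support
        a = np.array([0.1, 0.5, 0.9])
        b = np.array([0.2, 0.6, 0.6])
        grid = np.sort(np.concatenate([a, b]))
        d = max(
            abs((a <= g).mean() - (b <= g).mean()) for g in grid
        )
        assert res.statistic == pytest.approx(d)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            compare_tau_distributions([0.1, 0.2], [0.3, 0.4, 0.5])
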