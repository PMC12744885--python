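from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from coexscreen.cooccurrence import (
    anchor_modules,
    cooc_count,
    exact_tail,
    permutation_test,
)
from coexscreen.io import ConfigError, DataError, ModulePartition, UNASSIGNED
from conftest import random_partition


def make_partition(layout):
    """layout: {group: {gene: label}}"""
    return ModulePartition(assignments={g: dict(m) for g, m in layout.items()})


def single_group(n=10, anchor_module_size=4, candidate_in=True):
    """One group with N analysed genes and an anchor module of given size."""
    genes = {}
    genes["A1"] = genes["A2"] = "blue"
    extra = anchor_module_size - 2 - (1 if candidate_in else 0)
    if candidate_in:
        genes["cand"] = "blue"
    for i in range(extra):
        genes[f"m{i}"] = "blue"
    used = 2 + (1 if candidate_in else 0) + extra
    if not candidate_in:
        genes["cand"] = UNASSIGNED
        used += 1
    for i in range(n - used):
        genes[f"x{i}"] = UNASSIGNED
    genes = dict(list(genes.items())[:n]) if len(genes) > n else genes
    return make_partition({"g0": genes})


class TestAnchorModules:
    def test_counts_only_shared_real_modules(self):
        part = make_partition(
            {
                "A": {"A1": "M1", "A2": "M1", "x": "M2"},
                "B": {"A1": "M3", "A2": "M3", "x": "M3"},
                "C": {"A1": "M1", "A2": "M2", "x": "M1"},
            }
        )
        am = anchor_modules(part, "A1", "A2")
        assert am == {"A": "M1", "B": "M3", "C": None}

    def test_unassigned_shared_label_is_not_a_module(self):
        part = make_partition({"A": {"A1": UNASSIGNED, "A2": UNASSIGNED, "x": "M1"}})
        assert anchor_modules(part, "A1", "A2") == {"A": None}

    def test_anchors_absent_everywhere_is_error(self):
        part = make_partition({"A": {"x": "M1", "y": "M1", "z": "M1"}})
        with pytest.raises(DataError, match="no group"):
            anchor_modules(part, "A1", "A2")

    def test_matches_brute_force_on_seeded_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            part = random_partition(rng)
            am = anchor_modules(part, "A1", "A2")
            for group, genes in part.assignments.items():
                l1, l2 = genes.get("A1"), genes.get("A2")
                expected = l1 if (l1 == l2 and l1 not in (None, UNASSIGNED)) else None
                assert am[group] == expected


class TestCoocCount:
    def test_anchor_as_candidate_matches_everywhere(self):
        rng = np.random.default_rng(1)
        part = random_partition(rng)
        am = anchor_modules(part, "A1", "A2")
        t = sum(1 for v in am.values() if v is not None)
        assert cooc_count(part, "A1", am) == t

    def test_unassigned_candidate_never_matches(self):
        part = make_partition(
            {"A": {"A1": "M1", "A2": "M1", "cand": UNASSIGNED, "x": "M1"}}
        )
        am = anchor_modules(part, "A1", "A2")
        assert cooc_count(part, "cand", am) == 0

    def test_headline_table_semantics(self):
        # 8 groups, anchors co-assigned in all 8, candidate matching in 3
        layout = {}
        for i in range(8):
            genes = {"A1": "M1", "A2": "M1", "x1": "M1", "x2": "M2", "x3": "M2"}
            genes["cand"] = "M1" if i < 3 else "M2"
            layout[f"g{i}"] = genes
        part = make_partition(layout)
        am = anchor_modules(part, "A1", "A2")
        assert sum(1 for v in am.values() if v is not None) == 8
        assert cooc_count(part, "cand", am) == 3


class TestExactTail:
    def test_two_group_product(self):
        # q = (0.25, 0.5): P(S >= 2) = 0.25 * 0.5 = 0.125 by enumeration
        layout = {
            "A": {"A1": "M", "A2": "M", "m1": "M", "m2": "M",
                  **{f"x{i}": UNASSIGNED for i in range(6)}},  # m=4, N=10 -> 0.25
            "B": {"A1": "M", "A2": "M", "m1": "M", "m2": "M",
                  **{f"y{i}": UNASSIGNED for i in range(2)}},  # m=4, N=6 -> 0.5
        }
        part = make_partition(layout)
        assert exact_tail(part, "A1", "A2", 2) == pytest.approx(0.125, abs=1e-15)

    def test_zero_statistic_has_tail_one(self):
        rng = np.random.default_rng(3)
        part = random_partition(rng)
        assert exact_tail(part, "A1", "A2", 0) == 1.0

    def test_degenerate_group_size_is_error(self):
        part = make_partition({"A": {"A1": "M", "A2": "M"}})
        with pytest.raises(DataError, match="N="):
            exact_tail(part, "A1", "A2", 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_equals_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        part = random_partition(rng, max_groups=12)
        am = anchor_modules(part, "A1", "A2")
        qs = []
        for group, label in am.items():
            if label is None:
                continue
            genes = part.assignments[group]
            m = sum(1 for l in genes.values() if l == label)
            qs.append(Fraction(m - 2, len(genes) - 2))
        for s in range(len(qs) + 2):
            tail = Fraction(0)
            for combo in product([0, 1], repeat=len(qs)):
                if sum(combo) >= s:
                    prod = Fraction(1)
                    for c, q in zip(combo, qs):
                        prod *= q if c else 1 - q
                    tail += prod
            assert exact_tail(part, "A1", "A2", s) == pytest.approx(float(tail), abs=1e-12)


class TestPermutationTest:
    def test_zero_statistic_gives_p_one(self):
        part = single_group(n=10, anchor_module_size=4, candidate_in=False)
        res = permutation_test(part, "cand", ["cand", "x0", "x1"], "A1", "A2", b=500, seed=0)
        assert res.s_emp == 0
        assert res.p_mc == 1.0

    def test_single_group_closed_form(self):
        # N=10, anchor module size 4, S_emp=1: p = (m-2)/(N-2) = 0.25
        part = single_group(n=10, anchor_module_size=4, candidate_in=True)
        b = 10_000
        res = permutation_test(
            part, "cand", ["cand"] + [f"x{i}" for i in range(5)], "A1", "A2", b=b, seed=42
        )
        assert res.s_emp == 1 and res.t_total == 1
        assert res.p_exact == pytest.approx(0.25, abs=1e-15)
        tol = 3 * np.sqrt(0.25 * 0.75 / b)
        assert abs(res.p_mc - 0.25) <= tol

    def test_default_replicate_count_is_ten_thousand(self):
        import inspect

        from coexscreen.cooccurrence import permutation_test as pt

        assert inspect.signature(pt).parameters["b"].default == 10_000

    def test_p_monotone_in_empirical_statistic(self):
        rng = np.random.default_rng(7)
        part = random_partition(rng)
        am = anchor_modules(part, "A1", "A2")
        t = sum(1 for v in am.values() if v is not None)
        tails = [exact_tail(part, "A1", "A2", s) for s in range(t + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_anchors_never_coassigned_is_error(self):
        part = make_partition(
            {"A": {"A1": "M1", "A2": "M2", "cand": "M1", "x": "M2", "y": UNASSIGNED}}
        )
        with pytest.raises(DataError, match="never co-assigned"):
            permutation_test(part, "cand", ["cand", "x"], "A1", "A2", b=10, seed=0)

    def test_anchors_excluded_from_candidates(self):
        part = single_group()
        with pytest.raises(ConfigError, match="excluded"):
            permutation_test(part, "cand", ["A1", "cand"], "A1", "A2", b=10, seed=0)

    def test_zero_exceedance_reported_as_floor(self):
        # an impossible S_emp is never reached; p reported as < 1/B
        part = single_group(n=30, anchor_module_size=3, candidate_in=True)
        # make more groups so S_emp is large and null matches are rare
        layout = {f"g{i}": dict(part.assignments["g0"]) for i in range(6)}
        big = make_partition(layout)
        res = permutation_test(
            big, "cand", ["cand"] + [f"x{i}" for i in range(20)], "A1", "A2", b=200, seed=1
        )
        assert res.s_emp == 6
        if res.n_exceed == 0:
            assert res.below_resolution and res.p_mc == pytest.approx(1 / 200)
            assert res.p_display().startswith("<")

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        part = random_partition(rng)
        kw = dict(b=300, seed=123)
        a = permutation_test(part, "cand", ["cand", "g000"], "A1", "A2", **kw)
        b = permutation_test(part, "cand", ["cand", "g000"], "A1", "A2", **kw)
        assert (a.p_mc, a.null_counts) == (b.p_mc, b.null_counts)

    def test_candidate_exchangeability_of_null(self):
        # the null law of S does not depend on which candidate subset is drawn
        rng = np.random.default_rng(11)
        part = random_partition(rng, max_groups=6)
        res_a = permutation_test(part, "cand", ["cand"], "A1", "A2", b=4000, seed=5)
        res_b = permutation_test(part, "cand", ["cand", "g000", "g001"], "A1", "A2", b=4000, seed=6)
        mean_a = sum(s * c for s, c in res_a.null_counts.items()) / res_a.b
        mean_b = sum(s * c for s, c in res_b.null_counts.items()) / res_b.b
        assert abs(mean_a - mean_b) < 0.15

    def test_unconditioned_variant_runs_and_has_no_oracle(self):
        rng = np.random.default_rng(13)
        part = random_partition(rng, max_groups=4)
        res = permutation_test(
            part, "cand", ["cand"], "A1", "A2", b=500, seed=2, condition_on_anchors=False
        )
        assert np.isnan(res.p_exact)
        assert 0 < res.p_mc <= 1
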