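import numpy as np
import pytest

from coexscreen.io import ConfigError, DataError, UNASSIGNED
from coexscreen.network import (
    GeneNetwork,
    adjacency,
    detect_modules,
    module_eigengene,
    pick_soft_power,
    scale_free_fit,
    tom,
)


def block_expression(seed=0, n_samples=40, blocks=(10, 10), noise=0.15, n_background=10):
    """Metacell-like expression with planted correlated blocks."""
    rng = np.random.default_rng(seed)
    cols, names = [], []
    for b, size in enumerate(blocks):
        latent = rng.normal(size=n_samples)
        for i in range(size):
            cols.append(latent + rng.normal(scale=noise, size=n_samples))
            names.append(f"b{b}_{i:02d}")
    for i in range(n_background):
        cols.append(rng.normal(size=n_samples))
        names.append(f"bg_{i:02d}")
    return np.column_stack(cols), names


class TestAdjacency:
    def test_signed_transform_closed_forms(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 0.0], [4.0, -1.0]])
        net = adjacency(x, ["up", "down"], power=6)
        # r = -1 -> 0 under the signed transform
        assert net.weights[0, 1] == pytest.approx(0.0, abs=1e-12)
        y = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert adjacency(y, ["a", "b"], power=9).weights[0, 1] == pytest.approx(1.0)

    def test_uncorrelated_pair_at_power_six(self):
        # r = 0 -> 0.5 ** 6 exactly
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        net = adjacency(x, ["a", "b"], power=6)
        assert net.weights[0, 1] == pytest.approx(0.5**6, abs=1e-12)

    def test_constant_gene_is_error(self):
        x = np.ones((5, 2))
        x[:, 0] = np.arange(5)
        with pytest.raises(DataError, match="constant"):
            adjacency(x, ["a", "flat"], power=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_range_symmetry_diagonal(self, seed):
        x, names = block_expression(seed)
        net = adjacency(x, names, power=7)
        w = net.weights
        assert np.allclose(w, w.T)
        assert w.min() >= 0 and w.max() <= 1
        assert np.allclose(np.diag(w), 1)


class TestTom:
    def test_three_node_saturated_network(self):
        # all off-diagonal a = 1: omega = (1 + 1) / (2 + 1 - 1) = 1
        w = np.ones((3, 3))
        net = GeneNetwork(["a", "b", "c"], w, kind="adjacency")
        assert tom(net).weights[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_is_zero(self):
        w = np.eye(4)
        w[2, 3] = w[3, 2] = 0.9  # a pair elsewhere; (0,1) have a=0, no shared
        net = GeneNetwork(["a", "b", "c", "d"], w, kind="adjacency")
        assert tom(net).weights[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_range_on_random_adjacencies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        w = rng.uniform(0, 1, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        omega = tom(GeneNetwork([f"g{i}" for i in range(n)], w, kind="adjacency")).weights
        assert omega.min() >= 0 and omega.max() <= 1 + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_triple_loop(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 31))
        w = rng.uniform(0, 1, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        net = GeneNetwork([f"g{i}" for i in range(n)], w, kind="adjacency")
        omega = tom(net).weights
        a = w.copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert omega[i, j] == pytest.approx(expected, abs=1e-10)


class TestScaleFreeFit:
    def test_constructed_power_law_fits_well(self):
        # rank-one adjacency: k_i ~ w_i; draw w from an exact power law
        n = 500
        u = (np.arange(1, n + 1) - 0.5) / n
        w = 0.05 * u ** (-1 / 2.5)  # P(W > x) ~ x**-2.5
        a = np.outer(w, w)
        np.fill_diagonal(a, 1.0)
        a = np.clip(a, 0, 1)
        net = GeneNetwork([f"g{i}" for i in range(n)], a, kind="adjacency")
        assert scale_free_fit(net) >= 0.95

    def test_degenerate_equal_connectivities_return_zero(self, caplog):
        w = np.full((30, 30), 0.5)
        np.fill_diagonal(w, 1.0)
        net = GeneNetwork([f"g{i}" for i in range(30)], w, kind="adjacency")
        import logging

        with caplog.at_level(logging.WARNING):
            assert scale_free_fit(net) == 0.0
        assert "degenerate" in caplog.text or "bins" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_above_by_one(self, seed):
        x, names = block_expression(seed)
        fit = scale_free_fit(adjacency(x, names, power=6))
        assert fit <= 1.0


class TestPickSoftPower:
    def naive_scan(self, x, names, powers, target):
        """Independent re-implementation: exhaustive scan, same fallback rule."""
        from coexscreen.network import fallback_power

        for p in sorted(powers):
            if scale_free_fit(adjacency(x, names, power=p)) >= target:
                return p
        fb = fallback_power(x.shape[0])
        return min(max(fb, min(powers)), max(powers))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_scan(self, seed):
        x, names = block_expression(seed, n_samples=30, n_background=20)
        powers = range(1, 21)
        for target in (0.3, 0.8):
            assert pick_soft_power(x, names, powers=powers, target=target) == self.naive_scan(
                x, names, powers, target
            )

    def test_lowest_qualifying_power_wins(self):
        x, names = block_expression(3, n_samples=30)
        powers = range(1, 21)
        chosen = pick_soft_power(x, names, powers=powers, target=0.2)
        for p in range(1, chosen):
            assert scale_free_fit(adjacency(x, names, power=p)) < 0.2


class TestDetectModules:
    @staticmethod
    def block_tom(sizes, within=0.95, between=0.02, n_extra=0, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes) + n_extra
        w = np.full((n, n), between) + rng.uniform(0, 0.005, size=(n, n))
        w = (w + w.T) / 2
        start = 0
        for s in sizes:
            w[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(w, 1.0)
        return GeneNetwork([f"g{i:03d}" for i in range(n)], np.clip(w, 0, 1), kind="tom")

    def test_two_perfect_blocks_give_two_modules(self):
        net = self.block_tom([12, 12], within=1.0, between=0.0, n_extra=30)
        labels = detect_modules(net, min_module_size=10)
        mods = {m for m in labels.values() if m != UNASSIGNED}
        assert len(mods) == 2
        assert len({labels[f"g{i:03d}"] for i in range(12)}) == 1

    def test_small_block_below_min_size_unassigned(self):
        net = self.block_tom([5], within=1.0, between=0.0, n_extra=30)
        labels = detect_modules(net, min_module_size=10)
        assert all(labels[f"g{i:03d}"] == UNASSIGNED for i in range(5))

    def test_invariant_to_gene_input_order(self):
        net = self.block_tom([10, 14], n_extra=20, seed=3)
        labels = detect_modules(net)
        rng = np.random.default_rng(1)
        perm = rng.permutation(net.n_genes)
        shuffled = GeneNetwork(
            [net.gene_ids[i] for i in perm],
            net.weights[np.ix_(perm, perm)],
            kind="tom",
        )
        assert detect_modules(shuffled) == labels

    def test_absolute_cut_height_override(self):
        net = self.block_tom([12], within=1.0, between=0.0, n_extra=20)
        labels = detect_modules(net, cut_height=0.5)
        assert sum(1 for l in labels.values() if l != UNASSIGNED) == 12


class TestModuleEigengene:
    def test_identical_genes_have_kme_one(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=25)
        expr = np.column_stack([col, col, col, rng.normal(size=25)])
        es = module_eigengene(expr, ["a", "b", "c", "other"], ["a", "b", "c"])
        for g in ("a", "b", "c"):
            assert es.kme[g] == pytest.approx(1.0, abs=1e-9)

    def test_orientation_positive_with_module_mean(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            latent = rng.normal(size=30)
            expr = np.column_stack(
                [latent + rng.normal(scale=0.3, size=30) for _ in range(6)]
            )
            genes = [f"g{i}" for i in range(6)]
            es = module_eigengene(expr, genes, genes)
            assert np.corrcoef(es.eigengene, expr.mean(axis=1))[0, 1] >= 0
            assert np.linalg.norm(es.eigengene) == pytest.approx(1.0)

    def test_member_kme_beats_outsider(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(size=40)
        member_cols = [latent + rng.normal(scale=0.3, size=40) for _ in range(8)]
        outsider = rng.normal(size=40)
        expr = np.column_stack(member_cols + [outsider])
        genes = [f"m{i}" for i in range(8)] + ["out"]
        es = module_eigengene(expr, genes, genes[:-1], extra_genes=["out"])
        assert min(es.kme[g] for g in genes[:-1]) > es.kme["out"]

    def test_degenerate_module_is_error(self):
        expr = np.ones((10, 3))
        with pytest.raises(DataError, match="constant"):
            module_eigengene(expr, ["a", "b", "c"], ["a", "b"])
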