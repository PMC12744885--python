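import numpy as np
import pytest

from coexscreen.io import BulkExpressionTable, ModulePartition, SingleCellCounts, UNASSIGNED


@pytest.fixture
def small_table():
    """3 genes x 4 samples with known values."""
    return BulkExpressionTable(
        gene_ids=["gA", "gB", "gC"],
        sample_labels=["s1", "s2", "s3", "s4"],
        values=np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 3.0, 2.0, 1.0]]),
    )


def random_bulk_table(seed: int, n_genes: int = 12, n_samples: int = 7) -> BulkExpressionTable:
    rng = np.random.default_rng(seed)
    return BulkExpressionTable(
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        sample_labels=[f"s{j}" for j in range(n_samples)],
        values=rng.gamma(2.0, 10.0, size=(n_genes, n_samples)),
    )


def random_counts(seed: int, n_cells: int = 40, n_genes: int = 15, n_groups: int = 2) -> SingleCellCounts:
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    counts = sp.csr_matrix(rng.poisson(1.5, size=(n_cells, n_genes)))
    cells = [f"c{i:03d}" for i in range(n_cells)]
    groups = {c: f"t{i % n_groups}" for i, c in enumerate(cells)}
    return SingleCellCounts(
        cell_ids=cells,
        gene_ids=[f"g{j:03d}" for j in range(n_genes)],
        counts=counts,
        group_of=groups,
    )


def random_partition(rng: np.random.Generator, max_groups: int = 12) -> ModulePartition:
    """Random per-group module partition with the anchors co-assigned.

    Anchors A1/A2 share module "M1" in every group; a candidate gene "cand"
    and background genes are scattered over M1, an optional M2 and the
    unassigned block.
    """
    n_groups = int(rng.integers(2, max_groups + 1))
    parts = {}
    for t in range(n_groups):
        n = int(rng.integers(10, 40))
        genes = ["A1", "A2", "cand"] + [f"g{j:03d}" for j in range(n - 3)]
        labels = {}
        m_anchor = int(rng.integers(3, max(4, n // 3)))
        extra = list(rng.choice(genes[3:], size=m_anchor - 2, replace=False))
        for g in ["A1", "A2"] + extra:
            labels[g] = "M1"
        rest = [g for g in genes if g not in labels]
        if len(rest) > 5:
            m2 = int(rng.integers(3, len(rest) // 2 + 1))
            for g in rng.choice(rest, size=m2, replace=False):
                labels[g] = "M2"
        for g in genes:
            labels.setdefault(g, UNASSIGNED)
        parts[f"grp{t}"] = labels
    return ModulePartition(assignments=parts)
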