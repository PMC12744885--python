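"""KNN metacell aggregation within annotated cell groups.

A metacell is a set of exactly k transcriptionally neighbouring cells from a
single group (cell type), aggregated by averaging raw counts to reduce
sparsity. Metacells are built by acceptance-by-rejection: seed cells are
drawn without replacement by a seeded RNG, the seed's k nearest neighbours in
the reduced (PCA) space form a candidate, and the candidate is accepted iff
it shares at most ``max_shared`` members with every previously accepted
metacell of the same group. Correlations and regression lines downstream are
computed on the library-size-normalised, log1p metacell matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .bulk import pearson_r
from .io import ConfigError, DataError, SingleCellCounts
from .preprocess import ReducedSpace

__all__ = [
    "MetacellSet",
    "MetacellExpression",
    "build_metacells",
    "normalize_metacells",
    "metacell_correlation",
    "ols_line",
]

log = logging.getLogger(__name__)


@dataclass
class MetacellSet:
    """Aggregated metacells plus membership and provenance.

    ``expression`` rows are the mean raw counts of the k member cells;
    library-size renormalisation happens in :func:`normalize_metacells`.
    """

    metacell_ids: list[str]
    members: dict[str, list[str]]
    group_of: dict[str, str]
    gene_ids: list[str]
    expression: np.ndarray
    k: int
    max_shared: int
    seed: int
    skipped_groups: list[str]

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)


@dataclass
class MetacellExpression:
    """Metacells x genes normalised expression used for correlations/networks."""

    metacell_ids: list[str]
    gene_ids: list[str]
    group_of: dict[str, str]
    values: np.ndarray

    def column(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present") from None
        return self.values[:, j]

    def groups(self) -> list[str]:
        out, seen = [], set()
        for m in self.metacell_ids:
            g = self.group_of[m]
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def group_rows(self, group: str) -> np.ndarray:
        mask = np.array([self.group_of[m] == group for m in self.metacell_ids])
        return self.values[mask]


def build_metacells(
    reduced: ReducedSpace,
    counts: SingleCellCounts,
    k: int = 25,
    max_shared: int = 10,
    target_per_group: int | None = None,
    max_attempts: int | None = None,
    seed: int = 0,
) -> MetacellSet:
    """Build metacells per group under size and overlap constraints.

    ``target_per_group`` defaults to floor(group_size / (k - max_shared)), a
    feasibility-motivated cap; ``max_attempts`` to 5 x group size (seed cells
    are drawn without replacement, so a group can exhaust its seeds earlier).
    Groups with fewer than k cells are skipped with a logged warning.
    Deterministic given the seed.
    """
    if not k > max_shared >= 0:
        raise ConfigError(f"need k > max_shared >= 0, got k={k}, max_shared={max_shared}")
    if reduced.cell_ids != counts.cell_ids:
        raise DataError("reduced space and counts index different cells")
    rng = np.random.default_rng(seed)
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}

    metacell_ids: list[str] = []
    members: dict[str, list[str]] = {}
    group_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    skipped: list[str] = []

    for group in counts.groups():
        g_cells = [c for c in counts.cell_ids if counts.group_of[c] == group]
        if len(g_cells) < k:
            log.warning("group %r has %d < k=%d cells; skipped", group, len(g_cells), k)
            skipped.append(group)
            continue
        g_idx = np.array([cell_index[c] for c in g_cells])
        coords = reduced.coords[g_idx]
        nn = NearestNeighbors(n_neighbors=k).fit(coords)
        target = target_per_group if target_per_group is not None else len(g_cells) // (k - max_shared)
        limit = max_attempts if max_attempts is not None else 5 * len(g_cells)
        seed_order = rng.permutation(len(g_cells))
        accepted: list[set[int]] = []
        attempts = 0
        for s in seed_order:
            if len(accepted) >= target or attempts >= limit:
                break
            attempts += 1
            # k nearest neighbours of the seed cell, self included
            neigh = nn.kneighbors(coords[s : s + 1], return_distance=False)[0]
            cand = set(neigh.tolist())
            if all(len(cand & prev) <= max_shared for prev in accepted):
                accepted.append(cand)
                mc_id = f"{group}|mc{len(accepted):04d}"
                mem = sorted(cand)
                metacell_ids.append(mc_id)
                members[mc_id] = [g_cells[i] for i in mem]
                group_of[mc_id] = group
                sub = counts.counts[g_idx[mem]]
                rows.append(np.asarray(sub.mean(axis=0)).ravel())

    expression = np.vstack(rows) if rows else np.empty((0, counts.n_genes))
    return MetacellSet(
        metacell_ids=metacell_ids,
        members=members,
        group_of=group_of,
        gene_ids=list(counts.gene_ids),
        expression=expression,
        k=k,
        max_shared=max_shared,
        seed=seed,
        skipped_groups=skipped,
    )


def normalize_metacells(mc: MetacellSet, scale: float = 1e4) -> MetacellExpression:
    """Library-size normalise each metacell to ``scale`` and log1p.

    Same transform as the per-cell normalisation: entry =
    ln(1 + scale * value / metacell_total). A metacell whose aggregated total
    is zero is an error.
    """
    totals = mc.expression.sum(axis=1)
    if np.any(totals == 0):
        raise DataError("metacell with zero total aggregated count")
    values = np.log1p(scale * mc.expression / totals[:, None])
    return MetacellExpression(
        metacell_ids=list(mc.metacell_ids),
        gene_ids=list(mc.gene_ids),
        group_of=dict(mc.group_of),
        values=values,
    )


def metacell_correlation(expr: MetacellExpression, g1: str, g2: str, by_group: bool = False):
    """Pearson correlation of two genes over metacells.

    Overall mode returns a single r; per-group mode returns a mapping
    group -> r, with None (not a silent number) for groups with fewer than 3
    metacells or constant expression of either gene.
    """
    x = expr.column(g1)
    y = expr.column(g2)
    if not by_group:
        return pearson_r(x, y)
    out: dict[str, float | None] = {}
    for group in expr.groups():
        mask = np.array([expr.group_of[m] == group for m in expr.metacell_ids])
        xs, ys = x[mask], y[mask]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[group] = None
        else:
            out[group] = pearson_r(xs, ys)
    return out


def ols_line(x, y) -> tuple[float, float]:
    """Ordinary least squares fit y = slope * x + intercept.

    Minimises vertical residuals; constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ConfigError("ols_line requires two equal-length vectors of length >= 2")
    if np.ptp(x) == 0:
        raise DataError("ols_line undefined for constant x")
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)
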