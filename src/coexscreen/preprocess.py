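"""Single-cell QC, normalisation, feature selection and PCA.

The fixed processing order is::

    qc_filter -> normalize_log1p -> select_hvg -> scale_genes -> pca

with :func:`prevalence_filter` defining (together with the HVGs) the gene
universe the co-expression networks are built on. Every stage here is
deterministic — there is no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import ConfigError, DataError, SingleCellCounts

__all__ = [
    "NormalizedMatrix",
    "ReducedSpace",
    "qc_filter",
    "normalize_log1p",
    "select_hvg",
    "prevalence_filter",
    "scale_genes",
    "pca",
]


@dataclass
class NormalizedMatrix:
    """Cells x genes log-normalised expression (dense).

    An entry is 0 iff the underlying count is 0: the transform is
    log(1 + scale * count / cell_total) with natural log.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale: float = 1e4
    log_base: str = "e"

    def column(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present") from None
        return self.values[:, j]


@dataclass
class ReducedSpace:
    """Cell coordinates in a PCA space, components ordered by variance."""

    cell_ids: list[str]
    coords: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def qc_filter(counts: SingleCellCounts, min_genes: int = 200, max_genes: int | None = None) -> SingleCellCounts:
    """Keep cells whose detected-gene count lies in [min_genes, max_genes].

    A gene is detected in a cell when its count is nonzero. ``max_genes`` has
    no default: the appropriate ceiling is tissue-specific (2000-3500 in the
    motivating whole-tissue atlases) and must be stated per run.
    """
    if max_genes is None:
        raise ConfigError("max_genes is required (tissue-specific; no universal default)")
    if not min_genes < max_genes:
        raise ConfigError(f"min_genes ({min_genes}) must be < max_genes ({max_genes})")
    detected = counts.counts.getnnz(axis=1)
    keep = (detected >= min_genes) & (detected <= max_genes)
    if not keep.any():
        raise DataError(
            "QC removed every cell; review min_genes/max_genes against the "
            "detected-gene distribution"
        )
    return counts.subset_cells(keep)


def normalize_log1p(counts: SingleCellCounts, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalise to ``scale`` counts per cell, then log1p.

    entry = ln(1 + scale * count / cell_total). Doubling all counts of a cell
    leaves its normalised vector unchanged. Zero-total cells are an error —
    they must have been removed by QC.
    """
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        n = int((totals == 0).sum())
        raise DataError(f"{n} cell(s) with zero total count; run qc_filter first")
    mat = counts.counts.multiply(scale / totals[:, None]).toarray()
    return NormalizedMatrix(
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
        values=np.log1p(mat),
        scale=scale,
    )


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def select_hvg(norm: NormalizedMatrix, n: int = 2000, method: str = "trend") -> list[str]:
    """Select the n most variable genes of the log-normalised matrix.

    The default ``"trend"`` statistic standardises each gene's variance by a
    mean-variance trend fitted with a rolling median over mean-ordered genes,
    so highly expressed genes do not dominate purely through their mean;
    ``"variance"`` ranks by raw log-expression variance. Constant genes are
    never selected while any non-constant gene remains. Deterministic and
    invariant to cell order; ties broken by gene id.
    """
    if n > len(norm.gene_ids):
        raise ConfigError(f"n={n} exceeds the {len(norm.gene_ids)} available genes")
    if method not in ("trend", "variance"):
        raise ConfigError(f"unknown HVG method {method!r}")
    means = norm.values.mean(axis=0)
    variances = norm.values.var(axis=0)
    if method == "variance":
        score = variances.copy()
    else:
        order = np.argsort(means, kind="stable")
        window = min(51, len(order) if len(order) % 2 == 1 else len(order) - 1)
        window = max(window, 1)
        trend_sorted = _rolling_median(variances[order], window)
        trend = np.empty_like(trend_sorted)
        trend[order] = np.maximum(trend_sorted, 1e-12)
        score = variances / trend
    score = np.where(variances == 0, -np.inf, score)  # constant genes last
    ranked = sorted(range(len(score)), key=lambda j: (-score[j], norm.gene_ids[j]))
    return [norm.gene_ids[j] for j in ranked[:n]]


def prevalence_filter(counts: SingleCellCounts, min_frac: float = 0.05) -> list[str]:
    """Genes detected (count > 0) in at least ``min_frac`` of cells (inclusive)."""
    if not 0 < min_frac <= 1:
        raise ConfigError("min_frac must be in (0, 1]")
    frac = counts.counts.getnnz(axis=0) / counts.n_cells
    return [g for g, f in zip(counts.gene_ids, frac) if f >= min_frac]


def scale_genes(norm: NormalizedMatrix, hvg: list[str], clip: float = 10.0) -> np.ndarray:
    """Per-gene z-score over cells for the given genes, clipped to +/- clip.

    Constant genes yield an all-zero column rather than an error. Returns a
    dense cells x len(hvg) array in the order of ``hvg``.
    """
    missing = [g for g in hvg if g not in norm.gene_ids]
    if missing:
        raise DataError(f"genes absent from matrix: {missing[:5]}")
    if clip <= 0:
        raise ConfigError("clip must be > 0")
    idx = [norm.gene_ids.index(g) for g in hvg]
    sub = norm.values[:, idx]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    out = np.zeros_like(sub)
    nz = sd > 0
    out[:, nz] = (sub[:, nz] - mu[nz]) / sd[nz]
    return np.clip(out, -clip, clip)


def pca(scaled: np.ndarray, cell_ids: list[str], n_components: int = 50) -> ReducedSpace:
    """PCA scores of the scaled matrix with a fixed sign convention.

    Each component is oriented so that its largest-magnitude gene loading is
    positive, making the output deterministic across runs and solvers.
    """
    scaled = np.asarray(scaled, dtype=float)
    if n_components > min(scaled.shape):
        raise ConfigError(
            f"n_components={n_components} exceeds min(cells, genes)={min(scaled.shape)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(scaled)
    for j in range(n_components):
        loading = model.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    return ReducedSpace(
        cell_ids=list(cell_ids),
        coords=scores,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )
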