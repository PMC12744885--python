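"""Bulk-compendium candidate screen.

Given a genes x samples expression table (microarray intensity or RPKM) and a
reference gene, rank every candidate by its Pearson correlation with the
reference across samples, order genes by the timing of their expression peak,
and produce the per-gene max-normalised matrix used for brightness-coded
display.

Correlations are computed on raw expression values; Pearson r is invariant to
a positive per-gene rescaling, so this equals correlating the max-normalised
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io import BulkExpressionTable, ConfigError, DataError

__all__ = [
    "CorrelationRanking",
    "max_normalize",
    "pearson_r",
    "rank_candidates",
    "sort_by_peak",
    "coexpression_presence",
]


@dataclass
class CorrelationRanking:
    """Candidates ordered by correlation with the reference gene.

    ``entries`` is sorted by r descending; ties broken alphabetically by gene
    id; genes with undefined correlation (constant expression) carry r = NaN
    and rank last.
    """

    reference_gene: str
    entries: list[tuple[str, float]]
    dataset: str = ""

    def rank_of(self, gene_id: str) -> int:
        """1-based rank of a gene in the ordering."""
        for i, (g, _) in enumerate(self.entries, start=1):
            if g == gene_id:
                return i
        raise DataError(f"gene {gene_id!r} not in ranking")

    def r_of(self, gene_id: str) -> float:
        for g, r in self.entries:
            if g == gene_id:
                return r
        raise DataError(f"gene {gene_id!r} not in ranking")


def max_normalize(table: BulkExpressionTable) -> BulkExpressionTable:
    """Divide every gene row by its maximum; all-zero rows stay zero.

    The result lies in [0, 1] and is what brightness coding displays. The
    operation is idempotent.
    """
    values = table.values.copy()
    row_max = values.max(axis=1)
    nonzero = row_max > 0
    values[nonzero] = values[nonzero] / row_max[nonzero, None]
    return BulkExpressionTable(
        gene_ids=list(table.gene_ids),
        sample_labels=list(table.sample_labels),
        values=values,
    )


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient in [-1, 1].

    Raises :class:`DataError` for constant vectors rather than returning a
    silent 0: an undefined correlation must be visible to the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("pearson_r requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ConfigError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant vector")
    r = scipy.stats.pearsonr(x, y).statistic
    return float(min(1.0, max(-1.0, r)))


def rank_candidates(
    table: BulkExpressionTable,
    reference: str,
    candidates: list[str],
    dataset: str = "",
) -> CorrelationRanking:
    """Rank candidates by Pearson correlation with the reference gene.

    Candidates whose expression is constant across samples get r = NaN and
    rank last (alphabetically among themselves). A constant reference makes
    every correlation undefined and is an error.
    """
    missing = [g for g in [reference, *candidates] if g not in table.gene_ids]
    if missing:
        raise DataError(f"gene id(s) absent from table: {missing}")
    ref = table.row(reference)
    if np.ptp(ref) == 0:
        raise DataError(f"reference gene {reference!r} is constant; correlations undefined")
    scored: list[tuple[str, float]] = []
    for g in candidates:
        row = table.row(g)
        if np.ptp(row) == 0:
            scored.append((g, math.nan))
        else:
            scored.append((g, pearson_r(ref, row)))
    scored.sort(key=lambda e: (math.isnan(e[1]), -e[1] if not math.isnan(e[1]) else 0.0, e[0]))
    return CorrelationRanking(reference_gene=reference, entries=scored, dataset=dataset)


def sort_by_peak(table: BulkExpressionTable) -> list[str]:
    """Order genes by the sample index of their expression maximum.

    Earlier peaks come first; genes peaking at the same sample keep their
    input order (stable sort). Within a row, the first maximum is the peak.
    """
    peaks = table.values.argmax(axis=1)
    order = np.argsort(peaks, kind="stable")
    return [table.gene_ids[i] for i in order]


def coexpression_presence(
    table: BulkExpressionTable,
    reference: str,
    gene: str,
    threshold: float = 0.05,
) -> tuple[int, int]:
    """Count samples where the reference is visible and the gene co-occurs.

    A gene counts as "expressed" in a sample when its max-normalised value
    exceeds ``threshold`` (a fraction of its own maximum — the implied
    criterion for visibility in a brightness-coded image). Returns
    ``(n_ref_expressed, n_both)``.
    """
    if threshold < 0:
        raise ConfigError("threshold must be nonnegative")
    norm = max_normalize(table)
    ref = norm.row(reference)
    g = norm.row(gene)
    ref_on = ref > threshold
    both = ref_on & (g > threshold)
    return int(ref_on.sum()), int(both.sum())
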