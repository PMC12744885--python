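"""Module co-assignment statistic and its permutation test.

The headline statistic S counts the cell-type groups in which a candidate
gene occupies the same co-expression module as both anchor genes (the two
collagen IV subunits in the motivating screen). Significance is assessed by
a Monte Carlo permutation test: per group, the module labels of all
non-anchor genes are permuted uniformly (module sizes preserved, anchors
held fixed, so the set of anchor modules is conditioned on), one candidate
is drawn uniformly per replicate, and the p-value is the proportion of
replicates whose co-assignment count reaches the empirical value.

Because the null factorises over groups — a random non-anchor gene lands in
group g's anchor module with probability q_g = (|M_g| - 2) / (N_g - 2) —
the null law of S is Poisson-binomial, and :func:`exact_tail` evaluates its
upper tail by dynamic programming as an independent exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConfigError, DataError, ModulePartition, UNASSIGNED

__all__ = ["CoocResult", "anchor_modules", "cooc_count", "exact_tail", "permutation_test"]

DEFAULT_REPLICATES = 10_000


@dataclass
class CoocResult:
    """Outcome of the co-assignment permutation test."""

    candidate: str
    s_emp: int  #: groups where the candidate matched the anchor module
    t_total: int  #: groups whose partition co-assigns both anchors
    b: int  #: Monte Carlo replicates
    n_exceed: int  #: replicates with S_null >= S_emp
    p_mc: float  #: Monte Carlo p-value, floored at 1/B
    p_exact: float  #: Poisson-binomial tail oracle
    below_resolution: bool  #: True when no replicate reached s_emp (p < 1/B)
    null_counts: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    def p_display(self) -> str:
        return f"< {1.0 / self.b:g}" if self.below_resolution else f"{self.p_mc:g}"


def anchor_modules(partition: ModulePartition, a1: str, a2: str) -> dict[str, str | None]:
    """Per group, the shared non-"unassigned" module of the anchors, else None."""
    present = False
    out: dict[str, str | None] = {}
    for group, genes in partition.assignments.items():
        l1, l2 = genes.get(a1), genes.get(a2)
        if l1 is not None and l2 is not None:
            present = True
        if l1 is not None and l1 == l2 and l1 != UNASSIGNED:
            out[group] = l1
        else:
            out[group] = None
    if not present:
        raise DataError(f"anchors {a1!r}/{a2!r} analysed in no group")
    return out


def cooc_count(partition: ModulePartition, candidate: str, anchors_map: dict[str, str | None]) -> int:
    """Number of groups where the candidate shares the anchor module."""
    s = 0
    for group, label in anchors_map.items():
        if label is None:
            continue
        if partition.assignments.get(group, {}).get(candidate) == label:
            s += 1
    return s


def _group_null_probs(
    partition: ModulePartition, a1: str, a2: str, anchors_map: dict[str, str | None]
) -> list[tuple[str, float]]:
    """(group, q_g) for the groups with a co-assigned anchor module."""
    probs = []
    for group, label in anchors_map.items():
        if label is None:
            continue
        genes = partition.assignments[group]
        n_g = len(genes)
        if n_g <= 2:
            raise DataError(f"group {group!r} has N={n_g} <= 2 analysed genes")
        m_g = sum(1 for l in genes.values() if l == label)
        probs.append((group, (m_g - 2) / (n_g - 2)))
    return probs


def exact_tail(partition: ModulePartition, a1: str, a2: str, s_emp: int) -> float:
    """Exact P(S_null >= s_emp) under the conditioned permutation null.

    S_null is Poisson-binomial over the anchor-co-assigned groups with per
    group success probability q_g = (|M_g| - 2) / (N_g - 2); the distribution
    is accumulated by dynamic programming over groups.
    """
    anchors = anchor_modules(partition, a1, a2)
    probs = _group_null_probs(partition, a1, a2, anchors)
    dist = np.array([1.0])
    for _, q in probs:
        dist = np.convolve(dist, [1.0 - q, q])
    if s_emp <= 0:
        return 1.0
    return float(dist[s_emp:].sum())


def permutation_test(
    partition: ModulePartition,
    candidate: str,
    candidates: list[str],
    a1: str,
    a2: str,
    b: int = DEFAULT_REPLICATES,
    seed: int = 0,
    condition_on_anchors: bool = True,
) -> CoocResult:
    """Monte Carlo permutation test of module co-assignment.

    Each replicate permutes, per group, the module labels of all non-anchor
    genes (anchors held fixed by default, so the observed anchor modules are
    conditioned on), draws one candidate uniformly from ``candidates`` and
    records its co-assignment count. With ``condition_on_anchors=False`` the
    anchors' labels join the permutation and each replicate's anchor modules
    are recomputed (Monte Carlo only; no exact oracle for that variant).

    p_mc = #{replicates with S_null >= S_emp} / b, floored at 1/b when no
    replicate reaches the empirical value.
    """
    if b < 1:
        raise ConfigError("b must be >= 1")
    if not candidates:
        raise ConfigError("candidates must be non-empty")
    if a1 in candidates or a2 in candidates:
        raise ConfigError("anchors must be excluded from the candidate list")
    anchors = anchor_modules(partition, a1, a2)
    t_total = sum(1 for label in anchors.values() if label is not None)
    if t_total == 0:
        raise DataError("anchors never co-assigned; empirical statistic undefined")
    s_emp = cooc_count(partition, candidate, anchors)

    rng = np.random.default_rng(seed)
    cand_index = {c: i for i, c in enumerate(candidates)}
    matches = np.zeros((b, len(candidates)), dtype=np.int32)

    for group, genes in partition.assignments.items():
        gene_list = sorted(genes)
        if condition_on_anchors:
            anchor_label = anchors[group]
            if anchor_label is None:
                continue
            pool = [g for g in gene_list if g not in (a1, a2)]
            codes = np.array([genes[g] == anchor_label for g in pool], dtype=np.int8)
            pos = {c: i for i, c in enumerate(pool) if c in cand_index}
            if not pos:
                continue
            perm = rng.permuted(np.tile(codes, (b, 1)), axis=1)
            for c, i in pos.items():
                matches[:, cand_index[c]] += perm[:, i]
        else:
            labels = np.array([genes[g] for g in gene_list])
            perm = rng.permuted(np.tile(np.arange(len(gene_list)), (b, 1)), axis=1)
            lab = labels[perm]
            i1, i2 = gene_list.index(a1), gene_list.index(a2)
            shared = (lab[:, i1] == lab[:, i2]) & (lab[:, i1] != UNASSIGNED)
            for c in candidates:
                if c in genes:
                    ic = gene_list.index(c)
                    hit = shared & (lab[:, ic] == lab[:, i1])
                    matches[:, cand_index[c]] += hit.astype(np.int32)

    drawn = rng.integers(0, len(candidates), size=b)
    s_null = matches[np.arange(b), drawn]
    exceed = int((s_null >= s_emp).sum())
    below = exceed == 0
    p_mc = max(exceed, 1) / b
    p_exact = (
        exact_tail(partition, a1, a2, s_emp) if condition_on_anchors else float("nan")
    )
    vals, counts = np.unique(s_null, return_counts=True)
    return CoocResult(
        candidate=candidate,
        s_emp=int(s_emp),
        t_total=int(t_total),
        b=b,
        n_exceed=exceed,
        p_mc=float(p_mc),
        p_exact=p_exact,
        below_resolution=below,
        null_counts={int(v): int(c) for v, c in zip(vals, counts)},
        seed=seed,
    )
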