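"""Weighted gene co-expression networks per cell-type group.

The construction follows the standard weighted-correlation-network recipe:

1. signed adjacency  a_ij = ((1 + r_ij) / 2) ** beta  with r the Pearson
   correlation over metacells;
2. the soft power beta is the lowest integer whose connectivity distribution
   reaches a scale-free topology fit (signed R^2) of 0.8, falling back to the
   conventional sample-size default power when none does;
3. topological overlap (TOM) turns the adjacency into a neighbourhood-sharing
   similarity; 1 - TOM is the clustering dissimilarity;
4. modules come from an average-linkage dendrogram via a deterministic
   core / merge / attach procedure relative to the background dissimilarity
   level; clusters below ``min_module_size`` are labelled "unassigned";
5. each module is summarised by its eigengene (first principal component of
   the gene-standardised module submatrix) and per-gene eigengene
   connectivity kME.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .bulk import pearson_r
from .io import ConfigError, DataError, UNASSIGNED

__all__ = [
    "GeneNetwork",
    "EigengeneSet",
    "correlation_matrix",
    "adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "tom",
    "detect_modules",
    "module_eigengene",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_MODULE_SIZE = 10
DEFAULT_POWERS = tuple(range(1, 31))
DEFAULT_TARGET_FIT = 0.8


@dataclass
class GeneNetwork:
    """Symmetric genes x genes weight matrix in [0, 1] with unit diagonal."""

    gene_ids: list[str]
    weights: np.ndarray
    kind: str  # "adjacency" | "tom"
    power: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(self.gene_ids):
            raise ConfigError("weights must be square and match gene_ids")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ConfigError("network weights must be symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ConfigError("network weights must lie in [0, 1]")
        if not np.allclose(np.diag(w), 1.0):
            raise ConfigError("network diagonal must be 1")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def connectivity(self) -> np.ndarray:
        """Per-gene connectivity: row sum excluding the unit diagonal."""
        return self.weights.sum(axis=1) - 1.0


@dataclass
class EigengeneSet:
    """Module eigengene (unit norm, over metacells) and per-gene kME."""

    module_label: str
    eigengene: np.ndarray
    kme: dict[str, float]


def correlation_matrix(expr_values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Pearson correlation between gene columns of a metacells x genes matrix."""
    x = np.asarray(expr_values, dtype=float)
    if x.shape[1] != len(gene_ids):
        raise ConfigError("expression columns must match gene_ids")
    sd = x.std(axis=0)
    constant = [g for g, s in zip(gene_ids, sd) if s == 0]
    if constant:
        raise DataError(
            f"constant gene(s) have undefined correlations, pre-filter them: {constant[:5]}"
        )
    r = np.corrcoef(x, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def adjacency(
    expr_values: np.ndarray,
    gene_ids: list[str],
    power: int,
    mode: str = "signed",
    corr: np.ndarray | None = None,
) -> GeneNetwork:
    """Soft-thresholded adjacency from metacell expression.

    Signed transform (default): a_ij = ((1 + r_ij)/2) ** power, so r = -1
    maps to 0 and r = 1 to 1. The unsigned variant uses |r| ** power.
    A precomputed correlation matrix can be passed to avoid recomputation
    when scanning powers.
    """
    if power < 1:
        raise ConfigError("power must be >= 1")
    if mode not in ("signed", "unsigned"):
        raise ConfigError(f"unknown adjacency mode {mode!r}")
    r = correlation_matrix(expr_values, gene_ids) if corr is None else corr
    if mode == "signed":
        a = ((1.0 + r) / 2.0) ** power
    else:
        a = np.abs(r) ** power
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return GeneNetwork(gene_ids=list(gene_ids), weights=a, kind="adjacency", power=power)


def scale_free_fit(network: GeneNetwork, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency fit.

    Connectivities are binned on a log10 scale into ``n_bins`` bins; empty
    bins are dropped; log10(frequency) is regressed on log10(mean k) by least
    squares. The R^2 is negated when the slope is positive (a scale-free
    topology requires a decreasing frequency). Degenerate inputs (all
    connectivities equal, or too few occupied bins) return 0 with a warning.
    """
    if network.n_genes < 20:
        raise ConfigError("scale_free_fit requires at least 20 genes")
    k = network.connectivity()
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0:
        log.warning("scale-free fit undefined: connectivities are degenerate")
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        log.warning("scale-free fit undefined: fewer than 3 occupied bins")
        return 0.0
    slope, intercept = np.polyfit(xs, ys, deg=1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - fitted) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    if ss_tot == 0:
        log.warning("scale-free fit undefined: zero variance in bin frequencies")
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    return float(-r2 if slope > 0 else r2)


def fallback_power(n_samples: int, mode: str = "signed") -> int:
    """Conventional soft power by sample count when no power fits.

    The standard recommendation for data whose connectivity distribution
    does not reach the scale-free target: for signed networks 18 below 20
    samples, 16 for 20-30, 14 for 30-40, 12 above; half that, rounded to
    the usual table, for unsigned networks.
    """
    table = [(20, 18, 9), (30, 16, 8), (40, 14, 7)]
    for bound, signed_p, unsigned_p in table:
        if n_samples < bound:
            return signed_p if mode == "signed" else unsigned_p
    return 12 if mode == "signed" else 6


def pick_soft_power(
    expr_values: np.ndarray,
    gene_ids: list[str],
    powers=DEFAULT_POWERS,
    target: float = DEFAULT_TARGET_FIT,
    mode: str = "signed",
) -> int:
    """Lowest power whose adjacency reaches the scale-free fit target.

    Scans ``powers`` in ascending order and returns the first power whose
    signed R^2 is >= ``target``. If none qualifies the connectivity
    distribution is simply not scale-free at any strength; the fit profile
    is then a flat noisy plateau on which an argmax would be an arbitrary
    draw, so instead the conventional sample-size-based default power
    (:func:`fallback_power`, clipped to the scanned list) is returned with
    a logged warning.
    """
    if expr_values.shape[0] < 10:
        raise ConfigError("pick_soft_power requires at least 10 metacells")
    powers = sorted(powers)
    corr = correlation_matrix(expr_values, gene_ids)
    for p in powers:
        net = adjacency(expr_values, gene_ids, power=p, mode=mode, corr=corr)
        fit = scale_free_fit(net)
        if fit >= target:
            return p
    fb = min(max(fallback_power(expr_values.shape[0], mode), powers[0]), powers[-1])
    log.warning(
        "no power in %s reached scale-free fit %.2f; using the sample-size "
        "default power %d", list(powers), target, fb,
    )
    return fb


def tom(adj: GeneNetwork) -> GeneNetwork:
    """Topological overlap matrix of an adjacency network.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k the connectivity (row sums excluding the diagonal) and the
    shared-neighbour sum likewise excluding i and j themselves; diagonal 1.
    """
    if adj.kind != "adjacency":
        raise ConfigError("tom expects an adjacency network")
    a = adj.weights.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(w, 1.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return GeneNetwork(gene_ids=list(adj.gene_ids), weights=w, kind="tom", power=adj.power)


#: strict-cut height as a fraction of the background (median) 1 - TOM level
DEFAULT_CUT_FRACTION = 0.9
#: merge/attach ceiling as a fraction of the background level
DEFAULT_ATTACH_FRACTION = 0.88
#: smallest strict-cut cluster kept as a module core
DEFAULT_MIN_CORE_SIZE = 4


def detect_modules(
    network: GeneNetwork,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
    attach_fraction: float = DEFAULT_ATTACH_FRACTION,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
) -> dict[str, str]:
    """Detect modules from a TOM network; returns gene -> module label.

    Three deterministic stages, all thresholds relative to the background
    dissimilarity level (the median off-diagonal 1 - TOM; unrelated pairs
    dominate the matrix, so the median is a robust background estimate):

    1. *cores* — the average-linkage dendrogram of 1 - TOM is cut at
       ``cut_fraction`` x background (or the absolute ``cut_height`` when
       given); clusters of at least ``min_core_size`` genes become cores;
    2. *merge* — cores whose average inter-core dissimilarity is below
       ``attach_fraction`` x background are merged (closest pair first),
       repairing blocks the strict cut split;
    3. *attach* — every remaining gene joins its nearest core if its mean
       dissimilarity to that core is below ``attach_fraction`` x
       background, recovering the looser members of a block.

    Modules smaller than ``min_module_size`` after attachment are labelled
    "unassigned". Labels are deterministic: modules ordered by decreasing
    size, ties by lexicographically smallest member, named "M1", "M2", ...

    Relative thresholds are used because the dissimilarity scale moves with
    the soft power: under a signed adjacency the baseline overlap of
    unrelated genes is near (1/2)**beta rather than 0, so no absolute
    height separates co-expressed blocks from background across the powers
    the scale-free rule can select. The core/attach split mirrors the
    usual dynamic-cut-plus-PAM practice while staying fully specified:
    tight cores are found well below background, and block members too
    noisy for the strict cut are recovered by the attachment stage, which
    background genes (sitting at the background level by definition) fail.
    """
    if not 0 < cut_fraction < 1 or not 0 < attach_fraction < 1:
        raise ConfigError("cut_fraction and attach_fraction must be in (0, 1)")
    if min_core_size < 2:
        raise ConfigError("min_core_size must be >= 2")
    dist = 1.0 - network.weights
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(dist, checks=False)
    background = float(np.median(condensed)) if condensed.size else 0.0
    link = sch.linkage(condensed, method="average")
    cut = cut_height if cut_height is not None else cut_fraction * background
    attach_limit = attach_fraction * background if cut_height is None else cut_height
    raw = sch.fcluster(link, t=cut, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for gene, c in zip(network.gene_ids, raw):
        clusters.setdefault(int(c), []).append(gene)
    cores = [sorted(genes) for genes in clusters.values() if len(genes) >= min_core_size]
    cores.sort(key=lambda genes: (-len(genes), genes[0]))

    gene_pos = {g: i for i, g in enumerate(network.gene_ids)}

    def avg_dissim(genes_a: list[str], genes_b: list[str]) -> float:
        block = dist[np.ix_([gene_pos[g] for g in genes_a], [gene_pos[g] for g in genes_b])]
        return float(block.mean())

    # merge closest core pair while below the attach ceiling
    while len(cores) > 1:
        best = None
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                d_ij = avg_dissim(cores[i], cores[j])
                if best is None or d_ij < best[0]:
                    best = (d_ij, i, j)
        if best is None or best[0] >= attach_limit:
            break
        _, i, j = best
        merged = sorted(cores[i] + cores[j])
        cores = [c for idx, c in enumerate(cores) if idx not in (i, j)]
        cores.append(merged)
        cores.sort(key=lambda genes: (-len(genes), genes[0]))

    # attach leftover genes to their nearest core (decisions vs. the cores
    # as merged above, not vs. earlier attachments: order-independent)
    in_core = {g for core in cores for g in core}
    attachments: dict[int, list[str]] = {i: [] for i in range(len(cores))}
    for g in network.gene_ids:
        if g in in_core or not cores:
            continue
        dists = [avg_dissim([g], core) for core in cores]
        best_i = int(np.argmin(dists))
        if dists[best_i] < attach_limit:
            attachments[best_i].append(g)

    modules = [sorted(core + attachments[i]) for i, core in enumerate(cores)]
    kept = [m for m in modules if len(m) >= min_module_size]
    kept.sort(key=lambda genes: (-len(genes), genes[0]))
    labels = {g: UNASSIGNED for g in network.gene_ids}
    for i, genes in enumerate(kept, start=1):
        for g in genes:
            labels[g] = f"M{i}"
    return labels


def module_eigengene(
    expr_values: np.ndarray,
    gene_ids: list[str],
    module_genes: list[str],
    extra_genes: list[str] | None = None,
) -> EigengeneSet:
    """First-PC eigengene of a module and eigengene connectivity (kME).

    The eigengene is the unit-norm first principal component of the
    gene-standardised module submatrix over metacells, oriented to correlate
    positively with the mean module expression. kME(g) = Pearson r between a
    gene's expression and the eigengene, computed for module members plus any
    ``extra_genes``.
    """
    if len(module_genes) < 2:
        raise ConfigError("a module needs at least 2 genes")
    if expr_values.shape[0] < 3:
        raise ConfigError("module_eigengene requires at least 3 metacells")
    idx = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in module_genes if g not in idx]
    if missing:
        raise DataError(f"module gene(s) absent from expression: {missing[:5]}")
    sub = np.asarray(expr_values, dtype=float)[:, [idx[g] for g in module_genes]]
    sd = sub.std(axis=0)
    if np.all(sd == 0):
        raise DataError("degenerate module: all member genes constant")
    z = np.zeros_like(sub)
    nz = sd > 0
    z[:, nz] = (sub[:, nz] - sub[:, nz].mean(axis=0)) / sd[nz]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigengene = u[:, 0]
    mean_expr = sub.mean(axis=1)
    if np.ptp(mean_expr) > 0 and np.corrcoef(eigengene, mean_expr)[0, 1] < 0:
        eigengene = -eigengene
    norm = np.linalg.norm(eigengene)
    eigengene = eigengene / norm
    kme: dict[str, float] = {}
    for g in list(module_genes) + list(extra_genes or []):
        col = np.asarray(expr_values, dtype=float)[:, idx[g]]
        kme[g] = float("nan") if np.ptp(col) == 0 else pearson_r(col, eigengene)
    return EigengeneSet(module_label="", eigengene=eigengene, kme=kme)
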