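"""Synthetic expression data with planted co-regulation.

Two generators stand in for the public expression compendia the screen was
designed around, so every downstream stage can be exercised against a known
ground truth:

* :func:`gen_bulk` emulates a multi-sample bulk panel (the anatomy /
  development / cell-line compendium structure): a reference gene, its
  obligate partner (the two collagen IV subunits in the motivating screen)
  and one true candidate share a latent log-normal sample profile, while
  decoy candidates get independent profiles.

* :func:`gen_sc` emulates sparse overdispersed single-nucleus counts
  structured into cell-type groups. Within each group a handful of gene
  modules is planted: module members share a per-cell log-normal activity,
  counts are negative binomial (gamma-Poisson) around cell-size-scaled
  means. The anchor pair always occupies the first planted module; the
  candidate joins it in a configurable subset of groups and sits in a
  different module elsewhere. No explicit zero inflation is simulated —
  sparsity arises from low means, the standard snRNA-seq noise model.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ConfigError, SingleCellCounts, UNASSIGNED

__all__ = ["BulkSimConfig", "ScSimConfig", "SimTruth", "gen_bulk", "gen_sc"]


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    #: per group: gene -> planted module label ("unassigned" for background)
    module_map: dict[str, dict[str, str]] = field(default_factory=dict)
    #: groups in which the candidate shares the anchor module
    coocc_groups: list[str] = field(default_factory=list)
    #: planted co-assignment count (number of coocc_groups)
    s_true: int = 0
    #: per-gene qualitative correlation target with the reference (bulk only)
    correlation_targets: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bulk


@dataclass
class BulkSimConfig:
    """Configuration for the bulk-panel generator.

    ``n_decoys`` defaults to 25, emulating a 26-candidate screen with one
    true co-regulated gene. ``shared_profile_sd`` is the sd of the latent
    log-expression profile across samples; ``noise_sd`` the per-gene
    log-normal noise around it. The partner gene gets its own (smaller)
    noise so it tracks the reference nearly identically, as the second
    collagen IV subunit does in the real compendia.
    """

    n_samples: int = 25
    n_decoys: int = 25
    reference_gene: str = "Col4a1"
    partner_gene: str = "vkg"
    true_candidate: str = "PH4aEFB"
    shared_profile_sd: float = 1.0
    noise_sd: float = 0.3
    partner_noise_sd: float = 0.05
    base_level: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3")
        if self.n_decoys < 1:
            raise ConfigError("n_decoys must be >= 1")
        for name in ("shared_profile_sd", "noise_sd", "partner_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        ids = {self.reference_gene, self.partner_gene, self.true_candidate}
        if len(ids) != 3:
            raise ConfigError("reference, partner and candidate ids must be distinct")


def gen_bulk(config: BulkSimConfig):
    """Generate a bulk panel with one planted co-regulated candidate.

    Returns ``(BulkExpressionTable, SimTruth)``. The reference, partner and
    true candidate share one latent sample profile (log-normal) plus
    independent noise; each decoy follows an independent profile of the same
    magnitude.
    """
    from .io import BulkExpressionTable  # local import avoids cycle at module load

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    shared = rng.normal(0.0, config.shared_profile_sd, size=n)

    def expressed(profile: np.ndarray, noise_sd: float) -> np.ndarray:
        return config.base_level * np.exp(profile + rng.normal(0.0, noise_sd, size=n))

    gene_ids = [config.reference_gene, config.partner_gene, config.true_candidate]
    rows = [
        expressed(shared, config.noise_sd),
        expressed(shared, config.partner_noise_sd),
        expressed(shared, config.noise_sd),
    ]
    targets = {config.reference_gene: 1.0, config.partner_gene: 1.0, config.true_candidate: 1.0}
    width = len(str(config.n_decoys))
    for i in range(config.n_decoys):
        g = f"decoy_{i + 1:0{width}d}"
        gene_ids.append(g)
        profile = rng.normal(0.0, config.shared_profile_sd, size=n)
        rows.append(expressed(profile, config.noise_sd))
        targets[g] = 0.0
    samples = [f"sample_{j + 1:02d}" for j in range(n)]
    table = BulkExpressionTable(gene_ids=gene_ids, sample_labels=samples, values=np.array(rows))
    truth = SimTruth(correlation_targets=targets)
    return table, truth


# ---------------------------------------------------------------------------
# single cell


@dataclass
class ScSimConfig:
    """Configuration for the single-cell count generator.

    ``module_effect`` is the sd of the per-cell log activity shared by the
    members of a planted module (0 = no co-expression signal, the null).
    ``nb_dispersion`` is the negative-binomial size parameter theta
    (variance = mu + mu^2 / theta). Library sizes are log-normal around
    ``libsize_mean`` so the detected-gene QC filter has realistic tails to
    act on.
    """

    n_groups: int = 8
    cells_per_group: int = 500
    n_genes: int = 300
    n_modules_per_group: int = 3
    module_size: int = 10
    anchor_pair: tuple[str, str] = ("Col4a1", "vkg")
    candidate: str = "PH4aEFB"
    #: groups where the candidate is planted in the anchor module;
    #: None means the first 5 groups (or all groups if fewer).
    coocc_groups: list[str] | None = None
    libsize_mean: float = 600.0
    libsize_sd: float = 0.35
    nb_dispersion: float = 2.0
    module_effect: float = 1.0
    baseline_sd: float = 0.5
    seed: int = 0

    def group_names(self) -> list[str]:
        return [f"celltype_{i + 1}" for i in range(self.n_groups)]

    def resolved_coocc_groups(self) -> list[str]:
        if self.coocc_groups is None:
            return self.group_names()[: min(5, self.n_groups)]
        return list(self.coocc_groups)

    def validate(self) -> None:
        if self.n_groups < 1 or self.cells_per_group < 1:
            raise ConfigError("n_groups and cells_per_group must be positive")
        if self.module_size < 3:
            raise ConfigError("module_size must be >= 3")
        if self.n_modules_per_group < 2:
            raise ConfigError("n_modules_per_group must be >= 2")
        if self.n_modules_per_group * self.module_size > self.n_genes:
            raise ConfigError(
                "module assignments exceed n_genes: "
                f"{self.n_modules_per_group} x {self.module_size} > {self.n_genes}"
            )
        if self.module_effect < 0:
            raise ConfigError("module_effect must be >= 0")
        if self.nb_dispersion <= 0 or self.libsize_mean <= 0 or self.libsize_sd <= 0:
            raise ConfigError("nb_dispersion, libsize_mean and libsize_sd must be > 0")
        unknown = set(self.resolved_coocc_groups()) - set(self.group_names())
        if unknown:
            raise ConfigError(f"coocc_groups not a subset of groups: {sorted(unknown)}")
        a1, a2 = self.anchor_pair
        if len({a1, a2, self.candidate}) != 3:
            raise ConfigError("anchor pair and candidate ids must be distinct")


def _plant_modules(config: ScSimConfig, rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """Draw module memberships honouring the co-occurrence plan.

    Module compositions are shared across groups — co-expression modules
    keep their membership between cell types, as tissue programmes (e.g. an
    extracellular-matrix module) largely do — while module *activities* are
    drawn per cell and the candidate's membership varies by group: it sits
    in the anchor module in exactly ``coocc_groups`` and in the second
    module elsewhere.
    """
    a1, a2 = config.anchor_pair
    specials = [a1, a2, config.candidate]
    background = [f"gene_{i + 1:04d}" for i in range(config.n_genes - len(specials))]
    coocc = set(config.resolved_coocc_groups())

    pool = list(background)
    fixed_members: list[list[str]] = []
    for m in range(config.n_modules_per_group):
        # the anchors fill two slots of module 1; the mobile candidate is
        # always an extra member so no module ever falls below module_size
        n_fill = config.module_size - (2 if m == 0 else 0)
        idx = rng.choice(len(pool), size=n_fill, replace=False)
        fixed_members.append([pool[i] for i in sorted(idx)])
        for i in sorted(idx, reverse=True):
            pool.pop(i)
    fixed_members[0] = [a1, a2] + fixed_members[0]

    module_map: dict[str, dict[str, str]] = {}
    for g in config.group_names():
        assignment = {gene: UNASSIGNED for gene in specials + background}
        for m, members in enumerate(fixed_members):
            label = f"planted_{m + 1}"
            for gene in members:
                assignment[gene] = label
        assignment[config.candidate] = "planted_1" if g in coocc else "planted_2"
        module_map[g] = assignment
    return module_map


def gen_sc(config: ScSimConfig):
    """Generate grouped sparse NB counts with planted co-expression modules.

    Returns ``(SingleCellCounts, SimTruth)``. Per group, each planted module
    m carries a per-cell latent activity z ~ Normal(0, module_effect); member
    genes' means are the baseline times exp(z) (mean-corrected so module
    membership does not inflate average expression), scaled by a log-normal
    per-cell library size; counts are negative binomial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    module_map = _plant_modules(config, rng)
    a1, a2 = config.anchor_pair
    gene_ids = [a1, a2, config.candidate] + [
        f"gene_{i + 1:04d}" for i in range(config.n_genes - 3)
    ]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # global per-gene relative abundance
    w = np.exp(rng.normal(0.0, config.baseline_sd, size=config.n_genes))
    p_gene = w / w.sum()

    theta = config.nb_dispersion
    blocks: list[sp.csr_matrix] = []
    cell_ids: list[str] = []
    group_of: dict[str, str] = {}
    for g in config.group_names():
        nc = config.cells_per_group
        libsize = np.exp(
            rng.normal(np.log(config.libsize_mean), config.libsize_sd, size=nc)
        )
        mu = libsize[:, None] * p_gene[None, :]
        if config.module_effect > 0:
            labels = module_map[g]
            for m in range(config.n_modules_per_group):
                label = f"planted_{m + 1}"
                member_idx = [gene_index[x] for x, l in labels.items() if l == label]
                z = rng.normal(0.0, config.module_effect, size=nc)
                factor = np.exp(z - 0.5 * config.module_effect**2)
                mu[:, member_idx] *= factor[:, None]
        counts = rng.negative_binomial(theta, theta / (theta + mu))
        blocks.append(sp.csr_matrix(counts))
        ids = [f"{g}_cell_{i + 1:04d}" for i in range(nc)]
        cell_ids += ids
        group_of.update({c: g for c in ids})

    counts = sp.vstack(blocks, format="csr")
    sc = SingleCellCounts(
        cell_ids=cell_ids, gene_ids=gene_ids, counts=counts, group_of=group_of
    )
    coocc = config.resolved_coocc_groups()
    truth = SimTruth(module_map=module_map, coocc_groups=coocc, s_true=len(coocc))
    return sc, truth
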