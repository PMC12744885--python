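# Methods

## Overview

`coexscreen` asks whether a candidate gene is co-regulated with a reference
gene (or an anchor pair) at two resolutions: across bulk expression
compendia, and across cell types within single-cell data. The bulk branch
is a straightforward correlation ranking; the single-cell branch builds
weighted co-expression networks on metacell-aggregated counts and tests how
often the candidate lands in the same module as the anchors. This note
documents the models, the defaults and their rationale, the deterministic
numerical choices, and what the synthetic benchmark does and does not show.

## Bulk screen

Candidates are ranked by the sample Pearson correlation with the reference
gene's expression row. Correlations are computed on raw platform values
(microarray intensity or RPKM); since Pearson *r* is invariant to positive
per-gene rescaling this equals correlating the max-normalised rows used for
display. Genes with constant rows have no defined correlation and are
reported as NA and ranked last — never silently as 0. Ranking ties break
alphabetically by gene id. `sort_by_peak` orders genes by the sample index
of their row maximum (first maximum wins; the sort is stable so ties keep
input order). `coexpression_presence` calls a gene "visibly expressed" in a
sample when its max-normalised value exceeds a threshold, default 0.05 of
its own maximum: visibility in a brightness-coded image is the implied
criterion and no sharper number is canonical, so the threshold is exposed
as a parameter.

## Single-cell screen

### Preprocessing

Fixed order: detected-gene QC → library-size log-normalisation → HVG
selection → per-gene z-scaling (clip ±10) → PCA. All stages are
deterministic.

* **QC**: keep cells with a detected-gene count inside
  `[min_genes, max_genes]`. There is no default ceiling — the right value
  is tissue-specific (2000–3500 for whole-tissue atlases) and must be
  stated per run. The synthetic study, with its 300-gene panel, uses
  [100, 280].
* **Normalisation**: `ln(1 + 10^4 · count / cell_total)` (natural log).
  Zeros map to zeros; a cell's vector is invariant to depth.
* **HVG statistic**: variance of log-normalised expression standardised by
  a mean–variance trend (rolling median over mean-ordered genes, window
  51); a raw-variance alternative is available by flag. HVGs define the
  scaling/PCA geometry only.
* **Gene universe for networks**: genes detected in ≥ 5 % of cells
  (inclusive). Restricting the *analysis* universe to HVGs would silently
  drop candidates or anchors whose variance statistic happens to fall at
  the selection boundary, so feature selection is kept where it belongs —
  the neighbourhood geometry — and the co-expression analysis covers every
  adequately detected gene.
* **PCA**: full SVD, components sign-fixed so the largest-magnitude
  loading is positive (deterministic across solvers).

### Metacells

Within each annotated group, seed cells are drawn without replacement by a
seeded RNG; the seed's k nearest neighbours (Euclidean in the PCA space,
self included) form a candidate metacell, accepted iff its overlap with
every accepted metacell of that group is ≤ `max_shared`. Defaults k = 25,
max_shared = 10. `target_per_group` defaults to
`floor(group_size / (k − max_shared))`, a feasibility-motivated cap;
`max_attempts` to 5× the group size. Groups with fewer than k cells are
skipped with a warning. Metacell expression is the mean of member raw
counts, then library-size normalised and log1p-transformed exactly like
single cells.

A known caveat of KNN aggregation: any direction used for neighbour
selection becomes *real* variation at the metacell level, so noise
dimensions retained in the reduced space are partially reified as spurious
metacell-level correlation. Two defaults mitigate this on the synthetic
panel: HVG count 100 (of 300) and 10 PCs, so the selection geometry is
dominated by the planted activity directions rather than by accumulated
noise axes. The conventional 2000 HVGs / 50 PCs presume whole-transcriptome
data with far richer structure; on a 300-gene panel they would be almost
entirely noise axes. These two are therefore configuration, not constants.

### Networks and modules

Per group, on the group's metacells and the universe genes that vary there:

* **Signed adjacency** `a_ij = ((1 + r_ij)/2)^β` (unsigned `|r|^β` by
  flag); constant genes are an error upstream, not a silent 0.
* **Soft power**: lowest β in 1..30 whose connectivity distribution reaches
  a signed scale-free fit R² ≥ 0.8 (log-binned connectivity vs frequency,
  10 bins, least squares; R² negated for a positive slope; degenerate fits
  return 0 with a warning). When no power qualifies, the connectivity
  distribution is simply not scale-free at any strength and the fit profile
  is a flat noisy plateau whose argmax is an arbitrary draw; the fallback is
  instead the conventional sample-size-based default power for signed
  networks (18 below 20 samples, 16 for 20–30, 14 for 30–40, 12 above),
  clipped to the scanned list.
* **TOM**: `ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  diagonal 1; 1 − ω is the clustering dissimilarity.
* **Module detection** is a three-stage deterministic procedure mirroring
  dynamic-cut-plus-PAM practice while remaining fully specified. All
  thresholds are relative to the *background level*, the median
  off-diagonal 1 − TOM (unrelated pairs dominate the matrix, making the
  median a robust background estimate). (1) *Cores*: the average-linkage
  dendrogram is cut at 0.9 × background; clusters of ≥ 4 genes become
  cores. (2) *Merge*: cores whose average inter-core dissimilarity is
  below 0.88 × background merge, closest pair first. (3) *Attach*: every
  remaining gene joins its nearest core if its mean dissimilarity to it is
  below 0.88 × background; attachment decisions are taken against the
  merged cores, not against earlier attachments, so the result is
  independent of gene order. Modules below `min_module_size` (default 10)
  after attachment are labelled "unassigned". Labels are canonical: by
  decreasing size, ties by smallest member id, named M1, M2, …

  Relative thresholds are necessary because the dissimilarity scale moves
  with β: a signed adjacency maps r = 0 to (1/2)^β, so the background
  level of 1 − TOM depends on β and no absolute cut height separates
  co-expressed blocks from background across the powers the scale-free
  rule can select. The core/attach fractions were placed inside the wide
  empirical gap between block cohesion (core members sit well below
  0.85 × background) and the background's lower tail (above
  0.95 × background) observed on pilot simulations across that power
  range; an absolute `cut_height` override remains available.
* **Eigengenes**: the unit-norm first principal component of the
  gene-standardised module submatrix, oriented to correlate non-negatively
  with mean module expression; kME(g) is the Pearson correlation of gene g
  with the eigengene.

### Co-assignment statistic and its null

T is the number of groups whose partition places both anchors in one
non-"unassigned" module; S is the number of those groups where the
candidate carries that same label. Significance is a Monte Carlo
permutation test, B = 10,000 replicates: per group, the module labels of
all non-anchor genes are permuted uniformly (module sizes preserved,
anchors held fixed), one candidate is drawn uniformly per replicate, and
p = #{S_null ≥ S_emp}/B. Anchors are conditioned on rather than permuted:
the tested hypothesis is where the *candidate* falls given the observed
anchor modules, this matches a fixed denominator T, and it admits an exact
oracle — a random non-anchor gene lands in group g's anchor module with
probability `q_g = (|M_g| − 2)/(N_g − 2)`, making S_null Poisson-binomial
across groups; `exact_tail` evaluates `P(S_null ≥ s)` by dynamic
programming (convolution over groups). The unconditioned variant (anchors
permuted too, anchor modules recomputed per replicate) is available behind
a flag, Monte Carlo only. p is reported without the +1 correction, matching
the plain proportion definition; zero exceedances are reported as "< 1/B"
with the value floored at 1/B, so a p-value of exactly 0 is never claimed.
"Unassigned" genes participate in the permutation as a module-sized block;
a draw landing there never matches. Groups where the candidate was not
analysed contribute no match.

## Synthetic data

`gen_bulk` draws one latent log-profile per sample (sd 1.0); the reference,
partner and true candidate are `base · exp(profile + ε)` with independent
log-normal noise (sd 0.3; the partner uses 0.05 so it tracks the reference
nearly identically, the behaviour of the second collagen IV chain in the
real compendia), and each of the 25 decoys follows an independent profile
of the same magnitude. Defaults: 25 samples, 26 candidates of which one is
truly co-regulated.

`gen_sc` emulates sparse overdispersed single-nucleus counts: 8 cell-type
groups × 500 cells × 300 genes. Per group, each of 3 planted modules
(≥ 10 members) carries a per-cell latent activity z ~ N(0, module_effect²),
default module_effect 1.0; member-gene means are multiplied by
`exp(z − module_effect²/2)` (mean-corrected so membership does not inflate
average expression). Counts are negative binomial (gamma-Poisson,
θ = 2.0 — a mid-range single-nucleus overdispersion; variance
μ + μ²/θ) around `libsize · p_gene`, with log-normal library sizes
(mean 600 counts for the 300-gene panel, i.e. ≈ 2 counts/gene, giving
realistic per-gene zero fractions; sd 0.35 in log so the QC filter has
tails to act on) and log-normal relative gene abundances (sd 0.5). Module
*composition* is shared across groups — tissue programmes largely keep
their membership between cell types — while activities are per-cell and
the candidate's membership varies: it sits in the anchor module in exactly
the configured co-occurrence groups (default 5 of 8) and in the second
module elsewhere. One gene belongs to at most one module per group, so the
planted co-assignment count is unambiguous. No batch effects, doublets,
ambient RNA or explicit zero inflation are emulated — sparsity arises from
low means. Consequently, passing the planted-truth benchmark shows the
pipeline's machinery is correct and calibrated under its own model
assumptions; it does not certify performance on real tissue atlases, where
ambient contamination, nested subtypes and annotation errors add failure
modes this generator does not produce.

## Problem sizes

The default synthetic study (4000 cells, 300 genes, ~33 metacells per
group, B = 10,000) runs the full single-cell screen in roughly two seconds;
the null-calibration study repeats it over 50 seeds and the bulk ranking
study over 100 seeds. These sizes keep the whole benchmark suite and the
reproduction script within a couple of minutes on one CPU while leaving
every statistic measurable at useful precision (Monte Carlo error of p at
B = 10,000 is ≤ 0.005; 50 null runs bound the false-positive rate check at
its binomial tolerance).

## Known limitations

* The static module detector has no per-branch adaptivity; nested or
  strongly unequal-density modules may be merged or truncated where a true
  dynamic cut would split them.
* The scale-free fallback power is a convention, not an inference; on data
  that genuinely is scale-free just beyond the scanned list the clip to
  the list boundary is arbitrary.
* The exact oracle exists only for the anchor-conditioned null. The
  unconditioned variant is Monte Carlo only.
* Loom/H5AD ingestion is out of scope. Convert with scanpy/anndata:
  read the file, write `matrix.mtx` (cells × genes), `features.tsv`,
  `barcodes.tsv` and an `annotations.tsv` with columns `cell_id`, `group`
  — the directory layout `read_sparse_counts` consumes.
* Probeset-to-gene mapping for microarray tables is not performed;
  duplicated gene rows are an error, never silently aggregated.
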