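# coexscreen

Candidate-gene co-expression screening for transcriptomics: which of a set
of candidate genes is co-regulated with a reference gene (pair)?

The motivating problem comes from *Drosophila* collagen biology. Collagen IV
is built from two α chains, encoded by *Col4a1* and *viking* (*vkg*), which
are tightly co-expressed. Collagen needs intracellular prolyl 4-hydroxylation,
yet the fly genome carries 26 candidate prolyl-4-hydroxylase α-subunit genes
— the enzyme actually working on collagen IV must be *co-expressed with it in
the same cells*. `coexscreen` implements that screening logic as a reusable,
tested pipeline:

1. **Bulk compendium screen** — given a genes × samples expression table
   (microarray intensities or RPKM), rank every candidate by its Pearson
   correlation *r* with the reference gene across samples; order genes by
   expression-peak timing; export per-gene max-normalised matrices as plain
   "text images" for brightness-coded display.
2. **Metacell single-cell screen** — QC (detected-gene window), library-size
   log-normalisation, highly-variable-gene selection, PCA; aggregation of
   k-nearest-neighbour cells into *metacells* per annotated cell type
   (k = 25, pairwise membership overlap ≤ 10) to reduce count sparsity;
   per-cell-type weighted gene co-expression networks — signed adjacency
   `a_ij = ((1 + r_ij)/2)^β` with the soft power β chosen as the lowest
   value reaching a 0.8 scale-free topology fit, topological overlap (TOM),
   average-linkage module detection, module eigengenes and kME.
3. **Co-assignment statistic** — S = the number of cell types in which the
   candidate occupies the same module as *both* anchor genes, tested by a
   Monte Carlo permutation of module assignments (10,000 replicates,
   anchors held fixed) and cross-checked against the exact Poisson-binomial
   tail `P(S_null ≥ S_emp)` with per-type success probability
   `q_g = (|M_g| − 2)/(N_g − 2)`.

A synthetic-data module generates both kinds of input with *planted* ground
truth (a latent shared profile in the bulk panel; negative-binomial counts
with planted gene modules and a configurable candidate/anchor co-occurrence
pattern in the single-cell data), so every stage of the pipeline is testable
end to end without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data:

```sh
python analysis/01_simulate_data.py --seed 1     # writes results/data/
python analysis/02_bulk_screen.py
python analysis/03_sc_screen.py --seed 1
python analysis/04_null_calibration.py --seed 1
```

Script 02 prints (seed 1):

```
partner control: r(Col4a1, vkg) = 0.871
top candidate: PH4aEFB with r = 0.757 (next: decoy_04 at r = 0.439)
PH4aEFB visible in 24 of the 24 samples expressing Col4a1
```

The partner gene (the second collagen IV chain, sharing the same latent
profile with little noise) behaves as the positive control; the planted
candidate clearly tops the 26-candidate ranking while the best decoy trails
far behind. Script 03 prints, for the single-cell branch:

```
co-assignment: PH4aEFB shares the anchor module in 5 of 8 cell types;
p = < 0.0001 (Monte Carlo, B=10000), exact tail = 1.2e-06
module recovery ARI celltype_1: 0.961   ... celltype_8: 1.000
```

i.e. the screen recovers the planted co-occurrence (candidate planted with
the anchors in 5 of 8 cell types) and the planted modules themselves
(adjusted Rand index ≥ 0.94 per cell type), and the Monte Carlo p-value
agrees with the exact oracle. Script 04 verifies that with no planted
effect the screen claims significance in 0 of 50 runs.

The same stages are exposed as a CLI (`coexscreen simulate-bulk | bulk |
sc-preprocess | metacells | network | permtest | screen`) operating purely
on plain-text files (TSV, Matrix-Market, text images), and as a library
(`import coexscreen`).

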