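# Methods

`lrcrosstalk` analyses a four-group co-culture transcriptome design: two
cell populations — intramuscular preadipocytes (IMAdC) and skeletal muscle
satellite cells (SMSC) — each profiled in monoculture and in transwell
co-culture, with three biological replicates per group.  Three two-group
contrasts structure everything downstream:

| contrast | numerator | denominator |
|---|---|---|
| `IMAdC_mono_vs_co` | IMAdC monoculture | IMAdC co-culture |
| `CO_IMAdC_vs_CO_SMSC` | IMAdC co-culture | SMSC co-culture |
| `SMSC_mono_vs_co` | SMSC monoculture | SMSC co-culture |

The first-listed group is always the log2 fold-change numerator, so "UP" in
a mono-vs-co contrast means *higher in monoculture*.  This orientation is
fixed throughout and stamped into every output table.

## Normalization and QC

Expression is normalized to FPKM, `FPKM_gj = c_gj / ((L_g/10^3)(N_j/10^6))`
with `L_g` the transcript length in bp and `N_j` the column sum of the
count matrix, then transformed as `log10(FPKM + 1)` for all sample-level
summaries.  QC computes the sample-sample Pearson correlation matrix over
genes, a PCA with samples as observations (gene-centered, unscaled — the
common convention for replicate-consistency plots; gene scaling is not
applied), and average-linkage hierarchical clustering on `1 − r` distance.
Average linkage on correlation distance is a deliberate default recorded in
the output metadata; nothing downstream depends on the linkage choice.

Two closed-form lab utilities ride along: Phred quality
`Q = −10·log10(e)` for a base-call error probability `e`, and relative
qPCR expression `2^−ΔΔCt`.

## Differential expression

The count model is the standard bulk RNA-seq negative binomial:
`K_gj ~ NB(mean s_j·q_gj, var μ + α_g μ²)`.

* **Size factors** are median-of-ratios: for each sample, the median over
  all-positive genes of the count divided by the gene's geometric-mean
  reference, rescaled so the factors' geometric mean is 1.
* **Dispersion** is method-of-moments on normalized counts,
  `α̂_g = max(α_floor, (v_g − m_g)/m_g²)` with `v_g` the pooled
  within-group variance (all four design groups) and `m_g` the overall
  mean, then shrunk halfway toward a lowess mean-dispersion trend fitted on
  `log10 m_g` (frac 0.5).  `α_floor = 1e−8`; degenerate genes (zero mean or
  variance) sit at the floor.  With 12 samples and 4 groups the raw
  estimator has 8 df and is noisy; the halfway trend shrinkage is a
  deliberate compromise between per-gene fidelity and stability.  It is
  weaker than an empirical-Bayes shrinkage, so individual `α̂_g` can still
  be several-fold off at this replicate count.
* **Wald test**: `log2FC = log2(m̄_1/m̄_2)` on normalized group means; a
  pseudocount of 0.5 is added to *both* means only when either falls below
  0.5, keeping fold changes finite near zero without biasing expressed
  genes.  The SE comes from the delta method,
  `Var(log2 m̄) = Var(m̄)/(m̄ ln 2)²` with
  `Var(m̄) = n⁻² Σ_j (μ/s_j + α μ²)`; `z = log2FC/SE` is referred to the
  standard normal two-sided, and p-values are Benjamini–Hochberg adjusted
  across genes.
* **DEG status** uses strict thresholds: `|log2FC| > 1` *and* adjusted
  `p < 0.05`.  A gene at exactly log2FC 1.0 is not significant.  A flag
  switches the threshold to the raw p-value for users who read the
  screening rule that way; adjusted-p gating is the default.
* Genes with fewer than 10 total counts are removed before dispersion
  estimation; they cannot be called differential and destabilize the
  moment estimator.  The surviving genes define the enrichment universe.

On simulated data this estimator tracks DESeq2 closely (log2FC correlation
> 0.99, call agreement ~0.99 on a 300-gene check), but it is deliberately
its own implementation: agreement with any external tool's exact DEG
counts is not a goal.

Across ≥ 2 contrasts, genes are partitioned by overlap: UP if called up in
at least one contrast and never down, DOWN symmetrically, CONFLICT if
called in both directions, NS otherwise; per-Venn-region counts accompany
the partition.

## Over-representation

Classic hypergeometric ORA: for each gene set, `p = P(X ≥ k)` with
`X ~ Hypergeometric(N, K, n)` — `N` universe genes, `K` of them in the
set, `n` DEGs, `k` hits.  Sets are intersected with the universe first; BH
correction runs across all tested sets; significance is adjusted
`p < 0.05`.  Up- and down-regulated DEG lists are tested separately, each
with its own BH family.  Only over-representation (upper tail) is tested.
The universe is the expressed-gene universe, not the full annotation.

## Network hubs and modules

The interaction network is user-supplied (any undirected edge list; edge
confidence weights in [0,1] are honored when present).  The DEG-induced
subgraph is taken, hubs are ranked purely by degree (ties broken
alphabetically, so rankings are order-independent), and modules come from
spectral k-means: the k eigenvectors of the symmetric normalized Laplacian
`L = I − D^{−1/2} A D^{−1/2}` with smallest eigenvalues, rows normalized to
unit length, clustered by k-means with `n_init = 20` and a fixed seed.
`k = 3` by default — the number of subnetworks the study design reports per
DEG direction.  Isolated nodes carry no spectral information and are
excluded from clustering and listed separately.  On disconnected graphs the
0-eigenspace encodes the components exactly, so k components at `k`
clusters are recovered perfectly.

## Ligand–receptor crosstalk

The pairing universe is a curated ligand→receptor database (CellTalkDB
dialect, human symbols).  Symbols are uppercased at ingestion and matched
to the data at symbol level — the implicit orthology convention when a
human database is applied to livestock data; supply an orthology-mapped
database if symbol identity is too coarse.

Candidates are DEGs (UP or DOWN) of a contrast that appear as ligands or
receptors in the database.  Pairs are formed under explicit
`DirectionRule`s; the eight defaults cover two methods × two modes:

* **Method 1** (mono-vs-co contrasts): autocrine pairs take ligand and
  receptor from the same cell type's own contrast with no direction
  constraint; paracrine pairs take ligands UP in the source cell's
  contrast and receptors DOWN in the target cell's contrast.
* **Method 2** (co-vs-co contrast): direction encodes the expressing cell
  (UP = higher in co-cultured IMAdCs, DOWN = higher in co-cultured SMSCs).
  Autocrine IMAdC pairs require UP+UP, autocrine SMSC pairs DOWN+DOWN;
  paracrine SMSC→IMAdC pairs require ligand DOWN + receptor UP, and the
  mirrored rule for IMAdC→SMSC.

The method-1 paracrine direction rule implies the ligand is higher in the
*monoculture* source cell, which reads counterintuitively for co-culture
signaling; it is implemented as specified and left user-overridable (rules
are plain data) rather than silently "corrected".

Each pair's **communication score** is the product of fold-change
magnitudes, `CS = 2^{|log2FC_L|} · 2^{|log2FC_R|}`.  Magnitudes — not
signed fold changes — are used because a strongly downregulated member
would otherwise collapse the score toward zero and bury exactly the pairs
the direction rules select for; signed log2FCs are preserved in the output
for transparency.  Ranking is by CS descending within each
(mode, method, source, target) stratum, ties broken lexicographically by
(ligand, receptor); the tie rule is an artifact decision, as no convention
exists.  A soundness check (every emitted pair is in the database with
both members differentially expressed in the rule's contrasts) runs on
every invocation.

## Synthetic data

No expression data accompany the study design this package addresses, so
the generator is a first-class module.  It emulates:

* NB counts for the 2×2×3 design, mean `s_j·2^{baseline_g + offsets}`,
  variance `μ + αμ²` (dispersion constant or gamma-distributed per gene;
  below 1e−8 the Poisson limit is drawn directly);
* planted log2 fold changes per (gene, contrast), applied as a log2 offset
  to the contrast's numerator group — note that contrasts share groups, so
  an effect planted in the co-vs-co contrast (which raises the co-cultured
  IMAdC group) also shifts the IMAdC mono-vs-co comparison; this coupling
  is a property of the real design, not an artifact;
* LR scenarios: true pairs ride on planted DE genes satisfying a direction
  rule, decoys on genes with no planted effect;
* planted 3-block stochastic block-model networks and gene-set collections
  with one planted-enrichment set plus random null sets.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning, so a whole simulated study is bit-reproducible.

Defaults mirror the study scale: 2,000 genes, 4 groups × 3 replicates,
dispersion 0.1, log2-normal baseline (mean 6, sd 1.5), and an asymmetric
planted-DE design (100 effects in the IMAdC mono-vs-co contrast, 60 in
co-vs-co, 15 in SMSC mono-vs-co) echoing the asymmetry a co-culture
perturbation produces.  The generator does *not* model batch effects,
gene-gene correlation beyond the planted modules, library-preparation
artifacts, or read-level noise — so passing recovery tests demonstrates
correctness of the inference logic under the stated model, not robustness
to the full messiness of real RNA-seq.

The dedicated LR-recovery benchmark plants 60 effects among 300 genes at a
constant baseline of 2^9 counts: strongly expressed members make
detection essentially certain, so any recovery failure indicates a pairing
logic error rather than Wald sampling noise (power under marginal
conditions is measured separately by the DE recovery benchmark).

## Problem sizes and numerical choices

Simulation-based checks run at desk scale: 20 × 2,000 genes for null error
control, 1,000 genes with 200 planted effects for recovery, 45-node block
models for module recovery, 600-gene end-to-end runs for determinism.
These sizes were chosen so the full battery completes in a few minutes on
one core while keeping every Monte-Carlo margin wide.

Tolerances: BH and hypergeometric primitives are checked to 1e−12 against
exact oracles; PCA distance preservation to 1e−8; Monte-Carlo quantities
at 3σ-style margins.  Degenerate inputs (zero-variance samples, empty DEG
lists, fewer non-isolated nodes than k, missing contrasts) raise errors
that name the offender rather than propagating NaNs.

## Known limitations

* The NB Wald test has no covariate/batch terms, no LFC shrinkage, and no
  outlier replacement; it is anti-conservative at very low replicate
  counts, mitigated but not removed by the double (|log2FC|, padj)
  threshold.
* Symbol-level LR matching ignores orthology complexities
  (one-to-many mappings, renamed symbols).
* Module detection assumes assortative (block-diagonal) structure; the
  spectral embedding will not find disassortative roles.
* Printed whole-study outcome counts from any particular real dataset are
  release- and annotation-dependent and are not reproduction targets of
  the synthetic battery.
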