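# lrcrosstalk

Reusable analysis pipeline for **co-culture bulk RNA-seq** studies of two
interacting cell populations — built around the design in which
intramuscular preadipocytes (IMAdC) and skeletal muscle satellite cells
(SMSC) are each profiled in monoculture and in transwell co-culture
(three biological replicates per group).  It is aimed at researchers who
want the full chain from a count matrix to ranked ligand–receptor pairs as
an importable, testable library rather than a one-off script stack.

The pipeline covers:

* **QC / normalization** — FPKM, log10(FPKM+1), sample Pearson
  correlation, PCA, average-linkage hierarchical clustering.
* **Differential expression** — negative-binomial Wald test with
  median-of-ratios size factors and trend-shrunk moment dispersions;
  DEG status at |log2FC| > 1 and BH-adjusted p < 0.05; UP/DOWN/CONFLICT
  overlap partition across contrasts.
* **Over-representation** — exact hypergeometric tail tests of DEG lists
  against a GMT gene-set collection, BH-corrected per direction.
* **Network analysis** — DEG-induced subgraphs, degree hub ranking, and
  spectral k-means module detection (k = 3 by default).
* **Ligand–receptor crosstalk** — the core step: differentially expressed
  ligands and receptors are paired under explicit autocrine/paracrine
  direction rules by two methods (mono-vs-co contrasts; co-vs-co
  contrast) and ranked by the communication score

  $$\mathrm{CS} = 2^{|\log_2 FC_{\mathrm{ligand}}|}\cdot 2^{|\log_2 FC_{\mathrm{receptor}}|}.$$

* **Synthetic data** — a seeded generator of the whole four-group study
  (NB counts with planted log2 fold changes, LR databases with planted
  true pairs, block-model networks, gene sets) used for all recovery
  testing, since the pipeline's target studies rarely release raw data.

## Worked example

`examples/04_crosstalk.py` plants upregulated ligands in the SMSC
mono-vs-co contrast and downregulated receptors in the IMAdC mono-vs-co
contrast, builds an LR database of 3 true pairs plus 8 non-DE decoys, and
runs the full two-method inference:

```text
database: 11 pairs (3 true, rest decoys)
pairs emitted: 3

     mode  method source_cell target_cell ligand receptor    cs  rank
paracrine       1        SMSC       IMAdC   G010     G023 26.41     1
paracrine       1        SMSC       IMAdC   G005     G022 13.02     2
paracrine       1        SMSC       IMAdC   G011     G036  8.71     3

planted pairs: [('G010', 'G023'), ('G011', 'G036'), ('G005', 'G022')]
```

Exactly the three planted paracrine SMSC→IMAdC pairs are recovered — no
decoy passes the differential-expression gate — and they are ranked by CS:
the top pair's members carry estimated log2 fold changes whose magnitude
fold-change product is 26.4.

The other examples cover differential expression
(`01_differential_expression.py`: perfect direction recovery of 40 planted
|log2FC| = 2 genes, mean absolute estimation error 0.23), enrichment
(`02_…`: the planted set at p ≈ 6e−28, null sets non-significant), network
modules (`03_…`: ARI 1.0 against planted blocks), and an end-to-end run
(`05_…`).

## Command line

A thin CLI wraps the library for shell use:

```bash
lrcrosstalk validate --config cfg.yaml      # structural checks, all failures at once
lrcrosstalk simulate --config cfg.yaml --out sim/   # synthetic inputs + truth tables
lrcrosstalk run      --config cfg.yaml --out out/   # the full pipeline
```

Output is a fixed tree of TSVs (`qc/`, `de/<contrast>/`,
`enrichment/<contrast>/<direction>/`, `network/`, `crosstalk/`) plus a
`manifest.json` echoing the config, seed, and per-stage counts.  Identical
config and seed reproduce the tree byte for byte.  Exit codes: 0 ok,
1 stage failure, 2 config failure.

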