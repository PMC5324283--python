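# pifrif

Systems-level analysis of a two-group bulk RNA-seq contrast — high- versus
low-feed-efficiency (HFE vs LFE) broiler breast muscle — built around two
gene-ranking statistics, **PIF** and **RIF**, rather than per-gene
significance testing. With two very similar groups of six birds each,
gene-by-gene tests are crushed by multiple-testing penalties; instead the
pipeline ranks genes and regulators and interprets whole functional groups.

For each gene, with within-group means $\bar{x}^{HFE}_j$ and
$\bar{x}^{LFE}_j$ of log2 quantile-normalised RPM:

* $M_j = \bar{x}^{HFE}_j - \bar{x}^{LFE}_j$ (differential expression),
  $A_j = (\bar{x}^{HFE}_j + \bar{x}^{LFE}_j)/2$ (abundance)
* **PIF** (Phenotypic Impact Factor): $\mathrm{PIF}_j = A_j \times M_j$ —
  de-emphasises lowly abundant, noisy transcripts and defines the extreme
  5% target genes and the 40-gene discrimination panel.
* **RIF** (Regulatory Impact Factor), for regulator $r$ against the
  $n_{DE}$ extreme-PIF targets, with within-group Pearson correlations
  $r^{HFE}_{rj}, r^{LFE}_{rj}$ and
  $\mathrm{DC}_{rj} = r^{HFE}_{rj} - r^{LFE}_{rj}$:

$$\mathrm{RIF1}_r = \frac{1}{n_{DE}}\sum_j x_j\, d_j\, \mathrm{DC}_{rj}^2
\qquad
\mathrm{RIF2}_r = \frac{1}{n_{DE}}\sum_j \left[(x^{HFE}_j r^{HFE}_{rj})^2 -
(x^{LFE}_j r^{LFE}_{rj})^2\right]$$

RIF detects regulators that are *transcriptionally rewired* between
conditions — their correlation structure to the DE targets changes — even
when the regulator's own expression does not, the typical situation for
transcription factors controlled post-translationally. A gene-set
direction-skew module tests, by exact binomial statistics, whether a
designated set (the 699-gene mitoproteome) moves preferentially toward
one group (the study's split: 475 up vs 224 down in HFE, p < 1e-6).

Because no raw reads are deposited for the study, the package ships a
first-class **synthetic-data generator** that emulates the 6-vs-6 design
and plants exactly the structures the analysis is designed to detect
(strong DE at 1.5–4.5 fold, the mitoproteome skew, sign-flipping
regulator–regulon wiring), with truth tables for recovery testing.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (large intermediates under `scratch/`, small tables under
`results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_normalize.py
python analysis/03_de_pif.py
python analysis/04_mito_skew.py
python analysis/05_rif.py
python analysis/06_cluster_panel.py
```

Output at seed 1:

```
12000 genes read; 12000 complete after filter
provenance: rpm(all-gene totals) -> filter_complete -> log2(+1) -> quantile
PCA: PC1 32.9%, PC2 11.1% of variance; 0 misclassified -> separated=True

12000 genes; extreme sets: 300 up + 300 down
planted strong-DE genes inside the extreme sets: 74.0%

simulated mitoproteome: 476 up vs 223 down (0 tied) -> p = 5.49e-22, up-in-HFE
study's printed split 475:224 -> p = 1.17e-21 (< 1e-6: True)

898 regulators scored; 117 flagged at |z| >= 1.96
top 5 by max |z|:
  G11242  max|z| = 5.07 <- planted rewired
  G04839  max|z| = 4.99 <- planted rewired
  G07904  max|z| = 4.52 <- planted rewired
all 3 planted rewired regulators in a top-5: True

purity at k=2: 1.000
```

Reading: normalisation preserves the group structure (PCA separates the
12 samples); the extreme-PIF sets are dominated by planted DE genes; the
planted 68% up-skew of the mitoproteome is recovered and is wildly
incompatible with a 50:50 null; the three differentially wired regulators
take the top three RIF scores out of 898 candidates (the simulated
analogue of the progesterone-receptor cluster); and the 40-gene panel
clusters every bird into its correct group.

The same stages are exposed as a CLI (`pifrif simulate|normalize|de|skew|
rif|cluster|run-all`) and as plain library calls (`pifrif.generate_dataset`,
`pifrif.normalize_counts`, `pifrif.compute_de`, …).

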