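# Methods

## The analysis model

The pipeline contrasts two treatment groups (HFE vs LFE, six biological
replicates each) at the systems level. Its stages, in fixed order:

1. **Normalisation.** Counts → reads-per-million (RPM) → completeness
   filter → log2(x + 1) → quantile normalisation. RPM denominators are
   the per-sample totals over *all* detected genes, computed before the
   completeness filter (a flag swaps the order; totals over retained
   genes differ by < 1% in practice). "Missing value" means a zero
   count: RNA-seq count matrices contain no NA, so a gene is "complete"
   when its count is positive in every sample. The pseudocount of 1
   keeps the log total on arbitrary input; retained genes are positive
   anyway, so it only compresses the very bottom of the scale.
2. **PCA check.** Samples are projected on the top two principal
   components (genes centred, not variance-scaled — the default for
   expression matrices) and the groups count as separated when Fisher's
   linear discriminant on PC1–PC2 misclassifies at most one sample.
   A discriminant is used rather than an exhaustive best-boundary
   search because the latter badly overfits 12 points in two
   dimensions: with an exhaustive search, randomly labelled null data
   "separates" far too often for the check to mean anything. The test
   suite keeps an exhaustive-search oracle to confirm the positive
   case.
3. **DE/PIF.** Per gene: M, A, signed fold change (2^|M| carrying the
   sign of M, so M = −2.16 prints as −4.46), PIF = A × M on the log2
   scale — the literal product, no centring or scaling. A uses the mean
   of group means, identical to the grand mean for balanced designs and
   flagged for unbalanced ones. The extreme fraction is split
   symmetrically and floored: floor(0.025 n) per tail, giving 260 + 260
   = 520 of 10,412 (floor, not round, reproduces 260 from 10,412 and
   10,416 alike). Ties in PIF break by gene id, lexicographically, so
   selection is deterministic.
4. **Gene-set skew.** Members of a designated set are counted by
   direction of M; ties (M = 0) count for neither side and are
   reported. The exact binomial test against p = ½ is two-sided in the
   minimum-likelihood sense (every outcome no more probable than the
   observed one contributes). Two-sided is the conservative reading of
   a "50:50" null; with splits like 475:224 the sidedness choice cannot
   change the conclusion.
5. **RIF.** Within-group Pearson correlations between every regulator
   and every target, assembled into RIF1 and RIF2 exactly as printed in
   the README. x_j is the target's mean over all 12 samples. A
   zero-variance vector within a group yields r := 0 (with a logged
   count) rather than NaN, keeping DC defined. Regulators that are
   themselves targets stay in both roles — the self-pair has r = 1 in
   both groups and contributes DC = 0 — with a flag to drop them. Raw
   scores are z-standardised across regulators and |z| ≥ 1.96 flagged;
   the threshold is an exploration aid, not a significance claim, and
   the scores imply nothing about activation versus repression.
6. **Panel clustering.** The top-20 + bottom-20 PIF genes are
   row-normalised (population SD; the sample-SD variant only rescales
   rows and cannot change a correlation-distance tree) and the samples
   clustered agglomeratively. Defaults: correlation distance (1 − r),
   average linkage — common heatmap practice; both are flags, and Ward
   requires euclidean. Purity is measured at the k = 2 cut; dispersion
   is the mean pairwise within-group distance. Leaf-ordering/seriation
   is out of scope: group recovery does not depend on it.

## The synthetic-data generator

The generator emulates the study design — it is the package's study
population, not a tuning surface. Defaults: 12,000 genes, 6 + 6 samples,
898 regulators (3 rewired), 5% strong DE at 1.5–4.5 fold, a 699-gene
"mitoproteome" set planted up-in-HFE with probability 475/699 at milder
1.2–1.8 folds (the skew is a modest shift spread over many genes),
library sizes uniform on 50–85 million (the study averaged 67 million
reads per sample), and negative-binomial dispersion 0.05 (biological
CV ≈ 22%, the realistic regime for animals of one genetic line under
controlled conditions). The feed-efficiency phenotype itself is recorded
as the design constants 0.65 vs 0.46 g gain/g feed (a 1.4-fold
contrast).

Mechanics and the design choices behind them:

* Baseline log2 abundances ~ Normal(4, 2) on an RPM-like scale, spanning
  a bulk-muscle-like dynamic range.
* **Planted DE** multiplies the HFE/LFE mean ratio by the sampled fold,
  split half-and-half across the groups (HFE × √fold, LFE ÷ √fold).
  The symmetric split keeps a gene's abundance A at its baseline, so DE
  direction is not confounded with abundance; a one-sided shift would
  systematically depress the PIF extremeness (and RIF weight) of
  down-regulated genes relative to up-regulated ones.
* **Differential wiring** models one signalling cluster per DE
  direction: a standard-normal per-sample latent drives the regulators
  assigned to that direction (coefficient 1) and the direction's entire
  strong-DE regulon, with coefficient +c in HFE and −c in LFE
  ("sign_flip"; an "on_off" mode uses +c vs 0). One shared latent per
  direction, rather than one per regulator, is deliberate: independent
  6-sample latents are substantially correlated by chance and
  superimposed signals on common targets randomly cancel. Regulons are
  direction-coherent because the signed x·d weight in RIF1 would cancel
  over a mixed regulon. The latent is standardised within each group so
  rewired regulators are exactly non-DE on the log-mean scale, and c is
  calibrated per target and per group so the population
  regulator–target correlation on the log2 scale equals
  `wiring_strength` — count noise with variance (α + 1/mean)/ln²2 would
  otherwise attenuate the realized correlation below the requested
  magnitude (values of `wiring_strength` near 1 are unattainable under
  noise and are clamped).
* **Counts** are negative binomial per gene and sample (variance
  m + αm²), with the RPM-scale mean scaled to the sample's library
  size. `lfe_dispersion_scale` multiplies α for the LFE samples only,
  supporting noisier-group comparisons.
* `mito_set_size` may be 0 so a fully null configuration (no planted
  structure at all) is expressible; `null_config()` builds one.

What the generator does **not** emulate: read-level artefacts (mapping,
GC/length effects — hence no RPKM), correlated baseline co-expression
among null genes, batch structure, or fibre-type biology. Passing
recovery tests therefore show that the statistics detect the structures
they were designed for at realistic noise levels and sample sizes — not
that they are robust to every failure mode of real libraries.

## Numerical notes

* **Quantile normalisation** uses the classic rank-mean procedure; tied
  values receive the mean of the rank-means their run spans (the most
  common dialect). With integer counts a large fraction of a column's
  values are tied, and tie-averaging then perturbs the shared
  distribution: per-sample sorted vectors agree only up to the tie-span
  widths and a second pass can move values slightly. On tie-free input
  the textbook properties — identical sorted vectors, exact idempotence,
  equal column means — hold to 1e-9 and are asserted there.
* Pearson correlations are computed population-style (z-score products);
  values are clipped to [−1, 1] against rounding.
* Sample sizes used by the replicate-based checks (problem sizes chosen
  to keep full runs in seconds): rewiring recovery at the full default
  scale over 20 replicates; null-wiring, MA-centring and clustering
  suites at 4,000–5,000 genes over 20 replicates; label permutations,
  50.
* All randomness flows from a single integer seed per run; identical
  config + seed reproduces every table bit-for-bit.

## Known limitations

* With six samples per group, 6-sample Pearson correlations are fragile:
  a single outlying count can halve a regulator's apparent connectivity.
  At dispersions well above ~0.1 the planted-rewiring recovery guarantee
  degrades for exactly this reason; the default 0.05 reflects the
  homogeneous study population, not RNA-seq in general.
* The null distribution of RIF scores is heavier-tailed than normal
  (a regulator's correlations to many targets share its six samples per
  group), so the |z| ≥ 1.96 flag marks ~9% of null regulators, not 5%.
* The real study's gene identities (fold-change tables, the particular
  TFs) are not reproducible without the unpublished raw reads; the
  package reproduces the study's *procedures* and its self-contained
  numbers, and validates the procedures by planted-truth recovery.
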