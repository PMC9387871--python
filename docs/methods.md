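# Methods

## The model

`nmfomics` integrates a paired cohort — gene expression counts and array
methylation beta values measured on the same samples — through a single
joint non-negative matrix factorization

    A ≈ W H,    W ≥ 0 (m features × r),   H ≥ 0 (r × n samples),

where `A` stacks depth-normalised log2 expression on top of beta values,
each feature row divided by its maximum ('max' norm) so the two modalities
contribute on a common [0, 1] scale. Columns of `W` ("latent factors") carry
per-feature loadings spanning both modalities; rows of `H` give each
sample's weight on each factor and are the object stratification works on.
A factor is therefore simultaneously a gene programme, a CpG methylation
programme, and a patient axis.

Downstream, the two halves of the factorization are mined separately:

* **H (sample axis)** — per-factor two-sided Mann–Whitney tests of case vs
  control, a ridge-stabilised multivariate logistic regression with
  in-sample AUC, and k-means stratification (k = 4…7) scored by information
  gain (mutual information between cluster and group label, in bits) and a
  cluster × group chi-square test.
* **W (feature axis)** — per factor, features at or above the 90th
  percentile of the full column (genes and CpGs cut jointly, ties included)
  are selected; selections feed hypergeometric gene-set enrichment with
  BH-FDR, a Fisher test for regulatory-category (promoter / enhancer /
  TFBS) enrichment of the combined selected CpGs, and all-pairs gene × CpG
  Pearson correlation networks (two-sided p from the t transform, BH-FDR
  per factor, edges kept at q < 0.05). Node degrees identify hub genes
  (degree ≥ 90th percentile among gene nodes), intersected with
  differentially expressed genes (Welch tests, q < 0.05) and reduced to
  shared-CpG subnetworks (edges with R > 0.7, CpGs touching ≥ 2 of the
  genes of interest).
* **cis-mQTL contrast** — for each gene in the network, all CpGs on the
  same chromosome within ±10,000 bp of the TSS (closed interval, distance
  signed by strand) are correlated and BH-filtered; the resulting cis pair
  set is compared with the factor-derived edges by overlap and by the
  fraction of cross-chromosome (trans) pairs. "mQTL" here involves no
  genotypes — it is a proximity-constrained methylation–expression
  correlation.

## Factorization engine

Multiplicative updates (Lee–Seung), in the generalized Kullback–Leibler
form by default (the `brunet` variant) with squared-error (`frobenius`)
updates available by flag:

    KL:   H ← H ⊙ (Wᵀ(A ⊘ WH)) ⊘ colsum(W)ᵀ,   W ← W ⊙ ((A ⊘ WH)Hᵀ) ⊘ rowsum(H)
    FRO:  H ← H ⊙ (WᵀA) ⊘ (WᵀWH),              W ← W ⊙ (AHᵀ) ⊘ (W(HHᵀ))

Both updates are monotone; the test suite checks the recorded loss trace at
every iteration (tolerance 1e−9). Denominators are floored at 1e−12.
Each fit runs `n_runs` random restarts, every restart drawing its
uniform(ε, 1) initialisation from an independent substream of one seed
(`numpy` `SeedSequence.spawn`), and keeps the run with the lowest final
loss. Convergence is declared when the relative loss change drops below
`tol` (default 1e−6) or at `max_iter` (default 2000). After fitting, W
columns are rescaled to unit maximum and the inverse scale is absorbed into
H — the product is unchanged to 1e−12 and percentile thresholds on W become
comparable across factors and runs.

Rank selection scans a grid (default 2…10, 5 restarts per rank), recording
RSS = Σ(A − WH)², evar = 1 − RSS/ΣA² (uncentered total sum of squares) and
the evar gain over the previous rank. The advisory elbow rule returns the
largest rank whose own gain still reaches `drop_threshold` (default 0.01)
while the next rank's gain falls below it; the configured rank always wins,
mirroring how such scans are read by eye in practice.

The engine is exposed as a scikit-learn-style estimator (`JointNMF`, with
`fit` / `transform` / `get_params` and trailing-underscore fitted
attributes) operating in the omics orientation (rows = features); the rest
of the pipeline consumes it through the labelled `nmf_fit` front-end.

## Preprocessing

* Expression: median-of-ratios size factors (the median over zero-free
  genes of count/geometric-mean), upper-quartile fallback when no gene is
  zero-free, then log2(count/s + 1).
* Methylation: beta values go into the factorization untransformed (they
  are already in [0, 1]); M-values log2((β+ε)/(1−β+ε)) with ε = 1e−6 are
  computed only for the differential tests.
* Both matrices pass a mean/variance filter with *strict* inequalities
  (mean > `mean_min` and unbiased variance > `var_min`), so a constant row
  is removed even at a variance threshold of zero. Defaults
  (mean 1.25 / var 0.1 on log2 expression; mean 0.05 / var 0.005 on beta)
  are calibrated to the synthetic cohort's scales: they separate
  housekeeping/unloaded background features from factor-loaded ones.
* The 'max' norm is applied per feature row. Per-feature scaling is what
  makes gene and CpG magnitudes commensurable for a joint factorization; a
  `scale_axis` config key documents the choice.

## Statistical conventions

* Mann–Whitney U is reported in the min-U convention, ties counting ½;
  exact enumeration when both groups have ≤ 8 samples and no ties,
  otherwise the tie-corrected normal approximation. Two-sided throughout.
* Logistic regression is IRLS with a ridge term λ = 1e−6 so complete
  separation (a real possibility with a strongly differential factor on 57
  samples) keeps finite weights; Wald p-values come from the penalised
  information matrix; AUC is the in-sample rank statistic and equals
  U/(n₁n₂) on the fitted scores.
* Information gain is mutual information: H(group) − Σ_c (n_c/n) H(group |
  c), entropies in bits with 0·log 0 ≡ 0. Plain entropy cannot rank
  clusterings of the same samples; mutual information is the quantity the
  term "information gain" standardly denotes, and it is invariant under
  cluster relabeling.
* Enrichment is one-sided hypergeometric over-representation with BH-FDR
  across terms, fold = (overlap/|selected|)/(term/|universe|); regulatory
  categories use the one-sided 2×2 Fisher exact test with the analogous
  proportion-ratio fold. No gene-length bias weighting and no GO-DAG
  propagation: terms are flat sets supplied as GMT.
* Differential association is a deliberate simplification: Welch t-tests
  on normalised log2 expression (log2 fold change of group means) and on
  M-values (group mean difference), BH-FDR per modality. The pipeline's
  claims about these numbers are structural (which features are flagged),
  not count-model-faithful.
* Correlation p-values use t = R√((n−2)/(1−R²)); a permutation mode exists
  for tiny n and the test suite verifies t-based and permutation p agree at
  n = 8 within Monte-Carlo error.
* Replication re-computes Pearson R in an independent cohort for discovery
  edges with R > 0.7; the default criterion is validation p < 0.05 with the
  same sign, switchable to an R-threshold criterion.

## The synthetic cohort

The generator plants everything the pipeline is later asked to find.
Default design: 33 cases + 24 controls, 500 genes + 2,000 CpGs, K = 5
factors, factors 1 and 4 (0-based 0 and 3) differential with an additive
case shift of 1.0 on their H rows.

* `H_true` entries are Gamma(2.5, 0.5) (mean 1.25, sd ≈ 0.79); `W_true` is
  sparse with uniform(0.8, 1.5) loadings and the supports of the first K−1
  factors drawn disjointly (each loads ~12% of features). With overlapping
  supports, the case-shift component of the differential factors bled into
  non-differential estimated factors and inflated the per-factor type-I
  rate of the group tests; disjoint supports keep the planted basis
  identifiable. Factors still share features through the cis-pair
  co-loadings, and thresholded selections still overlap at loose cuts.
* The last factor is the hub block: exactly one gene (loading 2.5)
  co-loading with 50 CpGs (loadings 1.5–2.5), planting a top-degree
  network node. Giving the hub factor no other support removes within-
  factor competition at the selection step, so hub recovery measures the
  network analysis rather than a modality imbalance in W magnitudes.
* Expression: counts = round(s_j · exp(1.4·signal + noise)), s_j
  log-normal library sizes (σ = 0.2), Gaussian log-scale noise (σ = 0.3);
  the 1.4 gain keeps the softplus floor of log2(count+1) small relative to
  the signal. Genes with no factor loading are "housekeeping" background:
  constant moderate expression (level 20, tight noise), zero-free across
  samples. This gives the median-of-ratios normalisation an unchanged
  reference set — without it the size factors absorb the case shift of
  differential genes and push a spurious opposite group effect into every
  null gene row.
* Methylation: beta = logistic(signal − 2.5 + noise) with noise σ = 0.2,
  strictly inside (0, 1); unloaded probes sit at a low-methylation
  baseline (≈ 0.08) whose tiny variance the filter removes.
* Geometry: 22 synthetic chromosomes of 50 Mb. Genes live on chromosomes
  1–11, non-cis CpGs on 12–22 (trans to every gene by construction);
  `n_cis_pairs` CpGs (50 at the default 2,000-CpG size, i.e. 2.5%) are
  placed within ±10 kb of a gene TSS and share a factor with that gene, so
  the mQTL window analysis has recoverable targets.
* Enhancer flags: CpGs passing a truth-side version of the per-factor
  joint percentile selection (cut at the 94th percentile of each full
  W_true column — slightly above the pipeline's 90th because the pipeline
  selects among variance-filtered features, a smaller universe) get
  `enhancer_enrichment_odds` = 3-fold higher odds of `is_enhancer` over a
  base rate of 0.05; promoter and TFBS flags are independent background at
  0.10.
* A validation cohort shares `W_true` and the planted structure but draws
  fresh samples and noise.

What passing tests on this cohort show: the pipeline recovers planted
low-rank structure, group effects, co-loading correlation blocks, genomic
geometry and category enrichment under count-like, (0,1)-bounded,
noise-contaminated data. What they do not show: robustness to batch
effects, cell-type composition, probe chemistry, negative-binomial
dispersion, or correlated noise between neighbouring CpGs — none of which
the generator emulates.

## Numerical and design choices

* Percentiles are linear-interpolation (type-7) order statistics; ties at
  a selection threshold are always included on the selected side.
* The per-factor selection threshold spans both modalities jointly — one
  number per factor — so gene+CpG counts per factor sum to ~10% of all
  features.
* FDR for network edges is applied per factor across that factor's
  candidate pairs; the mQTL candidate set is corrected separately.
* The mQTL window is anchored at the TSS (closed interval); a gene-body
  anchor is available via the `anchor` option where the two conventions
  differ.
* Coordinates: BED input is 0-based half-open (TSS = start on "+", end on
  "−"); the CpG manifest is 1-based and converted to 0-based once, at read
  time.
* k-means uses k-means++ with `n_init` restarts and a fixed seed; on raw
  omics matrices samples are first projected onto 5 principal components.
* Determinism: every stochastic step (NMF restarts, k-means, random
  controls, background pair draws, the generator) is driven by explicit
  seeds; the same config and seed reproduce every output table
  byte-for-byte.
* Desk-scale defaults keep test-suite problems at a few hundred to a few
  thousand features; the full-scale paths (rank grids to 100, 30 restarts)
  are plain config values.

## Known limitations

* NMF is identifiable only up to permutation and positive scaling; all
  truth comparisons go through maximum-cosine assignment, and absolute W
  thresholds are meaningful only under the unit-max column convention used
  here.
* The softplus floor of log2(count+1) and the logistic floor of beta give
  every feature row a small constant component; a rank-r fit absorbs it
  across factors, which slightly couples the estimated H rows. At the
  default effect size this leaves a small excess of false-positive group
  tests on non-differential factors relative to the nominal 5%.
* In-sample AUC on 57 samples is optimistic by construction; no
  cross-validation is attempted, matching the single-cohort design the
  pipeline mirrors.
* The Welch-test differential stand-ins ignore count dispersion and array
  moderation; they are annotation machinery, not a differential-expression
  method.
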