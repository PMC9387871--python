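# nmfomics

Joint non-negative matrix factorization of paired transcriptome +
methylome cohorts: latent-factor patient stratification, gene–CpG
correlation networks, and a cis-mQTL contrast.

## The problem

Case/control cohorts profiled on both RNA-seq and methylation arrays are
usually analysed one data type at a time, then intersected. `nmfomics`
instead decomposes the two matrices jointly: depth-normalised log2
expression and beta values are filtered, stacked and row-scaled into one
non-negative matrix `A` (features × samples), and factorized

    A ≈ W H,   W ≥ 0,  H ≥ 0,  rank r,

so each latent factor is at once a gene programme, a CpG programme and a
patient axis. The encoding matrix `H` drives stratification (per-factor
Mann–Whitney group tests, logistic-regression AUC, k-means with
information gain); the basis matrix `W` drives feature work (90th-percentile
selections per factor, gene-set and regulatory-category enrichment,
all-pairs gene × CpG Pearson networks with node-degree hub analysis); and a
±10 kb cis-mQTL window analysis around each gene's TSS quantifies how much
of the factor-derived network is invisible to proximity-based correlation
(most of it — the network edges are overwhelmingly trans).

It is intended for bioinformaticians who want a tested, seeded, end-to-end
reimplementation of this analysis pattern, together with a synthetic-cohort
generator that plants every structure the pipeline is later asked to
recover (low-rank factors, differential factors, co-loading gene–CpG
blocks, cis/trans geometry, enhancer enrichment, a network hub).

## Worked example

Simulate a default cohort (33 cases + 24 controls, 500 genes + 2,000 CpGs,
K = 5 planted factors, factors 1 and 4 differential) and run the full
pipeline:

```bash
nmfomics --seed 1 --outdir cohort simulate
nmfomics --seed 1 --outdir results all --indir cohort
```

`results/` then contains diff-able TSV tables, each with the config hash
and seed in a `#` header: `W.tsv`, `H.tsv`, `factor_tests.tsv`,
`auc_report.tsv`, `clusters.tsv`, `information_gain.tsv`,
`selections.tsv`, `enrichment.tsv`, `edges.tsv`, `degrees.tsv`,
`hubs.tsv`, `mqtl_summary.tsv`, `replication.tsv`, `links.bedpe`.

`factor_tests.tsv` reports the per-factor group tests on H; at this seed
three factors reach p < 0.05, among them both planted differential factors
(the third is a borderline false positive for this draw):

```
factor  U       p_value                 direction
LF1     142     4.1809522111062777e-05  1
LF2     162     0.00016065622172124183  1
LF3     340     0.36970285296795957     -1
LF4     203     0.0018625258462139568   -1
LF5     365     0.62203909135793867     -1
```

`auc_report.tsv` gives the logistic-regression AUC of 0.953 with all five
factors (0.947 with only the significant ones), and `mqtl_summary.tsv`
shows the geometry contrast — per factor, hundreds to thousands of
significant factor-derived edges, ≥ 99% of them unique to the latent
factor analysis and ≥ 97% lying on different chromosomes
(`fraction_trans_nmf`), while every mQTL pair is same-chromosome within
the ±10 kb window by construction:

```
factor  n_nmf_pairs  n_mqtl_pairs  n_shared  fraction_unique_to_nmf  fraction_trans_nmf
LF3     1130         15            10        0.9911...               0.9725...
LF4     2727         4             0         1                       0.9992...
```

The same can be driven from Python:

```python
import nmfomics as nm

design = nm.SimulationDesign(seed=7)
expr, beta, sheet, annot, truth = nm.simulate_cohort(design)
expr_f, _ = nm.mean_variance_filter(nm.normalize_expression(expr), 1.25, 0.1)
beta_f, _ = nm.mean_variance_filter(beta, 0.05, 0.005)
A = nm.concatenate_and_scale(expr_f, beta_f)
model = nm.nmf_fit(A, r=5, n_runs=10, seed=7)
match = nm.truth_factor_match(model.W, truth, scale_rows=True)
print(match)          # matched cosines ~0.9+ per planted factor
```

The factorization engine itself is a scikit-learn-style estimator
(`nm.JointNMF(rank=5, objective="kl", n_runs=30, random_state=...)`) with
`fit`/`transform` and fitted attributes `W_`, `H_`, `loss_trace_`, so it
composes with sklearn tooling; `nmf_fit` is the labelled front-end the
pipeline uses.

See `docs/methods.md` for the model, the statistical conventions, the
synthetic-cohort design and its limitations.

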