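# nbshrink

Differential analysis of high-throughput count data (RNA-seq and other
counting assays) with negative-binomial generalized linear models and
empirical-Bayes shrinkage — of both dispersions and log fold changes —
plus Wald and fold-change-threshold tests with independent filtering,
Cook's-distance outlier handling, and a regularized-logarithm transform
for clustering and visualization. A built-in simulator generates
benchmark datasets with known truth.

The package is aimed at analysts comparing gene-level read counts
between conditions with few replicates, where per-gene variance
estimates are too noisy to use directly and information must be pooled
across genes.

## Model

Counts are modelled per gene *i* and sample *j* as

```
K_ij ~ NB(mean = mu_ij, dispersion = alpha_i),   mu_ij = s_ij * q_ij,
log q_ij = sum_r x_jr * beta_ir,
```

with variance `mu + alpha*mu^2`. Size factors `s_j` come from the
median-of-ratios estimator. Three pooling devices make small-*m*
inference workable:

* **Dispersion shrinkage.** Gene-wise dispersions are estimated by
  maximizing the Cox–Reid adjusted likelihood
  `l_CR(alpha) = l(alpha) − ½ log det(XᵗWX)`, a parametric trend
  `alpha_tr(mu) = a1/mu + alpha0` is fit across genes, and a log-normal
  prior `log alpha_i ~ N(log alpha_tr, sigma_d²)` with data-estimated
  width (trigamma-corrected, floored at 0.25) yields MAP dispersions.
  Genes more than two residual SDs *above* the trend keep their
  unshrunken estimate.
* **LFC shrinkage.** A zero-centered normal prior on non-intercept
  coefficients, with width matched to the 95% quantile of the MLE
  fold-change distribution, is applied via iteratively reweighted ridge
  regression on an *expanded* design matrix (one indicator per factor
  level) so that results do not depend on the choice of base level.
* **Testing.** Wald statistics `beta/SE(beta)` use the ridge sandwich
  covariance `(XᵗWX+λI)⁻¹(XᵗWX)(XᵗWX+λI)⁻¹`. Composite nulls
  `|beta| ≤ θ` and `|beta| ≥ θ` replace the point null when an effect
  size of biological relevance is specified. BH adjustment is applied
  after filtering genes with low mean normalized count, choosing the
  threshold that (after smoothing) maximizes discoveries at the target
  FDR.

Counts influencing a fit too strongly (Cook's distance above the 0.99
quantile of F(p, m−p)) flag the gene for removal (≤6 replicates per
condition) or count replacement and refitting (≥7 replicates).

## Worked example

```python
import numpy as np
from nbshrink import evaluate_performance, run_pipeline, simulate_dataset

sim = simulate_dataset(n_genes=2000, m=6, de_fraction=0.2,
                       fold_changes=[2, 3, 4], seed=1)
res = run_pipeline(sim.dataset, "~ condition")
print(res.results.head(6).round(4))
```

```
       baseMean  log2FoldChange   lfcSE    stat  pvalue    padj  maxCooks status
gene
gene1   69.3159         -0.1165  0.3789 -0.3075  0.7584  0.9416    1.0729     ok
gene2  756.7107          0.0200  0.2203  0.0906  0.9278  0.9852    0.7050     ok
gene3   21.9833         -0.5608  0.4629 -1.2116  0.2257  0.6407    0.6813     ok
gene4    2.4262         -0.9832  0.8047 -1.2219  0.2218  0.6347    1.5166     ok
gene5   57.2314         -0.1037  0.3573 -0.2901  0.7717  0.9522    0.7334     ok
gene6   74.2657          0.4746  0.3461  1.3711  0.1704  0.5644    0.3232     ok
```

`baseMean` is the mean of normalized counts, `log2FoldChange` the
shrunken (MAP) log2 fold change of condition B over A with its standard
error `lfcSE`, `stat` the Wald z-statistic, and `padj` the BH-adjusted
p value among genes passing the independent filter (NA otherwise). The
fitted hyperparameters are available on the result object:

```python
d = res.dispersion_model
print(f"dispersion trend: a1={d.trend_a1:.3f}, alpha0={d.trend_alpha0:.4f}, "
      f"sigma_d^2={d.prior_var:.3f}")
print(f"LFC prior sd (log2): {np.sqrt(res.lfc_prior.sigma2[1])/np.log(2):.3f}")
print(f"filter threshold (mean normalized count): {res.filter_threshold:.3f}")
rpt = evaluate_performance(res.results["padj"], sim.is_de, res.results["pvalue"])
print(f"sensitivity={rpt.sensitivity:.3f}, precision={rpt.precision:.3f}")
```

```
dispersion trend: a1=3.881, alpha0=0.0537, sigma_d^2=0.416
LFC prior sd (log2): 1.139
filter threshold (mean normalized count): 0.498
sensitivity=0.700, precision=0.897
```

At six samples and fold changes of 2–4, 70% of the truly changed genes
are recovered and about 90% of the calls are correct.

The same analysis is available from the shell:

```sh
nbshrink simulate --n-genes 2000 -m 6 --seed 1 \
    --counts-out counts.tsv --truth-out truth.tsv --metadata-out meta.tsv
nbshrink run counts.tsv meta.tsv --design "~ condition" -o results.tsv
nbshrink rlog counts.tsv -o rlog.tsv
nbshrink benchmark --n-genes 2000 -m 6 --replicates 10 -o bench.tsv
```

## Layout

| module | contents |
| --- | --- |
| `nbshrink.data` | count container, size factors, normalized counts |
| `nbshrink.design` | formula parsing, standard/expanded design matrices, contrasts |
| `nbshrink.glm` | NB likelihood, vectorized IRLS ridge fitting, sandwich covariance |
| `nbshrink.dispersion` | gene-wise MLEs, trend, prior width, MAP, outlier escape |
| `nbshrink.shrinkage` | LFC prior estimation and MAP fold changes |
| `nbshrink.inference` | Wald/composite tests, BH, independent filtering |
| `nbshrink.outliers` | Cook's distances and the remove/replace policy |
| `nbshrink.rlog` | regularized-logarithm transformation |
| `nbshrink.simulate` | benchmark data generator and performance metrics |
| `nbshrink.pipeline`, `nbshrink.io`, `nbshrink.cli` | orchestration, file formats, CLI |

See `docs/methods.md` for the statistical details and design choices.
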