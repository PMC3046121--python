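# batchbench

Batch effects — the systematic, non-biological variation shared by samples
processed together at one site over a short period — are among the largest
nuisance signals in expression microarray data. `batchbench` is a simulation
framework for *measuring how well batch-adjustment algorithms work*: it
generates log2 expression matrices with controlled batch effects, applies
several widely used adjustment methods, and scores each one with metrics of
variance attribution, precision, accuracy, and overall detection
performance. It is aimed at statisticians and computational biologists who
need to choose (or validate) a batch-correction step for microarray-style
data.

## The model

Simulated data follow a location/scale (L/S) model. For gene *g* of sample
*j* run in batch *i*:

```
Y_ijg = alpha_g + X_j * beta_g + gamma_ig + delta_ig * eps_jg,
eps_jg ~ N(0, sigma_g^2)
```

where `alpha_g` is the baseline log2 intensity, `beta_g` the biological
(log2 fold change) effect carried by the design indicator `X_j`,
`gamma_ig ~ N(0, gamma_sd^2)` an additive batch shift, and
`delta_ig` (with `delta^2 ~ InverseGamma`) a multiplicative inflation of
measurement noise. Ground truth (DE flags, nominal fold changes, realized
batch effects) is emitted with every data set.

Three study designs are built in:

* **VAS** (variation assessment): 100 samples (65/35 split over two
  biological profiles), 1,000 genes, measured twice — one clean single-batch
  replicate and one replicate split over two batches with injected effects.
* **AAS** (accuracy assessment): 10,000 genes, 100 cases vs 100 controls in
  five batches with deliberately imbalanced case/control ratios
  (10/30 and 30/10 in two of them); 1,200 genes DE at 12 log2 fold-change
  levels (±0.14, ±0.26, ±0.58, ±1, ±1.32, ±1.58), 100 genes per level.
* **Confounded**: all cases in one batch, all controls in the other —
  biology and batch are inseparable by construction.

## Methods and metrics

Adjustments: gene-wise per-batch mean-centering (PAMR-style), geometric
ratio adjustment against reference samples (Ratio_G), parametric and
non-parametric empirical-Bayes location/scale adjustment (ComBat; verified
numerically identical to the Bioconductor reference implementation), and a
surrogate-variable (SVA-style) adjustment based on residual SVD with
permutation selection.

Metrics: principal variance component analysis (PVCA; sample-space PCA
followed by EM-REML random-effects variance attribution, eigenvalue
weighted), per-gene replicate Pearson correlation and one-way
random-effects ICC with Fisher-z summaries, nominal-vs-observed fold-change
agreement (Spearman r² and the signal-detection slope, plus an ANCOVA
homogeneity-of-slope test), and per-gene Welch-test rankings scored by
ROC-AUC (paired DeLong comparisons) and the Matthews correlation
coefficient after Benjamini–Hochberg correction.

## Worked example

```python
import batchbench as bb

expr, sheet, truth = bb.simulate_aas(seed=0)          # 10,000 x 200 design
de = truth.genes["is_de"].to_numpy(bool)
nominal = truth.genes["nominal_log2_fc"].to_numpy()

p = bb.de_pvalues(expr, sheet)                         # Welch t per gene
auc_raw = bb.roc_auc(bb.ranking_scores(p), de).auc
r2, slope = bb.fc_agreement(nominal, bb.observed_log2_fc(expr, sheet), de)

adjusted, fit = bb.combat(expr, sheet, covariates=("group",))
p_adj = bb.de_pvalues(adjusted, sheet)
auc_adj = bb.roc_auc(bb.ranking_scores(p_adj), de).auc
```

This prints (seed 0):

```
unadjusted:  slope=0.975  r2=0.926  AUC=0.866
ComBat_p:    AUC=0.965  MCC=0.707  DeLong p=2.64e-69
```

The unadjusted slope near 1 says fold changes are recovered without bias
even before correction (batch shifts average out of a balanced contrast),
but the AUC shows ranking power is lost to batch noise; the empirical-Bayes
adjustment recovers most of it. On the VAS design, PVCA attributes ~30% of
overall variance to batch before adjustment and ~0% after mean-centering or
ComBat:

```
PVCA before: {'batch': 0.297, 'group': 0.144, 'batchxgroup': 0.001, 'resid': 0.558}
PVCA after mean-centering: {'batch': 0.0, 'group': 0.172, 'batchxgroup': 0.002, 'resid': 0.826}
```

A command-line interface covers the same pipeline:

```bash
batchbench simulate --design aas --seed 1 --out-dir sim/
batchbench correct --method combat_p --expr sim/expression.tsv \
    --sheet sim/sample_sheet.tsv --out adjusted.tsv
batchbench pvca --expr sim/expression.tsv --sheet sim/sample_sheet.tsv \
    --factors batch,group --out pvca.tsv
batchbench benchmark --config bench.yaml --out report/
```

`correct` exits with status 2 when ratio adjustment is structurally
impossible (a batch without reference samples, as in the confounded design).

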