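"""Precision, accuracy and overall-performance metrics, plus the benchmark runner.

Precision metrics compare technical replicates: per-gene Pearson correlation
between duplicate runs, one-way random-effects intraclass correlation across
replicate groups, and Fisher z transforms with a paired signed-rank test for
distribution shifts.  Accuracy metrics compare observed to nominal log2 fold
changes (Spearman agreement and the signal-detection slope, with an ANCOVA
homogeneity-of-slope test).  Overall performance scores a per-gene
differential-expression ranking against ground truth with ROC-AUC (paired
DeLong comparison between methods) and the Matthews correlation coefficient
of the post-FDR confusion matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from . import simulate
from .core_data import ExpressionMatrix, SampleSheet, group_levels, \
    write_expression_tsv, write_sample_sheet
from .correct import (BatchAdjustmentError, ConfoundingError, combat,
                      mean_center, ratio_g, sva_adjust)
from .pvca import run_pvca

SD_FLOOR = 1e-8


# ---------------------------------------------------------------- precision

def standardize_genes(expr: ExpressionMatrix, sheet: SampleSheet | None = None,
                      within: str | None = None) -> ExpressionMatrix:
    """Scale every gene to mean 0 / s.d. 1 (sample s.d., ddof=1).

    With ``within`` naming a sample-sheet column, standardization is done
    separately inside each stratum of that column (e.g. per replicate
    group).  Removing the per-gene location/scale suppresses the probe
    effect that otherwise inflates sample-pair correlations.
    """
    y = expr.values.copy()
    if within is None:
        strata = [np.arange(expr.n_samples)]
    else:
        if sheet is None or within not in sheet.data.columns:
            raise ValueError(f"stratum column {within!r} requires a sample sheet")
        labels = sheet.data.loc[expr.sample_ids, within].to_numpy(dtype=str)
        strata = [np.flatnonzero(labels == lev) for lev in dict.fromkeys(labels)]
    for idx in strata:
        if idx.size < 3:
            raise ValueError("each standardization stratum needs >= 3 samples")
        block = y[:, idx]
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd < SD_FLOOR):
            warnings.warn("zero-variance gene(s); s.d. floored at 1e-8")
            sd = np.maximum(sd, SD_FLOOR)
        y[:, idx] = (block - block.mean(axis=1, keepdims=True)) / sd
    return expr.with_values(y)


def replicate_gene_correlation(expr_a: ExpressionMatrix,
                               expr_b: ExpressionMatrix) -> np.ndarray:
    """Per-gene Pearson correlation between two paired replicate matrices."""
    if expr_a.gene_ids != expr_b.gene_ids or expr_a.sample_ids != expr_b.sample_ids:
        raise ValueError("replicate matrices must share gene and sample ids")
    if expr_a.n_samples < 3:
        raise ValueError("need at least 3 paired samples per gene")
    a = expr_a.values - expr_a.values.mean(axis=1, keepdims=True)
    b = expr_b.values - expr_b.values.mean(axis=1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    denom = np.maximum(denom, SD_FLOOR)
    return (a * b).sum(axis=1) / denom


def icc_per_gene(expr: ExpressionMatrix, sheet: SampleSheet,
                 replicate_col: str = "replicate_group",
                 subject_col: str = "subject") -> np.ndarray:
    """One-way random-effects ICC per gene across replicate groups.

    ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW), with subjects as the random
    grouping and the k replicate groups providing repeated measurements.
    The design must be complete: every subject measured once in every
    replicate group.
    """
    meta = sheet.data.loc[expr.sample_ids]
    subjects = meta[subject_col].to_numpy(dtype=str)
    reps = meta[replicate_col].to_numpy(dtype=str)
    subj_levels = list(dict.fromkeys(subjects))
    rep_levels = list(dict.fromkeys(reps))
    counts = pd.crosstab(subjects, reps)
    if (counts.to_numpy() != 1).any():
        missing = [(s, r) for s in subj_levels for r in rep_levels
                   if counts.loc[s, r] != 1] if counts.size else []
        raise ValueError(f"incomplete replicate design; offending cells: {missing[:10]}")
    k = len(rep_levels)
    if k < 2:
        raise ValueError("need at least 2 replicate groups")
    s = len(subj_levels)
    ind = np.stack([(subjects == lev).astype(float) for lev in subj_levels], axis=1)
    y = expr.values
    subj_means = (y @ ind) / k                              # G x s
    grand = y.mean(axis=1, keepdims=True)
    ssb = k * ((subj_means - grand) ** 2).sum(axis=1)
    ssw = ((y - subj_means @ ind.T) ** 2).sum(axis=1)
    msb = ssb / (s - 1)
    msw = ssw / (s * (k - 1))
    denom = msb + (k - 1) * msw
    return (msb - msw) / np.maximum(denom, SD_FLOOR)


def fisher_z(r) -> np.ndarray:
    """Variance-stabilizing transform z = atanh(r); |r| = 1 is clipped."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    clip = 1.0 - 1e-12
    if np.any(np.abs(r) >= clip):
        warnings.warn("correlation(s) at +/-1 clipped before the z transform")
    out = np.arctanh(np.clip(r, -clip, clip))
    return out if out.ndim else float(out)


def paired_z_shift_test(z_before, z_after):
    """Median paired difference and Wilcoxon signed-rank p-value."""
    z_before = np.asarray(z_before, dtype=float)
    z_after = np.asarray(z_after, dtype=float)
    if z_before.shape != z_after.shape:
        raise ValueError("paired vectors must have equal length")
    diff = z_after - z_before
    median = float(np.median(diff))
    if np.all(diff == 0):
        return 0.0, 1.0
    p = stats.wilcoxon(z_after, z_before, zero_method="wilcox").pvalue
    return median, float(p)


# ----------------------------------------------------------------- accuracy

def observed_log2_fc(expr: ExpressionMatrix, sheet: SampleSheet,
                     group_col: str = "group") -> np.ndarray:
    """Per-gene mean difference (second group level minus first) on log2 data."""
    series = sheet.data.loc[expr.sample_ids, group_col]
    levels = group_levels(series)
    if len(levels) != 2:
        raise ValueError(f"column {group_col!r} must have exactly 2 levels, got {levels}")
    vals = series.to_numpy(dtype=str)
    y = expr.values
    return (y[:, vals == str(levels[1])].mean(axis=1)
            - y[:, vals == str(levels[0])].mean(axis=1))


def fc_agreement(nominal, observed, de_mask):
    """Spearman rho^2 and OLS slope of observed on nominal, DE genes only."""
    nominal = np.asarray(nominal, dtype=float)
    observed = np.asarray(observed, dtype=float)
    de_mask = np.asarray(de_mask, dtype=bool)
    if de_mask.sum() < 3:
        raise ValueError("need at least 3 DE genes")
    x, y = nominal[de_mask], observed[de_mask]
    rho = stats.spearmanr(x, y).statistic
    slope = stats.linregress(x, y).slope
    return float(rho ** 2), float(slope)


def slope_homogeneity_test(x1, y1, x2, y2) -> float:
    """ANCOVA F-test of equal slopes between two (x, y) data sets."""
    x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
    if min(x1.size, x2.size) < 3:
        raise ValueError("each data set needs >= 3 points")
    if np.var(x1) == 0 or np.var(x2) == 0:
        raise ValueError("degenerate x values (zero variance)")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = y.size - design.shape[1]
    mse = (resid ** 2).sum() / df
    cov = mse * np.linalg.inv(design.T @ design)
    if mse == 0:
        return 1.0 if coef[3] == 0 else 0.0
    t = coef[3] / np.sqrt(cov[3, 3])
    return float(2 * stats.t.sf(abs(t), df))


# ------------------------------------------------------- overall performance

def de_pvalues(expr: ExpressionMatrix, sheet: SampleSheet,
               group_col: str = "group") -> np.ndarray:
    """Two-sided Welch t-test p-value per gene between the two groups."""
    series = sheet.data.loc[expr.sample_ids, group_col]
    levels = group_levels(series)
    if len(levels) != 2:
        raise ValueError("Welch test needs exactly 2 groups")
    vals = series.to_numpy(dtype=str)
    a = expr.values[:, vals == str(levels[0])]
    b = expr.values[:, vals == str(levels[1])]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    return np.where(np.isfinite(p), p, 1.0)


def bh_significant(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR ``q``."""
    return multipletests(np.asarray(pvalues, dtype=float), alpha=q,
                         method="fdr_bh")[0]


class RocCurve(NamedTuple):
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, truth) -> RocCurve:
    """ROC curve (threshold sweep) and trapezoid AUC for a gene ranking.

    Higher scores must mean stronger differential-expression evidence.  The
    trapezoid area equals the Mann-Whitney concordance probability with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), scores)
    return RocCurve(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def ranking_scores(pvalues) -> np.ndarray:
    """-log10 p ranking statistic (larger = stronger evidence)."""
    p = np.maximum(np.asarray(pvalues, dtype=float), 1e-300)
    return -np.log10(p)


def _delong_placements(scores: np.ndarray, truth: np.ndarray):
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # placements of positives
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # placements of negatives
    return auc, v_pos, v_neg


def auc_difference_test(scores_a, scores_b, truth) -> float:
    """Paired DeLong test comparing two rankings' AUCs on the same truth."""
    truth = np.asarray(truth, dtype=bool)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    auc_a, va_pos, va_neg = _delong_placements(scores_a, truth)
    auc_b, vb_pos, vb_neg = _delong_placements(scores_b, truth)
    m, n = va_pos.size, va_neg.size
    s_pos = np.cov(np.stack([va_pos, vb_pos]))
    s_neg = np.cov(np.stack([va_neg, vb_neg]))
    var = (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m \
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    if var <= 0:
        return 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient of a confusion matrix."""
    counts = np.array([tp, fp, tn, fn], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def confusion_counts(significant, truth):
    significant = np.asarray(significant, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((significant & truth).sum())
    fp = int((significant & ~truth).sum())
    fn = int((~significant & truth).sum())
    tn = int((~significant & ~truth).sum())
    return tp, fp, tn, fn


# ------------------------------------------------ standardization experiment

def standardization_experiment(seed=0, n_genes: int = 1000, n_samples: int = 50,
                               alpha_sd: float = 6.0):
    """Demonstrate the probe effect on sample-pair correlations.

    Simulates a homogeneous cohort whose per-gene baselines have a large
    spread (``alpha_sd``, emulating the dominant probe effect of real
    arrays) relative to measurement noise, then compares all distinct
    sample-pair Pearson correlations before and after per-gene
    standardization.  Returns a dict with both correlation vectors and
    their summary statistics.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.normal(simulate.ALPHA_MEAN, alpha_sd, size=n_genes)
    sigma = np.clip(rng.normal(0.5, 0.15, size=n_genes), 0.1, None)
    sheet = SampleSheet(pd.DataFrame(
        {"batch": ["B1"] * n_samples, "group": ["cohort"] * n_samples},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample_id"),
    ))
    params = simulate.LSModelParams(
        alpha, np.zeros(n_genes), sigma,
        {"B1": np.zeros(n_genes)}, {"B1": np.ones(n_genes)},
        treatment_group="cohort",
    )
    expr = simulate.sample_ls_model(params, sheet, rng)

    def _pair_corr(matrix: np.ndarray) -> np.ndarray:
        c = np.corrcoef(matrix.T)
        return c[np.triu_indices_from(c, k=1)]

    before = _pair_corr(expr.values)
    after = _pair_corr(standardize_genes(expr).values)
    return {
        "corr_before": before,
        "corr_after": after,
        "min_before": float(before.min()),
        "median_after": float(np.median(after)),
    }


# ------------------------------------------------------------ benchmark runner

METHODS = ("mean_center", "ratio_g", "combat_p", "combat_n", "sva")
REPORT_COLUMNS = ("method", "pvca_batch_fraction", "median_repl_z",
                  "median_icc_z", "fc_r2", "slope", "auc", "mcc", "note")


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run (YAML-serializable)."""

    design: str = "aas"                       # vas | aas | confounded
    seed: int = 0
    methods: Sequence[str] = METHODS
    batch_layout: Sequence | None = None      # (size, n_cases, n_controls) triples
    gamma_sd: float | None = None
    delta_shape: float | None = None
    delta_scale: float | None = None
    pvca_threshold: float = 0.6
    protect_group: bool = True
    reference_group: str = "control"
    n_genes: int | None = None
    de_per_level: int = 100
    sva_n_perm: int = 100
    compute_pvca: bool = True

    def batch_effect_spec(self) -> simulate.BatchEffectSpec:
        kwargs = {}
        if self.gamma_sd is not None:
            kwargs["gamma_sd"] = self.gamma_sd
        if self.delta_shape is not None:
            kwargs["delta_shape"] = self.delta_shape
        if self.delta_scale is not None:
            kwargs["delta_scale"] = self.delta_scale
        return simulate.BatchEffectSpec(**kwargs)


@dataclass
class BenchmarkReport:
    """Per-method metric table plus provenance."""

    table: pd.DataFrame
    design: str
    seed: int
    config: BenchmarkConfig
    adjusted: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.tsv", sep="\t", index=False)
        for name, expr in self.adjusted.items():
            write_expression_tsv(expr, out / f"adjusted_{name}.tsv")


def apply_method(name: str, expr: ExpressionMatrix, sheet: SampleSheet,
                 config: BenchmarkConfig):
    """Dispatch a named adjustment; returns the adjusted matrix.

    ComBat protects the group variable when configured; if protection makes
    the design rank deficient (group fully confounded with batch) the fit
    is retried unprotected, mirroring how such designs must be handled in
    practice.
    """
    if name == "unadjusted":
        return expr
    if name == "mean_center":
        return mean_center(expr, sheet)
    if name == "ratio_g":
        return ratio_g(expr, sheet, reference_group=config.reference_group)
    if name in ("combat_p", "combat_n"):
        covs = ("group",) if config.protect_group else ()
        try:
            adjusted, _ = combat(expr, sheet, covariates=covs,
                                 parametric=name == "combat_p")
        except ConfoundingError:
            adjusted, _ = combat(expr, sheet, covariates=(),
                                 parametric=name == "combat_p")
        return adjusted
    if name == "sva":
        adjusted, _ = sva_adjust(expr, sheet, primary="group",
                                 n_perm=config.sva_n_perm, seed=config.seed)
        return adjusted
    raise ValueError(f"unknown method {name!r}")


def _vas_metrics(rep1, adjusted, sheet, config):
    row = {}
    if config.compute_pvca:
        pv = run_pvca(adjusted, sheet, factors=("batch", "group"),
                      include_interactions=True, threshold=config.pvca_threshold)
        row["pvca_batch_fraction"] = pv.weighted_proportions.get("batch", 0.0)
    r = replicate_gene_correlation(rep1, adjusted)
    row["median_repl_z"] = float(np.median(fisher_z(r)))
    # ICC across the duplicate runs: subjects = samples, k = 2 replicate groups.
    combined = ExpressionMatrix(
        rep1.gene_ids,
        [f"{s}.R1" for s in rep1.sample_ids] + [f"{s}.R2" for s in adjusted.sample_ids],
        np.hstack([rep1.values, adjusted.values]),
    )
    icc_sheet = SampleSheet(pd.DataFrame(
        {"batch": ["R1"] * rep1.n_samples + ["R2"] * adjusted.n_samples,
         "group": ["all"] * (2 * rep1.n_samples),
         "replicate_group": ["R1"] * rep1.n_samples + ["R2"] * adjusted.n_samples,
         "subject": rep1.sample_ids + adjusted.sample_ids},
        index=pd.Index(combined.sample_ids, name="sample_id"),
    ))
    icc = icc_per_gene(combined, icc_sheet)
    row["median_icc_z"] = float(np.median(fisher_z(np.clip(icc, -1.0, 1.0))))
    return row


def _aas_metrics(adjusted, sheet, truth, config):
    row = {}
    if config.compute_pvca:
        pv = run_pvca(adjusted, sheet, factors=("batch", "group"),
                      include_interactions=True, threshold=config.pvca_threshold)
        row["pvca_batch_fraction"] = pv.weighted_proportions.get("batch", 0.0)
    nominal = truth.genes["nominal_log2_fc"].to_numpy()
    de = truth.genes["is_de"].to_numpy(dtype=bool)
    observed = observed_log2_fc(adjusted, sheet)
    row["fc_r2"], row["slope"] = fc_agreement(nominal, observed, de)
    pvals = de_pvalues(adjusted, sheet)
    row["auc"] = roc_auc(ranking_scores(pvals), de).auc
    tp, fp, tn, fn = confusion_counts(bh_significant(pvals), de)
    row["mcc"] = mcc_from_counts(tp, fp, tn, fn)
    return row


def run_benchmark(config: BenchmarkConfig, keep_adjusted: bool = False,
                  out_dir=None) -> BenchmarkReport:
    """Generate a design, apply every configured method, score everything.

    A method that is structurally inapplicable (e.g. ratio adjustment on a
    fully confounded design) yields an NA row carrying the error message,
    not a crash.
    """
    spec = config.batch_effect_spec()
    design = config.design.lower()
    gene_kwargs = {}
    if config.n_genes is not None:
        gene_kwargs["n_genes"] = config.n_genes

    if design == "vas":
        rep1, rep2, sheet, truth = simulate.simulate_vas(spec, config.seed, **gene_kwargs)
        target = rep2
    elif design == "aas":
        target, sheet, truth = simulate.simulate_aas(
            config.batch_layout, spec, config.seed,
            de_per_level=config.de_per_level, **gene_kwargs)
    elif design == "confounded":
        target, sheet, truth = simulate.simulate_confounded(
            spec, config.seed, de_per_level=config.de_per_level, **gene_kwargs)
    else:
        raise ValueError(f"unknown design {config.design!r}")

    rows, adjusted_store = [], {}
    for name in ("unadjusted", *config.methods):
        row = {c: np.nan for c in REPORT_COLUMNS}
        row["method"], row["note"] = name, ""
        try:
            adjusted = apply_method(name, target, sheet, config)
            if design == "vas":
                row.update(_vas_metrics(rep1, adjusted, sheet, config))
            else:
                row.update(_aas_metrics(adjusted, sheet, truth, config))
            if keep_adjusted or out_dir is not None:
                adjusted_store[name] = adjusted
        except BatchAdjustmentError as exc:
            row["note"] = f"not applicable: {exc}"
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    report = BenchmarkReport(table=table, design=design, seed=config.seed,
                             config=config, adjusted=adjusted_store)
    if out_dir is not None:
        report.write(out_dir)
        write_sample_sheet(sheet, Path(out_dir) / "sample_sheet.tsv")
        truth.write_tsv(Path(out_dir) / "truth.tsv")
        if not keep_adjusted:
            report.adjusted = {}
    return report


def batch_size_sweep(config: BenchmarkConfig, sizes=(20, 40, 100)) -> dict:
    """Re-run the accuracy design at several batch sizes; one report each."""
    reports = {}
    for size in sizes:
        cfg = BenchmarkConfig(**{**asdict(config),
                                 "batch_layout": simulate.aas_batch_layout(size)})
        reports[size] = run_benchmark(cfg)
    return reports
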