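"""Batch-adjustment algorithms.

Four families of adjustment are implemented, all operating on log2
expression matrices and returning a matrix with unchanged gene/sample ids:

* ``mean_center`` — gene-wise per-batch mean centering (the PAMR-style
  one-way ANOVA adjustment).
* ``ratio_g`` — geometric ratio adjustment: subtract, per batch and gene,
  the mean of that batch's reference-group samples (the geometric mean on
  the raw scale is the arithmetic mean on log2).
* ``combat`` — empirical-Bayes location/scale adjustment, with a parametric
  (normal / inverse-gamma priors) and a non-parametric posterior mode.
* ``sva_adjust`` — surrogate-variable adjustment: SVD of the residual
  matrix after removing the primary biological effect, permutation-based
  selection of significant components, then regression-based removal of the
  retained surrogates while preserving the primary effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, SampleSheet, group_levels

VAR_FLOOR = 1e-8


class BatchAdjustmentError(ValueError):
    """An adjustment cannot be applied to this design."""


class ConfoundingError(BatchAdjustmentError):
    """Batch structure is confounded with the design (rank-deficient model)."""


def _batch_indicator(sheet: SampleSheet):
    batches = sheet.batches
    labels = sheet.batch.to_numpy(dtype=str)
    ind = np.stack([(labels == b).astype(float) for b in batches], axis=1)  # N x B
    return batches, ind


def mean_center(expr: ExpressionMatrix, sheet: SampleSheet,
                restore_grand_mean: bool = False) -> ExpressionMatrix:
    """Set every gene's mean within each batch to zero.

    With ``restore_grand_mean`` the gene's overall mean (weighted across
    batches) is added back, which re-anchors values on the original
    intensity scale without changing any batch contrast.
    """
    batches, ind = _batch_indicator(sheet)
    y = expr.values
    n_per = ind.sum(axis=0)
    batch_means = (y @ ind) / n_per                      # G x B
    centered = y - batch_means @ ind.T
    if restore_grand_mean:
        centered = centered + y.mean(axis=1, keepdims=True)
    return expr.with_values(centered)


def ratio_g(expr: ExpressionMatrix, sheet: SampleSheet,
            reference_group: str = "control") -> ExpressionMatrix:
    """Subtract each batch's per-gene reference-sample mean (log2 scale).

    Every batch must contain at least one sample of ``reference_group``;
    a batch without any is the classic failure mode of ratio adjustment on
    confounded designs and raises :class:`BatchAdjustmentError` naming it.
    """
    labels = sheet.batch.to_numpy(dtype=str)
    groups = sheet.group.to_numpy(dtype=str)
    y = expr.values.copy()
    for b in sheet.batches:
        in_batch = labels == b
        ref = in_batch & (groups == str(reference_group))
        if not ref.any():
            raise BatchAdjustmentError(
                f"no {reference_group!r} reference samples in batch {b!r}; "
                "ratio adjustment cannot be applied"
            )
        y[:, in_batch] -= y[:, ref].mean(axis=1, keepdims=True)
    return expr.with_values(y)


@dataclass
class CombatFit:
    """All intermediate estimates of an empirical-Bayes adjustment run."""

    batches: list
    grand_mean: np.ndarray            # per-gene standardization mean (alpha_hat)
    coef: np.ndarray                  # covariate coefficients, P x G (may be empty)
    pooled_var: np.ndarray            # per-gene pooled variance
    gamma_hat: pd.DataFrame           # raw per-batch location estimates (B x G)
    delta_hat_sq: pd.DataFrame        # raw per-batch scale estimates (B x G)
    gamma_star: pd.DataFrame          # shrunken locations
    delta_star_sq: pd.DataFrame       # shrunken scales
    gamma_bar: np.ndarray             # prior means per batch
    tau_sq: np.ndarray                # prior variances per batch
    prior_lambda: np.ndarray          # inverse-gamma shape per batch
    prior_theta: np.ndarray           # inverse-gamma scale per batch
    parametric: bool = True


def _encode_covariates(sheet: SampleSheet, covariates) -> np.ndarray:
    """Covariate design block: drop-first dummies for labels, numerics as-is."""
    cols = []
    for cov in covariates:
        if cov not in sheet.data.columns:
            raise BatchAdjustmentError(f"covariate {cov!r} not in sample sheet")
        series = sheet.data[cov]
        if pd.api.types.is_numeric_dtype(series) and not isinstance(
                series.dtype, pd.CategoricalDtype):
            cols.append(series.to_numpy(dtype=float)[:, None])
        else:
            levels = group_levels(series)
            vals = series.to_numpy(dtype=str)
            for lev in levels[1:]:
                cols.append((vals == str(lev)).astype(float)[:, None])
    if not cols:
        return np.empty((len(sheet.sample_ids), 0))
    return np.hstack(cols)


def _it_solve(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, t2: float, lam: float, th: float,
              tol: float = 1e-4, max_iter: int = 500):
    """Fixed-point iteration for the parametric posterior (one batch).

    ``z`` is the standardized data of the batch (G x n_i); returns the
    shrunken (gamma_star, delta_star_sq) vectors.
    """
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ssq = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (th + 0.5 * ssq) / (n / 2 + lam - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _np_posterior(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                  chunk: int = 256):
    """Non-parametric posterior: likelihood-weighted average over other genes.

    For gene g the posterior (gamma*, delta*^2) is the average of the other
    genes' raw estimates weighted by the normal likelihood of gene g's
    standardized batch data under those estimates.  Exact (no subsampling),
    computed in row chunks to bound memory.
    """
    G, n = z.shape
    sum_z = z.sum(axis=1)
    sum_z2 = (z ** 2).sum(axis=1)
    g_star = np.empty(G)
    d_star = np.empty(G)
    log_norm = -0.5 * n * np.log(2 * np.pi * d_hat)          # per candidate gene
    for start in range(0, G, chunk):
        stop = min(start + chunk, G)
        # rss[i, j] = sum_k (z[i, k] - g_hat[j])^2 for rows i in the chunk
        rss = (sum_z2[start:stop, None]
               - 2.0 * np.outer(sum_z[start:stop], g_hat)
               + n * (g_hat ** 2)[None, :])
        loglik = log_norm[None, :] - rss / (2.0 * d_hat[None, :])
        idx = np.arange(start, stop)
        loglik[np.arange(stop - start), idx] = -np.inf      # exclude the gene itself
        loglik -= loglik.max(axis=1, keepdims=True)
        w = np.exp(loglik)
        w /= w.sum(axis=1, keepdims=True)
        g_star[start:stop] = w @ g_hat
        d_star[start:stop] = w @ d_hat
    return g_star, d_star


def combat(expr: ExpressionMatrix, sheet: SampleSheet,
           covariates=("group",), parametric: bool = True):
    """Empirical-Bayes location/scale batch adjustment.

    Standardizes each gene by a least-squares fit on covariates plus batch
    indicators (batch coefficients constrained to a weighted sum of zero),
    shrinks the per-batch location/scale estimates toward across-gene
    priors — normal / inverse-gamma with moment-matched hyperparameters in
    parametric mode, likelihood-weighted averages of the other genes'
    estimates in non-parametric mode — and then removes the shrunken batch
    effects while restoring the protected covariate signal.

    Returns ``(adjusted_matrix, CombatFit)``.
    """
    batches, ind = _batch_indicator(sheet)
    if len(batches) < 2:
        raise BatchAdjustmentError("combat needs at least two batches")
    cov = _encode_covariates(sheet, covariates or ())
    design = np.hstack([ind, cov])                       # N x (B + P)
    n, p_full = design.shape
    if np.linalg.matrix_rank(design) < p_full:
        raise ConfoundingError(
            "design matrix is rank deficient: a covariate is confounded with "
            "batch; drop the covariate (it cannot be protected on this design)"
        )
    y = expr.values                                      # G x N
    n_per = ind.sum(axis=0)
    frac = n_per / n

    b_hat = np.linalg.solve(design.T @ design, design.T @ y.T)   # (B+P) x G
    batch_coef = b_hat[: len(batches)]                            # B x G
    cov_coef = b_hat[len(batches):]                               # P x G
    grand_mean = frac @ batch_coef                                # per-gene alpha_hat
    fitted = (design @ b_hat).T
    pooled_var = ((y - fitted) ** 2).mean(axis=1)
    pooled_var = np.maximum(pooled_var, VAR_FLOOR)

    stand_mean = grand_mean[:, None] + (cov @ cov_coef).T        # G x N
    z = (y - stand_mean) / np.sqrt(pooled_var)[:, None]

    gamma_hat = np.empty((len(batches), y.shape[0]))
    delta_hat = np.empty_like(gamma_hat)
    members = [np.flatnonzero(ind[:, i]) for i in range(len(batches))]
    for i, cols in enumerate(members):
        if cols.size < 2:
            raise BatchAdjustmentError(f"batch {batches[i]!r} has fewer than 2 samples")
        zb = z[:, cols]
        gamma_hat[i] = zb.mean(axis=1)
        delta_hat[i] = np.maximum(zb.var(axis=1, ddof=1), VAR_FLOOR)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    v = delta_hat.var(axis=1, ddof=1)
    prior_lambda = m ** 2 / v + 2.0
    prior_theta = m * (prior_lambda - 1.0)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, cols in enumerate(members):
        zb = z[:, cols]
        if parametric:
            gamma_star[i], delta_star[i] = _it_solve(
                zb, gamma_hat[i], delta_hat[i],
                gamma_bar[i], tau_sq[i], prior_lambda[i], prior_theta[i],
            )
        else:
            gamma_star[i], delta_star[i] = _np_posterior(zb, gamma_hat[i], delta_hat[i])
    delta_star = np.maximum(delta_star, VAR_FLOOR)

    adjusted = z.copy()
    for i, cols in enumerate(members):
        adjusted[:, cols] = (z[:, cols] - gamma_star[i][:, None]) / \
            np.sqrt(delta_star[i])[:, None]
    adjusted = adjusted * np.sqrt(pooled_var)[:, None] + stand_mean

    gene_ids = expr.gene_ids
    fit = CombatFit(
        batches=list(batches),
        grand_mean=grand_mean,
        coef=cov_coef,
        pooled_var=pooled_var,
        gamma_hat=pd.DataFrame(gamma_hat, index=batches, columns=gene_ids),
        delta_hat_sq=pd.DataFrame(delta_hat, index=batches, columns=gene_ids),
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=gene_ids),
        delta_star_sq=pd.DataFrame(delta_star, index=batches, columns=gene_ids),
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        prior_lambda=prior_lambda,
        prior_theta=prior_theta,
        parametric=parametric,
    )
    return expr.with_values(adjusted), fit


@dataclass
class SvaFit:
    """Result of surrogate-variable estimation."""

    n_surrogates: int
    surrogates: np.ndarray            # N x K, orthonormal columns
    p_values: np.ndarray              # permutation p-value per candidate PC
    variance_shares: np.ndarray       # observed residual-variance share per PC


def _residual_eig_shares(resid: np.ndarray) -> np.ndarray:
    """Eigenvalue shares of the residual cross-product (descending)."""
    ev = np.linalg.eigvalsh(resid.T @ resid)[::-1]
    ev = np.maximum(ev, 0.0)
    return ev / ev.sum()


def sva_adjust(expr: ExpressionMatrix, sheet: SampleSheet, primary: str = "group",
               n_perm: int = 100, alpha: float = 0.05, seed=0,
               remove: bool = True):
    """Surrogate-variable adjustment of hidden structure such as batch.

    1. Fit per-gene least squares on the primary design (intercept + the
       ``primary`` column's dummies) and form the residual matrix.
    2. Take the SVD of the residuals; each right singular vector is a
       candidate surrogate with an observed residual-variance share.
    3. Keep the leading components whose share beats a permutation null in
       which every gene's residuals are independently permuted across
       samples (row-wise permutation), stopping at the first component with
       permutation p-value above ``alpha``.
    4. With ``remove`` on, regress the retained surrogates out of the data
       in a joint fit with the primary design, so the primary effect is
       preserved; otherwise the input is returned with the fit only.

    Returns ``(adjusted_matrix, SvaFit)``; zero retained components return
    the input unchanged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable permutation null")
    series = sheet.data[primary]
    levels = group_levels(series)
    if len(levels) < 2:
        raise BatchAdjustmentError(f"primary column {primary!r} has < 2 levels")
    vals = series.to_numpy(dtype=str)
    x = np.column_stack([np.ones(len(vals))] +
                        [(vals == str(lev)).astype(float) for lev in levels[1:]])
    y = expr.values
    proj = x @ np.linalg.solve(x.T @ x, x.T)
    resid = y - y @ proj.T                                    # G x N residuals

    shares = _residual_eig_shares(resid)
    rng = np.random.default_rng(seed)
    max_k = min(resid.shape[1] - np.linalg.matrix_rank(x), len(shares))
    exceed = np.zeros(len(shares))
    for _ in range(n_perm):
        order = rng.random(resid.shape).argsort(axis=1)
        perm = np.take_along_axis(resid, order, axis=1)
        # Re-residualize: permuted rows must live in the same model-orthogonal
        # space as the observed residuals, or the null spectrum is biased.
        perm -= perm @ proj.T
        exceed += _residual_eig_shares(perm) >= shares
    p_values = (exceed + 1.0) / (n_perm + 1.0)

    k = 0
    while k < max_k and p_values[k] <= alpha:
        k += 1
    if k == 0:
        fit = SvaFit(0, np.empty((y.shape[1], 0)), p_values, shares)
        return expr.with_values(y.copy()), fit

    # Right singular vectors of the residual matrix = surrogate candidates.
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    surrogates = vt[:k].T                                     # N x k, orthonormal
    fit = SvaFit(k, surrogates, p_values, shares)
    if not remove:
        return expr.with_values(y.copy()), fit

    design = np.hstack([x, surrogates])
    coef = np.linalg.solve(design.T @ design, design.T @ y.T)  # (p+k) x G
    sv_part = (surrogates @ coef[x.shape[1]:]).T
    return expr.with_values(y - sv_part), fit
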