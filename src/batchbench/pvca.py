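"""Principal variance component analysis (PVCA).

PVCA attributes overall expression variance to named experimental factors
in two steps: a PCA in sample space on gene-standardized data, followed by
a random-effects variance-component fit of each retained principal
component on the factors (and, optionally, their pairwise interactions).
Per-PC variance fractions are then weighted by the PC eigenvalues and
renormalized, yielding one proportion per factor plus a residual.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, SampleSheet

COMPONENT_FLOOR = 1e-12


@dataclass
class PVCAResult:
    """Eigenvalue-weighted variance attribution.

    weighted_proportions maps every factor (plus ``"resid"``) to its share
    of the modeled variance; shares are nonnegative and sum to one.
    """

    retained_pc_count: int
    eigenvalues: np.ndarray
    per_pc_components: pd.DataFrame       # factors (+resid) x retained PCs
    weighted_proportions: dict

    def to_series(self) -> pd.Series:
        return pd.Series(self.weighted_proportions, name="weighted_proportion")


def _factor_design(labels: np.ndarray) -> np.ndarray:
    levels = list(dict.fromkeys(labels))
    return np.stack([(labels == lev).astype(float) for lev in levels], axis=1)


def estimate_variance_components(y, factor_assignments: dict, tol: float = 1e-6,
                                 max_iter: int = 1000) -> dict:
    """EM-REML variance components for crossed random intercepts.

    Fits ``y = mu + sum_f Z_f u_f + e`` with ``u_f ~ N(0, s_f^2 I)`` and
    returns ``{factor: s_f^2, ..., "resid": s_e^2}``.  Components are
    nonnegative (clipped at a small floor); a factor with a single level is
    assigned component 0 with a warning.  Convergence is declared when the
    relative change of the REML log-likelihood drops below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = y.size

    active, degenerate = {}, []
    for name, labels in factor_assignments.items():
        labels = np.asarray(labels, dtype=str)
        if labels.size != n:
            raise ValueError(f"factor {name!r} has wrong length")
        if len(set(labels)) < 2:
            warnings.warn(f"factor {name!r} has a single level; component set to 0")
            degenerate.append(name)
        else:
            active[name] = _factor_design(labels)

    total = y.var(ddof=1) if n > 1 else 0.0
    if total <= COMPONENT_FLOOR:
        out = {name: 0.0 for name in factor_assignments}
        out["resid"] = 0.0
        return out

    names = list(active)
    x = np.ones((n, 1))
    zzt = {f: z @ z.T for f, z in active.items()}
    s = {f: total / (len(names) + 1) for f in names}
    s_e = total / (len(names) + 1)
    prev_ll = None
    for _ in range(max_iter):
        v = s_e * np.eye(n)
        for f in names:
            v += s[f] * zzt[f]
        vinv = np.linalg.inv(v)
        xtvx = x.T @ vinv @ x
        p = vinv - vinv @ x @ np.linalg.solve(xtvx, x.T @ vinv)
        py = p @ y
        for f in names:
            z = active[f]
            q = z.shape[1]
            quad = py @ zzt[f] @ py
            trace = np.trace(z.T @ p @ z)
            s[f] = max(s[f] + (s[f] ** 2 / q) * (quad - trace), COMPONENT_FLOOR)
        s_e = max(s_e + (s_e ** 2 / (n - 1)) * (py @ py - np.trace(p)), COMPONENT_FLOOR)

        sign, logdet_v = np.linalg.slogdet(v)
        ll = -0.5 * (logdet_v + np.linalg.slogdet(xtvx)[1] + y @ py)
        if prev_ll is not None and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            break
        prev_ll = ll

    out = {f: (0.0 if s[f] <= 2 * COMPONENT_FLOOR else float(s[f])) for f in names}
    for name in degenerate:
        out[name] = 0.0
    out["resid"] = float(s_e)
    return out


def _interaction_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array([f"{x}*{y}" for x, y in zip(a, b)])


def run_pvca(expr: ExpressionMatrix, sheet: SampleSheet, factors=("batch", "group"),
             include_interactions: bool = True, threshold: float = 0.6) -> PVCAResult:
    """Attribute expression variance to factors, eigenvalue-weighted.

    Genes are standardized to mean 0 / s.d. 1 before the sample-space PCA,
    so the attribution is invariant to gene-wise rescaling.  The smallest
    set of leading PCs whose cumulative eigenvalue share reaches
    ``threshold`` is retained; each retained PC is decomposed by
    :func:`estimate_variance_components` on the requested factors plus, if
    asked, all their pairwise interactions.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    missing = [f for f in factors if f not in sheet.data.columns]
    if missing:
        raise ValueError(f"factors not in sample sheet: {missing}")
    n = expr.n_samples
    labels = {f: sheet.data[f].to_numpy(dtype=str) for f in factors}
    assignments = dict(labels)
    if include_interactions:
        flist = list(factors)
        for i in range(len(flist)):
            for j in range(i + 1, len(flist)):
                name = f"{flist[i]}x{flist[j]}"
                assignments[name] = _interaction_labels(labels[flist[i]],
                                                        labels[flist[j]])

    y = expr.values
    sd = y.std(axis=1, ddof=1, keepdims=True)
    sd = np.maximum(sd, COMPONENT_FLOOR)
    z = (y - y.mean(axis=1, keepdims=True)) / sd           # gene-standardized

    cov = (z.T @ z) / (expr.n_genes - 1)                   # sample-by-sample
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    shares = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(shares, threshold) + 1)
    k = min(k, n)

    comp_rows = {f: np.zeros(k) for f in assignments}
    comp_rows["resid"] = np.zeros(k)
    for pc in range(k):
        comps = estimate_variance_components(evecs[:, pc], assignments)
        for f, val in comps.items():
            comp_rows[f][pc] = val

    table = pd.DataFrame(comp_rows, index=[f"PC{i + 1}" for i in range(k)]).T
    per_pc_total = table.sum(axis=0).to_numpy()
    per_pc_frac = table.to_numpy() / np.maximum(per_pc_total, COMPONENT_FLOOR)
    w = evals[:k] / evals[:k].sum()
    weighted = per_pc_frac @ w
    weighted = weighted / weighted.sum()
    proportions = dict(zip(table.index, weighted))
    return PVCAResult(
        retained_pc_count=k,
        eigenvalues=evals[:k],
        per_pc_components=table,
        weighted_proportions=proportions,
    )
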