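"""Synthetic expression-matrix generators under a location/scale batch model.

The generative model for gene ``g`` of sample ``j`` run in batch ``i`` is

    Y_ijg = alpha_g + x_j * beta_g + gamma_ig + delta_ig * eps_jg,
    eps_jg ~ Normal(0, sigma_g^2),

where ``alpha_g`` is the baseline log2 intensity, ``beta_g`` the group
(log2 fold-change) effect carried by design indicator ``x_j``, ``gamma_ig``
an additive per-batch shift and ``delta_ig`` a positive multiplicative
inflation of the measurement noise.  Batch shifts are drawn from a normal
distribution and squared noise scales from an inverse gamma.

Three fixed study designs are provided:

* ``simulate_vas`` — the variation-assessment design: 100 samples
  (65 "Profile1", 35 "Profile2"), 1,000 genes all differentially expressed,
  measured twice: once as a single clean batch and once split over two
  batches carrying batch effects.
* ``simulate_aas`` — the accuracy-assessment design: 10,000 genes in 100
  cases and 100 controls, 1,200 genes differentially expressed at 12 log2
  fold-change levels (100 genes per level), samples spread over batches
  with deliberately imbalanced case/control ratios.
* ``simulate_confounded`` — the pathological variant with every case in one
  batch and every control in the other, so batch and biology are
  inseparable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix, SampleSheet, group_levels

#: The 12 nominal log2 fold-change levels (fold changes -3 ... -1.1, 1.1 ... 3).
FOLD_CHANGE_LEVELS = (
    -1.58, -1.32, -1.0, -0.58, -0.26, -0.14,
    0.14, 0.26, 0.58, 1.0, 1.32, 1.58,
)

#: Additive batch-shift s.d. (log2 units).  Calibrated once by simulation so
#: that the batch share of overall variance in the default VAS design is
#: about 30%, the one quantitative anchor the benchmark is built around.
DEFAULT_GAMMA_SD = 0.53

#: Inverse-gamma parameters for the squared noise-scale factor delta^2:
#: shape 8 and scale 8.05 give E[delta^2] = 8.05/7 ~ 1.15 with mild spread.
DEFAULT_DELTA_SHAPE = 8.0
DEFAULT_DELTA_SCALE = 8.05

#: Detection margin used to set per-gene noise: sigma_g is chosen so that a
#: two-sample comparison on clean data has expected t of about Z_STAR, i.e.
#: genes are genuinely differentially expressed but not trivially so.
Z_STAR = 3.3

#: Baseline log2-intensity distribution (typical post-summarization range).
ALPHA_MEAN = 7.0
ALPHA_SD = 2.0


class SimulationError(ValueError):
    """Inconsistent simulation parameters or design layout."""


@dataclass(frozen=True)
class BatchEffectSpec:
    """Distributional settings for the injected batch effects.

    gamma_sd
        Standard deviation (log2 units) of the normal distribution the
        additive shifts ``gamma_ig`` are drawn from.
    delta_shape, delta_scale
        Shape/scale of the inverse-gamma distribution of ``delta_ig^2``.
        Shape must exceed 2 so the distribution has finite variance.
    additive, multiplicative
        Per-effect toggles; switching one off fixes gamma at 0 or delta at 1.
    """

    gamma_sd: float = DEFAULT_GAMMA_SD
    delta_shape: float = DEFAULT_DELTA_SHAPE
    delta_scale: float = DEFAULT_DELTA_SCALE
    additive: bool = True
    multiplicative: bool = True

    def __post_init__(self) -> None:
        if self.gamma_sd < 0:
            raise SimulationError("gamma_sd must be >= 0")
        if self.delta_shape <= 2 or self.delta_scale <= 0:
            raise SimulationError("need delta_shape > 2 and delta_scale > 0")
        mean_delta_sq = self.delta_scale / (self.delta_shape - 1)
        if not 0.25 < mean_delta_sq < 4:
            raise SimulationError(
                f"E[delta^2] = {mean_delta_sq:.3f} outside the sane range (0.25, 4)"
            )

    @classmethod
    def none(cls) -> "BatchEffectSpec":
        """A spec that injects no batch effect at all."""
        return cls(gamma_sd=0.0, additive=False, multiplicative=False)

    def draw(self, n_batches: int, n_genes: int, rng: np.random.Generator):
        """Draw (gamma, delta) grids of shape (n_batches, n_genes)."""
        if self.additive and self.gamma_sd > 0:
            gamma = rng.normal(0.0, self.gamma_sd, size=(n_batches, n_genes))
        else:
            gamma = np.zeros((n_batches, n_genes))
        if self.multiplicative:
            delta_sq = stats.invgamma.rvs(
                self.delta_shape, scale=self.delta_scale,
                size=(n_batches, n_genes), random_state=rng,
            )
            delta = np.sqrt(delta_sq)
        else:
            delta = np.ones((n_batches, n_genes))
        return gamma, delta


@dataclass
class LSModelParams:
    """Fully specified location/scale model parameters.

    ``gamma`` and ``delta`` map each batch label to a per-gene vector;
    ``treatment_group`` names the group level that carries ``beta`` (defaults
    to the second level of the sheet's group column).
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    gamma: Mapping[str, np.ndarray]
    delta: Mapping[str, np.ndarray]
    treatment_group: str | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        g = self.alpha.size
        if self.beta.size != g or self.sigma.size != g:
            raise SimulationError("alpha, beta, sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise SimulationError("sigma_g must be positive")
        self.gamma = {str(b): np.asarray(v, dtype=float) for b, v in self.gamma.items()}
        self.delta = {str(b): np.asarray(v, dtype=float) for b, v in self.delta.items()}
        if set(self.gamma) != set(self.delta):
            raise SimulationError("gamma and delta must cover the same batches")
        for b in self.gamma:
            if self.gamma[b].size != g or self.delta[b].size != g:
                raise SimulationError(f"batch {b!r} effect vectors must have length {g}")
            if np.any(self.delta[b] <= 0):
                raise SimulationError(f"delta must be positive (batch {b!r})")

    @property
    def n_genes(self) -> int:
        return self.alpha.size


@dataclass
class SimulationTruth:
    """Ground truth emitted with every simulated data set.

    genes
        Frame indexed by gene id with ``is_de`` and ``nominal_log2_fc``.
    samples
        Frame indexed by sample id with batch/group assignments.
    gamma, delta
        Realized batch-effect draws, batches x genes.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    gamma: pd.DataFrame
    delta: pd.DataFrame

    def __post_init__(self) -> None:
        null = ~self.genes["is_de"].to_numpy(dtype=bool)
        if np.any(self.genes.loc[null, "nominal_log2_fc"] != 0.0):
            raise SimulationError("null genes must have nominal_log2_fc == 0")

    @property
    def n_de(self) -> int:
        return int(self.genes["is_de"].sum())

    def write_tsv(self, path) -> None:
        out = self.genes.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def detection_sigma(beta: np.ndarray, n1: int, n2: int, z_star: float = Z_STAR) -> np.ndarray:
    """Noise s.d. that keeps an effect of size beta detectable but non-trivial.

    sigma_g = |beta_g| * sqrt(n1 n2 / (n1 + n2)) / z*, so the expected
    two-sample t statistic on clean data is z* for every DE gene.
    """
    return np.abs(np.asarray(beta, dtype=float)) * np.sqrt(n1 * n2 / (n1 + n2)) / z_star


def sample_ls_model(params: LSModelParams, sheet: SampleSheet, seed) -> ExpressionMatrix:
    """Draw one expression matrix from the location/scale model.

    The design indicator is 1 for samples in ``params.treatment_group``
    (default: the second group level) and 0 otherwise.  The same seed always
    reproduces the same matrix.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    batches = sheet.batch.to_numpy(dtype=str)
    unknown = sorted(set(batches) - set(params.gamma))
    if unknown:
        raise SimulationError(f"sheet has batches without model parameters: {unknown}")
    levels = group_levels(sheet.group)
    treated = params.treatment_group
    if treated is None:
        if len(levels) != 2:
            raise SimulationError("treatment_group required unless the sheet has 2 groups")
        treated = levels[-1]
    x = (sheet.group.to_numpy(dtype=str) == str(treated)).astype(float)

    g, n = params.n_genes, len(sheet.sample_ids)
    gamma = np.column_stack([params.gamma[b] for b in batches])          # G x N
    delta = np.column_stack([params.delta[b] for b in batches])
    eps = rng.standard_normal((g, n)) * params.sigma[:, None]
    values = params.alpha[:, None] + np.outer(params.beta, x) + gamma + delta * eps
    gene_ids = [f"g{i + 1:05d}" for i in range(g)]
    return ExpressionMatrix(gene_ids, sheet.sample_ids, values)


def _spawn(seed, n: int):
    """Split one master seed into independent per-stage generators."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _fold_changes(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Cycle the 12-level grid over n_genes genes, in shuffled gene order."""
    reps = int(np.ceil(n_genes / len(FOLD_CHANGE_LEVELS)))
    beta = np.tile(FOLD_CHANGE_LEVELS, reps)[:n_genes].astype(float)
    rng.shuffle(beta)
    return beta


def _truth_frames(gene_ids, is_de, beta, sheet: SampleSheet, gamma, delta, batch_order):
    genes = pd.DataFrame(
        {"is_de": np.asarray(is_de, dtype=bool), "nominal_log2_fc": beta}, index=gene_ids
    )
    gamma_df = pd.DataFrame(gamma, index=batch_order, columns=gene_ids)
    delta_df = pd.DataFrame(delta, index=batch_order, columns=gene_ids)
    return SimulationTruth(genes, sheet.data.copy(), gamma_df, delta_df)


def simulate_vas(spec: BatchEffectSpec | None = None, seed=0, n_genes: int = 1000):
    """Variation-assessment design: technical duplicates, 1 vs 2 batches.

    Returns ``(replicate1, replicate2, sheet, truth)``.  Both replicates
    share alpha, beta, sigma and the 65/35 profile assignment; replicate 1
    is generated as a single clean batch (its unidentifiable common batch
    shift is absorbed into alpha), replicate 2 is split over two batches
    that carry the injected batch effects.  The sheet's ``batch`` column
    refers to replicate 2, which is the matrix batch adjustment acts on.
    """
    spec = spec or BatchEffectSpec()
    rng_gene, rng_assign, rng_batch, rng_n1, rng_n2 = _spawn(seed, 5)

    n1, n2 = 65, 35
    beta = _fold_changes(n_genes, rng_gene)
    alpha = rng_gene.normal(ALPHA_MEAN, ALPHA_SD, size=n_genes)
    sigma = detection_sigma(beta, n1, n2)

    sample_ids = [f"S{i + 1:03d}" for i in range(n1 + n2)]
    group = ["Profile1"] * n1 + ["Profile2"] * n2
    # Stratified 50/50 batch split for replicate 2, so batch is (close to)
    # orthogonal to profile rather than confounded with it.
    batch = np.empty(n1 + n2, dtype=object)
    for g_level, idx in (("Profile1", np.arange(n1)), ("Profile2", np.arange(n1, n1 + n2))):
        perm = rng_assign.permutation(idx)
        half = len(perm) // 2
        batch[perm[:half]] = "B1"
        batch[perm[half:]] = "B2"
    sheet = SampleSheet(pd.DataFrame(
        {"batch": batch,
         "group": pd.Categorical(group, categories=["Profile1", "Profile2"])},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    gamma, delta = spec.draw(2, n_genes, rng_batch)
    clean = {"B1": np.zeros(n_genes), "B2": np.zeros(n_genes)}
    unit = {"B1": np.ones(n_genes), "B2": np.ones(n_genes)}
    params1 = LSModelParams(alpha, beta, sigma, clean, unit, treatment_group="Profile2")
    params2 = LSModelParams(
        alpha, beta, sigma,
        {"B1": gamma[0], "B2": gamma[1]},
        {"B1": delta[0], "B2": delta[1]},
        treatment_group="Profile2",
    )
    rep1 = sample_ls_model(params1, sheet, rng_n1)
    rep2 = sample_ls_model(params2, sheet, rng_n2)
    truth = _truth_frames(rep1.gene_ids, np.ones(n_genes, bool), beta, sheet,
                          gamma, delta, ["B1", "B2"])
    return rep1, rep2, sheet, truth


#: Default batch layout for the accuracy-assessment design: five batches of
#: 40 samples, two of them with deliberately reversed 10/30 and 30/10
#: case/control ratios, the rest balanced.
DEFAULT_AAS_LAYOUT = (
    (40, 10, 30),
    (40, 30, 10),
    (40, 20, 20),
    (40, 20, 20),
    (40, 20, 20),
)


def aas_batch_layout(batch_size: int):
    """Layout with the given batch size, keeping 100 cases + 100 controls.

    The first two batches keep the reversed 25%/75% case fraction of the
    default design; remaining batches are balanced.
    """
    if 200 % batch_size:
        raise SimulationError("batch_size must divide 200")
    n_batches = 200 // batch_size
    if n_batches < 2 or batch_size % 4:
        raise SimulationError("need >= 2 batches and batch_size divisible by 4")
    quarter = batch_size // 4
    layout = [(batch_size, quarter, batch_size - quarter),
              (batch_size, batch_size - quarter, quarter)]
    layout += [(batch_size, batch_size // 2, batch_size // 2)] * (n_batches - 2)
    return tuple(layout)


def simulate_aas(
    batch_layout: Sequence[tuple] | None = None,
    spec: BatchEffectSpec | None = None,
    seed=0,
    n_genes: int = 10_000,
    de_per_level: int = 100,
):
    """Accuracy-assessment design; returns ``(expr, sheet, truth)``.

    ``batch_layout`` is a sequence of ``(batch_size, n_cases, n_controls)``
    triples summing to 100 cases and 100 controls.  Exactly
    ``de_per_level * 12`` genes are differentially expressed, with the
    log2 fold-change grid allocated ``de_per_level`` genes per level.
    """
    spec = spec or BatchEffectSpec()
    layout = tuple(batch_layout) if batch_layout is not None else DEFAULT_AAS_LAYOUT
    for size, ncase, nctrl in layout:
        if ncase + nctrl != size or min(ncase, nctrl) < 0:
            raise SimulationError(f"inconsistent layout entry {(size, ncase, nctrl)}")
    total_cases = sum(c for _, c, _ in layout)
    total_controls = sum(c for _, _, c in layout)
    if total_cases != 100 or total_controls != 100:
        raise SimulationError(
            f"layout sums to {total_cases} cases / {total_controls} controls; need 100/100"
        )
    n_de = de_per_level * len(FOLD_CHANGE_LEVELS)
    if n_de > n_genes:
        raise SimulationError("more DE genes than genes")

    rng_gene, rng_batch, rng_noise = _spawn(seed, 3)

    beta = np.zeros(n_genes)
    de_idx = rng_gene.choice(n_genes, size=n_de, replace=False)
    beta[de_idx] = np.repeat(FOLD_CHANGE_LEVELS, de_per_level)
    is_de = beta != 0.0
    alpha = rng_gene.normal(ALPHA_MEAN, ALPHA_SD, size=n_genes)
    sigma = np.empty(n_genes)
    sigma[is_de] = detection_sigma(beta[is_de], total_cases, total_controls)
    # Null genes: resample noise levels from the empirical spread of DE genes.
    sigma[~is_de] = rng_gene.choice(sigma[is_de], size=n_genes - n_de, replace=True)

    rows = []
    for i, (size, ncase, nctrl) in enumerate(layout, start=1):
        rows += [(f"B{i}", "case")] * ncase + [(f"B{i}", "control")] * nctrl
    sample_ids = [f"S{i + 1:03d}" for i in range(len(rows))]
    sheet = SampleSheet(pd.DataFrame(
        {"batch": [b for b, _ in rows],
         "group": pd.Categorical([g for _, g in rows], categories=["control", "case"])},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    batch_order = [f"B{i + 1}" for i in range(len(layout))]
    gamma, delta = spec.draw(len(layout), n_genes, rng_batch)
    params = LSModelParams(
        alpha, beta, sigma,
        {b: gamma[i] for i, b in enumerate(batch_order)},
        {b: delta[i] for i, b in enumerate(batch_order)},
        treatment_group="case",
    )
    expr = sample_ls_model(params, sheet, rng_noise)
    truth = _truth_frames(expr.gene_ids, is_de, beta, sheet, gamma, delta, batch_order)
    return expr, sheet, truth


def simulate_confounded(spec: BatchEffectSpec | None = None, seed=0,
                        n_genes: int = 10_000, de_per_level: int = 100):
    """Fully confounded design: all cases in B1, all controls in B2."""
    return simulate_aas(
        batch_layout=((100, 100, 0), (100, 0, 100)),
        spec=spec, seed=seed, n_genes=n_genes, de_per_level=de_per_level,
    )
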