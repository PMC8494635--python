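"""Synthetic data with the statistical structure each analysis assumes.

Three generators:

* :func:`simulate_atlas` — a multi-cluster count matrix with disjoint marker
  gene blocks, per-cluster lobule compositions (uniform or enriched) and
  replicate labels, for the composition pipeline.
* :func:`simulate_trajectory_pair` — expression following a logistic
  activation along a latent pseudotime, steep (discrete) or shallow
  (continuous), for the continuity metric.
* :func:`simulate_spatial_expression` — region-level summaries with a
  Poisson-like background and a subset of genes carrying extra cross-region
  variance, for the logVMR selector.

Counts use a negative-binomial (gamma-Poisson) model by default; dispersion
phi gives variance mu + phi mu^2.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellAnnotation, ExpressionMatrix, NormalizedMatrix, ValidationError

__all__ = [
    "ClusterSpec",
    "AtlasSimConfig",
    "TrajectorySimConfig",
    "simulate_atlas",
    "simulate_trajectory_pair",
    "simulate_spatial_expression",
]

DEFAULT_DISPERSION = 0.2


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts with mean mu and variance mu + dispersion*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


@dataclass(frozen=True)
class ClusterSpec:
    """One simulated cluster: name, coarse type, size, lobule composition."""

    name: str
    outer_type: str
    n_cells: int
    lobule_composition: tuple

    def __post_init__(self) -> None:
        comp = np.asarray(self.lobule_composition, dtype=float)
        if comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
            raise ValidationError(
                f"cluster {self.name}: lobule_composition must be a probability vector"
            )
        if self.n_cells < 1:
            raise ValidationError(f"cluster {self.name}: n_cells must be positive")


@dataclass
class AtlasSimConfig:
    n_genes: int = 100
    clusters: list = field(default_factory=list)
    n_regions: int = 16
    replicate_proportions: tuple = (0.5, 0.5)
    marker_effect: float = 8.0
    n_marker_genes: int = 10
    base_rate: float = 0.5
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0

    def __post_init__(self) -> None:
        rep = np.asarray(self.replicate_proportions, dtype=float)
        if rep.min() < 0 or not np.isclose(rep.sum(), 1.0):
            raise ValidationError("replicate_proportions must be a probability vector")
        if self.n_regions < 1 or self.n_genes < 1:
            raise ValidationError("n_genes and n_regions must be positive")
        for c in self.clusters:
            if len(c.lobule_composition) != self.n_regions:
                raise ValidationError(
                    f"cluster {c.name}: composition has {len(c.lobule_composition)} "
                    f"entries but n_regions={self.n_regions}"
                )
        if self.n_marker_genes * len(self.clusters) > self.n_genes:
            raise ValidationError("not enough genes for disjoint marker blocks")


def simulate_atlas(config: AtlasSimConfig) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Draw a clustered atlas: counts plus cluster/lobule/replicate labels.

    Each cluster gets a disjoint block of ``n_marker_genes`` marker genes
    with mean ``marker_effect * base_rate``; background genes have mean
    ``base_rate``.  Lobule and replicate labels are drawn independently per
    cell from the configured probability vectors.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = np.array([f"gene_{i:05d}" for i in range(config.n_genes)], dtype=object)
    lobules = [f"lobule_{j + 1:02d}" for j in range(config.n_regions)]
    replicates = [f"rep_{r + 1}" for r in range(len(config.replicate_proportions))]

    blocks, rows = [], []
    cell_counter = 0
    for ci, cl in enumerate(config.clusters):
        mu = np.full(config.n_genes, config.base_rate)
        lo = ci * config.n_marker_genes
        mu[lo: lo + config.n_marker_genes] *= config.marker_effect
        counts = _nb_draw(
            rng, np.broadcast_to(mu[:, None], (config.n_genes, cl.n_cells)).copy(),
            config.dispersion,
        )
        blocks.append(counts)
        lob_idx = rng.choice(config.n_regions, size=cl.n_cells,
                             p=np.asarray(cl.lobule_composition, float))
        rep_idx = rng.choice(len(replicates), size=cl.n_cells,
                             p=np.asarray(config.replicate_proportions, float))
        for j in range(cl.n_cells):
            rows.append((f"cell_{cell_counter:07d}", cl.name, cl.outer_type,
                         lobules[lob_idx[j]], replicates[rep_idx[j]]))
            cell_counter += 1

    values = np.concatenate(blocks, axis=1)
    ann = CellAnnotation(pd.DataFrame(
        rows, columns=["cell_id", "cluster", "outer_type", "lobule", "replicate"]
    ))
    expr = ExpressionMatrix(values, gene_ids, ann.cell_ids.copy())
    return expr, ann


class TrajectorySimConfig:
    """Two populations joined by a latent pseudotime t ~ Uniform(0, 1).

    Gene g has mean a_g + d_g / (1 + exp(-b_g (t - x0_g))): steepness b
    controls discreteness (b=0 gives a flat, trajectory-independent gene),
    d is the dynamic range.  Per-gene parameters accept scalars (broadcast)
    or length-n_genes arrays.  ``count_model='gaussian'`` adds N(0, noise_sd)
    noise to the mean (exact parameter-recovery mode); ``'negative_binomial'``
    draws NB counts around the (positive) mean.
    """

    def __init__(self, n_cells=1000, n_genes=50, steepness=8.0, midpoint=0.5,
                 baseline=0.0, dynamic_range=1.0, noise_sd=0.25,
                 count_model="gaussian", dispersion=DEFAULT_DISPERSION,
                 time_sampling="uniform", seed=0):
        self.n_cells = int(n_cells)
        self.n_genes = int(n_genes)
        self.steepness = np.broadcast_to(np.asarray(steepness, float), (self.n_genes,)).copy()
        self.midpoint = np.broadcast_to(np.asarray(midpoint, float), (self.n_genes,)).copy()
        self.baseline = np.broadcast_to(np.asarray(baseline, float), (self.n_genes,)).copy()
        self.dynamic_range = np.broadcast_to(
            np.asarray(dynamic_range, float), (self.n_genes,)).copy()
        self.noise_sd = float(noise_sd)
        self.count_model = count_model
        self.dispersion = float(dispersion)
        self.time_sampling = time_sampling
        self.seed = int(seed)
        if time_sampling not in ("uniform", "grid"):
            raise ValidationError(f"unknown time_sampling {time_sampling!r}")
        if (self.steepness < 0).any():
            raise ValidationError("steepness must be non-negative")
        if ((self.midpoint < 0) | (self.midpoint > 1)).any():
            raise ValidationError("midpoint must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if count_model not in ("gaussian", "negative_binomial"):
            raise ValidationError(f"unknown count_model {count_model!r}")


def simulate_trajectory_pair(
    config: TrajectorySimConfig,
) -> tuple[NormalizedMatrix, np.ndarray, pd.DataFrame]:
    """Simulate a population pair along a latent pseudotime.

    Returns (matrix, true pseudotime per cell, per-gene truth table with
    columns steepness/midpoint/baseline/dynamic_range).  With the gaussian
    model the matrix holds the logistic mean plus noise directly; with the
    negative-binomial model it holds integer counts (as a NormalizedMatrix
    wrapper is not meaningful for counts, an ExpressionMatrix is returned).
    """
    rng = np.random.default_rng(config.seed)
    if config.time_sampling == "grid":
        # evenly spaced latent times: rank/N equals t exactly, so noise-free
        # fits can recover steepness without empirical-quantile distortion
        t = np.arange(1, config.n_cells + 1) / config.n_cells
        rng.shuffle(t)
    else:
        t = rng.uniform(0.0, 1.0, size=config.n_cells)
    b = config.steepness[:, None]
    x0 = config.midpoint[:, None]
    a = config.baseline[:, None]
    d = config.dynamic_range[:, None]
    mean = a + d / (1.0 + np.exp(-b * (t[None, :] - x0)))

    gene_ids = np.array([f"gene_{i:05d}" for i in range(config.n_genes)], dtype=object)
    cell_ids = np.array([f"cell_{j:06d}" for j in range(config.n_cells)], dtype=object)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "steepness": config.steepness,
        "midpoint": config.midpoint,
        "baseline": config.baseline,
        "dynamic_range": config.dynamic_range,
    })

    if config.count_model == "gaussian":
        values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
        mat = NormalizedMatrix(values, gene_ids, cell_ids,
                               normalization_record="simulated logistic + gaussian noise")
    else:
        counts = _nb_draw(rng, np.maximum(mean, 1e-9), config.dispersion)
        mat = ExpressionMatrix(counts, gene_ids, cell_ids)
    return mat, t, truth


def simulate_spatial_expression(
    n_genes: int = 1000,
    n_regions: int = 16,
    frac_spatial: float = 0.0,
    effect_sd: float = 0.0,
    mean_log_mu: float = 3.0,
    sd_log_mu: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Region-level expression summaries with an optional spatial subset.

    Null genes: per-gene mean mu_g ~ LogNormal(mean_log_mu, sd_log_mu) and
    region summaries x_gj ~ Poisson(mu_g), so the index of dispersion sits
    near 1 for every gene regardless of its mean and the logVMR distribution
    is unimodal and near-symmetric about its mode.  Spatial genes (a
    ``frac_spatial`` fraction) multiply mu_g by exp(N(0, effect_sd)) per
    region before the Poisson draw, inflating cross-region variance.
    Returns (genes x regions means, boolean truth flags).
    """
    if n_regions < 2:
        raise ValidationError("n_regions must be >= 2")
    if not 0.0 <= frac_spatial <= 1.0:
        raise ValidationError("frac_spatial must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    mu = rng.lognormal(mean_log_mu, sd_log_mu, size=n_genes)
    n_spatial = int(round(frac_spatial * n_genes))
    flags = np.zeros(n_genes, dtype=bool)
    flags[rng.choice(n_genes, size=n_spatial, replace=False)] = True

    lam = np.broadcast_to(mu[:, None], (n_genes, n_regions)).copy()
    if effect_sd > 0 and n_spatial:
        lam[flags] *= np.exp(rng.normal(0.0, effect_sd, size=(n_spatial, n_regions)))
    x = rng.poisson(lam).astype(float)
    means = pd.DataFrame(x, index=gene_ids,
                         columns=[f"region_{j + 1:02d}" for j in range(n_regions)])
    return means, pd.Series(flags, index=gene_ids, name="is_spatial")
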