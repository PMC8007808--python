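"""Synthetic datasets with planted co-expression modules and wired traits.

A dataset consists of an expression matrix whose non-background genes load
on per-module latent factors, a trait table whose traits are linear
combinations of a subset of those factors plus covariates, and a matching
gene-set collection.  Ground truth is returned alongside so downstream
stages can be tested for recovery.

All randomness flows through a single ``numpy`` generator seeded from the
configuration.  Draws are consumed in a fixed, documented order (factors,
loadings, expression noise, covariates, trait noise, in that sequence) so
equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    COVARIATE_NAMES,
    DEFAULT_TRAIT_GROUPS,
    DEFAULT_TRAITS,
    ConfigurationError,
    ExpressionMatrix,
    TraitTable,
)
from .enrichment import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "default_trait_effects",
    "generate_dataset",
    "generate_gene_sets",
    "compute_mineral_content",
]


def default_trait_effects(
    n_modules: int, trait_names: tuple[str, ...] = DEFAULT_TRAITS
) -> np.ndarray:
    """Default trait-effect matrix (traits x modules).

    Module 0 is a dual-disease driver (two atherosclerosis and two
    osteoporosis traits), module 1 is osteoporosis-only, any further
    modules are null.  Effect size 0.3 throughout.
    """
    gamma = np.zeros((len(trait_names), n_modules))
    name_to_row = {t: i for i, t in enumerate(trait_names)}
    if n_modules >= 1:
        for t in ("CIMTavg", "CIMTmax", "DRToBMC", "TSCoBMC"):
            if t in name_to_row:
                gamma[name_to_row[t], 0] = 0.3
    if n_modules >= 2:
        for t in ("DRTrD", "DTToBMC"):
            if t in name_to_row:
                gamma[name_to_row[t], 1] = 0.3
    return gamma


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_samples
        Number of simulated participants (>= 10).
    module_sizes
        Genes per planted module; all >= 1.
    n_background
        Pure-noise genes with no module membership.
    loading_range
        Interval within (0, 1] from which gene loadings are drawn uniformly.
    noise_sd
        Residual SD of gene expression around its factor component.
    trait_effects
        traits x modules matrix of factor->trait effects (``None`` uses
        :func:`default_trait_effects`).
    covariate_effects
        traits x covariates matrix of (standardised) covariate->trait
        effects; default all zero.
    factor_covariate_loadings
        Optional modules x covariates matrix: when nonzero, module factors
        are partially driven by standardised covariates (used to construct
        confounded scenarios); residual factor variance is rescaled so each
        factor keeps unit variance.
    trait_noise_sd
        SD of the trait residual.
    seed
        Seed of the single RNG stream used for everything.
    """

    n_samples: int = 500
    module_sizes: tuple[int, ...] = (50, 30, 20)
    n_background: int = 1400
    loading_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 1.0
    trait_effects: np.ndarray | None = None
    covariate_effects: np.ndarray | None = None
    factor_covariate_loadings: np.ndarray | None = None
    trait_noise_sd: float = 1.0
    seed: int = 0
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    trait_groups: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_GROUPS)
    )

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ConfigurationError("n_samples must be >= 10")
        if len(self.module_sizes) == 0:
            raise ConfigurationError("module_sizes must be non-empty")
        if any(int(m) < 1 for m in self.module_sizes):
            raise ConfigurationError("module sizes must all be >= 1")
        if self.n_background < 0:
            raise ConfigurationError("n_background must be >= 0")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("loading_range must lie within (0, 1]")
        if self.noise_sd <= 0 or self.trait_noise_sd <= 0:
            raise ConfigurationError("noise SDs must be positive")
        gamma = self.resolved_trait_effects()
        if gamma.shape != (len(self.trait_names), len(self.module_sizes)):
            raise ConfigurationError(
                f"trait_effects must be {len(self.trait_names)} x "
                f"{len(self.module_sizes)}, got {gamma.shape}"
            )

    def resolved_trait_effects(self) -> np.ndarray:
        if self.trait_effects is None:
            return default_trait_effects(len(self.module_sizes), self.trait_names)
        return np.asarray(self.trait_effects, dtype=float)

    def resolved_covariate_effects(self) -> np.ndarray:
        if self.covariate_effects is None:
            return np.zeros((len(self.trait_names), len(COVARIATE_NAMES)))
        delta = np.asarray(self.covariate_effects, dtype=float)
        if delta.shape != (len(self.trait_names), len(COVARIATE_NAMES)):
            raise ConfigurationError(
                f"covariate_effects must be {len(self.trait_names)} x "
                f"{len(COVARIATE_NAMES)}, got {delta.shape}"
            )
        return delta


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset.

    ``gene_module_labels`` maps every gene id to its module index, with 0
    meaning background; planted modules are numbered from 1.
    ``driver_modules`` holds module indices with a nonzero effect on at
    least one osteoporosis and one atherosclerosis trait.
    """

    gene_module_labels: dict[str, int]
    factor_scores: np.ndarray
    trait_effects: np.ndarray
    driver_modules: set[int]
    gene_loadings: dict[str, float]

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.gene_module_labels.items() if m == module]


def compute_mineral_content(area, density):
    """Bone mineral content (mg) from cross-sectional area (mm^2) and density (mg/cm^3).

    Computed as ``0.2 * (area / 100) * density``; accepts scalars or arrays.
    """
    area = np.asarray(area, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.any(area < 0) or np.any(density < 0):
        raise ValueError("area and density must be non-negative")
    out = 0.2 * (area / 100.0) * density
    return float(out) if out.ndim == 0 else out


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates with population-realistic marginals, drawn in fixed order."""
    age = rng.uniform(30.0, 45.0, n)
    sex = (rng.random(n) < 0.56).astype(float)  # 1 = female
    bmi = rng.normal(25.7, 4.4, n)
    smoking = (rng.random(n) < 0.14).astype(float)
    alcohol = rng.lognormal(mean=-0.7, sigma=1.1, size=n)  # units/day, skewed
    activity = np.clip(rng.normal(19.8, 21.0, n), 0.0, None)  # MET-h/wk
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "alcohol": alcohol,
            "physical_activity": activity,
        }
    )


def _standardise(df: pd.DataFrame) -> np.ndarray:
    z = df.to_numpy(dtype=float)
    mu = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (z - mu) / sd


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TraitTable, PlantedTruth]:
    """Simulate one dataset.

    Expression of a gene in module m is ``beta_g * f_m + eps`` with
    ``beta_g ~ U(loading_range)`` and ``eps ~ N(0, noise_sd^2)``;
    background genes are pure noise.  Traits are
    ``sum_m gamma_{t,m} f_m + sum_c delta_{t,c} z_c + eta`` with
    standardised covariates ``z_c`` and ``eta ~ N(0, trait_noise_sd^2)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sizes = [int(m) for m in config.module_sizes]
    n_mod = len(sizes)
    n_planted = sum(sizes)
    n_genes = n_planted + config.n_background

    # Draw order is fixed: factors, loadings (module by module),
    # expression noise, covariates, trait noise.
    factors = rng.standard_normal((n, n_mod))
    lo, hi = config.loading_range
    loadings = [rng.uniform(lo, hi, m) for m in sizes]
    noise = rng.normal(0.0, config.noise_sd, (n, n_genes))
    covariates = _draw_covariates(rng, n)
    trait_noise = rng.normal(0.0, config.trait_noise_sd, (n, len(config.trait_names)))

    z_cov = _standardise(covariates)
    if config.factor_covariate_loadings is not None:
        lam = np.asarray(config.factor_covariate_loadings, dtype=float)
        if lam.shape != (n_mod, len(COVARIATE_NAMES)):
            raise ConfigurationError(
                f"factor_covariate_loadings must be {n_mod} x {len(COVARIATE_NAMES)}"
            )
        resid_var = np.clip(1.0 - (lam**2).sum(axis=1), 0.0, None)
        factors = z_cov @ lam.T + factors * np.sqrt(resid_var)

    gene_ids = [f"G{i + 1:06d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    values = noise
    labels: dict[str, int] = {}
    betas: dict[str, float] = {}
    col = 0
    for m, (size, beta) in enumerate(zip(sizes, loadings), start=1):
        values[:, col : col + size] += factors[:, m - 1 : m] * beta[None, :]
        for j in range(size):
            labels[gene_ids[col + j]] = m
            betas[gene_ids[col + j]] = float(beta[j])
        col += size
    for g in gene_ids[col:]:
        labels[g] = 0
        betas[g] = 0.0

    gamma = config.resolved_trait_effects()
    delta = config.resolved_covariate_effects()
    traits = factors @ gamma.T + z_cov @ delta.T + trait_noise

    expr = ExpressionMatrix(values, sample_ids, gene_ids)
    trait_df = pd.DataFrame(traits, index=sample_ids, columns=list(config.trait_names))
    covariates.index = pd.Index(sample_ids)
    table = TraitTable(trait_df, covariates, dict(config.trait_groups))

    groups = np.array(
        [1 if config.trait_groups[t] == "osteo" else 0 for t in config.trait_names]
    )
    drivers = {
        m + 1
        for m in range(n_mod)
        if np.any(gamma[groups == 1, m] != 0) and np.any(gamma[groups == 0, m] != 0)
    }
    truth = PlantedTruth(labels, factors, gamma, drivers, betas)
    return expr, table, truth


def generate_gene_sets(
    truth: PlantedTruth,
    n_decoy_sets: int = 20,
    overlap_fraction: float = 1.0,
    seed: int = 0,
    n_fillers: int = 0,
    decoy_size: int = 25,
) -> GeneSetCollection:
    """Gene-set collection matched to a simulated dataset.

    Emits one "true" set per planted module holding ``overlap_fraction`` of
    its genes (plus ``n_fillers`` random non-member genes) and
    ``n_decoy_sets`` random decoy sets of ``decoy_size`` genes, all drawn
    from the dataset's gene universe.
    """
    if not truth.gene_module_labels:
        raise ValueError("truth is empty")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ConfigurationError("overlap_fraction must be within [0, 1]")
    if n_decoy_sets < 0:
        raise ConfigurationError("n_decoy_sets must be >= 0")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(truth.gene_module_labels))
    modules = sorted({m for m in truth.gene_module_labels.values() if m != 0})

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for m in modules:
        members = np.array(truth.module_members(m))
        n_true = int(round(overlap_fraction * len(members)))
        chosen = list(rng.choice(members, size=n_true, replace=False)) if n_true else []
        if n_fillers:
            pool = np.setdiff1d(universe, members)
            chosen += list(rng.choice(pool, size=min(n_fillers, len(pool)), replace=False))
        if overlap_fraction == 0.0:
            # degenerate request: fall back to a random set of module size
            chosen = list(rng.choice(universe, size=len(members), replace=False))
        sets[f"TRUE_MODULE_{m}"] = (
            f"planted set for module {m}",
            tuple(dict.fromkeys(chosen)),
        )
    for d in range(n_decoy_sets):
        size = min(decoy_size, len(universe))
        chosen = rng.choice(universe, size=size, replace=False)
        sets[f"DECOY_{d + 1:03d}"] = (f"random decoy set {d + 1}", tuple(chosen))
    return GeneSetCollection(sets=sets, source="custom")
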