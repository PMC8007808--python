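"""Core data containers shared across the pipeline.

The internal orientation for expression data is samples x genes (rows are
observations), which is the natural orientation for correlation and linear
model work.  File formats use the transcriptomics convention of genes in
rows; the IO layer transposes on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Atherosclerosis ultrasound traits (intima-media thickness).
ATHERO_TRAITS: tuple[str, ...] = ("CIMTavg", "CIMTmax", "BIMTavg", "BIMTmax")

#: Osteoporosis pQCT traits (bone mineral density / content).
OSTEO_TRAITS: tuple[str, ...] = (
    "DRTrD",
    "DTTrD",
    "DRToBMC",
    "RSCoBMC",
    "DTToBMC",
    "TSCoBMC",
)

#: Default trait column order: 4 atherosclerosis traits then 6 osteoporosis traits.
DEFAULT_TRAITS: tuple[str, ...] = ATHERO_TRAITS + OSTEO_TRAITS

#: Default trait -> disease-group map.
DEFAULT_TRAIT_GROUPS: dict[str, str] = {
    **{t: "athero" for t in ATHERO_TRAITS},
    **{t: "osteo" for t in OSTEO_TRAITS},
}

#: Fixed covariate vocabulary (order matters for simulation draw order).
COVARIATE_NAMES: tuple[str, ...] = (
    "age",
    "sex",
    "bmi",
    "smoking",
    "alcohol",
    "physical_activity",
)


class ConfigurationError(ValueError):
    """Raised when user-supplied parameters violate a documented contract."""


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric expression matrix with string identifiers.

    Parameters
    ----------
    values
        2-D float array, rows are samples, columns are genes.  Missing
        values are NaN.
    sample_ids, gene_ids
        Ordered, unique identifier lists matching the array dimensions.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.gene_ids)} genes"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(self.values[:, idx], self.sample_ids, list(gene_ids))

    def to_frame(self) -> pd.DataFrame:
        """Samples x genes DataFrame indexed by sample id."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def drop_constant_genes(self) -> tuple["ExpressionMatrix", list[str]]:
        """Remove zero-variance genes; returns the filtered matrix and the ids dropped."""
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(self.values, axis=0)
        keep = sd > 0
        dropped = [g for g, k in zip(self.gene_ids, keep) if not k]
        if not dropped:
            return self, []
        sub = ExpressionMatrix(
            self.values[:, keep],
            self.sample_ids,
            [g for g, k in zip(self.gene_ids, keep) if k],
        )
        return sub, dropped


@dataclass
class TraitTable:
    """Per-sample trait values, disease-group map and covariates.

    ``traits`` and ``covariates`` are DataFrames indexed by sample id.
    Every trait column must be assigned to exactly one group
    (``osteo`` or ``athero``); covariate columns come from the fixed
    vocabulary in :data:`COVARIATE_NAMES`.
    """

    traits: pd.DataFrame
    covariates: pd.DataFrame
    trait_groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRAIT_GROUPS))

    def __post_init__(self) -> None:
        missing = [t for t in self.traits.columns if t not in self.trait_groups]
        if missing:
            raise ValueError(f"traits missing from group map: {missing}")
        bad_groups = {g for g in self.trait_groups.values()} - {"osteo", "athero"}
        if bad_groups:
            raise ValueError(f"unknown trait groups: {sorted(bad_groups)}")
        unknown_cov = [c for c in self.covariates.columns if c not in COVARIATE_NAMES]
        if unknown_cov:
            raise ValueError(f"unknown covariate columns: {unknown_cov}")
        if not self.traits.index.equals(self.covariates.index):
            raise ValueError("traits and covariates must share the same sample index")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.traits.index]

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def traits_in_group(self, group: str) -> list[str]:
        return [t for t in self.traits.columns if self.trait_groups[t] == group]
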