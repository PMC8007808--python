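"""Signed weighted co-expression network construction.

Correlation matrix -> soft-threshold power selection by scale-free fit ->
signed adjacency -> topological overlap -> dissimilarity.  All matrices are
dense in memory; a warning is emitted above 20,000 genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ConfigurationError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "SoftThresholdReport",
    "correlation_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "tom_dissimilarity",
]

DENSE_GENE_WARN_LIMIT = 20_000


@dataclass
class CorrelationMatrix:
    """Symmetric genes x genes Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape inconsistent with gene ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class AdjacencyMatrix:
    """Weighted network adjacency in [0, 1] with unit diagonal."""

    a: np.ndarray
    beta: int
    mode: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.mode not in ("signed", "unsigned"):
            raise ValueError(f"unknown adjacency mode {self.mode!r}")
        if np.any(self.a < -1e-12) or np.any(self.a > 1 + 1e-12):
            raise ValueError("adjacency entries must lie in [0, 1]")


@dataclass
class TOMMatrix:
    """Topological overlap similarity; ``1 - tom`` is a valid dissimilarity."""

    tom: np.ndarray
    gene_ids: list[str]


@dataclass
class SoftThresholdReport:
    """Per-candidate-power scale-free fit and connectivity summary."""

    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen: int
    fallback: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "power": self.powers,
                "fit_r2": self.fit_r2,
                "mean_connectivity": self.mean_connectivity,
            }
        )
        df["chosen"] = df["power"] == self.chosen
        return df


def correlation_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation over pairwise-complete observations.

    Constant (zero-variance) genes get correlation 0 to every other gene,
    with a logged warning; any gene pair with fewer than 3 complete
    observations is an error.
    """
    x = expr.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation")
    finite = np.isfinite(x)
    if finite.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, rowvar=False)
    else:
        overlap = finite.T.astype(np.int64) @ finite.astype(np.int64)
        if overlap.min() < 3:
            raise ValueError("some gene pairs have fewer than 3 shared observations")
        r = (
            pd.DataFrame(x, columns=expr.gene_ids)
            .corr(min_periods=3)
            .to_numpy()
        )
    bad = ~np.isfinite(np.diag(r))
    if bad.any():
        names = [g for g, b in zip(expr.gene_ids, bad) if b]
        logger.warning(
            "%d constant gene(s) have undefined correlations, set to 0: %s",
            len(names),
            names[:5],
        )
        r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(r, list(expr.gene_ids))


def signed_adjacency(
    cor: CorrelationMatrix, beta: int = 10, mode: str = "signed"
) -> AdjacencyMatrix:
    """Soft-thresholded adjacency.

    Signed mode: ``a_ij = ((1 + r_ij) / 2) ** beta``; unsigned mode:
    ``a_ij = |r_ij| ** beta``.  The diagonal is forced to 1.
    """
    if beta < 1:
        raise ConfigurationError("beta must be >= 1")
    if mode == "signed":
        a = ((1.0 + cor.r) / 2.0) ** beta
    elif mode == "unsigned":
        a = np.abs(cor.r) ** beta
    else:
        raise ConfigurationError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    if len(cor.gene_ids) > DENSE_GENE_WARN_LIMIT:
        warnings.warn(
            f"dense network on {len(cor.gene_ids)} genes exceeds the "
            f"recommended limit of {DENSE_GENE_WARN_LIMIT}",
            RuntimeWarning,
            stacklevel=2,
        )
    return AdjacencyMatrix(a, int(beta), mode, list(cor.gene_ids))


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit statistic.

    Bins the connectivities into ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean bin connectivity) over non-empty bins
    and returns R^2 times ``-sign(slope)``, so the statistic is positive
    only for decaying degree distributions.

    Raises
    ------
    ValueError
        If fewer than 2 distinct connectivity values (or non-empty bins)
        are available — the fit is undefined.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.ndim != 1 or np.any(k < 0):
        raise ValueError("connectivity must be a 1-D non-negative vector")
    if np.unique(k).size < 2:
        raise ValueError("scale-free fit undefined: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    nonempty = freq > 0
    mean_k = np.divide(sums, freq, out=np.zeros(n_bins), where=nonempty)
    use = nonempty & (mean_k > 0)
    if use.sum() < 2:
        raise ValueError("scale-free fit undefined: fewer than 2 usable bins")
    res = stats.linregress(np.log10(mean_k[use]), np.log10(freq[use]))
    r2 = res.rvalue**2
    return float(-np.sign(res.slope) * r2) if res.slope != 0 else 0.0


def pick_soft_threshold(
    cor: CorrelationMatrix,
    powers: list[int] | None = None,
    r2_cut: float = 0.80,
    mode: str = "signed",
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Evaluate candidate soft powers and pick the smallest passing one.

    For each power the whole-network connectivity ``k_i = sum_{j != i} a_ij``
    is scored with :func:`scale_free_fit`; the chosen power is the smallest
    with fit >= ``r2_cut``.  If none qualifies the report falls back to
    power 10 with ``fallback=True``.
    """
    powers = list(powers) if powers is not None else list(range(1, 21))
    if not powers:
        raise ConfigurationError("powers must be non-empty")
    fits: list[float] = []
    mean_k: list[float] = []
    for p in powers:
        adj = signed_adjacency(cor, beta=p, mode=mode)
        a0 = adj.a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        mean_k.append(float(k.mean()))
        try:
            fits.append(scale_free_fit(k, n_bins=n_bins))
        except ValueError:
            fits.append(float("nan"))
    passing = [p for p, f in zip(powers, fits) if np.isfinite(f) and f >= r2_cut]
    if passing:
        chosen, fallback = passing[0], False
    else:
        chosen, fallback = 10, True
        logger.warning(
            "no candidate power reached scale-free fit %.2f; falling back to 10",
            r2_cut,
        )
    return SoftThresholdReport(powers, fits, mean_k, chosen, fallback)


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix.

    For ``i != j``: ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.
    """
    a = np.asarray(adj.a, dtype=float)
    if np.any(a < 0) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    # (a0 @ a0)_ij sums over all u; u = i and u = j contribute 0 because
    # the diagonal of a0 is 0, so it equals L_ij directly.
    L = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    if np.any(tom > 1 + 1e-10):
        raise AssertionError("TOM entries exceeded 1; invalid adjacency?")
    tom = np.clip(tom, 0.0, 1.0)
    return TOMMatrix(tom, list(adj.gene_ids))


def tom_dissimilarity(tom: TOMMatrix) -> np.ndarray:
    """Dissimilarity ``1 - TOM``: zero diagonal, entries in [0, 1]."""
    d = 1.0 - np.asarray(tom.tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d
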