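"""Module detection: clustering of the TOM dissimilarity, static-height tree
cut, eigengenes, module membership (MM), gene significance (GS) and the
GS-MM quality check."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .data import ConfigurationError, ExpressionMatrix, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ModuleAssignment",
    "EigengeneMatrix",
    "GSMMRecord",
    "average_linkage_cluster",
    "dynamic_tree_cut",
    "module_eigengenes",
    "module_membership",
    "gene_significance",
    "gs_mm_quality",
    "MODULE_COLORS",
]

#: Conventional module colour vocabulary, in assignment order; the unassigned
#: label 0 is always "grey".
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "honeydew",
    "darkseagreen", "lightcoral", "sienna",
)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes.

    ``merges`` is a SciPy linkage matrix: each row is
    (left, right, height, size); heights are non-decreasing and there are
    n - 1 merges for n leaves.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows of 4 columns")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max())

    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent/child height differences."""
        n = len(self.leaf_ids)
        text: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for row, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + row
            text[node] = (
                f"({text.pop(a)}:{h - height.pop(a):.10g},"
                f"{text.pop(b)}:{h - height.pop(b):.10g})"
            )
            height[node] = float(h)
        return text[n + len(self.merges) - 1] + ";"


@dataclass
class ModuleAssignment:
    """Gene -> module labels; label 0 ("grey") means unassigned."""

    labels: dict[str, int]
    colors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 0 not in self.colors:
            self.colors[0] = "grey"

    @property
    def module_labels(self) -> list[int]:
        return sorted({m for m in self.labels.values() if m != 0})

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out

    def color_of(self, module: int) -> str:
        return self.colors.get(module, f"module_{module}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.labels),
                "module": list(self.labels.values()),
                "color": [self.color_of(m) for m in self.labels.values()],
            }
        )


@dataclass
class EigengeneMatrix:
    """Per-module summary profiles (first principal component scores).

    ``scores`` is samples x modules, each column standardised to zero mean
    and unit SD and oriented so its correlation with the mean member
    profile is non-negative.
    """

    scores: pd.DataFrame
    module_labels: list[int]
    variance_explained: np.ndarray
    orientation_sign: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.scores.index]


@dataclass
class GSMMRecord:
    """GS-MM quality check of one module against one trait."""

    module: int
    trait: str
    r_gs_mm: float
    p_value: float
    n_members: int
    gs: np.ndarray
    mm: np.ndarray


def average_linkage_cluster(
    diss: np.ndarray, gene_ids: list[str]
) -> Dendrogram:
    """UPGMA (average linkage) clustering of a symmetric dissimilarity matrix."""
    d = np.asarray(diss, dtype=float)
    if d.shape != (len(gene_ids), len(gene_ids)):
        raise ValueError("dissimilarity shape inconsistent with gene ids")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-10):
        raise ValueError("dissimilarity diagonal must be zero")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(merges, list(gene_ids))


def dynamic_tree_cut(
    dend: Dendrogram,
    min_module_size: int = 10,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static-height tree cut with a minimum module size.

    Merges above ``cut_height`` are removed; the remaining branches become
    clusters.  The default cut is ``median(h) - 3 * MADN(h)`` over the merge
    heights ``h`` (MADN = normalised median absolute deviation): the bulk
    of merges in a co-expression dendrogram sit in a dense band of
    near-maximal heights formed by unrelated genes, and genuine module
    branches complete well below that band, so cutting a few robust
    deviations below the band isolates them.  A fixed fraction of the
    maximum height is not robust here because the band is much narrower
    than the heights themselves.  Clusters smaller than ``min_module_size``
    are demoted to label 0; survivors are relabelled 1, 2, ... by
    decreasing size and mapped to colour names.
    """
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be >= 2")
    h_max = dend.max_height
    if cut_height is None:
        h = dend.heights
        madn = 1.4826 * float(np.median(np.abs(h - np.median(h))))
        cut_height = max(float(np.median(h)) - 3.0 * madn, 0.0)
    elif not (0 < cut_height <= h_max):
        raise ConfigurationError(
            f"cut_height must lie in (0, {h_max:.6g}], got {cut_height!r}"
        )
    raw = fcluster(dend.merges, t=cut_height, criterion="distance")
    counts: dict[int, int] = {}
    for c in raw:
        counts[c] = counts.get(c, 0) + 1
    kept = [c for c, n in counts.items() if n >= min_module_size]
    # order by decreasing size, ties by first-occurrence (lowest raw label)
    kept.sort(key=lambda c: (-counts[c], c))
    relabel = {c: i + 1 for i, c in enumerate(kept)}
    labels = {
        g: relabel.get(int(c), 0) for g, c in zip(dend.leaf_ids, raw)
    }
    colors = {0: "grey"}
    for c, new in relabel.items():
        colors[new] = (
            MODULE_COLORS[new - 1] if new - 1 < len(MODULE_COLORS) else f"module_{new}"
        )
    n_grey = sum(1 for v in labels.values() if v == 0)
    logger.info(
        "tree cut at %.4g: %d modules (sizes %s), %d genes unassigned",
        cut_height,
        len(kept),
        sorted((counts[c] for c in kept), reverse=True)[:10],
        n_grey,
    )
    return ModuleAssignment(labels, colors)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return (x - mu) / sd


def module_eigengenes(
    expr: ExpressionMatrix, assign: ModuleAssignment
) -> EigengeneMatrix:
    """First-principal-component summary profile per module.

    Member genes are z-scored across samples; the first right-singular
    direction of the samples x members matrix gives the component, whose
    score vector is re-standardised and sign-oriented so that its
    correlation with the mean member profile is non-negative.
    ``variance_explained`` is the top eigenvalue over the trace of the
    member correlation matrix.
    """
    frame = expr.to_frame()
    cols: dict[str, np.ndarray] = {}
    labels: list[int] = []
    var_expl: list[float] = []
    signs: list[int] = []
    for m in assign.module_labels:
        members = [g for g in assign.members(m) if g in frame.columns]
        if not members:
            raise ValueError(f"module {m} has no member present in the expression matrix")
        x = frame[members].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [g for g, s in zip(members, sd) if s == 0]
            logger.warning("module %d: excluding constant member genes %s", m, const[:5])
            x = x[:, sd > 0]
            if x.shape[1] == 0:
                raise ValueError(f"module {m} has only constant member genes")
        z = _zscore_columns(x)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = z @ vt[0]
        sign = 1 if np.corrcoef(scores, z.mean(axis=1))[0, 1] >= 0 else -1
        scores = sign * scores
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        cols[assign.color_of(m)] = scores
        labels.append(m)
        var_expl.append(float(s[0] ** 2 / np.sum(s**2)))
        signs.append(sign)
    scores_df = pd.DataFrame(cols, index=expr.sample_ids)
    return EigengeneMatrix(
        scores_df, labels, np.asarray(var_expl), np.asarray(signs, dtype=int)
    )


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation matrix between two sample-aligned blocks."""
    xz = x - x.mean(axis=0)
    yz = y - y.mean(axis=0)
    xn = np.linalg.norm(xz, axis=0)
    yn = np.linalg.norm(yz, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz.T @ yz) / np.outer(xn, yn)
    return np.clip(r, -1.0, 1.0)


def module_membership(
    expr: ExpressionMatrix, eig: EigengeneMatrix
) -> pd.DataFrame:
    """MM: Pearson correlation of every gene with every eigengene (genes x modules)."""
    frame = expr.to_frame().loc[eig.scores.index]
    mm = _pearson_columns(frame.to_numpy(dtype=float), eig.scores.to_numpy())
    if np.isnan(mm).any():
        n_bad = int(np.isnan(mm).any(axis=1).sum())
        logger.warning("module membership undefined for %d constant gene(s)", n_bad)
    return pd.DataFrame(mm, index=expr.gene_ids, columns=eig.scores.columns)


def gene_significance(expr: ExpressionMatrix, traits: TraitTable) -> pd.DataFrame:
    """GS: Pearson correlation of every gene with every trait over shared samples."""
    shared = [s for s in expr.sample_ids if s in set(traits.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    x = expr.to_frame().loc[shared].to_numpy(dtype=float)
    y = traits.traits.loc[shared].to_numpy(dtype=float)
    gs = _pearson_columns(x, y)
    return pd.DataFrame(gs, index=expr.gene_ids, columns=traits.traits.columns)


def gs_mm_quality(
    gs_col: pd.Series | np.ndarray,
    mm_col: pd.Series | np.ndarray,
    member_genes: list[str],
    module: int = 0,
    trait: str = "",
) -> GSMMRecord:
    """Correlation of |GS| against MM over a module's member genes.

    The magnitude of GS is used because the sign depends on the trait's
    direction while the quality check asks whether trait-relevant genes
    are also central module members.  p is a two-sided t test with
    m - 2 degrees of freedom.
    """
    if len(member_genes) < 3:
        raise ValueError("need at least 3 member genes for the GS-MM check")
    if isinstance(gs_col, pd.Series):
        gs = gs_col.loc[member_genes].to_numpy(dtype=float)
    else:
        gs = np.asarray(gs_col, dtype=float)
    if isinstance(mm_col, pd.Series):
        mm = mm_col.loc[member_genes].to_numpy(dtype=float)
    else:
        mm = np.asarray(mm_col, dtype=float)
    if gs.shape != mm.shape or gs.shape[0] != len(member_genes):
        raise ValueError("GS and MM vectors must align on the member genes")
    r = float(np.corrcoef(np.abs(gs), mm)[0, 1])
    m = len(member_genes)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((m - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=m - 2))
    return GSMMRecord(module, trait, r, p, m, gs, mm)
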