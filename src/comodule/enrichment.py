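"""Gene-set over-representation and pathway clustering.

Hypergeometric over-representation of module member genes against GMT
collections with Bonferroni adjustment, then average-linkage clustering of
the significant terms by Jaccard similarity of their overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from .data import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "PathwayClusterResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "enrich_module",
    "cluster_enriched_pathways",
]


@dataclass
class GeneSetCollection:
    """Named gene sets: term id -> (term name, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]
    source: str = "custom"

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return out


@dataclass
class EnrichmentResult:
    """One hypergeometric over-representation record."""

    term: str
    name: str
    k: int  # overlap
    n: int  # query size (within universe)
    K: int  # set size (within universe)
    N: int  # universe size
    p: float
    p_adj: float
    core_genes: tuple[str, ...] = ()
    module: str = ""


@dataclass
class PathwayClusterResult:
    """Clustering of enriched terms by gene-overlap similarity."""

    terms: list[str]
    distance: np.ndarray  # 1 - Jaccard, symmetric, zero diagonal
    merges: np.ndarray  # average-linkage linkage matrix
    cluster_labels: dict[str, int]
    k_clusters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "cluster": [self.cluster_labels[t] for t in self.terms]}
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, name, description, tab-separated genes.

    Duplicate genes within a line are dropped; a line with no member genes
    is a parse error reported with its line number.
    """
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected name, description and "
                    f">= 1 gene, got {len(fields)} field(s)"
                )
            name, desc = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g.strip()))
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate term id {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term, (desc, genes) in coll.sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail (inclusive) hypergeometric p-value.

    Probability of observing >= ``k`` successes when drawing ``n`` items
    without replacement from a universe of ``N`` containing ``K`` successes.
    """
    from scipy.stats import hypergeom

    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_module(
    module_genes: list[str],
    coll: GeneSetCollection,
    universe: list[str],
    min_size: int = 10,
    max_size: int = 500,
    module: str = "",
) -> list[EnrichmentResult]:
    """Over-representation of a query gene list against a collection.

    Gene sets are intersected with the universe; sets with effective size
    outside [min_size, max_size] are skipped.  Bonferroni family = number
    of sets actually tested.  Results are sorted by raw p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    query = set(module_genes) & uni
    n = len(query)
    N = len(uni)
    tested: list[tuple[str, str, set[str]]] = []
    for term, (name, genes) in coll.sets.items():
        members = set(genes) & uni
        if min_size <= len(members) <= max_size:
            tested.append((term, name, members))
    family = len(tested)
    results = []
    for term, name, members in tested:
        core = tuple(sorted(query & members))
        p = hypergeometric_test(len(core), n, len(members), N)
        results.append(
            EnrichmentResult(
                term, name, len(core), n, len(members), N, p,
                min(1.0, p * family), core, module,
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    logger.info(
        "enrichment of %r: %d/%d sets tested (size filter %d-%d), family %d",
        module, family, len(coll), min_size, max_size, family,
    )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module": [r.module for r in results],
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "core_genes": [";".join(r.core_genes) for r in results],
        }
    )


def cluster_enriched_pathways(
    results: list[EnrichmentResult],
    k_clusters: int = 4,
    use_core_genes: bool = True,
) -> PathwayClusterResult:
    """Cluster enriched terms by similarity of their member genes.

    Distance is 1 - Jaccard over the enrichment core genes (or the full
    set membership when ``use_core_genes`` is false), clustered with
    average linkage and cut into ``k_clusters`` groups.
    """
    from .detection import average_linkage_cluster

    if len(results) < 2:
        raise ValueError("need >= 2 enriched terms to cluster; skip this step")
    if k_clusters < 1:
        raise ConfigurationError("k_clusters must be >= 1")
    terms = [r.term for r in results]
    if len(set(terms)) != len(terms):
        terms = [f"{r.module}:{r.term}" if r.module else r.term for r in results]
    gene_sets = [set(r.core_genes) for r in results]
    m = len(terms)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = gene_sets[i], gene_sets[j]
            union = len(a | b)
            jac = len(a & b) / union if union else 0.0
            d[i, j] = d[j, i] = 1.0 - jac
    dend = average_linkage_cluster(d, terms)
    k = min(k_clusters, m)
    raw = fcluster(dend.merges, t=k, criterion="maxclust")
    # relabel clusters by decreasing size, ties by lowest raw label
    counts: dict[int, int] = {}
    for c in raw:
        counts[c] = counts.get(c, 0) + 1
    order = sorted(counts, key=lambda c: (-counts[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = {t: relabel[int(c)] for t, c in zip(terms, raw)}
    return PathwayClusterResult(terms, d, dend.merges, labels, k)
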