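"""Eigengene-trait screening: correlations with Bonferroni adjustment,
dual-disease candidate selection and per-module trait-pair choice."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TraitTable
from .detection import EigengeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleTraitResult",
    "CandidateSelection",
    "module_trait_correlations",
    "select_candidate_modules",
    "select_trait_pair",
]


@dataclass
class ModuleTraitResult:
    """Module x trait correlation screen.

    ``r``, ``p`` and ``p_adj`` are modules x traits DataFrames (rows
    indexed by eigengene column name); ``p_adj = min(1, p * family_size)``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame
    family_size: int

    def to_long_frame(self, trait_groups: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for module in self.r.index:
            for trait in self.r.columns:
                rows.append(
                    {
                        "module": module,
                        "trait": trait,
                        "group": (trait_groups or {}).get(trait, ""),
                        "r": self.r.loc[module, trait],
                        "p": self.p.loc[module, trait],
                        "p_adj": self.p_adj.loc[module, trait],
                        "n": self.n.loc[module, trait],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CandidateSelection:
    """Modules passing the dual-disease screen and their chosen trait pairs."""

    selected: list[str]
    trait_pairs: dict[str, tuple[str, str]]  # module -> (osteo trait, athero trait)
    alpha: float
    rule: str = "min p_adj per disease group < alpha in both groups"


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r and two-sided t-distribution p."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"only {n} complete observations; need >= 4")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def module_trait_correlations(
    eig: EigengeneMatrix,
    traits: TraitTable,
    family_size: int | None = None,
) -> ModuleTraitResult:
    """Correlate every eigengene with every trait.

    p-values come from the t distribution with n - 2 df; the Bonferroni
    family defaults to (#modules x #traits) and is logged.
    """
    shared = [s for s in eig.sample_ids if s in set(traits.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need >= 4")
    me = eig.scores.loc[shared]
    ty = traits.traits.loc[shared]
    modules = list(me.columns)
    names = list(ty.columns)
    if family_size is None:
        family_size = len(modules) * len(names)
    r = np.zeros((len(modules), len(names)))
    p = np.zeros_like(r)
    n = np.zeros_like(r, dtype=int)
    for i, mcol in enumerate(modules):
        xv = me[mcol].to_numpy(dtype=float)
        for j, tcol in enumerate(names):
            r[i, j], p[i, j], n[i, j] = _corr_with_p(xv, ty[tcol].to_numpy(dtype=float))
    p_adj = np.minimum(1.0, p * family_size)
    logger.info(
        "module-trait screen: %d modules x %d traits, Bonferroni family %d",
        len(modules),
        len(names),
        family_size,
    )
    mk = lambda a: pd.DataFrame(a, index=modules, columns=names)
    return ModuleTraitResult(mk(r), mk(p), mk(p_adj), mk(n), int(family_size))


def select_trait_pair(
    module: str,
    res: ModuleTraitResult,
    trait_groups: dict[str, str],
) -> tuple[str, str]:
    """The (osteo, athero) trait pair with the smallest adjusted p per group.

    Ties are broken by smaller raw p, then by trait column order.
    """
    if module not in res.p_adj.index:
        raise KeyError(f"unknown module {module!r}")
    pair = {}
    for group in ("osteo", "athero"):
        cands = [t for t in res.p_adj.columns if trait_groups.get(t) == group]
        if not cands:
            raise ValueError(f"no traits in group {group!r}")
        row_adj = res.p_adj.loc[module, cands]
        row_raw = res.p.loc[module, cands]
        if row_adj.isna().all():
            raise ValueError(f"module {module!r}: all cells missing in group {group!r}")
        order = {t: i for i, t in enumerate(res.p_adj.columns)}
        pair[group] = min(cands, key=lambda t: (row_adj[t], row_raw[t], order[t]))
    return pair["osteo"], pair["athero"]


def select_candidate_modules(
    res: ModuleTraitResult,
    trait_groups: dict[str, str],
    alpha: float = 0.05,
) -> CandidateSelection:
    """Dual-disease screen: a module qualifies iff its smallest adjusted p
    is below ``alpha`` in the osteoporosis group AND in the atherosclerosis
    group."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    missing = [t for t in res.p_adj.columns if t not in trait_groups]
    if missing:
        raise ValueError(f"traits missing from group map: {missing}")
    osteo = [t for t in res.p_adj.columns if trait_groups[t] == "osteo"]
    athero = [t for t in res.p_adj.columns if trait_groups[t] == "athero"]
    selected = [
        m
        for m in res.p_adj.index
        if res.p_adj.loc[m, osteo].min() < alpha and res.p_adj.loc[m, athero].min() < alpha
    ]
    pairs = {m: select_trait_pair(m, res, trait_groups) for m in selected}
    logger.info("dual-disease screen at alpha=%g: %d candidate module(s)", alpha, len(selected))
    return CandidateSelection(selected, pairs, alpha)
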