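"""Joint association of a predictor with a bivariate trait outcome via
Pillai's trace under three covariate-adjustment models.

Model 1 has no covariates; model 2 adjusts for age, sex and BMI; model 3
additionally adjusts for smoking, alcohol consumption and physical
activity.  The hypothesis SSCP is Type II (predictor after covariates) and
every test is complete-case.  With a single-df predictor the Pillai F test
is exact, not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import CandidateSelection
from .data import ExpressionMatrix, TraitTable
from .detection import EigengeneMatrix, ModuleAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_COVARIATES",
    "ManovaResult",
    "fit_mlm_sscp",
    "pillai_trace",
    "pillai_f_test",
    "manova_test",
    "module_joint_association",
    "gene_joint_association",
]

#: Covariate sets of the three adjustment models.
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age", "sex", "bmi"),
    3: ("age", "sex", "bmi", "smoking", "alcohol", "physical_activity"),
}


@dataclass
class ManovaResult:
    """One Pillai's-trace test of a predictor against a bivariate outcome."""

    predictor: str
    model: int
    pillai: float
    f_value: float
    df1: float
    df2: float
    p: float
    p_adj: float
    n_used: int

    def significance(self, alpha: float = 0.05, suggestive: float = 0.25) -> str:
        if self.p_adj < alpha:
            return "significant"
        if self.p_adj < suggestive:
            return "suggestive"
        return ""


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns beyond the numerical rank (QR with column pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_mlm_sscp(
    y: np.ndarray,
    x_full: np.ndarray,
    predictor_cols: list[int],
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Multivariate least-squares fit returning (H, E, error df).

    ``E`` is the residual SSCP of the full model; ``H`` is the Type-II
    hypothesis SSCP of the predictor term, i.e. the extra residual SSCP of
    the model without the predictor columns.  The error df is
    ``n - rank(x_full)``.
    """
    y = np.asarray(y, dtype=float)
    x_full = np.asarray(x_full, dtype=float)
    n, k = x_full.shape
    if y.ndim != 2 or y.shape[0] != n:
        raise ValueError("Y must be n x p and aligned with the design")
    rank = np.linalg.matrix_rank(x_full)
    if rank < k:
        names = column_names or [f"col{i}" for i in range(k)]
        bad = _collinear_columns(x_full, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n <= rank + y.shape[1]:
        raise ValueError(f"too few complete cases (n={n}) for rank-{rank} design")

    def resid_sscp(x: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return r.T @ r

    e_full = resid_sscp(x_full)
    keep = [i for i in range(k) if i not in set(predictor_cols)]
    e_reduced = resid_sscp(x_full[:, keep]) if keep else y.T @ y
    h = e_reduced - e_full
    return h, e_full, int(n - rank)


def pillai_trace(h: np.ndarray, e: np.ndarray) -> float:
    """Pillai's trace ``V = trace(H (H + E)^-1)``."""
    h = np.asarray(h, dtype=float)
    e = np.asarray(e, dtype=float)
    if not np.allclose(h, h.T, atol=1e-8) or not np.allclose(e, e.T, atol=1e-8):
        raise ValueError("H and E must be symmetric")
    total = h + e
    if np.linalg.matrix_rank(total) < total.shape[0]:
        raise np.linalg.LinAlgError("H + E is singular")
    return float(np.trace(h @ np.linalg.inv(total)))


def pillai_f_test(
    v: float, p_resp: int, df_h: int, df_err: int
) -> tuple[float, float, float, float]:
    """F statistic and p-value for Pillai's trace.

    Uses the Pillai-Bartlett transformation with
    ``s = min(p_resp, df_h)``, ``m = (|p_resp - df_h| - 1)/2`` and
    ``n' = (df_err - p_resp - 1)/2``:
    ``df1 = s(2m + s + 1)``, ``df2 = s(2n' + s + 1)`` and
    ``F = (df2/df1) V/(s - V)``.  Exact when ``s = 1`` (every
    single-predictor test here).
    """
    if df_err <= p_resp:
        raise ValueError("error df must exceed the number of responses")
    s = min(p_resp, df_h)
    if not (-1e-12 <= v <= s + 1e-12):
        raise ValueError(f"Pillai's trace {v} outside [0, {s}]")
    v = min(max(v, 0.0), float(s))
    m = (abs(p_resp - df_h) - 1) / 2.0
    n_prime = (df_err - p_resp - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_prime + s + 1)
    if v >= s:
        return float("inf"), df1, df2, 0.0
    f = (df2 / df1) * v / (s - v)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), p


def manova_test(
    y: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None,
    predictor_name: str = "predictor",
    model: int = 1,
    covariate_names: list[str] | None = None,
) -> ManovaResult:
    """Complete-case Pillai's-trace test of one predictor (p_adj left = p)."""
    y = np.asarray(y, dtype=float)
    predictor = np.asarray(predictor, dtype=float).reshape(-1)
    blocks = [y, predictor[:, None]]
    if covariates is not None and covariates.size:
        covariates = np.asarray(covariates, dtype=float)
        blocks.append(covariates)
    complete = np.all(np.isfinite(np.column_stack(blocks)), axis=1)
    y_c = y[complete]
    pred_c = predictor[complete]
    names = ["intercept"]
    cols = [np.ones(complete.sum())]
    if covariates is not None and covariates.size:
        cov_c = covariates[complete]
        cols.extend(cov_c.T)
        names.extend(covariate_names or [f"cov{i}" for i in range(cov_c.shape[1])])
    cols.append(pred_c)
    names.append(predictor_name)
    x_full = np.column_stack(cols)
    h, e, df_err = fit_mlm_sscp(y_c, x_full, [x_full.shape[1] - 1], names)
    v = pillai_trace(h, e)
    f, df1, df2, p = pillai_f_test(v, p_resp=y.shape[1], df_h=1, df_err=df_err)
    return ManovaResult(predictor_name, model, v, f, df1, df2, p, p, int(complete.sum()))


def _covariate_block(
    traits: TraitTable, model: int, sample_ids: list[str]
) -> tuple[np.ndarray | None, list[str]]:
    names = list(MODEL_COVARIATES[model])
    if not names:
        return None, []
    missing = [c for c in names if c not in traits.covariates.columns]
    if missing:
        raise ValueError(f"model {model} requires absent covariates: {missing}")
    return traits.covariates.loc[sample_ids, names].to_numpy(dtype=float), names


def _results_frame(results: list[ManovaResult], extra: dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "predictor": [r.predictor for r in results],
            "model": [r.model for r in results],
            "pillai": [r.pillai for r in results],
            "F": [r.f_value for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "n_used": [r.n_used for r in results],
            "significance": [r.significance() for r in results],
        }
    )
    for k, v in extra.items():
        df.insert(0, k, v)
    return df


def module_joint_association(
    eig: EigengeneMatrix,
    sel: CandidateSelection,
    traits: TraitTable,
    models: tuple[int, ...] = (1, 2, 3),
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pillai's-trace tests of each candidate eigengene against its trait pair.

    The Bonferroni family defaults to the number of candidate modules
    (applied per model).  Returns an empty table when nothing was selected.
    """
    results: list[ManovaResult] = []
    mods: list[str] = []
    family = family_size if family_size is not None else max(len(sel.selected), 1)
    shared = [s for s in eig.sample_ids if s in set(traits.sample_ids)]
    for module in sel.selected:
        osteo_t, athero_t = sel.trait_pairs[module]
        y = traits.traits.loc[shared, [osteo_t, athero_t]].to_numpy(dtype=float)
        pred = eig.scores.loc[shared, module].to_numpy(dtype=float)
        for model in models:
            cov, cov_names = _covariate_block(traits, model, shared)
            res = manova_test(y, pred, cov, module, model, cov_names)
            res.p_adj = min(1.0, res.p * family)
            results.append(res)
            mods.append(module)
    logger.info(
        "module MANOVA: %d candidates x models %s, Bonferroni family %d",
        len(sel.selected),
        list(models),
        family,
    )
    return _results_frame(results, {"module": mods})


def gene_joint_association(
    expr: ExpressionMatrix,
    module: int,
    assign: ModuleAssignment,
    pair: tuple[str, str],
    traits: TraitTable,
    models: tuple[int, ...] = (1, 2, 3),
    family_size: int | None = None,
) -> pd.DataFrame:
    """Member-gene Pillai's-trace tests for one module and its trait pair.

    The Bonferroni family defaults to the module size (per model); output
    is sorted by adjusted p within model and carries a rank column.
    """
    members = assign.members(module)
    if not members:
        raise ValueError(f"module {module} has no members")
    present = [g for g in members if g in set(expr.gene_ids)]
    skipped = set(members) - set(present)
    if skipped:
        logger.warning(
            "module %s: %d member gene(s) absent from expression, skipped",
            module,
            len(skipped),
        )
    family = family_size if family_size is not None else len(members)
    shared = [s for s in expr.sample_ids if s in set(traits.sample_ids)]
    frame = expr.to_frame().loc[shared]
    osteo_t, athero_t = pair
    y = traits.traits.loc[shared, [osteo_t, athero_t]].to_numpy(dtype=float)
    results: list[ManovaResult] = []
    for model in models:
        cov, cov_names = _covariate_block(traits, model, shared)
        for g in present:
            res = manova_test(
                y, frame[g].to_numpy(dtype=float), cov, g, model, cov_names
            )
            res.p_adj = min(1.0, res.p * family)
            results.append(res)
    df = _results_frame(results, {"module": [module] * len(results)})
    df = df.sort_values(["model", "p_adj", "p"], kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("model").cumcount() + 1
    return df
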