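"""End-to-end pipeline: expression -> network -> modules -> screening ->
joint MANOVA -> enrichment, with every intermediate table written to a run
directory plus a machine-readable manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, detection, enrichment, manova, network
from .data import DEFAULT_TRAIT_GROUPS, ExpressionMatrix, TraitTable
from .io import FLOAT_FORMAT, read_expression, read_traits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_data", "STAGES"]

#: The nine pipeline stages recorded in the run manifest.
STAGES: tuple[str, ...] = (
    "expression_input",
    "correlation_network",
    "clustering",
    "module_detection",
    "eigengenes",
    "module_trait_correlation",
    "gs_mm_quality",
    "manova",
    "pathway_analysis",
)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    expression_path: str = ""
    traits_path: str = ""
    gene_sets_path: str = ""
    output_dir: str = "run"
    orientation: str = "genes-rows"
    # network
    beta: int | None = 10  # None = pick by scale-free fit
    adjacency_mode: str = "signed"
    power_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_cut: float = 0.80
    # module detection
    min_module_size: int = 10
    cut_height: float | None = None  # None = 0.99 * max merge height
    # screening
    alpha: float = 0.05
    screening_family: int | None = None  # None = modules x traits
    # manova
    models: tuple[int, ...] = (1, 2, 3)
    # enrichment
    enrich_min_size: int = 10
    enrich_max_size: int = 500
    k_pathway_clusters: int = 4
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.models, list):
            cfg.models = tuple(cfg.models)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["models"] = list(self.models)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based entry point: read inputs per config, run, write artifacts."""
    expr = read_expression(config.expression_path, config.orientation)
    traits = read_traits(config.traits_path)
    gene_sets = (
        enrichment.read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    )
    return run_pipeline_data(expr, traits, gene_sets, config)


def run_pipeline_data(
    expr: ExpressionMatrix,
    traits: TraitTable,
    gene_sets: enrichment.GeneSetCollection | None,
    config: PipelineConfig,
) -> Path:
    """Run all stages on in-memory inputs; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("comodule")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest: dict = {
        "stages": list(STAGES),
        "parameters": {**dataclasses.asdict(config), "models": list(config.models)},
        "seed": config.seed,
    }
    try:
        # 1. expression input
        expr, dropped = expr.drop_constant_genes()
        if dropped:
            logger.info("dropped %d constant gene(s) before network construction", len(dropped))
        shared = [s for s in expr.sample_ids if s in set(traits.sample_ids)]
        logger.info(
            "orientation check: %d samples x %d genes; %d samples shared with traits",
            expr.n_samples, expr.n_genes, len(shared),
        )
        if not shared:
            raise ValueError("expression and trait tables share no samples")
        manifest["expression_input"] = {
            "n_samples": expr.n_samples,
            "n_genes": expr.n_genes,
            "n_shared_samples": len(shared),
            "n_constant_genes_dropped": len(dropped),
        }

        # 2. correlation, soft threshold, adjacency, TOM
        cor = network.correlation_matrix(expr)
        report = network.pick_soft_threshold(
            cor, config.power_grid, config.r2_cut, config.adjacency_mode
        )
        beta = config.beta if config.beta is not None else report.chosen
        report.to_frame().to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False,
                                 float_format=FLOAT_FORMAT)
        adj = network.signed_adjacency(cor, beta=beta, mode=config.adjacency_mode)
        tom = network.topological_overlap(adj)
        diss = network.tom_dissimilarity(tom)
        manifest["correlation_network"] = {
            "beta": int(beta),
            "beta_source": "config" if config.beta is not None else "scale_free_fit",
            "fallback": bool(report.fallback),
            "mode": config.adjacency_mode,
        }

        # 3. clustering
        dend = detection.average_linkage_cluster(diss, tom.gene_ids)
        (outdir / "gene_dendrogram.newick").write_text(dend.to_newick() + "\n")
        manifest["clustering"] = {"max_merge_height": dend.max_height}

        # 4. module detection
        assign = detection.dynamic_tree_cut(dend, config.min_module_size, config.cut_height)
        _write_tsv(assign.to_frame(), outdir / "modules.tsv")
        sizes = assign.sizes()
        manifest["module_detection"] = {
            "n_modules": len(assign.module_labels),
            "min_module_size": config.min_module_size,
            "cut_height": config.cut_height
            if config.cut_height is not None
            else max(
                float(np.median(dend.heights))
                - 3.0 * 1.4826 * float(np.median(np.abs(dend.heights - np.median(dend.heights)))),
                0.0,
            ),
            "module_sizes": {assign.color_of(m): sizes[m] for m in assign.module_labels},
            "n_unassigned": sizes.get(0, 0),
        }
        if not assign.module_labels:
            raise ValueError("module_detection: no modules found above the minimum size")

        # 5. eigengenes
        eig = detection.module_eigengenes(expr, assign)
        eig_out = eig.scores.copy()
        eig_out.index.name = "sample_id"
        eig_out.to_csv(outdir / "eigengenes.tsv", sep="\t", float_format=FLOAT_FORMAT)
        manifest["eigengenes"] = {
            "variance_explained": {
                c: float(v) for c, v in zip(eig.scores.columns, eig.variance_explained)
            }
        }

        # 6. module-trait screening
        screen = association.module_trait_correlations(eig, traits, config.screening_family)
        _write_tsv(screen.to_long_frame(traits.trait_groups), outdir / "module_trait.tsv")
        sel = association.select_candidate_modules(screen, traits.trait_groups, config.alpha)
        manifest["module_trait_correlation"] = {
            "family_size": screen.family_size,
            "alpha": config.alpha,
            "candidates": sel.selected,
            "trait_pairs": {m: list(p) for m, p in sel.trait_pairs.items()},
        }
        (outdir / "candidates.json").write_text(
            json.dumps(manifest["module_trait_correlation"], indent=2) + "\n"
        )

        # 7. GS-MM quality check for the candidates
        gs = detection.gene_significance(expr, traits)
        mm = detection.module_membership(expr, eig)
        color_to_label = {assign.color_of(m): m for m in assign.module_labels}
        qc_rows = []
        for mcol in sel.selected:
            m = color_to_label[mcol]
            members = [g for g in assign.members(m) if g in gs.index]
            for trait in sel.trait_pairs[mcol]:
                rec = detection.gs_mm_quality(gs[trait], mm[mcol], members, m, trait)
                qc_rows.append(
                    {"module": mcol, "trait": trait, "r_gs_mm": rec.r_gs_mm,
                     "p": rec.p_value, "n_members": rec.n_members}
                )
        import pandas as pd

        _write_tsv(pd.DataFrame(qc_rows), outdir / "gs_mm_quality.tsv")
        manifest["gs_mm_quality"] = {"n_checks": len(qc_rows)}

        # 8. MANOVA: modules, then member genes of significant modules
        mod_res = manova.module_joint_association(eig, sel, traits, config.models)
        _write_tsv(mod_res, outdir / "manova_modules.tsv")
        if len(mod_res):
            sig_modules = sorted(
                mod_res.loc[mod_res["p_adj"] < config.alpha, "module"].unique()
            )
        else:
            sig_modules = []
        gene_frames = []
        for mcol in sig_modules:
            m = color_to_label[mcol]
            df = manova.gene_joint_association(
                expr, m, assign, sel.trait_pairs[mcol], traits, config.models
            )
            df["module"] = mcol
            gene_frames.append(df)
        gene_res = (
            pd.concat(gene_frames, ignore_index=True) if gene_frames
            else pd.DataFrame(columns=["module", "predictor", "model", "pillai", "F",
                                       "df1", "df2", "p", "p_adj", "n_used",
                                       "significance", "rank"])
        )
        _write_tsv(gene_res, outdir / "manova_genes.tsv")
        manifest["manova"] = {
            "module_family": max(len(sel.selected), 1),
            "models": list(config.models),
            "significant_modules": list(sig_modules),
        }

        # 9. enrichment + pathway clustering
        manifest["pathway_analysis"] = {"skipped": True, "reason": ""}
        if gene_sets is not None and sig_modules:
            universe = sorted(set(expr.gene_ids) & gene_sets.genes())
            all_results: list[enrichment.EnrichmentResult] = []
            for mcol in sig_modules:
                m = color_to_label[mcol]
                res = enrichment.enrich_module(
                    assign.members(m), gene_sets, universe,
                    config.enrich_min_size, config.enrich_max_size, module=mcol,
                )
                all_results.extend(res)
            _write_tsv(enrichment.enrichment_frame(all_results), outdir / "enrichment.tsv")
            significant = [r for r in all_results if r.p_adj < config.alpha and r.k > 0]
            if len(significant) >= 2:
                clust = enrichment.cluster_enriched_pathways(
                    significant, config.k_pathway_clusters
                )
                _write_tsv(clust.to_frame(), outdir / "pathway_clusters.tsv")
                pd_dend = detection.Dendrogram(clust.merges, clust.terms)
                (outdir / "pathway_dendrogram.newick").write_text(pd_dend.to_newick() + "\n")
                manifest["pathway_analysis"] = {
                    "skipped": False,
                    "n_terms_tested": len(all_results),
                    "n_significant_terms": len(significant),
                    "k_clusters": clust.k_clusters,
                }
            else:
                manifest["pathway_analysis"] = {
                    "skipped": True,
                    "reason": f"only {len(significant)} significant term(s); need >= 2 to cluster",
                    "n_terms_tested": len(all_results),
                }
        elif gene_sets is None:
            manifest["pathway_analysis"]["reason"] = "no gene-set collection supplied"
        else:
            manifest["pathway_analysis"]["reason"] = "no significant modules after MANOVA"

        config_out = dataclasses.replace(config)
        config_out.to_yaml(outdir / "resolved_config.yaml")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return outdir
    except Exception as exc:
        (outdir / "manifest.json").write_text(
            json.dumps({**manifest, "error": str(exc)}, indent=2, sort_keys=True, default=str) + "\n"
        )
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
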