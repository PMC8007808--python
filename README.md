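# comodule

Signed weighted gene co-expression network analysis with dual-disease
module screening, multivariate joint association and gene-set
over-representation.

The package builds a signed co-expression network from a gene expression
matrix, detects modules on the topological-overlap dissimilarity, screens
module eigengenes for joint correlation with two groups of clinical traits
(six osteoporosis and four atherosclerosis traits by default), tests the
joint association of candidate modules and their member genes with a
bivariate trait outcome via Pillai's trace under three covariate-adjustment
models, and performs hypergeometric over-representation of module genes
against GMT gene-set collections with similarity-based clustering of the
enriched terms.  A simulation module generates expression matrices with
planted co-expression modules, wired trait tables and matching gene sets so
the whole pipeline is testable without access-restricted cohort data.

## Layout

| module                 | contents |
|------------------------|----------|
| `comodule.simulate`    | planted-module expression/trait/gene-set simulator |
| `comodule.network`     | correlation matrix, soft-threshold selection, signed adjacency, TOM |
| `comodule.detection`   | UPGMA clustering, static tree cut, eigengenes, MM/GS, GS–MM QC |
| `comodule.association` | eigengene–trait screen, Bonferroni, dual-disease candidate selection |
| `comodule.manova`      | SSCP fits, Pillai's trace, exact F test, module/gene joint association |
| `comodule.enrichment`  | GMT IO, hypergeometric test, pathway clustering |
| `comodule.io` / `comodule.pipeline` / `comodule.cli` | file formats, end-to-end runner, CLI |

## CLI

```bash
# write a synthetic dataset (expression.tsv, traits.csv, truth.tsv, gene_sets.gmt)
comodule simulate --n-samples 500 --module-sizes 50,30,20 --n-background 1400 \
    --seed 1 --out data/

# full pipeline: network -> modules -> screening -> MANOVA -> enrichment
comodule run-all --expression data/expression.tsv --traits data/traits.csv \
    --gene-sets data/gene_sets.gmt --out run/ --seed 1
```

`run-all` writes every intermediate table (TSV), dendrograms (Newick), the
resolved configuration (YAML) and a `manifest.json` recording all nine
pipeline stages, parameter values, Bonferroni family sizes and the chosen
soft power.  Individual stages are also exposed as `network`, `detect`,
`relate`, `manova` and `enrich` subcommands; `comodule run-all --config
cfg.yaml` reads a YAML configuration with CLI overrides.

Expression files default to genes-in-rows TSV; pass
`--orientation samples-rows` for the transposed layout.  Internally the
package works samples × genes.

## Acceptance

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance criteria for this artifact are property- and
simulation-based (TOM against a brute-force oracle, exact hypergeometric
enumeration, MANOVA type-I-error calibration, planted-module recovery,
confounding behaviour, end-to-end determinism); they are implemented in
`tests/test_acceptance.py`.  There are no numeric per-target values to
report, so the script runs a seeded end-to-end sanity check and writes an
empty JSON object.
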