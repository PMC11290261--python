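# mgpflux

Prediction of metabolite–gene–pathway sets (MGPs) — metabolites and
biosynthetic pathways whose activity differs significantly between samples
carrying a somatic mutation and wild-type samples — from three inputs:

1. a genome-scale metabolic model (SBML Level 3 + FBC, with GPR rules and
   subsystem/pathway annotations),
2. a per-sample gene expression table (TPM, TSV), and
3. a per-sample somatic variant table (gene, sample, alt-read count,
   consequence class).

The four-stage workflow:

1. **Flux-sums** — per-sample intracellular fluxes are fitted by
   least-absolute-deviation (LAD) matching of reaction flux magnitudes to
   GPR-derived expression scores (AND = min, OR = sum) under `S·v = 0`;
   each metabolite's flux-sum is its total production flux, decomposed by
   producing pathway.
2. **Metabolite–gene pairing** — flux-sums are quantile-normalized per
   cohort (exact zeros restored), then compared between mutant and
   wild-type groups with a two-sided Wilcoxon rank-sum test (p < 0.05).
3. **Pathway attribution** — per-pathway adjusted target flux-sums are
   tested the same way; exchange/demand/unassigned pathways and
   non-essential-amino-acid transport are excluded; pairs with no
   significant pathway are dropped.
4. **Outlier selection** — within each (metabolite, pathway) group, genes
   whose mean target flux-sum has |modified Z| > 3.5 are selected (groups
   of fewer than three genes are selected wholesale).

A metabolome validation arm is included: missingness filtering (>20%
dropped), feature-wise KNN imputation (k = 10), sum-normalization /
generalized log / autoscaling, direction-agnostic ROC-AUC per
(metabolite, gene), and a resampling-based empirical p-value for the
number of pairs exceeding an AUC threshold.

## CLI

```sh
# generate a toy model + simulated cohort with a planted effect
mgpflux simulate --out-dir sim --seed 3 --n-pathways 4 --reactions-per-pathway 5

# run all stages from a YAML config
mgpflux run --config config.yaml
```

Minimal `config.yaml`:

```yaml
model: sim/model.xml
expression: sim/expression.tsv
variants: sim/variants.tsv
metabolome: sim/metabolome.tsv   # optional
output_dir: out
alpha: 0.05
z_threshold: 3.5
knn_k: 10
seed: 3
```

Outputs in `output_dir`: per-sample flux states (`flux_states/*.tsv`),
`flux_sums.tsv`, `mg_pairs.tsv`, `mgps.tsv` (metabolite, gene, pathway,
p-values, modified Z, selection reason), optional `auc.tsv`, and
`manifest.json` (config hash, seed, stage tallies).

Individual stages are also exposed: `mgpflux fit-flux`, `mgpflux
flux-sum`, `mgpflux predict-mgp`, `mgpflux eval-metabolome`. Use `-v`
before the subcommand for debug logging.

## Package layout

- `mgpflux.gem` — SBML I/O, GPR parsing, reaction classification
  (metabolic / exchange / demand / transport / unassigned), currency and
  essential-amino-acid lists (defaults ship in `mgpflux/data/`).
- `mgpflux.flux` — expression→reaction scoring, two-stage LAD flux
  fitting (scipy HiGHS), flux-sums and pathway decomposition.
- `mgpflux.stats` — quantile normalization with zero restoration,
  Wilcoxon pairing (exact for small tie-free groups), modified Z-score,
  MGP selection, compartment-level pair deduplication.
- `mgpflux.cohort` — mutation filter cascade (alt reads ≥ 7,
  non-synonymous, ≥3 mutant and ≥3 wild-type, subset-gene removal),
  metabolome filtering/imputation/normalization, AUC, empirical p-value.
- `mgpflux.simulate` — deterministic toy models and simulated cohorts
  with planted ground truth.
- `mgpflux.benchmark` — seeded end-to-end recovery/null benchmarks.
- `mgpflux.pipeline` / `mgpflux.cli` — orchestration and the `mgpflux`
  command.
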