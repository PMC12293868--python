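# mcpkit

Estimating circulating malignant T-cell burden from bulk PBMC gene
expression, for treatment monitoring in leukemic cutaneous T-cell lymphoma
(CTCL / Sézary syndrome).

Sézary cells are CD4⁺CD26⁻ T cells that can make up most of a patient's
circulating lymphocytes before treatment and dwindle to a few percent during
remission — too few for routine flow cytometry to call confidently.  Because
bulk PBMC expression is (to first order) a mixture of malignant and normal
cells, a gene whose expression tracks the malignant fraction *f* behaves as

    x_g ≈ a_g + b_g · f        (a_g: normal-cell level, b_g: mixture slope)

`mcpkit` builds a full analysis pipeline around this mixture view:

- **Burden calibration** — a four-parameter Gaussian decay
  `f(t) = floor + p0·exp(−(t−t0)²/(2σ²))` fitted to the sparse
  flow-cytometry observations of a responding patient, extrapolating the
  malignant fraction to every treatment visit.
- **Malignancy-gene selection** — per-gene regression of abundance on the
  burden trajectory with batch covariates, Benjamini–Hochberg FDR < 5%, a
  positive-slope requirement, and a healthy-floor filter (genes whose
  late-treatment level drops significantly below healthy donors are
  discarded, one-sided p > 0.5 to keep).
- **Malignant cell predictor (MCP)** — per-gene calibration lines inverted
  by precision weighting, `f̂ = Σ w_g b_g (x_g − a_g) / Σ w_g b_g²` with
  `w_g = b_g²/s_g²`, clipped to [0, 100] percent, plus location/scale
  standardization for cross-platform cohorts.
- **Signatures** — surface-marker candidates (GO plasma-membrane/receptor
  annotation plus four differential-expression criteria), relapse
  re-expression flags, and the two-stage residual-disease cascade
  (remission ≥ 1.2-fold over healthy at FDR < 5%, then ≥ 20% further relapse
  increase at FDR < 5%).
- **Regulatory layers** — binding-motif enrichment (Bonferroni),
  treatment-induced miRNA families (≥ 2-fold, FDR < 0.1%) and their target
  coverage, methylation changes (|Δβ| ≥ 0.20, FDR < 5%), the activator/
  repressor ("yin-yang") Spearman anti-correlation, and hypergeometric
  overlaps with expected count (A×B)/C.
- **Synthetic cohorts** — a generator that plants all of the above with
  ground-truth tables (mixture expression, burden archetypes, batch
  effects, an anti-correlated TF pair, hypomethylated probes, induced miRNA
  families), so every stage is testable without any external data.

## Worked example

```python
from mcpkit import pipeline
from mcpkit.synthetic import CohortConfig, generate_cohort

bundle = generate_cohort(CohortConfig(seed=17))
core = pipeline.run_core_analysis(bundle)
print(len(core["selected_genes"]), core["burden_model"].r_squared)
```

Running the narrative scripts in `examples/` on the default cohort prints
(abridged):

```
$ python examples/02_burden_fit.py
fitted parameters: p0=0.900, t0=-0.00, sigma=6.16 visits, floor=0.030
goodness of fit R^2 = 1.0000

$ python examples/03_malignant_cell_predictor.py
selected 301 genes (recall of planted signature: 99.0%); strong (>=2-fold) subset: 245
training series:   r = 1.0000, MAE = 0.14 points
held-out patients: r = 0.9998, MAE = 0.31 points
healthy validation donors: max predicted 0.05%
external cohort (1.5x platform distortion, standardized): r = 0.9839

$ python examples/05_regulatory_layers.py
top motif: PARBZIP_MOTIF (fold 6.46, Bonferroni p = 1.64e-94)
treatment-induced miRNA families: 24 selected, 24/24 planted recovered
activator/repressor Spearman rho = -0.976 (p = 2.2e-19)
genes regulated by all three layers: 11
```

The burden fit recovers the planted decay exactly (observations are
noise-free in the generator); the predictor transfers to patient archetypes
it never saw while staying near zero on healthy donors; and the regulatory
screens rediscover exactly the planted miRNA families, motif and
triple-regulated gene core.

## Command line

`mcpkit` exposes the pipeline as subcommands over plain-text files
(TSV matrices, GMT gene sets, JSON models):

```bash
mcpkit simulate --seed 17 --out cohort/
mcpkit burden-fit --samples cohort/samples.tsv --out traj.tsv --model burden.json
mcpkit mcp-select --expr cohort/expression.tsv --samples cohort/samples.tsv \
    --trajectory traj.tsv --out assoc.tsv
mcpkit mcp-train --expr cohort/expression.tsv --trajectory traj.tsv \
    --associations assoc.tsv --model mcp.json
mcpkit mcp-predict --model mcp.json --expr new_samples.tsv --out pred.tsv
mcpkit report --bundle cohort/ --out summary.json
```

## Layout

```
src/mcpkit/     containers, io, cli, synthetic, preprocess, burden,
                mcp, signatures, regulation, pipeline
examples/       one narrative script per capability
docs/methods.md model, assumptions, parameter choices, limitations
tests/          pytest suite (unit, property, and acceptance tests)
```
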