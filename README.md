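# dabench

Benchmarking framework for differential-abundance (DA) methods on
feature-by-sample microbiome count matrices. It answers four questions about
a dataset and a set of DA methods:

1. **Goodness of fit** (`dabench gof`) — how well do five count
   distributions (NB, zero-inflated NB, zero-inflated Gaussian, hurdle /
   truncated Gaussian on log counts, Dirichlet-multinomial) estimate each
   feature's average count and probability of a zero?
2. **Type-I-error control** (`dabench tiec`) — on mock two-group labelings
   with no true DA, what are each method's false positive rate, false
   discovery readings, and KS departure of its p-values from uniformity?
3. **Concordance** (`dabench concordance`) — how stable are each method's
   top-ranked features across stratified half-splits (WMC), and how much do
   methods agree with each other on the same data (BMC), measured by
   concordance-at-top curves summarized into a rescaled area (1 = identical
   rankings, ~0 = independent)?
4. **Enrichment & power** (`dabench enrichment`, `dabench power`) —
   direction-aware 2x2 contingency tables against prior annotation with
   Fisher exact tests, features found by multiple methods, TP−FP ranking
   curves, and power / observed FDR on simulated data with known truth.

Three native DA methods are included (Wilcoxon rank-sum on normalized
abundances, Welch t-test on CLR-transformed counts with optional Dirichlet
Monte-Carlo instances, and NB regression with a Wald test), plus a plugin
contract (`test: plugin:<module.func>`) for custom methods. Normalizations:
TSS, CLR, TMM, RLE, CSS, none. Seeded synthetic generators
(`dabench simulate`, `dabench.synthetic`) provide null tables and spike-in
scenarios with known truth.

## CLI

Inputs are plain text: a TSV/CSV count matrix (`feature_id` column + one
column per sample) or a MatrixMarket triplet with `<stem>.rows.txt` /
`<stem>.cols.txt` sidecars; a metadata TSV with a `sample_id` column and a
group column; methods are declared in YAML:

```yaml
methods:
  - method_id: wilcox_tss
    test: wilcoxon          # wilcoxon | ttest_clr | negbin_wald | plugin:<module.func>
    normalization: TSS      # TSS | CLR | TMM | RLE | CSS | none
  - method_id: aldex_like
    test: ttest_clr
    normalization: none
    params: {mc_samples: 128}
    seed: 1
```

Examples:

```bash
dabench simulate --scenario scenario.yaml --out sim/
dabench gof --counts sim/counts.tsv --models nb,zinb,zig,hurdle,dm --out gof/
dabench tiec --counts sim/counts.tsv --methods methods.yaml --n-mocks 1000 --seed 7 --out tiec/
dabench concordance --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --group group --methods methods.yaml --n-splits 100 --maxk 100 --seed 7 --out conc/
dabench enrichment --counts sim/counts.tsv --metadata sim/metadata.tsv --group group \
    --annotation ann.tsv --direction-map dmap.yaml --methods methods.yaml --out enr/
dabench power --scenarios scenarios.yaml --methods methods.yaml --replicates 20 --seed 7 --out pow/
dabench all --config run.yaml --out results/
```

Every output directory contains tidy, plot-ready TSVs plus `config.yaml`
(the echoed effective configuration) and `manifest.json`. All computation is
deterministic given the seeds: rerunning a command reproduces its TSV
outputs byte-for-byte.

## Package layout

- `dabench.core` — count-table/metadata containers, validation, TSV/CSV/MTX
  I/O, BH adjustment.
- `dabench.normalization` — TSS/CLR/TMM/RLE/CSS factors.
- `dabench.gof` — the five distribution fitters and fit metrics (MD, ZPD,
  RMSEs).
- `dabench.methods` — method registry, native DA methods, plugin dispatch.
- `dabench.tiec` — mock labelings, FPR/FDR/KS summaries.
- `dabench.concordance` — half-splits, CAT curves, WMC/BMC.
- `dabench.enrichment` — contingency tables, Fisher tests, mutual findings,
  TP−FP curves, power analysis.
- `dabench.synthetic` — seeded null and spike-in generators with truth.
- `dabench.cli` — the `dabench` command.
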