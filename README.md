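# bpa-transform

Transform gene × cell log-expression matrices into **gene-set activity
profiles**: each cell's expression is rank-transformed to standard-normal
quantiles, and each gene set's normalized enrichment score (NES) is the sum
of its members' quantiles divided by √(set size). Because NES values are
approximately standard normal z-scores, activity matrices from different
datasets — and different species, when the gene-set *names* are shared —
can be merged directly without renormalization or ortholog prediction.

The package also ships the supporting machinery:

- `bpa.geneset_io` — GMT reader/writer, size-window and `_UP`-suffix
  filters, restriction of sets to the measured-gene universe.
- `bpa.bpa_core` — rank signatures, the NES transform, SD-based set
  selection; TSV/MTX input, TSV + JSON-provenance output.
- `bpa.crossspecies` — merging NES matrices on shared set names, ortholog
  collapse of expression matrices (the baseline the transform is compared
  against), dynamic time warping of staged trajectories.
- `bpa.mixing_stats` — pooled within-group variance, the species/batch
  mixing F-test, classical (Torgerson) MDS, dendrogram top-split purity.
- `bpa.dropout_sim` — four-parameter logistic drop-out curve: empirical
  fitting and seeded injection of drop-outs into complete matrices.
- `bpa.synthetic_fixtures` — deterministic generators for multi-cell-type /
  multi-batch matrices, two-species datasets with disjoint gene
  namespaces, and warped stage trajectories, with matched gene sets and
  ground-truth annotations.

## CLI

All functionality is exposed through the `bpa` command:

```sh
bpa fixtures --kind celltype --seed 7 --out-dir fx/           # synthetic inputs
bpa transform fx/expression.tsv fx/genesets.gmt \
    --min-size 50 --max-size 100 --annotations fx/annotations.tsv \
    --out activity.tsv
bpa mixing-test activity.tsv fx/annotations.tsv               # F-test JSON
bpa select-sd activity.tsv --top-k 10 --out selected.tsv
bpa fit-dropout-curve sc_expression.tsv --out curve.json
bpa simulate-dropout bulk.tsv --curve curve.json --seed 1 --out dropped.tsv
bpa merge activity_a.tsv activity_b.tsv --out merged.tsv
bpa dtw staged_a.tsv staged_b.tsv --stage-col stage
```

Expression input is TSV/CSV (genes in rows, cell-id header) or MatrixMarket
`.mtx` with `features.tsv` / `barcodes.tsv` sidecars. Gene sets are GMT.
Every output gets a `<name>.run.json` provenance sidecar; stochastic
commands require `--seed` and are bit-reproducible given it.

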