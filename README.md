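# birw

Prediction of disease–microbe associations by a step-limited **bi-random
walk** on a heterogeneous network, with the full cross-validation
evaluation protocol and a synthetic block-model data generator.

The pipeline:

1. **Associations** — read a two-column (disease, microbe) table,
   deduplicate it, and build a binary disease × microbe adjacency matrix
   `A` (diseases on rows, first-appearance index order).
2. **Similarities** — Gaussian interaction-profile (GIP) kernel similarity
   for microbes (columns of `A`) and diseases (rows of `A`); the disease
   kernel is additionally regulated by a logistic transform
   `SD = 1 / (1 + exp(c·K + d))` with defaults `c = −15`, `d = ln 9999`
   (so `K = 0` maps to exactly 0.0001).
3. **Walk** — two simultaneous, step-limited random walks propagate the
   association seed through the microbe similarity network (`l` steps,
   right multiplication) and the disease similarity network (`r` steps,
   left multiplication); active walks are averaged each step, weighted by
   a decay factor `α` against the seed. Defaults: `α = 0.4`, `l = r = 2`.
   By default both similarity matrices are Laplacian-normalized and the
   seed is scaled to unit mass (`--raw` disables both and iterates the
   update equations verbatim).
4. **Evaluation** — leave-one-out CV (similarities recomputed every
   round; each held-out association is ranked against all unverified
   pairs) and seeded repeated k-fold CV, plus per-disease top-k candidate
   ranking, ROC curves and Mann–Whitney AUC.

## CLI

```bash
# self-contained smoke test: simulate a block-structured network, evaluate it
birw simulate --n-diseases 20 --n-microbes 60 --n-blocks 4 \
    --p-in 0.6 --p-out 0.02 --seed 1 --out assoc.tsv
birw loocv assoc.tsv --alpha 0.4 --l 2 --r 2
birw kfold assoc.tsv --k 5 --repeats 100 --seed 0
birw predict assoc.tsv --out scores.tsv
birw rank assoc.tsv D1 --top-k 10
birw sweep assoc.tsv --alphas 0.2,0.4 --steps 1,2,3
```

All subcommands accept `--alpha --l --r --gamma-m --gamma-d --c
--d-offset --normalize/--raw`, a YAML `--config` with the same keys
(CLI flags win), and `--delimiter` / `--no-header` for the input table.

## The curated dataset

The published curated association export (483 records → 450 distinct
associations between 292 microbes and 39 diseases, from the HMDAD
database) is **not redistributed** in this repository. To run the
dataset-dependent evaluation paths, place the export as
`data/associations.tsv` (TSV with a header naming a disease column and a
microbe column) or set `BIRW_ASSOCIATIONS=/path/to/table`. Without it,
the dataset-dependent acceptance tests fail with a pointer to this
section and the acceptance report omits the dataset targets.

## Package layout

| module | contents |
| --- | --- |
| `birw.associations` | table parsing, deduplication, adjacency matrix, degree summaries |
| `birw.similarity`   | GIP bandwidth/kernel, logistic regulation, microbe/disease similarity |
| `birw.walk`         | Laplacian normalization, bi-random walk, end-to-end `predict` |
| `birw.evaluation`   | AUC/ROC, LOOCV, repeated k-fold CV, candidate ranking |
| `birw.synthetic`    | bipartite stochastic block model with closed-form expected density |
| `birw.datasets`     | locating/loading a locally supplied curated association table |
| `birw.cli`          | `birw` command-line interface |
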