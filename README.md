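# raregraph

Rare and major cell-population detection from matched single-cell
multiome data (scRNA-seq + scATAC-seq measured in the same cells), with
per-cluster enhancer–gene regulatory network (eGRN) inference.

Rare populations — clusters holding less than 3% of cells — are easily
absorbed into their nearest major population by standard clustering, or
conversely invented out of noise. `raregraph` addresses both failure
modes with a heterogeneous graph transformer over a cell–gene–peak graph:

- **Graph**: cells, genes and peaks are nodes; unweighted directed edges
  connect a gene or peak to every cell in which it is expressed or
  accessible. Node features are the raw count-matrix slices.
- **Rare-signal sampling**: training mini-batches are subgraphs of 30
  cells whose genes/peaks are drawn with probability proportional to
  cell-specificity, `x_ik / Σ_k x_ik` (after dropping genes below the
  first quartile of the cell's non-zero expression), so features private
  to few cells — the rare signal — dominate the batches.
- **Model**: per-edge-type multi-head attention with gated residual
  updates produces joint embeddings `H ∈ R^D`; a row-softmax head over
  `n_init` columns gives the cluster membership matrix `P`, and
  concatenated gene‖peak embeddings give per-cluster link memberships.
- **Objective** (minimized):

      L = KL_cluster − Cos_loss + KL_link + δ·Reg_loss

  reconstruction of both count matrices from embedding inner products,
  within-cluster cosine tightness, agreement of predicted link-cluster
  memberships with a count-derived baseline, and a class-balanced,
  label-smoothed cross-entropy (ε = 0.3) against Louvain clusters from
  the RNA modality that anchors major structure without forbidding rare
  splits.
- **eGRN**: per cluster CT, peak–gene links are scored by
  `PGS(i,j,CT) = Σ_{k∈CT} x^R_ik · x^RA_ij · x^A_jk / |CT|`, where
  `x^RA_ij = 2^(−d_ij/d0)` is the TSS distance-decay regulatory
  potential (half-decay 10 kb, zero beyond 150 kb); TF binding sites
  with p ≤ 0.05 overlapping a linked peak complete TF → peak → gene
  triplets.

A fully seeded synthetic multiome generator ships with the package and
reproduces the benchmark designs the method is evaluated on (300–5000
cells, rare fractions 0.5–3%, known marker programs and ground-truth
peak–gene links), so everything is testable offline. See
`docs/methods.md` for the model details and design rationale.

## Worked example

Simulate a 500-cell immune-style dataset with one 10-cell rare
population, train at reduced scale, and evaluate against the ground
truth:

```sh
raregraph simulate --preset sim-pbmc-1 --seed 1 --out data/
printf 'n_steps: 300\ndim: 64\nheads: 4\nlayers: 2\nseed: 0\n' > cfg.yaml
raregraph run --data data/ --config cfg.yaml --out run/
```

which prints

```
{
 "purity": 0.996,
 "entropy": 0.01081346901279131,
 "nmi": 0.8897025008586361,
 "tp": 10,
 "fp": 2,
 "fn": 0,
 "tn": 488,
 "precision": 0.8333333333333334,
 "recall": 1.0,
 "f1": 0.9090909090909091
}
```

All 10 truly rare cells land in one 12-cell cluster flagged rare
(`tp = 10`, `fn = 0`); the two other cells in that cluster are the only
false positives, giving rare-cell F1 = 0.909. Purity 0.996 and NMI 0.89
say the two-population structure is recovered essentially exactly.
`run/labels.tsv` holds per-barcode cluster ids and rare flags,
`run/history.tsv` the four loss components per training step, and
`run/model.npz` the checkpoint (reusable via `raregraph predict`).

The library API mirrors the CLI: `simulate_multiome`, `build_graph`,
`regulatory_potential`, `train`, `predict_full`, `peak_gene_score`,
`assemble_egrn`, and the metrics in `raregraph.metrics_eval`.

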