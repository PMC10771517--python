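"""Two-phase mini-batch training, whole-graph prediction, rare/major calls.

Phase 1 (default first 30% of steps) optimizes embedding quality only
(reconstruction KL minus within-cluster cosine); phase 2 optimizes the
full four-component objective. Batches are probability-sampled subgraphs
whose anchor-cell union covers every cell once per epoch. After training,
the model runs on the entire graph; non-empty clusters are renumbered by
decreasing size and clusters holding less than 3% of cells are flagged
rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .autodiff import Adam, Tensor, no_grad
from .hetgraph import HeteroGraph
from .hgt_core import (HGTConfig, ModelParams, batch_graph, cell_assignment,
                       encode, full_graph, init_params, link_assignment)
from .objective import (LossTerms, baseline_link_matrix,
                        class_balance_weights, cos_loss, kl_cluster,
                        kl_link, louvain_baseline, reg_loss,
                        smoothed_targets)
from .sampler import SubgraphSampler


@dataclass
class TrainConfig:
    n_steps: int = 300
    phase1_frac: float = 0.3        # share of steps in the warm-up phase
    n_cells_per_batch: int = 30
    cap: int = 20                   # genes and peaks per cell
    lr: float = 0.001
    weight_decay: float = 0.1
    smoothing: float = 0.3          # label-smoothing epsilon
    delta: float = 1.0              # weight of the regularizer
    seed: int = 0
    dim: int = 256
    heads: int = 8
    layers: int = 2
    n_init: int | None = 100        # cluster-head width; None -> dim
    # coarse anchor on purpose: the regularizer protects robust major
    # structure; over-resolved anchors inject arbitrary sub-classes of
    # homogeneous populations that no feature-based head can reproduce
    louvain_resolution: float = 0.5
    rare_threshold: float = 0.03

    def __post_init__(self):
        if self.n_steps < 0 or self.n_cells_per_batch <= 0 or self.cap <= 0:
            raise ValueError("counts must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    def model_config(self) -> HGTConfig:
        return HGTConfig(dim=self.dim, heads=self.heads, layers=self.layers,
                         n_init=self.n_init)


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-cell cluster id, 1..K, size-ordered
    P: np.ndarray               # full membership matrix (cells x n_init)
    cluster_sizes: np.ndarray   # length K
    rare: np.ndarray            # per-cluster rare flag, length K
    cell_ids: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.cluster_sizes.size

    def cell_rare_flags(self) -> np.ndarray:
        return self.rare[self.labels - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.cell_ids,
                             "cluster": self.labels,
                             "rare_flag": self.cell_rare_flags()})


def rare_flag(cluster_sizes: np.ndarray, n_cells: int,
              threshold: float = 0.03) -> np.ndarray:
    """A cluster is rare iff it holds strictly less than ``threshold``
    (default 3%) of all cells."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    return sizes / n_cells < threshold


def _candidate_links(batch, xra: sp.spmatrix):
    """Gene-peak pairs inside the batch with positive regulatory potential;
    returns local gene/peak indices and their scores."""
    sub = sp.coo_matrix(xra[batch.genes][:, batch.peaks])
    return sub.row, sub.col, sub.data


def _loss_terms(params, batch, bg, config, louvain_labels, n_louvain,
                xra, class_weights=None
                ) -> tuple[LossTerms, Tensor, np.ndarray]:
    Hc, Hg, Hp = encode(params, bg)
    P, pred = cell_assignment(params, Hc)
    klc = kl_cluster(Hg, Hp, Hc, batch.xr, batch.xa)
    cos = cos_loss(Hc, pred)
    nk = params.config.n_clusters
    if xra is not None and batch.genes.size and batch.peaks.size:
        gi, pj, vals = _candidate_links(batch, xra)
    else:
        gi = np.array([], dtype=int)
    if gi.size:
        o_hat = link_assignment(params, Hg, Hp, gi, pj)
        o_base = baseline_link_matrix(batch.xr, batch.xa, vals, gi, pj,
                                      pred, nk)
        kll = kl_link(o_hat, o_base)
    else:
        kll = Tensor(0.0)
    batch_louvain = louvain_labels[batch.cells]
    y = smoothed_targets(batch_louvain, n_louvain, config.smoothing)
    w = (class_weights[batch_louvain - 1]
         if class_weights is not None else None)
    reg = reg_loss(P, y, weights=w)
    terms = LossTerms(klc, cos, kll, reg, delta=config.delta)
    return terms, P, pred


def train(graph: HeteroGraph, config: TrainConfig,
          xra: sp.spmatrix | None = None
          ) -> tuple[ModelParams, pd.DataFrame]:
    """Train the graph transformer on probability-sampled subgraphs.

    ``xra`` is the gene x peak regulatory-potential matrix; without it the
    link component is skipped. Returns trained parameters and a per-step
    history of all loss components.
    """
    rng = np.random.default_rng(config.seed)
    params = init_params(rng, cell_feat=graph.n_genes,
                         gene_feat=graph.n_cells,
                         peak_feat=graph.n_cells,
                         config=config.model_config())
    history: list[dict] = []
    if config.n_steps == 0:
        return params, pd.DataFrame(history)

    louvain_labels, n_louvain = louvain_baseline(
        graph.xr, seed=config.seed, resolution=config.louvain_resolution)
    class_weights = class_balance_weights(louvain_labels, n_louvain)
    if params.config.n_clusters < n_louvain:
        raise ValueError(
            f"cluster head width {params.config.n_clusters} is smaller "
            f"than the {n_louvain} Louvain classes; increase dim/n_init")

    opt = Adam(params.tensors, lr=config.lr,
               weight_decay=config.weight_decay,
               no_decay=params.no_decay_keys())
    sampler = SubgraphSampler(graph, config.n_cells_per_batch, config.cap)
    phase1_steps = int(round(config.n_steps * config.phase1_frac))
    batches = sampler.epoch(rng)
    for step in range(config.n_steps):
        try:
            batch = next(batches)
        except StopIteration:
            batches = sampler.epoch(rng)
            batch = next(batches)
        bg = batch_graph(graph, batch)
        terms, _, _ = _loss_terms(params, batch, bg, config,
                                  louvain_labels, n_louvain, xra,
                                  class_weights=class_weights)
        phase = 1 if step < phase1_steps else 2
        loss = (terms.kl_cluster - terms.cos_loss if phase == 1
                else terms.total)
        row = terms.values()
        if not all(np.isfinite(v) for v in row.values()):
            bad = [k for k, v in row.items() if not np.isfinite(v)]
            raise RuntimeError(f"non-finite loss component(s) at step "
                               f"{step}: {bad}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        row.update(step=step, phase=phase)
        history.append(row)
    return params, pd.DataFrame(history)


def predict_full(graph: HeteroGraph, params: ModelParams,
                 rare_threshold: float = 0.03) -> ClusterResult:
    """Apply a trained model to the whole graph (all edges, no sampling).

    Cluster ids are the argmax columns of P; empty clusters are dropped and
    survivors renumbered by decreasing size (ties: lower column first).
    """
    bg = full_graph(graph)
    with no_grad():
        Hc, _, _ = encode(params, bg)
        P, raw = cell_assignment(params, Hc)
    present, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((present, -counts))
    mapping = {int(present[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([mapping[int(r)] for r in raw])
    sizes = counts[order]
    return ClusterResult(labels=labels, P=P.data, cluster_sizes=sizes,
                         rare=rare_flag(sizes, graph.n_cells,
                                        rare_threshold),
                         cell_ids=np.asarray(graph.cell_ids, dtype=object))
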