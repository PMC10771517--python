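"""Heterogeneous graph transformer: typed input projections, per-edge-type
multi-head attention, gated residual updates, and the two prediction heads.

Each node type (cell, gene, peak) has its own input projection to a shared
embedding width D. Within a layer, shared query/key/value maps are split
into H heads; every edge type carries its own attention and message
transforms (W^ATT, W^MSG). Attention is a softmax over *all* neighbors of
the target node (across edge types), messages are attention-weighted sums
per head, and the layer output is a gated residual
``alpha * ReLU(aggregate) + (1 - alpha) * previous`` with a trainable gate
alpha clamped to [0, 1].

Cell cluster assignment: the cell embedding row-softmax is the membership
matrix P, so the number of candidate clusters equals the embedding width
(an optional linear head decouples the two). Link assignment concatenates
gene and peak embeddings and maps them through linear + ReLU to a
per-cluster probability row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .hetgraph import HeteroGraph
from .sampler import SubgraphBatch


@dataclass
class HGTConfig:
    dim: int = 256          # embedding width D
    heads: int = 8          # attention heads H
    layers: int = 2         # transformer layers L
    n_init: int | None = None  # cluster-head width; None -> dim (identity)

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")

    @property
    def n_clusters(self) -> int:
        return self.dim if self.n_init is None else self.n_init


N_EDGE_TYPES = 4  # gene->cell, cell->gene, peak->cell, cell->peak


class ModelParams:
    """Named parameter collection plus hyperparameters."""

    def __init__(self, tensors: dict, config: HGTConfig, feat_dims: tuple):
        self.tensors = tensors
        self.config = config
        self.feat_dims = feat_dims  # (cell_feat, gene_feat, peak_feat)

    def __getitem__(self, key) -> Tensor:
        return self.tensors[key]

    def no_decay_keys(self) -> set:
        return {k for k in self.tensors
                if k.startswith("b_") or k.startswith("alpha")}

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: Parameter(v.data.copy()) for k, v in self.tensors.items()},
            self.config, self.feat_dims)


def init_params(rng: np.random.Generator, cell_feat: int, gene_feat: int,
                peak_feat: int, config: HGTConfig | None = None
                ) -> ModelParams:
    config = config or HGTConfig()
    D, H, L = config.dim, config.heads, config.layers
    d = D // H
    t: dict = {}
    for name, fan_in in (("C", cell_feat), ("G", gene_feat),
                         ("E", peak_feat)):
        t[f"W_{name}"] = ad.glorot(rng, fan_in, D)
        t[f"b_{name}"] = Parameter(np.zeros(D))
    for l in range(L):
        for name in ("q", "k", "v"):
            t[f"W_{name}{l}"] = ad.glorot(rng, D, D)
            t[f"b_{name}{l}"] = Parameter(np.zeros(D))
        t[f"W_att{l}"] = ad.glorot(rng, d, d, shape=(N_EDGE_TYPES, H, d, d))
        t[f"W_msg{l}"] = ad.glorot(rng, d, d, shape=(N_EDGE_TYPES, H, d, d))
        t[f"alpha{l}"] = Parameter(np.array(0.5))
    nk = config.n_clusters
    t["W_link"] = ad.glorot(rng, 2 * D, nk)
    t["b_link"] = Parameter(np.zeros(nk))
    if config.n_init is not None and config.n_init != D:
        # near-zero init: cluster columns are carved by the training
        # signal instead of random projections, so unused columns never
        # win an argmax
        t["W_cell"] = Parameter(rng.normal(0.0, 1e-3, size=(D,
                                                            config.n_init)))
        t["b_cell"] = Parameter(np.zeros(config.n_init))
    return ModelParams(t, config, (cell_feat, gene_feat, peak_feat))


# -- batch graph: node features + typed edge arrays --------------------------

@dataclass
class BatchGraph:
    """Induced subgraph in the layout the transformer consumes.

    Global node order is [cells | genes | peaks]; ``edges[t]`` holds
    (src, dst) global index arrays for edge type t in the order
    gene->cell, cell->gene, peak->cell, cell->peak.
    """

    feat_c: sp.csr_matrix
    feat_g: sp.csr_matrix
    feat_p: sp.csr_matrix
    edges: list
    n_cells: int
    n_genes: int
    n_peaks: int

    @property
    def n_nodes(self) -> int:
        return self.n_cells + self.n_genes + self.n_peaks


def _typed_edges(xr_sub: sp.spmatrix, xa_sub: sp.spmatrix,
                 nc: int, ng: int) -> list:
    gc = sp.coo_matrix(xr_sub)
    pc = sp.coo_matrix(xa_sub)
    goff, poff = nc, nc + ng
    return [(goff + gc.row, gc.col),          # gene -> cell
            (gc.col, goff + gc.row),          # cell -> gene
            (poff + pc.row, pc.col),          # peak -> cell
            (pc.col, poff + pc.row)]          # cell -> peak


def batch_graph(graph: HeteroGraph, batch: SubgraphBatch) -> BatchGraph:
    feat_c = sp.csr_matrix(graph.xr[:, batch.cells].T)
    feat_g = sp.csr_matrix(graph.xr[batch.genes]) if batch.genes.size \
        else sp.csr_matrix((0, graph.n_cells))
    feat_p = sp.csr_matrix(graph.xa[batch.peaks]) if batch.peaks.size \
        else sp.csr_matrix((0, graph.n_cells))
    edges = _typed_edges(batch.xr, batch.xa, batch.n_cells,
                         batch.genes.size)
    return BatchGraph(feat_c, feat_g, feat_p, edges, batch.n_cells,
                      batch.genes.size, batch.peaks.size)


def full_graph(graph: HeteroGraph) -> BatchGraph:
    edges = _typed_edges(graph.xr, graph.xa, graph.n_cells, graph.n_genes)
    return BatchGraph(graph.cell_features(), graph.gene_features(),
                      graph.peak_features(), edges, graph.n_cells,
                      graph.n_genes, graph.n_peaks)


# -- forward pass ------------------------------------------------------------

def _log1p_sparse(mat: sp.spmatrix) -> sp.csr_matrix:
    out = sp.csr_matrix(mat, copy=True).astype(float)
    out.data = np.log1p(out.data)
    return out


def init_embed(params: ModelParams, bg: BatchGraph) -> Tensor:
    """Layer-0 embeddings: per-type linear projection of the node features.

    Counts are log1p-transformed before projection (variance
    stabilization; raw counts remain the reconstruction targets and the
    sampling weights).
    """
    cf, gf, pf = params.feat_dims
    for mat, dim, name in ((bg.feat_c, cf, "cell"), (bg.feat_g, gf, "gene"),
                           (bg.feat_p, pf, "peak")):
        if mat.shape[0] and mat.shape[1] != dim:
            raise ValueError(f"{name} feature dim {mat.shape[1]} != "
                             f"projection fan-in {dim}")
    parts = []
    if bg.n_cells:
        parts.append(ad.spmm(_log1p_sparse(bg.feat_c), params["W_C"])
                     + params["b_C"])
    if bg.n_genes:
        parts.append(ad.spmm(_log1p_sparse(bg.feat_g), params["W_G"])
                     + params["b_G"])
    if bg.n_peaks:
        parts.append(ad.spmm(_log1p_sparse(bg.feat_p), params["W_E"])
                     + params["b_E"])
    return ad.concat(parts, axis=0) if len(parts) > 1 else parts[0]


def hgt_layer(params: ModelParams, layer: int, H_prev: Tensor,
              bg: BatchGraph) -> Tensor:
    cfg = params.config
    D, nh = cfg.dim, cfg.heads
    d = D // nh
    n = bg.n_nodes
    Q = ad.matmul(H_prev, params[f"W_q{layer}"]) + params[f"b_q{layer}"]
    K = ad.matmul(H_prev, params[f"W_k{layer}"]) + params[f"b_k{layer}"]
    V = ad.matmul(H_prev, params[f"W_v{layer}"]) + params[f"b_v{layer}"]
    Watt, Wmsg = params[f"W_att{layer}"], params[f"W_msg{layer}"]

    live = [(t, src, dst) for t, (src, dst) in enumerate(bg.edges)
            if src.size]
    if not live:
        Hp = Tensor(np.zeros((n, D)))
    else:
        dst_all = np.concatenate([dst for _, _, dst in live])
        head_outs = []
        for h in range(nh):
            sl = slice(h * d, (h + 1) * d)
            Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
            scores, msgs = [], []
            scale = 1.0 / np.sqrt(d)  # standard attention temperature
            for t, src, dst in live:
                KW = ad.matmul(Kh[src], Watt[t, h])
                scores.append(ad.mul(ad.tsum(ad.mul(KW, Qh[dst]), axis=1),
                                     scale))
                msgs.append(ad.matmul(Vh[src], Wmsg[t, h]))
            s_all = ad.concat(scores) if len(scores) > 1 else scores[0]
            m_all = ad.concat(msgs, axis=0) if len(msgs) > 1 else msgs[0]
            att = ad.segment_softmax(s_all, dst_all, n)
            agg = ad.segment_sum(ad.mul(att.reshape((-1, 1)), m_all),
                                 dst_all, n)
            head_outs.append(agg)
        Hp = ad.concat(head_outs, axis=1)
    alpha = ad.clip(params[f"alpha{layer}"], 0.0, 1.0)
    return ad.add(ad.mul(alpha, ad.relu(Hp)),
                  ad.mul(1.0 - alpha, H_prev))


def encode(params: ModelParams, bg: BatchGraph
           ) -> tuple[Tensor, Tensor, Tensor]:
    """Full forward pass; returns final-layer (cells, genes, peaks)."""
    H = init_embed(params, bg)
    for l in range(params.config.layers):
        H = hgt_layer(params, l, H, bg)
    nc, ng = bg.n_cells, bg.n_genes
    return H[:nc], H[nc:nc + ng], H[nc + ng:]


def cell_assignment(params: ModelParams, H_cells: Tensor
                    ) -> tuple[Tensor, np.ndarray]:
    """Cluster membership P (row softmax) and argmax labels (0-based,
    ties to the lowest index)."""
    if "W_cell" in params.tensors:
        logits = ad.matmul(H_cells, params["W_cell"]) + params["b_cell"]
    else:
        logits = H_cells
    P = ad.softmax_rows(logits)
    return P, P.data.argmax(axis=1)


def link_assignment(params: ModelParams, H_genes: Tensor, H_peaks: Tensor,
                    gene_idx: np.ndarray, peak_idx: np.ndarray) -> Tensor:
    """Per-link cluster membership O-hat for candidate gene-peak pairs.

    Rows are linear+ReLU scores of the concatenated embeddings, floored at
    1e-8 and normalized to sum to one.
    """
    Q = ad.concat([H_genes[gene_idx], H_peaks[peak_idx]], axis=1)
    scores = ad.relu(ad.matmul(Q, params["W_link"]) + params["b_link"])
    floored = ad.clip(scores, 1e-8, None)
    return ad.div(floored, ad.tsum(floored, axis=1, keepdims=True))


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(params: ModelParams, path) -> None:
    """Binary array archive + JSON sidecar of hyperparameters."""
    stem = str(path)
    if stem.endswith(".npz"):
        stem = stem[:-4]
    Path(stem).parent.mkdir(parents=True, exist_ok=True)
    np.savez(stem + ".npz", **{k: v.data for k, v in params.tensors.items()})
    sidecar = {"config": asdict(params.config),
               "feat_dims": list(params.feat_dims)}
    Path(stem + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> ModelParams:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    arrays = np.load(path)
    sidecar = json.loads(Path(path[:-4] + ".json").read_text())
    tensors = {k: Parameter(arrays[k]) for k in arrays.files}
    return ModelParams(tensors, HGTConfig(**sidecar["config"]),
                       tuple(sidecar["feat_dims"]))
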