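"""Multi-task training objective.

total = KL_cluster - Cos_loss + KL_link + delta * Reg_loss

(1) KL_cluster: the gene-cell and peak-cell embedding inner products,
    rectified and normalized to distributions, should reconstruct the
    RNA / ATAC count slices (KL(predicted || target)).
(2) Cos_loss: mean pairwise cosine similarity of cell embeddings within
    the currently predicted clusters (maximized, hence subtracted);
    normalized by the pair count so the term is bounded in [-1, 1].
(3) KL_link: predicted link-cluster memberships against a baseline built
    from regulatory potential weighted by per-cluster expression and
    accessibility.
(4) Reg_loss: label-smoothed cross-entropy of the cluster memberships
    against Louvain labels computed on the RNA modality, which anchors the
    major populations while the smoothing factor leaves room for rare
    cells to deviate.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-8


# -- component (1): reconstruction KL ----------------------------------------

def kl_flat(pred: Tensor, target: np.ndarray) -> Tensor:
    """KL(pred~ || target~) after flattening, flooring at 1e-8 and
    normalizing both sides to probability vectors."""
    t = np.asarray(target, dtype=float).ravel()
    if t.size == 0 or t.sum() <= 0:
        warnings.warn("all-zero target slice: KL term contributes 0")
        return Tensor(0.0)
    q = np.maximum(t, EPS)
    q = q / q.sum()
    p = ad.clip(pred.reshape((-1,)), EPS, None)
    p = ad.div(p, ad.tsum(p))
    return ad.tsum(ad.mul(p, ad.log(p) - np.log(q)))


def kl_cluster(H_genes: Tensor, H_peaks: Tensor, H_cells: Tensor,
               xr_batch, xa_batch) -> Tensor:
    """Reconstruction KL for both modalities on the batch slices."""
    total = Tensor(0.0)
    if H_genes.shape[0]:
        rec = ad.relu(ad.matmul(H_genes, H_cells.T))
        total = total + kl_flat(rec, _dense(xr_batch))
    if H_peaks.shape[0]:
        rec = ad.relu(ad.matmul(H_peaks, H_cells.T))
        total = total + kl_flat(rec, _dense(xa_batch))
    return total


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x)


# -- component (2): within-cluster cosine ------------------------------------

def cos_loss(H_cells: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cosine similarity over unordered within-cluster cell pairs.

    For unit rows h, sum_{a<b in c} cos(h_a, h_b) =
    (||sum_c h||^2 - n_c) / 2, so the whole term needs one segment sum.
    Returns 0 when every cluster is a singleton.
    """
    labels = np.asarray(labels)
    k = labels.max() + 1 if labels.size else 0
    counts = np.bincount(labels, minlength=k)
    n_pairs = float((counts * (counts - 1) // 2).sum())
    if n_pairs == 0:
        return Tensor(0.0)
    norms = ad.sqrt(ad.tsum(ad.mul(H_cells, H_cells), axis=1,
                            keepdims=True) + 1e-12)
    Hn = ad.div(H_cells, norms)
    S = ad.segment_sum(Hn, labels, k)
    sq = ad.tsum(ad.mul(S, S))
    return ad.mul(sq - float(labels.size), 0.5 / n_pairs)


# -- component (3): link KL ---------------------------------------------------

def baseline_link_matrix(xr_batch, xa_batch, xra_vals: np.ndarray,
                         gene_idx: np.ndarray, peak_idx: np.ndarray,
                         labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Row-normalized baseline O for candidate links.

    O_raw[(i,j), c] = mean over cells k in cluster c of
    x^R_ik * x^RA_ij * x^A_jk; empty clusters receive the floor value.
    """
    xr = _dense(xr_batch)
    xa = _dense(xa_batch)
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_clusters).astype(float)
    onehot = np.zeros((labels.size, n_clusters))
    onehot[np.arange(labels.size), labels] = 1.0
    per_cell = xr[gene_idx] * xa[peak_idx]          # links x cells
    raw = (per_cell @ onehot) * xra_vals[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(counts > 0, raw / np.maximum(counts, 1.0), EPS)
    raw = np.maximum(raw, EPS)
    return raw / raw.sum(axis=1, keepdims=True)


def kl_link(o_hat: Tensor, o_base: np.ndarray) -> Tensor:
    """Mean over candidate links of KL(predicted row || baseline row)."""
    if o_hat.shape[0] == 0:
        return Tensor(0.0)
    row_kl = ad.tsum(ad.mul(o_hat, ad.log(o_hat) - np.log(o_base)), axis=1)
    return ad.mean(row_kl)


# -- component (4): Louvain-anchored smoothed cross-entropy ------------------

def louvain_baseline(xr, seed: int = 0, resolution: float = 1.0,
                     n_hvg: int = 2000, n_pcs: int = 50,
                     n_neighbors: int = 15) -> tuple[np.ndarray, int]:
    """Louvain cluster labels (1..T) from the RNA modality.

    Pipeline: library-size normalization to the median depth + log1p, top
    variable genes, PCA, 15-NN graph with shared-nearest-neighbor Jaccard
    edge weights (the Seurat convention, which suppresses spurious
    fragmentation of homogeneous regions), igraph multilevel (Louvain)
    community detection at the given resolution; fully seeded.
    """
    values = xr.values if hasattr(xr, "values") else xr
    X = np.asarray(sp.csr_matrix(values).T.todense(), dtype=float)
    n = X.shape[0]
    if n < 2:
        return np.ones(max(n, 1), dtype=int), 1
    totals = X.sum(axis=1)
    target = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    X = np.log1p(X / np.maximum(totals, 1.0)[:, None] * target)
    if X.shape[1] > n_hvg:
        hvg = np.argsort(X.var(axis=0))[::-1][:n_hvg]
        X = X[:, hvg]
    if np.allclose(X, X[0]):  # identical cells: one trivial cluster
        return np.ones(n, dtype=int), 1
    ncomp = min(n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=ncomp, random_state=seed).fit_transform(X)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    keep = rows != cols
    adj = sp.csr_matrix((np.ones(keep.sum()), (rows[keep], cols[keep])),
                        shape=(n, n))
    adj = adj.maximum(adj.T)
    # shared-neighbor (Jaccard) weights on the union KNN graph
    common = adj @ adj.T
    deg = adj.getnnz(axis=1)
    coo = sp.coo_matrix(sp.triu(adj, k=1))
    c = np.asarray(common[coo.row, coo.col]).ravel()
    jac = c / (deg[coo.row] + deg[coo.col] - c)
    igraph.set_random_number_generator(random.Random(seed))
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(),
                                         coo.col.tolist())))
    member = g.community_multilevel(weights=jac.tolist(),
                                    resolution=resolution).membership
    labels = np.asarray(member, dtype=int) + 1
    return labels, int(labels.max())


def smoothed_targets(labels: np.ndarray, n_classes: int,
                     smoothing: float = 0.3) -> np.ndarray:
    """Label-smoothed targets: 1 - eps + eps/T on the own class, eps/T
    elsewhere (labels are 1-based)."""
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    labels = np.asarray(labels)
    y = np.full((labels.size, n_classes), smoothing / n_classes)
    y[np.arange(labels.size), labels - 1] += 1.0 - smoothing
    return y


def class_balance_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-class-frequency weights, N / (T * class size), so each
    anchor class contributes equally to the regularizer regardless of its
    abundance — this is what keeps a small population's anchor from being
    swallowed by the majority's gradient."""
    labels = np.asarray(labels)
    freq = np.bincount(labels, minlength=n_classes + 1)[1:]
    return labels.size / (n_classes * np.maximum(freq, 1))


def reg_loss(P: Tensor, y: np.ndarray,
             weights: np.ndarray | None = None) -> Tensor:
    """Smoothed cross-entropy of cluster memberships vs targets, summed
    over the batch cells (optionally per-cell weighted).

    The sum (not mean) form keeps the anchor strong relative to the
    bounded embedding terms; class-balance weights (see
    :func:`class_balance_weights`) equalize the rare and major signal.
    ``y`` has T columns; the first T columns of P carry the Louvain
    classes, so P must be at least T wide.
    """
    t = y.shape[1]
    if P.shape[1] < t:
        raise ValueError(f"P has {P.shape[1]} columns but targets need {t}")
    logp = ad.log(P[:, :t] + EPS)
    ce_rows = ad.tsum(ad.mul(Tensor(-y), logp), axis=1)
    if weights is None:
        return ad.tsum(ce_rows)
    return ad.tsum(ad.mul(ce_rows, Tensor(np.asarray(weights, dtype=float))))


# -- combination --------------------------------------------------------------

@dataclass
class LossTerms:
    kl_cluster: Tensor
    cos_loss: Tensor
    kl_link: Tensor
    reg_loss: Tensor
    delta: float = 1.0

    @property
    def total(self) -> Tensor:
        return (self.kl_cluster - self.cos_loss + self.kl_link
                + ad.mul(self.reg_loss, self.delta))

    def values(self) -> dict:
        return {"kl_cluster": self.kl_cluster.item(),
                "cos_loss": self.cos_loss.item(),
                "kl_link": self.kl_link.item(),
                "reg_loss": self.reg_loss.item(),
                "total": self.total.item()}
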