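"""Probability-based subgraph sampling that favors rare-cell signal.

For each anchor cell, lowly expressed genes are dropped (below the first
quartile of the cell's non-zero expression values), and the remaining
genes/peaks are drawn without replacement with probability proportional to
their cell-specificity: the count in the anchor cell divided by the
feature's total count across all cells. A feature private to one cell thus
gets maximal weight, a ubiquitous one is down-weighted. Subgraphs hold 30
anchor cells with up to 20 genes and 20 peaks per cell by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hetgraph import HeteroGraph


def gene_threshold(cell_expression: np.ndarray) -> float:
    """First quartile (linear interpolation) of a cell's non-zero counts.

    Returns 0 when the cell expresses fewer than four genes, so the
    low-expression filter becomes vacuous for near-empty cells.
    """
    v = np.asarray(cell_expression, dtype=float)
    if (v < 0).any():
        raise ValueError("negative expression values")
    nz = v[v > 0]
    if nz.size == 0:
        warnings.warn("all-zero cell: threshold 0, no candidates will pass")
        return 0.0
    if nz.size < 4:
        return 0.0
    return float(np.percentile(nz, 25))


def _specificity_probs(column: np.ndarray, row_sums: np.ndarray,
                       candidates: np.ndarray) -> np.ndarray:
    prop = column[candidates] / row_sums[candidates]
    total = prop.sum()
    if total <= 0:
        raise ValueError("degenerate candidate weights")
    return prop / total


def gene_select_probs(xr, cell: int, a: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Candidate gene indices and their selection probabilities for a cell.

    Candidates are genes with expression strictly above the quartile
    threshold ``a``; if that set is empty (degenerate ties), all expressed
    genes are used instead.
    """
    values = xr.values if hasattr(xr, "values") else xr
    col = np.asarray(values[:, cell].todense()).ravel()
    row_sums = np.asarray(values.sum(axis=1)).ravel()
    cand = np.flatnonzero(col > a)
    if cand.size == 0:
        cand = np.flatnonzero(col > 0)
    if cand.size == 0:
        raise ValueError(f"cell {cell} has no expressed genes")
    return cand, _specificity_probs(col, row_sums, cand)


def peak_select_probs(xa, cell: int) -> tuple[np.ndarray, np.ndarray]:
    """Accessible-peak indices and selection probabilities for a cell.

    No quartile step: near-binary ATAC counts make it uninformative; all
    accessible peaks are candidates.
    """
    values = xa.values if hasattr(xa, "values") else xa
    col = np.asarray(values[:, cell].todense()).ravel()
    cand = np.flatnonzero(col > 0)
    if cand.size == 0:
        warnings.warn(f"cell {cell} has no accessible peaks")
        return cand, np.array([])
    row_sums = np.asarray(values.sum(axis=1)).ravel()
    return cand, _specificity_probs(col, row_sums, cand)


def weighted_sample_without_replacement(items: np.ndarray,
                                        weights: np.ndarray, k: int,
                                        rng: np.random.Generator
                                        ) -> np.ndarray:
    """Draw min(k, n) items without replacement, probability ~ weight.

    Uses exponential sort keys (one key log(u)/w per item, top-k), which is
    distributionally identical to sequential weighted draws without
    replacement.
    """
    items = np.asarray(items)
    n = items.size
    if k >= n:
        return items.copy()
    keys = np.log(rng.random(n)) / weights
    top = np.argpartition(-keys, k - 1)[:k]
    return items[top]


@dataclass
class SubgraphBatch:
    """One mini-batch: anchor cells, their selected genes/peaks, and the
    edges induced among the selected nodes."""

    cells: np.ndarray                 # indices into the full graph
    genes: np.ndarray                 # unique, sorted
    peaks: np.ndarray
    genes_per_cell: dict = field(repr=False, default_factory=dict)
    peaks_per_cell: dict = field(repr=False, default_factory=dict)
    xr: sp.csr_matrix = None          # genes x cells induced RNA slice
    xa: sp.csr_matrix = None          # peaks x cells induced ATAC slice
    rng_seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.cells.size


class SubgraphSampler:
    """Samples probability-weighted subgraphs from a heterogeneous graph."""

    def __init__(self, graph: HeteroGraph, n_cells: int = 30, cap: int = 20):
        self.graph = graph
        self.n_cells = n_cells
        self.cap = cap
        self._xr_csc = graph.xr.tocsc()
        self._xa_csc = graph.xa.tocsc()
        self._gene_sums = np.asarray(graph.xr.sum(axis=1)).ravel()
        self._peak_sums = np.asarray(graph.xa.sum(axis=1)).ravel()

    # per-cell selections ----------------------------------------------------
    def _select_genes(self, cell: int, rng) -> np.ndarray:
        col = self._xr_csc[:, cell]
        idx, vals = col.indices, col.data
        if idx.size == 0:
            return np.array([], dtype=int)
        a = gene_threshold(vals) if idx.size >= 4 else 0.0
        mask = vals > a
        if not mask.any():  # degenerate ties: fall back to all expressed
            mask = np.ones(idx.size, dtype=bool)
        cand = idx[mask]
        w = vals[mask] / self._gene_sums[cand]
        return weighted_sample_without_replacement(cand, w, self.cap, rng)

    def _select_peaks(self, cell: int, rng) -> np.ndarray:
        col = self._xa_csc[:, cell]
        idx, vals = col.indices, col.data
        if idx.size == 0:
            return np.array([], dtype=int)
        w = vals / self._peak_sums[idx]
        return weighted_sample_without_replacement(idx, w, self.cap, rng)

    # batch assembly ---------------------------------------------------------
    def assemble(self, cells: np.ndarray, rng: np.random.Generator,
                 seed: int | None = None) -> SubgraphBatch:
        gsel = {int(c): self._select_genes(c, rng) for c in cells}
        psel = {int(c): self._select_peaks(c, rng) for c in cells}
        genes = np.unique(np.concatenate([*gsel.values(),
                                          np.array([], dtype=int)]))
        peaks = np.unique(np.concatenate([*psel.values(),
                                          np.array([], dtype=int)]))
        xr_sub = self.graph.xr[genes][:, cells] if genes.size else \
            sp.csr_matrix((0, cells.size))
        xa_sub = self.graph.xa[peaks][:, cells] if peaks.size else \
            sp.csr_matrix((0, cells.size))
        return SubgraphBatch(cells=np.asarray(cells), genes=genes,
                             peaks=peaks, genes_per_cell=gsel,
                             peaks_per_cell=psel, xr=sp.csr_matrix(xr_sub),
                             xa=sp.csr_matrix(xa_sub), rng_seed=seed)

    def sample(self, rng: np.random.Generator,
               seed: int | None = None) -> SubgraphBatch:
        n = self.graph.n_cells
        if n < self.n_cells:
            warnings.warn(f"graph has only {n} cells; sampling all of them")
            cells = np.arange(n)
        else:
            cells = rng.choice(n, size=self.n_cells, replace=False)
        return self.assemble(np.sort(cells), rng, seed)

    def epoch(self, rng: np.random.Generator):
        """Yield batches whose anchor-cell union covers every cell once.

        Cells are shuffled and chunked; a final partial chunk is topped up
        with already-seen cells so every batch has the full size.
        """
        n = self.graph.n_cells
        perm = rng.permutation(n)
        for start in range(0, n, self.n_cells):
            chunk = perm[start:start + self.n_cells]
            if chunk.size < self.n_cells and n >= self.n_cells:
                others = np.setdiff1d(np.arange(n), chunk)
                extra = rng.choice(others, self.n_cells - chunk.size,
                                   replace=False)
                chunk = np.concatenate([chunk, extra])
            yield self.assemble(np.sort(chunk), rng)


def sample_subgraph(graph: HeteroGraph, n_cells: int = 30, cap: int = 20,
                    seed: int | None = None) -> SubgraphBatch:
    """One-shot convenience wrapper around :class:`SubgraphSampler`."""
    rng = np.random.default_rng(seed)
    return SubgraphSampler(graph, n_cells, cap).sample(rng, seed=seed)
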