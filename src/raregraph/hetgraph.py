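"""The cell-gene-peak heterogeneous graph.

Three node types (cells, genes, peaks) and four directed, unweighted edge
types: gene->cell and cell->gene wherever the RNA count is positive,
peak->cell and cell->peak wherever the ATAC count is positive. Node
features are the raw matrix slices: a cell's RNA column, a gene's RNA row,
a peak's ATAC row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

EDGE_TYPES = ("gene->cell", "cell->gene", "peak->cell", "cell->peak")


@dataclass
class HeteroGraph:
    xr: sp.csr_matrix      # genes x cells
    xa: sp.csr_matrix      # peaks x cells
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    peak_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.xr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.xr.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.xa.shape[0]

    @property
    def n_edges(self) -> int:
        """Directed edge count: 2*nnz(X^R) + 2*nnz(X^A)."""
        return 2 * self.xr.nnz + 2 * self.xa.nnz

    # feature views ----------------------------------------------------------
    def cell_features(self) -> sp.csr_matrix:
        """cells x genes sparse feature matrix (RNA columns)."""
        return sp.csr_matrix(self.xr.T)

    def gene_features(self) -> sp.csr_matrix:
        """genes x cells sparse feature matrix (RNA rows)."""
        return self.xr

    def peak_features(self) -> sp.csr_matrix:
        """peaks x cells sparse feature matrix (ATAC rows)."""
        return self.xa

    def edges(self, edge_type: str) -> tuple[np.ndarray, np.ndarray]:
        """(source, target) index arrays for one directed edge type."""
        gc = sp.coo_matrix(self.xr)
        pc = sp.coo_matrix(self.xa)
        if edge_type == "gene->cell":
            return gc.row, gc.col
        if edge_type == "cell->gene":
            return gc.col, gc.row
        if edge_type == "peak->cell":
            return pc.row, pc.col
        if edge_type == "cell->peak":
            return pc.col, pc.row
        raise ValueError(f"unknown edge type {edge_type!r}; "
                         f"one of {EDGE_TYPES}")

    # serialization ----------------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, ids in (("cells", self.cell_ids), ("genes", self.gene_ids),
                          ("peaks", self.peak_ids)):
            pd.Series(ids).to_csv(path / f"{name}.tsv", sep="\t",
                                  header=False, index=False)
        for mat, fname in ((self.xr, "edges_rna.tsv"),
                           (self.xa, "edges_atac.tsv")):
            coo = sp.coo_matrix(mat)
            pd.DataFrame({"feature": coo.row, "cell": coo.col,
                          "count": coo.data}).to_csv(
                path / fname, sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "HeteroGraph":
        path = Path(path)
        ids = {}
        for name in ("cells", "genes", "peaks"):
            ids[name] = pd.read_csv(path / f"{name}.tsv", sep="\t",
                                    header=None)[0].to_numpy(dtype=object)
        er = pd.read_csv(path / "edges_rna.tsv", sep="\t")
        ea = pd.read_csv(path / "edges_atac.tsv", sep="\t")
        xr = sp.csr_matrix((er["count"], (er["feature"], er["cell"])),
                           shape=(len(ids["genes"]), len(ids["cells"])))
        xa = sp.csr_matrix((ea["count"], (ea["feature"], ea["cell"])),
                           shape=(len(ids["peaks"]), len(ids["cells"])))
        return cls(xr, xa, ids["cells"], ids["genes"], ids["peaks"])


def build_graph(xr: CountMatrix, xa: CountMatrix) -> HeteroGraph:
    """Assemble the heterogeneous graph from matched RNA and ATAC matrices.

    The two matrices must share an identical, identically ordered cell set.
    """
    if xr.n_features == 0 or xa.n_features == 0 or xr.n_cells == 0:
        raise ValueError("empty count matrix: graph would have no nodes")
    if (len(xr.cell_ids) != len(xa.cell_ids)
            or not np.array_equal(xr.cell_ids, xa.cell_ids)):
        only_r = set(xr.cell_ids) - set(xa.cell_ids)
        only_a = set(xa.cell_ids) - set(xr.cell_ids)
        if only_r or only_a:
            raise ValueError(
                "cell sets differ between modalities; unmatched barcodes "
                f"(rna-only: {sorted(only_r)[:5]}, "
                f"atac-only: {sorted(only_a)[:5]})")
        raise ValueError("cell barcodes are ordered differently in the two "
                         "modalities")
    return HeteroGraph(sp.csr_matrix(xr.values), sp.csr_matrix(xa.values),
                       xr.cell_ids, xr.feature_ids, xa.feature_ids)
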