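"""Core data containers: count matrices, gene annotation, peaks, and the
peak-to-gene regulatory-potential matrix.

Coordinates are 0-based half-open (BED convention) throughout. The TSS of a
'+'-strand gene is its start, of a '-'-strand gene its end - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse feature x cell non-negative count matrix.

    ``values`` has features (genes or peaks) as rows and cells as columns,
    mirroring the 10x on-disk layout.
    """

    values: sp.csr_matrix
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    modality: str  # "rna" or "atac"

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        nf, nc = self.values.shape
        if nf != len(self.feature_ids) or nc != len(self.cell_ids):
            raise ValueError("id lists inconsistent with matrix shape")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature ids")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, rows=None, cols=None) -> "CountMatrix":
        v = self.values
        fids, cids = self.feature_ids, self.cell_ids
        if rows is not None:
            v = v[rows]
            fids = fids[rows]
        if cols is not None:
            v = v[:, cols]
            cids = cids[cols]
        return CountMatrix(v, fids, cids, self.modality)


@dataclass
class GeneAnnotation:
    """Per-gene TSS, strand and exon intervals on a shared chromosome set.

    ``genes``: DataFrame with columns gene_id, chrom, strand, tss.
    ``exons``: DataFrame with columns gene_id, start, end ([start, end) bp).
    The gene body is the [min(start), max(end)) span of its exons
    (extended to include the TSS).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self):
        self.genes = self.genes.reset_index(drop=True)
        self.exons = self.exons.reset_index(drop=True)
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if not set(self.genes["strand"]).issubset({"+", "-"}):
            raise ValueError("strand must be '+' or '-'")
        if (self.exons["start"] >= self.exons["end"]).any():
            raise ValueError("exon intervals must satisfy start < end")
        missing = set(self.genes["gene_id"]) - set(self.exons["gene_id"])
        if missing:
            raise ValueError(f"genes without exons: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy(dtype=object)

    def bodies(self) -> pd.DataFrame:
        """Gene body [start, end) per gene (exon span union TSS)."""
        span = self.exons.groupby("gene_id").agg(start=("start", "min"),
                                                 end=("end", "max"))
        out = self.genes.set_index("gene_id").join(span)
        out["start"] = np.minimum(out["start"], out["tss"])
        out["end"] = np.maximum(out["end"], out["tss"] + 1)
        return out.reset_index()


@dataclass
class PeakSet:
    """Peak intervals; ``center`` is floor((start + end) / 2)."""

    peaks: pd.DataFrame  # columns: peak_id, chrom, start, end

    def __post_init__(self):
        self.peaks = self.peaks.reset_index(drop=True)
        if self.peaks["peak_id"].duplicated().any():
            raise ValueError("duplicate peak ids")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")

    @property
    def peak_ids(self) -> np.ndarray:
        return self.peaks["peak_id"].to_numpy(dtype=object)

    @property
    def centers(self) -> np.ndarray:
        return ((self.peaks["start"].to_numpy()
                 + self.peaks["end"].to_numpy()) // 2)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class RegulatoryPotentialMatrix:
    """Gene x peak distance-decay scores.

    Scores halve every ``d0`` bp of TSS distance and are zero beyond
    ``max_distance``; a peak centered in an exon of the gene scores
    1/exon length instead.
    """

    values: sp.csr_matrix  # genes x peaks
    gene_ids: np.ndarray
    peak_ids: np.ndarray
    d0: float = 10_000.0
    max_distance: float = 150_000.0

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.peak_ids = np.asarray(self.peak_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.peak_ids)):
            raise ValueError("id lists inconsistent with matrix shape")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative regulatory potentials")
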