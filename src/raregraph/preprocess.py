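"""Quality control, peak-to-gene regulatory potential, and ATAC binning.

The regulatory potential of peak j for gene i decays as 2^(-d_ij/d0) with
the distance d_ij between the peak center and the gene's TSS (half-decay
d0 = 10 kb by default), is cut to zero beyond 150 kb or when the peak
center sits inside the body of a different gene, and equals 1/exon-length
when the center falls in an exon of gene i itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (CountMatrix, GeneAnnotation, PeakSet,
                         RegulatoryPotentialMatrix)


class EmptyAfterQCError(ValueError):
    pass


def qc_filter(matrix: CountMatrix, min_nonzero_frac: float = 0.001,
              max_feature_frac_per_cell: float | None = None) -> CountMatrix:
    """Drop rows, then columns, with fewer than ``min_nonzero_frac``
    non-zero entries.

    Rows are filtered first (against the current column count), then
    columns (against the filtered row count); the pass repeats until
    stable, since dropping columns can push a previously passing row back
    under the threshold — the fixpoint makes the filter idempotent.
    ``max_feature_frac_per_cell`` optionally drops cells in which a
    flagged feature subset (e.g. mitochondrial genes, marked by a "MT-"
    prefix) exceeds the given count fraction; off by default.
    """
    v = sp.csr_matrix(matrix.values)
    rows = np.arange(v.shape[0])
    cols = np.arange(v.shape[1])
    changed = True
    while changed:
        n_rows, n_cols = v.shape
        keep_r = np.flatnonzero(v.getnnz(axis=1)
                                >= min_nonzero_frac * n_cols)
        if keep_r.size == 0:
            raise EmptyAfterQCError("all features removed by QC")
        v = v[keep_r]
        keep_c = np.flatnonzero(v.getnnz(axis=0)
                                >= min_nonzero_frac * keep_r.size)
        if keep_c.size == 0:
            raise EmptyAfterQCError("all cells removed by QC")
        v = v[:, keep_c]
        rows = rows[keep_r]
        cols = cols[keep_c]
        changed = keep_r.size < n_rows or keep_c.size < n_cols
    out = matrix.subset(rows=rows, cols=cols)
    if max_feature_frac_per_cell is not None:
        flagged = np.array([str(f).upper().startswith("MT-")
                            for f in out.feature_ids])
        if flagged.any():
            frac = (out.values[flagged].sum(axis=0).A1
                    / np.maximum(out.values.sum(axis=0).A1, 1))
            out = out.subset(cols=np.flatnonzero(
                frac <= max_feature_frac_per_cell))
    return out


def regulatory_potential(genes: GeneAnnotation, peaks: PeakSet,
                         d0: float = 10_000.0,
                         max_distance: float = 150_000.0
                         ) -> RegulatoryPotentialMatrix:
    """Compute the gene x peak regulatory-potential matrix.

    Branch order per gene i / peak j (same chromosome only):
      1. peak center inside an exon of gene i  ->  1 / exon length
      2. d_ij > max_distance, or center inside the body of another gene -> 0
      3. otherwise 2^(-d_ij / d0)
    """
    gdf = genes.genes
    pdf = peaks.peaks
    known = set(gdf["chrom"])
    bad = pdf.loc[~pdf["chrom"].isin(known), "peak_id"].tolist()
    if bad:
        raise ValueError(f"peaks on unknown chromosomes: {bad[:10]}")

    bodies = genes.bodies()
    centers = peaks.centers
    rows, cols, vals = [], [], []
    for chrom, gsub in gdf.groupby("chrom", sort=False):
        pmask = np.flatnonzero((pdf["chrom"] == chrom).to_numpy())
        if pmask.size == 0:
            continue
        cen = centers[pmask]
        gidx = gsub.index.to_numpy()
        tss = gsub["tss"].to_numpy()

        bsub = bodies[bodies["chrom"] == chrom]
        # which genes' bodies contain each peak center
        in_body = ((cen[:, None] >= bsub["start"].to_numpy()[None, :])
                   & (cen[:, None] < bsub["end"].to_numpy()[None, :]))
        body_gene_pos = {g: t for t, g in enumerate(bsub["gene_id"])}

        # exon host lookup: peak p -> {gene: exon length}
        esub = genes.exons.merge(
            gsub[["gene_id"]], on="gene_id", how="inner")
        exon_hit = {}
        if len(esub):
            es = esub["start"].to_numpy()
            ee = esub["end"].to_numpy()
            eg = esub["gene_id"].to_numpy()
            for p, c in enumerate(cen):
                hit = np.flatnonzero((c >= es) & (c < ee))
                for h in hit:
                    # smallest containing exon wins if several of one gene
                    cur = exon_hit.setdefault((p, eg[h]), ee[h] - es[h])
                    exon_hit[(p, eg[h])] = min(cur, ee[h] - es[h])

        d = np.abs(cen[None, :] - tss[:, None]).astype(float)
        base = np.power(2.0, -d / d0)
        for a, (gi, gene_id) in enumerate(zip(gidx, gsub["gene_id"])):
            gpos = body_gene_pos[gene_id]
            other = in_body.copy()
            other[:, gpos] = False
            blocked = other.any(axis=1)
            for p in range(cen.size):
                key = (p, gene_id)
                if key in exon_hit:
                    val = 1.0 / exon_hit[key]
                elif d[a, p] > max_distance or blocked[p]:
                    continue
                else:
                    val = base[a, p]
                if val > 0:
                    rows.append(gi)
                    cols.append(pmask[p])
                    vals.append(val)
    mat = sp.csr_matrix((vals, (rows, cols)),
                        shape=(len(gdf), len(pdf)))
    return RegulatoryPotentialMatrix(mat, genes.gene_ids, peaks.peak_ids,
                                     d0, max_distance)


def bin_atac(samples: list[tuple[CountMatrix, PeakSet]],
             bin_width: int = 5000) -> tuple[CountMatrix, PeakSet]:
    """Merge multi-sample ATAC data onto fixed genome bins.

    The genome is partitioned into [k*w, (k+1)*w) bins; each peak is
    assigned to the bin containing its center and same-bin counts are
    summed per cell. Output cells are the concatenation of all samples'
    cells; all-zero bins are dropped.
    """
    if not samples:
        raise ValueError("need at least one sample")
    styles = {str(next(iter(ps.peaks["chrom"]))).startswith("chr")
              for _, ps in samples if len(ps)}
    if len(styles) > 1:
        raise ValueError("inconsistent chromosome naming across samples "
                         "(mixed 'chr' prefixes)")

    # global bin index: (chrom, k)
    bin_index: dict[tuple, int] = {}
    sample_cols = []
    cell_ids = []
    triplets = []  # (bin, cell_offset_local, count) per sample
    offset = 0
    for cm, ps in samples:
        if cm.n_features != len(ps):
            raise ValueError("peak set size does not match matrix rows")
        bins = ps.centers // bin_width
        keys = list(zip(ps.peaks["chrom"], bins))
        for key in keys:
            if key not in bin_index:
                bin_index[key] = len(bin_index)
        rows = np.array([bin_index[k] for k in keys])
        coo = sp.coo_matrix(cm.values)
        triplets.append((rows[coo.row], coo.col + offset, coo.data))
        cell_ids.extend(cm.cell_ids)
        sample_cols.append(cm.n_cells)
        offset += cm.n_cells
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell barcodes across samples")
    n_bins = len(bin_index)
    r = np.concatenate([t[0] for t in triplets])
    c = np.concatenate([t[1] for t in triplets])
    d = np.concatenate([t[2] for t in triplets])
    mat = sp.csr_matrix((d, (r, c)), shape=(n_bins, offset))

    keep = np.flatnonzero(mat.getnnz(axis=1) > 0)
    mat = mat[keep]
    inv = {v: k for k, v in bin_index.items()}
    kept_keys = [inv[i] for i in keep]
    bdf = pd.DataFrame({
        "peak_id": [f"{ch}:{k * bin_width}-{(k + 1) * bin_width}"
                    for ch, k in kept_keys],
        "chrom": [ch for ch, _ in kept_keys],
        "start": [k * bin_width for _, k in kept_keys],
        "end": [(k + 1) * bin_width for _, k in kept_keys]})
    binned = CountMatrix(mat, bdf["peak_id"].to_numpy(dtype=object),
                         np.asarray(cell_ids, dtype=object), "atac")
    return binned, PeakSet(bdf)
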