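"""Readers and writers for the standard on-disk formats.

Matrices use the 10x-style MatrixMarket layout (matrix.mtx + features.tsv +
barcodes.tsv) with a dense-CSV fallback for toy inputs. Gene annotation
comes from GTF or a BED-like table; peaks and TF binding sites from BED.
All intervals are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneAnnotation, PeakSet

# -- count matrices ----------------------------------------------------------


def read_mtx_dir(path, modality: str) -> CountMatrix:
    """Read a 10x-style directory: matrix.mtx, features.tsv, barcodes.tsv."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"missing matrix file: {mtx}")
    values = sp.csr_matrix(scipy.io.mmread(mtx))
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    return CountMatrix(values, features.to_numpy(dtype=object),
                       barcodes.to_numpy(dtype=object), modality)


def write_mtx_dir(matrix: CountMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.values))
    pd.Series(matrix.feature_ids).to_csv(path / "features.tsv", sep="\t",
                                         header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)


def read_dense_csv(path, modality: str) -> CountMatrix:
    """Dense CSV fallback: rows = features, columns = cells, both labeled."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(sp.csr_matrix(df.to_numpy()),
                       df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object), modality)


# -- gene annotation ---------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_genes_gtf(path) -> GeneAnnotation:
    """Parse exon records of a GTF into a GeneAnnotation.

    The TSS is derived from the exon span and strand (start of the span for
    '+', end-1 for '-'); GTF's 1-based closed intervals are converted to
    0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"GTF exon without gene_id: {line[:80]}")
            rows.append((gid, f[0], f[6], int(f[3]) - 1, int(f[4])))
    if not rows:
        raise ValueError(f"no exon records in {path}")
    ex = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                     "start", "end"])
    genes = ex.groupby("gene_id", sort=False).agg(
        chrom=("chrom", "first"), strand=("strand", "first"),
        lo=("start", "min"), hi=("end", "max")).reset_index()
    genes["tss"] = np.where(genes["strand"] == "+", genes["lo"],
                            genes["hi"] - 1)
    return GeneAnnotation(genes[["gene_id", "chrom", "strand", "tss"]],
                          ex[["gene_id", "start", "end"]])


def read_genes_bed(path) -> GeneAnnotation:
    """BED-like gene table: chrom, start, end, gene_id, score, strand.

    Each gene becomes a single-exon annotation spanning [start, end).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("gene BED needs >= 6 columns (incl. strand)")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    genes = df[["gene_id", "chrom", "strand"]].copy()
    genes["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    exons = df[["gene_id", "start", "end"]]
    return GeneAnnotation(genes, exons)


# -- peaks and TFBS ----------------------------------------------------------

_PEAK_ID = re.compile(r"^(\S+):(\d+)-(\d+)$")


def read_peaks_bed(path) -> PeakSet:
    """BED peaks; a 4th column is used as peak_id, else chrom:start-end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df["peak_id"] = df[3]
    else:
        df["peak_id"] = (df["chrom"].astype(str) + ":"
                         + df["start"].astype(str) + "-"
                         + df["end"].astype(str))
    return PeakSet(df[["peak_id", "chrom", "start", "end"]])


def parse_peak_ids(ids) -> PeakSet:
    """Build a PeakSet from 'chr:start-end'-style identifiers."""
    rows = []
    for pid in ids:
        m = _PEAK_ID.match(str(pid))
        if not m:
            raise ValueError(f"cannot parse peak id {pid!r}")
        rows.append((pid, m.group(1), int(m.group(2)), int(m.group(3))))
    return PeakSet(pd.DataFrame(rows, columns=["peak_id", "chrom",
                                               "start", "end"]))


def read_tfbs_bed(path, score_is_neglog10p: bool = False) -> pd.DataFrame:
    """BED6+ TF binding sites: chrom, start, end, tf_name, score(p), strand.

    With ``score_is_neglog10p`` the score column holds -10*log10(p)
    (JASPAR genome-track convention) and is converted to a plain p-value.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 5:
        raise ValueError("TFBS BED needs >= 5 columns")
    out = df.iloc[:, :5].copy()
    out.columns = ["chrom", "start", "end", "tf_name", "p_value"]
    if score_is_neglog10p:
        out["p_value"] = 10.0 ** (-out["p_value"].astype(float) / 10.0)
    return out


# -- regulatory-potential triplets -------------------------------------------


def write_rp_triplets(rp, path) -> None:
    """Write a RegulatoryPotentialMatrix as (gene_id, peak_id, score) TSV."""
    coo = sp.coo_matrix(rp.values)
    pd.DataFrame({"gene_id": rp.gene_ids[coo.row],
                  "peak_id": rp.peak_ids[coo.col],
                  "score": coo.data}).to_csv(path, sep="\t", index=False)


def read_rp_triplets(path, gene_ids, peak_ids, d0=10_000.0,
                     max_distance=150_000.0):
    from .containers import RegulatoryPotentialMatrix

    df = pd.read_csv(path, sep="\t")
    gidx = {g: i for i, g in enumerate(gene_ids)}
    pidx = {p: j for j, p in enumerate(peak_ids)}
    rows = df["gene_id"].map(gidx)
    cols = df["peak_id"].map(pidx)
    if rows.isna().any() or cols.isna().any():
        raise ValueError("triplet file references unknown gene/peak ids")
    mat = sp.csr_matrix((df["score"], (rows.astype(int), cols.astype(int))),
                        shape=(len(gene_ids), len(peak_ids)))
    return RegulatoryPotentialMatrix(mat, np.asarray(gene_ids, dtype=object),
                                     np.asarray(peak_ids, dtype=object),
                                     d0, max_distance)
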