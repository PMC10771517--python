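"""Per-cluster peak-gene link scoring and eGRN assembly.

The peak-gene score of a pair (gene i, peak j) in cluster CT is the mean
over the cluster's cells of expression x regulatory potential x
accessibility:

    PGS(i, j, CT) = sum_{k in CT} x^R_ik * x^RA_ij * x^A_jk / |CT|

computed for every pair with positive regulatory potential. eGRNs add the
transcription-factor layer: binding sites surviving the p-value filter
(p <= 0.05 kept) that overlap a linked peak yield TF -> peak -> gene
triplets per cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import PeakSet, RegulatoryPotentialMatrix


def peak_gene_score(xr, xa, xra: RegulatoryPotentialMatrix,
                    labels: np.ndarray, min_score: float = 0.0,
                    top_m: int | None = None) -> pd.DataFrame:
    """Per-cluster PGS table for all pairs with positive regulatory
    potential.

    ``labels`` assigns every cell a cluster id. Optional output filters:
    drop scores below ``min_score``; keep only the ``top_m`` highest
    scoring links per cluster.
    """
    xr_v = sp.csr_matrix(xr.values if hasattr(xr, "values") else xr)
    xa_v = sp.csr_matrix(xa.values if hasattr(xa, "values") else xa)
    labels = np.asarray(labels)
    if labels.size != xr_v.shape[1]:
        raise ValueError("labels must cover all cells")
    coo = sp.coo_matrix(xra.values)
    frames = []
    for cluster in np.unique(labels):
        cells = np.flatnonzero(labels == cluster)
        if cells.size == 0:  # pragma: no cover - unique() excludes this
            warnings.warn(f"cluster {cluster} is empty; skipped")
            continue
        # (Xr_CT @ Xa_CT^T)[i, j] evaluated only on the xra support
        prod = np.asarray(
            (xr_v[:, cells][coo.row] .multiply(xa_v[:, cells][coo.col]))
            .sum(axis=1)).ravel()
        scores = coo.data * prod / cells.size
        df = pd.DataFrame({"gene_id": xra.gene_ids[coo.row],
                           "peak_id": xra.peak_ids[coo.col],
                           "cluster": cluster, "score": scores})
        df = df[df["score"] >= min_score]
        if top_m is not None:
            df = df.nlargest(top_m, "score")
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["gene_id", "peak_id", "cluster",
                                     "score"])
    return pd.concat(frames, ignore_index=True)


def filter_tfbs(track: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Keep binding sites with p-value <= p_max (removal is strictly
    'more than p_max')."""
    p = track["p_value"].astype(float)
    bad = track[(p < 0) | (p > 1)]
    if len(bad):
        raise ValueError(f"p-values outside [0, 1] in rows "
                         f"{bad.index.tolist()[:10]}")
    return track[p <= p_max].reset_index(drop=True)


def _overlaps(sites: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """All (site, peak) pairs with a non-empty half-open intersection."""
    out = []
    for chrom, ssub in sites.groupby("chrom", sort=False):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        ss = ssub["start"].to_numpy()[:, None]
        se = ssub["end"].to_numpy()[:, None]
        ps = psub["start"].to_numpy()[None, :]
        pe = psub["end"].to_numpy()[None, :]
        hit = (ss < pe) & (se > ps)
        si, pi = np.nonzero(hit)
        if si.size:
            out.append(pd.DataFrame({
                "tf_name": ssub["tf_name"].to_numpy()[si],
                "p_value": ssub["p_value"].to_numpy()[si],
                "peak_id": psub["peak_id"].to_numpy()[pi]}))
    if not out:
        return pd.DataFrame(columns=["tf_name", "p_value", "peak_id"])
    return pd.concat(out, ignore_index=True)


def assemble_egrn(links: pd.DataFrame, track: pd.DataFrame,
                  peaks: PeakSet) -> pd.DataFrame:
    """Join the link table with TF binding sites overlapping each peak.

    Emits one row per (cluster, tf, peak, gene); duplicate triplets keep
    the minimum site p-value. The track must already be p-filtered.
    """
    site_chroms = set(track["chrom"])
    peak_chroms = set(peaks.peaks["chrom"])
    if site_chroms and not site_chroms & peak_chroms:
        raise ValueError(
            f"chromosome namespaces do not intersect: sites on "
            f"{sorted(site_chroms)[:3]}, peaks on "
            f"{sorted(peak_chroms)[:3]}")
    tf_peak = _overlaps(track, peaks.peaks)
    merged = links.merge(tf_peak, on="peak_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["cluster", "tf_name", "peak_id",
                                     "gene_id", "score", "p_value"])
    merged = (merged.sort_values("p_value")
              .drop_duplicates(["cluster", "tf_name", "peak_id", "gene_id"])
              .reset_index(drop=True))
    return merged[["cluster", "tf_name", "peak_id", "gene_id", "score",
                   "p_value"]]
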