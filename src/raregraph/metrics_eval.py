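"""Clustering and rare-cell classification metrics.

Clustering-style output is scored with purity, entropy and NMI (all from
the predicted-vs-true contingency table, natural log, NMI normalized by
min(H(S), H(T))). Rare-vs-common calls are scored with precision, recall
and F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _contingency(pred, true) -> np.ndarray:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("label vectors must be non-empty and equal length")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(true, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1))
    np.add.at(table, (pi, ti), 1.0)
    return table


def purity(pred, true) -> float:
    """Fraction of cells in their cluster's majority class; 1 is best."""
    table = _contingency(pred, true)
    return float(table.max(axis=1).sum() / table.sum())


def entropy_score(pred, true) -> float:
    """Size-weighted Shannon entropy of class composition per cluster
    (natural log, 0*log 0 = 0); lower is better, 0 for pure clusters."""
    table = _contingency(pred, true)
    n = table.sum()
    sizes = table.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = table / sizes[:, None]
        h = -np.where(table > 0, frac * np.log(frac), 0.0).sum(axis=1)
    return float((sizes / n * h).sum())


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(pred, true) -> float:
    """Mutual information normalized by min(H(S), H(T)); 0/0 -> 0.

    Two single-cluster partitions are identical, hence defined as 1.
    """
    table = _contingency(pred, true)
    n = table.sum()
    hs = _entropy(table.sum(axis=1))
    ht = _entropy(table.sum(axis=0))
    if hs == 0 and ht == 0:
        return 1.0
    ps = table.sum(axis=1, keepdims=True) / n
    pt = table.sum(axis=0, keepdims=True) / n
    pst = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pst > 0, pst * np.log(pst / (ps * pt)), 0.0)
    mi = float(terms.sum())
    denom = min(hs, ht)
    return 0.0 if denom == 0 else mi / denom


# -- rare-cell classification -------------------------------------------------

@dataclass
class RareConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def rare_prf(confusion: RareConfusion,
             paper_eq33: bool = False) -> tuple[float, float, float]:
    """(precision, recall, F1) for rare-vs-common calls; 0/0 -> 0.

    F1 is the harmonic mean TP / (TP + 0.5*(FP + FN)). ``paper_eq33``
    reproduces an alternative printed denominator TP + 0.5*(TP + FN) for
    audit; under it a perfect classifier scores 2/3, so it is not the
    default.
    """
    tp, fp, fn = confusion.tp, confusion.fp, confusion.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    half = 0.5 * ((tp + fn) if paper_eq33 else (fp + fn))
    f1 = tp / (tp + half) if tp + half else 0.0
    return precision, recall, f1


def rare_cell_calls(predicted_rare: np.ndarray,
                    true_rare: np.ndarray) -> RareConfusion:
    """Tabulate per-cell rare/common calls against the ground truth."""
    p = np.asarray(predicted_rare, dtype=bool)
    t = np.asarray(true_rare, dtype=bool)
    if p.size != t.size:
        raise ValueError("call vectors must have equal length")
    return RareConfusion(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                         fn=int((~p & t).sum()), tn=int((~p & ~t).sum()))


def rare_calls_from_result(result, truth,
                           threshold: float | None = None) -> RareConfusion:
    """Confusion table from a clustering result and simulator truth.

    A cell is called rare iff its predicted cluster is rare-flagged;
    passing ``threshold`` re-derives the flags from the cluster sizes.
    """
    if threshold is None:
        pred = result.cell_rare_flags()
    else:
        flags = result.cluster_sizes / result.labels.size < threshold
        pred = flags[result.labels - 1]
    return rare_cell_calls(pred, truth.rare_cell_flags())


def evaluate_clustering(pred, true) -> dict:
    return {"purity": purity(pred, true),
            "entropy": entropy_score(pred, true),
            "nmi": nmi(pred, true)}


def evaluate_rare(predicted_rare, true_rare) -> dict:
    conf = rare_cell_calls(predicted_rare, true_rare)
    precision, recall, f1 = rare_prf(conf)
    return {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn,
            "precision": precision, "recall": recall, "f1": f1}
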