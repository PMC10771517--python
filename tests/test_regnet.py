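"""Peak-gene scoring and eGRN assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix, make_peaks
from raregraph.containers import RegulatoryPotentialMatrix
from raregraph.regnet import assemble_egrn, filter_tfbs, peak_gene_score


def make_rp(arr, gene_ids=None, peak_ids=None):
    arr = np.asarray(arr, dtype=float)
    return RegulatoryPotentialMatrix(
        arr,
        gene_ids or np.array([f"gene{i}" for i in range(arr.shape[0])],
                             dtype=object),
        peak_ids or np.array([f"peak{j}" for j in range(arr.shape[1])],
                             dtype=object))


def pgs_bruteforce(xr, xa, rp, labels):
    rows = []
    for ct in np.unique(labels):
        cells = np.flatnonzero(labels == ct)
        for i in range(rp.shape[0]):
            for j in range(rp.shape[1]):
                if rp[i, j] <= 0:
                    continue
                s = sum(xr[i, k] * rp[i, j] * xa[j, k] for k in cells)
                rows.append((f"gene{i}", f"peak{j}", ct, s / len(cells)))
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "cluster",
                                       "score"])


class TestPGS:
    def test_single_cell_hand_value(self):
        table = peak_gene_score(make_count_matrix([[2.0]]),
                                make_count_matrix([[1.0]], "atac"),
                                make_rp([[0.5]]), np.array([1]))
        assert table["score"].tolist() == [1.0]

    def test_inaccessible_peak_scores_zero(self):
        table = peak_gene_score(make_count_matrix([[2.0, 2.0]]),
                                make_count_matrix([[0.0, 0.0]], "atac"),
                                make_rp([[0.5]]), np.array([1, 1]))
        assert table["score"].tolist() == [0.0]

    def test_mean_over_cluster_cells(self):
        # per-cell products (1.0, 3.0) -> PGS 2.0
        table = peak_gene_score(make_count_matrix([[2.0, 6.0]]),
                                make_count_matrix([[1.0, 1.0]], "atac"),
                                make_rp([[0.5]]), np.array([1, 1]))
        assert table["score"].tolist() == [2.0]

    def test_zero_potential_pairs_excluded(self):
        table = peak_gene_score(make_count_matrix([[1.0]]),
                                make_count_matrix([[1.0]], "atac"),
                                make_rp([[0.0]]), np.array([1]))
        assert table.empty

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        xr = rng.integers(0, 5, (6, 10)).astype(float)
        xa = rng.integers(0, 3, (8, 10)).astype(float)
        rp = rng.random((6, 8)) * (rng.random((6, 8)) < 0.4)
        labels = rng.integers(1, 4, 10)
        got = peak_gene_score(make_count_matrix(xr),
                              make_count_matrix(xa, "atac"), make_rp(rp),
                              labels)
        want = pgs_bruteforce(xr, xa, rp, labels)
        key = ["gene_id", "peak_id", "cluster"]
        merged = got.merge(want, on=key, suffixes=("_got", "_want"))
        assert len(merged) == len(want) == len(got)
        assert np.allclose(merged["score_got"], merged["score_want"])

    def test_linear_in_accessibility(self):
        rng = np.random.default_rng(1)
        xr = rng.integers(0, 5, (3, 6)).astype(float)
        xa = rng.integers(0, 3, (4, 6)).astype(float)
        rp = rng.random((3, 4))
        labels = np.ones(6, dtype=int)
        base = peak_gene_score(make_count_matrix(xr),
                               make_count_matrix(xa, "atac"),
                               make_rp(rp), labels)
        doubled = peak_gene_score(make_count_matrix(xr),
                                  make_count_matrix(2 * xa, "atac"),
                                  make_rp(rp), labels)
        assert np.allclose(doubled["score"], 2 * base["score"])

    def test_labels_must_cover_cells(self):
        with pytest.raises(ValueError, match="cover"):
            peak_gene_score(make_count_matrix([[1.0, 1.0]]),
                            make_count_matrix([[1.0, 1.0]], "atac"),
                            make_rp([[0.5]]), np.array([1]))


class TestFilterTFBS:
    def track(self, pvals):
        return pd.DataFrame({"chrom": "chr1",
                             "start": range(len(pvals)),
                             "end": [s + 10 for s in range(len(pvals))],
                             "tf_name": "TF",
                             "p_value": pvals})

    def test_boundary_at_p_equal_005(self):
        out = filter_tfbs(self.track([0.05, 0.051, 0.01]))
        assert out["p_value"].tolist() == [0.05, 0.01]

    def test_empty_track(self):
        assert filter_tfbs(self.track([])).empty

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            filter_tfbs(self.track([0.5, 1.7]))


class TestAssembleEGRN:
    def links(self):
        return pd.DataFrame({"gene_id": ["gA", "gA"],
                             "peak_id": ["pk1", "pk2"],
                             "cluster": [1, 1],
                             "score": [1.5, 0.7]})

    def peaks(self):
        return make_peaks([("pk1", "chr1", 110, 300),
                           ("pk2", "chr1", 400, 500)])

    def test_overlap_emits_triplet(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [120], "tf_name": ["TF1"],
                              "p_value": [0.01]})
        out = assemble_egrn(self.links(), track, self.peaks())
        assert len(out) == 1
        assert out.iloc[0]["peak_id"] == "pk1"
        assert out.iloc[0]["gene_id"] == "gA"

    def test_half_open_abutment_is_no_overlap(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [110], "tf_name": ["TF1"],
                              "p_value": [0.01]})
        out = assemble_egrn(self.links(), track, self.peaks())
        assert out.empty

    def test_duplicate_triplets_keep_min_p(self):
        track = pd.DataFrame({"chrom": ["chr1"] * 2,
                              "start": [120, 150], "end": [130, 160],
                              "tf_name": ["TF1", "TF1"],
                              "p_value": [0.04, 0.002]})
        out = assemble_egrn(self.links(), track, self.peaks())
        assert len(out) == 1
        assert out.iloc[0]["p_value"] == 0.002

    def test_chromosome_namespace_mismatch_raises(self):
        track = pd.DataFrame({"chrom": ["1"], "start": [100],
                              "end": [120], "tf_name": ["TF1"],
                              "p_value": [0.01]})
        with pytest.raises(ValueError, match="namespace"):
            assemble_egrn(self.links(), track, self.peaks())

    def test_overlap_agrees_with_intervaltree(self):
        from intervaltree import IntervalTree
        rng = np.random.default_rng(6)
        starts = rng.integers(0, 2000, 50)
        peaks_df = [(f"pk{i}", "chr1", int(s), int(s) + 80)
                    for i, s in enumerate(starts)]
        sstarts = rng.integers(0, 2000, 60)
        track = pd.DataFrame({"chrom": "chr1", "start": sstarts,
                              "end": sstarts + 15,
                              "tf_name": [f"TF{i}" for i in range(60)],
                              "p_value": 0.01})
        links = pd.DataFrame({"gene_id": "g",
                              "peak_id": [p[0] for p in peaks_df],
                              "cluster": 1, "score": 1.0})
        out = assemble_egrn(links, track, make_peaks(peaks_df))
        tree = IntervalTree()
        for i, s in enumerate(sstarts):
            tree.addi(int(s), int(s) + 15, f"TF{i}")
        expect = set()
        for pid, _, s, e in peaks_df:
            for hit in tree.overlap(s, e):
                expect.add((hit.data, pid))
        got = set(zip(out["tf_name"], out["peak_id"]))
        assert got == expect
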