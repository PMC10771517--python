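import numpy as np
import pytest
import scipy.sparse as sp

from raregraph.containers import CountMatrix, GeneAnnotation, PeakSet
from raregraph.hetgraph import build_graph
from raregraph.preprocess import regulatory_potential
from raregraph.simulate import Population, SimConfig, simulate_multiome


def make_count_matrix(arr, modality="rna", prefix=None):
    arr = np.asarray(arr)
    prefix = prefix or ("gene" if modality == "rna" else "peak")
    return CountMatrix(
        sp.csr_matrix(arr),
        np.array([f"{prefix}{i}" for i in range(arr.shape[0])], dtype=object),
        np.array([f"cell{j}" for j in range(arr.shape[1])], dtype=object),
        modality)


@pytest.fixture
def tiny_rna():
    return make_count_matrix([[0, 2], [3, 0]], "rna")


@pytest.fixture
def tiny_atac():
    return make_count_matrix([[1, 1]], "atac")


@pytest.fixture(scope="session")
def small_multiome():
    """Two well-separated populations plus a rare one; used by training
    and end-to-end tests. 200 cells keeps everything fast."""
    config = SimConfig(populations=[Population("alpha", 110),
                                    Population("beta", 80),
                                    Population("gamma", 10, rare=True)],
                       n_genes=200, n_peaks=400, seed=7)
    return simulate_multiome(config)


@pytest.fixture(scope="session")
def small_graph(small_multiome):
    rna, atac, _, _, _ = small_multiome
    return build_graph(rna, atac)


@pytest.fixture(scope="session")
def small_rp(small_multiome):
    _, _, annotation, peaks, _ = small_multiome
    return regulatory_potential(annotation, peaks)


@pytest.fixture
def simple_annotation():
    """Two genes on chr1, one on chr2; plus strand; single exons."""
    genes = {
        "genes": [("gA", "chr1", "+", 1000), ("gB", "chr1", "+", 500_000),
                  ("gC", "chr2", "+", 1000)],
        "exons": [("gA", 1000, 1500), ("gB", 500_000, 500_500),
                  ("gC", 1000, 2000)],
    }
    import pandas as pd
    return GeneAnnotation(
        pd.DataFrame(genes["genes"],
                     columns=["gene_id", "chrom", "strand", "tss"]),
        pd.DataFrame(genes["exons"], columns=["gene_id", "start", "end"]))


def make_peaks(rows):
    import pandas as pd
    return PeakSet(pd.DataFrame(rows,
                                columns=["peak_id", "chrom", "start",
                                         "end"]))
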