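import numpy as np
import pandas as pd
import pytest

from tadrisk.catalog import catalog_from_dataframe
from tadrisk.tads import ContactMatrix


@pytest.fixture
def two_block_matrix() -> ContactMatrix:
    """6-bin matrix with two planted blocks {0..2}, {3..5}: within-block
    contacts 5, cross-block 1, zero diagonal."""
    m = np.ones((6, 6))
    for s, e in ((0, 3), (3, 6)):
        m[s:e, s:e] = 5.0
    np.fill_diagonal(m, 0.0)
    return ContactMatrix("chr1", 10_000, m)


@pytest.fixture
def toy_catalog():
    """3 diseases / 5 association rows with one duplicated (disease, SNP)."""
    rows = [
        # efoId, snpId, chrom, pos (1-based), isCancer
        ("EFO_1", "rs1", "chr1", 110_001, True),
        ("EFO_1", "rs1", "chr1", 110_001, True),  # duplicate study entry
        ("EFO_1", "rs2", "chr1", 500_001, True),
        ("EFO_2", "rs2", "chr1", 500_001, False),
        ("EFO_3", "rs3", "chr2", 50_001, False),
    ]
    df = pd.DataFrame(rows, columns=["efoId", "snpId", "chrom", "pos", "isCancer"])
    df["diseaseLabel"] = df["efoId"]
    return catalog_from_dataframe(df)


@pytest.fixture
def triangle_plus_isolate():
    """Graph with a triangle A-B-C and an isolated node D."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from("ABCD")
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g
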