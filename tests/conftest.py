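"""Shared fixtures: small deterministic count tables and graphs."""

import networkx as nx
import numpy as np
import pytest

from menpipe.io_formats import CountTable


@pytest.fixture
def toy_table() -> CountTable:
    """6 OTUs x 8 samples with mixed kingdoms and one methanogen."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    counts[0] = counts[1] + rng.integers(0, 3, size=8)  # a correlated pair
    return CountTable.from_arrays(
        [f"OTU_{i}" for i in range(6)],
        [f"S{j}" for j in range(8)],
        counts,
        taxonomy=[
            "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;FamA",
            "Bacteria;Proteobacteria;ClassB;OrderB;FamB",
            "Bacteria;Firmicutes;ClassC;OrderC;FamC",
            "Fungi;Ascomycota;ClassD;OrderD;FamD",
            "Fungi;Basidiomycota;ClassE;OrderE;FamE",
            "Eukaryota;Cercozoa;ClassF;OrderF;FamF",
        ],
        kingdom=[
            "prokaryote",
            "prokaryote",
            "prokaryote",
            "fungus",
            "fungus",
            "cercozoa",
        ],
        guild=["methanogen", "none", "none", "none", "none", "none"],
    )


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two disconnected 4-cliques, the Q = 0.5 closed-form example."""
    g = nx.complete_graph(4)
    h = nx.relabel_nodes(nx.complete_graph(4), {i: i + 4 for i in range(4)})
    return nx.union(g, h)


@pytest.fixture
def star_graph() -> nx.Graph:
    """Star with center 0 and five leaves."""
    return nx.star_graph(5)
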