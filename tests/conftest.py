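import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pmena.containers import CountTable, EcoNetwork, EnvTable, TaxonomyMap


@pytest.fixture
def two_group_labels():
    samples = [f"H{i}" for i in range(1, 9)] + [f"L{i}" for i in range(1, 9)]
    return pd.Series(["H"] * 8 + ["L"] * 8, index=samples)


@pytest.fixture
def small_table(two_group_labels):
    rng = np.random.default_rng(42)
    counts = rng.poisson(20, size=(16, 30))
    return CountTable(
        pd.DataFrame(
            counts,
            index=two_group_labels.index,
            columns=[f"OTU{i}" for i in range(30)],
        ),
        group=two_group_labels,
    )


@pytest.fixture
def toy_taxonomy():
    rows = {
        "OTU_A1": {"domain": "Bacteria", "phylum": "Acidobacteria", "genus": "Gp6"},
        "OTU_A2": {"domain": "Bacteria", "phylum": "Acidobacteria", "genus": "Gp6"},
        "OTU_C1": {"domain": "Bacteria", "phylum": "Chloroflexi", "genus": "Chloro_g"},
        "OTU_C2": {"domain": "Bacteria", "phylum": "Chloroflexi", "genus": "Chloro_g"},
        "OTU_F1": {"domain": "Bacteria", "phylum": "Firmicutes", "genus": "Fusibacter"},
    }
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture
def toy_network():
    """Star around OTU_A1: +links to two Chloroflexi, -link to one Firmicutes."""
    g = nx.Graph()
    edges = [
        ("OTU_A1", "OTU_C1", 0.95),
        ("OTU_A1", "OTU_C2", 0.93),
        ("OTU_A1", "OTU_F1", -0.91),
        ("OTU_A2", "OTU_C1", 0.92),
    ]
    for u, v, r in edges:
        g.add_edge(u, v, r=r, sign=1 if r >= 0 else -1, weight=abs(r))
    return EcoNetwork(g, st=0.9)


@pytest.fixture
def toy_env(two_group_labels):
    rng = np.random.default_rng(3)
    data = {v: rng.uniform(1, 100, 16) for v in ("Hg", "Zn", "C")}
    return EnvTable(pd.DataFrame(data, index=two_group_labels.index))
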