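import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from saltscreen import simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Desk-scale study configuration used across module tests."""
    return simulate.SimConfig(seed=7, n_accessions=30, n_genes=2000,
                              n_terms=40, genes_per_term=(5, 30),
                              ppi_nodes=60, planted_clique_sizes=(5, 3),
                              background_edge_prob=0.02)


@pytest.fixture
def toy_census():
    """One accession, control vs salt, single replicate, days 2/4/6/8."""
    rows = []
    for cond, counts in (("control", [4, 10, 16, 18]), ("salt", [1, 5, 8, 9])):
        for day, germ in zip([2, 4, 6, 8], counts):
            rows.append({"accession": "A1", "condition": cond, "replicate": 1,
                         "day": day, "germinated": germ, "sown": 20,
                         "plumule_length": 12.0 if cond == "control" else 6.0,
                         "radicle_length": 15.0 if cond == "control" else 7.5})
    return pd.DataFrame(rows)


@pytest.fixture
def null_counts():
    """Counts with no planted effects (both conditions identically distributed)."""
    cfg = simulate.SimConfig(seed=1, n_genes=5000, deg_fraction=0.0,
                             nb_dispersion=0.05)
    counts, lengths, truth = simulate.generate_counts(cfg)
    conditions = pd.Series({c: c.split("_")[0] for c in counts.columns})
    return counts, lengths, conditions
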