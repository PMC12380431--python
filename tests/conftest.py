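import numpy as np
import pandas as pd
import pytest

from spotrank import SimulationConfig, SpotMatrix, simulate_visium_dataset


def make_matrix(counts, roles=None, **meta):
    """Small hand-built SpotMatrix for rule-level tests."""
    counts = np.asarray(counts)
    n_spots, n_genes = counts.shape
    if roles is None:
        roles = ["other"] * n_genes
    spot_meta = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(n_spots)],
            "x": np.zeros(n_spots),
            "y": np.zeros(n_spots),
            "sample": meta.get("sample", ["s1"] * n_spots),
            "group": meta.get("group", ["g1"] * n_spots),
            "section": meta.get("section", ["sec1"] * n_spots),
            "soma_flag": meta.get("soma_flag", [True] * n_spots),
        }
    )
    for key, val in meta.items():
        if key != "symbols" and key not in spot_meta.columns:
            spot_meta[key] = val
    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{j}" for j in range(n_genes)],
            "symbol": meta.get("symbols", [f"Gene{j}" for j in range(n_genes)]),
            "role": roles,
        }
    )
    return SpotMatrix(counts=counts, spot_meta=spot_meta, gene_meta=gene_meta)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 0), shared across tests."""
    return simulate_visium_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def null_dataset():
    """Same design with every planted effect switched off."""
    config = SimulationConfig(seed=7)
    config.deg_effects = {g: 1.0 for g in config.default_deg_effects()}
    return simulate_visium_dataset(config)
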