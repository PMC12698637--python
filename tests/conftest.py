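import numpy as np
import pandas as pd
import pytest

from rhizopheno.containers import RANKS, AsvTable
from rhizopheno.synthetic import SceneDesign


def make_asv_table(counts: np.ndarray, sample_ids=None, taxon_ids=None,
                   production=None, plant=None) -> AsvTable:
    counts = np.asarray(counts)
    n, D = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(D)]
    tax = pd.DataFrame(
        {r: [f"{r}_{t}" for t in taxon_ids] for r in RANKS}, index=taxon_ids
    )
    meta = pd.DataFrame(
        {
            "production": production or ["conventional"] * n,
            "plant": plant or ["carrot"] * n,
            "latitude": np.linspace(42.0, 42.1, n),
            "longitude": np.linspace(-76.0, -75.9, n),
        },
        index=sample_ids,
    )
    return AsvTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        taxonomy=tax, metadata=meta,
    )


@pytest.fixture
def tiny_table() -> AsvTable:
    return make_asv_table(
        [[3, 1, 2], [5, 5, 5], [1, 1, 0], [10, 0, 0]],
        production=["conventional", "conventional", "organic", "organic"],
        plant=["carrot", "lettuce", "carrot", "lettuce"],
    )


@pytest.fixture
def small_scene_design() -> SceneDesign:
    """A fast, small joint scene used by several integration-style tests."""
    return SceneDesign(
        n_taxa=30, plant_species=("carrot", "lettuce"), replicates_per_plant=3,
        n_da_taxa=0, n_opu_templates=3, spectra_per_sample=20,
        junk_fraction=0.15, outlier_fraction=0.05,
        couplings=(), coupling_strength=0.0,
    )
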