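import numpy as np
import pandas as pd
import pytest

from soilmep import synthgen
from soilmep.synthgen import EffectConfig, ProteomeConfig


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture(scope="session")
def small_scenario():
    """Neutral 5-taxon community, 3 samples per compartment."""
    return synthgen.simulate_community(
        n_taxa=5, n_samples=3, depth=50.0, effect_config=EffectConfig(), seed=42
    )


@pytest.fixture(scope="session")
def small_metagenome(small_scenario):
    return synthgen.simulate_metagenome(
        small_scenario, orfs_per_megabase=5.0, seed=42
    )


@pytest.fixture(scope="session")
def small_psm_set(small_scenario):
    cfg = ProteomeConfig(n_proteins=120, ms_depth=6000.0)
    return synthgen.simulate_psm_table(small_scenario, cfg, seed=42)


def random_peptide_protein_map(rng, n_proteins, n_peptides):
    """Random bipartite map: each peptide to a nonempty protein subset."""
    proteins = [f"P{i}" for i in range(n_proteins)]
    mapping = {}
    for j in range(n_peptides):
        k = int(rng.integers(1, n_proteins + 1))
        owners = rng.choice(proteins, size=k, replace=False)
        mapping[f"pep{j}"] = sorted(owners)
    return mapping
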