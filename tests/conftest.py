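"""Shared fixtures: small simulated stands reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from oakforge import SimConfig, TraitSpec, pedigree_nrm, simulate_stand


@pytest.fixture(scope="session")
def small_stand():
    """A compact two-species stand: 60 parents, 300 saplings, both SNP panels."""
    cfg = SimConfig(
        n_parents_per_species=30, plot_width=160.0, plot_height=160.0,
        n_snps_small=82, n_snps_large=600, n_offspring=300,
        seed_kernel_scale=15.0, pollen_kernel_scale=40.0, fecundity_cv=1.0,
        trait_specs=[TraitSpec("growth", 100.0, 40.0, 40.0, 0.6),
                     TraitSpec("leaf", 10.0, 2.0, 2.0, -0.3)],
        rng_seed=2024,
    )
    return cfg, simulate_stand(cfg)


def full_pedigree(stand: pd.DataFrame, truth) -> pd.DataFrame:
    """G1 founders (unknown parents) followed by the G2 parentage records."""
    g1 = stand.loc[stand.generation == "G1", "tree_id"]
    founders = pd.DataFrame({"tree_id": g1, "mother_id": None, "father_id": None})
    return pd.concat([founders, truth.pedigree], ignore_index=True)


def g2_nrm(stand, truth):
    """Pedigree numerator relationship matrix restricted to the G2 cohort."""
    g2 = stand.loc[stand.generation == "G2", "tree_id"]
    return pedigree_nrm(full_pedigree(stand, truth)).reindex(g2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
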