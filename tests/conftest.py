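"""Shared fixtures: small synthetic studies with known planted structure."""

import numpy as np
import pytest

import voxgex as vg


@pytest.fixture(scope="session")
def atlas():
    """16^3 ellipsoidal atlas with the default 54 regions (~1500 voxels)."""
    return vg.make_atlas((16, 16, 16), n_regions=54, seed=7)


@pytest.fixture(scope="session")
def small_atlas():
    """Coarser 12^3 atlas with 8 regions for fast replicate loops."""
    return vg.make_atlas((12, 12, 12), n_regions=8, seed=3)


@pytest.fixture(scope="session")
def study(atlas):
    """Default-scale synthetic study: 6 donors, planted modules and links."""
    truth, profiles = vg.simulate_gene_library(
        atlas, n_genes=30, n_modules=2, module_size=5,
        within_module_cor=0.85, noise_sd=1.0, seed=11)
    donors = [vg.sample_donor(atlas, profiles, 400, measurement_noise_sd=0.3,
                              seed=100 + d, donor_id=f"donor_{d + 1}")
              for d in range(6)]
    terms = vg.simulate_term_maps(atlas, truth, n_terms=10,
                                  active_fraction=0.08, z_effect=4.0, seed=21)
    return truth, profiles, donors, terms


@pytest.fixture(scope="session")
def noiseless_donors(atlas):
    """Zero-noise donors: sample values equal their region's true value."""
    truth, profiles = vg.simulate_gene_library(
        atlas, n_genes=6, n_modules=0, module_size=0,
        within_module_cor=0.0, noise_sd=1.0, seed=5)
    donors = [vg.sample_donor(atlas, profiles, 600, measurement_noise_sd=0.0,
                              seed=200 + d, donor_id=f"donor_{d + 1}")
              for d in range(6)]
    return truth, profiles, donors
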