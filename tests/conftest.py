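import numpy as np
import pytest

import idpens as ip


@pytest.fixture(scope="session")
def liganded_ensemble():
    """Small covalent-adduct ensemble with coupled observables."""
    cfg = ip.GeneratorConfig(n_frames=20, helix_propensity=ip.two_region_profile(),
                             helix_cooperativity=0.9, ligand_site=13,
                             mc_sweeps_per_frame=3, seed=101)
    ens, truth = ip.sample_ensemble(cfg)
    return ens, truth


@pytest.fixture(scope="session")
def coil_ensemble():
    cfg = ip.GeneratorConfig(n_frames=30, helix_propensity=0.2,
                             mc_sweeps_per_frame=3, seed=102)
    ens, truth = ip.sample_ensemble(cfg)
    return ens, truth


@pytest.fixture(scope="session")
def planted_families():
    """Two well-separated conformational families (60 frames each):
    compact-helical vs tight extended ribbon."""
    helical, _ = ip.sample_ensemble(ip.GeneratorConfig(
        n_frames=60, helix_propensity=0.95, helix_cooperativity=0.9,
        rg_target=1.2, rg_force_constant=150.0, mc_sweeps_per_frame=10,
        seed=111))
    extended, _ = ip.sample_ensemble(ip.GeneratorConfig(
        n_frames=60, helix_propensity=0.0,
        coil_phi_range=(-130.0, -110.0), coil_psi_range=(110.0, 130.0),
        mc_sweeps_per_frame=3, seed=112))
    labels = np.array([0] * 60 + [1] * 60)
    return helical, extended, labels


@pytest.fixture(scope="session")
def random_frames():
    """Random annotated frames covering every interaction class."""
    from idpens.synthetic import random_interaction_ensemble
    return random_interaction_ensemble(n_frames=40, seed=77)
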