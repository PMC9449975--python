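import numpy as np
import pytest

from bsapkit import synth_fixtures as sf
from bsapkit.core_io import HydrophobicityScale
from bsapkit.sasa import build_exposure_reference


@pytest.fixture(scope="session")
def bm_scale():
    return HydrophobicityScale.black_mould()


@pytest.fixture(scope="session")
def exposure_reference():
    # single-conformer reference keeps the session fast; determinism is
    # covered separately
    return build_exposure_reference(conformers=1)


@pytest.fixture(scope="session")
def toy_protein():
    """Small mixed hydrophobic/hydrophilic extended peptide."""
    return sf.make_toy_protein(
        ["LEU", "PHE", "GLY", "SER", "ILE", "ALA", "VAL"], "extended", seed=11
    )


@pytest.fixture(scope="session")
def hydrophobic_patch():
    """All-hydrophobic peptide: every neighborhood scores positive."""
    return sf.make_toy_protein(["LEU", "ILE", "VAL", "LEU", "PHE"], "extended", seed=5)


@pytest.fixture()
def adsorption_fixture(toy_protein):
    system, frame = toy_protein
    traj, truth = sf.make_adsorption_trajectory(
        system, frame, k_on=0.01, n_frames=300, seed=23, n_neutral=2, n_charged=1
    )
    return traj, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
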