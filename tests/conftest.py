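import numpy as np
import pytest

from photopull.builders import ideal_helix, seven_tm_bundle, toy_pdb
from photopull.fd import WLCParams
from photopull.structure import BeadChain, native_chirality, prepare_topology


@pytest.fixture(scope="session")
def bundle():
    """The synthetic seven-TM membrane-protein stand-in (348 residues)."""
    return seven_tm_bundle()


@pytest.fixture(scope="session")
def bundle_chain(bundle):
    return prepare_topology(bundle.pdb_text, "A")


@pytest.fixture()
def wlc():
    return WLCParams()


@pytest.fixture()
def toy_three_residue_pdb():
    """Three residues with backbone + side-chain heavy atoms at 3.8 A spacing."""
    residues = [
        ("ALA", [0.0, 0.0, 0.0]),
        ("GLY", [0.0, 0.0, 3.8]),
        ("LEU", [0.0, 0.0, 7.6]),
    ]
    extra = [
        (1, "N", "N", [-1.2, 0.3, -0.5]),
        (1, "C", "C", [1.2, 0.2, 0.6]),
        (1, "O", "O", [2.0, 1.0, 0.6]),
        (1, "CB", "C", [1.4, -0.8, -0.4]),
        (2, "N", "N", [-1.1, 0.2, 3.2]),
        (2, "C", "C", [1.1, 0.3, 4.4]),
        (2, "O", "O", [2.1, 0.9, 4.5]),
        (3, "N", "N", [-1.2, 0.1, 7.0]),
        (3, "C", "C", [1.2, 0.1, 8.2]),
        (3, "O", "O", [2.0, 0.8, 8.3]),
        (3, "CB", "C", [1.3, -0.9, 7.2]),
    ]
    return toy_pdb(residues, extra_atoms=extra)


def make_helix_chain(n_res: int = 50, seed: int = 0, cutoff: float = 7.0) -> BeadChain:
    """A bead chain from an ideal helix with contacts assigned by C-alpha
    proximity (i, i+3 / i+4 pairs for the default cutoff), for integrator
    and force tests. A larger ``cutoff`` adds i, i+5 contacts and makes the
    fold distinctly more stable than the working temperature."""
    rng = np.random.default_rng(seed)
    pos = ideal_helix(n_res) + rng.normal(0, 0.01, (n_res, 3))
    contacts = []
    for i in range(n_res):
        for j in range(i + 3, n_res):
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d < cutoff:
                contacts.append((i, j, d))
    chain = BeadChain(positions=pos, sequence="A" * n_res,
                      native_contacts=contacts)
    chain.native_chi = native_chirality(chain)
    chain.hydrophobic = np.ones(n_res, dtype=bool)
    chain.membrane_contact = np.zeros(n_res, dtype=bool)
    return chain


@pytest.fixture()
def helix_chain():
    return make_helix_chain()
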