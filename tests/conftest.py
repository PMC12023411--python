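"""Shared fixtures: small synthetic structures and a pre-trained family VAE."""

import numpy as np
import pytest

import biotite.structure as struc

from coldzyme import evofit, synthetic


@pytest.fixture(scope="session")
def toy_family():
    """Synthetic MSA with invariant, conserved and free columns."""
    return synthetic.gen_msa(
        n_seq=200, length=40, n_invariant=8, n_conserved=8, gap_p=0.03, seed=1
    )


@pytest.fixture(scope="session")
def trained_vae(toy_family):
    """Family VAE trained once per session on the toy family."""
    arch = evofit.VaeArch(
        encoder_hidden=[64, 32], decoder_hidden=[32, 64],
        latent_dim=8, epochs=300, seed=0,
    )
    model, trace = evofit.train_vae(toy_family, arch)
    return model, trace


def make_two_chain_structure(n_res_per_chain: int, atoms_per_res: int = 3, seed: int = 0,
                             chain_offset: float = 15.0):
    """Random two-chain AtomArray for contact/SASA tests."""
    rng = np.random.default_rng(seed)
    n = 2 * n_res_per_chain * atoms_per_res
    arr = struc.AtomArray(n)
    coords, chain_ids, res_ids, elements, atom_names = [], [], [], [], []
    for c, chain in enumerate("AB"):
        base = np.array([c * chain_offset, 0.0, 0.0])
        for r in range(n_res_per_chain):
            center = base + rng.uniform(-10, 10, 3)
            for a in range(atoms_per_res):
                coords.append(center + rng.uniform(-1.5, 1.5, 3))
                chain_ids.append(chain)
                res_ids.append(r + 1)
                elements.append("C")
                atom_names.append(f"C{a}")
    arr.coord = np.asarray(coords)
    arr.chain_id = np.asarray(chain_ids)
    arr.res_id = np.asarray(res_ids)
    arr.element = np.asarray(elements)
    arr.atom_name = np.asarray(atom_names)
    arr.res_name = np.full(n, "ALA")
    return arr


@pytest.fixture
def two_chain_structure():
    return make_two_chain_structure(100, seed=7)
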