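"""Shared fixtures: desk-scale render geometry, small stacks, reference bank.

Everything is generated programmatically and seeded; session scope keeps
the rendering cost paid once.
"""

import numpy as np
import pytest

from dcxmt.classify import build_references
from dcxmt.simulate import desk_params, make_dataset


@pytest.fixture(scope="session")
def rp_clean():
    """Noiseless, undecorated desk-scale rendering parameters."""
    return desk_params(noise_sigma=0.0, occupancy_p=0.0, seed=101)


@pytest.fixture(scope="session")
def stack13_decorated():
    """30 fully decorated 13-PF segments at default (moderate) noise."""
    return make_dataset([(13, 1.0, 1.0)], 30, desk_params(seed=7))


@pytest.fixture(scope="session")
def stack13_undecorated():
    """30 undecorated 13-PF segments at default noise."""
    return make_dataset([(13, 1.0, 0.0)], 30, desk_params(seed=7))


@pytest.fixture(scope="session")
def bank():
    """Reference bank for N = 11..16 at desk scale (15 A low-pass, 2x bin,
    giving the same 5.56 A binned pixel as 4x binning at full scale)."""
    return build_references(rp=desk_params(), bin_factor=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_random_protein_fixture(rng, n_res=40):
    """~160-atom two-chain model with realistic residue/atom names, for
    brute-force comparisons of the interface engine."""
    from dcxmt.structure import StructureModel

    menu = {
        "LYS": [("N", "N"), ("CA", "C"), ("CB", "C"), ("NZ", "N")],
        "GLU": [("N", "N"), ("CA", "C"), ("OE1", "O"), ("OE2", "O")],
        "ARG": [("N", "N"), ("CA", "C"), ("NH1", "N"), ("NE", "N")],
        "ASP": [("N", "N"), ("CA", "C"), ("OD1", "O"), ("OD2", "O")],
        "SER": [("N", "N"), ("CA", "C"), ("CB", "C"), ("OG", "O")],
        "ALA": [("N", "N"), ("CA", "C"), ("CB", "C"), ("O", "O")],
    }
    names = list(menu)
    rows = []
    for r in range(n_res):
        chain = "A" if r < n_res // 2 else "B"
        resname = names[int(rng.integers(len(names)))]
        center = rng.uniform(0, 25, size=3)
        for atname, element in menu[resname]:
            rows.append((chain, r + 1, resname, atname, element,
                         *(center + rng.normal(0, 1.0, size=3))))
    cols = list(zip(*rows))
    return StructureModel(
        chain=np.array(cols[0]), resnum=np.array(cols[1], dtype=int),
        icode=np.array([""] * len(rows)), resname=np.array(cols[2]),
        atname=np.array(cols[3]), element=np.array(cols[4]),
        xyz=np.column_stack(cols[5:8]).astype(float), occ=np.ones(len(rows)))


@pytest.fixture()
def random_protein_model(rng):
    return make_random_protein_fixture(rng)
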