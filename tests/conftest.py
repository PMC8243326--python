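import numpy as np
import pytest

from ensdock import extract_ca, make_helical_bundle
from ensdock.structio import Atom, Structure


@pytest.fixture(scope="session")
def bundle():
    """Deterministic 12-helix membrane-protein fixture (300 residues)."""
    return make_helical_bundle(seed=0)


@pytest.fixture(scope="session")
def bundle_ca(bundle):
    return extract_ca(bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """Lighter 4-helix bundle for per-test ANM work."""
    return make_helical_bundle(n_helices=4, len_per_helix=12, ring_radius=10.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   2      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   3      12.489   7.227  -4.620  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


def make_point_structure(coords, element="C", vdw=None, res_name="UNK",
                         names=None, chain="A", res_indices=None, hetero=False):
    """Helper: one atom per coordinate, one residue per atom by default."""
    from ensdock.structio import VDW_RADII

    atoms = []
    for i, p in enumerate(np.asarray(coords, dtype=float)):
        el = element if isinstance(element, str) else element[i]
        atoms.append(
            Atom(
                element=el,
                name=(names[i] if names else el),
                res_index=(res_indices[i] if res_indices else i + 1),
                res_name=res_name,
                chain=chain,
                xyz=tuple(p),
                vdw=vdw if vdw is not None else VDW_RADII.get(el, 1.7),
                hetero=hetero,
            )
        )
    return Structure(atoms=atoms)
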