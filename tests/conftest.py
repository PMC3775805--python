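import numpy as np
import pytest

from xlmod.structure_model import Atom, Chain, Residue, Structure
from xlmod.synthetic_fixtures import make_helix, make_two_chain_complex


def toy_structure(coords, res_name="LYS", atom_name="CB", chain_id="A",
                  element="C", radius=1.70):
    """One single-atom residue per coordinate, numbered from 1."""
    chain = Chain(id=chain_id)
    for i, c in enumerate(coords, start=1):
        res = Residue(res_name, i, "", chain_id)
        res.atoms = [Atom(name=atom_name, element=element, res_name=res_name,
                          res_seq=i, chain_id=chain_id,
                          coord=np.asarray(c, dtype=float), vdw_radius=radius)]
        chain.residues.append(res)
    return Structure(id="toy", chains=[chain])


@pytest.fixture(scope="session")
def helix():
    return make_helix(20)


@pytest.fixture(scope="session")
def two_chain():
    return make_two_chain_complex()
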