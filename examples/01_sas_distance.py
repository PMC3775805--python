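"""Euclidean vs solvent-accessible-surface (SAS) distance on a toy protein.

Builds a solid slab with a lysine on each face and measures the distance
between their CB atoms both ways.  The straight line tunnels through the
slab; the SAS path has to walk around it, which is what a chemical
cross-linker would have to do.
"""

import numpy as np

from xlmod.sasd import mono_link_accessible, sas_distance
from xlmod.structure_model import Atom, AtomSpec, Residue
from xlmod.synthetic_fixtures import make_hollow_shell, make_slab


def add_cb_probe(structure, coord, seq):
    res = Residue("LYS", seq, "", "A")
    res.atoms = [Atom(name="CB", element="C", res_name="LYS", res_seq=seq,
                      chain_id="A", coord=np.asarray(coord, float),
                      vdw_radius=1.70)]
    structure.chains[0].residues.append(res)
    return AtomSpec("LYS", seq, "A", "CB")


slab = make_slab(nx=6, ny=6, nz=4)  # a 10 x 10 x 6 A solid block
below = add_cb_probe(slab, (5.0, 5.0, -4.0), seq=900)
above = add_cb_probe(slab, (5.0, 5.0, 10.0), seq=901)

xl = sas_distance(slab, below, above, spacing=1.0)
print(f"Euclidean distance : {xl.euclidean:6.2f} A   (cuts through the slab)")
print(f"SAS distance       : {xl.sasd:6.2f} A   (walks around the surface)")
print(f"traced path        : {len(xl.path)} grid points")

# a site sealed inside a hollow shell has no path to bulk solvent at all
shell = make_hollow_shell()
probe_seq = shell.chains[0].residues[-1].seq
buried = mono_link_accessible(shell, AtomSpec("LYS", probe_seq, "A", "CB"))
print(f"shell-enclosed site accessible: {buried}  (mono-links require exposure)")
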