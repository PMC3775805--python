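"""Deterministic toy structures, decoy ensembles and cross-link tables.

Everything downstream of the PDB parser is testable on structures whose
geometry is known exactly: ideal poly-lysine helices, close-packed atom
slabs with lysine sites planted at chosen surface positions, hollow shells
enclosing a buried probe, and two-slab complexes whose virtual cross-link
content and interface size follow from the construction.  Decoy ensembles
are rigid-body perturbations of a reference complex; the generator records
each decoy's exact ligand RMSD and a pseudo energy score correlated with it,
so selection cascades have a verifiable signal.

All outputs are bit-reproducible from (parameters, seed).  None of this is
physically realistic packing - it stands in for real PDB inputs only in the
geometric respects the algorithms consume (occupancy of space, surface
exposure, rigid-body pose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_model import Atom, Chain, Residue, RigidPose, Structure, rmsd
from .virtual_xl import XLDB_BINS, BinDistribution

__all__ = [
    "FixtureSpec",
    "Decoy",
    "make_structure",
    "make_helix",
    "make_slab",
    "make_hollow_shell",
    "make_dumbbell",
    "make_two_chain_complex",
    "make_decoys",
    "make_wrapping_ensemble",
    "make_xldb_table",
]

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind, geometric parameters, seed."""

    kind: str
    params: tuple = field(default_factory=tuple)  # sorted (key, value) pairs
    seed: int = 0

    @classmethod
    def of(cls, kind: str, seed: int = 0, **params) -> "FixtureSpec":
        return cls(kind=kind, params=tuple(sorted(params.items())), seed=seed)


def make_structure(spec: FixtureSpec) -> Structure:
    """Build the structure a :class:`FixtureSpec` describes."""
    makers = {
        "helix": make_helix,
        "slab": make_slab,
        "hollow_shell": make_hollow_shell,
        "dumbbell": make_dumbbell,
        "two_chain_complex": make_two_chain_complex,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return makers[spec.kind](**dict(spec.params))


def _atom(name: str, element: str, coord, res_name: str, seq: int, chain: str) -> Atom:
    return Atom(name=name, element=element, res_name=res_name, res_seq=seq,
                chain_id=chain, coord=np.asarray(coord, dtype=float),
                vdw_radius=_VDW[element])


def make_helix(n_res: int = 20, chain_id: str = "A", res_name: str = "LYS") -> Structure:
    """Ideal alpha-helical trace of poly-lysine.

    C-alpha atoms on a helix of radius 2.3 A, rise 1.5 A and 100 deg per
    residue (consecutive CA-CA distance ~3.8 A); each residue carries N, CA,
    C, O plus CB and NZ pseudo-side-chain atoms pointing radially outward.
    """
    chain = Chain(id=chain_id)
    for i in range(n_res):
        theta = math.radians(100.0 * i)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward
        v = np.array([-math.sin(theta), math.cos(theta), 0.0])  # tangential
        w = np.array([0.0, 0.0, 1.0])
        ca = 2.3 * u + np.array([0.0, 0.0, 1.5 * i])
        seq = i + 1
        res = Residue(name=res_name, seq=seq, icode="", chain_id=chain_id)
        res.atoms = [
            _atom("N", "N", ca - 0.9 * v - 0.8 * w, res_name, seq, chain_id),
            _atom("CA", "C", ca, res_name, seq, chain_id),
            _atom("C", "C", ca + 0.9 * v + 0.8 * w, res_name, seq, chain_id),
            _atom("O", "O", ca + 0.9 * v + 2.0 * w, res_name, seq, chain_id),
            _atom("CB", "C", ca + 1.53 * u, res_name, seq, chain_id),
            _atom("NZ", "N", ca + 4.5 * u, res_name, seq, chain_id),
        ]
        chain.residues.append(res)
    return Structure(id=f"helix{n_res}", chains=[chain])


def _face_sign(face: str) -> float:
    if face == "+z":
        return 1.0
    if face == "-z":
        return -1.0
    raise ValueError(f"unsupported lysine face {face!r}")


def make_slab(
    nx: int = 8,
    ny: int = 8,
    nz: int = 3,
    lattice: float = 2.0,
    chain_id: str = "A",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    lys_xy: Sequence[tuple[float, float]] = (),
    lys_face: str = "+z",
    start_seq: int = 1,
) -> Structure:
    """Close-packed rectangular block of CA pseudo-atoms with planted lysines.

    The bulk is a (nx, ny, nz) lattice of single-CA alanine residues; at the
    lattice spacing of 2.0 A the solvent-excluded volumes overlap, so the
    block is solid to the grid search.  Each ``lys_xy`` entry plants a LYS
    residue on the chosen z-face at that in-plane position (relative to
    ``origin``): CA 1.2 A outside the face, CB at 2.7 A, NZ at 5.0 A.
    """
    o = np.asarray(origin, dtype=float)
    chain = Chain(id=chain_id)
    seq = start_seq
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                coord = o + lattice * np.array([i, j, k], dtype=float)
                res = Residue(name="ALA", seq=seq, icode="", chain_id=chain_id)
                res.atoms = [_atom("CA", "C", coord, "ALA", seq, chain_id)]
                chain.residues.append(res)
                seq += 1
    sign = _face_sign(lys_face)
    face_z = o[2] + (0.0 if sign < 0 else lattice * (nz - 1))
    for (x, y) in lys_xy:
        base = np.array([o[0] + x, o[1] + y, face_z])
        res = Residue(name="LYS", seq=seq, icode="", chain_id=chain_id)
        res.atoms = [
            _atom("CA", "C", base + sign * np.array([0, 0, 1.2]), "LYS", seq, chain_id),
            _atom("CB", "C", base + sign * np.array([0, 0, 2.7]), "LYS", seq, chain_id),
            _atom("NZ", "N", base + sign * np.array([0, 0, 5.0]), "LYS", seq, chain_id),
        ]
        chain.residues.append(res)
        seq += 1
    return Structure(id=f"slab{chain_id}", chains=[chain])


def make_hollow_shell(
    radius: float = 8.0,
    point_spacing: float = 1.2,
    chain_id: str = "A",
    probe: bool = True,
) -> Structure:
    """Spherical shell of carbon atoms enclosing an interior probe lysine.

    The shell atoms sit on a golden-spiral sphere dense enough that their
    solvent-excluded volumes seal the wall; the probe CB at the center is
    therefore walled off from bulk solvent (mono-link accessibility False,
    SAS distance to any outside atom -1).
    """
    n = max(32, int(round(4.0 * math.pi * radius**2 / point_spacing**2)))
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    chain = Chain(id=chain_id)
    for seq, p in enumerate(pts, start=1):
        res = Residue(name="ALA", seq=seq, icode="", chain_id=chain_id)
        res.atoms = [_atom("CA", "C", p, "ALA", seq, chain_id)]
        chain.residues.append(res)
    if probe:
        seq = len(pts) + 1
        res = Residue(name="LYS", seq=seq, icode="", chain_id=chain_id)
        res.atoms = [
            _atom("CA", "C", (0.0, 0.0, -0.8), "LYS", seq, chain_id),
            _atom("CB", "C", (0.0, 0.0, 0.8), "LYS", seq, chain_id),
        ]
        chain.residues.append(res)
    return Structure(id="hollow_shell", chains=[chain])


def make_dumbbell(separation: float = 10.0, chain_ids: tuple[str, str] = ("A", "B")) -> Structure:
    """Two compact 7-atom octahedral clusters separated along x.

    Each cluster is one chain, so BSA between the chains is well defined and
    vanishes as ``separation`` grows.
    """
    offsets = np.array([
        [0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2], [0, 0, -2],
    ], dtype=float)
    chains = []
    for ci, (cid, center) in enumerate(
        zip(chain_ids, [np.zeros(3), np.array([separation, 0.0, 0.0])])
    ):
        chain = Chain(id=cid)
        for seq, off in enumerate(offsets, start=1):
            res = Residue(name="ALA", seq=seq, icode="", chain_id=cid)
            res.atoms = [_atom("CA", "C", center + off, "ALA", seq, cid)]
            chain.residues.append(res)
        chains.append(chain)
    return Structure(id="dumbbell", chains=chains)


def make_two_chain_complex(
    gap: float = 12.0,
    nx: int = 8,
    ny: int = 8,
    nz: int = 3,
    lattice: float = 2.0,
    lys_a: Sequence[tuple[float, float]] = ((2.0, 2.0), (7.0, 7.0), (12.0, 12.0)),
    lys_b: Sequence[tuple[float, float]] = ((3.0, 10.0), (10.0, 3.0), (11.0, 11.0)),
    ligand_nx: int | None = None,
    ligand_ny: int | None = None,
    ligand_nz: int | None = None,
    ligand_offset_xy: Sequence[float] = (0.0, 0.0),
) -> Structure:
    """Receptor slab (chain A) facing a ligand slab (chain B) across ``gap``.

    ``gap`` is the distance between the receptor's top plane and the ligand's
    bottom plane; receptor lysines point up into the gap, ligand lysines
    point down, so every inter-chain lysine pair spans the gap.  With the
    defaults all nine pairs lie within the 34 A SAS ruler.
    """
    receptor = make_slab(nx=nx, ny=ny, nz=nz, lattice=lattice, chain_id="A",
                         lys_xy=lys_a, lys_face="+z")
    z_top = lattice * (nz - 1)
    lnx = ligand_nx if ligand_nx is not None else nx
    lny = ligand_ny if ligand_ny is not None else ny
    lnz = ligand_nz if ligand_nz is not None else nz
    ligand = make_slab(
        nx=lnx, ny=lny, nz=lnz, lattice=lattice, chain_id="B",
        origin=(ligand_offset_xy[0], ligand_offset_xy[1], z_top + gap),
        lys_xy=lys_b, lys_face="-z",
    )
    return Structure(id="two_chain_complex",
                     chains=[receptor.chains[0], ligand.chains[0]])


# ---------------------------------------------------------------------------
# Decoy ensembles


@dataclass
class Decoy:
    """One perturbed model with its generator-recorded ground truth."""

    model_id: str
    structure: Structure
    pose: RigidPose  # world-frame ligand transform relative to the reference
    lrmsd: float  # exact CA ligand RMSD recorded at generation time
    score: float  # pseudo energy: lrmsd + seeded noise


def _transform_ligand(reference: Structure, ligand_chains: Sequence[str],
                      pose: RigidPose, model_id: str) -> Structure:
    st = reference.copy()
    st.id = model_id
    for chain in st.chains:
        if chain.id in ligand_chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.coord = pose.apply(a.coord[None, :])[0]
    return st


def _ligand_pose_about(center: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> RigidPose:
    # x -> R (x - c) + c + t
    return RigidPose(rot, center - rot @ center + trans)


def make_decoys(
    reference: Structure,
    n: int = 200,
    max_trans: float = 40.0,
    max_rot_deg: float = 180.0,
    seed: int = 0,
    receptor_chains: Sequence[str] = ("A",),
    ligand_chains: Sequence[str] = ("B",),
    score_noise: float = 20.0,
    clash_cutoff: float | None = 3.4,
    include_reference: bool = False,
) -> list[Decoy]:
    """Rigid-body perturbed ligand poses around a reference complex.

    Each decoy rotates the ligand about its centroid by a uniformly random
    axis and angle in [0, max_rot_deg] and translates it by a uniformly
    random direction and magnitude in [0, max_trans]; poses whose ligand
    comes closer than ``clash_cutoff`` to the receptor are resampled, the
    way docking samplers exclude interpenetrating poses.  The default floor
    is carbon-carbon van der Waals contact, so no decoy can squeeze its
    cross-linked residues closer than physical packing allows.  The exact ligand
    CA RMSD is recorded (receptor untouched, so no refit is needed) together
    with a pseudo energy score = L-RMSD + Gaussian noise.  The default noise
    amplitude makes the score a weak predictor of pose quality, emulating
    how poorly low-resolution docking energies rank nativeness (blind
    best-score models are routinely tens of Angstrom off).
    """
    rng = np.random.default_rng(seed)
    lig_ca_ref = reference.ca_coords(ligand_chains)
    lig_all = np.array([
        a.coord for c in reference.chains if c.id in ligand_chains
        for a in (at for r in c.residues for at in r.atoms)
    ])
    rec_all = np.array([
        a.coord for c in reference.chains if c.id in receptor_chains
        for a in (at for r in c.residues for at in r.atoms)
    ])
    from scipy.spatial import cKDTree
    rec_tree = cKDTree(rec_all)
    centroid = lig_all.mean(axis=0)
    decoys = []
    if include_reference:
        decoys.append(Decoy("ref", reference.copy(), RigidPose.identity(), 0.0,
                            float(score_noise * rng.standard_normal())))
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        for _attempt in range(1000):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = math.radians(rng.uniform(0.0, max_rot_deg))
            rot = Rotation.from_rotvec(axis * angle).as_matrix()
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            trans = direction * rng.uniform(0.0, max_trans)
            pose = _ligand_pose_about(centroid, rot, trans)
            if clash_cutoff is None:
                break
            min_dist = rec_tree.query(pose.apply(lig_all))[0].min()
            if min_dist >= clash_cutoff:
                break
        else:
            raise RuntimeError("could not sample a clash-free decoy pose")
        model_id = f"d{i:0{width}d}"
        st = _transform_ligand(reference, ligand_chains, pose, model_id)
        lrmsd = rmsd(pose.apply(lig_ca_ref), lig_ca_ref)
        score = lrmsd + float(score_noise * rng.standard_normal())
        decoys.append(Decoy(model_id, st, pose, lrmsd, score))
    return decoys


def make_wrapping_ensemble(
    seed: int = 0,
    n_native: int = 60,
    n_backside: int = 60,
    jitter: float = 1.5,
    score_noise: float = 20.0,
) -> tuple[Structure, list[Decoy], dict]:
    """Ensemble where only the SAS distance exposes wrong-side poses.

    The reference is a small ligand docked on the top face of a thin, wide
    receptor plate.  "Backside" decoys park the (flipped) ligand under the
    plate: the straight line from their lysines to the receptor's top-face
    lysines cuts through the plate and is about as short as in the native
    pose, so the Euclidean metric cannot tell the two families apart - but
    the solvent path has to wrap around the whole plate and exceeds the 34 A
    ruler, so the SAS metric rejects them.  Backside ligand RMSDs are ~20 A.

    Returns (reference, decoys, info) where info names the chain split.
    """
    rng = np.random.default_rng(seed)
    reference = make_two_chain_complex(
        gap=12.0, nx=20, ny=20, nz=2, lattice=2.0,
        lys_a=((15.0, 19.0), (19.0, 15.0), (23.0, 19.0)),
        lys_b=((17.0, 17.0), (21.0, 21.0), (17.0, 21.0)),
        ligand_nx=8, ligand_ny=8, ligand_nz=2,
        ligand_offset_xy=(12.0, 12.0),
    )
    ligand_chains = ("B",)
    lig_ca_ref = reference.ca_coords(ligand_chains)
    lig_all = np.array([
        a.coord for c in reference.chains if c.id in ligand_chains
        for a in (at for r in c.residues for at in r.atoms)
    ])
    centroid = lig_all.mean(axis=0)
    flip = Rotation.from_rotvec([math.pi, 0.0, 0.0]).as_matrix()
    # flip about the ligand centroid, then drop it below the receptor plate so
    # its lysines point up at the plate's underside
    lig_lys_cb_z = 14.0 - 2.7  # bottom-face CB height in the reference
    flipped_cb_z = 2.0 * centroid[2] - lig_lys_cb_z
    backside_trans_z = -2.0 - flipped_cb_z  # put flipped CBs just under the plate
    decoys = []
    for i in range(n_native + n_backside):
        t = rng.uniform(-jitter, jitter, size=3)
        if i < n_native:
            pose = _ligand_pose_about(centroid, np.eye(3), t)
            model_id = f"n{i:03d}"
        else:
            pose = _ligand_pose_about(
                centroid, flip, np.array([0.0, 0.0, backside_trans_z]) + t
            )
            model_id = f"b{i:03d}"
        st = _transform_ligand(reference, ligand_chains, pose, model_id)
        lrmsd = rmsd(pose.apply(lig_ca_ref), lig_ca_ref)
        score = lrmsd + float(score_noise * rng.standard_normal())
        decoys.append(Decoy(model_id, st, pose, lrmsd, score))
    info = {"receptor_chains": ("A",), "ligand_chains": ligand_chains}
    return reference, decoys, info


# ---------------------------------------------------------------------------
# Synthetic cross-link database table


def make_xldb_table(
    n_intra: int = 506,
    n_inter: int = 62,
    n_publications: int = 14,
    frac_within_ruler: float = 0.80,
    bins: BinDistribution = XLDB_BINS,
    beyond_max: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a literature-curated cross-link table.

    Emulates the composition of the curated DSS/BS3 cross-link compilation:
    506 intra- plus 62 inter-protein links from 14 publications, with about
    80 % of SAS distances inside the 34 A ruler, distributed over the five
    distance bins 0-10/10-15/15-20/20-25/25-34 A with probabilities
    9/18/34/22/16 %; the remainder is spread uniformly up to ``beyond_max``.
    Euclidean distances are drawn as a fraction of the SAS distance (the
    straight line is never longer than the surface path).  This synthetic
    table exercises the reader and the distribution statistics; it contains
    no real experimental identifications.
    """
    rng = np.random.default_rng(seed)
    n = n_intra + n_inter
    rows = []
    edges = np.asarray(bins.edges, dtype=float)
    probs = np.asarray(bins.probabilities, dtype=float)
    for i in range(n):
        inter = i >= n_intra
        if rng.uniform() < frac_within_ruler:
            b = rng.choice(len(probs), p=probs)
            sasd = rng.uniform(edges[b], edges[b + 1])
        else:
            sasd = rng.uniform(edges[-1], beyond_max)
        euclid = sasd * rng.uniform(0.70, 1.0)
        chain2 = "B" if inter else "A"
        r1 = int(rng.integers(1, 400))
        r2 = int(rng.integers(1, 400))
        rows.append({
            "publication": f"pub{(i % n_publications) + 1:02d}",
            "pdb_id": f"{1000 + (i % 37):04d}",
            "residue1": f"LYS-{r1}-A-CB",
            "residue2": f"LYS-{r2}-{chain2}-CB",
            "type": "inter" if inter else "intra",
            "euclidean": round(float(euclid), 2),
            "sasd": round(float(sasd), 2),
        })
    return pd.DataFrame(rows)
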