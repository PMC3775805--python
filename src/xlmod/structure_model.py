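"""Protein structure model, atom addressing and superposition primitives.

A deliberately small hierarchical model (Structure -> Chain -> Residue ->
Atom) tailored to cross-link work: atoms are addressed by the dash-delimited
``RES-seq-chain[-atom]`` specification used in cross-link distance files,
residue numbering is kept verbatim from the PDB file, and every atom carries
a van der Waals radius so that surface and grid computations need no lookup
of their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "VDW_RADII",
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomSpec",
    "RigidPose",
    "PDBParseError",
    "AtomLookupError",
    "parse_pdb",
    "write_pdb",
    "resolve_spec",
    "kabsch_superpose",
    "ligand_rmsd",
]

#: Element-based van der Waals radii in Angstrom (Bondi-style values).
#: The cross-link literature never prescribes a specific table; these are the
#: customary ones and can be overridden per call via ``radii=``.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class AtomLookupError(KeyError):
    """Raised when an atom specification matches no atom (or several)."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


@dataclass
class Atom:
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str = ""
    chains: list[Chain] = field(default_factory=list)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self) -> Iterator[Atom]:
        for res in self.iter_residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array (copy)."""
        return np.array([a.coord for a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.iter_atoms()], dtype=float)

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def select_chains(self, chain_ids: Iterable[str], id: str | None = None) -> "Structure":
        """New Structure holding only the named chains (atoms are shared)."""
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chain_ids()]
        if missing:
            raise KeyError(f"chains not present in structure {self.id!r}: {missing}")
        chains = [c for c in self.chains if c.id in wanted]
        return Structure(id=id if id is not None else self.id, chains=chains)

    def ca_coords(self, chain_ids: Iterable[str] | None = None) -> np.ndarray:
        """C-alpha coordinates in chain/residue order; errors on missing CA."""
        ids = set(chain_ids) if chain_ids is not None else None
        out, missing = [], []
        for res in self.iter_residues():
            if ids is not None and res.chain_id not in ids:
                continue
            ca = res.get("CA")
            if ca is None:
                missing.append(f"{res.name}-{res.seq}-{res.chain_id}")
            else:
                out.append(ca.coord)
        if missing:
            raise AtomLookupError(f"residues lacking CA atoms: {', '.join(missing)}")
        return np.array(out, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        """Deep copy (coordinates are independent arrays)."""
        new = Structure(id=self.id)
        for chain in self.chains:
            nc = Chain(id=chain.id)
            for res in chain.residues:
                nr = Residue(res.name, res.seq, res.icode, res.chain_id)
                for a in res.atoms:
                    nr.atoms.append(
                        Atom(a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                             a.coord.copy(), a.vdw_radius)
                    )
                nc.residues.append(nr)
            new.chains.append(nc)
        return new

    def transform(self, pose: "RigidPose") -> None:
        """Apply a rigid transform to all atoms in place."""
        for a in self.iter_atoms():
            a.coord = pose.apply(a.coord[None, :])[0]


@dataclass(frozen=True)
class AtomSpec:
    """Dash-delimited atom address, e.g. ``LYS-1-C-CB``.

    ``atom_name`` may be absent (residue-level spec, as used for mono-links);
    it then resolves to CB, or CA for glycine.
    """

    res_name: str
    res_seq: int
    chain_id: str
    atom_name: str | None = None

    @classmethod
    def from_string(cls, text: str) -> "AtomSpec":
        parts = text.strip().split("-")
        if len(parts) not in (3, 4):
            raise ValueError(
                f"bad atom spec {text!r}: expected RES-seq-chain or RES-seq-chain-atom"
            )
        res_name, seq_s, chain = parts[0], parts[1], parts[2]
        try:
            seq = int(seq_s)
        except ValueError:
            raise ValueError(f"bad atom spec {text!r}: residue number {seq_s!r}") from None
        if not res_name or not chain:
            raise ValueError(f"bad atom spec {text!r}: empty field")
        atom = parts[3] if len(parts) == 4 else None
        return cls(res_name.upper(), seq, chain, atom.upper() if atom else None)

    def to_string(self) -> str:
        base = f"{self.res_name}-{self.res_seq}-{self.chain_id}"
        return f"{base}-{self.atom_name}" if self.atom_name else base

    def __str__(self) -> str:
        return self.to_string()


@dataclass
class RigidPose:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-6):
            raise ValueError("rotation matrix must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def angle_to(self, other: "RigidPose") -> float:
        """Relative rotation angle in degrees: arccos((tr(Ri^T Rj) - 1) / 2)."""
        tr = float(np.trace(self.rotation.T @ other.rotation))
        return math.degrees(math.acos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# PDB I/O


def _prescan_pdb(text: str) -> int:
    """Validate fixed-column coordinate records; return number of ATOM records."""
    n_atom = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            int(line[22:26])
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError:
            raise PDBParseError(f"line {lineno}: malformed fixed-column fields") from None
        if rec == "ATOM  ":
            n_atom += 1
    return n_atom


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if el and el != "X":
        return el
    stripped = atom.name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def parse_pdb(
    text: str,
    id: str = "",
    include_hetatm: bool = False,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Waters and (by default) HETATM records are excluded, hydrogens dropped,
    and for alternate locations the highest-occupancy conformer is kept
    (ties: first encountered).  Only the first model of multi-model files is
    read.  Chain and residue order and author residue numbering are preserved.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    if _prescan_pdb(text) == 0:
        raise PDBParseError("no ATOM records in input")
    radii = radii or VDW_RADII

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError("no models in input")
    model = st[0]

    structure = Structure(id=id)
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            if gres.het_flag == "H" and not include_hetatm:
                continue
            res = Residue(
                name=gres.name,
                seq=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                chain_id=gchain.name,
            )
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                if ga.name not in best:
                    best[ga.name] = ga
                    order.append(ga.name)
                elif ga.occ > best[ga.name].occ:
                    best[ga.name] = ga
            for name in order:
                ga = best[name]
                el = _element_of(ga)
                res.atoms.append(
                    Atom(
                        name=name,
                        element=el,
                        res_name=gres.name,
                        res_seq=res.seq,
                        chain_id=gchain.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        vdw_radius=radii.get(el, DEFAULT_RADIUS),
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            structure.chains.append(chain)
    if not structure.chains:
        raise PDBParseError("no protein atoms retained from input")
    return structure


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to fixed-column PDB text."""
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                x, y, z = a.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:4s} {a.res_name:>3s} {chain.id:1s}"
                    f"{res.seq:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def resolve_spec(structure: Structure, spec: AtomSpec) -> Atom:
    """Resolve an :class:`AtomSpec` to the unique matching atom.

    Residue-level specs (no atom name) resolve to CB, falling back to CA for
    glycine (and for any residue lacking a CB).
    """
    matches = [
        res
        for res in structure.iter_residues()
        if res.chain_id == spec.chain_id
        and res.seq == spec.res_seq
        and res.name.upper() == spec.res_name.upper()
    ]
    if not matches:
        raise AtomLookupError(f"no residue matching spec {spec}")
    if len(matches) > 1:
        raise AtomLookupError(f"ambiguous residue spec {spec}: {len(matches)} matches")
    res = matches[0]
    if spec.atom_name is not None:
        atom = res.get(spec.atom_name)
        if atom is None:
            raise AtomLookupError(f"no atom {spec.atom_name!r} in residue for spec {spec}")
        return atom
    atom = res.get("CB")
    if atom is None:
        atom = res.get("CA")
    if atom is None:
        raise AtomLookupError(f"residue for spec {spec} has neither CB nor CA")
    return atom


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidPose, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform (Kabsch, via SVD of the
    covariance matrix) and the post-fit RMSD in Angstrom.  Requires at least
    three non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape[0]} vs {target.shape[0]}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    m = mobile - cm
    t = target - ct
    if np.linalg.matrix_rank(m, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = m.T @ t
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    pose = RigidPose(rot, ct - rot @ cm)
    diff = pose.apply(mobile) - target
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return pose, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("point count mismatch")
    return float(np.sqrt(((a - b) ** 2).sum() / a.shape[0]))


def ligand_rmsd(
    model: Structure,
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
) -> float:
    """Ligand RMSD (L-RMSD): receptor-fit, ligand-measured C-alpha RMSD.

    The model is superposed onto the reference using receptor-chain CA atoms
    only; the returned value is the CA RMSD over the ligand chains without
    refitting, the standard docking-quality measure for the smaller partner.
    """
    rec_m = model.ca_coords(receptor_chains)
    rec_r = reference.ca_coords(receptor_chains)
    lig_m = model.ca_coords(ligand_chains)
    lig_r = reference.ca_coords(ligand_chains)
    pose, _ = kabsch_superpose(rec_m, rec_r)
    return rmsd(pose.apply(lig_m), lig_r)
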