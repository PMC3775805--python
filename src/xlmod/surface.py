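"""Solvent-accessible surface area (SASA) and buried surface area (BSA).

Shrake-Rupley numerical SASA with a deterministic golden-spiral point set,
plus the standard interface-size measure for a two-part complex:

    BSA = SASA(A alone) + SASA(B alone) - SASA(complex)

and the >= 900 A^2 interface-size filter applied during docking-model
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Structure

__all__ = [
    "SasaResult",
    "sphere_points",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "bsa_filter",
]

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent accessible surface areas (A^2)."""

    per_atom: list[float]
    per_residue: dict[tuple[str, int, str], float]
    total: float


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA: per atom, (exposed points / n) * 4 pi (r + probe)^2.

    Deterministic for a given ``n_points`` (fixed golden-spiral construction,
    no randomness), so repeated runs are bit-identical.
    """
    if n_points < 32:
        raise ValueError("n_points < 32 gives too coarse a surface estimate")
    atoms = list(structure.iter_atoms())
    if not atoms:
        raise ValueError("structure has no atoms")
    centers = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(centers)
    max_r = radii.max()
    per_atom: list[float] = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = c + r * unit
        neigh = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - centers[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        per_atom.append(4.0 * np.pi * r * r * exposed.sum() / n_points)

    per_residue: dict[tuple[str, int, str], float] = {}
    k = 0
    for res in structure.iter_residues():
        area = 0.0
        for _ in res.atoms:
            area += per_atom[k]
            k += 1
        per_residue[res.key] = area
    return SasaResult(per_atom=per_atom, per_residue=per_residue, total=float(sum(per_atom)))


def buried_surface_area(
    complex: Structure,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Interface size of a two-part complex.

    The two chain groups must partition the complex's chains; the components
    are evaluated with their coordinates unchanged (no re-relaxation), so the
    result is purely the area occluded by the partner.
    """
    if not chains_a or not chains_b:
        raise ValueError("both chain groups must be non-empty")
    all_ids = complex.chain_ids()
    if sorted(list(chains_a) + list(chains_b)) != sorted(all_ids):
        raise ValueError(
            f"chain groups {list(chains_a)}+{list(chains_b)} do not partition {all_ids}"
        )
    sasa_a = shrake_rupley_sasa(complex.select_chains(chains_a), probe_radius, n_points).total
    sasa_b = shrake_rupley_sasa(complex.select_chains(chains_b), probe_radius, n_points).total
    sasa_ab = shrake_rupley_sasa(complex, probe_radius, n_points).total
    return sasa_a + sasa_b - sasa_ab


def bsa_filter(records: Iterable, threshold: float = 900.0) -> list:
    """Keep model records whose interface is large enough (BSA >= threshold).

    Input order is preserved; an empty result is allowed.  Records must carry
    a ``bsa`` attribute.
    """
    out = []
    for rec in records:
        if rec.bsa is None:
            raise ValueError(f"record {getattr(rec, 'model_id', rec)!r} has no BSA value")
        if rec.bsa >= threshold:
            out.append(rec)
    return out
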