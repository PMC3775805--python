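"""Solvent-accessible-surface (SAS) distances on a cubic grid.

The SAS distance between two cross-linked atoms is the length of the
shortest path connecting them that runs only through solvent, never through
the protein body.  Euclidean distance underestimates the span a chemical
cross-linker must bridge whenever the straight line cuts through the
protein; the SAS distance mimics the linker hugging the surface instead.

Space is discretised on a cubic grid: a cell is PROTEIN when its center lies
within (vdw radius + solvent radius) of any retained atom, SOLVENT otherwise.
Distances propagate from the start cell through solvent cells with
26-neighbor steps weighted by the true center-to-center length, i.e. the
uniform-cost shortest-path metric on the grid graph.  The propagation here is
a synchronous relaxation (repeated vectorised minimum over the 26 shifted
distance fields until convergence) which yields exactly the Dijkstra
distances for these positive weights; cells whose tentative distance exceeds
the search cutoff are pruned, which bounds the number of sweeps.

Endpoint atoms sit inside the protein's own solvent-excluded shell, so a
solvent bubble of radius (vdw + solvent radius) is carved around each
endpoint - the footprint that the flexible, cross-linked side chain itself
would otherwise block.  Pairs whose shortest solvent path exceeds the cutoff
(or that are walled off entirely, e.g. a buried site) report the sentinel
-1.0 rather than raising, so ensemble filters can simply count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .structure_model import Atom, AtomSpec, Structure, resolve_spec

__all__ = [
    "SolventGrid",
    "CrossLink",
    "DistanceFileError",
    "build_solvent_grid",
    "sas_distance",
    "euclidean_distance",
    "mono_link_accessible",
    "parse_distance_file",
    "write_distance_file",
]

DEFAULT_SPACING = 1.0
DEFAULT_SOLVENT_RADIUS = 2.0  # grid solvent radius (the "-radius 2.0" convention)
DEFAULT_MAX_DIST = 34.0  # DSS/BS3 SAS-distance ruler, Angstrom

BACKBONE_ATOMS = {"N", "CA", "C", "O", "CB", "OXT"}

#: 26-neighbor offsets and their step lengths in units of the grid spacing.
NEIGHBOR_OFFSETS: list[tuple[int, int, int]] = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]
NEIGHBOR_WEIGHTS = np.array([math.sqrt(dx * dx + dy * dy + dz * dz)
                             for dx, dy, dz in NEIGHBOR_OFFSETS])


class DistanceFileError(ValueError):
    """Raised for malformed cross-link distance files."""


try:  # optional JIT acceleration of the grid search
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

if _numba is not None:
    _NEIGHBOR_ARRAY = np.array(NEIGHBOR_OFFSETS, dtype=np.int64)

    @_numba.njit(cache=False)
    def _dijkstra_core(blocked, nx, ny, nz, src, offs, ws, cutoff):  # pragma: no cover
        n = nx * ny * nz
        dist = np.full(n, np.inf)
        dist[src] = 0.0
        cap = 27 * n + 1
        heap_d = np.empty(cap)
        heap_i = np.empty(cap, np.int64)
        heap_d[0] = 0.0
        heap_i[0] = src
        hs = 1
        while hs > 0:
            d = heap_d[0]
            u = heap_i[0]
            hs -= 1
            # sift the last element down from the root
            last_d = heap_d[hs]
            last_i = heap_i[hs]
            pos = 0
            while True:
                child = 2 * pos + 1
                if child >= hs:
                    break
                if child + 1 < hs and heap_d[child + 1] < heap_d[child]:
                    child += 1
                if heap_d[child] < last_d:
                    heap_d[pos] = heap_d[child]
                    heap_i[pos] = heap_i[child]
                    pos = child
                else:
                    break
            heap_d[pos] = last_d
            heap_i[pos] = last_i
            if d > dist[u]:
                continue  # stale entry
            ux = u // (ny * nz)
            rem = u % (ny * nz)
            uy = rem // nz
            uz = rem % nz
            for t in range(offs.shape[0]):
                vx = ux + offs[t, 0]
                vy = uy + offs[t, 1]
                vz = uz + offs[t, 2]
                if vx < 0 or vx >= nx or vy < 0 or vy >= ny or vz < 0 or vz >= nz:
                    continue
                v = (vx * ny + vy) * nz + vz
                if blocked[v]:
                    continue
                nd = d + ws[t]
                if cutoff >= 0.0 and nd > cutoff:
                    continue
                if nd < dist[v]:
                    dist[v] = nd
                    # sift the new entry up from the end
                    pos = hs
                    hs += 1
                    while pos > 0:
                        parent = (pos - 1) // 2
                        if heap_d[parent] > nd:
                            heap_d[pos] = heap_d[parent]
                            heap_i[pos] = heap_i[parent]
                            pos = parent
                        else:
                            break
                    heap_d[pos] = nd
                    heap_i[pos] = v
        return dist


@dataclass
class SolventGrid:
    """Cubic grid labeling space as protein-occupied or solvent."""

    origin: np.ndarray  # world coordinate of cell (0,0,0) center
    spacing: float
    shape: tuple[int, int, int]
    protein: np.ndarray  # bool, True = PROTEIN cell

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        i, j, k = (int(v) for v in idx)
        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1] and 0 <= k < self.shape[2]):
            raise ValueError(f"point {point} outside grid region")
        return i, j, k

    def center(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    @property
    def n_protein(self) -> int:
        return int(self.protein.sum())


@dataclass
class CrossLink:
    """One cross-link (pair of atom specs) or mono-link (single spec).

    ``sasd`` is the SAS distance in Angstrom, -1.0 when no solvent path of
    acceptable length exists, or None when not yet computed.  ``path`` holds
    the traced shortest path as world coordinates of the grid cells.
    """

    index: int
    file_label: str
    spec1: AtomSpec
    spec2: AtomSpec | None = None
    euclidean: float | None = None
    sasd: float | None = None
    path: np.ndarray | None = None
    accessible: bool | None = None

    @property
    def is_mono(self) -> bool:
        return self.spec2 is None


def _default_region(
    points: Sequence[np.ndarray], margin: float
) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return pts.min(axis=0) - margin, pts.max(axis=0) + margin


def build_solvent_grid(
    structure: Structure,
    spacing: float = DEFAULT_SPACING,
    solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
    region: tuple[np.ndarray, np.ndarray] | None = None,
    exclude: Callable[[Atom], bool] | None = None,
    free_spheres: Sequence[tuple[np.ndarray, float]] = (),
) -> SolventGrid:
    """Label a cubic grid over ``region`` as protein/solvent.

    A cell is PROTEIN iff its center lies within (vdw_radius + solvent_radius)
    of any retained atom.  ``exclude`` drops atoms from labeling (side-chain
    stripping); ``free_spheres`` force-carves solvent balls (endpoint bubbles).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    atoms = [a for a in structure.iter_atoms() if exclude is None or not exclude(a)]
    if region is None:
        if not atoms:
            raise ValueError("cannot infer region for an empty structure")
        coords = np.array([a.coord for a in atoms])
        pad = max(a.vdw_radius for a in atoms) + solvent_radius + spacing
        region = (coords.min(axis=0) - pad, coords.max(axis=0) + pad)
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("grid region is empty")
    shape = tuple(int(np.floor((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    grid = SolventGrid(origin=lo, spacing=spacing, shape=shape,
                       protein=np.zeros(shape, dtype=bool))
    if atoms:
        # cells within (vdw + solvent) of any atom, via one nearest-neighbor
        # query per distinct radius (atoms grouped by their blocking radius)
        from scipy.spatial import cKDTree

        axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
        centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        blocked = np.zeros(centers.shape[0], dtype=bool)
        by_radius: dict[float, list[np.ndarray]] = {}
        for a in atoms:
            by_radius.setdefault(a.vdw_radius + solvent_radius, []).append(a.coord)
        for r, coords in by_radius.items():
            tree = cKDTree(np.asarray(coords))
            d, _ = tree.query(centers, k=1, distance_upper_bound=r + 1e-12)
            blocked |= d <= r
        grid.protein = blocked.reshape(shape)
    for center, radius in free_spheres:
        _mark_ball(grid, np.asarray(center, dtype=float), radius, value=False)
    return grid


def _mark_ball(grid: SolventGrid, center: np.ndarray, radius: float, value: bool) -> None:
    """Set ``protein`` to ``value`` on all cells whose center is within radius."""
    lo_i = np.maximum(np.floor((center - radius - grid.origin) / grid.spacing), 0).astype(int)
    hi_i = np.minimum(
        np.ceil((center + radius - grid.origin) / grid.spacing).astype(int),
        np.array(grid.shape) - 1,
    )
    if np.any(hi_i < lo_i):
        return
    ax = [grid.origin[d] + grid.spacing * np.arange(lo_i[d], hi_i[d] + 1) for d in range(3)]
    dx2 = (ax[0] - center[0])[:, None, None] ** 2
    dy2 = (ax[1] - center[1])[None, :, None] ** 2
    dz2 = (ax[2] - center[2])[None, None, :] ** 2
    inside = dx2 + dy2 + dz2 <= radius * radius
    sub = grid.protein[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
    sub[inside] = value


def _propagate(
    blocked: np.ndarray,
    src: tuple[int, int, int],
    spacing: float,
    max_dist: float | None,
) -> np.ndarray:
    """Shortest solvent-path distance from ``src`` to every cell.

    Uniform-cost search over the 26-neighbor graph with center-to-center
    step weights.  A JIT-compiled heap Dijkstra is used when numba is
    available; the pure-numpy fallback is a synchronous relaxation that
    converges to the same distances (both compute the minimum over exact
    per-path weight sums, so the results are identical bit for bit).
    """
    nx, ny, nz = blocked.shape
    if _numba is not None:
        src_flat = (src[0] * ny + src[1]) * nz + src[2]
        cutoff = -1.0 if max_dist is None else max_dist + 1e-9
        dist = _dijkstra_core(
            np.ascontiguousarray(blocked.reshape(-1)), nx, ny, nz, src_flat,
            _NEIGHBOR_ARRAY, NEIGHBOR_WEIGHTS * spacing, cutoff,
        )
        return dist.reshape(blocked.shape)
    inf = np.inf
    dist = np.full(blocked.shape, inf)
    dist[src] = 0.0
    pad = np.full((nx + 2, ny + 2, nz + 2), inf)
    weights = NEIGHBOR_WEIGHTS * spacing
    cutoff = None if max_dist is None else max_dist + 1e-9
    while True:
        pad[1:-1, 1:-1, 1:-1] = dist
        best = dist.copy()
        for (dx, dy, dz), w in zip(NEIGHBOR_OFFSETS, weights):
            cand = pad[1 + dx:nx + 1 + dx, 1 + dy:ny + 1 + dy, 1 + dz:nz + 1 + dz] + w
            np.minimum(best, cand, out=best)
        best[blocked] = inf
        if cutoff is not None:
            best[best > cutoff] = inf
        best[src] = 0.0
        if np.array_equal(best, dist):
            return dist
        dist = best


def _traceback(
    dist: np.ndarray,
    src: tuple[int, int, int],
    dst: tuple[int, int, int],
    spacing: float,
) -> list[tuple[int, int, int]]:
    """Walk the distance field from dst back to src along exact predecessors."""
    path = [dst]
    cur = dst
    shape = dist.shape
    guard = dist.size
    while cur != src and guard > 0:
        guard -= 1
        d = dist[cur]
        best_nb, best_d = None, np.inf
        for (dx, dy, dz), w in zip(NEIGHBOR_OFFSETS, NEIGHBOR_WEIGHTS * spacing):
            nb = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
            if not all(0 <= nb[i] < shape[i] for i in range(3)):
                continue
            dn = dist[nb]
            if np.isfinite(dn) and abs(dn + w - d) <= 1e-9 and dn < best_d:
                best_nb, best_d = nb, dn
        if best_nb is None:  # numerically stuck; should not happen
            break
        cur = best_nb
        path.append(cur)
    path.reverse()
    return path


def _linked_side_chain_filter(
    spec_keys: set[tuple[str, int]],
    side_chain_handling: str,
) -> Callable[[Atom], bool]:
    if side_chain_handling == "none":
        return lambda a: False
    if side_chain_handling == "all":
        return lambda a: a.name not in BACKBONE_ATOMS
    # "linked": only the cross-linked residues shed their distal side chain
    return lambda a: (a.chain_id, a.res_seq) in spec_keys and a.name not in BACKBONE_ATOMS


def pair_grid(
    structure: Structure,
    spec1: AtomSpec,
    spec2: AtomSpec,
    spacing: float = DEFAULT_SPACING,
    solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
    max_dist: float | None = DEFAULT_MAX_DIST,
    backbone_mode: bool = True,
    side_chain_handling: str | None = None,
    region_margin: float | None = None,
) -> tuple[SolventGrid, tuple[int, int, int], tuple[int, int, int]]:
    """The labeled grid a SAS-distance search for this pair runs on.

    The region covers both endpoints with half the distance cutoff as
    margin; the linked residues' distal side chains are stripped per
    ``side_chain_handling`` and a solvent bubble is carved around each
    endpoint.  Returns (grid, cell of spec1, cell of spec2) with both
    endpoint cells forced SOLVENT.
    """
    a1 = resolve_spec(structure, spec1)
    a2 = resolve_spec(structure, spec2)
    handling = side_chain_handling or ("linked" if backbone_mode else "none")
    exclude = _linked_side_chain_filter(
        {(spec1.chain_id, spec1.res_seq), (spec2.chain_id, spec2.res_seq)}, handling
    )
    margin = region_margin if region_margin is not None else (
        max_dist / 2.0 if max_dist is not None else 17.0
    )
    margin = max(margin, solvent_radius + 3.0 * spacing)
    region = _default_region([a1.coord, a2.coord], margin)
    grid = build_solvent_grid(
        structure, spacing, solvent_radius, region=region, exclude=exclude,
        free_spheres=[(a1.coord, a1.vdw_radius + solvent_radius),
                      (a2.coord, a2.vdw_radius + solvent_radius)],
    )
    c1 = grid.index_of(a1.coord)
    c2 = grid.index_of(a2.coord)
    grid.protein[c1] = False
    grid.protein[c2] = False
    return grid, c1, c2


def euclidean_distance(structure: Structure, spec1: AtomSpec, spec2: AtomSpec) -> float:
    """Straight-line distance between the resolved atoms, Angstrom."""
    a1 = resolve_spec(structure, spec1)
    a2 = resolve_spec(structure, spec2)
    return float(np.linalg.norm(a1.coord - a2.coord))


def sas_distance(
    structure: Structure,
    spec1: AtomSpec,
    spec2: AtomSpec,
    spacing: float = DEFAULT_SPACING,
    solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
    max_dist: float | None = DEFAULT_MAX_DIST,
    backbone_mode: bool = True,
    side_chain_handling: str | None = None,
    region_margin: float | None = None,
    index: int = 1,
    file_label: str = "",
    with_path: bool = True,
) -> CrossLink:
    """SAS and Euclidean distance between two cross-linked atoms.

    Returns a :class:`CrossLink` with ``euclidean`` always set and ``sasd``
    either the shortest solvent-path length, or -1.0 when the second atom is
    unreachable or the path exceeds ``max_dist``.  ``side_chain_handling``
    chooses which side chains beyond CB are treated as solvent: "linked"
    (default with ``backbone_mode``, the two cross-linked residues only),
    "all", or "none".
    """
    a1 = resolve_spec(structure, spec1)
    a2 = resolve_spec(structure, spec2)
    euclid = float(np.linalg.norm(a1.coord - a2.coord))
    xl = CrossLink(index=index, file_label=file_label, spec1=spec1, spec2=spec2,
                   euclidean=euclid)

    # a grid path between cell centers can undercut the atom-atom line by at
    # most sqrt(3)*spacing per endpoint; beyond that the cutoff is decisive
    if max_dist is not None and euclid - 2.0 * math.sqrt(3.0) * spacing > max_dist:
        xl.sasd = -1.0
        return xl

    grid, c1, c2 = pair_grid(
        structure, spec1, spec2, spacing=spacing, solvent_radius=solvent_radius,
        max_dist=max_dist, backbone_mode=backbone_mode,
        side_chain_handling=side_chain_handling, region_margin=region_margin,
    )
    # canonical source: propagation from the lexicographically smaller cell,
    # so that sas_distance(a, b) == sas_distance(b, a) bit-for-bit
    src, dst = (c1, c2) if c1 <= c2 else (c2, c1)
    dist = _propagate(grid.protein, src, spacing, max_dist)
    d = dist[dst]
    if not np.isfinite(d) or (max_dist is not None and d > max_dist + 1e-9):
        xl.sasd = -1.0
        return xl
    xl.sasd = float(d)
    if with_path:
        cells = _traceback(dist, src, dst, spacing)
        if c1 != src:
            cells = cells[::-1]
        xl.path = np.array([grid.center(c) for c in cells])
    return xl


def mono_link_accessible(
    structure: Structure,
    spec: AtomSpec,
    spacing: float = DEFAULT_SPACING,
    solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
    backbone_mode: bool = True,
    region_margin: float = 12.0,
) -> bool:
    """True iff the mono-link site is solvent-exposed.

    The endpoint's solvent bubble must connect through solvent cells
    (26-connectivity) to the boundary of a grid placed ``region_margin``
    around the site; a site buried inside the protein or walled into an
    interface has no such connection.
    """
    atom = resolve_spec(structure, spec)
    handling = "linked" if backbone_mode else "none"
    exclude = _linked_side_chain_filter({(spec.chain_id, spec.res_seq)}, handling)
    region = _default_region([atom.coord], region_margin)
    grid = build_solvent_grid(
        structure, spacing, solvent_radius, region=region, exclude=exclude,
        free_spheres=[(atom.coord, atom.vdw_radius + solvent_radius)],
    )
    src = grid.index_of(atom.coord)
    grid.protein[src] = False
    labels, _ = ndimage.label(~grid.protein, structure=np.ones((3, 3, 3), dtype=int))
    lab = labels[src]
    if lab == 0:
        return False
    on_boundary = (
        np.any(labels[0, :, :] == lab) or np.any(labels[-1, :, :] == lab)
        or np.any(labels[:, 0, :] == lab) or np.any(labels[:, -1, :] == lab)
        or np.any(labels[:, :, 0] == lab) or np.any(labels[:, :, -1] == lab)
    )
    return bool(on_boundary)


# ---------------------------------------------------------------------------
# Distance file format (tab-delimited)
#
#   index \t file_label \t RES-seq-chain-atom \t RES-seq-chain-atom
#
# Mono-links carry the first three columns only.  When distances have been
# computed, the Euclidean and SAS distances are appended as two extra columns.


def parse_distance_file(text: str) -> list[CrossLink]:
    xls: list[CrossLink] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise DistanceFileError(
                f"line {lineno}: expected >= 3 tab-delimited columns, got {len(cols)}"
            )
        try:
            index = int(cols[0])
        except ValueError:
            raise DistanceFileError(f"line {lineno}: bad index {cols[0]!r}") from None
        try:
            spec1 = AtomSpec.from_string(cols[2])
        except ValueError as e:
            raise DistanceFileError(f"line {lineno}: {e}") from None
        if len(cols) == 3:
            xls.append(CrossLink(index=index, file_label=cols[1], spec1=spec1))
            continue
        try:
            spec2 = AtomSpec.from_string(cols[3])
        except ValueError as e:
            raise DistanceFileError(f"line {lineno}: {e}") from None
        xl = CrossLink(index=index, file_label=cols[1], spec1=spec1, spec2=spec2)
        if len(cols) >= 5:
            try:
                xl.euclidean = float(cols[4])
                if len(cols) >= 6:
                    xl.sasd = float(cols[5])
            except ValueError:
                raise DistanceFileError(
                    f"line {lineno}: bad distance columns {cols[4:6]!r}"
                ) from None
        xls.append(xl)
    if not xls:
        raise DistanceFileError("no cross-link rows in input")
    return xls


def write_distance_file(xls: Iterable[CrossLink]) -> str:
    lines = []
    for xl in xls:
        cols = [str(xl.index), xl.file_label, xl.spec1.to_string()]
        if xl.spec2 is not None:
            cols.append(xl.spec2.to_string())
            if xl.euclidean is not None:
                cols.append(f"{xl.euclidean:.2f}")
                if xl.sasd is not None:
                    cols.append(f"{xl.sasd:.2f}")
        lines.append("\t".join(cols))
    return "\n".join(lines) + ("\n" if lines else "")
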