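"""Independent reference implementations used only as test oracles.

Each function here deliberately re-derives a quantity along a different
route than the package (scipy graph Dijkstra, Monte-Carlo surface sampling,
naive agglomeration, exhaustive enumeration) so that agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from xlmod.sasd import NEIGHBOR_OFFSETS, NEIGHBOR_WEIGHTS


def grid_shortest_path_oracle(blocked: np.ndarray, src: tuple[int, int, int],
                              spacing: float) -> np.ndarray:
    """Shortest-path distances on the labeled grid via scipy's Dijkstra."""
    nx, ny, nz = blocked.shape
    n = blocked.size
    idx = np.arange(n).reshape(blocked.shape)
    free = ~blocked
    rows, cols, w = [], [], []
    for (dx, dy, dz), wt in zip(NEIGHBOR_OFFSETS, NEIGHBOR_WEIGHTS * spacing):
        sl_a = (slice(max(0, -dx), nx - max(0, dx)),
                slice(max(0, -dy), ny - max(0, dy)),
                slice(max(0, -dz), nz - max(0, dz)))
        sl_b = (slice(max(0, dx), nx - max(0, -dx)),
                slice(max(0, dy), ny - max(0, -dy)),
                slice(max(0, dz), nz - max(0, -dz)))
        m = free[sl_a] & free[sl_b]
        rows.append(idx[sl_a][m])
        cols.append(idx[sl_b][m])
        w.append(np.full(int(m.sum()), wt))
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    d = dijkstra(g, directed=False,
                 indices=[np.ravel_multi_index(src, blocked.shape)])[0]
    return d.reshape(blocked.shape)


def mc_sasa_total(structure, probe_radius: float, n_points: int, seed: int) -> float:
    """Monte-Carlo estimate of total SASA with random sphere points."""
    rng = np.random.default_rng(seed)
    atoms = list(structure.iter_atoms())
    centers = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    total = 0.0
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = rng.standard_normal((n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = c + r * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            exposed &= ((pts - centers[j]) ** 2).sum(axis=1) > radii[j] ** 2
        total += 4.0 * np.pi * r * r * exposed.mean()
    return total


def naive_complete_linkage_labels(matrix: np.ndarray, height: float) -> list[set[int]]:
    """Textbook agglomerative complete linkage, cut at ``height``.

    Returns the partition as a list of index sets: repeatedly merge the two
    clusters with the smallest maximum inter-point distance while that
    distance is <= height.
    """
    clusters: list[set[int]] = [{i} for i in range(matrix.shape[0])]
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(matrix[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, (a, b))
        if best[0] > height:
            break
        a, b = best[1]
        clusters[a] |= clusters[b]
        del clusters[b]
    return clusters


def same_partition(labels_a: dict, partition_b: list[set[int]], ids: list[str]) -> bool:
    """Whether a label map and an index partition describe the same clustering."""
    groups_a: dict[int, frozenset[str]] = {}
    for mid, cid in labels_a.items():
        groups_a.setdefault(cid, set())
        groups_a[cid] = groups_a[cid] | {mid}  # type: ignore[assignment]
    set_a = {frozenset(g) for g in groups_a.values()}
    set_b = {frozenset(ids[i] for i in grp) for grp in partition_b}
    return set_a == set_b


def exhaustive_qt_representatives(similar: np.ndarray, ids: list[str],
                                  scores: dict[str, float]) -> list[str]:
    """QT elections by brute-force neighbor counting on a similarity matrix."""
    remaining = list(range(len(ids)))
    reps = []
    while remaining:
        counts = {i: sum(1 for j in remaining if similar[i, j]) for i in remaining}
        rep = min(remaining, key=lambda i: (-counts[i], scores[ids[i]], ids[i]))
        members = [j for j in remaining if similar[rep, j]]
        reps.append(ids[rep])
        remaining = [j for j in remaining if j not in members]
    return reps
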