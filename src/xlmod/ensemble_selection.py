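"""Decoy-selection cascades over model ensembles.

Given an ensemble of candidate models (docking decoys or fold predictions),
a cross-link list and an energy score per model, the selection proceeds:

1. count satisfied cross-links / mono-links per model (Euclidean distance
   first as a cheap bound, SAS distance only where it could still satisfy);
2. keep the models satisfying the most links (capped at the 500 lowest
   scoring; score-only fallback when nothing satisfies anything);
3. optionally require a real binding interface (BSA >= 900 A^2);
4. keep the 300 models with the shortest mean SAS distance;
5. cluster by all-against-all (ligand) RMSD, complete linkage, cut at a
   fixed height (10 A for folds, 20 A for docking), or by
   quality-threshold clustering on rigid-body pose distances (< 3 A, < 8 deg);
6. elect the lowest-scoring member of the largest cluster as the best model.

Every tie anywhere is broken by ascending score and then lexicographic
model id, so the whole cascade is deterministic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .restraints import (EUCLIDEAN_SCORING_RULE, Metric, SASD_FILTER_RULE,
                         SatisfactionRule, is_satisfied)
from .sasd import CrossLink, mono_link_accessible, sas_distance
from .structure_model import (RigidPose, Structure, kabsch_superpose,
                              resolve_spec, rmsd)

__all__ = [
    "ModelRecord",
    "ClusterResult",
    "evaluate_model",
    "evaluate_ensemble",
    "select_top",
    "shortest_mean_sasd",
    "rmsd_matrix",
    "hierarchical_cut",
    "qt_cluster",
    "pick_best",
    "pick_best_comparative",
    "run_selection_cascade",
    "read_score_table",
    "write_cluster_table",
]


@dataclass
class ModelRecord:
    """Bookkeeping for one decoy: distances, counts, interface size, cluster."""

    model_id: str
    score: float
    per_xl: dict[int, CrossLink] = field(default_factory=dict)
    n_satisfied: int = 0
    mean_sasd: float = math.inf
    bsa: float | None = None
    cluster: int | None = None
    lrmsd: float | None = None
    rmsd_to_template: float | None = None


@dataclass
class ClusterResult:
    labels: dict[str, int]
    sizes: dict[int, int]
    representatives: list[str]


def _order_key(rec: ModelRecord) -> tuple[float, str]:
    return (rec.score, rec.model_id)


def evaluate_model(
    structure: Structure,
    xls: Sequence[CrossLink],
    *,
    sasd_rule: SatisfactionRule = SASD_FILTER_RULE,
    metric: Metric = Metric.SASD,
    spacing: float = 1.0,
    solvent_radius: float = 2.0,
    backbone_mode: bool = True,
    prefilter: bool = True,
) -> tuple[dict[int, CrossLink], int, float]:
    """Evaluate all cross-links on one structure.

    Returns (per-cross-link evaluations, satisfied count under ``metric``,
    mean SAS distance over reachable pairwise links).  With ``prefilter`` the
    SAS search is skipped when the Euclidean distance already exceeds the SAS
    threshold by more than the grid discretisation slack (safe because
    SASD >= Euclidean up to that slack).
    """
    per_xl: dict[int, CrossLink] = {}
    n_sat = 0
    sasd_vals: list[float] = []
    slack = 2.0 * math.sqrt(3.0) * spacing
    for xl in xls:
        if xl.is_mono:
            ev = CrossLink(index=xl.index, file_label=xl.file_label, spec1=xl.spec1)
            ev.accessible = mono_link_accessible(
                structure, xl.spec1, spacing=spacing, solvent_radius=solvent_radius,
                backbone_mode=backbone_mode,
            )
            if ev.accessible:
                n_sat += 1
        else:
            a1 = resolve_spec(structure, xl.spec1)
            a2 = resolve_spec(structure, xl.spec2)
            eu = float(np.linalg.norm(a1.coord - a2.coord))
            if prefilter and eu - slack > sasd_rule.threshold:
                ev = CrossLink(index=xl.index, file_label=xl.file_label,
                               spec1=xl.spec1, spec2=xl.spec2,
                               euclidean=eu, sasd=-1.0)
            else:
                ev = sas_distance(
                    structure, xl.spec1, xl.spec2, spacing=spacing,
                    solvent_radius=solvent_radius, max_dist=sasd_rule.threshold,
                    backbone_mode=backbone_mode, index=xl.index,
                    file_label=xl.file_label, with_path=False,
                )
            if ev.sasd is not None and ev.sasd >= 0:
                sasd_vals.append(ev.sasd)
            rule = sasd_rule if metric is Metric.SASD else EUCLIDEAN_SCORING_RULE
            if is_satisfied(ev, rule):
                n_sat += 1
        per_xl[xl.index] = ev
    mean_sasd = float(np.mean(sasd_vals)) if sasd_vals else math.inf
    return per_xl, n_sat, mean_sasd


def evaluate_ensemble(
    models: Mapping[str, Structure],
    xls: Sequence[CrossLink],
    scores: Mapping[str, float],
    **kwargs,
) -> list[ModelRecord]:
    """Evaluate every model against every cross-link (see evaluate_model)."""
    records = []
    for model_id in models:
        try:
            per_xl, n_sat, mean_sasd = evaluate_model(models[model_id], xls, **kwargs)
        except KeyError as e:
            raise KeyError(f"model {model_id!r}: {e}") from e
        records.append(
            ModelRecord(model_id=model_id, score=float(scores[model_id]),
                        per_xl=per_xl, n_satisfied=n_sat, mean_sasd=mean_sasd)
        )
    return records


def select_top(records: Sequence[ModelRecord], max_n: int = 500) -> list[ModelRecord]:
    """Models satisfying the most cross-links, capped at the lowest scoring.

    If more than ``max_n`` models share the maximal count, the ``max_n``
    lowest-scoring are kept; if no model satisfies any link at all, the
    ``max_n`` lowest-scoring overall are kept.  Output order is (score, id),
    independent of input order.
    """
    if not records:
        raise ValueError("empty ensemble")
    best = max(r.n_satisfied for r in records)
    pool = [r for r in records if r.n_satisfied == best] if best > 0 else list(records)
    pool.sort(key=_order_key)
    return pool[:max_n]


def shortest_mean_sasd(records: Sequence[ModelRecord], n: int = 300) -> list[ModelRecord]:
    """The ``n`` records with the smallest mean SAS distance (ties: score, id)."""
    return sorted(records, key=lambda r: (r.mean_sasd, r.score, r.model_id))[:n]


def rmsd_matrix(
    models: Mapping[str, Structure],
    ligand_only: bool = False,
    receptor_chains: Sequence[str] | None = None,
    ligand_chains: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """All-against-all C-alpha RMSD matrix.

    With ``ligand_only`` each pair is superposed on the receptor chains and
    measured over the ligand chains (pairwise L-RMSD); otherwise a plain
    Kabsch-fit CA RMSD over everything.  The matrix is exactly symmetric with
    a zero diagonal.
    """
    ids = list(models)
    if ligand_only and (receptor_chains is None or ligand_chains is None):
        raise ValueError("ligand_only requires receptor_chains and ligand_chains")
    rec_cas, lig_cas = [], []
    for mid in ids:
        st = models[mid]
        if ligand_only:
            rec_cas.append(st.ca_coords(receptor_chains))
            lig_cas.append(st.ca_coords(ligand_chains))
        else:
            lig_cas.append(st.ca_coords())
    if ligand_only and len({c.shape[0] for c in rec_cas}) != 1:
        raise ValueError("models have inconsistent receptor residue sets")
    if len({c.shape[0] for c in lig_cas}) != 1:
        raise ValueError("models have inconsistent residue sets")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ligand_only:
                pose, _ = kabsch_superpose(rec_cas[j], rec_cas[i])
                val = rmsd(pose.apply(lig_cas[j]), lig_cas[i])
            else:
                _, val = kabsch_superpose(lig_cas[j], lig_cas[i])
            mat[i, j] = mat[j, i] = val
    return ids, mat


def hierarchical_cut(
    matrix: np.ndarray,
    height: float,
    ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Complete-linkage clustering of a dissimilarity matrix, cut at ``height``.

    Clusters are the dendrogram components after cutting at the given height
    (10 A is the customary cut for fold ensembles, 20 A for docking
    ensembles).  Semantics match R's hclust(..., "complete") + cutree(h=...).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    n = matrix.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length does not match matrix")
    if n == 1:
        return ClusterResult(labels={ids[0]: 1}, sizes={1: 1}, representatives=[ids[0]])
    z = linkage(squareform(matrix, checks=False), method="complete")
    flat = fcluster(z, t=height, criterion="distance")
    labels = {mid: int(c) for mid, c in zip(ids, flat)}
    sizes = dict(Counter(labels.values()))
    reps = [
        min(m for m, c in labels.items() if c == cid)
        for cid, _ in sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ClusterResult(labels=labels, sizes=sizes, representatives=reps)


def qt_cluster(
    poses: Mapping[str, RigidPose],
    scores: Mapping[str, float],
    trans_thresh: float = 3.0,
    rot_thresh: float = 8.0,
    n_clusters: int = 3,
    centroid: np.ndarray | None = None,
) -> ClusterResult:
    """Quality-threshold clustering by rigid-body pose distance.

    Two ligand poses are similar iff their translational distance (measured
    at ``centroid``, default the origin) is strictly below ``trans_thresh``
    AND their relative rotation angle is strictly below ``rot_thresh``
    degrees.  The model with the most similar neighbours (ties: lower score,
    then id) is elected cluster representative, it and its members are
    removed, and the election repeats until every model is assigned.  The
    first ``n_clusters`` representatives are reported.
    """
    ids = sorted(poses)
    c = np.zeros(3) if centroid is None else np.asarray(centroid, dtype=float)
    pts = {mid: poses[mid].apply(c[None, :])[0] for mid in ids}
    n = len(ids)
    similar = np.zeros((n, n), dtype=bool)
    for i in range(n):
        similar[i, i] = True
        for j in range(i + 1, n):
            td = float(np.linalg.norm(pts[ids[i]] - pts[ids[j]]))
            ang = poses[ids[i]].angle_to(poses[ids[j]])
            ok = td < trans_thresh and ang < rot_thresh
            similar[i, j] = similar[j, i] = ok

    remaining = list(range(n))
    labels: dict[str, int] = {}
    representatives: list[str] = []
    cid = 0
    while remaining:
        cid += 1
        counts = {i: sum(similar[i, j] for j in remaining) for i in remaining}
        rep = min(remaining, key=lambda i: (-counts[i], scores[ids[i]], ids[i]))
        members = [j for j in remaining if similar[rep, j]]
        for j in members:
            labels[ids[j]] = cid
        representatives.append(ids[rep])
        remaining = [j for j in remaining if j not in members]
    sizes = dict(Counter(labels.values()))
    return ClusterResult(labels=labels, sizes=sizes,
                         representatives=representatives[:n_clusters])


def pick_best(
    cluster_result: ClusterResult, records: Sequence[ModelRecord]
) -> ModelRecord:
    """Lowest-scoring member of the largest cluster.

    Cluster-size ties go to the cluster with the lower mean score (then lower
    id).  If the clustering produced only singletons, fall back to the model
    with the smallest RMSD to the template when available, else the lowest
    score.
    """
    if not cluster_result.labels:
        raise ValueError("empty clustering")
    by_id = {r.model_id: r for r in records}
    members: dict[int, list[ModelRecord]] = {}
    for mid, cid in cluster_result.labels.items():
        members.setdefault(cid, []).append(by_id[mid])
    if max(len(m) for m in members.values()) == 1:
        pool = [by_id[mid] for mid in cluster_result.labels]
        if any(r.rmsd_to_template is not None for r in pool):
            return min(
                (r for r in pool if r.rmsd_to_template is not None),
                key=lambda r: (r.rmsd_to_template, r.score, r.model_id),
            )
        return min(pool, key=_order_key)
    best_cid = min(
        members,
        key=lambda cid: (
            -len(members[cid]),
            float(np.mean([r.score for r in members[cid]])),
            cid,
        ),
    )
    return min(members[best_cid], key=_order_key)


def pick_best_comparative(records: Sequence[ModelRecord]) -> ModelRecord:
    """Comparative-modeling election: among the models satisfying the most
    cross-links, the one with the lowest RMSD to the template structure."""
    if not records:
        raise ValueError("empty ensemble")
    best = max(r.n_satisfied for r in records)
    pool = [r for r in records if r.n_satisfied == best] if best > 0 else list(records)
    if any(r.rmsd_to_template is not None for r in pool):
        return min(
            (r for r in pool if r.rmsd_to_template is not None),
            key=lambda r: (r.rmsd_to_template, r.score, r.model_id),
        )
    return min(pool, key=_order_key)


def run_selection_cascade(
    models: Mapping[str, Structure],
    xls: Sequence[CrossLink],
    scores: Mapping[str, float],
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    max_models: int = 500,
    mean_n: int = 300,
    bsa_threshold: float | None = 900.0,
    cut_height: float = 20.0,
    spacing: float = 2.0,
    solvent_radius: float = 2.0,
    backbone_mode: bool = True,
) -> tuple[ModelRecord, list[ModelRecord], ClusterResult]:
    """The full docking decoy-selection cascade.

    evaluate -> keep max-satisfying (<= ``max_models`` lowest scoring) ->
    optional BSA >= threshold filter -> ``mean_n`` shortest mean SAS
    distance -> all-against-all L-RMSD, complete linkage, cut at
    ``cut_height`` -> lowest-scoring member of the largest cluster.

    Returns (best record, surviving records in cascade order, clustering).
    Deterministic for fixed inputs.
    """
    from .surface import bsa_filter, buried_surface_area

    records = evaluate_ensemble(
        models, xls, scores, spacing=spacing, solvent_radius=solvent_radius,
        backbone_mode=backbone_mode,
    )
    kept = select_top(records, max_n=max_models)
    if bsa_threshold is not None:
        for rec in kept:
            if rec.bsa is None:
                rec.bsa = buried_surface_area(
                    models[rec.model_id], receptor_chains, ligand_chains
                )
        filtered = bsa_filter(kept, threshold=bsa_threshold)
        if filtered:  # an empty interface filter would leave nothing to cluster
            kept = filtered
    kept = shortest_mean_sasd(kept, n=mean_n)
    ids, mat = rmsd_matrix(
        {r.model_id: models[r.model_id] for r in kept},
        ligand_only=True, receptor_chains=receptor_chains,
        ligand_chains=ligand_chains,
    )
    clusters = hierarchical_cut(mat, cut_height, ids=ids)
    for rec in kept:
        rec.cluster = clusters.labels[rec.model_id]
    best = pick_best(clusters, kept)
    return best, kept, clusters


# ---------------------------------------------------------------------------
# Tables


def read_score_table(text: str) -> dict[str, float]:
    """Read model scores from delimited text.

    Accepts either a simple two-column (model_id, score) table, or a
    ROSETTA-score-file-style whitespace table whose header names a ``score``
    and a ``description`` column.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty score table")
    header = lines[0].split()
    lowered = [h.lower() for h in header]
    if "score" in lowered and "description" in lowered:
        i_score = lowered.index("score")
        i_desc = lowered.index("description")
        out = {}
        for ln in lines[1:]:
            cols = ln.split()
            if len(cols) <= max(i_score, i_desc):
                continue
            out[cols[i_desc]] = float(cols[i_score])
        if not out:
            raise ValueError("no data rows in score table")
        return out
    out = {}
    for lineno, ln in enumerate(lines, start=1):
        cols = ln.replace(",", "\t").split()
        if len(cols) < 2:
            raise ValueError(f"score table line {lineno}: need model_id and score")
        try:
            out[cols[0]] = float(cols[1])
        except ValueError:
            if lineno == 1:  # a non-numeric first row is a header
                continue
            raise ValueError(
                f"score table line {lineno}: bad score {cols[1]!r}") from None
    if not out:
        raise ValueError("no data rows in score table")
    return out


def write_cluster_table(result: ClusterResult) -> str:
    """Cluster assignments as 'model_id<TAB>cluster' lines."""
    return "\n".join(f"{mid}\t{cid}" for mid, cid in sorted(result.labels.items())) + "\n"
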