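# Methods

## Background

Chemical cross-linking mass spectrometry (XL-MS) with amine-reactive
reagents such as DSS or BS3 identifies pairs of lysine residues that lie
close enough in space for the ~11.4 A spacer to bridge them.  Each
identified pair is a low-resolution distance restraint; mono-links (only
one reactive end attached) additionally imply that the modified site is
solvent exposed.  This package implements the computational machinery that
turns such restraints into model selection: surface-aware distance
measurement, restraint scoring, decoy filtering and clustering, and a
benchmark that quantifies how much a given number of cross-links improves
docking selection.

## The SAS distance

The straight-line (Euclidean) distance between two linked CB atoms
understates what a cross-linker must span whenever the line cuts through
the protein body.  The solvent-accessible-surface (SAS) distance is instead
the length of the shortest path between the two atoms that runs only
through solvent.

Space is discretised on a cubic grid (default spacing 1.0 A).  A cell is
labelled PROTEIN when its center lies within `vdw_radius + solvent_radius`
of any retained atom, with `solvent_radius` = 2.0 A by default; everything
else is SOLVENT.  Distances propagate from the start cell with 26-neighbor
steps weighted by the true center-to-center length
(`spacing x {1, sqrt2, sqrt3}`), i.e. uniform-cost search on the grid
graph.  The implementation is a JIT-compiled binary-heap Dijkstra (numba)
with a pure-numpy synchronous-relaxation fallback; both return bit-identical
distances because each computes the minimum over the same exact per-path
weight sums.  Pairs whose shortest path exceeds the cutoff (default 34.0 A,
the DSS/BS3 "distance ruler") or that are walled off report the sentinel
-1.0, so counting filters never crash.

Two details make searches from buried endpoints well defined:

* **Side-chain stripping.** With `backbone_mode` on (the default), atoms
  beyond CB of the two cross-linked residues are treated as solvent when
  labelling the grid, emulating side-chain flexibility.  A stricter variant
  (`side_chain_handling="all"`) strips all side chains; `"none"` strips
  nothing.  The stripping set for the flexible side chains is
  `{N, CA, C, O, CB, OXT}`-complement per linked residue.
* **Endpoint bubbles.** A CB atom sits inside its own residue's
  solvent-excluded shell, so a solvent bubble of radius
  `vdw + solvent_radius` is carved around each endpoint - exactly the
  footprint the flexible linked side chain itself would otherwise block.
  A genuinely buried site (e.g. enclosed in a cavity) stays disconnected
  and correctly reports -1 / inaccessible.

The search region covers both endpoints with `max_dist / 2` margin per
side.  Propagation prunes tentative distances beyond the cutoff, which
bounds work; searches are symmetric bit-for-bit because propagation always
starts from the lexicographically smaller endpoint cell.  The 26-neighbor
chamfer metric overestimates free-space straight lines by at most ~12.8 %
(worst direction), plus up to `sqrt(3)/2 x spacing` snapping error per
endpoint; axis-aligned paths are exact.

Mono-link accessibility uses the same grid: a site is accessible iff its
solvent bubble connects through 26-connected solvent cells to the boundary
of a box 12 A around the site.

## Surface areas

SASA is Shrake-Rupley with a deterministic golden-spiral point set
(default 960 points per atom, probe 1.4 A), so results are bit-reproducible
and converge within 1 % against a 4x denser point set on the test fixtures.
Van der Waals radii are a fixed element table (C 1.70, N 1.55, O 1.52,
S 1.80 A ...), overridable per call.  The buried surface area of a
two-part complex is the plain difference

    BSA = SASA(A) + SASA(B) - SASA(AB)

with component coordinates unchanged, and the docking cascade keeps only
models with BSA >= 900 A^2 (a standard minimum for a real biological
interface).  Note the grid solvent radius (2.0 A) and the SASA probe
radius (1.4 A) are deliberately independent parameters.

## Restraints and satisfaction

The flat-harmonic penalty is zero on `[x0 - tol, x0 + tol]` and
`((|d - x0| - tol) / sigma)^2` outside.  DSS defaults `x0 = 15.0`,
`tol = 15.0`, `sigma = 1.0` A mean models are penalised only beyond a
30.0 A Euclidean CB-CB distance.  Constraint files are emitted in ROSETTA's
AtomPair format with the field order `FLAT_HARMONIC x0 sigma tolerance`.

Satisfaction is rule-based because two thresholds coexist: 30.0 A on the
Euclidean distance during scoring, and 34.0 A on the SAS distance for
filtering and virtual cross-links (the distance ~80 % of published DSS/BS3
links exhibit).  Both thresholds are inclusive; a SAS distance of -1 is
never satisfied; mono-links are satisfied iff accessible.

## Selection cascades

Ensemble evaluation computes the Euclidean distance for every cross-link
and runs the SAS search only where the Euclidean distance could still
satisfy (SASD >= Euclidean up to the discretisation slack
`2 sqrt(3) x spacing`, so the pre-filter provably never changes a count).
The cascade then:

1. keeps the models satisfying the most links, capped at the 500 lowest
   scoring (score-only fallback when nothing satisfies anything);
2. optionally drops models with BSA < 900 A^2;
3. keeps the 300 models with the shortest mean SAS distance (mean over
   pairwise links with a finite SAS distance; mono-links carry no
   distance);
4. clusters by all-against-all ligand RMSD (receptor-fit, ligand-measured
   CA RMSD), complete linkage, dendrogram cut at a fixed height - 10 A for
   fold ensembles, 20 A for docking ensembles.  The scipy
   linkage/fcluster pair reproduces R's `hclust(..., "complete")` +
   `cutree(h=...)` semantics, and the tests verify membership against a
   naive agglomerative reference;
5. elects the lowest-scoring member of the largest cluster (cluster-size
   ties to the lower mean score; singleton-only clusterings fall back to
   the smallest RMSD-to-template when available).

Quality-threshold (QT) clustering is the alternative for seeding local
refinement: two ligand poses are similar iff their translational distance
is strictly below 3 A and their relative rotation angle
(`arccos((tr(Ri^T Rj) - 1)/2)`) strictly below 8 deg; the member with the
most similar neighbours is elected representative (ties: lower score, then
id), its cluster removed, and the election repeated.

All ties everywhere break by ascending score then lexicographic model id,
making every cascade deterministic for fixed inputs.

## Virtual cross-links and the benchmark

A virtual cross-link is an inter-chain lysine pair on a bound complex with
SAS distance <= 34.0 A.  Sampling k of them simulates an XL-MS experiment:
each draw picks one of five distance bins (0-10, 10-15, 15-20, 20-25,
25-34 A) with empirical probabilities 9/18/34/22/16 % - as printed these
sum to 99 %, so they are renormalised to unit mass - then a uniform
unchosen link within the bin.  Draws are without replacement with
renormalisation over bins that still contain unchosen links.  Bin
membership is half-open `[lo, hi)` with the last bin closed at 34.0.

For each selection, the decoy satisfying all k links with the shortest
mean link distance is elected (ties: score, then id; if no decoy satisfies
all links, the shortest mean over the whole ensemble is used) and judged
by its ligand RMSD against the reference.  k = 0 is the blind baseline:
selection by energy score alone.  Both the SAS and the Euclidean metric
are scored on the same selections so the metrics can be compared directly.

## Synthetic fixtures and what they do / do not show

All tests run on generated structures with exact ground truth:

* **helix** - ideal poly-lysine alpha-helical trace (2.3 A radius, 1.5 A
  rise, 100 deg/residue; consecutive CA-CA ~3.8 A) with CB/NZ pseudo-side
  chains;
* **slab** - a close-packed block of single-carbon residues, solid to the
  grid search, with lysines planted at chosen surface positions;
* **hollow shell** - a sealed sphere enclosing a probe lysine (buried-site
  ground truth);
* **two-slab complex** - receptor and ligand slabs facing across a gap,
  with facing lysines; the virtual cross-link count (3 x 3 = 9 by default)
  follows from the construction;
* **decoy ensembles** - rigid-body perturbations of the ligand (uniform
  random axis/angle up to 180 deg, direction/magnitude up to 40 A), with
  poses closer than carbon-carbon van der Waals contact (3.4 A) to the
  receptor resampled, the way docking samplers reject interpenetration.
  The generator records each decoy's exact ligand CA RMSD and a pseudo
  energy score = L-RMSD + Gaussian noise.  In the benchmark experiments
  the noise amplitude (200 A-equivalents) deliberately swamps the signal:
  low-resolution docking energies rank nativeness poorly on difficult
  targets, so the blind baseline behaves like a near-random pick.
* **wrapping ensemble** - a small ligand docked on a thin, wide receptor
  plate, mixed with "backside" decoys parked under the plate.  Their
  cross-link straight lines tunnel through the plate and are about as
  short as the native ones, but the solvent paths must wrap around the
  whole plate and exceed the ruler - the construction that separates the
  SAS from the Euclidean metric.

The benchmark experiment pools 12 such ensembles (each with its own
slightly varied complex: gap 10/12/14 A, lysine sites jittered +-1.5 A,
its own decoys and selections, 20 replicates per k), mirroring how the
original experiment pooled many distinct complexes; per-k medians are then
estimated from 240 selections.  Grid spacing 2.0 A is used in ensemble
evaluation - at the 34 A scale the coarser grid changes distances by well
under the satisfaction tolerance and keeps the full benchmark within a few
CPU-minutes.

These fixtures reproduce the geometric phenomena the algorithms consume -
occupancy, exposure, surface detours, rigid-body pose error - but not real
protein shape, packing heterogeneity, conformational change on binding, or
experimental noise in link identification.  Passing tests therefore
validate the machinery and its selection logic, not prediction accuracy on
real complexes.

The synthetic cross-link table emulates only the published summary
composition of the curated compilation (506 intra / 62 inter links, 14
publications, ~80 % of SAS distances within 34 A distributed by the stated
bin probabilities); its individual rows are random and carry no
experimental content.

## Numerical choices and edge cases

* Grid spacing default 1.0 A (2.0 A in the desk-scale ensemble runs);
  refining the spacing changes fixture distances by less than one step
  length.
* The Euclidean short-circuit inside the SAS search fires only when
  `euclid - 2 sqrt(3) x spacing > max_dist`, so it can never flip a
  result near the cutoff.
* Unreachable or beyond-cutoff pairs return -1.0, never raise.
* Alternate locations keep the highest occupancy (ties: first
  encountered); hydrogens, waters and (by default) HETATM records are
  dropped; only the first model of multi-model files is read.
* Kabsch superposition requires >= 3 non-collinear points and raises on
  degenerate input; ligand RMSD never refits on the ligand.
* Empty BSA-filter results fall back to the unfiltered set inside the
  cascade (a selection must always return a model); the standalone filter
  happily returns an empty list.
* The published bin probabilities are accepted within print-rounding (2 %)
  of unit mass and stored renormalised.

## Known limitations

* The SAS distance is a grid approximation; distances carry O(spacing)
  discretisation error and the chamfer-metric overestimate above.
* The endpoint solvent bubble can tunnel a path through a wall thinner
  than ~2 x (vdw + solvent_radius) adjacent to an endpoint.
* BSA on point-set SASA inherits point-set noise (~1 % of the areas
  involved).
* `mono_link_accessible` tests connectivity to a finite box boundary; a
  site at the end of a solvent channel longer than the box margin would be
  called buried.
* The cross-link table reader is schema-tolerant by header matching, not a
  validator; exotic spreadsheet layouts may need renamed columns.
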