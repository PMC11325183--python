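# Methods

## The model

`welltree` treats a molecular trajectory as a point cloud in a reduced
conformational space and assumes that residence in energy wells produces
local density maxima in that cloud. The method itself makes no energetic
claim: it is a purely geometric construction over the projected frames.

**Superposition.** Frames are rigid-body aligned (Kabsch least squares,
via `scipy.spatial.transform.Rotation.align_vectors`) to a single
reference frame, by default frame 0 of the (possibly concatenated)
ensemble. Single-reference alignment is deterministic; aligning all
frames "to each other" admits other conventions (progressive, iterative
mean-structure), which are deliberately not offered. All selected atoms
enter the alignment with uniform weight. Coordinates are nm internally;
PDB input (Å) is converted on load.

**PCA.** The positional covariance over frames uses 1/n normalisation
(the trajectory is treated as the full sample, not a draw from a larger
population), so the projected variance along component *i* equals the
eigenvalue λᵢ exactly — tests rely on that identity. Components fix
their sign by making the largest-magnitude coordinate positive, making
output independent of the linear-algebra backend. No mass weighting (the
intended use is single-atom-type selections such as carbon-α). The
default of k = 10 retained components follows common practice for
essential-dynamics clustering; k is always explicit in the API.

**Adaptive tree.** DBSCAN (L2 norm) runs at ε_L = ε_init + L·Δε for
L = 0, 1, 2, …. A point is core when at least `minpts` points (itself
included) lie within ε — the self-inclusive convention matches reading
the density bar `minpts / V_d(ε)` as "conformations expected within the
sphere" and the dominant DBSCAN implementations. Clusters are maximal
density-connected sets of core points plus border points. Two
determinism rules are imposed where textbook DBSCAN is ambiguous:

* clusters are numbered in order of their lowest-index core point;
* a border point reachable from several clusters joins the cluster of its
  lowest-index core neighbor.

The sweep stops when a single cluster holds every frame (the root) or at
`max_levels` (default 10 000), in which case the result is a forest
explicitly flagged incomplete — never silently truncated. Each cluster
becomes a tree node; a cluster identical to its predecessor extends that
node's [ε_first, ε_last] interval instead of creating a new one. Parent
links use majority overlap with ties broken toward the candidate
containing the lowest frame index; because clusters nest monotonically in
ε under the rules above (core status is monotone in ε, and clustered
points never regress to noise), the majority rule is exact subset nesting
in practice, and `validate_tree` verifies exactly that (containment
fraction 1.0) besides single-rootedness and sibling disjointness.

No spatial index is required for correctness; the production path uses a
k-d tree for neighborhoods and is verified bit-identically against a
brute-force distance-matrix implementation (`welltree.reference`) and
against scikit-learn's DBSCAN on core-point partitions.

**ε-schedule choice.** ε_init, Δε and minpts are data-scale parameters
with no universal default. The package ships the four published
schedules for ABC-transporter ensembles as presets
(`SCHEDULE_PRESETS`); for new data the intended procedure is the manual
one: inspect a 2-D PCA to estimate point spacing, pick ε_init by
bisection until the first level shows the expected cluster count, and
shrink Δε if the tree is too shallow. This loop is documented, not
automated.

**Annotation.** For a categorical label, a node's intensity for value v
is `I = log10(count_v in node) / log10(total_v)`, clamped to [0, 1]:
normalisation is per label value ("all conformations of the specific
type"), so the root always renders at full intensity for every value.
Nodes with fewer than `min_display` (default 5) conformations of a value
render white for it; the full-count limit (count = total) takes
precedence over the floor so that tiny but complete label populations are
still visible. Overlaps mix additively over a configurable palette whose
first three entries are cyan/magenta/yellow. Numeric covariates are
discretised at empirical terciles by default (constant covariates raise a
degenerate-breaks error) and then treated as categorical.

**Representatives and RMSD.** A node's representative is its member frame
of latest simulation time (ties: lowest frame index) — the rationale
being that late frames are the most relaxed visit to the well.
Representative comparison defaults to superposed RMSD; the
non-superposed variant is available because either convention is
defensible and published numbers do not always state which was used.

## The synthetic landscape

The generator emulates exactly one feature of MD data: *density wells
with a known hierarchy*. Wells are isotropic Gaussian mixture components
(`WellSpec`); DBSCAN density modes then map one-to-one onto mixture
modes, and the merge hierarchy is computable in closed form
(`expected_merge_order`: single linkage on center gaps discounted by
width sums, a proxy for barrier height that is only meaningful for
clearly separated wells). Two samplers are provided: ancestral sampling,
and a Metropolis walk on U = −log p (burn-in default 10 % of steps,
proposal σ = half the smallest width, start at the heaviest well's
center) which adds MD-like serial correlation and rare barrier
crossings.

What the generator does **not** emulate: anisotropic and curved wells,
heavy non-Gaussian tails, slow drift, solvent/periodicity artifacts, and
correlated noise across atoms. Passing tests therefore demonstrate the
algorithmic correctness of the pipeline on well-structured data, not
robustness to every pathology of real trajectories.

For end-to-end tests the low-dimensional well samples are embedded as
displacements of a random base structure along orthonormal directions
chosen **orthogonal to the base's six rigid-body modes**
(`embed_in_ensemble`), so Kabsch superposition is the identity to first
order and the well topology survives the superpose → PCA → tree pipeline
by construction rather than by accident.

## Fixture conditions and problem sizes

Test and acceptance fixtures use 2–5 wells of unit width with ≥ 8-width
separations, 200–250 points per well, and consecutive separation
increments of 4 widths. The increment matters: the ε at which two
*sampled* wells become density-connected is set by the extreme points in
the gap and fluctuates on the scale of one width, so gap differences of
only 1–2 widths are not statistically resolvable merge orders —
4-width increments are. The fixture schedule (ε_init = 2 × width,
Δε = width/4, minpts = 4) follows the manual tuning rule above: a radius
of twice the width spans a well's core, so each well forms exactly one
level-0 cluster. DBSCAN verification uses ≥ 100 random instances with
n ≤ 300 and 1–10 dimensions, where the O(n²) brute-force reference is
exact and cheap. These sizes keep the full suite and the acceptance
script in the tens of seconds on one CPU while leaving all measured
quantities at their asymptotic values (purity 1.0, containment 1.0).

## Numerical choices and degenerate inputs

* Hypersphere volumes are computed in log space (`gammaln`) to stay
  finite at high dimension.
* Distance comparisons use `<= ε` exactly; no tolerance is added, so
  points at distance exactly ε are neighbors, and tests use data where
  this boundary is unambiguous.
* Superposition of fewer than 3 non-collinear atoms raises a degenerate
  error in the trajectory path; plain RMSD with superposition still
  accepts such input because the *minimised value* is well defined even
  when the rotation is not unique.
* `n = minpts` identical points yield a root at level 0; empty inputs
  yield empty levels; a constant ensemble makes the explained-variance
  ratio undefined and raises.
* All samplers and the whole pipeline are deterministic for a fixed seed;
  pipeline outputs are byte-identical across runs, and the manifest
  records versions, parameters, seed and input checksums (no
  timestamps, deliberately).

## Known limitations

* DBSCAN degrades in very high dimensions (distance concentration); the
  package follows the standard practice of clustering in a ≤ 10-D PCA
  subspace and makes no claim beyond it.
* Border-point determinism rules are this package's own; other
  implementations may place individual border points differently, which
  can move a handful of frames between sibling branches without changing
  the tree's structure.
* The merge-order oracle uses center separation as a barrier proxy; for
  overlapping or strongly unequal-width wells the notion of a single
  merge order is itself ill-defined, and no guarantee is offered there.
* `expected_merge_order` and `well_recovery` are evaluation tools for
  synthetic data; they have no meaning for real trajectories, where the
  ground-truth well structure is unknown.
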