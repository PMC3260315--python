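# Methods

`assemblage` determines the architecture of a macromolecular assembly by
integrating heterogeneous information: every piece of data becomes a
scoring term (a *restraint*), candidate structures are searched for
configurations that satisfy all terms at once, and the resulting ensemble
is clustered and audited.  This note records the model, the numerical
choices, and what the synthetic test bed does and does not show.

## Representation

A candidate structure is a collection of particles — spheres with
coordinates (Å), radius (Å), mass (Da), a subunit label, an optional
1-based residue range, and an open string→number attribute map for
anything else.  Protein chains are coarse-grained into beads by
`coarse_grain_chain`: residues are split into contiguous blocks whose
sizes differ by at most one (earlier blocks larger, so the partition is
deterministic), each block becomes a bead of mass `n_res · m_res`
(default residue mass 110 Da) and radius `(3 V_res n_res / 4π)^(1/3)`
with `V_res = 130 Å³`, a typical amino-acid partial volume.  Total mass
and total volume are therefore conserved exactly.  Groups of particles
can be declared rigid bodies; rigid motions rotate about the body
centroid (unit quaternions, scalar-first) and then translate, preserving
internal geometry to machine precision.  One resolution per particle
set: simultaneous multi-resolution bookkeeping is an extension point,
not implemented.

## Scoring

A scoring function is a weighted sum of restraints; each raw term score
is nonnegative and zero exactly when the term is satisfied.  Each term
also carries a threshold: a model is **good-scoring** when every *raw*
term score is at or below its threshold.  Thresholds deliberately apply
to raw scores so that pruning and satisfaction reports are independent
of the weights used to steer optimisation.

* **Harmonic distance** `0.5·k·(d−d0)²`, with one-sided upper/lower
  variants that are zero inside the bound.  The `0.5·k·x²` convention
  makes the gradient `k·x`.
* **Excluded volume** `0.5·k·Σ max(0, r_i+r_j−d_ij)²` over unordered
  pairs, skipping pairs inside one rigid body (their overlap is fixed
  and carries no information).
* **Connectivity** builds the complete graph on a particle set with edge
  weights `g_ij = max(0, d_ij − r_i − r_j − slack)` and scores
  `0.5·k·Σ g²` over a minimum spanning tree — zero for any mutually
  touching cluster.  A constant is added to all edges before the sparse
  MST call so zero-gap edges are not dropped; adding a constant leaves
  the minimal tree unchanged.  The gradient holds the tree fixed (a
  subgradient; the edge set changes only at ties).
* **EM fit** is a forward model: each particle is rasterised as an
  isotropic Gaussian with σ = resolution / (2√(2 ln 2)) (resolution read
  as FWHM), integral equal to its mass, truncated at 4σ (mass loss
  < 0.01%); the simulated map is compared with the experimental one by
  the mean-centred Pearson correlation over all voxels (no masking), and
  the raw score is 1 − CCC ∈ [0, 2].  A model entirely off the map
  scores 1 (correlation treated as zero).  During sampling, out-of-grid
  particles are clipped rather than rejected; the strict variant that
  raises is used when building maps.

Gradients of the pairwise and MST terms are analytic.  The EM term's
gradient is also analytic: d(sim)/dx for one particle is its own
Gaussian block times `(voxel − centre)/σ²`, and the mean-removal term of
the correlation vanishes because the correlation weights sum to zero.
This is the exact derivative of the implemented forward model (no grid
interpolation is involved), verified against central finite differences
to 1e-7 relative; the generic finite-difference fallback (step 0.1·voxel
for grid terms) remains in the base class.  The EM restraint caches
per-particle rasterisation blocks keyed by coordinates, so re-scoring
after a single-body move only re-rasterises that body.

## Sampling

* **Metropolis Monte Carlo** with symmetric proposals only (no Hastings
  correction needed): single-particle ball displacements (uniform in a
  sphere), rigid-body moves (uniform random axis, angle uniform in
  [0, max], about the centroid, plus a ball translation), and a swap
  move that exchanges two bodies' centroid positions — its own inverse,
  hence symmetric — letting the sampler tunnel between assignments of
  subunits to density lobes.  Temperature follows a geometric schedule
  `T_i = T_start·(T_end/T_start)^(i/(n−1))`.  One seeded generator per
  run; identical seeds give bit-identical trajectories.
* **Conjugate gradients** (scipy, strong-Wolfe line search, termination
  on gradient max-norm) over free-particle coordinates.  Models with
  rigid bodies are rejected: constrained continuous optimisation is the
  job of the rigid-body refiner below, and global search the job of
  Monte Carlo.
* **Rigid-body refinement** (`refine_rigid_bodies`): per-body net force
  and torque assembled from per-particle gradients, applied with an
  adaptive step (largest particle displacement ≈ step size; grow 1.3× on
  success, halve on failure).  A local polish, not a global search.
* **The pipeline protocol** for each independent run: scatter the bodies
  randomly (uniform orientations; centroids uniform in a sphere centred
  on the map), anneal, quench at low temperature with quarter-size
  moves, gradient-polish, and optionally *rectify*: enumerate all body
  permutations crossed with end-over-end flips of multi-bead bodies
  (the slow, discrete degrees of freedom annealing gets stuck in),
  re-seat the best few variants with a short quench plus polish, and
  keep the result only if it beats the incoming state.  Rectification is
  a config switch (`sampling.rectify`) because it is a convergence
  accelerator: when the aim is to *sample* the whole good-scoring set —
  as in round 1 of the two-round experiment, where the ambiguity is the
  result — greedy cross-basin moves would bias every run toward one
  optimum and hide the degeneracy.
* **DOMINO-style discrete enumeration**: per-component candidate state
  lists plus the graph of components sharing a restraint.  Components
  merge along a maximum-weight spanning forest (edge weight = number of
  shared terms), heaviest edges first; at each merge any partial
  assignment violating a term fully contained in the merged subset is
  pruned.  Pruning is admissible — scores are nonnegative and the
  good-scoring test is per-term — so the result equals brute-force
  enumeration exactly (property-tested on hundreds of random instances).
  A per-subset cap (default 10⁵ partial states) aborts rather than
  truncating silently, since truncation would break the exactness
  contract.  Terms spanning more than two components are checked once
  all covered components are merged.  An empty result is a valid outcome
  and the platform's signature for inconsistent data.

## Analysis

Superposition uses the SVD-based least-squares rotation (proper rotation
enforced); inputs whose centred covariance has rank < 2 (collinear
points) get a flagged translation-only fit.  The placement score of a
subunit is the pair (centroid displacement in Å, rotation angle of the
least-squares superposition in degrees, `2·arccos|q_w|` ∈ [0, 180]) — an
interpretation of the usual placement metric, recorded as such.  Before
any clustering, all configurations are superposed onto the best-scoring
member using all particles, removing the global-pose degeneracy that
map-free scoring terms cannot fix.  Clustering is either seeded k-means
(10 restarts, best inertia) on flattened coordinates or greedy RMSD
binning: members are visited in ascending score order and join the first
cluster whose representative is within the cutoff, else found a new one;
visiting in score order makes each cluster's founder its lowest-scoring
member, so representatives are well-defined and every member is within
the cutoff of its representative.  RMSD is over matched particle ids, no
symmetry correction.  The localization density of a subunit is the plain
voxelwise mean of its forward-modelled map over ensemble members; each
member's map integrates to the subunit mass (up to the 4σ truncation),
so the mean does too, and a single-member ensemble reproduces that
member's map exactly — no renormalisation is applied, keeping the mean
exact.  The satisfaction report evaluates every raw term score on every
member; the ensemble is flagged inconsistent when no member satisfies
all terms.

## Synthetic test bed

`generate_assembly` builds a connected, non-overlapping toy assembly:
4 subunits of 1–3 collinear touching beads, radii 8–14 Å, placed by
sequential random attachment (each new subunit rotated randomly and set
touching an already-placed one, rejection-sampled against overlaps
> 0.1 Å; up to 10⁴ attempts before a diagnostic error).  Within a
multi-bead subunit the radii are spread evenly across the range in
random order rather than drawn independently: near-symmetric rods make a
subunit's end-over-end flip almost density-degenerate at 20 Å, which
would leave "the data determine a single structure" demonstrations
ill-posed for any sampler; heterogeneous rods keep orientation
identifiable while staying inside the stated size range.

`simulate_crosslinks` emulates proximity data: true links from
inter-subunit bead pairs with surface gap within a cutoff, false
positives from beyond-cutoff pairs at a stated rate, each record's
centre-distance bound = cutoff + both radii, annotated with the bead
pair it was drawn for.  With no noise and no requested count it emits
each distinct true pair exactly once; sampled draws are with replacement
(a toy assembly has far fewer distinct contact pairs than a realistic
record count).  `pairwise_crosslinks` is the idealized exhaustive
experiment: one true upper bound (distance + 2 Å) for *every*
inter-subunit bead pair.  The fixture bundle (`write_fixture_bundle`,
`assemblage simulate`) packages ground truth PDB, a simulated 20 Å map
on a 48³ grid (box padding σ + max radius — tight, so the voxel Pearson
is not diluted by empty background), the pairwise cross-link CSV, and
ready-to-run configs for the two-round experiment.

### The two-round experiment

The demonstration runs on one designed reference assembly (the
generator's seed-1 instance: connected, all four subunit sizes
distinct), re-sampled stochastically — one system, many independent
runs, exactly how a modeling study treats its target.  Each run starts
*anchor-seeded*: a mass-weighted k-means over the brightest map voxels
yields one anchor per subunit, and the run deals the subunits onto the
anchors in a random permutation with random orientations, so every run
explores a different discrete hypothesis about which subunit occupies
which density lobe.  Twelve runs of 3000 annealing steps (T 5 → 0.1)
with rigid-body, flip-capable and swap moves, then quench and gradient
polish.

Round 1 scores against the map plus excluded volume only (EM weight 100,
threshold 0.2; no rectification — the point of the round is to *sample*
the good-scoring set).  At 20 Å a four-lobe map is satisfied by many
arrangements — permutations and reorientations of subunits are nearly
density-degenerate — so the twelve runs land in many distinct binning
clusters (cutoff = smallest bead radius): the data are insufficient,
and the ensemble says so.  Round 2 adds the complete pairwise proximity
set (k = 0.2, threshold 0.01, i.e. bound violations ≲ 0.3 Å) and
demands a near-perfect map fit (EM threshold 0.003), with rectification
enabled so runs cross the permutation/flip barriers.  On the reference
fixture, runs that reach the true arrangement polish to 1 − CCC below
about 0.001 while the best discrete impostors (flipped rods, swapped
subunits) bottom out above 0.006, so the thresholds sit in a measured
score gap; the good-scoring set collapses to one cluster whose
representative sits a fraction of a bead radius from the truth
(replicated across independent sampling seeds).  Thresholds and weights
are part of this designed protocol; they encode how tightly each data
type should be honoured, exactly the per-term judgement a practitioner
makes when setting up such an analysis.

Upper-bound-only proximity data deserve a warning that generalises
beyond the toy: any configuration in which all restrained distances
*shrink* satisfies every upper bound, so such data constrain adjacency
but not chirality and not expansion-free rearrangements; the density
map supplies the missing discrimination.  Distance data alone (the
parameter-recovery setting: complete true pairwise distances + excluded
volume, two-sided harmonics) cannot distinguish enantiomers at all —
recovery runs that converge to the mirror image are expected and are
what the ≥ 5-of-10 success criterion accommodates.

### What the synthetic bed does not show

Beads are ideal spheres with exact masses; maps are noise-free and
perfectly calibrated (no scale, origin, or B-factor errors); cross-links
have exactly known bounds and, in round 2, complete coverage.  Real data
have none of these properties, so passing these tests demonstrates the
*machinery* — exact enumeration, correct gradients, calibrated
acceptance, mass-conserving forward model, faithful round trips — and
the logic of the integrative cycle, not performance on experimental
maps.  Sizes (8 beads, 48³ grids, thousands of MC steps) were chosen so
a full cycle completes in minutes on one CPU.

## Reproducibility and formats

Every stochastic entry point takes an integer seed; per-run seeds are
derived through `numpy.random.SeedSequence`.  Each pipeline run writes a
resolved-config echo (defaults filled, seed recorded) and a log with
version, seed and per-stage wall-clock next to its outputs; rerunning
the echoed config reproduces outputs byte-identically.  Bead models
travel as a PDB v3.3 subset (one HETATM "CA" per bead, residue BEA,
chain = subunit, occupancy = mass/1000, B-factor = radius, REMARK 99
lines mapping chains to long subunit labels; ensembles as MODEL/ENDMDL
blocks) so standard viewers render them; maps as MRC2014 mode 2 with
cubic voxels and the plain axis order only (anything else is rejected,
never silently permuted; ORIGIN header words take precedence over
NXSTART with a logged warning on disagreement); proximity tables as CSV
with '#' comments; configs as strictly-validated JSON or YAML (unknown
keys rejected by name; a missing seed is drawn, warned about, and
recorded in the echo).
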