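# Methods

This note documents the models and numerical choices behind
`tqcoupling`: what each stage computes, the assumptions it rests on, what
the synthetic generator does and does not emulate, and the package's own
resolutions of points the underlying procedure leaves open.

## Coordinate decomposition

A frame is decomposed relative to a reference structure and a chain
partition. For each chain `c` the Kabsch superposition of the frame's
chain onto the reference chain gives a proper rigid transform `A_{f,c}`;
the tertiary-only frame applies `A_{f,c}` (removing the chain's rigid
motion), the quaternary-only frame applies the stored inverse pose
`A_{f,c}^{-1}` to the *reference* chain (removing the internal motion).
Because the pose is stored rather than re-fitted, recombination —
applying the pose to the tertiary-only chain — reproduces the raw frame
to machine precision (measured ≤ 4e-15 nm; the package guarantees
≤ 1e-9 nm).

Orthogonality of the two subspaces is a consequence of Kabsch
optimality, not an extra projection: at the optimum the fitted chain's
displacement field `d` satisfies `Σ d_i = 0` and `Σ r_i × d_i = 0`
(with `r_i` the reference coordinates about the chain centroid), i.e. it
is *exactly* orthogonal to the chain's six rigid-body basis vectors.
The test suite asserts this to 1e-6 relative; in practice it holds to
~1e-12.

Consequently the tertiary covariance has rank ≤ `3N − 6C` exactly
(`3N − 24` for a tetramer). The quaternary subspace has `6C − 6 = 18`
degrees of freedom after the whole-molecule fit removes the 6 global
ones — **at linear order**. Finite rigid rotations are nonlinear in the
angle: a rotation by θ contributes a second-order displacement along
`K²r` of relative amplitude ~θ/2, so the Cartesian covariance of a
quaternary-only trajectory with realistic amplitudes (θ ~ 0.1 rad) shows
curvature eigenvalues at ~1e-6..1e-3 of the largest, beyond the 18
linear ones. The spectrum still identifies the linear dimensionality
through a sharp gap (measured ≥ 240× between eigenvalues 18 and 19 at
the default amplitudes). `covariance_rank` therefore takes a
configurable relative threshold: 1e-12 (the default) counts exact-zero
modes and gives exactly 18 on linear-regime trajectories
(`rank_probe_spec`, jitter ~1e-7); 1e-4 counts the linear DOF on
finite-amplitude data.

Superposition weighting is uniform over the atoms present (heavy atoms
under the default loaders); mass weighting is available through the
`weights` argument of the fitting functions but is not the default, as
the simplest reproducible choice.

## Collective modes

PCA is an SVD of the centred frame matrix; eigenvalues are variances in
nm² (`ddof = 1`), eigenvector signs are fixed so the largest-magnitude
component is positive (prevents seed-dependent flips in downstream
artifacts). The functional target for the coupling analysis is the
projection of the (globally fitted) quaternary-only trajectory onto the
first quaternary mode cQ, anchored at the reference structure. Coupling
to the full 18-dimensional quaternary space, and nonlinear or
time-lagged models, are out of scope.

PLS-FMA uses PLS1 regression (scikit-learn, no variance scaling — the
coordinates share units) of the target on the tertiary-only coordinates.
The model is constructed on the first half of the concatenated frames
and cross-validated on the second half; the component count is the
maximiser of the cross-validation correlation over 1..k_max, and the
final model is refit with that count on all frames. The coupling mode
cT is the coordinate-space gradient of the fitted linear model,
normalised and exposed as an explicit 3N-vector; it lies in the tertiary
subspace by construction (it is a combination of rows of the tertiary
data). The ensemble-weighted mode is

    cTew ∝ Σ_k c_k σ²_k v_k

with latent vectors `v_k` (PLS rotations), regression coefficients
`c_k` and data variances `σ²_k` along `v_k`. The reweighting formula is
this package's documented choice for "weight each latent vector by its
contribution to the overall variance"; it reduces to cT for a single
latent vector and for isotropic score variances, which is what the tests
pin down. cT is the *maximally correlated* direction and accumulates
estimation noise as components are added; cTew, dominated by the
high-variance components, is the stabler object and is what the
coupling-plane analysis uses.

Numerical guard: if the requested component count exceeds the effective
rank of the (deflated) data, PLS divides by vanishing norms and the
coefficient vector degenerates; the fit detects score variances below
1e-10 of the first component's and refits with the supported count,
logging the reduction.

## Coupling plane, backprojection, path

The plane is spanned by cQ and cTew and anchored at the T-state
reference (configurable). The two modes are near-orthogonal in practice
(overlap ~0.005 on synthetic data); projections simply take the two dot
products, and an overlap ≥ 0.5 is rejected as an ill-defined plane.
The grid divides the span of the projections per axis into `n` equal
intervals (default 20 → 400 cells) and uses the interval midpoints as
cell centres — "cell centres of equal parts" being this package's
reading of an equidistant division; the grid is not re-anchored to make
the T/R projections exact grid points. Backprojection is linear,
`x(a, b) = origin + a·cQ + b·cTew`; it ignores the curvature of finite
rigid rotations, consistent with treating the modes as linear
directions. Backprojected structures are therefore approximate off the
sampled region, which is precisely why they can exhibit nonzero steric
overlap: the plane is a 2-D reduction of the motion.

The L-shaped path runs from the cell containing the T-state projection
to the cell containing the R-state projection, first varying the cQ
index, then the cTew index, visiting the corner exactly once
(`|Δi| + |Δj| + 1` cells).

## Interactions

vdW overlap sums `max(0, r_i + r_j − d_ij)` over unordered inter-chain
atom pairs; intra-chain pairs are never counted. Radii come from a
bundled Bondi-style element table (nm), replaceable via a two-column
text file or a mapping argument. Summing per unordered pair once is the
default; a per-atom accounting (each atom accumulates its penetrations,
doubling the total) is available via `double_count=True` since either
bookkeeping is defensible. Neighbor search uses a k-d tree with radius
`2·max(r)` — exhaustive for this score by the triangle inequality — and
the suite verifies exact agreement with an all-pairs oracle.

Contacts are residue pairs on different chains with any heavy-atom
distance strictly below 0.3 nm (the conventional heavy-atom contact
range). Along the path, classification splits the cells into a T-end
segment, an elbow segment around the corner and an R-end segment
(defaults: end width `min(3, L//3)`, elbow = corner ± 2 clipped between
the ends; configurable because only the qualitative scheme is fixed):

* static — present at every cell;
* pulling — present in both end segments, absent throughout the elbow;
* pushing — absent at both ends, present in the elbow;
* switching — assigned per residue: non-empty but different partner sets
  at the two ends; the pairs involved are tagged;
* other — remaining patterns.

Precedence is static > pulling > pushing > switching > other, and the
scheme is invariant under path reversal (T/R relabelling).

## Transition analysis

The difference mode between two end states (R globally fitted onto T
first) is normalised and decomposed with the same per-chain machinery,
giving tertiary and quaternary components; a vanishing component (pure
rigid or pure internal difference) is reported as absent rather than as
a zero vector. A trajectory is a transition if its projection onto the
full difference vector covers ≥ 80% of the T→R distance at any frame
(each frame globally fitted to T first, so the verdict is
rigid-motion-invariant). Among transitions, trajectories whose peak
coverage exceeds the median by more than 5 MAD plus an absolute margin
of 0.05 are flagged as outliers — an explicit, configurable stand-in for
a qualitative exclusion rule; the margin keeps sets that are identical
up to noise from self-excluding when the MAD vanishes. The R-state must
be supplied as a complete assembly (no symmetry completion is
performed).

## Synthetic data

The generator builds a 4-chain (configurable) bead assembly: clipped
Gaussian blobs (σ 0.35 nm, max radius 0.7 nm, 50 beads of radius
0.15 nm each) on a ring of spacing 0.9 nm, leaving a ≥ 0.1 nm clearance
beyond the bead-diameter contact distance at the reference — the
reference is clash-free by construction. A logistic reaction coordinate
`q(t)` (width 4% of the trajectory) drives the quaternary path — each
chain translates 0.35 nm toward the centre and rotates 0.1 rad about z
(alternating sign) — and, through the coupling coefficient α = 1 nm, the
planted tertiary mode: a per-chain radial contraction field, which is
*exactly* orthogonal to the rigid subspace and retracts the interface
beads as the chains approach. Independent tertiary noise modes (5,
amplitude sd 0.3 nm), per-chain rigid jitter (0.02 rad / 0.02 nm — this
is what excites all 18 quaternary DOF) and isotropic positional noise
(σ 0.05 nm) complete the frame. With `std(q) ≈ 0.48` the
signal-to-noise ratio along the planted mode, `std(α q)/σ`, is ≈ 10.
All draws flow from one seeded generator; regeneration is bit-identical.

Because a single trajectory crosses T→R once at its midpoint — exactly
the model/validation boundary of the split-half protocol —
`generate_ensemble` concatenates independent realizations of one system
(shared geometry seed, per-segment noise seeds), emulating an ensemble
of transition simulations; with two segments each half of the
concatenation contains one full transition. The headline measurements
(cross-validated r ≈ 0.99, planted-mode recovery cosine ≈ 0.998 at 2000
frames) use this configuration.

What the generator does *not* emulate: chemical detail (no force field,
no realistic protein geometry or side chains), anharmonic or
multi-basin internal dynamics, time correlation in the noise, and any
asymmetry between chain types. Passing tests therefore demonstrate the
correctness and statistical behaviour of the *method* under its own
assumptions (linear coupling, Gaussian noise), not performance on real
MD data.

## Problem sizes and determinism

Default analysis sizes — 200 beads, 2000 frames, 20 × 20 grid, k_max 10
— keep every stage seconds-fast on one CPU; the full test suite runs in
about half a minute and `scripts/acceptance.py` in under a minute. The
pipeline's outputs are a pure function of (inputs, config, seed): reruns
are byte-identical, which the suite asserts on the CSV artifacts.

## Known limitations

* Backprojection linearises rigid motion; far off-diagonal structures
  are geometric extrapolations, useful for ranking steric strain, not
  as physical conformations.
* The grid anchors to the min/max of the *observed* projections, so grid
  coordinates are dataset-dependent; compare overlap surfaces only
  within one run.
* The vdW radii table is generic; absolute overlap values depend on the
  chosen radii and should be read comparatively.
* The component count for PLS-FMA is selected on a single split-half;
  for short or strongly autocorrelated inputs a blocked or multi-fold
  scheme would be more robust.
* Heavy-atom selection policies identify solvent and ions by residue
  name; nonstandard naming requires a custom selection.
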