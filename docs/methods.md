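# Methods

## Model and conventions

A limb is a static kinetostatic snapshot: moment-arm matrix `R` (n_muscles
x n_joints, meters), endpoint Jacobian `J` (endpoint DOFs x joints), maximal
isometric forces `F0` (newtons), at a posture `q` (radians).

* **Stretch sign.** Stretch is `s = -R dq`, positive = lengthening: a
  positive moment arm means a positive joint rotation shortens the muscle,
  the standard biomechanics convention. This convention is fixed here and
  all activity patterns follow from it.
* **Jacobian.** Rows are ordered translations first, then one dimensionless
  orientation row (all ones for a planar serial chain). Including the
  endpoint orientation makes `J` square, so it is generically invertible;
  inversion refuses Jacobians whose condition number exceeds a configurable
  bound (default 1e8) and reports the condition number.
* **Action matrix.** `A = J^-T R^T diag(F0)`; column i is the endpoint
  wrench of muscle i at activation 1.
* **Posture-dependent moment arms.** Each entry may be a polynomial in its
  own joint's angle (anchored at the neutral posture). Small-perturbation
  analyses always use the linearization `s = -R(q) J(q)^-1 dx` at the
  posture — this is what makes the planar stretch rank bound *exact* — while
  `compute_stretch(..., integrate=True)` provides the exact polynomial path
  integral for finite excursions.

## Feedback-related pipeline

Per perturbation direction: `dq = J^-1 dx`, `s = -R dq`,
`EMG = transform(s)`. The default transform is rectified linear,
`G * max(0, s)`, with one gain `G` shared by all muscles; since EMG units
are arbitrary, `G` rescales the cloud and can never change dimensionality
(tested). Exponential and sigmoidal alternatives (shifted to output 0 at
zero stretch) are provided because any monotone transform preserves the
active/silent pattern; an unrectified `linear` control transform is also
available, and is the only transform allowed to produce signed values.
The exact parameterizations of the exponential and sigmoidal variants are
exposed (`rate`; `midpoint`, `slope`), not inferred from anything.

Dimensionality uses PCA (mean-centered by default, flag to disable) on the
muscles x conditions EMG matrix; component signs are fixed by making each
component's largest-magnitude coordinate positive.

Two component-count rules coexist, and results objects report both:

* `n_components` — smallest k whose cumulative explained variance *strictly*
  exceeds the threshold ("more than 80%"; ties broken upward, threshold 0
  gives 1);
* `n_components_generalizing` — smallest k whose self-reconstruction has
  per-muscle VAF > 0.8 in every muscle. The global rule can be met while
  individual muscles remain badly reconstructed, so cross-posture
  generalization maps default to this per-muscle count (it always exists:
  the full basis reconstructs exactly).

**VAF.** `VAF_i = 1 - SS_resid / SS_total` with the *uncentered* total sum
of squares, per muscle; a basis "generalizes" when `VAF_i > 0.8` for every
muscle. Reconstruction subtracts the reference-basis mean and adds it back
(a flag switches to the test-condition mean). A never-active muscle (zero
denominator) scores 1 if its residual is also zero, else 0, with a warning.

**Generalization map.** A rectangular endpoint-space grid is mapped to test
postures through linearized inverse kinematics (`q = q0 + J^-1 dx`; grid
spacing and extent configurable). Each test posture gets its own moment
arms and Jacobian; postures with singular/ill-conditioned Jacobians are
recorded as excluded, never fatal.

## Feedforward-related pipeline

For a force target `magnitude * direction` in the planar force subspace,
with all listed extra wrench components (out-of-plane forces, torques)
pinned to exactly 0, the solution set is `{a in [0,1]^n : A_eq a = b_eq}`.

* **Scan rule.** Force levels are positive multiples of the increment that
  are feasible in *all* k directions (min over directions of the LP
  max-feasible magnitude) — the concentric circles that fit inside the
  feasible force set. An empty scan warns and returns cleanly.
* **Vertex enumeration** is exact: coefficients convert to rationals
  (binary floats convert exactly), equalities are eliminated by rational
  Gaussian reduction, and the free-coordinate box is cut one inequality at
  a time; after each cut, candidate points survive only if the gradients of
  their tight constraints span the reduced space (the basic-feasible-
  solution characterization). This handles the heavy degeneracy typical of
  activation polytopes without tolerance tuning. Output vertices are
  deduplicated (1e-8) and sorted lexicographically; an empty set means
  infeasible, distinct from the single-vertex point polytope. Cost is
  exponential in `n - rank(A_eq)`; enumeration refuses models above a
  16-muscle cap — grouping (below) is the intended route for larger models.
* **Pooled PCA** runs on the vertices pooled across all directions at one
  level (and optionally across levels), unweighted, with natural
  multiplicity. Vertices are taken as the canonical finite description of
  the solution set — they span its affine hull; interior sampling is
  deliberately not implemented.
* **Bootstrap.** Percentile bootstrap over per-unit statistics (per level,
  per model, per posture — whatever the caller supplies), seeded.

**Muscle grouping.** A detailed many-muscle table collapses to groups by
averaging moment arms weighted by maximal force and summing forces:
`r_g F_g = sum_i r_i F_i` per joint, so torque capacity about every joint is
conserved exactly.

## Synthetic models

All named models are deterministic, with documented stand-in parameters at
physiologically plausible magnitudes — none are measurements, and every
default can be overridden from a limb-model JSON file.

* **Schematic** (3 muscles / 2 joints): two monoarticular muscles and one
  biarticular antagonist; rank-2 moment arms; 2-link chain Jacobian.
* **Finger-like** (7 muscles / 3 joints, wrench fx, fy, tz): standard
  index-finger muscle names; two posture presets ("extended", "flexed" —
  the quantitative angles are arbitrary documented defaults). The stand-in
  moment arms and strengths were chosen so the muscle torque vectors
  positively span joint-torque space, i.e. the feasible force set contains
  the origin in its interior and several 1 N levels fit in every direction
  at both presets; without that, the magnitude-scan procedure would be
  degenerate on a synthetic model.
* **Leg-like** (14 groups / hip-knee-ankle): link lengths scaled from
  stature by standard anthropometric fractions (0.245 / 0.246 / 0.152 of
  stature); gastrocnemius split into medial/lateral heads to reach 14
  groups. The default posture is a mildly crouched stance away from the
  straight-leg singularity. Its feasible force set is strongly elongated
  (max/min radial feasibility over 16 directions is about 25 under the
  defaults).
* **Random models** are reproducible from their seed, full-column-rank, and
  antagonistic about every joint (so feasible sets are nondegenerate).
* **Workspace movements**: uniform over a planar disc by rejection sampling
  (default radius 10% of limb length — the linearization regime), with a
  reflected random-walk alternative behind a flag; the orientation
  component is identically zero (endpoint orientation held fixed).
* **Synthetic detailed leg**: a 44-muscle stand-in table made by splitting
  each group into constituents with scattered arms and Dirichlet-partitioned
  forces. It exercises the grouping and many-muscle feedback machinery; it
  is *not* the published lower-extremity model, and the package ships no
  third-party model data.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the original inputs — muscle
counts and names, planar tasks, 16-direction scans, 10 cm leg / few-mm
finger perturbations, 1 N force increments, on/off 10 N tension protocols —
but not measured geometry. Passing tests therefore demonstrate the
mechanical mechanisms (rank bounds, feasibility geometry, dimensionality of
pooled solution sets, cross-posture generalization) and the correctness of
the machinery, not the numeric values a specific cadaver specimen or a
published musculoskeletal model would give. Users reproducing
published-model numbers must supply that model's moment arms and forces via
the JSON format.

## Numerical choices

* Vertex dedup tolerance 1e-8 activation units; equality satisfaction is
  exact by construction and asserted to 1e-8 in tests.
* LPs use scipy's HiGHS; unboundedness is impossible with box bounds and is
  asserted, not tolerated.
* PCA via SVD; degenerate all-identical data returns a zero-variance basis
  with a warning rather than failing.
* Protocol generation caps at 20 muscles (2^n rows), enumeration at 16
  muscles, both with explicit refusals naming the cap.
* Problem sizes used by the shipped analyses (16 directions, 2000 workspace
  samples, 1 N x ~7 levels on the finger, 5x5 generalization grids, 200
  oracle instances) keep every pipeline in the seconds-to-minutes range on
  one CPU.

## Known limitations

No dynamics, tendon elasticity, activation dynamics, or physiological EMG
modeling; no NMF-based synergy extraction; no optimization-based activation
selection (the object of study is the full solution set, not a chosen
pattern); no parsing of third-party musculoskeletal model files (external
tables enter only through the JSON/CSV formats). The linearized inverse
kinematics used for the generalization grid is a small-displacement
approximation; for large grids the mapped postures are nominal test
postures, not exact endpoint positions.
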