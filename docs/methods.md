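# Methods

`budmorph` simulates one budding cycle of a *S. cerevisiae* cell as a
coupled mechano-chemical system on a closed triangulated surface.  This
note records the model, its discretization, the parameter choices, and
what the synthetic study conditions do and do not show about real cells.

## Mechanical submodel

The cell wall is a coarse-grained elastic network on the triangle mesh.
Each node moves by the overdamped law

    c dx_i/dt = -∇_i E_total + F_turgor,i

with

    E_total = Σ_edges (k_s/2)(L-L0)²                  (linear springs)
            + Σ_ring  (k_s/(2 L0²))(L-L0)²            (septin-ring springs)
            + Σ_hinges k_b (1 - cos(θ-θ0))            (cosine bending)
            + Σ_faces (k_a/(2 A0))(A-A0)²             (area resistance)
            + Σ_pairs D_m (1 - e^{-a_m (L-L_m)})², L ≤ L_m   (Morse, self-avoidance)

and the turgor load lumped to face corners, `F_i = P Σ_f (A_f/3) n̂_f`.
The septin ring's `1/L0²` scaling makes the ring resist *strain* rather
than absolute extension, so the neck stays narrow while the bud balloons.

The dihedral angle θ is the *signed* angle between the unit normals of the
two faces of a hinge (positive = convex, as everywhere on the initial
sphere).  The signed form is smooth through the flat configuration, which
keeps the analytic bending force well defined; for the convex shapes the
model visits it coincides with the unsigned angle between normals.  All
forces are analytic gradients; the suite checks them against central
finite differences to 10⁻⁶ relative accuracy.

Integration is explicit forward Euler.  Two numerical guards matter in the
growth regime: a per-step displacement cap (`max_step_frac`, default 0.2 ×
the shortest current edge) protects the explicit integrator when repeated
splits create locally fine, stiff patches, and a step producing non-finite
positions raises immediately with a suggestion to lower `dt`.  When numba
is importable the relaxation inner loop runs through a compiled kernel; a
test asserts near-machine-precision agreement with the vectorized numpy
path, which remains the fallback.

Mechanical defaults (dimensionless): c = 1, ks = 30 (both regions),
kb = 2 (mother) / 0.25 (bud; the bud wall's higher stretch-to-bend
stiffness ratio), ka = 20, P = 4, Morse D_m = 0.5, a_m = 20, L_m = 0.12,
dt = 2·10⁻³.  At these values turgor inflates the rest sphere by ≈ 2–3 %
strain (the relaxed radius is verified in a test against a one-parameter
radial energy minimization), and a full mechanical relaxation of a frame's
growth fits in a few hundred Euler steps.  A config-level scale pair
(`length_um`, `frame_min`) converts simulation units for plots only.

## Growth by triangle-pair splitting

Material insertion splits the shared edge of two adjacent triangles at its
midpoint: two triangles / four nodes become four triangles / five nodes
(V+1, E+3, F+2; the Euler characteristic is invariant).  New elements take
their rest quantities from the current geometry scaled by
`rest_growth_factor` g = 1.15; new hinge rest angles equal their current
angles.  One amendment to the plain multiplicative rule proved necessary:
when a recently inserted (still compressed) pair is split again, `g ×
current area` can fall below the pair's existing rest area, which would
remove material.  The implementation therefore grows from
`max(current area, parent rest area)`, so every split strictly increases
the local rest area.  With this rule a constant number of insertions per
frame adds a near-constant rest-area increment, which is what produces the
linear bud-area growth the model is calibrated to (OLS R² > 0.99 in the
scenario runs).  Splits that would create a corner angle below 0.02 rad
are refused (and the growth event redraws another candidate edge); if a
growth region is too small to own an interior edge, candidates fall back
to same-compartment edges bordering it, so growth cannot silently stall.

## Metropolis edge swapping

Wall rearrangement flips the shared edge of a triangle pair to connect the
two previously unconnected vertices, accepted with probability
min(1, e^{-ΔE/kT}).  ΔE is computed from the local stencil only (central
edge spring, the two face areas, five hinge bending terms, and the two
Morse pair terms that change connectivity); a test verifies it against a
full re-computation of E_total to machine precision.  Accepted flips patch
the cached mesh topology surgically (O(1) per flip); a test compares the
patched caches against a from-scratch rebuild.  Flips are rejected as
illegal if they would duplicate an edge, drop an endpoint below valence 3,
touch the septin ring, or create a triangle with a corner angle below
0.1 rad (needles make the area term explosively stiff).

Rest-state bookkeeping after a flip follows one of two modes.  In the
default `material` mode the rest state is treated as a property of the
wall material: the new central edge takes the mean rest length *and* mean
rest dihedral of the four boundary edges, and the conserved local rest
area is split evenly between the two faces.  In `plastic` mode the central
rest angle is instead reset to the current angle and rest areas follow the
current face areas; each accepted flip then erases shape memory.  The
distinction matters: with plastic flips, swapping behaves as stress-
relieving creep that *assists* tip elongation, whereas material flips bias
accepted moves toward the wall's preferred shape.

kT defaults to 0.2.  On a well-formed mesh any flip is intrinsically
uphill by roughly the spring energy of the quad diagonal (ΔE ≈ 1–2.5 in
simulation units), so at this temperature swapping is close to greedy
energy descent — the stated purpose of the rearrangement — and accepts
mainly in strained, freshly grown regions.  Hotter temperatures (kT ≈ 2–3,
which would accept 30–60 % of proposals on a mildly distorted sphere) turn
swapping into plastic churn and were rejected for that reason.

Swap proposals are drawn from the bud surface (`swap_domain="bud"`), where
the paper situates wall rearrangement; whole-surface proposals mostly hit
the rest-state mother and dilute the dose.

## Signaling submodel

Active Cdc42 `a` (per vertex) and one well-mixed inhibitor `b` obey

    ∂a/∂t = Dc Δ_Γ a + k0/(1+(βu)^-q) + k1/(1+(γ p a)^-h) - k2 a - k3 b a
    db/dt = k4 (ā - kss) b,        p = 1/(1+(βu)^-q)

on the deforming surface Γ.  The inhibitor is an integral controller: at
any steady state with b > 0 the surface average ā equals kss exactly — the
suite asserts this homeostasis after every frame's solve.  The spatial cue

    u = umin + (umax - umin) ((H_T - H_min)/H_total)^{n(t)}

is evaluated at face centers from their height along the bud axis and
mass-averaged to vertices for the reaction terms; heights are normalized
by the face-center range so the tip face carries exactly umax and the
bottom face exactly umin.  Time variation enters only through the exponent
schedule n(t).

Discretization: linear finite elements with cotangent stiffness and
barycentric lumped mass (cotangents clamped, with a warning, for corner
angles within 5·10⁻³ rad of degeneracy).  The l = 1 spherical-harmonic
eigencheck (Δz = -2z on the unit sphere) converges through subdivisions
3→4→5 and is below 2 % at subdivision 5.  Stepping is a positivity-
preserving splitting: production terms explicit, the linear inactivation
(k2 + k3 b) implicit in the reaction substep, then implicit diffusion via
a cached sparse LU factorization, then the exact exponential update of b
(rate-limited to ±0.2 per step).  A fully explicit scheme goes stiff when
b grows large and sustains a clipping oscillation that biases ā upward and
winds the controller up irrecoverably; the semi-implicit form is stable
for arbitrary b.

Quasi-steady coupling: the field is re-converged on the current geometry
every frame (warm-started from the previous frame, typically a handful of
iterations); no sub-frame chemical history is kept.  Convergence requires
max|Δa|/dt < tol and |ā - kss| < tol.

### Signaling parameter regime

Defaults: Dc = 0.05, k0 = 6, k1 = 4.5, k2 = 1, k3 = 1, k4 = 2,
kss = 0.03, β = 2, γ = 2, q = 4, h = 2.  The rate constants are not
determined by any measurement here; they were chosen once to place the
system in the regime the model needs and then frozen:

* **Signal-following, not winner-take-all.**  Self-enhancement (k1, h) is
  kept weak relative to cue-driven activation (k0, q) so the activator
  profile tracks the cue u: a shallow cue (n = 2) yields a bud-wide
  high-concentration region, a sharp cue (n = 8) a tip cluster.  With
  strong autocatalysis the uniform state is Turing-unstable and even the
  n = 2 case spontaneously collapses to a tip cluster, destroying the
  spherical-budding regime.
* **Reachable set point.**  With a sharp cue, production is confined to a
  small patch, so the largest achievable surface average is roughly
  (k0+k1)·A_patch/(k2·A_total).  kss = 0.03 sits below that bound for the
  whole growth trajectory; otherwise b decays toward zero and homeostasis
  becomes unattainable.
* **Resolved diffusion length.**  sqrt(Dc/k2) ≈ 0.22 of the cell radius,
  a few edge lengths on the scenario meshes.  The remeshing-stability
  check (100 random swaps move the converged field by < 1 % relative L2)
  is run on a subdivision-4 sphere where this length is well resolved; on
  coarser meshes the peak is under-resolved and its discretization is
  mesh-dependent.

## Shape metrics

* **Bud area**: sum of bud-face areas.
* **Aspect ratio**: by default the ratio of the largest to the smallest
  extent of the bud vertex cloud along its principal axes (SVD); a
  height/width estimator (tip height above the neck plane over the
  maximal perpendicular diameter) is reported alongside in the CSV.  The
  microscopy analogue is measured on 2-D outlines, which fixes neither
  3-D estimator; both are provided.  Early in a run the bud is a shallow
  cap whose point cloud is plate-like, so the PCA ratio starts high and
  falls as the bud inflates — only late-run values are comparable between
  scenarios.
* **Polarization height**: z-distance from the bud tip to the lowest bud
  vertex with a ≥ 0.8 of the bud maximum; relative PH divides by the
  tip-to-neck height (mean septin-ring z) and is clipped to [0, 1].
* **Growth rate**: ordinary least squares of bud area against frame.

## Scenario conditions and problem sizes

A scenario frame is: cue → quasi-steady solve → threshold gating (bud
faces with mean vertex concentration ≥ 0.8 of the bud maximum) → a growth
event of `insertions_per_event` splits, each immediately followed by its
scheduled edge-swap dose (so ES counts are per-insertion relaxation
doses) → mechanical relaxation → metrics.  All presets start from a
subdivision-2 icosphere (162 vertices, unit radius) with a 0.5 rad bud
cap and run 160 frames; signaling-coupled presets insert 6 times per
frame with g = 1.15 and relax up to 400 Euler steps per frame.  These
sizes resolve the reported shape effects while keeping a full preset run
at a few minutes on one core.

The relaxation budget is itself a study condition, not merely a solver
setting: relaxation does not fully converge between frames (the locally
refined tip keeps oscillating inside the step-size guard), so the budget
sets the ratio of growth to mechanical relaxation per frame.  The
spherical scenario's final aspect ratio is sensitive to it (roughly 1.1
at 400 steps/frame and 1.3 at 600 at these mesh sizes); the tubular
scenario is not.  The default of 400 steps/frame keeps the shallow-cue
scenario in the round-bud regime.

The fixed-tip ablation (the ES-count experiments) pins the growth region
to the top tenth of the bud height, skips the signaling solve, inserts
once per frame, and caps mechanical relaxation at 150 steps per frame so
that the scheduled edge swapping — not the mechanical budget — is the
dominant relaxation channel, which is the competition those experiments
probe.

The test suite runs the same presets at reduced frame counts (100–160
frames, 3 seeds) chosen so each asserted effect is already established;
`scripts/acceptance.py` runs the two headline scenarios at the full 160
frames, 3 seeds each.

## What the synthetic conditions do not show

The generator produces idealized spherical mothers with a single
pre-placed bud site; there is no bud-site selection, no septin dynamics,
no Cdc42 cluster competition, no actin-mediated delivery, no osmotic
feedback, and no cell division.  Passing tests demonstrate that the
*mechanisms* — tip-restricted insertion producing tubes, bud-wide
insertion producing round lobes, cue-schedule decay stabilizing the
aspect ratio — operate as described in this model, not that the parameter
values are those of any real cell.  Aspect-ratio magnitudes depend on the
mechanical constants; only their orderings and trends are meaningful.

## Known limitations

* Explicit mechanical integration bounds dt; very stiff configurations
  rely on the displacement cap rather than true stability.
* The quasi-steady assumption drops any chemical transient slower than a
  frame.
* Vertex fields transferred across splits (midpoint averaging) do not
  exactly conserve ∮a ds; the per-split drift is bounded by the new
  vertex's lumped mass times its value (tested) and is erased by the next
  frame's re-solve.
* No mesh coarsening: long runs monotonically refine the bud region.
* The influence of the edge-swap count on final bud roundness in the
  fixed-tip ablation is weak relative to seed-to-seed variability at this
  mesh resolution: single runs scatter by ±0.3–0.5 in final aspect ratio
  while the 25-vs-125 swap contrast shifts the median by only ~0.1–0.3,
  and the direction of the shift is itself configuration-sensitive.
  Distinguishing the swap-count effect cleanly would need finer meshes
  and many more seeds than the bundled scenarios use.
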