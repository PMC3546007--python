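# Methods

`spineplan` plans posterior instrumentation for adolescent idiopathic
scoliosis (AIS) in four stages: it quantifies a 3D spine geometry with
twelve standard deformity descriptors, scores candidate strategies with a
surgeon-weighted corrective objective Ф, simulates each strategy's
manoeuvres on a simplified flexible-multibody spine, and searches the
six-variable strategy space with a uniform experimental design and linear
response-surface surrogates. This note records the models, the defaults and
their rationale, and the limits of what the synthetic tests demonstrate.

## Coordinate conventions

Global frame: origin at the pelvis body center, +z cephalad, +x anterior,
+y patient-left; coronal plane = y–z, sagittal = x–z, transverse = x–y.
Units are millimetres internally; apical vertebral translation (AVT) is
reported in centimetres, angles in degrees. A patient-right convexity has
its apex at y < 0. Vertebral local frames are built from landmarks only:
local z along the inferior→superior endplate centers, local y along the
right→left pedicle chord orthogonalized against z (Gram–Schmidt), x = y×z.
Source data never state a frame recipe, so this construction — which uses
only landmarks the data model carries — is our own and is applied
uniformly.

## Synthetic patient generator

The generator stands in for radiographic 3D reconstruction. Vertebral body
centers sit at fixed anthropometric stations (center spacings 19–30 mm,
scaled to a configurable T1→pelvis height, default 430 mm). Deformity is
parameterized per curve region (PT, MT, TL/L: end vertebrae, apex, side,
coronal amplitude, apical axial rotation) plus two sagittal bow amplitudes
(kyphosis T4–T12, lordosis T12–L5, signed, positive = conventional
direction).

The coronal profile is a C1 cubic-Hermite spline: zero deflection at every
station outside the active regions, the signed amplitude at each apex (zero
slope there), and solved tangent angles at the neutral (end) vertebrae.
Each active region demands a tangent-angle drop equal to its
amplitude-implied Cobb angle, w = 2·atan(πA/2L); the boundary tangents are
the minimum-norm solution of these constraints. Two properties follow by
construction: neutral vertebrae are clean inflexion points of the coronal
projection, and adjacent Cobb angles decouple (each is a monotone function
of its own amplitude), which is what makes calibration well-posed. An
earlier piecewise half-sine basis was abandoned: its slope kinks at shared
neutral vertebrae corrupt spline-based inflexion detection and couple
adjacent Cobb angles so strongly that dissimilar adjacent targets become
unreachable. The sagittal profile is a natural cubic spline with two bows;
the two bows share the T12 tangent, a real anatomical coupling that the
calibration handles (see below).

The axial-rotation parameter is defined in the transverse plane — the
quantity the Stokes pedicle-projection method measures. For each vertebra
the generator solves (closed form) for the local rotation about the
centerline tangent whose pedicle-chord projection equals the requested
profile value, so imposed and measured apical rotation agree exactly, not
just to small-angle order. The rotation profile is a per-region half-sine
peaking at the apex.

Calibration (`calibrate_to_targets`) adjusts the five amplitude parameters
by damped per-parameter secant iteration until the measured PT/MT/TL-L
Cobb, kyphosis and lordosis hit requested targets (default tolerance
0.5°, ≤25 sweeps). Secant rather than multiplicative updates because the
sagittal amplitudes may legitimately cross zero and the coronal measures
carry residual leakage from strong neighbours. Targeted coronal amplitudes
are floored at 0.5 mm: at exactly zero a region releases its tangent
constraint and the measured Cobb becomes discontinuous in the amplitude.
Calibration converges across independent target draws (Cobb 15–70°, TK
10–50°, LL 30–70°); extreme combinations — e.g. a 65° curve directly
adjacent to a 20° one, which no smooth single-apex family represents — can
still fail, and fail loudly with residuals.

The packaged index patient is a Lenke 2B double-thoracic pattern: PT T1–T5
(apex T3, left), MT T5–T11 (apex T8, right), TL/L T11–L4 (apex L2, left),
calibrated to 51/56/38° Cobb with 22° kyphosis and 44° lordosis. Only the
MT apex (T8) and the five angles are given by the source case description;
the other apices/end vertebrae are chosen consistent with the curve type
and are configurable. Apical rotations default to 8/15/8° (only the MT
value is anchored); the plane-of-maximum-curvature orientations are
emergent, not calibrated. Optional Gaussian landmark jitter (σ, default 0,
seed-controlled) emulates reconstruction noise for robustness studies; all
shipped results use the noise-free, fully deterministic path.

What the generator does *not* emulate: rib cage and pelvis morphology,
vertebral shape asymmetries (wedging), reconstruction bias, or
population-level shape statistics. Tests passing on this family show the
measurement/optimization machinery is correct and self-consistent, not that
it is validated on real reconstructions.

## Descriptors

* **Coronal Cobb (PT, MT, TL/L)** — angle between perpendiculars to the
  fitted spine curve at the segment end vertebrae. The curve is a cubic
  spline through the coronal-projected body centers (interpolating by
  default; a smoothing parameter is available for noisy landmarks). The
  measure needs only a differentiable curve; segment ends are taken from
  the segment definition (the preoperative end vertebrae are reused for
  postoperative measurements, the standard radiographic convention).
* **Inflexion points** — prominent local extrema of the fitted coronal
  slope (equivalently sign changes of curvature), with peak prominence
  ≥10% of the slope range to reject interpolation wiggle, snapped to the
  nearest laterally neutral vertebra. Boundaries weaker than the prominence
  threshold are not reported.
* **AVT** — lateral offset (cm) of the main-curve apex body center from the
  T1 plumb line. T1 proxies the clinical C7 plumb line because the model
  spans T1→pelvis; on this geometry the difference is the (small) lateral
  offset of C7 relative to T1.
* **Sagittal Cobb** — endplate-line angles in the sagittal projection:
  kyphosis from the superior endplate of T4 to the inferior endplate of
  T12, lordosis from the superior endplate of T12 to the inferior endplate
  of L5 (as printed in the source definitions, including the unusual T12
  upper reference for lordosis), signs fixed so kyphotic/lordotic are
  positive.
* **Stokes apical rotation** — transverse-plane angle of the right→left
  pedicle chord against +y, about +z. With full 3D landmarks this chord
  projection replaces the original radiographic offset formula.
* **PMC orientation** — angle between the plane through a segment's two end
  and apical body centers and the sagittal plane, folded to [0°, 90°]
  (orientation-symmetric; the source reports unsigned values). Collinear
  points raise a geometry error; `compute_all` reports such degenerate
  segments as 0°.
* **F** — unfused vertebrae among T1..L5: 17 minus the UIV..LIV span
  counted in vertebrae. (The published strategy table mixes vertebra and
  disc counting between rows; the definition "number of unfused vertebrae"
  is the one implemented.)

## Corrective objective Ф

Ф is the weighted sum of squared dimensionless ratios described in the
module docstring: coronal block (a1..a4 on PT/MT/TL-L Cobb and AVT ratios
against floored preoperative values), sagittal block (b1, b2 on
(θ−θⁿ)/(θ⁰−θⁿ) for kyphosis/lordosis), transverse block (c1..c3 on the
three apical rotations, c4..c6 on the three PMC orientations — the pairing
follows the published weight table; a switch selects the alternative
rendering), and mobility W4·(F⁰/F)². Weights are stored as percentages and
normalized inside the evaluation, so Ф at the preoperative state with
F = F⁰ is exactly 1 for every profile. Preoperative angular denominators
are floored at 5°, and |AVT⁰| at 0.5 cm (the analogous guard for the one
non-angular descriptor; configurable). Normal sagittal targets default to
θ_TKⁿ = 35°, θ_LLⁿ = 50° — inside published normal ranges and >5° from the
index patient's values, as the construction requires. F⁰ defaults to the
maximum unfused count over the full feasible strategy space (17 − the
shortest instrumentable span).

## Flexible-multibody simulator

A deliberately simplified quasi-static model; no claim is made of numeric
agreement with any proprietary calibrated simulator, and the published
per-strategy outcome tables are not reproduction targets.

**Structure.** Rigid vertebrae (6 DOF each); pelvis fixed except
sagittal-plane rotation; T1 free in translation and frontal-plane rotation
with weak springs (1e4 N·mm/rad) on its other rotations. Adjacent bodies
couple through 6-component generalized springs at the inter-body midpoint:
diagonal stiffness, defaults 100/100/300 N/mm (shear/axial) and
1.5e5/1.5e5/3e5 N·mm/rad (lateral bending / flexion–extension / torsion),
in the range of published functional-spinal-unit data; expressed in the
global frame of the intraoperative pose (a small-strain simplification).
Implants are point bodies offset 10 mm posterior of the pedicle entry on
the rod side (the concave side of the main curve by default), linked to
their vertebra by the generalized nonlinear element: a piecewise-linear
stiffening spring (soft toe k1 up to δ0, stiff engagement k2; screws
200/2000 N/mm, δ0 0.3 mm; hooks 100/1000 N/mm, δ0 0.5 mm with a 0.2 axial
weight — hooks differ only by softer coefficients and an axial-sliding
allowance). Gravity is omitted (prone, supported patient). The reference
configuration is stress-free.

**Rod.** A rigid planar two-arc curve: tangent sweeps equal the thoracic
and lumbar bend angles, arc lengths split at T12 in proportion to the
instrumented span, scaled to the UIV→LIV implant-head chord. Initial
orientation: plane coronal, thoracic bulge toward the main-curve convexity
(how a rod is contoured to the coronal deformity before derotation). One
rod is modelled; the published strategies likewise report a single rod
shape.

**Manoeuvres.** All load-driven, solved to equilibrium at every increment.
*Attachment* ramps point-to-curve seating springs (k = 2e4 N/mm at full
engagement, geometric ramp 0.002/0.02/0.2/1.0) pulling each implant head
onto the rod; the seated spring acts only perpendicular to the rod
centerline, i.e. it *is* the cylindrical joint (free sliding along and
rotation about the rod axis), with the rod ends acting as sliding stops.
A weak "surgeon's grip" (0.5 N/mm, 1e4 N·mm/rad) regularizes the rod's
otherwise free axial-slide and roll modes. *Derotation* drives the rod
plane normal from its coronal start to the sagittal plane (±y) along the
geodesic, in 15° increments, through a stiff rotational spring
(1e9 N·mm) — the spring applies the gradually increasing torque; the
rotation sense is chosen so the thoracic bulge ends posterior (kyphotic).
Final plane angle tolerance 0.5°. *Compression/distraction* ramps a spring
(2000 N/mm) between two named implants toward a target separation
(tolerance 0.5 mm); it is only run when explicitly sequenced — the default
sequence is attach, then derotate.

**Solver.** Newton iteration on the generalized force balance with an
almost-exact Hessian: Gauss–Newton part plus the rotational
geometric-stiffness, rotation–translation cross terms, and the
piecewise-stiffening rank-1 term (verified against directional second
differences to ~0.2%). The attachment energy is ½k·dist²(head, rod curve),
whose frozen-foot gradient is exact by Danskin's theorem; the free sliding
appears only as a negative tangential rank-1 Hessian term.
Levenberg–Marquardt damping handles the flat sliding modes and any
transient indefiniteness and vanishes near the solution. Convergence:
scaled residual (rotational entries divided by a 100 mm moment arm) below
1e-6 × the characteristic load (the largest element force, ≥1 N). A
non-convergent increment fails the configuration, which is returned flagged
rather than raised; batch runs require ≥80% convergence. The whole path is
deterministic — identical inputs give bitwise-identical results.

**Extraction.** Post-operative landmarks follow each body's rigid motion;
descriptors are then measured exactly as preoperatively, with F from the
configuration.

## Design space and optimization

Default space (1296 strategies): UIV ∈ {T2..T5}, LIV ∈ {T11..L4}, implant
density ∈ {every level, alternate, ends+apex}, implant pattern ∈
{all-screw, hybrid (hooks at the two uppermost implant levels)}, thoracic
bend ∈ {10°, 20°, 30°}, lumbar bend ∈ {30°, 45°, 60°}. Every combination
is feasible by construction; spaces containing infeasible UIV/LIV pairs
are rejected whole rather than silently filtered, so the cardinality is
always the product of level counts.

The U-type design (default 702 runs — the published search-space size,
treated as a chosen run count over the larger grid) starts from a
good-lattice-point construction (one coprime generator per variable, which
gives exact level balance ⌊n/q⌋/⌈n/q⌉), repairs duplicate rows by balanced
in-column swaps, and then runs 300 seeded greedy swap iterations minimizing
the centered L2 discrepancy, with incremental (two-row) updates of the
discrepancy terms. The result is distinct, balanced, feasible and
deterministically seeded, and beats the mean random design on discrepancy.

Surrogates are main-effects ordinary least squares per descriptor over the
ordinal codes scaled to [−1, 1] (interactions available behind a flag, off
by default, matching the "linear regression coefficients" description).
All 12 descriptor responses are fitted; F is computed exactly from the
configuration rather than regressed. Non-converged rows are excluded; rank
deficiency is reported with the offending variable named. R² of the linear
surrogate on this simulator is moderate (≈0.2–0.9 depending on the
descriptor) — the simulator's response is genuinely nonlinear, which is
exactly why the optimum is verified by re-simulation.

Minimization is two-stage: L-BFGS-B on the continuous [−1,1]⁶ relaxation
(multi-start: center + 8 corners; F interpolated continuously from the
UIV/LIV codes), then exhaustive evaluation of the surrogate objective on
the full discrete grid. The exhaustive stage makes the reported strategy a
true grid minimum regardless of the continuous stage (which is retained
for methodological fidelity and reported alongside); ties break toward
fewer fused levels, then the most cephalad UIV. The returned strategy
carries the surrogate-predicted descriptors, its Ф, and a verification
re-simulation.

Strategy-table statistics use the population (N-divisor) standard
deviation, with means truncated (not rounded) to one decimal and SDs
rounded to one decimal — the convention that reproduces the published
summary values (sample SDs do not); full-precision values are returned
alongside.

## Problem sizes and determinism

The test suite runs the full published problem size — 702 simulated
strategies plus surrogate fit, minimization and verification — on the
index patient (about 0.8 s per simulation), a 54-run subsample for the
correction-property check, and 100-design Monte-Carlo baselines for the
discrepancy comparison. Every pipeline stage is deterministic given its
seed; the only random streams are the design seed, the optional landmark
jitter, and Monte-Carlo baselines in tests.

## Known limitations

* Single rod; no contact, no bone–implant force limits or failure, no rib
  cage, no balance/decompensation prediction, no cervical spine.
* Intervertebral stiffness is generic, not personalized from flexibility
  tests; implant-link coefficients are plausible placeholders.
* The corrective-objective weights scalarize the trade-off; no Pareto
  analysis.
* The inflexion detector reports only boundaries whose slope prominence
  clears the threshold; weak curves beside dominant ones may be missed.
* The generator's curve family cannot represent arbitrarily dissimilar
  adjacent curve magnitudes; calibration then fails explicitly.
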