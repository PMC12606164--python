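# Methods

## Constitutive model

Ligament tissue is modelled as a fully incompressible, transversely
isotropic hyperelastic solid with a single dominant collagen-fiber family
aligned with the loading axis (`a0 = (1, 0)` by default, configurable per
element in the FE model).  The strain energy is the additive split
`W = Wm(I1, I2) + Wf(I4)` with Neo-Hookean, Mooney–Rivlin or Yeoh ground
matrix and the quartic fiber polynomial
`Wf = C4 (I4−1)² + C5 (I4−1)⁴`.  Because J ≡ 1, isochoric ("bar") and
plain invariants coincide, and the fifth pseudo-invariant (fiber–matrix
interaction) is omitted — its contribution is generally regarded as
negligible for highly hydrated tissue.  All stresses and coefficients are
in MPa; stretches are dimensionless.

The initial shear modulus µ of the ground substance is prescribed, not
identified: a uniaxial test of a fiber-dominated tissue barely constrains
it.  Policy: `C10 = µ/2` (NH, Yeoh); for MR, `C10` is a-priori reduced to
0.0005 MPa so the second-invariant term carries the matrix response, and
`C01 = µ/2 − C10`.  Typical values explored are µ ∈ {0.002, 0.2, 1, 2} MPa
with µ = 1 MPa as the default.

Uniaxial tension has the closed form
`P = 2λ(1−λ⁻³) W₁ + 2(1−λ⁻³) W₂ + 2λ W₄` (W₂ only for MR), which the test
suite verifies against numerical differentiation of W along the
incompressible uniaxial path and against the plane-stress Cauchy
evaluation (`σ22 = 0`, `P = σ11/λ`).

## Curve segmentation

Characteristic points (I and II transitions, failure = maximum stress) are
extracted per specimen:

1. Savitzky–Golay pre-smoothing (cubic, window ≈ n/15 samples).  Cubic
   windows reproduce polynomial segments exactly, so clean data are
   essentially untouched.
2. Discrete second derivative (three-point central differences, non-uniform
   grids supported) and linear interpolation of its sign changes.  Samples
   whose |d²P/dλ²| falls below a tolerance (relative to the curvature peak,
   with an absolute floor at the round-off scale) count as zero so an
   exactly straight mid-region yields one clean crossing.
3. For each inflection candidate, a line through the two bracketing samples
   is grown outward while `|P − P_line| / max(|P_line|, P_floor) < 1%`
   (`P_floor` = 1% of the curve's peak stress guards the near-zero toe).
   Growth tolerates up to two consecutive off-band samples (isolated noise
   excursions), and a single least-squares refit-and-regrow pass removes
   the noise of the two anchoring samples.
4. Slope filter: the linear region of a ligament curve is its stiffest
   phase (the toe is still recruiting fibers; the subfailure phase is
   softening).  Candidate anchors where the doubly smoothed tangent slope
   is below 90% of the robust (95th-percentile) maximum slope are
   discarded.  Without this filter, shallow arcs of the toe or subfailure
   can hide inside the 1% band — a chord through an arc of curvature c
   stays in a band of width b over an extent √(8b/c) — and, for cohorts
   whose subfailure span exceeds the linear span, would frequently win the
   "longest region" contest under noise.
5. The longest surviving region wins; its raw end samples are the I and II
   transitions.

Structural accuracy limit: any growth criterion with a relative band of
width r overshoots a softening onset of slope drop Δm by about
`r·P_II/Δm` in stretch.  For the stiff ALL cohort this is ≈ 3 grid
spacings at 200 samples per curve, which is why round-trip tests assert
≤ 5 spacings on clean data and per-ligament bounds (2.5–5.5 spacings
median) at 1% noise.

## Averaged curves

Cohort characteristic points are averaged arithmetically (sample SD,
n−1).  The averaged curve is an exact interpolant: a toe segment through
the origin, point I and point II — either the quadratic-through-origin
polynomial `a(λ−1)² + b(λ−1)` or the saturating exponential
`A(e^{B(λ−1)} − 1)` (default; solved by bracketed root-finding on B, with
a linear fallback when the three points are collinear) — continued by a
subfailure quadratic matching value and slope at point II and passing
through the failure point.  Both toe forms interpolate exactly, so the
choice only affects between-point shape.  Monotonicity is *checked*, not
forced: for some cohorts (e.g. the ligamentum flavum) the exact polynomial
interpolant has a negative initial slope and only the exponential form is
a physically usable reconstruction; `AveragedCurve.is_monotone()` exposes
the check.

## Parameter identification

Bounded multistart nonlinear least squares (trust-region reflective) on
100 uniform stretch samples in [1, λ_II]; free coefficients bounded to
[0.001, ∞) MPa; 8 log-spaced starts over [0.01, 10] MPa with
seed-deterministic jitter, best final objective wins.  RMSE is reported on
the fit grid in MPa.  The optimizer is an implementation detail — the
contract is the minimized objective, the bounds and determinism under a
seed.

## Admissibility diagnostics

* **C1** — `W(λ1, λ2)` with `λ3 = 1/(λ1 λ2)` is sampled on a 101×101 grid
  over `λ1 ∈ [1, λ_max] × λ2 ∈ [1/√λ_max, 1]`; central-difference Hessians
  at interior points must not have eigenvalues of strictly mixed sign
  beyond 1e−8 MPa (semi-definite points are admissible, avoiding false
  saddles from round-off).  The explored range defaults to [1, λ_II] of
  the ligament at hand.
* **C2** — fiber dominance `Wf > Wm` along the uniaxial path (1, λ_max],
  200 samples; the report carries the largest failing sub-interval, the
  crossover stretch and the full energy partition.

## Membrane finite elements

Total-Lagrangian bilinear quadrilaterals with 2×2 full Gauss integration;
nodal unknowns are the in-plane displacements.  Substituting the
incompressibility constraint `λ3 = 1/det F2` into W eliminates both the
thickness stretch and the hydrostatic pressure: the gradient of the
reduced energy is exactly the in-plane first Piola–Kirchhoff stress of the
plane-stress problem (verified against finite differences).  Membrane
theory is adequate because the simulated load case is pure in-plane
tension — no bending or transverse shear arises, so no rotational DOFs,
shear-correction factors or hourglass control are needed.

Boundary conditions mirror the tensile test: one edge clamped at the bone
interface; the opposite edge given a prescribed axial displacement with
the transverse displacements of all its nodes tied to one common unknown
(the edge translates rigidly — the coupled-edge reading consistent with
nonzero edge-adjacent transverse fields; `u2 = 0` and free variants are
config options).  A roller variant of the fixed edge produces an exact
homogeneous uniaxial patch for verification.

Solver: displacement increments of Δλ = 0.01, Newton iterations with a
forward-difference consistent tangent assembled element-wise (batched over
elements), convergence at `‖R‖ / max(|reaction|, 1 mN) ≤ 1e−6`, step
halving on failure (max 4 cutbacks), partial results flagged rather than
raised.  Ligament simulations use the mean geometry with effective
thickness `t = A0/b`, so the membrane cross-section equals the cohort's
mean area and `reaction/A0` is directly comparable with the closed-form
engineering stress (the published mean thickness and mean area are
mutually inconsistent — ratio of means vs mean of ratios — and the
engineering-stress normalization fixes the choice).  Post-processing
reports the engineering curve `P(λ) = reaction/A0`, the contraction ratio
`max |u2| / u1` at the final step, and the mean `σ22/σ11` over the 10% of
elements nearest the sheet center (Cauchy stresses at element centroids).
Mesh convergence: halving the 0.5 mm default element size changes the ALL
reaction at stretch 1.3 by < 0.1%.

## Synthetic cohort generator

The generator emulates the *statistical structure* of the published cohort
tables (five ligament groups; geometry and characteristic-point means and
SDs), not raw machine output: no preconditioning cycles, no strain-rate
effects, no force–displacement conversion.

* **Sampling.**  Each specimen's six characteristic-point coordinates are
  normal draws with the published marginal means/SDs, sharing an
  equicorrelation of 0.7 (a stiff specimen is stiff throughout; marginals
  are unchanged).  Draws are rejected (max 100 redraws) unless positive,
  ordered (1 < λ_I < λ_II < λ_fail, 0 < P_I < P_II < P_fail) and
  *three-phase shape consistent*: both the origin-to-I secant and the
  II-to-failure secant must stay below 85% of the linear-region slope, so
  every accepted specimen has a discernible toe / linear / subfailure
  structure.  Truncation biases the accepted means: stretch means shift by
  ≲ 0.04 and stress means by roughly +20–35% for the stiff cohorts (the
  shape rules favour steep linear regions).  Tests therefore validate the
  sampler against an independent vectorised draw of the same truncated
  law; recovery tests compare segmentation output against the *generator's*
  construction points pairwise, which is unaffected by truncation.
* **Curves.**  The reference function is exponential-toe (end slope 30% of
  the way from the origin secant to the linear slope, C¹-blended into the
  exact I–II line over a window of 1% of the stretch span), exact line,
  then a concave subfailure quadratic through the failure point whose
  entry slope drops abruptly at the II transition (85% of the feasible
  drop — softening onset).  The sharp onset keeps the extracted linear
  region from bleeding into the subfailure phase; the blend window gives
  the discrete second derivative a clean zero crossing.  Curves are
  sampled on 200 uniform stretch points with multiplicative Gaussian
  stress noise (SD 1% by default) and the first sample clamped to (1, 0).
* **Forward-model curves** (`model_curve`) sample the closed-form uniaxial
  law directly and are the ground truth for parameter-recovery tests.

What passing tests show about real data: that the pipeline is internally
consistent and robust at the published noise scale and cohort sizes.  What
they cannot show: behaviour under correlated measurement noise, drift,
preconditioning history, or specimen shapes outside the three-phase
family.

## Problem sizes and determinism

Default analyses run in seconds on one core: 285-element ALL mesh
(×4 at the half-size mesh check), 200-sample curves, 500-specimen recovery
cohorts, 8-start fits.  Every stochastic component draws from
`numpy.random.default_rng` seeded through the public configuration
objects; identical seeds give bit-identical cohorts, fits and simulations.

## Known limitations

* Static hyperelasticity only: no viscoelasticity, damage, failure or
  poroelasticity; fitting stops at the II transition.
* One fiber family; no dispersion; no fifth pseudo-invariant.
* Membrane kinematics: no bending stiffness, so compressive transverse
  states that would wrinkle a real sheet are represented without
  out-of-plane relief (irrelevant in tension).
* The published coefficient tables were fitted to the authors' raw
  averaged curves; refitting to 3-point reconstructions reproduces the
  quadratic fiber coefficient C4 closely but not always the quartic C5,
  which is sensitive to between-point curve shape (see the acceptance
  suite).
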