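# Model and numerical methods

## Physical model

The domain is a 2D axisymmetric (r, z) cross-section of a cylindrical
container: a CPA column (7.05M DMSO by default, radius 5 mm, fill height
27.5 mm) inside an L-shaped polystyrene wall (thickness 1.25 mm, height
45 mm). z = 0 is the inner bottom; gravity acts in −z.

**Heat transfer.** One conforming temperature field spans CPA and wall
(temperature and flux continuity at the interface are automatic), with
conduction plus advection by the fluid velocity; viscous dissipation is
neglected. The chamber couples through Robin conditions: the forced-
convection coefficient h₂ = 350 W/m²·°C on the outer side and bottom
surfaces, and the free-convection value h₁ = 10 W/m²·°C on the CPA free
surface, the wall top rim, and the inner wall strip above the fill line.
The last three assignments are modelling assumptions (the cuvette interior
above the CPA actually encloses a small air pocket): sensitivity runs
replacing them with insulation change the final centerline displacement by
about 1%, so the choice is not load-bearing. The chamber temperature
follows an idealized linear ramp (rate in °C/min, clamped at the final
temperature); a measured (t, T) table can be supplied instead.

**Flow.** Creeping flow: the inertial terms are dropped entirely, making
each step a quasi-static Stokes solve (a configuration flag could retain
ρ∂v/∂t, but at these viscosities its contribution is far below
discretization error). Mass conservation with ρ = ρ(T) becomes a
prescribed divergence, ∇·v = −(1/ρ)(dρ/dT)(DT/Dt), evaluated nodally from
the material temperature derivative; for the default density polynomial
the logarithmic contraction coefficient (1/ρ)|dρ/dT| is nearly constant
(6.34×10⁻⁴ to 6.41×10⁻⁴ /°C across the protocol range), which is why a
one-point-per-step evaluation conserves global CPA mass to better than
0.1% over a full run (tested). The −⅔μ(∇·v)I compressibility term is
retained since ∇·v ≠ 0. Free surface: zero total traction, no surface
tension. Walls: no slip. Axis: v_r = 0, zero shear.

**Viscosity.** A single-exponential law μ(T) = μ_ref·exp(b(T_ref − T))
calibrated through two anchors, by default μ_ref = 10⁻² Pa·s at 10 °C and
μ_glass = 10¹² Pa·s at the glass transition −132 °C (b ≈ 0.227 /°C,
14 decades over the protocol range). The anchors are config-exposed
because measured values for 7.05M DMSO are scarce; sensitivity runs moving
μ_ref by one to two decades (or using a 15-decade span) change the final
displacements by under 5% — the displacement field is controlled by the
viscosity *contrast* across the domain, not its absolute scale, exactly as
Stokes linearity suggests. A numerical cap (default 10⁸ Pa·s) bounds the
contrast for conditioning; raising it to 10¹² changes results by a few
percent (the solution is effectively cap-converged at 10¹⁰).

**Arrested-flow switch.** A configuration option (`arrest_threshold`)
excludes material above a viscosity threshold from the Stokes system with
v = 0. It is off by default: hard-freezing arrested material while ρ(T)
keeps increasing violates mass conservation by ~2% over a run and clips
the slow-cooling contraction limit; the capped-viscosity solve keeps the
constraint exact everywhere.

**Maxwell solid (TM model).** The total strain rate splits into elastic,
creep (S/2μ, deviatoric) and thermal (αṪI) parts. Per-element stresses are
integrated implicitly: the volumetric response is elastic
(tr σ increments by E/(1−2ν)·tr(Δε − αΔT I)) and the deviatoric part
relaxes with time constant τ = 2μ(1+ν)/E. In a TM run, elements whose
uncapped viscosity passes `arrest_viscosity` (default 10⁸ Pa·s) are
latched as solid (one-way; temperature is monotone during cooling): their
volume source switches from the liquid contraction to the much smaller
solid thermal strain 3α·DT/Dt (α = 1.1×10⁻⁵ /°C versus ~6.4×10⁻⁴ /°C
volumetric for the liquid) and their viscosity follows the physical
exponential up to 10¹², so creep is negligible and the material
effectively adheres to the walls. Elsewhere the loop is identical to TF —
bitwise identical until the first element arrests. E = 1 GPa and ν = 0.33
are placeholders (no measured values): the TF/TM displacement comparison
is insensitive to them, but reported stress magnitudes scale with E and
must be read as parameter-dependent.

## Discretization

**Mesh.** A structured, conforming triangulation (right triangles on a
tensor grid, alternating diagonals) covering CPA and wall, with region
tags and one tag per boundary edge. Default ~4000 elements (a deliberately
desk-scale resolution; mesh-refinement studies at 2–4× show ~1% changes in
the final displacement). Element quality is measured as q = 2r_in/r_circ
(= 16A²/(perimeter·abc)), 1 for equilateral, 0 for degenerate; the
structured cells start at q ≈ 0.83.

**Thermal step.** P1 elements, backward Euler, lumped mass (with the
non-obtuse structured cells this yields a discrete maximum principle,
tested). Properties are evaluated at the element mean of the previous
temperature (one-step lag). Streamline diffusion is added only on elements
with cell Péclet number above 1 — never triggered in practice here, since
the creeping velocities give Pe ~ 10⁻². Verified against the symmetric
Robin-slab eigenfunction series (max nodal error 0.02 °C at Fo = 0.2,
Bi = 1 on a 40-cell strip) with observed spatial convergence order ≈ 1.9.

**Stokes step.** Equal-order continuous P1 velocity/pressure with
pressure stabilization of Brezzi–Pitkäranta/PSPG type,
δ_K = 0.1·h_K²/μ_K, including the body-force term so that hydrostatic
equilibrium (v = 0, p = ρg(h−z)) is reproduced to machine precision
(tested). Element viscosity is the geometric mean of nodal values —
log-linear interpolation, the natural rule for an exponential law. The
saddle-point system is assembled sparse, symmetrically diagonal-equilibrated
(the viscosity contrast spans up to ten decades) and factorized with
SuperLU.

**Implicit free-surface stabilization.** Moving the surface explicitly
with the computed normal velocity is unstable at any practical step while
the CPA is watery: the gravity-leveling time scale μ/(ρgR) is ~10⁻⁷ s at
10⁻² Pa·s. Displacing the surface by v·dt perturbs the hydrostatic load by
−ρg(v·n̂ dt)n̂; treating this restoring traction implicitly adds the
positive semi-definite boundary form dt·∫ρg(v·n̂)(w·n̂) ds to the momentum
operator. This makes the surface-height dynamics backward-Euler stable and
converges to quasi-static leveling where the fluid is mobile, while being
negligible against viscous resistance once μ is large.

**ALE motion and remeshing.** Free-surface nodes move v·n̂ dt along local
normals (the axis node's normal is vertical by symmetry; the surface–wall
contact node is pinned — the material adheres to the wall). Interior CPA
nodes follow by Laplacian smoothing with wall and bottom displacements
zero; axis nodes keep r = 0 but slide vertically. The thermal advection
uses the ALE convective velocity v − v_mesh. If the minimum quality drops
below 0.1, nodes are redistributed along their original radial columns
between the bottom and the current surface graph z = η(r), with 1-D linear
re-interpolation of nodal fields; connectivity and tags never change, so
the operation is cheap and exactly tag-preserving. Motions that invert
elements raise a remesh-required signal; the driver halves dt and retries.

**Time stepping.** Backward Euler with dt capped at 20 s and additionally
limited so the surface moves at most 0.3 mm (~1% of the fill height) per
step; one Picard pass per step by default (additional passes change final
displacements by ~0.2%; an optional tolerance-controlled inner loop is
available). Halving both caps changes the final displacement by ~0.6%.
The pipeline contains no randomness: identical configurations give
bit-identical CSV output (tested).

## Verification fixtures and what they show

The package carries its own oracles: the Robin-slab series solution
(checked in turn against an independent implicit finite-difference
solution to 10⁻³ of the temperature scale); the uniform-contraction closed
form u_s = h₀(ρ(T₀)/ρ(T₁) − 1) (checked against a brute-force stepwise
mass integration); and a synthetic cryomacroscopy frame generator that
inverts the screen-scaling reduction exactly and reproduces the
repeated-measurement uncertainty scheme in Monte-Carlo expectation. The
generator emulates ideal frames — Gaussian measurement noise, a fixed
scale factor, no lens distortion, no segmentation error — so passing the
metrics tests demonstrates the algebra and propagation are right, not that
real video reduces this cleanly.

## Behaviour of the coupled model, and limitations

- The cavity deepens monotonically during cooling and its centerline
  displacement grows with cooling rate and with deeper final temperature
  (both orderings tested). Faster cooling steepens radial gradients, so
  the near-wall annulus stiffens while the center is still mobile and the
  (mass-fixed) volume loss concentrates at the centerline.
- In the slow-cooling limit the *surface-averaged* displacement matches
  the uniform-contraction closed form to 0.1% (this is exactly global mass
  conservation). The *centerline* value, however, overshoots the closed
  form even at 0.1 °C/min: gravity leveling freezes once μ/(ρgR) exceeds
  the remaining protocol time (around −73 °C at that rate), and the
  contraction accrued below that temperature deposits preferentially at
  the center with the no-slip-wall flow profile (center ≈ 1.9× mean). The
  approach to the flat-surface limit is logarithmically slow in the
  cooling rate; treat the closed form as a bound on the mean, not the
  centerline.
- The pinned contact line meeting the traction-free surface is a corner
  stress singularity: the pointwise surface-traction residual grows under
  refinement near the wall while converging elsewhere (the diagnostic
  exposes a corner-exclusion option for convergence studies).
- Late in cooling, how sharply the remaining flow localizes into the warm
  center core is sensitive to the viscosity law and its cap, to the actual
  chamber thermal history, and to resolution of the narrow core; the
  final-temperature sensitivity of the centerline displacement inherits
  that uncertainty and is the least certain output of the model.
- Not modelled: initial meniscus curvature (the surface starts flat),
  surface tension, crystallization, fracturing, rewarming, radiative
  exchange, the 3D rectangular geometry, and image processing upstream of
  the per-frame measurements.
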