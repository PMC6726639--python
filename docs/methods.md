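# Methods

`mvmech` models the passive mechanics of the mitral valve — the two
leaflets and the chordae tendineae that tether them — and demonstrates
how the choice of constitutive law propagates into valve dynamics under
flow. This note records the models, the numerical choices, and what the
synthetic studies do and do not show.

## Constitutive models

All tissue laws are incompressible and strain-invariant based, with
`I1 = tr C` (`C = FᵀF`) describing the isotropic matrix response and
`I4 = a0·(C a0)` the squared stretch along the collagen fiber direction
`a0`. Three transversely isotropic leaflet laws are implemented:

    M1:  Ψ = c (I1 − 3) + a/(2b) (exp[b (I4* − 1)²] − 1)
    M2:  Ψ = c̄0 (exp[c̄1 (I1 − 3)² + c̄2 (√I4* − 1)⁴] − 1)
    M3:  Ψ = c0 (exp[c1 (I1 − 3)² + c2 (I4* − 1)²] − 1)

and two isotropic chordae laws, neo-Hookean `Ψ = C (I1 − 3)` and
exponential `Ψ = a1 (exp[a2 (I1 − 3)] − 1)`. Collagen fibers carry load
only in tension: every fiber term is evaluated at `I4* = max(I4, 1)`,
which zeroes both the fiber energy and the fiber stress for `I4 ≤ 1`.

The Cauchy stress is always derived from the energy,

    σ = −λ_mult I + 2 Ψ₁ B + 2 Ψ₄ (F a0) ⊗ (F a0),    B = FFᵀ,

with the incompressibility multiplier `λ_mult` eliminated in closed form
from the zero-stress condition of the test at hand: plane stress
(`σ33 = 0`) for leaflet sheets, uniaxial (`σ22 = σ33 = 0`) for chordae.
Three stress formulas that circulate in print disagree with the
derivative of their stated energies (an `I4` where the derivative gives
`I4 − 1` in the M1 fiber factor; `CB` where the neo-Hookean derivative
gives `2CB`; a missing `a2` factor in the exponential chordae stress).
The package implements the derivative-consistent forms — hyperelasticity
demands `σ` be the energy derivative — and the test suite enforces this
against central finite differences of `Ψ` at 1e-6 relative tolerance.
The as-printed variants remain available behind `as_printed=True` for
comparison, and are never used elsewhere.

Units: stresses in kPa; 1 mmHg = 0.1333 kPa; the flow solver works in
CGS (1 kPa = 10⁴ dyn/cm²). The exponents `c̄1, c̄2, c1, c2` are treated
as dimensionless since they multiply powers of dimensionless invariants;
published tables sometimes print kPa for them, a reading this package
does not follow (both readings are noted here deliberately — the
dimensionally consistent one is implemented).

### Reference parameter sets

Anterior/posterior M1 parameters from in-vitro human-valve biaxial
testing are built in (anterior `c=17.43, a=1.35, b=5.93` kPa/kPa/–;
posterior `10.25, 0.06, 3.48`), along with published M2/M3 calibration
results. A caution that the package's own experiments make concrete:
exponential-law parameters are meaningful only together with the stretch
protocol they were calibrated on. The built-in M2/M3 sets produce
stresses wildly different from M1 outside their (unpublished)
calibration range, which is why the pipeline re-derives M2/M3 by fitting
rather than treating the tabulated values as reproduction targets.

## Inverse problem

Parameters are estimated by minimising the summed squared stress
residuals over all recorded components (`σ11` and `σ22` for biaxial
data, `σ11` for uniaxial), subject to non-negativity `params ≥ g`
(default `g = 1e-6`). The solver is SciPy's trust-region-reflective
least squares run in **log-parameter space** (`params = exp(z)`): this
equalises the wildly different parameter scales of exponential laws and
turns the positivity constraint into a simple box. Twenty seeded
log-uniform starts over `[1e-3, 1e3]` guard against the non-convexity of
the exponential laws; the best start by objective wins, making the fit
deterministic given `(dataset, seed)`. Unweighted residuals are used
(both components weight 1).

Goodness of fit is reported per component as `R² = 1 − SSE/SST` (SST
about the component mean; negative values possible and meaningful), and
as the mean absolute residual in kPa ("average error" — a declared
interpretation, since no canonical definition exists; it is never used
as a pass/fail quantity).

### Pseudo-biaxial calibration and its stretch range

M2/M3 leaflet parameters are determined by fitting to noiseless
pseudo-biaxial data generated from M1 (`generate_pseudo_data`). The
default protocol uses three loading paths — equibiaxial, fiber-only
(`λ2 = 1`), cross-fiber-only (`λ1 = 1`) — with 30 points each over
`λ ∈ [1.0, 1.40]`. The upper end of the range was chosen by a
calibration study: M2/M3 have zero stress slope at the reference state,
so on ranges that stop before the collagen-stiffening regime dominates
(λ_max ≲ 1.3) the globally best fit is a degenerate quasi-linear
parameter set (`c0 → ∞`, exponents `→ 0`) with fiber-direction R² of
only 0.81–0.89. From λ_max = 1.4 the fiber term dominates the objective,
both laws reach R²_fiber ≥ 0.99, and the recovered M3 leading
coefficient lands at the ~0.3 kPa scale of published M3 calibrations —
evidence that published pseudo-biaxial fits also reached into this
regime. The trade-off is visible and expected: the cross-fiber R² is
sacrificed (M2/M3 cannot match M1's finite small-strain stiffness), and
the fitted exponential parameters must not be reused outside the range.

## Synthetic experiments

No public stretch–stress records exist for porcine mitral biaxial or
chordae uniaxial tests, so `mvmech.synthetic` emulates them in
stress–stretch space: a stretch-controlled protocol (stretch is the
controlled variable in both rigs, so noise is applied to stress only), a
ground-truth law, and a declared noise model — `none`,
`additive_gaussian(σ_noise kPa)`, or `proportional_gaussian(cv)`.
Defaults: leaflet protocols as in the fitting module; chordae protocol
`λ ∈ [1.0, 1.10]` with 50 points (cords are stiff; the range is small).
Chordae truth parameters are not published; the defaults (`a1 = 10` kPa,
`a2 = 30`; linear `C = 5000` kPa) put peak uniaxial stress in the
0.4–3 MPa range at 10% stretch, the physiological chordae scale. The
noise magnitude (cv = 5% in the discrimination study) is likewise a
declared choice, not an inferred one.

What the generator does **not** emulate: preconditioning cycles (only
the post-preconditioned loading curve is produced), force/geometry-level
behaviour of the rigs (load cells, thickness measurement), stretch
noise, and specimen-to-specimen variability. Passing recovery tests
therefore show that the estimation machinery is correct and
well-conditioned under the declared noise — not that it would be
unbiased on real rig data with its richer error structure.

## 2D immersed-boundary/finite-element demonstrator

The FSI component is a deliberate dimensional reduction: published
valve-resolving simulations of this kind run on ~80×80×128 3D grids
with dt ~ 1e-5 s on clusters and patient-specific geometry. `mvmech.ibfe`
realises the same coupling structure at desk scale in 2D, to exercise
the numerical machinery and metrics — its outputs are qualitative sign
patterns and orderings, never patient quantities.

* **Fluid**: incompressible Navier–Stokes on a staggered MAC grid in a
  2 × 1 cm channel (no-slip walls; prescribed-pressure inlet/outlet),
  explicit projection stepping: first-order upwind advection, explicit
  centred diffusion, exact pressure projection via a pre-factorised
  sparse Poisson solve (post-projection divergence at rounding level).
  Blood-like constants ρ = 1 g/cm³, μ = 0.04 P (declared assumptions).
* **Structure**: each leaflet is a chain of 1D fiber-aligned elements
  with the fiber along the element; the element deformation is completed
  to 3D by plane-strain completion (stretches `(λ, 1/λ, 1)`), so `I1 =
  λ² + λ⁻² + 1`, `I4 = λ²` and all five tissue laws plug in unchanged.
  Nodal forces are the exact negative gradient of the total elastic
  energy (element + quadratic bending regularisation + stiff target
  springs anchoring the base nodes + tethers), verified against central
  differences. Default leaflet thickness 0.04 cm; bending coefficient
  1e5 dyn·cm ≈ E t³/12 Δs⁻³ for that thickness.
* **Coupling**: Peskin's 4-point regularized delta; force spreading and
  velocity interpolation use identical stencils and are exact adjoints;
  spreading conserves total force by the partition of unity.
* **Chordae tethers**: tension-only 1D elements (uniaxial incompressible
  completion) from each leaflet tip to a fixed "papillary" anchor placed
  on the channel centreline downstream. This placement is load-bearing
  for the study design: a tip moving away from the centreline (opening)
  or upstream past the closed position (prolapse) both lengthen the
  cord, so the cords restrain exactly those two excursions. Peak opening
  then measures leaflet-plus-cord compliance — a quasi-static,
  material-controlled quantity — rather than the nearly free rigid
  rotation of an untethered flap, which saturates at full opening for
  any realistic stiffness and would make stiffness orderings
  meaningless.
* **Driving pressure**: piecewise-linear transvalvular waveform through
  the physiological phase anchors +10 mmHg (open, diastolic filling),
  −80 mmHg (just closed), −150 mmHg (fully loaded). The *pressures* are
  the anchored facts; the time axis is compressed (forward hold to
  25 ms, −150 mmHg reached at 65 ms, 80 ms total) so that a desk-scale
  run resolves the whole open–close cycle in ~10⁴–10⁵ explicit steps.
* **Time step**: adaptive and deterministic — the minimum of the
  advective CFL bound (safety 0.4), the explicit-diffusion bound, and a
  structural bound `0.5·2·√(m/k_max)` with `m = ρh²` the dragged fluid
  mass and `k_max` the stiffest current tangent spring constant
  (estimated each step from the laws' tangent moduli). Collapse of the
  stable step below `dt_min` aborts with diagnostics, as does field
  blow-up or a node leaving the domain. Mesh positions are clipped to
  the channel box (leaflets cannot penetrate walls).

Default problem sizes: 128 × 64 cells for the full demonstrator (about
1–2.5 minutes per cycle), 48 × 24 for smoke tests, and an 8 × 64 channel
for the Poiseuille benchmark (steady profile within 2% of the closed
form at 64 transverse cells; the benchmark uses μ = 0.2 P to shorten the
viscous transient).

Known limitations: no leaflet–leaflet contact model (coaptation is
mediated by the fluid and the tethers; the stiffened variant can show
post-closure flutter), no papillary-muscle motion, no valve–ventricle
interaction, first-order advection, and 2D per-unit-depth fluxes that
are deliberately unit-tagged (`cm²/s`) so they can never be read as 3D
mL/s values.

## Metrics

`flow_rate` integrates the normal velocity over a fixed downstream
cross-section (the exact section is a free choice; the default sits
0.8 cm behind the valve). `regurgitation_volume` is `∫ max(−Q, 0) dt`
(trapezoidal) over the closure window, defined as [pressure-reversal
time, end of trace] unless overridden. `orifice_area` projects a 3D
free-edge polygon onto the annular plane and applies the shoelace
formula (self-intersecting projections warn and return the absolute
value); in 2D its stand-in is `gap_opening`, the tip-to-tip distance.
`peak_velocity` is the max of |u| over space and time.

## Testing strategy

Analytic results are checked against independent oracles: matrix-product
invariants, central-difference energy derivatives, hand-summed
objectives, closed-form Poiseuille profiles, convex-hull areas and
fine-grid quadrature. Property tests (seeded/derandomised) cover frame
indifference, partition of unity, adjointness, conservation, tension-only
switches, monotonicity and determinism. The acceptance layer re-runs the
whole pipeline: five-law stress–energy consistency, five-law parameter
recovery to 1%, cross-law calibration to R²_fiber ≥ 0.95, chordae
discrimination on 100 noisy replicates, the FSI core identities, and the
valve demonstrator's sign/ordering properties at 128 × 64.
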