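# Methods

## Model and assumptions

The breast cross-section is idealized as a semicircle of radius R1 (mm)
resting on the chest wall, with a circular tumor inclusion of radius R2 at
(x, y); lengths are mm, temperatures Kelvin internally.  Heat transport is
the Pennes bioheat equation: conduction with conductivity k, a perfusion
sink `omega_b rho_b c_b (T - T_a)` exchanging heat with arterial blood, and
a metabolic volumetric source `q_met`.  The flat base is a Dirichlet
boundary at the core temperature T_core; the curved arc is skin losing heat
by convection `h_f (T_s - T_f)` and grey-body radiation
`sigma eps (T_s^4 - T_f^4)`.  The model is two-dimensional (per unit depth):
it neglects out-of-plane conduction, discrete vasculature, anatomical
asymmetry and any imaging noise.

Two modelling choices deserve emphasis:

- **T_a = T_f = 293 K by default.**  The parameter set this package ships
  identifies the perfusion reference temperature with the ambient air
  temperature.  Physiologically arterial blood is near core temperature;
  with T_a = 293 K perfusion acts as a bulk coolant.  `TissueProps.T_a` is
  an independent field, so users can set T_a = 310 K to study the
  conventional regime.
- **Tumor contrast is a model input, not an output of first principles.**
  The tumor is ordinary tissue with elevated `q_met` and `omega_b`; both are
  configurable per region.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| k | thermal conductivity (both regions) | 0.48 | W/(m·K) |
| rho, c | tissue density / specific heat (transient term) | 1100, 3300 | kg/m³, J/(kg·K) |
| omega_b | healthy perfusion rate | 1e-4 | 1/s |
| rho_b, c_b | blood density / specific heat | 1100, 3300 | kg/m³, J/(kg·K) |
| T_a | perfusion reference temperature | 293 | K |
| T_core | chest-wall temperature | 309.5 | K |
| T_f | ambient air | 293 | K |
| h_f | convection coefficient | 15 | W/(m²·K) |
| sigma | Stefan–Boltzmann constant (as given in the reference parameter set) | 5.69e-8 | W/(m²·K⁴) |
| eps | skin emissivity | 0.98 | – |
| q_met (tumor) | tumor metabolic source | 4.7e5 | W/m³ |
| omega_b (tumor) | tumor perfusion | 5e-4 | 1/s |
| spacing | default mesh size | 0.5 | mm |

The perfusion screening length `sqrt(k / (omega_b rho_b c_b))` is ≈ 36 mm at
the healthy default, comparable to the breast radius, so perfusion shapes
the baseline field but does not dominate it.

## Discretization

Cell-centred finite volumes on a uniform Cartesian grid, symmetric about
x = 0 so bilateral mirror images rasterize to exact x-flips.  A cell belongs
to a region iff its centre is inside the analytic shape; geometric accuracy
comes from refinement (boundary rasterization is first-order).  Fluxes use
the conservative 5-point stencil with harmonic-mean conductivity across
region interfaces; perfusion and sources are cell-lumped.  The base
Dirichlet condition is a half-cell face flux (conductance 2k per face).

The staircase skin boundary gets two corrections:

1. **Arc-length rescaling.**  Exposed staircase faces are scaled by
   (analytic arc length) / (staircase length) so the total exchange area is
   unbiased (the staircase overestimates the arc by up to 4/π).
2. **Series resistance to the true arc.**  Each skin cell exchanges heat
   with the environment through `1/(d/k + 1/(h_f + h_rad))`, where d is the
   radial gap between the cell centre and the analytic arc and `h_rad =
   sigma eps (T_s² + T_f²)(T_s + T_f)` is the secant linearization of the
   radiative term (exact through T_f).  The skin temperature T_s is
   recovered per cell by scalar Newton iteration.  This removes the O(h)
   position bias of lumping the boundary at staircase cell centres; it is
   what lets a 0.5 mm mesh match the closed-form disc solution to well
   under 1% of the centre excess.

The nonlinear radiation enters only through h_rad(T_s); a fixed-point outer
loop (linear solve → per-cell Newton update of T_s → reassemble the skin
diagonal) converges in 3–6 iterations at ~310 K.  Linear systems are solved
by sparse LU with two steps of iterative refinement; convergence is declared
when the relative nonlinear residual drops below `tol` (default 1e-8).  The
transient solver is backward Euler with the skin coefficient lagged one
step — unconditionally stable for the linearized system.  Everything is
deterministic: identical inputs give bit-identical outputs.

Degenerate inputs are rejected rather than coerced: tumors touching the
boundary, meshes coarser than R2/2, perfusion-free fully insulated systems
(singular), non-finite transient states (aborted with the step index).

## Surface statistic and inverse estimation

The diagnostic is `dT = max - min` of the temperature over the curved arc
only; the base is a boundary condition, not observable skin.  Corner cells
(theta near 0 and π) are part of the arc and are included.  Because they sit
half a cell away from the heated base, the tumor-free model already has
dT ≈ 13–14 °C — the arc maximum is pinned near T_core at the corners while
the apex, a full R1 away from the chest wall, is the coldest point.  Tumor
presence therefore expresses itself as an *increment* on this geometric
baseline, and for deep tumors the increment is negative (the tumor warms
the cold apex, shrinking max − min).  Simulated charts store the tumor-free
baseline per R1 so the presence flag can compare an observation against
baseline + margin (default 0.05 °C); the packaged reference charts tabulate
pure contrast and use baseline 0.

Inverse estimation is a discrete nearest-dT lookup within the R1 column of a
chart: no interpolation across R1 or dT (the published procedure is a table
lookup), ties break toward the smallest R2 (the convention recoverable from
the published worked examples, e.g. the 70 mm column of the (0, 10) chart
holds four 0.55 °C entries and the published answer is the smallest, 6 mm).
All tied candidates are returned.  Several published columns are
non-monotonic in R2, so the inverse map is genuinely non-unique between
entries; nearest-match with an explicit tie set is the honest behaviour.

## Tumor-contrast calibration

The forward model needs tumor `q_met`/`omega_b` values to produce any skin
contrast.  The defaults were fixed by a one-off calibration of the
magnitude of the simulated dT increment at the reference
scenario (R1 = 60 mm, R2 = 3 mm, tumor at (0, 10) mm, 0.5 mm mesh) to
0.5 °C — the centre of the 0.2–0.8 °C band the packaged charts span.  The
result, q_met ≈ 4.7e5 W/m³, is roughly an order of magnitude above measured
tumor metabolic rates.  That gap is informative: under this geometry and
parameter set, metabolic heat alone cannot produce tenth-of-a-degree skin
contrasts from a 3 mm tumor at 10 mm depth, so the packaged reference charts
are treated throughout as fixture data for the estimator, never as
forward-solver ground truth.  `calibrate_tumor_props` exposes the same
machinery to users: a deterministic grid scan plus Nelder-Mead refinement
(box-clipped, run in box-scaled coordinates) over `q_met` and/or `omega_b`
against any target chart.

## What the tests do and do not show

The suite verifies the solver against independent closed forms (uniform
source disc with Dirichlet rim; 1D perfused slab, both cross-checked by
dense `solve_bvp` integration), the structural physics of the discretization
(discrete maximum principle, energy balance to 0.1%, emissivity
monotonicity, exact bilateral mirror symmetry to 1e-10 K), mesh convergence
of dT across 1.0/0.5/0.25 mm spacings, exact-inverse behaviour of the
estimator over all 150 packaged entries, and recovery of a known synthetic
tumor source within 5% from a chart the solver generated.  Problem sizes in
the tests (R1 = 40–60 mm at 0.25–2 mm spacing, single-entry calibration
sweeps at 1 mm) were chosen to exercise every code path at desk scale.

None of this validates the model against real thermograms: the synthetic
charts inherit every idealization listed above, and passing tests show
internal consistency and numerical correctness, not clinical accuracy.

## Known limitations

- 2D geometry; no out-of-plane heat loss, no anatomical breast contour.
- The tumor-free baseline dT is dominated by the corner-to-apex gradient of
  the semicircle; real skin measurements would mask the region near the
  chest wall, which this package deliberately does not do (the arc is the
  declared observable).
- Presence detection is one-sided (observation must *exceed* baseline +
  margin), while deep tumors lower the arc dT under this model; a two-sided
  detector would be a behavioural change and is left to users via the
  stored baselines.
- Tumor position is an input family (one chart per position), not inferred;
  joint position/size inference from a single dT is out of scope.
- No uncertainty quantification on the estimate and no sensor noise model
  (`--seed` is reserved for that extension).
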