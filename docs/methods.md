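# Methods

## Model and assumptions

The tumor is a sphere of radius *R* (cm) with spatially uniform
transport properties, no functional intratumoral lymphatics, and
lymphatic drainage confined to the peri-tumoral rim. Transport of
liposome-sized particles (~80 nm, ~100 MDa) is convection-only:
transvascular and interstitial diffusion are negligible at this
molecular weight compared with pressure-driven flow.

**Pressure field.** Fluid filtration CFC·(p_e − p_i) balances Darcy
flow ∇·(−K∇p_i) at steady state, giving the closed-form profile
p_i(r) = p_e[1 − sinh(αx)/(x sinh α)], x = r/R, with
α = R√(CFC/K). The effective driving pressure p_e is set equal to the
microvascular pressure p_v: osmotic terms are omitted, consistent with
IFP approaching MVP at large α. An override is available
(`steady_state_ifp(..., p_e=...)`). The IFP is quasi-static: computed
once per parameter set, with R held fixed over the simulation.

**Solute transport.** ∂C_i/∂t = CFC(1−σ)(p_v − p_i)C_p(t) −
(1/r²)∂_r[r² r_F u C_i], with C_i the interstitial liposome (iodine)
concentration per unit tissue volume. The outer boundary is a pure
advective outflow; mass crossing r = R is tallied as peri-tumoral
lymphatic clearance. Measured tumor enhancement corresponds to
C_i + f_v·C_blood, where f_v is the plasma volume fraction.

In scaled coordinates the solution depends only on (CFC·(1−σ)·p_v, α,
r_F): R and K enter only through α and the products below.

## Parameters

| symbol | meaning | units | default / bounds |
| --- | --- | --- | --- |
| CFC (`cfc`) | capillary filtration coefficient L_pS/V | mmHg⁻¹ s⁻¹ | fit bounds [1e-7, 1e-4] |
| K (`k_int`) | interstitial hydraulic conductivity | cm² mmHg⁻¹ s⁻¹ | fit bounds [1e-8, 1e-5] |
| p_v | microvascular pressure (MVP) | mmHg | fit bounds [1, 60] |
| σ | filtration reflection coefficient | — | 0.9, fixed in fits |
| r_F | retardation coefficient | — | 1.0, fixed in fits |
| R | equivalent tumor radius | cm | measured (from volume) |
| α | R√(CFC/K) | — | physiological range 0.5–150 |
| Hct | arterial hematocrit | — | 0.40, configurable |

The fit bounds were chosen to keep α inside its physiological range for
tumors up to a few cm; σ and r_F are fixed because an average curve
cannot separate them from the remaining amplitude parameters.

## Numerics

- **Pressure:** all sinh ratios are evaluated in log-domain-stable form
  (e.g. sinh(αx)/sinh α = e^{α(x−1)}(1−e^{−2αx})/(1−e^{−2α})), so
  α = 150 and far beyond never overflow; r = 0 uses analytic limits
  (p_i(0) = p_e(1 − α/sinh α), u(0) = 0), and the velocity numerator is
  switched to its series y³/3 + y⁵/30 for αx < 0.05 to avoid
  cancellation. p_i(R) = 0 exactly.
- **Solver:** node-centered finite volumes on a uniform radial grid
  (default 201 nodes), first-order upwinding (flow is always outward),
  explicit Heun (SSP-RK2) stepping with Δt = 0.5 × the advective
  stability limit, capped at 0.25 h so the plasma decay stays resolved
  when advection is negligible. The influx/outflux ledgers use the same
  quadrature as the update, so mass conservation closes to round-off by
  construction; the independent check is against analytic quadrature of
  the source term (<1% on the default grid). The scheme preserves
  non-negativity for CFL-admissible steps; a negative concentration
  beyond round-off raises an error rather than being masked.
- **Volume averaging and shell masses** integrate the piecewise-linear
  nodal profile exactly (so a uniform field averages to itself and a
  linear profile gives 3/4 exactly).
- **Grid sizes used in practice:** simulations and synthetic-data
  generation use 201 nodes; optimization uses 101 nodes (the two agree
  to <1% in volume-averaged concentration for α up to 30; the
  replicate study below uses 61 nodes).
- **One-compartment plasma fit:** log-linear regression (exact on
  noiseless data), followed by a nonlinear least-squares refinement of
  c₀·2^(−t/t½) when more than two points are available.
- **Transport fit:** bounded trust-region least squares on
  (log₁₀CFC, log₁₀K, p_v) with a deterministic start set (box center
  plus scrambled Sobol points, seeded; 8 starts by default), winner
  chosen by (cost, parameters) so permuting starts cannot change the
  result. Unweighted SSE on concentration.
- **Confidence intervals:** linearized 95% intervals from an SVD of the
  residual Jacobian. Directions with singular values below 1e-6 of the
  largest are treated as unidentifiable: the affected parameters are
  flagged and given unbounded intervals instead of the numerically
  meaningless values a near-singular normal matrix would produce.
  Derived intervals (for α) use the delta method restricted to the
  identifiable subspace. Estimates at a box bound get one-sided,
  flagged intervals.

## Identifiability

The forward model is exactly invariant under
(CFC, K, p_v) → (λCFC, λK, p_v/λ): the source term is ∝ CFC·p_v, the
interstitial velocity ∝ K·p_v, and α depends only on CFC/K. An average
accumulation curve therefore determines α and the products CFC·p_v and
K·p_v, while p_v — and with it the peak-IFP prediction
p_v(1 − α/sinh α) — lies on an exactly flat ridge (verified to ~1e-16
relative in the solver). Fixing σ or r_F does not help; fixing any one
of CFC, K or p_v to an external measurement (via
`ParameterBounds(fixed=...)`) removes the ridge and makes the remaining
two unique. Fits with all three parameters free are still useful — they
recover α (the quantity that controls the accumulation regime) with a
finite interval — but the per-parameter intervals are reported as
unbounded, and a peak-IFP value from such a fit reflects an arbitrary
point on the ridge, not information in the data.

## Image-based pipeline

Baseline (pre-injection) HU is subtracted before applying the linear
calibration (50.1 HU per mgI cm⁻³ for mouse scans, 38.0 for rabbit);
aorta concentrations are converted to plasma by dividing by (1 − Hct).
f_v is the tumor/blood concentration ratio at the first post-injection
scan (5 min mice, 30 min rabbits), when liposomes are assumed
predominantly intravascular. That assumption is only approximate: the
model itself predicts a small interstitial concentration at the
calibration time, so the raw ratio over-subtracts. The pipeline fit
(`fit_imaging_series`) therefore (i) excludes the calibration sample
from the transport fit — after subtraction it is zero by construction —
and (ii) performs one model-based correction, removing the fitted
model's own C_i(t₁)/C_blood(t₁) from the ratio and refitting. Negative
post-subtraction concentrations are clipped to zero with a logged
warning. The equivalent radius is (3V/4π)^{1/3} of the mean contoured
volume.

## Synthetic data

Presets emulate the study structure of three tumor models: imaging
schedules (pre scan plus 5 min–144 h for the mouse models, the lung
model skipping the 1 h and 120 h scans; 30 min–336 h for the rabbit
model), plasma kinetics (c₀/t½ = 11.2/38, 8.0/35, 5.1/64 mgI cm⁻³/h),
calibration factors, and equivalent radii (0.41, 0.12, 1.1 cm). The
transport truths are not published; they were chosen once so that each
preset's peak IFP matches the mean value reported for its tumor type:
ME180-like α = 3, p_v = 6.71 (p_peak 4.70 mmHg); H520-like α = 2,
p_v = 6.46 (2.90 mmHg); VX2-like α = 8, p_v = 20 (19.9 mmHg), with
K values inside the fit bounds. Noise is multiplicative log-normal
(default SD 5%) on the post-injection HU enhancements — CT enhancement
noise at these levels is roughly proportional — applied with a fixed
seed; the pre-injection row stays at baseline. The generator produces
region-mean time series only: it does not emulate spatial heterogeneity
of vascularization, necrosis, partial-volume effects, contouring error
or tumor growth, so passing recovery tests demonstrates correctness of
the pipeline on data obeying the model's assumptions, not robustness to
real-tissue deviations from them.

## Regime behavior

Raising α drives central IFP toward MVP, suppresses interior
filtration, and concentrates delivery at the rim. Because the scaled
problem depends on α only through shape and clearance, the clean
monotone statements hold for the *attainable* accumulation: the peak of
the volume-averaged curve decreases strictly with α, and the outer-shell
mass fraction increases with α during the uptake phase (measured at
8 h), flipping the classification from uniform to peripheral just above
α = 3 (default shell 0.2, enrichment threshold 1.5× the uniform
baseline 1 − 0.8³ — a labelled package convention). At late, washout-
dominated times these orderings can invert: strong rim clearance strips
the periphery of high-α tumors while their interiors retain little, so
a 144 h snapshot is not a reliable regime indicator. Sweep horizons are
user-configurable (default 144 h, the last mouse imaging time) and the
sensitivity examples use 8 h when the regime question is the target.

## Replicate studies and test sizes

The interval-calibration study uses 50 replicates of 5% multiplicative
noise on an ME180-like curve, generated and fitted on the same 61-node
grid (so coverage reflects noise, not discretization bias) with a
2-start fit; the 95% interval for α is required to cover the generating
value at a rate within 80–100%. Noiseless self-fits use matched grids
and recover the identifiable quantities to <2%.

## Known limitations

- Uniform transport properties: no necrosis, perfusion heterogeneity,
  or spatially varying vascular density; non-spherical geometry is out
  of scope.
- Convection-only: not valid for small-molecule agents where diffusion
  competes.
- p_v is structurally unidentifiable from average accumulation curves
  (see above); peak-IFP predictions require one externally fixed
  parameter.
- The quasi-static IFP and fixed R ignore tumor growth over the
  imaging window (relevant for fast-growing large tumors).
- First-order upwinding is diffusive; sharp internal concentration
  fronts are smoothed, though volume-averaged quantities converge to
  <1% on the default grid.
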