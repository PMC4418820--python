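# Methods

## Model

Drug amounts in blood, peripheral tissue and tumor evolve under the linear
system

```
dN_bl/dt = -(k_el + k_epr + k_p) N_bl + k_d N_p + k_b N_t
dN_p /dt =   k_p N_bl - k_d N_p
dN_t /dt =   k_epr N_bl - k_b N_t
```

with all rate constants first-order and nonnegative. Assumptions inherited
from this structure:

- every compartment is well mixed; there is a single, homogeneous tumor
  compartment (no core/periphery distinction, no interstitial-pressure
  physics);
- extravasation is proportional to the blood amount and intravasation to the
  tumor amount; nothing is assumed about the fate of drug after
  extravasation (diffusion, binding, cellular uptake are all folded into
  k_b);
- disposition is linear — no saturable clearance or uptake, single bolus
  dose (no multi-dose superposition).

Internal units are fixed: hours, milligrams, h⁻¹, litres. Concentrations are
converted to amounts at the boundary with the blood volume (default 5 L),
and doses per body surface area with the BSA (default 1.8 m²).

### Mapping from biexponential fits

Clinical blood curves reported as `N_bl = A e^(-αt) + B e^(-βt)` map onto the
closed two-compartment system via `k_21 = (βA + αB)/(A + B)`,
`k_10 = αβ/k_21`, `k_12 = α + β − k_21 − k_10`. The construction
canonicalizes α ≥ β (the algebra is not symmetric under relabelling); the
degenerate α = β is accepted and yields k_12 = 0, a one-compartment system.
A negative implied k_12 means the parameters are not realizable by the model
and is rejected with a diagnostic rather than clipped.

When a fit is imported, k_el is set equal to k_10 and k_epr is added on top.
Total blood elimination during simulation is then k_el + k_epr, slightly
exceeding the fitted k_10; the alternative (k_el = k_10 − k_epr) would keep
the total exact but make k_el depend on the sweep variable. The
approximation is excellent in the regime of interest (k_epr/k_el ≤ 0.1) and
its blood-curve consequence is measurable with `detectability_delta` (<1%
perturbation at ratio 10⁻³ over 10 days).

The inverse mapping (rate constants → A, B, α, β) exists for the closed
system only and is used as a round-trip oracle. α is the large root of
`x² − (k_p+k_d+k_10)x + k_d k_10`; β is computed as the Vieta product
`k_d k_10 / α` and each amplitude directly as
`A = n0(α − k_d)/(α − β)`, `B = n0(k_d − β)/(α − β)` — both choices avoid
catastrophic cancellation at large rate-scale separation and keep the
round-trip exact to ~1e-12 relative across rates spanning 10⁻⁴–10² h⁻¹.

## Solvers and numerical choices

- Reference back-end: eigen-decomposition of the 3×3 rate matrix,
  `N(t) = V e^(Λt) V⁻¹ N(0)`, exact up to linear algebra roundoff. If the
  matrix is nearly defective (eigenvalue gap < 10⁻¹² h⁻¹ or eigenvector
  condition number > 10¹²) the solver falls back to a dense matrix
  exponential per grid point — repeated eigenvalues occur on measure-zero
  parameter sets but must not crash a sweep.
- Numerical back-end: LSODA (stiffness-switching) at rtol 10⁻⁹,
  atol 10⁻¹² mg, retained as an independent cross-check and for future
  nonlinear rate laws. The suite requires 10⁻⁶ relative agreement between
  back-ends over random rate sets spanning 10⁻⁴–10² h⁻¹.
- Dissipation check: the rate-matrix column sums are (−k_el, 0, 0), so
  `d(N_bl+N_p+N_t)/dt + k_el N_bl = 0` identically. The residual is
  evaluated analytically (M·N) for closed-form trajectories and by finite
  differences for integrated ones, with contract
  max|residual| ≤ 10⁻⁶ × initial amount × max rate.
- Time grids: geometric by default (first point 0, then 10⁻³ h to t_end,
  400 points), resolving both the ~3.6 min distribution half-time of free
  doxorubicin and the multi-day tail of the liposomal formulation. Default
  horizons: 240 h (liposomal), 48 h (free drug).
- Sweep metrics: t_max is refined by quadratic interpolation through the
  three grid points around the maximum (geometric grids are coarse near late
  maxima); `net_loss_onset` is the first grid time where the ODE right-hand
  side k_epr N_bl − k_b N_t is negative — computed exactly, not by
  differencing.
- Solver roundoff can produce amounts of order −10⁻¹⁵; values above
  −10⁻⁹ × scale are clipped to zero, anything below that raises.

## Tumor-uptake analysis

Sweeps cover k_epr/k_el ∈ {0, 10⁻¹, 10⁻², 10⁻³, 10⁻⁴} and
k_b/k_epr ∈ {0, 10, 100, 1000} by default, spanning leaky xenograft-like
tumors down to weakly permeable human tumors. Useful closed forms:

- with k_b = 0, the tumor fraction of the initial blood amount converges to
  the branching probability `k_epr/(k_el + k_epr)` (every molecule exits
  blood through one of the two absorbing routes; the peripheral compartment
  only delays). At k_epr/k_el = 0.1 this is 1/11 = 9.09%; the 240 h horizon
  samples 8.92%, ~98% of the plateau, which is reached to three digits only
  after ~500 h.
- for k_epr ≪ k_el the tumor amount is linear in k_epr at every fixed time
  (first-order perturbation), hence the log-log slope-1 scaling of uptake
  versus leakiness ratio verified in the tests.
- %ID is quoted against the simulated initial blood amount A + B by default
  (95.5 mg for the liposomal set). The nominal dose (dose/m² × BSA = 90 mg,
  or a configured 100 mg) can be set via `id_denominator_mg`; the default
  keeps %ID internally consistent with the simulated trajectories.

## Per-segment microdosimetry

Vessel arithmetic is exact unit conversion: 1 cm³ × 150 mm/mm³ = 150 m of
vessel = 1.5 × 10⁶ segments of 100 µm. The per-segment rate divides
`k_epr N_bl − k_b N_t` (mg/h) by the segment count after converting to
particles with Avogadro's number, the molar mass and the carrier payload.
All conversion factors live in one table (`units.py`) so the flux numbers
are pure arithmetic on ODE outputs.

Defaults that matter (all configurable):

- doxorubicin molar mass 543.52 g/mol (free base, not the HCl salt);
- payload 15,000 molecules per liposome, the top of the reported
  10,000–15,000 range;
- "first-hour rate" means the time-average of the instantaneous rate over
  [0, 1] h on a fine linear grid (721 points, trapezoid rule), not the t = 0
  value. The instantaneous t = 0 rate is ~30 liposomes/s at these defaults;
  the hour average is ~28. These three conventions are one consistent
  reconstruction of an underdetermined set (the sources do not pin down
  payload, salt form, or averaging), and they are flagged as such here.

## Fitting and synthetic data

The fit minimizes squared log residuals of the biexponential model —
amounts span orders of magnitude over a sampling window, so raw residuals
would let the early phase dominate. Parameters are optimized in log space
(positivity without bounds) with Levenberg–Marquardt; initialization is
deterministic curve peeling (terminal slope on the last third of points
gives B, β; the peeled remainder gives A, α), so fits are reproducible
without seeds. Guards: at least 5 samples whose times span a factor of 5.
Collapse to a mono-exponential (α/β < 1.05 or a vanishing amplitude) is
flagged `degenerate`, not an error. The covariance proxy is
`s²(JᵀJ)⁻¹` in log-parameter space — a local curvature estimate, not a
rigorous confidence region.

The synthetic generator multiplies the true curve by mean-one lognormal
noise (σ² = ln(1 + CV²), µ = −σ²/2), emulating the positivity and roughly
constant relative error of plasma assays. Defaults emulate the reference
clinical cohort: 14 subjects, 12 geometric sampling times over
0.1–240 h, CV 10%, seed 20150504. What it does *not* emulate: between-subject
parameter variability (all subjects share one true curve; noise is purely
residual), below-quantification censoring, and correlated assay drift. A
passing recovery study therefore shows the estimator is unbiased and
noise-stable, not that it handles population heterogeneity — a mixed-effects
model would be the tool for that, and is out of scope.

Parameter-recovery study (in the test suite): 200 replicates of a pooled
14-subject cohort at CV 10%; median recovered k_10 error is required < 10%,
and the noiseless fit is exact to 10⁻⁶ relative.

## Problem sizes

Default runs use 400-point grids per trajectory, 16–20 cell sweeps, 721-point
averaging windows, and 200-replicate recovery studies; the full suite and the
reproduction script each run in a few seconds on one core. These sizes were
chosen as the smallest that leave every reported quantity grid-converged
(halving any of them changes no reported digit at the precision quoted).

## Known limitations

- Single homogeneous tumor compartment: spatial heterogeneity of leakiness
  and vascular density, core/periphery gradients and interstitial pressure
  are all outside the model; k_epr and k_b are effective whole-tumor
  constants.
- k_el = k_10 import convention slightly double-counts elimination when
  k_epr is large (ratio ~0.1); acceptable for the regimes studied, wrong if
  someone pushes k_epr/k_el toward 1.
- The asymptotic tumor fraction has no finite closed form for k_b > 0 (the
  tumor empties as t → ∞); metrics there are horizon-dependent, and the
  interior maximum of the k_b/k_epr = 10 case appears only on horizons
  beyond the default 240 h.
- Biexponential (two-compartment) disposition only; three-exponential or
  saturable kinetics are non-goals.
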