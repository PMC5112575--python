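# Methods

## Governing equation and discretisation

The forward model integrates the head-based Richards equation in one
vertical dimension with a root-uptake sink,

    c(h) ∂h/∂t = ∂/∂z [ K ∂h/∂z ] − ∂K/∂z − S(z, t),

with z in metres positive downward (surface at 0), pressure head h in
metres of water, conductivity K in m/s, soil water capacity c = dθ/dh, and
S the volumetric uptake rate (1/s). The minus sign on ∂K/∂z follows from
the downward-positive axis: gravity head decreases in the direction of
increasing z.

Space is discretised on a uniform block-centered grid: nz blocks of
thickness Δz, state (h, θ) at block centres z_i = (i − ½)Δz,
conductivities and Darcy fluxes at block edges. Interface conductivity is
the arithmetic mean of the adjacent block values by default (geometric
selectable via `kmean`); the bottom interface carries the bottom block's
own conductivity because the lower boundary is a unit hydraulic gradient
(gravity drainage, J_bottom = K_nz).

Time integration is non-iterative and implicit in h only: capacities and
conductivities are evaluated at the old time, giving one tridiagonal
system per step,

    A_i h*_{i−1} + B_i h*_i + C_i h*_{i+1} = D_i,   A_1 = C_nz = 0,

solved by the Thomas algorithm (hand-written; the test suite checks it
against a dense solve on random diagonally dominant systems to 1e-10).
For internal blocks A_i = −K_{i−½}/Δz², C_i = −K_{i+½}/Δz²,
B_i = c_i/Δt + (K_{i−½}+K_{i+½})/Δz², and
D_i = c_i h_i/Δt − (K_{i+½}−K_{i−½})/Δz − S_i. Only D changes between the
boundary variants: under a prescribed surface head the extra
K_½ h(0,t)/Δz² term uses a full-Δz spacing from the surface value to the
first block centre; under a prescribed surface flux the flux is *withheld*
from the matrix pass entirely (see next section). The sink is explicit
(old-time heads), consistent with the old-time treatment of every
non-differentiated variable.

## The flux-update step

Each step proceeds in three stages:

1. assemble with old-time K and c, surface flux withheld, and solve for
   the trial heads h*;
2. re-evaluate block conductivities at h*, form interface Darcy fluxes
   J_{i+½} = −K_{i+½}(h*_{i+1} − h*_i)/Δz + K_{i+½} (the +K term is
   gravity with z positive downward), re-introduce the withheld surface
   flux as J_½, set J_{nz+½} = K_nz, and update
   θ*_i = θ_i − Δt (J_{i+½} − J_{i−½})/Δz − Δt S_i.
   This telescopes exactly: column storage change equals net boundary flux
   minus total uptake, to machine precision;
3. accept θ*_i only if block i and its immediate neighbours are
   unsaturated (θ < θ_s − 10⁻⁹, a float-safe version of the binary test);
   accepted blocks get h from the retention curve at θ*, rejected blocks
   keep h* and recompute θ from the retention curve at h*.

Design choices in stage 3 where the scheme is underdetermined:

* the surface counts as a saturated upper neighbour only under a head
  boundary with h(0,t) ≥ 0 (ponded). Under a flux boundary the surface
  block's own saturation is what triggers rejection, which produces the
  same observable behaviour without a separate ponding detector;
* the bottom block's lower neighbour is the block itself;
* a trial θ at or below θ_r + 10⁻⁷ (evaporative or uptake overdraw, not
  covered by the three-bullet scheme) also takes the rejection branch.
  Stage-2 evaporation limiting makes this rare.

Rejection is the only place the scheme loses exact mass balance; the
ledger's PCTDIF statistic (below) surfaces exactly that loss.

Two numerical safeguards: the capacity entering the matrix is floored at
10⁻⁸ 1/m — a tiny specific-storage term, without which a fully saturated
region (c = 0 everywhere, flux boundary withheld) makes the matrix
singular — and a step that produces non-finite values is retried at half
Δt, recursively, up to 12 halvings. The base step defaults to Δt = 300 s
(600 s in the reduced test scenario); daily forcing is held piecewise
constant while the surface flux and the sink are refreshed every sub-step
from the evolving state.

## Soil hydraulics

Per layer, either van Genuchten retention with Mualem conductivity
(θ_r, θ_s, α [1/m], n, K_s; m = 1 − 1/n, connectivity exponent 0.5) or
tabulated (h, θ) and (θ, K) curves with linear interpolation and flat
extrapolation beyond the end nodes — the latter mirrors the
measured-curve-from-file workflow of the historical Fortran lineage, the
former is the smooth default for synthetic work. Saturation is h ≥ 0 with
θ clamped to θ_s and c = 0. Retention inversion round-trips to 1e-8
relative; the analytic capacity matches a central finite difference to
1e-4 relative (both property-tested).

## Surface partition and evaporation

Daily potential evapotranspiration ET0 splits by canopy light
interception: T_p = ET0 (1 − e^(−k_ext·LAI)), E_p = ET0 − T_p, with
k_ext = 0.5 by default. Actual evaporation is the minimum of E_p and the
exfiltration capacity of the surface block — the upward Darcy flux it can
sustain toward an air-dry surface head (default −1000 m) across one block
spacing, using its current conductivity. The net surface flux is
(rain − E_actual)/86 400 000 m/s, positive downward. Air temperature and
relative humidity are parsed and carried for file fidelity but enter no
formula; computing ET0 from raw meteorology is out of scope.

## Root uptake

The trapezoidal stress factor α(h) is zero at and above the anaerobiosis
head h₁ (default −0.1 m) and at and below the wilting head h₄ (default
−150 m), one on [h₃, h₂] (h₂ default −0.25 m), linear between. h₁, h₂ and
h₄ defaults are conventional values, exposed in configuration; only h₃
is dynamic: h₃ = a T_p + h₃₁ − a T_p1 with a = (h₃₁ − h₃₂)/(T_p1 − T_p2),
anchored at T_p1 = 1 and T_p2 = 5 mm/day, clamped to [h₃₁, h₃₂] outside
the anchor range so extreme transpiration cannot push h₃ past h₂ or h₄.
The three (h₃₁, h₃₂) option sets are (−11, −5), (−14, −8) and
(−16, −10) m (IHTH = 1, 2, 3).

Root depth grows linearly from a seed depth l0 (default one block) at day
JTHAW to Z_r at day JMATUR — the growth function between those days is not
prescribed by the uptake models themselves; linear is the simplest
defensible choice — and is capped at the profile depth.

The three sink models share the 86 400 000 factor (86 400 s/day ×
1000 mm/m) converting mm/day per metre of soil into 1/s:

* ICPS = 1: S_i = α_i T_p (β+1)(1 − z_i/L)^β / (86 400 000 L) for
  z_i ≤ L. The normalised density integrates to one analytically; the
  block-centre (midpoint-rule) sum converges to it at second order in Δz
  (0.06% at Δz = L/20 for β = 2).
* ICPS = 3: the cubic density L_nrd(z_r) = R₁ + R₂ z_r + R₃ z_r² + R₄ z_r³
  (z_r = z/L) gives weights w_i = L_nrd(z_i/L)Δz; T_p is allocated
  proportionally and scaled by α_i. The allocation rule itself (the
  density's conversion into an uptake profile) is this package's
  construction, mirroring the structure of model 1; with α ≡ 1 the total
  equals T_p exactly by discrete normalisation. Negative polynomial values
  (possible for user coefficients; the defaults stay positive on [0, 1])
  are floored at zero before normalising — a density cannot be negative.
* ICPS = 2: compensatory uptake
  S_i = α_i² L_nrd,i^λ T_p / (Δz Σ_j α_j L_nrd,j^λ), λ ∈ [0.01, 2.0]
  (enforced by validation). Algebraic identities tested against a direct-
  summation oracle: total/T_p = Σα²L^λ / ΣαL^λ ∈ [min α, max α]; uniform
  α = a gives exactly a·T_p; binary wet/dry stress gives exactly T_p
  (full compensation). An all-stressed profile yields a zero sink flagged
  `fully_stressed`, not an exception.

Total uptake never exceeds T_p; uptake is identically zero below the
current root depth. `compute_sink` refreshes h₃ from T_p and the root
depth from the calendar before dispatching; it returns a zero profile when
no block centre lies inside the root zone (earliest season on a coarse
grid) rather than erroring.

## Water-balance ledger

All terms in mm of water. WADD integrates the applied net surface flux;
WBELOW integrates bottom drainage; C_AEVA and C_ATRA accumulate actual
evaporation and transpiration; BIGI is the infiltration implied by the
profile budget, Δstorage + WBELOW + C_ATRA. Because the mass-balance
update telescopes, BIGI ≡ WADD whenever every trial θ was accepted, and
PCTDIF = (BIGI − WADD)/WADD × 100 measures exactly the mass defect of
rejection steps (reported as 0 while |WADD| < 10⁻⁹ mm). On the standard
111-day synthetic run PCTDIF is at rounding level (no rejections occur);
the acceptance suite requires |PCTDIF| < 1%.

## Parameter search

One independent forward simulation per (β, Z_r) lattice point — cells
share no state, so the sweep is order-invariant and trivially parallel.
Default lattice: β = 0.5 + 0.25k (16 values, to 4.25) and
Z_r = 0.75 + 0.05k m (22 values, to 1.80 m), 352 runs. Score: ARD, the
mean over all (day, depth) observations of |θ_sim − θ_obs|/θ_obs — a
pooled mean over days and depths (averaging per-day first was the
plausible alternative; pooling is the most literal reading of "average
relative discrepancy" and is what `ard_score` implements). Observed
depths map to the nearest block centre; days must match a simulated day
exactly; non-positive observations are rejected. A failed cell records a
NaN sentinel plus a diagnostic instead of aborting the sweep. The fitted
estimate is the ARD-minimising cell; because the estimator is an
exhaustive search, `RootZoneResults` reports uncertainty as the set of
near-optimal cells (ARD within 10% of the minimum by default) rather than
standard errors.

## Synthetic scenarios: what they emulate, and what they do not

The fixture generator builds a homogeneous loam-like profile
(van Genuchten θ_r = 0.05, θ_s = 0.45, α = 2 1/m, n = 1.8,
K_s = 10⁻⁶ m/s — fixture conventions), a uniform initial water content of
0.32, and a deterministic weather table: ET0 = 4 mm/day with a 15%
30-day sinusoidal modulation, 16 mm rain pulses every 8 days, LAI ramping
0.1 → 2.5 over the growth window (JTHAW = 134, JMATUR = 180). The
standard window is 111 days starting day 134; the truth root parameters
are β = 2, Z_r = 1 m (both on the default search lattice). "Measured"
observations are the truth run's water contents at planned (day, depth)
points times (1 + ε), ε ~ N(0, sd) with a fixed seed; sd = 0 gives exact
observations.

The reduced scenario used by the fast sweeps shortens the window to 54
days, coarsens the grid to 20 blocks of 0.1 m and the step to 600 s, pulls
root maturity to day 154 so the post-maturity drydown falls inside the
window, and observes daily at eight depths from day 140 — the measurement
mode of a logging sensor profile. This design matters: β and Z_r trade off
along a valley of the ARD surface (a deep, top-heavy root system mimics a
shallow, uniform one), and root depth is informative only once roots are
mature and the profile is drying. Sparse observation plans leave that
valley unresolved at 2% observation noise. With the daily plan, the 8 × 8
reduced-lattice recovery experiment returns the exact truth cell in all
20 seeded noisy replicates (the acceptance requirement is within one
lattice step in ≥ 90%).

What passing these tests does *not* show about field data: the generator
has no layer heterogeneity or hysteresis, no interception or snow, no
measurement-depth mismatch, its forcing is piecewise-daily and noise-free,
and — most importantly — the "measurements" are produced by the same
forward model that the search runs, so structural model error is absent by
construction. Real applications should expect a broader near-optimal set
and a biased β–Z_r trade-off when the soil description is imperfect.

## Numerical sizes used by the shipped experiments

Chosen as the package's standard problem sizes: standard scenario 40
blocks × 0.05 m, Δt = 300 s, 111 days; reduced scenario 20 blocks × 0.1 m,
Δt = 600 s, 54 days; recovery lattice 8 × 8 (β 0.5…4.0 step 0.5,
Z_r 0.4…1.8 m step 0.2 m). Halving Δz and Δt changes cumulative
infiltration by well under 2% on the reduced scenario (consistency, not
formal order, is what the scheme offers — the old-time-K linearisation is
first-order in time).

## Known limitations

Non-iterative old-time-K stepping needs small steps near sharp fronts
(mitigated by automatic step halving); no 2-D/3-D flow, vapour flow,
preferential flow, freezing, osmotic stress, or root hydraulic
architecture; evaporation and ET-partition formulas are declared
substitutes for site-calibrated ones; the historical Fortran byte formats
are replaced by documented plain-text dialects.
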