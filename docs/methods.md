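# Methods

## Model

The tumor is modeled as an incompressible, spherically symmetric continuum
of constant cell density, fed by a diffusible substrate (oxygen/nutrients)
whose capillary source is uniform but insufficient. At quasi-steady state
the substrate concentration inside a tumor of dimensionless radius R
(length unit: the oxygen diffusion length L_D) solves the diffusion–uptake
balance and has the closed form

    sigma(r) = (R / sinh R) · sinh(r)/r,        sigma(R) = 1,

so the core is substrate-starved for large R (sigma(0) ≈ 2R·e^−R).
Proliferation is proportional to local substrate, apoptosis is uniform, and
mass balance plus Darcy-type cell motion reduce, for a sphere, to a single
ODE for the boundary radius in G-scaled time τ′ = |G|·t:

    dR/dτ′ = s · [ −A·R/3 + coth R − 1/R ],     s = sign(G),

with two dimensionless groups:

* **A = (λ_A/λ_M − B)/(1 − B)** — apoptosis strength relative to the
  vascular supply surplus;
* **B = [λ_B/(λ+λ_B)] · σ_B/σ∞** — vascularization: substrate transfer
  from vasculature relative to cellular uptake, times the
  capillary-to-tissue concentration ratio;
* **G = λ_M(1 − B)/λ_R** — mitosis over tissue relaxation (cell
  mobility/adhesion). Only sign(G) = sign(1 − B) affects the radial
  dynamics; |G| rescales time and is never fixed numerically here.

Velocity asymptotics: dR/dτ′ → R(1 − A)/3 as R → 0 and → 1 − A·R/3 as
R → ∞. Hence for 0 < A < 1 there is a unique stationary radius R∞
(**low-vascularization regime**, B < λ_A/λ_M < 1: growth arrested by
diffusion); for A ≤ 0 growth is unbounded — linear (velocity → 1·G) at
A = 0 and exponential with relative rate |A|/3 for A < 0 (**moderate**,
λ_A/λ_M ≤ B < 1); for B > 1 the flow reverses (**high**, G < 0). The tie
A = 0 is classified moderate (the inclusive A ≤ 0 branch). B = 1 is a
degenerate boundary (G = 0, A undefined) and is rejected explicitly.

For A < 0 the large-R velocity magnitude is |A|·G·R/3 with *growth*: the
implementation keeps the sign convention that negative A accelerates
expansion.

## Calibration

Monolayer kinetics are exponential over the exposure window T:
N_C = N_I·e^{λ_M T} for untreated control and N(d) = N_I·e^{(λ_M−λ_A)T}
under dose d, giving λ_M = ln(N_C/N_I)/T and λ_A = −ln(f)/T from the viable
fraction f = N(d)/N_C. Rates are treated as constants for a given cell line
and condition over the treatment window (an optimal-exposure
approximation — no pharmacokinetic decay of the drug is modeled).
Replicates are aggregated by the arithmetic mean of fractions; replicate
fractions above 1 are clipped to 1 with a warning since λ_A ≥ 0 by
definition; a delta-method standard error is attached for reporting but
not propagated into the model.

## Vascularization chain

Only the composite transfer fraction λ_B/(λ+λ_B) is identifiable from the
data used, so it is the exposed parameter (0.5 when supply balances
uptake). Defaults: σ_B = 40 mmHg (capillary PO₂), σ∞ = 8 mmHg (tissue),
giving B = 2.5 in normal tissue. Tumor B is the normal-tissue value scaled
by the tumor/normal microvessel-density ratio, computed from unrounded ROI
means; the chain 2.5 × (0.27/1.56) = 0.433 is reported at two decimals
(0.43), and the pipeline's parameter table uses the two-decimal value —
matching the reporting convention of the source analysis
(`b_decimals=None` disables this). ROI-level spread is reported as a
sample sd; B is a point estimate, with an optional first-order
delta-method sd provided as an extension.

## Unit conversions

Radius ↔ cell number uses N = φ·(R/r_cell)³ with packing fraction
φ = 0.761 and cell radii 9 µm (MiaPaCa-2) / 7 µm (S2-VP10). The same φ is
applied to the 2-D ROI count estimate and the 3-D volume conversion — an
approximation bracketed by circle packing (0.813) and random sphere packing
(0.74) references. Bioluminescent signal is linear in cell number with zero
intercept; the constant `signal_per_cell` has no published value and is a
required calibration input (default 100 photons/s per cell in the
generator — an arbitrary linear constant that cancels in every round
trip). Constant-exposure AUC uses the gemcitabine free-base molecular
weight 263.2 g/mol (the HCl salt, 299.7, is configurable but is not the
default because the free base reproduces the reported in-vitro exposure of
1.90 µg·hr/mL at 300 nM × 24 h). The nM → mg/kg bolus equivalent is the
standard molarity × plasma-volume conversion (1.2 mL plasma, 20 g mouse).

## Numerical choices

* Boundary velocity: below R = 10⁻³ the series R(1−A)/3 − R³/45 replaces
  coth R − 1/R (catastrophic cancellation; the two agree to 1e−10 at the
  switchover). The nutrient profile is evaluated via expm1/exp-shifted
  ratios so it neither overflows nor loses precision for large R.
* Stationary radius: Brent's method on a bracket grown geometrically from
  R = 1 (the velocity is provably positive at small R and negative at
  large R for 0 < A < 1); relative tolerance 1e−12.
* Trajectories: RK45 with rtol 1e−10 / atol 1e−12; integration terminates
  (flagged, with the event time recorded) if R falls below the extinction
  radius, default 1e−6 dimensionless.
* Gompertz fits: bounded nonlinear least squares on the radius scale with
  uniform weights (matching how such series are presented), start values
  a₀ = 1.05·max(r), c₀ from the slope of log(log(a₀/r)) vs t, b₀ from its
  intercept. Fits with rate or displacement pinned at ~0 are flagged
  non-converged (constant series make c unidentifiable) rather than raised.
  The growth delay is t_alt(r*) − t_ref(r*) via the closed-form inverse
  t(r) = −ln(ln(a/r)/b)/c; the default reference radius r* is the midpoint
  between the fitted initial radius and the smaller asymptote, chosen
  because a pure time shift then yields the shift exactly and the statistic
  is insensitive to r* in that case.

## Dimensionalization

Neither |G| nor L_D is fixed by the inputs; all dynamics are reported in
G-scaled time and L_D-scaled radius. For presentation an optional
L_D = 200 µm (a conventional oxygen diffusion length) converts R to mm,
and the default treatment-start radius 1.5 mm maps to R₀ = 7.5. Note that
whether the one growth-arrested condition (S2-VP10 at 300 nM, R∞ ≈ 13.5)
starts above R∞ (slight regression) or below it (bounded growth) depends
on L_D: at 200 µm it grows to its stationary radius; regression would
require L_D ≲ 110 µm. The arrested-vs-unbounded contrast between
conditions does not depend on this choice.

## Synthetic data

The generator emulates the three input kinds at the study's design points:
viability assays (2000 cells/well seeded, doses 0/3/30/300 nM, T = 1 day,
n = 4 replicates, 5% lognormal viability CV), histology ROI tables (true
area fractions 1.56% normal / 0.27% tumor, 10 ROIs, CV 0.6 — the reported
ROI spreads correspond to CVs of ~0.6–1.0), and weekly bioluminescence
series over 50 days from either a Gompertz path (a = 3.5 mm, b = 2,
c = 0.05/day) or an integrated model trajectory, with 10% signal CV.
Noise is multiplicative, mean-one lognormal throughout: the three
measurements are positive and right-skewed, and mean-one factors make the
zero-CV limit exactly the noise-free model, which is what the round-trip
tests exploit. One global seed is fanned into fixed per-generator
substreams so adding a generator never shifts another's draws.

What the generator does **not** emulate: plate-position and batch effects
in viability assays, spatial correlation of vessels within a slide,
imaging-depth attenuation or scattering of bioluminescence, inter-animal
heterogeneity, and attrition. Passing recovery tests therefore demonstrate
correctness of the inference chain under the stated noise model, not
robustness to these real-data artifacts.

## Known limitations

* The three-regime classification and trajectory integration assume a
  compact sphere; shape instabilities, the pressure/curvature field and
  full 3-D dynamics are out of scope.
* Rates calibrated from one 24 h monolayer exposure are extrapolated as
  constants over weeks of simulated growth.
* B folds all vascular geometry into one scalar; MVD is a crude proxy for
  perfusion.
* The published per-condition table has one internally inconsistent row
  (MiaPaCa-2 at 300 nM: its ratio cell disagrees with its own rate cells);
  the rate-derived value is used and the discrepancy is surfaced in tests
  rather than patched.
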