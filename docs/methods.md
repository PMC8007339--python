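# Methods

This note documents the models implemented in `extempore-be`, the defaults
they ship with, why those defaults were chosen, and what the package's
tests do and do not demonstrate.

## Scope

The package reproduces the computational workflow for assessing an
extemporaneously compounded oral suspension against its source tablet:
in-vitro dissolution comparison, mechanistic oral-absorption simulation
coupled to compartmental disposition, non-compartmental analysis,
percent-prediction-error verification against observed tablet
pharmacokinetics, Monte-Carlo virtual bioequivalence, and the supporting
compounding/stability/rheology arithmetic. The bundled worked example is
an amlodipine/valsartan 5/80 mg suspension compounded from fixed-dose
combination tablets.

## Dissolution comparison (f1/f2)

f1 and f2 are computed on the timepoints common to both profiles; when
sampling schedules differ the caller interpolates first
(`interpolate_profile` is monotone piecewise-linear, anchored at (0, 0)
— dissolution starts at dosing — and holds the last observed value beyond
the final sample). The regulatory convention of dropping timepoints after
both profiles exceed 85% is available behind `drop_after_85` but is **off
by default**: the plain formulas are the primary definition here, and the
bundled two-timepoint data leave nothing to drop. Percentages above 100
(assay variability; the bundled table contains values up to 104.4%) are
accepted in profiles and clamped to 100 only when converted to released
mass.

The verdict rule is: similar iff f2 > 50 and f1 ≤ 15; when the two
criteria disagree (f2 > 50 but f1 > 15) the result is flagged
`indeterminate` rather than silently resolved.

## pH-dependent solubility

Solubility scales with the Henderson–Hasselbalch total/neutral ratio
HH(pH) — `1 + 10^(pKa−pH)` for a monoprotic base, `1 + 10^(pH−pKa1) +
10^(2pH−pKa1−pKa2)` for a diprotic acid — applied to an intrinsic
solubility back-calculated from the reference point: `S0 =
S_ref/min(HH(ref_pH), sr_max)`, `S(pH) = S0·min(HH(pH), sr_max)`. The cap
`sr_max = 1000` (configurable) reflects the roughly 1000-fold
solubilization reported for valsartan between pH 4 and 6; without it the
diprotic-acid form extrapolates to a physically absurd intrinsic
solubility (~10⁻⁵ mg/mL) from the pH 8 reference value. The construction
guarantees `S(ref_pH) = S_ref` exactly and monotone behaviour on each side
of the cap.

pKa species assignments in the bundled records are amlodipine: one basic
site (8.7); valsartan: two acidic sites (3.9, 4.73).

## Absorption model

### Structure

Nine well-mixed GI compartments in series; drug exists per compartment as
undissolved solid, dissolved drug, and precipitated solid. Processes:

* **Transit** — first-order, rate 1/(transit time); all three species move
  with luminal contents; outflow from the ascending colon is unabsorbed
  loss.
* **Dissolution** — mechanistic mode: the Johnson/Nernst–Brunner law,
  rate = 3D/(ρ·r·h) · M · max(S_local − C_local, 0), with diffusion-layer
  thickness h = min(r, 30 µm) and a monodisperse particle radius shrinking
  as r = r₀·(M/M₀)^(1/3) (M₀ = dose; transit mixing makes a per-particle
  radius ill-defined, and for the bundled drugs dissolution is not
  rate-limiting, so this approximation is benign). Default r₀ = 25 µm
  (crushed-tablet powder). Tabulated mode: a compartment-local fractional
  release rate k(t) = F′(t)/(1 − F(t)) derived from the in-vitro profile
  whose medium pH is nearest the compartment pH (only pH 1.2, 4.5 and 6.8
  were measured; nearest-neighbour avoids inventing profiles). The release
  clock is time since dosing. When the profile has reached 100%, solid
  arriving later dissolves at a fast first-order rate (1000/h); when the
  in-vitro window ends with release incomplete, the model falls back to
  the mechanistic law — the data are simply uninformative beyond the last
  sample, and holding the plateau would strand solid forever.
* **Precipitation** — supersaturated excess (C > S) precipitates
  first-order with the mean precipitation time (default 900 s);
  precipitate re-dissolves like solid.
* **Absorption** — first-order on dissolved mass,
  kₐ,ₙ = (2·P_eff/rₙ)·ASFₙ·(drug absorption scale), from absorbing
  compartments only.

The system is integrated with LSODA at rtol 1e−8 / atol 1e−10 mg (dense
output every 0.05 h by default); mass balance is checked at every output
step against a 10⁻⁶·dose tolerance, and the cumulative absorbed mass
differentiates into the systemic input rate for the PK stage.

### Default fasted physiology

| segment | volume mL | pH | transit h | radius cm | ASF |
|---|---|---|---|---|---|
| stomach | 50 | 1.3 | 0.25 | 10.0 | 0 |
| duodenum | 42 | 6.0 | 0.26 | 1.60 | 1.0 |
| jejunum 1 | 154 | 6.2 | 0.95 | 1.50 | 1.0 |
| jejunum 2 | 122 | 6.4 | 0.76 | 1.34 | 1.0 |
| ileum 1 | 94 | 6.6 | 0.59 | 1.24 | 1.0 |
| ileum 2 | 71 | 6.9 | 0.43 | 1.09 | 1.0 |
| ileum 3 | 49 | 7.4 | 0.31 | 0.95 | 1.0 |
| caecum | 50 | 6.4 | 4.5 | 3.40 | 0.1 |
| asc. colon | 51 | 6.8 | 13.5 | 2.90 | 0.1 |

pH and transit times follow the widely published fasted-human
compartmental-absorption-and-transit parameterisation (small-intestinal
transit ≈ 3.3 h); radii and fluid volumes are standard fasted anatomical
figures. The stomach does not absorb; caecum/colon absorb at a 0.1 scale
(reduced effective surface area and free fluid). Everything is
overridable from a physiology file.

### Per-drug absorption calibration

The effective-permeability inputs are used exactly as tabulated (the
caco-2 value for amlodipine, the rat value for valsartan; the assay→human
conversion map defaults to identity). Raw 2·P_eff/r fluxes from such assay
values do not reproduce human oral exposure — published caco-2 and rat
conversions would move the two drugs in opposite directions — so each
bundled drug record carries one calibrated constant, `absorption_scale`,
multiplying all compartmental ASFs. It was fixed once, by bisection,
so that the simulated **tablet** fraction absorbed matches the literature
anchor for each drug, and then frozen:

* amlodipine: Fa = 0.90 (well-absorbed BCS class 1) → scale 16.5;
* valsartan: Fa = 0.23 (the reported fraction of dose absorbed and
  systemically available) → scale 0.56, with `colonic_absorption: false`
  because valsartan's absorption window is the upper GI tract, where it is
  fully ionized.

Cmax, Tmax and the suspension predictions are genuine model outputs — only
the tablet-model fraction absorbed was anchored. With these frozen
defaults the tablet model predicts Cmax/AUC₀₋∞ within 5% of the observed
values for both drugs.

## Disposition and NCA

Default disposition is **one-compartment** (first-order elimination,
C = A_c/V_c): clearance and central volume are the identifiable printed
parameters, and no distribution micro-constants are available for either
drug. Two-compartment kinetics (k12/k21) are fully supported via
configuration; in exploratory runs they only degraded the Cmax prediction
(distribution drains the central compartment during the absorption phase).
Missing parameters are filled by the one-compartment relations
CL = ln2·V_c/t½ and t½ = ln2·V_c/CL — this is how the valsartan clearance
(2.00 L/h) is derived from V_c = 0.23 L/kg × 70 kg and t½ = 5.58 h, whose
printed clearance entry is a typographic artifact. The amlodipine record
is over-determined and inconsistent (printed t½ 27.03 h vs 29.46 h implied
by CL 28 L/h and V_c 17 L/kg × 70 kg); CL and V_c are treated as primary
and a warning is emitted. No first-pass extraction term is modelled;
systemic clearance embodies all elimination.

NCA uses the linear trapezoid for AUC₀₋ₜ and an unweighted log-linear
regression for λz over the last 3 positive post-Tmax samples (window size
configurable; adjusted-R² window maximisation available as
`lambda_z_method="best_r2"`). AUC₀₋∞ = AUC₀₋ₜ + C_last/λz. Degenerate
inputs degrade explicitly: an all-zero profile returns Cmax = 0 with λz
undefined (warning); fewer than three usable terminal points omit AUC₀₋∞
(warning); a non-negative terminal slope raises an error.

## Virtual bioequivalence

The published workflow reports 90% CIs from a deterministic simulator
without describing the population mechanism; the Monte-Carlo design here
is therefore this package's own construction and is stated explicitly.
Each virtual subject draws one lognormal multiplier (median 1, stated CV%)
per varied parameter — defaults: CV 20% on clearance, V_c, P_eff and
gastric transit — and both formulations are simulated with the **same**
multipliers (a crossover without within-subject error). The per-subject
log-ratios of Cmax and AUC₀₋∞ give the geometric mean ratio and a 90%
t-interval; the verdict requires the whole interval inside 80–125%. Two
consequences worth knowing: with identical formulations the ratios are
exactly 1 and the interval is degenerate at 100%; with nearly identical
formulations the interval is very tight around the formulation effect,
because the design cancels between-subject variability. Runs are
bit-reproducible for a fixed seed, which is mandatory for stochastic
stages (a missing seed is a configuration error, not a silent default).

## Quality checks

* Stability: pass iff every %-remaining value lies within [90, 110]%
  (pharmacopeial band; the study states only the 90% floor). The series
  minimum and first out-of-range week are reported.
* Rheology: classification by total relative viscosity change across the
  shear sweep with a 5% tolerance (dilatant/pseudoplastic/newtonian); the
  data are too few (n ≈ 3–5) for a formal trend test.
* Batch arithmetic: pure label arithmetic; non-integer dose division
  floors with a warning. Amlodipine label strengths are free-base
  equivalents; the besylate molecular weight is used only where molar
  quantities would be needed.

## Synthetic data

`gen_dissolution` draws from a Weibull release family
F(t) = f_max(1 − exp(−(t/t_d)^β)) — flexible, monotone, and spanning the
very-rapid to slow profiles seen in the bundled table — with additive
Gaussian assay noise clamped to [0, 110]%. `gen_plasma` uses the Bateman
solution with multiplicative lognormal noise (standard for
concentrations); `gen_stability` uses first-order degradation with
additive assay noise. All generators are bit-deterministic per seed.

What passing tests on synthetic data show: correctness of the numerics
(recovery of known AUCs, f2 = 100 on identical curves, noise scales
reproduced over replicates). What they do not show: that real dissolution
follows Weibull kinetics, that real profiles are monoexponential, or that
the between-subject CVs match any particular population.

## Numerical choices

* Stiff-capable LSODA everywhere; GI rtol 1e−8/atol 1e−10 mg, disposition
  rtol 1e−8/atol 1e−12. Virtual-BE scenarios may relax to 1e−6 for speed.
* The PK stage consumes the absorption input as a linearly interpolated
  rate series on the output grid; with very fast absorption (input time
  constants near the grid step) use a finer `output_step_h`.
* Transient solver undershoot of luminal states is tolerated to
  −10⁻⁶·dose, the same scale as the mass-balance tolerance.
* Cumulative dissolution data may decrease by up to 2 percentage points
  (clamped to the running maximum); larger decreases are a data-quality
  error.
* Ties in Cmax resolve to the earliest time (argmax).

## Known limitations

* Fasted physiology only; no fed state, transporters, gut-wall metabolism,
  enterohepatic recycling, or particle-size distributions beyond
  monodisperse.
* The tabulated dissolution inputs carry only two timepoints (15/30 min)
  per medium; the five-point curves exist only as figures and are not
  reproducible inputs, so early-time release is linearly interpolated.
* The printed diffusion coefficients (4.2×10⁻⁸ and 1.1×10⁻⁸ cm²/s) are
  ~100× below typical small-molecule values; they are used as printed
  (exposed as configuration), which makes the mechanistic Johnson mode
  conservative about valsartan's intestinal dissolution — another reason
  the pipeline defaults to tabulated mode, where measured release data
  exist.
* The reference simulator's internal dissolution variant, absorption-scale
  model and population mechanism are proprietary; bit-level agreement with
  its reported "calculated" values is not attainable and not claimed. The
  package instead verifies against analytic oracles and reproduces the
  observed PK within the study's own <10% prediction-error criterion.
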