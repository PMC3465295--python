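# Methods

## Growth

Mass-at-age is the mass-form von Bertalanffy growth function (VBGF)

    W(t) = W∞ (1 − exp(−k (t − t₀)))^b

with analytic derivative `dW/dt = W∞ b k s^{b−1}(1−s)`, `s = 1 − e^{−k(t−t₀)}`.
Defaults: `W∞ = 319 kg`, `k = 0.299 yr⁻¹`, `b = 2.86`, `a = 2.14×10⁻⁴ kg cm⁻²·⁸⁶`.
The asymptotic mass is configurable; 319 kg is the adult value the integrated
results are built on, with the documented range 267–379 kg entering only
through the Monte Carlo module.

`t₀` is not an observable: it is anchored in closed form so that `W(0)`
equals a configurable hatchling mass (default 0.046 kg, typical for the
species). Anchoring matters for the hatchling-stage energetics — a curve
through zero mass at age zero is biologically wrong and makes mass-specific
rates blow up — but the integrated population totals are insensitive to the
exact anchor (<2%).

`fit_growth` uses nonlinear least squares (scipy `curve_fit`) on mass or
log-mass, with `b` and `W∞` fixed by default: a juvenile cohort far from the
asymptote cannot identify `W∞`, and `b` comes from the separate length–mass
regression. Standard errors derive from the local curvature. Fitting
log-mass is the right choice under multiplicative weighing error and is used
in the recovery tests.

The pooled fit assumes independent observation errors. If individual growth
heterogeneity is present (animals with their own `k_i`, as the synthetic
generator can produce), the pooled standard error is anticonservative;
per-animal fits or a mixed model would be needed. The recovery tests
therefore certify the pooled fitter under measurement noise only.

## Food conversion and consumption

Gross food-conversion efficiency (mass gained per wet mass eaten) follows
the Pauly allometry

    K₁(W) = 1 − (W/W∞)^β.

This is the standard single-constant form with the required property that
K₁ → 0 as W → W∞. With β = 0.0328 a hatchling converts ~25% of wet intake
into body mass and a full-grown adult ~0%.

`fit_beta` implements the classical estimator: per weekly record,
`K₁ = ΔW / food` assigned to the interval mean mass, then a through-origin
regression of `log(1 − K₁)` on `log(W/W∞)`. Two numerical refinements:

- **Retransformation bias correction.** Multiplicative noise on weighed food
  enters `log(1 − K₁)` nonlinearly, shifting its expectation by
  `−σ²/2 · K₁/(1−K₁)²` to second order (σ the SD of the log food error). At
  realistic study sizes this bias exceeds one standard error. The fit
  iterates: estimate β, estimate σ² from the residuals scaled by the local
  gain `K₁/(1−K₁)`, add the correction term back to the response, refit
  (three iterations; convergence is immediate). With noiseless data the
  correction vanishes and recovery is exact.
- **Robust SE.** Residual scale varies ~3× across the observed mass range
  (small animals have large K₁ and hence noisier `log(1−K₁)`), so the
  reported standard error is the heteroscedasticity-robust (sandwich) form.

Records with zero food or `K₁ ≥ 1` are excluded with a warning.

Individual intake at age is `F(t) = (dW/dt)/K₁(W(t))` in gelatin-diet units.
The 0/0 at `W = W∞` is replaced by its analytic limit `k W∞ / β` whenever
`K₁ < 10⁻¹²`; at `0.999 W∞` the general formula and the limit agree to
≲0.2%, so the switch is seamless. Jellyfish equivalents multiply wet mass by
exactly 10 — the printed conversion between the ~2.0 kJ g⁻¹ WM gelatin diet
and ~0.2 kJ g⁻¹ WM jellyfish — rather than recomputing the ratio from the
energy densities (which would give 10.08; the container validates
consistency to 1%). Cumulative consumption uses adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 10⁻⁹).

## Metabolic rate and energy budget

Mass-specific metabolic rate is derived from intake:

    MR = F_diet · E_diet · A · (1 − K₁) / W,

where `E_diet = 2.016 kJ g⁻¹` wet mass and `A = 0.63` is the usable-energy
fraction (80% digestive × 80% assimilation efficiency, kept at the rounded
0.63 rather than 0.64; both conventions are expressible through
`MetabolicParams`). Unit conversion uses the Julian year
(1 kJ yr⁻¹ = 1000/31,557,600 W); any year convention changes results by
<0.3%, and one is fixed for reproducibility. The curve runs from
~2.1 W kg⁻¹ at hatching to ~0.37 W kg⁻¹ at the adult asymptote, declining
monotonically after the first half year.

The independent cross-check: an adult body (319 kg, 71.2% water, 21.1 kJ g⁻¹
dry tissue) contains ~1938 MJ; dividing by the mean conversion constant β
and the jellyfish energy density per tonne (200 MJ t⁻¹) gives ~295 t to
reach maturity, consistent with the ~315 t from integrating the consumption
curve to age 16.

## Demography

Annual hatchling production is the product of seven nesting-ecology factors
per rookery (eastern and western Pacific), summed. Stage-wise abundance is
piecewise exponential with recruitment at 0.0027 yr (first day at sea),
1 yr, and 16 yr (maturity), and longevity 40 yr (the adult stage spans 31
years in the normalisation of the adult mortality coefficient); both
constants are configurable.

Two coefficient modes exist:

- **printed** (default, the reproduction setting): the published rounded
  stage counts (41,275/128,031/303,578 hatchlings; 10,425/32,338/76,679
  yearlings; 1,217/1,268/1,318 recruits) and mortality coefficients
  (1.38; 0.143/0.216/0.271; 0.333/0.229/0.177 yr⁻¹).
- **derived**: yearlings recomputed as 25% of hatchlings and Z from the
  stage boundary conditions, which makes abundance exactly continuous
  across stage boundaries.

The two differ by ~1% because the published yearling counts are not exactly
25% of the published hatchling counts, and the printed adult coefficient
0.229 differs slightly from its defining expression (≈0.2305); the printed
values are what reproduce the published population totals. The low/high
adult coefficients (0.333, 0.177) have no stated derivation and are treated
as given inputs in both modes. Population totals use discrete annual age
classes — the hatchling pulse plus cohort sizes at integer ages 1–15
(juveniles) and 16–46 (adults) — the convention that reproduces the
~294,000-turtle total; a brute-force integer-age loop is the test oracle.

## Population integration

`Q(t) = N·F` and `B(t) = N·W/1000` are evaluated on a weekly (1/52 yr) age
grid from hatch to 40 yr and integrated by composite trapezoid; the
quadrature error is well under 1%, far below parameter uncertainty, and a
1-yr annual-sum mode is provided since the original integration scheme is
not documented (the two agree within 5%). Age-band shares default to the
discrete annual-cohort convention ("2–7-year-olds" = cohorts at integer
ages 2..7 inclusive), which is the convention the published band numbers
follow; trapezoid-mode bands are exactly additive over a partition and are
used for the conservation tests. Restoration scenarios scale the entire age
structure uniformly to hit a target adult count — the only structure-free
choice, and the one consistent with the published scaled totals. Foraging
footprints divide annual consumption by an areal prey density (t km⁻²) or by
a volumetric density (g m⁻³) with an epipelagic depth to express the volume
as area.

## Uncertainty

Monte Carlo draws are independent across parameters (no covariance structure
is available): β, b, k normal with their reported SEMs; W∞ uniform on
(267, 379) kg by default, with a fixed-319 mode selectable because the
original resampling of W∞ is ambiguous. Out-of-domain draws (e.g. a negative
tail) are redrawn and logged. Each run evaluates the requested curve
(individual intake, population intake, biomass, or MR) on the weekly grid;
envelopes are rank-based 2.5/97.5 percentiles per grid point (float32
storage for the run matrix; percentile resolution requires ≥100 draws), and
totals' CIs come from run-wise trapezoid integrals. The mean-of-runs curve
is reported alongside the plug-in (point-estimate) curve; their difference
reflects model nonlinearity and is kept visible as a diagnostic. 10,000
draws complete in a few seconds.

Demographic uncertainty is deliberately not Monte Carlo: the low/mean/high
nesting scenarios (±2 SEM per factor, or ranges where no error was given)
propagate deterministically through the full pipeline.

## Synthetic data

The generator emulates the captive feeding study: 20 hatchlings, weekly
weighings over two years, food weighed before and residue after feeding,
plus bomb-calorimetry assays of the diet (dry fraction ~0.10, energy
20.16 kJ g⁻¹ DM, SD 0.58). Individual variation enters through `k_i`
(lognormal, 5% default) with `b` and `W∞` shared — the simplest identifiable
structure — and each animal's `t₀` is rescaled so all start at the hatchling
mass. Observation noise is multiplicative lognormal: 2% on weighed masses,
5% on weighed food (both positive measured quantities). Feeding records
keep the internally consistent pre-noise masses (interval end equals next
start); the weighed mass series carries the mass noise. Weekly feeding
records are exactly conversion-consistent before noise, so noiseless
simulation makes both fitters' recovery an equivalence-with-oracle test.

Not emulated: satiation dynamics, temperature effects, tank conditions,
correlated errors between food and mass measurements. Passing recovery
tests therefore demonstrate estimator correctness under iid measurement
noise at the study's scale, not robustness to every failure mode of real
husbandry data.

## Problem sizes and numerical defaults

Weekly age step (1/52 yr) everywhere, matching the feeding-trial cadence;
ages 0–40 yr; quadrature tolerance 10⁻⁹ for adaptive integrals; 10,000
Monte Carlo draws; 100 replicates for the coverage simulations; all RNG
through `numpy.random.default_rng` with explicit seeds recorded in specs
and outputs.

## Known limitations

- Growth and conversion come from captive animals on a gelatin diet;
  field growth or prey-handling costs may differ.
- The adult ration at the default W∞ tops out near 80 kg day⁻¹; rations
  quoted for 450 kg animals require evaluating the model at a larger W∞
  (the parameter is per-call, no intent is guessed).
- Demographic inputs are point estimates from heterogeneous literature
  sources; the low/high scenarios bound but do not characterise their joint
  uncertainty.
- `K₁` is a gross conversion efficiency: reproduction, storage, and
  excretion are not separated, only the single 0.63 usable-energy factor.
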