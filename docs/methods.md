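# Methods

## Model structure

`cvdpm` is a deterministic cohort (cell-proportion) Markov model: the
population is real-valued mass distributed over discrete states, advanced
by transition probabilities in annual cycles. No individuals are sampled,
so every run is exactly reproducible and tallies are linear
(homogeneous of degree 1) in the initial counts — a property the test
suite exploits.

States are (age 35–94 in single years) × (sex) × compartment. The CVD-free
compartment is further stratified into 486 risk cells (3 SBP × 3 LDL ×
3 HDL × 3 smoking × 2 diabetes × 3 BMI levels). Three prior-CVD
compartments (prior CHD, prior stroke, prior both) carry no risk profile:
their transitions depend only on age, sex and history. Five-year age bands
exist only as derived views for standardization.

### The annual cycle, in order

1. **Competing events in the CVD-free compartment.** Cause-specific
   hazards h_c for incident CHD, incident stroke and non-CVD death come
   from the proportional-hazards risk function; one-cycle probabilities
   are allocated as p_c = (1 − e^(−Σh)) · h_c/Σh, which conserves
   probability exactly. If the low-SES multiplier is enabled, p_CHD and
   p_stroke are multiplied by RR (capped at 1) *after* allocation; a
   diagnostic error fires if any cell's cause probabilities then exceed 1.
2. **Incident-CHD split.** A fraction `case_fatality(age, sex)` dies
   acutely (tallied `chd_death`); survivors move to prior-CHD. Stroke has
   no acute fatality in this implementation; survivors move to
   prior-stroke.
3. **Diabetes incidence** among cycle survivors moves mass from
   diabetes=no cells to the matching diabetes=yes cells (probability
   1 − e^(−h); applied sequentially after the exit causes, before aging).
4. **Prior-CVD transitions.** Each history faces competing
   {recurrent CHD, stroke, CVD death, non-CVD death} rates; a stroke from
   prior-CHD or a recurrent CHD from prior-stroke moves mass to
   prior-both, whose rates are the elementwise maximum of the two
   single-history rate sets (no combined-history rates exist to calibrate
   from). CVD deaths out of prior-CHD and prior-both are attributed to CHD
   death with a configurable fraction (default 1.0); prior-stroke CVD
   deaths are tallied `other_cvd_death`.
5. **Aging, exit, entry.** Survivors age one year; mass reaching 95
   exits; new 35-year-olds enter *at cycle end* with the scenario's joint
   risk distribution and no prior CVD, so entrants are first at risk the
   following year and contribute no person-years in their entry year.

Person-years use the half-cycle convention: each person alive at cycle
start contributes 1, in-cycle deaths contribute 0.5. Mass conservation
(next total = total − deaths + entrants − exits, to 1e-9 relative) is
checked inside every cycle and raises on breach.

### The SES multiplier on the probability scale

The independent low-SES effect (default RR 1.58, 95% CI 1.31–1.90,
applying to CHD and stroke incidence) is applied to annual probabilities,
not hazards. Consequence: the first-cycle incident-CHD rate ratio between
two otherwise-identical populations equals the configured RR *exactly*,
matching the rate-ratio semantics of the estimate's source. Whether the
multiplier should also touch stroke or CHD case fatality is not
determined by the available evidence; the default is
{incident CHD, incident stroke} with incidence only, and `applies_to` is
configurable. Only incident CHD feeds the headline outputs either way.

## Scenarios and decomposition

Canonical scenarios: `low` (low-SES joint distribution, multiplier on),
`high` (high-SES distribution, multiplier off), `m1` (low-SES
distribution, multiplier off), `ideal` (`m1` with every factor forced to
its ideal stratum: SBP→<130 via the 110 mmHg target, LDL→<100 (the 70 and
100 mg/dL targets land in the same stratum), HDL→40–59.9 via the 50 mg/dL
target, BMI→<25, no smoking, no diabetes). Idealization acts on the joint
distribution before the run and is idempotent. Ideal runs are constructed
symmetrically for either SES group.

Standardized rates are Σ_band w_band · (events/person-years) · 10⁴ over
the six 5-year bands of ages 35–64. The standard weights are the pooled
person-year distribution of the `high` (comparator) run and are used for
*every* scenario of an analysis: with per-scenario weights the
decomposition identities fail (tested).

Gap decomposition: rf_excess = r_m1 − r_high, ses_excess = r_low − r_m1,
and overall_excess is *defined* as their sum, so two-term additivity is
exact in floating point; pct_ses is defined as 100 − pct_rf for the same
reason. The three-component within-population split (SES-independent /
suboptimal management / unmodifiable = r_ideal) cannot telescope exactly
in floating point — each component carries its own rounding — so
additivity there is asserted at 1e-12 relative, i.e. to the last ulp.
Display rounding (rates 1 decimal, RR 2, percentages 1) is applied only
at output; percentages are computed from unrounded excesses.

Entering 35-year-olds use the scenario's fixed joint distribution (no
year-specific drift): secular trends in entrant risk are out of scope.

## Synthetic calibration

The generator emulates the study conditions the analysis needs, because
the original calibration sources (survey microdata, census projections,
Framingham-estimated Cox coefficients, vital statistics) are not
distributable:

* **Risk-factor marginals** default to the published survey values by sex
  and SES stratum — e.g. low-SES men: active smoking 31.7%, SBP 137.5
  (SD 17.0) mmHg, diabetes 15.7%, BMI 29.6 (SD 4.3); high-SES men: 23.8%,
  133.6 (13.4), 13.2%, 28.7 (3.5); analogous values for women. Continuous
  factors are modeled normal with those means/SDs and discretized at the
  stratum cutpoints via the normal CDF. The survey's printed category
  proportions (e.g. "SBP ≥110: 96.7%") are *not* force-matched; the
  normal approximation's implied proportions deviate from them slightly.
  Secondhand-smoke prevalence (0.10) and all lipid parameters are
  synthetic defaults — the survey prints neither — and lipids are
  identical across SES strata by design (no SES difference was observed
  in total cholesterol, which this model does not use).
* **Joint cell distributions** default to independence across factors, so
  every recovered marginal equals its input exactly (tested at 1e-9). An
  optional Gaussian copula introduces dependence via correlated latent
  normals thresholded at the marginal quantiles, integrated by Monte
  Carlo (200,000 latent draws by default, deterministic given the seed);
  under the copula marginal recovery is exact only up to sampling error.
* **Baseline hazards** are exponential in age,
  h(age) = h₃₅ · e^(slope·(age−35)), per cause, with male excess for CHD
  (female/male ratio 0.5) and a small seeded lognormal jitter (clipped to
  ±0.1 on the log scale) on each cause's scale so distinct seeds yield
  distinct but equally-shaped calibrations. Shape constants (e.g. CHD
  h₃₅ = 0.0012/yr, slope 0.055/yr for the reference cell) were chosen
  once so that simulated incident-CHD rates land in the tens per 10,000
  person-years for ages 35–64 — the order of magnitude of middle-income
  country burden — and so that no cell's one-year per-cause probability
  reaches 0.5 even at age 94 in the worst risk cell with the SES
  multiplier applied (a generation-time guard enforces this).
* **Covariate log-hazard-ratios** are round synthetic values with the
  qualitative Framingham structure (CHD: up to +0.6 for active smoking
  and diabetes, graded +0.25/+0.5 for SBP strata, protective −0.2/−0.4
  for higher HDL; stroke SBP-dominant; diabetes incidence BMI-dominant).
  User-supplied coefficient files are accepted through the same
  `RiskFunction` container, with strict schema validation (missing
  non-reference betas are a configuration error; non-zero reference
  betas are rejected). BMI acts as a direct covariate; mediation through
  SBP or diabetes is not modeled.
* **Demographics** are a flat age structure over 35–94 with the
  configured SES split (56% low) and female shares (51.3% low / 52.8%
  high), constant annual entrants equal to one age-slice, and mildly
  age-increasing prior-CVD prevalences. Census-projection realism
  (cohort bulges, migration) is deliberately absent.

What passing tests on this synthetic calibration do show: the model's
arithmetic — conservation, linearity, competing-risk allocation, the
exact first-cycle RR, decomposition additivity, marginal recovery — and
the qualitative ordering of scenario rates. What they do not show:
agreement of absolute rates with any real population; those depend
entirely on calibration inputs this package does not ship. Published
decomposition figures are reproduced from their printed rate inputs (the
arithmetic layer), not re-derived from microdata.

## Uncertainty propagation

2000 draws by default. Varied parameters: the CHD-incidence
log-hazard-ratios, drawn normal on the coefficient scale with
sd = (CI_high − CI_low)/(2·1.96), and the SES RR, drawn normal on the
*log* scale (sd = (ln 1.90 − ln 1.31)/3.92 ≈ 0.0948) and exponentiated —
its printed CI is near-symmetric on the log scale; a linear-scale option
is retained in `ParameterPrior`. Which coefficient set to vary is
ambiguous in principle; the default (CHD betas + RR) matches the
parameters that drive the reported outcomes, and `default_priors` is
replaceable. Within one iteration all four scenarios share the same draw,
so decomposition components remain additive draw by draw. UIs are
empirical 2.5/97.5 percentiles with linear interpolation between order
statistics (`numpy.percentile` default). A draw whose simulation fails —
e.g. an extreme coefficient draw pushing a worst-cell probability sum
past 1, which the engine treats as a diagnostic error rather than
silently renormalizing — is excluded with a warning and counted in
`n_failed`; at the default calibration this affects well under 1% of
draws. All randomness flows from one integer seed through one
`numpy.random.Generator`.

## Problem sizes and numerical choices

The default analysis simulates 2015–2024 (10 cycles) on a 100,000-person
synthetic population; because the model is deterministic cell arithmetic,
runtime is independent of population size. Per-cell probabilities are
precomputed once per (scenario, parameter set) — hazards are
time-invariant — so a full four-scenario analysis runs in well under a
second and 2000-draw uncertainty propagation in a few minutes on one
core. Test fixtures use a 10,000-person bundle; results are identical up
to scale by linearity (tested as scale invariance of standardized
rates).

Tolerances: joint distributions must sum to 1 within 1e-9; mass
conservation 1e-9 relative per cycle; marginal recovery 1e-9;
plausibility guard: every one-year per-cause probability < 0.5.
Degenerate inputs: a zero comparator rate flags (not raises) an undefined
RR; zero overall excess flags undefined percentages; bands with zero
person-years contribute zero to standardized rates and all-zero bands
raise.

## Known limitations

* Counts are expected values; stochastic microsimulation variance is out
  of scope, as are intra-year time steps and treatment modeling.
* Prior-CVD compartments carry no risk profile, so risk-factor
  interventions do not alter prior-CVD transition rates.
* The independence default for the joint risk-cell distribution
  understates clustering of risk factors; the copula option exists but no
  published correlation structure calibrates it.
* The `prior_both` rate construction (elementwise max) is a modeling
  convention, not an estimate.
* Absolute synthetic rates are order-of-magnitude realistic only; every
  substantive conclusion from this package should be read as conditional
  on its calibration inputs.
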