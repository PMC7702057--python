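# Methods

## The estimation problem

Secondary production — the rate at which an invertebrate community forms new
biomass, in mg ash-free dry mass (AFDM) m⁻² d⁻¹ or g AFDM m⁻² y⁻¹ — is not
observable directly. The instantaneous growth method reconstructs it from two
measurable pieces: mass-specific individual growth rates *g* (d⁻¹) and
standing biomass *B* (mg AFDM m⁻²). For one sampling interval of length Δt
days,

    P = g · Δt · (B_t + B_{t+Δt}) / 2 ,

summed over size classes, populations and intervals. Every input is
uncertain: *B* comes from a handful of replicate 0.023 m² Surber samples, *g*
from chamber incubations or shifting size-frequency distributions. The
package propagates all of it by a paired bootstrap: a single seed produces
one replicate index shared by growth, biomass, production and every derived
ratio, so community production is the exact replicate-wise sum of population
production, P:B times B reproduces P to machine precision, and percentile
intervals of derived quantities are internally consistent.

## Temperature scaling

Temperatures enter as the standardised inverse Boltzmann temperature

    x(T) = 1/(k·T_ref) − 1/(k·T),   k = 8.62×10⁻⁵ eV K⁻¹,  T_ref = 15 °C,

so an OLS slope of a log-transformed quantity on *x* is an apparent
activation energy *E* in eV, zero-centred at 15 °C. The constant uses the
conventional three-digit value of the metabolic-ecology literature rather
than the full CODATA value; the difference is far below estimation noise and
keeping it fixed makes results reproducible against the field's standard
practice.

Community biomass and turnover carry theoretical body-size effects
(*B* ∝ M^0.25, *P:B* ∝ M^−0.25). Before slope estimation these are removed by
dividing by M_c^±0.25, where M_c is the biomass-weighted mean individual
mass. Removal (division) rather than multiplication is the direction under
which the corrections cancel in the product B × P:B, preserving the exact
identity E(P) = E(B_corr) + E(PB_corr) per bootstrap replicate — asserted to
10⁻¹⁰ in the test suite. The opposite direction is available via
`mass_correction_direction="multiply"`.

Slope uncertainty uses a two-level bootstrap: each of n_boot (default
10 000) outer replicates draws one inner bootstrap replicate of the quantity
per unit (stream, or interval within a stream) and refits the OLS slope;
confidence bounds are the 2.5/97.5 percentiles. Resampling the *units*
themselves is available (`unit_resample=True`) but off by default: with six
streams it frequently produces degenerate designs, and the inner-draw CI is
the estimator the field convention describes. The cost of that convention is
that among-unit residual scatter not generated by within-unit sampling is
invisible to the CI; this limitation is inherent to the method, not to this
implementation.

## Growth rates

Instantaneous growth is g = ln(W_{t+Δt}/W_t)/Δt. Chamber incubations may
yield negative rates (mass loss); these are retained in raw tables but
excluded (and counted) from the log-linear model fit, where ln g is
undefined. Cohort growth from size-frequency distributions resamples
individual masses on both dates with replacement (sample sizes = observed
counts, overridable) and rejects replicate pairs whose resampled means do
not increase — a synchronous cohort cannot shrink — redrawing both dates up
to 1000 times before declaring the cohort invalid. Rejection of the pair
preserves both marginal distributions better than truncating one of them.

The community growth model is

    ln g = ln g₀ + a·ln M + E_ind·x(T),

fit by OLS with the initial mass as the size covariate (it is what is known
at prediction time). For production, every taxon × size class receives a
model-predicted rate at the class mass and interval mean temperature, with
replicates drawn from the coefficients' asymptotic multivariate normal so
that growth-model uncertainty propagates into production intervals. Pooled
raw measured rates (`growth_assignment="measured"`) are available but not
the default: they ignore the mass dependence, and on synthetic data with
known truth they overestimate production of size-structured populations by
10–20 % because small, fast-growing individuals dominate a pooled mean.

## Biomass and production bootstrap

Per date, biomass replicates resample the replicate field samples with
replacement (n = number of replicates present); one resampling is shared
across all taxa and size classes of the date, preserving spatial covariance.
Sub-sampled records (split fractions 1/2–1/16) are expanded by 1/split on
reading, assuming the counted fraction shares the abundance and size
distribution of the rest. Interval mean biomass is the endpoint average,
computed replicate-wise from independently resampled endpoint dates. Annual
production is the replicate-wise sum over intervals (first interval starts
at the first sampling date; gaps over 45 d are logged, not fatal); annual
mean biomass is the Δt-weighted mean of interval biomasses.

## Resource models

Annual chlorophyll *a* per stream is bootstrapped hierarchically: dates with
replacement, then stones within each drawn date. Its temperature dependence
uses the same two-level slope bootstrap as production.

Among streams, candidate OLS models for ln P (null, temp, ln chla, additive,
interaction) are ranked by AICc on each of n_rep resampled datasets (inner
draws of P and chla; temperature is a fixed covariate). k counts the
residual variance, so with six streams the full interaction model's AICc
correction is undefined (n ≤ k+1) and the candidate is simply never
selectable at that sample size. Ties break toward fewer parameters. The
temperature coefficient of the additive model is the resource-corrected
temperature dependence; the temp-only coefficient is the apparent one.

Within streams, the response is daily interval production and candidates
are all sub-models of temp × ln chla × ln light with a random stream
intercept. Fixed structures are compared by ML + AICc, the modal winner
refit by REML — ML for comparison, REML for coefficients. The
random-intercept model is fitted by its profiled likelihood: with a single
variance component the fixed effects and residual variance profile out
analytically, leaving a one-dimensional criterion in the variance ratio that
a bounded scalar optimisation solves in milliseconds. The zero-variance
boundary (equivalent to OLS) is evaluated explicitly instead of failing on a
singular information matrix there. The test suite cross-checks this fitter
against statsmodels' full mixed-model machinery (REML log-likelihoods agree
to 10⁻⁴). Zero light values (polar-night months) are floored at half the
smallest positive observation before logging, with applications logged.

GPP is modelled as ln GPP ~ x + ln light + ln chla on monthly data from the
instrumented streams, with case-resampled coefficient distributions. The
resource-corrected within-stream temperature dependence is the difference
E_p_within − E_gpp_within under independent draws from the two coefficient
distributions.

## The synthetic generator

The generator emulates the study design the package targets: six streams at
5.0–27.2 °C mean annual temperature, ~monthly sampling (twelve dates), five
replicate 0.023 m² samples, three taxa with length-mass allometries
(M = aL^b), 0.25 mm measurement bins with a 250 µm mesh floor, chamber
incubations of 7–15 d, and chlorophyll sampled from five stones per date.

Key generating choices, with defaults and reasons:

- **Environment.** Temperature is a noise-free sinusoid (amplitude 4 °C,
  peak mid-July) so configured annual means are exact; configurations that
  would push the coldest stream below −2 °C are rejected. Light is a
  phase-shifted sinusoid whose lag is solved numerically to hit the target
  temperature-light Pearson correlation (default 0.42, the middle of the
  −0.09 to 0.67 range such systems show), plus small Gaussian noise.
- **Growth truth.** ln g = ln g₀ + a ln M + E_ind·x with a = −0.25,
  E_ind = 0.65 eV, ln g₀ = −3.5 (≈0.03 d⁻¹ at 1 mg and 15 °C, a realistic
  chironomid rate), lognormal noise σ = 0.4. Final masses are constructed
  through the growth identity, so recomputing g is exact by construction.
- **Resource truth.** The stream resource level is lognormal around the
  Boltzmann line with slope E_chla = 0.53 eV. Two noise scales matter:
  date-level (σ = 0.3) and stream-level (σ = 0.55). The stream-level term
  is what makes temperature and resources statistically separable — if
  chlorophyll were an exact function of temperature, "temperature acts only
  through resources" would be unidentifiable. Its default is calibrated so
  the chlorophyll-temperature r² is near 0.5, the magnitude reported for
  such geothermal stream systems.
- **Production truth.** Annual community production is
  P_ref · (chla_annual/chla_ref)^1.2 · exp(E_direct·x) with E_direct = 0 by
  default: temperature influences production *only* through the resource.
  Within the year, biomass tracks the light-driven resource profile with
  date-level lognormal noise (σ = 0.2); the whole trajectory is rescaled so
  that true annual production — the instantaneous-growth identity applied
  per size class to the true g and B series — hits the target exactly. True
  growth is the biomass-share-weighted mean over size classes, matching
  what a per-class estimator sums to; defining truth at the taxon-mean mass
  instead would build in a Jensen bias of order 10 %.
- **Counting.** Catches are negative-binomial around density × area
  (dispersion 2, Poisson available); replicate-to-replicate overdispersion
  of Surber samples is a free parameter with no field-reported value, so it
  is deliberately conservative. Large fine-fraction catches (>30
  individuals under 1 mm) are binomially thinned at a split fraction drawn
  from {1/2 … 1/16}, so read-time expansion is unbiased by construction.

Every simulated study carries a truth record (generating parameters plus
realised per-stream annual production, chlorophyll and temperatures);
recovery tests compare estimates against this record only.

**What the generator does not emulate.** Within-stream biomass seasonality
follows resources (light), not temperature, so the within-stream apparent
temperature dependence of production in synthetic data is near E_ind
(≈0.6 eV) rather than the much steeper values field data can show; tests of
the within-stream machinery are structural, not calibrations. Heavier-
tailed noise, species interactions, emergence/drift losses and
between-year variation are out of scope. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every feature of real field data.

## Problem sizes and numerical choices

Package defaults follow field convention: 500 cohort-growth resamples, 1000
production iterations, 10 000 slope bootstraps, 1000 selection replicates.
The test suite and the acceptance script use structure-identical scaled-down
sizes (bootstrap sizes 200–2000, 300 selection replicates, 100 recovery
seeds) chosen so the whole suite runs in minutes; all such sizes are
parameters, not separate code paths. Percentile (not BCa) intervals are used
throughout. All randomness flows from one integer seed through
`numpy.random.SeedSequence` children per stage; outputs are byte-identical
across reruns with the same inputs and seed. Degenerate inputs are handled
explicitly: zero-width distributions reduce estimators to their point
analogues; all-zero communities, single temperatures, too-few units and
shrinking cohorts raise typed errors naming the offending unit.
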