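# Methods

## Dose–response model and likelihood

The endpoint is a strictly positive continuous measurement (micronucleated
reticulocyte frequency in %, treated as continuous data). Responses are
modelled as lognormal around a sigmoidal median curve: for animal *i* in a
group at dose *x*,

    ln y_i = ln m(x) + ε_i,   ε_i ~ N(0, σ²)

where σ is the residual SD on the natural-log scale and m(x) is one of two
four-parameter families (increasing endpoints, so the maximum fold-change
c > 1):

    exponential:  m(x) = a·[c − (c−1)·exp(−b·x^d)]
    Hill:         m(x) = a·[1 + (c−1)·x^d / (b^d + x^d)]

Both are reparameterized in the critical effect dose (CED): given a
critical effect size CES (fractional increase over background; default
0.50, the value considered appropriate for in-vivo micronucleus data), b is
eliminated by solving m(CED) = a·(1+CES):

    exponential:  b = −ln((c−1−CES)/(c−1)) / CED^d
    Hill:         b = CED·((c−1−CES)/CES)^(1/d)

This requires CES < c − 1; otherwise the CED is undefined and the model
layer raises. The log-likelihood is defined as the normal log-density of
ln(response) about ln m(x) — without the lognormal change-of-variable
term, a data-dependent constant that affects no estimate, interval or AIC
comparison, but makes the zero-residual likelihood exactly
−(N/2)·ln(2πσ²).

**Sufficient statistics.** Internally every group is reduced to
(n, mean of ln y, Σ(ln y − mean)²), which is exact for individual data and
makes a likelihood evaluation O(#groups) regardless of group size — this
is what keeps the simulation-based checks (coverage, precision gain)
affordable. Group summaries reported as arithmetic (n, mean m, SD s) are
converted by the lognormal method of moments, μ = ln(m/√(1+s²/m²)),
σ_g² = ln(1+s²/m²), with within-group sum of squares taken as n·σ_g²
(denominator-n convention, matching the ML variance convention used on
individual data).

**Zero responses.** Non-positive responses are rejected by default; an
explicit additive offset (applied to both data and model median, and
recorded in the fit) may be configured. No silent offset is ever applied,
because offsets shift potency estimates.

## Fitting

All positive parameters are optimized on the log scale; c is parameterized
as 1 + CES + e^u so every iterate keeps the CED defined. d is constrained
to [0.25, 4] to prevent degenerate infinite-steepness fits on sparse
designs (4-point designs cannot resolve d; the bound is recorded with the
fit). Bounds for a and the CED are data-driven (×/÷ 50 around the observed
geometric means; CED within [d_min/100, 100·d_max] of the positive doses).

Optimization is multi-start L-BFGS-B: one data-driven heuristic start plus
20 Latin-hypercube draws over the bounded box (seeded; scipy's QMC engine),
keeping the best local optimum. Identical inputs and seed give bit-identical
results. A fit requires ≥ 3 distinct doses per covariate level.

## Covariate structure

When several comparable studies (or strains) are analysed jointly, the
background a and the CED may take level-specific values while the shape
parameters c and d are always shared; the residual log-SD may optionally
split. Four candidate structures — all shared; a split; a+CED split;
a+CED+log-SD split — are fitted and compared by AIC = 2k − 2·logL. The
lowest AIC wins, except that any candidate within 2 AIC of the best with
fewer free parameters is preferred (parsimony on effective ties). All
candidate AICs are retained in the fit diagnostics. Both model families
are fitted and reported; the headline result is taken from the lower-AIC
family, and cross-family averaging is deliberately not done.

This joint "combined covariate" analysis is what buys precision: the small
study borrows strength for c, d and (often) the CED from the large one.
The test suite verifies the gain directly (the small study's profile
interval narrows in ≥ 80% of replicates).

## Profile-likelihood confidence limits

BMCL/BMCU for each level's CED are the values where the profile
log-likelihood (all other parameters re-optimized at each fixed CED) falls
χ²₁(level)/2 below the maximum — 1.3528 for the default two-sided 90%
interval (conventional one-sided 95% benchmark-dose limits; the level is
configurable). The search marches geometrically away from the MLE
(warm-starting each refit from the neighbouring solution, monitoring that
the profile decreases monotonically), brackets the crossing, and bisects
on the log-dose scale to a relative tolerance of 1e-4. If no crossing
occurs within [CED/1000, 1000·CED] the corresponding side is reported as
open (None) and flagged rather than given a fabricated number.

## Synthetic data

The generator draws per-animal responses exactly from the fitted model:
median from the chosen family, multiplicative lognormal noise, seeded
`numpy` Generator streams. It deliberately omits overdispersion, litter
effects, toxicokinetics and cytotoxic dropout, so parameter-recovery and
coverage tests are well-posed: passing them demonstrates the estimator and
intervals are correct *under the model's own assumptions*, not that real
micronucleus data meet those assumptions.

The two-study fixture mirrors the benzene inhalation designs: a DO-like
study (doses 0/1/10/100 ppm, 75 animals/group, 6 h/day, 5 days/week,
4 weeks) and a smaller B6C3F1-like study (0–200 ppm, 10/group). Its true
parameters — DO background 0.25%, CED 10 ppm; B6C3F1 background 0.15%,
CED 14 ppm; shared c = 4, d = 1, log-SD 0.3 — are **arbitrary**: order-of-
magnitude plausible for MN-RET potency (~10 ppm) but not estimates of any
real study, whose raw data are not public.

## Risk-characterization arithmetic

Unit conversions use the ideal-gas relation c[mg/m³] = c[ppm]·MW/V_m with
benzene MW 78.11 g/mol and molar volume 24.04 L/mol (20 °C, 101.3 kPa) —
the temperature convention under which both standard reference conversions
(0.05 ppm = 0.16 mg/m³; 5 µg/m³ = 1.5 ppb) hold; 25 °C does not reproduce
the second.

The human-equivalent PoD multiplies each bound by
(animal h/day ÷ human h/day) × (animal-equivalent inhaled volume ÷ human
inhaled volume). Presets: worker 6/8 × 6.7/10 = 0.5025; general population
6/24 with volume ratio 1 (activity assumed comparable to the animals).
Assessment factors are user-supplied config — never hard-coded policy; the
shipped worker (2.5×6×5×3 = 225) and general-population (2.5×6×10×3 = 450)
sets are examples carrying an explicit no-precedent caveat in every report.
Factors below 1 warn but are not forbidden; an empty set composes to 1
with a warning.

**Rounding policy.** Every reported intermediate is rounded half-up
(decimal, not banker's) to 2 significant figures, and the rounded value
feeds the next reported step: 14.2 × 0.25 = 3.55 → 3.6; 3.6/450 → 8 ppb
(full-precision chaining would give 7.9). Full precision is used
internally up to each reporting boundary; round-trip unit conversions are
exact.

The verdict compares ranges: "above" if the exposure lower bound exceeds
the acceptable upper bound, "below" if the exposure upper bound is under
the acceptable lower bound, otherwise "within" (any overlap, including
touching endpoints). The margin of exposure (PoD/exposure) is available
but reported only on request, with a note that the benzene assessment did
not use the MOE approach (genotoxicity considered secondary to other
effects).

## Problem sizes used in the checks

Simulation-based tests run at the fixture's own designs (75 and 10 per
group): profile-interval coverage over 200 replicate two-strain studies
(three Monte-Carlo SEs around the nominal 90%), covariate-structure
selection over 50 replicates per scenario, combined-analysis precision
gain over 50 replicates, fixture CED recovery over 40 replicates, and a
500-replicate parametric bootstrap as the independent oracle for the
profile endpoints (15% relative agreement). Recovery and coverage checks
fit the generating covariate structure (a+CED split) directly: with only a
1.4-fold true CED difference and 10 animals/group in the smaller study,
AIC legitimately favours a shared CED in many replicates, which is a
statement about selection power, not interval calibration.

## Known limitations

- Only the two 4-parameter families; nested sub-models arise by fixing
  parameters, and no model averaging or Bayesian fitting is provided.
- No litter/clustered random effects; animals are exchangeable within
  groups.
- The covariate lattice is fixed to the four structures above; c and d
  cannot split by level.
- Profile intervals assume a unimodal profile; non-monotone search paths
  are flagged in the result rather than repaired.
- The risk layer is inhalation-only, deterministic arithmetic: no route
  extrapolation, PBPK, or probabilistic exposure modelling.
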