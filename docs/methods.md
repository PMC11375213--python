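# Methods

## The model

Individuals enter the population at the points of an inhomogeneous
Poisson process and carry independent lifespans drawn from a
cohort-dependent law. An individual is a marked point (tᵢ, xᵢ): entry
time and lifespan. The record age is

    Y_t = max { (t − tᵢ) · 1{t ∈ [tᵢ, tᵢ + xᵢ)} },

which grows at slope one and jumps down at the incumbent's death.
Because people older than age x at time t form a Poisson process
(births at rate λ thinned by survival), the law of Y_t is explicit:

    P(Y_t < x) = exp( −∫_x^∞ g_t(u) du ),
    g_t(u) = λ_E(t−u+E) · (1 − F^E_{t−u+E}(u−E)),

where E is the *entry age* (0, 30 or 60): individuals are injected at
age E with the thinned intensity λ_E(t) = C_E e^{κ_E t} and the
remaining-lifespan law of their cohort. Differentiating gives the
density h_t and the atom m_t at zero (nobody above E alive); stopping
the integral at a death age y gives the downward-jump kernel, whose
continuous part is j_{y,t}(x) = exp(−∫_x^y g_t) g_t(x) with an atom at
zero.

### Lifespan law

Remaining lifespans are gamma–Gompertz: a Gompertz hazard a·e^{bx}
mixed over a gamma frailty of variance γ, survival
S(x) = (1 + (aγ/b)(e^{bx} − 1))^{−1/γ}, hazard plateau b/γ. A Makeham
term c (extrinsic, age-independent mortality) is carried through all
distribution code but defaults to 0: it is unidentifiable from data
that only constrain ages 107–123, and it is irrelevant there. The level
declines across cohorts, a_E(t) = K_E e^{−α_E (t−2000)} (the year-2000
anchor only keeps K readable); b and γ are constant in time.

The integral of the survival function has the closed form

    ∫_x^∞ S(u) du = (b/(aγ))^{1/γ} e^{−(c+b/γ)x} / (b/γ + c)
        · ₂F₁(1/γ, 1/γ + c/b; 1 + 1/γ + c/b; ((aγ−b)/(aγ)) e^{−bx}),

used wherever the law is time-frozen. Adaptive quadrature of the
survival *ratio* S(x+v)/S(x) (so absolute tolerances stay meaningful in
the far tail) is the documented fallback and the test oracle; the two
agree to better than 1e−8 relative over the full calibrated parameter
range.

### Stationary (homogeneous) theory

With a constant rate λ and a fixed law F, Y is stationary and
everything is closed-form in S1(x) = ∫_x^∞ (1−F):
h(x) = e^{−λS1(x)} λ (1−F(x)) with atom m = e^{−λ·E[lifespan]}; the
ages at death of successive record holders (the peaks chain) have
stationary density z ∝ f·e^{−λS1}; the reign length has density

    r(w) = [∫ h(y) f(y+w) dy + m·(f ∗ Exp(λ))(w)] / [∫ h(y)(1−F(y)) dy + m],

whose mean reduces to ∫ h·S1 / ∫ h·(1−F) (plus atom terms) because
∫_0^∞ w f(y+w) dw = S1(y). The convolution term counts the empty-
population waiting time towards the next holder's reign; the simulator
measures reigns the same way (differences of consecutive death events,
resets included). These identities — the second-order ODEs for h and
z/f, the equilibrium balance, the peaks integral equation, and the
denominator identity — are exercised as oracles in the test-suite, not
used as computational paths.

### Fixed-point approximation

Inside the tail integral the level a depends on the integration
variable (each age u at time t belongs to a different cohort), so
moments of Y_t have no closed form. For mean-age curves and reign
lengths the level is *frozen* at a_E(t−d) and d is iterated to the
fixed point of d ↦ E[Y_t | frozen at a_E(t−d)]; ten iterations are the
default (the map contracts by roughly a factor 3–5 per step; the
residual step is ~1e−6 of a year). The standard deviation is computed
under the same frozen density, and the atom is ignored in moments (it
is below 1e−300 at calibrated rates). Reign lengths additionally freeze
λ; the default freezes both at the cohort time t − d* experienced by
the typical record holder, with `freeze="current"` (time t itself)
exposed as the alternative convention — the two differ by well under
0.01 years at the calibrated growth rates. Exceedance probabilities and
density series never use the approximation; they integrate the fully
time-dependent exponent.

## Likelihood

The data are transitions (tᵢ, yᵢ, zᵢ) subject to the consistency
relation tᵢ − zᵢ = tᵢ₊₁ − yᵢ₊₁ (both sides are the successor's birth
date; tolerance 0.01 years, since day-resolved sources rounded to
decimal years carry ≤ 1/365 slack). Each transition contributes the
density of the incumbent's death age (conditioned on having reached the
previous successor age) times the jump kernel at the successor age; the
conditioning survival factors telescope across the chain, leaving

    l(α,K,γ) = Σᵢ [ log f^E at the death age − ∫_{zᵢ}^{yᵢ} g_{tᵢ}(u) du ]
               + log S^E at the final successor age + (constants),

with constants n·log C + κ Σ(tᵢ−zᵢ+E) that do not depend on (α,K,γ)
and are omitted during maximisation (a flag restores them so absolute
values are comparable across sources). The final survival term uses
cohort time tₙ − zₙ + E and age zₙ − E, the same convention as every
other factor in the chain.

Each record's exponent integral is evaluated with a composite
Gauss–Legendre rule (24 cells × 6 nodes on [zᵢ, yᵢ]), vectorised over
the whole sample; it matches per-record adaptive quadrature (absolute
tolerance 1e−10) to better than 1e−8 and makes a full likelihood
evaluation ~100 µs, so the fit and the simulation batteries stay cheap.

Optimisation is Nelder–Mead in log-parameter space (positivity for
free), wrapped in a meta-loop: start at relative tolerance 1e−3, rerun
warm-started, and rescale the tolerance by the ratio of successive
improvements (clamped to [0.1, 1]); stop when the improvement falls
below 1e−6 or after 12 rounds. Defaults (`MetaNelderMead`) and the
starting point (α, K, γ) = (0.01, 1e−4, 0.1) are configurable.

Freeing the rate of aging b as a fourth parameter reproducibly drives K
below 1e−10 ("almost no mortality before 100"): titleholder data only
see the extreme tail, and the four-parameter family can match that tail
with degenerate laws. The fit emits `DegenerateFitWarning` and flags
the result; fixing b (0.09 by default, with 0.11/0.13/0.15 as the
sensitivity grid) is the supported procedure.

## Synthetic data

`make_synthetic_titleholders` emulates the study conditions: entry-age-0
intensity (C = 6270, κ = 0.004987), calibrated trend (α = 0.01277,
K = 2.951e−5, b = 0.09, γ = 0.08596), observation window 1955–2019, a
130-year warm-up so the initial holder is exact, and an extreme-age
floor of 104 years. The floor makes world-scale rates tractable: only
individuals whose lifespan reaches 104 are generated, via the exactly
thinned process λ(t)(1 − F_t(104)) with conditional inverse-cdf
lifespans, and births after (window end − floor) are skipped because
they cannot reach the floor inside the window. The record trajectory is
exact wherever Y stays above the floor; under the calibrated parameters
P(Y_t < 106) is below 1e−6 throughout the window, so the truncation is
invisible. Sampling uses per-strip thinning bounds (strip endpoints and
midpoint with 2% headroom — exact for monotone rates such as these); a
single seed spawns independent substreams for births and lifespans.

What the generator does *not* emulate: age validation errors,
reporting lag, incomplete coverage of early decades, and any deviation
of real mortality from the GG trend family. Passing recovery tests
therefore show that the estimator inverts the model's own mechanism at
realistic sample sizes (~55 transitions per 65-year window), not that
real titleholder lists are free of data artefacts. At that sample size
the sampling error of γ̂ is itself ~15%, so recovery is asserted on the
battery median (10 seeds), with every K̂ within a factor two.

## Numerical choices

- Decimal calendar years everywhere (365.2425-day conversion,
  centralised in `recordage.io`); ages in decimal years.
- Age integrals truncated at x_max = 150 (survival there < 1e−12 under
  all shipped laws). One caveat discovered in testing: at world-scale
  rates the *rate-weighted* tail λ·S1(150) ≈ 4e−8 is not negligible at
  1e−8 tolerances, so normalisation checks of frozen world-scale models
  extend x_max to 160. Adaptive quadrature runs at absolute tolerance
  1e−12, relative 1e−10.
- Grid evaluations (density series, fixed point, jump sampling) use
  composite Gauss–Legendre cells with a nested rule for the
  log-survivor at interior nodes, making each returned density an exact
  derivative of its own cdf up to rule error (normalisation holds to
  ~1e−12).
- Finite-difference residual oracles use step 1e−4 for first
  derivatives but 1e−3 for second derivatives: second differences
  amplify the ~1e−12 evaluation noise of the hypergeometric survival
  tail by 1/h², which at step 1e−4 would swamp the 1e−6 residual
  criterion.
- Residual and integral-equation oracles are evaluated where the
  stationary densities carry mass (the record-age law is only a few
  years wide, a property of the model, not a numerical artefact);
  where every term underflows to zero the scale-free residual is
  defined as zero.
- The jump sampler inverts the kernel cdf on a cached grid; draws
  below the atom map to zero.

## Limitations

- Exceedance probabilities inherit the sensitivity of the tail to the
  within-year death-date convention: ±0.5 year moves them by ~7%
  (growth κ plus the α/γ amplification of the level trend). Reign
  lengths and means move by < 0.01 of their scale.
- The exponential intensity is extrapolated far beyond the demographic
  data that motivated it; century-scale forecasts (e.g. 2060–2100
  density series) are model extrapolations, not projections with
  uncertainty bands. No parameter uncertainty is propagated (the fit
  reports point estimates only).
- The entry-age variants (E = 30, 60) are separately calibrated
  approximations; they agree with E = 0 on tail probabilities within a
  factor ~1.01 at age 115 but are not constrained to be mutually
  consistent.
- The fixed-point mean/sd and the frozen reign lengths are
  approximations controlled by the concentration of the record-age
  law; their error is far below the Monte-Carlo noise of any
  comparable simulation but is not bounded analytically.
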