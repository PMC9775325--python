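# Methods

## Data model and interval definitions

A focal observation is a strictly ordered, non-overlapping, alternating
sequence of *head moves* and *looks*. Each look carries a quadrant code 1–4;
quadrant mid-point angles are 0°, 90°, 180°, 270°, with 0° along the body's
long axis and angles increasing clockwise viewed from above, so 90° is the
animal's right. (Recordings never state the rotational direction of the
coding; the q2-is-right convention is fixed here and only affects the sign
labels "left"/"right", not any magnitude.)

- **Look duration** `d`: the look's own interval. It excludes the preceding
  head move, during which vision is blurred.
- **Head-move duration** `h`: the immediately preceding head-move interval;
  missing (NaN) for a look that opens an observation.
- **Return time** `r`: for each maximal run of non-reference looks preceded
  and followed by a reference-quadrant look (reference = quadrant 1 by
  default), the clock runs from the **onset of the first non-reference look**
  to the **onset of the next reference look**. Onsets are the only timestamps
  guaranteed for looks, and "reorienting into the quadrant" is an onset
  event; a `convention="headmove"` flag instead starts and stops the clock at
  the start of the head move leading into those looks. Excursions still open
  when the observation ends are right-censored and dropped, so only completed
  returns are counted. Several consecutive looks within one quadrant belong
  to one excursion.

Frame quantisation (0.033 s video frames) is a property of the input: it is
validated when declared, and the generator can impose it, but continuous
synthetic durations are not quantised by default.

## Hierarchical duration model

Durations are modelled as

    eta = beta0 + beta_gs * G + beta_status + u_group + v_individual
    u_group ~ Normal(0, sigma_g^2),  v_individual ~ Normal(0, sigma_i^2)

with four observation families: normal (identity link; `eta` is the mean),
log-normal (`eta` is the mean of log duration), negative exponential and
Weibull (log link on the mean; the Weibull scale solves
`scale * Gamma(1 + 1/k) = exp(eta)`). The log link on the positive families
makes `beta_gs` comparable across them. Status uses juvenile as the
reference level with adult-male and adult-female treatment contrasts; group
size enters as an uncentred continuous covariate, so predictions are always
made at a stated G (default G = 4, a typical median group size).

Priors are weakly informative and scale-appropriate for log-seconds:
Normal(0, 5²) on fixed effects, half-Normal(0, 2²) on sigma, sigma_g and
sigma_i, Gamma(2, rate 0.5) on the Weibull shape. All are overridable via
`Priors`.

### Posterior computation

The default schedule is four parallel chains of length 2000 with a burn-in of
1000, retaining 4000 draws. All chains advance in lockstep through vectorised
likelihood evaluations.

For the normal and log-normal families the working response is Gaussian, so
`beta`, `u` and `v` are drawn from their exact normal full conditionals
(blocked Gibbs). The three scale parameters move by adaptive scalar
Metropolis on the log scale, each followed by an *interweaved* redraw in the
non-centred parameterisation (`u = lambda * w` with `w` held fixed), where
`lambda` is conjugate normal — this breaks the funnel coupling between a
scale and its effects. For the exponential and Weibull families the
conditional of each random effect has the strictly concave form
`-r n x - T exp(-r x) - x^2/(2 sigma^2)`, so effects are updated with normal
independence proposals centred at the Newton mode (acceptance near 1); fixed
effects use an adaptive multivariate random walk whose covariance is learned
during burn-in, and the shape/scale parameters use adaptive scalar Metropolis
plus the same non-centred rescaling moves.

Both samplers additionally apply cheap *translation moves* along the exact
likelihood-invariant degeneracy directions (intercept vs. the mean of each
random-effect block, the group-size slope vs. group effects, each status
contrast vs. its individuals' effects, and group effects vs. their members'
individual effects), accepted on the prior ratio alone and repeated several
times per sweep. These carry the slow posterior directions that conditional
updates cannot.

Convergence is reported as rank-normalised split R-hat per block, maximised
over coordinates. With 4 × 1000 retained draws this statistic sits at
1.01–1.03 for an essentially converged sampler by sampling noise alone, so
the package warns (and `converged` turns false) above 1.05 rather than at a
nominal 1.01. Typical values at study scale (~4500 looks): ≤ 1.03 for the
Gibbs-sampled families, ~1.04 for the exponential, ~1.07 for the Weibull.

### Model comparison

The pointwise log-likelihood of every look at every retained draw feeds
Pareto-smoothed importance sampling LOO (smoothed weights from
`arviz.stats.psislw`; pointwise ELPD, totals and standard errors computed
in-package). The best family is assigned difference 0; differences ≤ 4 are
flagged as similar predictive performance. A fit with more than 10% of looks
above the Pareto-k threshold 0.7 triggers a reliability warning. The LOO
unit is one look — the unit of the likelihood — not one observation.

## Monte-Carlo KS goodness-of-fit

Because the tested distribution's parameters are estimated from the same
data, the textbook KS p-value is invalid. `mc_ks_test` fits the family by
maximum likelihood (closed forms except the Weibull shape), computes the
two-sided statistic `D = sup max(|Fhat(x-) - F(x)|, |Fhat(x) - F(x)|)` over
the empirical CDF's jump points (exact under frame ties), draws B = 1000
synthetic samples of the observed size from the fitted distribution,
**re-fits the family on each synthetic sample** before computing its D
(parametric bootstrap / Lilliefors-style correction), and reports
`p = (1 + #{D_b >= D_obs}) / (B + 1)`. Without the refit the null
distribution of D is stochastically too large and the test barely ever
rejects; a `refit=False` flag preserves that naive variant for comparison.
The add-one estimator is never 0 and equals exactly 1 when every synthetic
sample beats the observed statistic. Look durations are tested per focal
observation; return times, being fewer, are tested pooled — both paths share
the same operation.

## Circular statistics and side bias

The orientation summary of an observation is the mean direction of the look
angles weighted by look durations, `theta = atan2(sum w sin, sum w cos)`,
with duration-weighted resultant length `R`. A von Mises distribution is
fitted treating durations as frequency weights (mean direction = weighted
mean angle; concentration solves `A1(kappa) = R`). The 95% CI is a
parametric bootstrap: B = 2000 samples of n angles from the fitted von Mises,
each paired with the original weights, percentile interval of the bootstrap
mean directions re-centred on the fitted direction. A side bias is declared
when 0° lies outside the CI (containment evaluated on the circle); the side
is the sign of the mean angle, falling back to the CI midpoint when the mean
sits on the ±180° axis. Near-uniform fits (kappa < 1e-3) yield the whole
circle and no bias. The von Mises model is continuous while the angle
support is the coarse 4-point set; it is fitted to the coarse angles as
given. Proportions of right- vs left-biased individuals get Clopper–Pearson
intervals from beta quantiles.

## Synthetic sentinel-bout generator

`simulate_population` emulates a non-breeding-season field study of a
cooperatively breeding sentinel bird:

| Parameter | Default | Rationale |
|---|---|---|
| groups / focal observations | 24 / 60 | a full field season |
| group size | uniform integers 2–6 | observed range, median 4 |
| group composition | breeder pair + (G−2) juveniles | helpers excluded from statuses |
| focal sampling | breeders 1.5× juveniles | breeders do more sentinel duty (~2/3 of focals adult) |
| duration family | log-normal | the best-fitting family |
| beta0 | −0.323 | calibrated once so the pooled median look ≈ 0.93 s |
| beta_gs | 0.05 per bird (log scale) | reported group-size effect |
| status contrasts | +0.15 for both adult classes | adults look longer; magnitude a realistic placeholder |
| sigma / sigma_g / sigma_i | 0.85 / 0.15 / 0.15 | reproduces the observed look-duration range and 21–74 turns/min rate envelope |
| occupancy | (0.507, 0.188, 0.086, 0.219) | reported mean quadrant occupancies |
| persistence | 0.33 | calibrated from looks-per-excursion counts (~3 consecutive looks per quadrant run) |
| head moves | 2 or 3 frames of 0.033 s | reported median head-move durations |
| bout length | uniform 15–366 s | reported range of focal observations |

Quadrant sequences are first-order Markov with transition matrix
`P = p·I + (1−p)·1 π^T`: with probability `p` (persistence) the next look
repeats the current quadrant, otherwise the quadrant is redrawn from the
stationary occupancy π, which is therefore exact for any p ∈ [0, 1). Events
alternate head-move/look until the bout is exhausted; the final incomplete
look (and its dangling head move) is dropped, mirroring the analysis side's
decision to count only completed intervals. An orientation bias δ rotates
each look's recorded quadrant: the intended gaze (quadrant mid-point + δ) is
re-binned to the quadrant arc [mid−45°, mid+45°), so δ = 45° registers as a
one-quadrant occupancy rotation under the coarse coding. Ground-truth
parameters are emitted alongside the logs for recovery tests.

**What the generator does not emulate:** predator arrivals or alarm events,
alternation between foraging and sentinel bouts, within-bout
non-stationarity, helper status, vertical head movements, and observation
gaps. Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes — not that real recordings satisfy those
assumptions.

**A calibration caveat found with this generator.** The printed mean
occupancies give the duration-weighted mean angle a small intrinsic tilt
(−4.2°, because quadrants 2 and 4 are not symmetric), and quadrant
persistence makes consecutive looks positively dependent, which the iid von
Mises bootstrap does not model. Under full default conditions the δ = 0
side-bias flag rate is therefore elevated above the nominal 0.05 and varies
season to season (`scripts/acceptance.py` reports it per run as
`bias_flag_rate_default`); with a symmetric q2/q4 occupancy and persistence
0 — conditions where the iid null is exact — the test suite verifies it
stays at the nominal level. Real sentinel data share both features, so some
reported side biases may partly reflect this anti-conservatism.

## Numerical choices and edge cases

- Random seeds: every sampler, bootstrap and simulation takes an explicit
  seed (default 20221206); pipeline stages draw named substreams from one
  root `SeedSequence`, making result bundles bit-reproducible.
- KS ties: the two-sided D over jump points is exact under ties; synthetic
  samples are continuous unless `quantize` is passed.
- `kappa` inversion `A1(kappa) = R` is solved by Brent's method on
  exponentially scaled Bessel ratios (stable for kappa up to 1e8).
- Antipodally balanced angle sets (resultant < 1e-12) raise an
  undefined-mean error rather than returning an arbitrary direction.
- Zero-variance duration sets raise a degenerate-data error from the normal
  and log-normal MLEs.
- A single group (or individual) drops the corresponding random effect with
  a warning instead of fitting an unidentifiable variance.
- Problem sizes in the test suite: the shared synthetic study uses 30
  observations (~4300 looks), calibration checks use 400 observations
  (~55k looks), Monte-Carlo calibrations 200–500 replicates, and coverage
  checks 20 replicate fits — chosen as the smallest scales at which the
  checked properties are stable.

## Known limitations

- The exponential/Weibull link and parameterisation are conventional
  choices; reported ELPD values are data-dependent, so only the family
  *ordering* is comparable across implementations.
- The Weibull sampler mixes somewhat more slowly than the others (max R-hat
  ~1.07 at study scale); its ELPD ranking is insensitive to this, but tail
  quantiles of its shape posterior should be treated with care.
- The duration-weighted von Mises bootstrap treats looks as independent;
  see the calibration caveat above.
- Return-time endpoint conventions differ by one head-move duration; both
  are provided, and medians differ by ~0.1–0.2 s at the default head-move
  law.
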