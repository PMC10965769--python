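# Methods

This note documents the models, parameter conventions, and numerical choices
behind `acuitywm`, and what the synthetic-data tests do and do not establish
about real data.

## Generative model of change detection

An observer with capacity *k* (items, real-valued) presented with a set-size
*N* memory array stores `s = min(k*, N)` items, where the per-trial integer
realization `k*` is `floor(k)` plus one additional item with probability
`k − floor(k)`.  This realization matches the reading of capacity as the
*average* number of items memorized, and makes the expected stored count
exactly `min(k, N)` for integer-crossing capacities.  A change is detected
iff the changed item is stored.  Otherwise — and on every no-change trial —
the observer responds "different" with guess rate *g*.  With lapse rate
λ the final response is replaced by a fair coin with probability λ.
Closed-form expectations (λ = 0):

    E[hit rate]         h = s/N + (1 − s/N) g
    E[false-alarm rate] f = g

Substituting into Pashler's whole-display correction
`K = N (h − f)/(1 − f)` returns `s` exactly, so the estimator is unbiased
for `min(k, N)` under this model for any guess rate.  This inversion is the
reason the whole-display formula (and not the single-probe variant) is used
throughout.

Parameter defaults for simulated cohorts: capacity drawn from a normal
(mean 3.25 items, SD 0.9) truncated to [1.5, 5]; guess rate 0.5 (a free
parameter of the generator — guessing is not modeled in the estimator, and
the expectation above shows the estimator is insensitive to it); lapse 0.02.
The non-zero lapse default matters: with λ = 0 every observer with k ≥ 2 is
at a hard ceiling at set-size 2, giving a zero-variance K column that no
empirical cohort shows (observed SDs at the smallest set-size are small but
strictly positive).  Parameter-recovery tests that stipulate a lapse-free
observer set λ = 0 explicitly.

## Capacity estimation conventions

* **K**: raw hit/false-alarm proportions enter the formula; the reported K
  is clamped to [0, N] and the raw value is retained (`k_raw`) for moment
  computations.  `f = 1` yields an explicit undefined (NaN) result.
* **d′ = Z(h) − Z(f)**: rates of exactly 0 or 1 are replaced by `1/(2n)` and
  `1 − 1/(2n)` (n = trials in that cell) *for d′ only*.  The log-linear
  (add ½) correction is a reasonable alternative; the `1/(2n)` rule is used
  because it leaves non-extreme cells untouched.
* **Maximum capacity**: K at the largest tested set-size, with a per-subject
  flag when K at a smaller set-size exceeded it (an indication the largest
  set-size did not capture that subject's plateau).
* **Repeated-measures ANOVA**: one-way within-subject decomposition with
  uncorrected degrees of freedom (no sphericity correction, stated in the
  output), partial eta squared as `SS_effect / (SS_effect + SS_error)`;
  pairwise contrasts are paired t-tests with Benjamini–Hochberg step-up
  adjustment (via statsmodels).  The ANOVA is implemented in closed form and
  cross-checked against `pingouin.rm_anova` in the test suite.
* **Exclusions**: overall change-detection accuracy strictly below 0.60
  excludes a subject; dot-task mean accuracy more than 3 SD from the cohort
  mean (single pass, strict inequality) excludes a subject.  Both rules log
  the subjects they remove.

## Psychometric model of numerosity comparison

The probability of judging the comparison array (numerosity N, reference
N_ref) more numerous is `½(1 + erf( ln(N/N_ref) / (√2 ω) ))` — Gaussian
internal noise on log numerosity with Weber fraction ω.  Natural log is the
fixed convention; any other base would only rescale ω.  Acuity is reported
as 1 − ω.

Fitting minimizes squared error between observed and predicted per-cell
proportions of "comparison larger" responses over the 16 (reference ×
comparison) cells, with R² = 1 − SSE/SST as goodness of fit; this
variance-explained criterion is the package default, and binomial maximum
likelihood is available (`objective="ml"`) and agrees closely on clean data.
A per-ratio formulation (8 pooled cells on proportion correct) is offered as
an option.  The fit is one-parameter by design: no lapse term, following
common practice for this two-reference design (the generator supports lapse;
the fitter does not estimate it).  Optimization is a 64-point log-spaced
grid over ω ∈ [0.01, 2] followed by bounded scalar refinement — effectively
a multi-start that is immune to the objective's flat shoulders at extreme ω.

Design note: the 192-trial design carries limited information about large
Weber fractions.  At ω = 0.3 the Cramér–Rao bound for this design is an SD
of ≈ 0.05 per subject, i.e. a median absolute single-subject error of
≈ 0.034 for any unbiased estimator.  Recovery claims are therefore stated
about the *median recovered* ω (bias ≈ 0.003 across ω ∈ {0.1, 0.2, 0.3}),
not about single-replicate precision.

## Stimulus geometry

Dot-array pairs are feature-matched under one of two regimes: equal total
dot surface (radius ∝ 1/√n, exact by construction, verified post hoc at 1%)
or equal density, operationalized as numerosity / convex-hull area (the
package's explicit definition, with mean nearest-neighbor distance reported
as a secondary spacing metric).  Density matching first calibrates the
placement envelope against realized hull densities to within 1%, then
accepts a fresh draw within 5%: convex hulls fill their envelope more
completely at higher numerosity, so accepting first draws within the band
would leave a numerosity-correlated residual — the calibrate-then-redraw
scheme leaves symmetric sampling noise instead.  The audit path (hull,
surface, density, spacing, and their correlation with numerosity difference
across a pool, flagged at |r| > 0.3) shares no code with generation, so the
matching claims are falsifiable.

No display parameters were available for this design; the defaults — 7°
square field, 0.25° base dot radius, minimum center spacing of 3 dot radii —
are explicit choices.  The 3-radius minimum (rather than a more conservative
4) is deliberate: random sequential placement jams near 55% disc coverage,
and 1.0°-exclusion discs in a 7° field cap out near 34 dots, below the
design's 40-dot maximum.

## Moment extrapolation and the Pearson system

To ask what capacity estimates would look like at an untested set-size, an
independent least-squares line over set-size is fitted to each of the first
four moments of the per-set-size K distributions (SD with n−1; skewness and
kurtosis population-style by default, bias-corrected variants available;
kurtosis raw, normal = 3) and evaluated at the target.  Replicate cohorts
are then drawn from the Pearson-system member with the predicted moments,
truncated to the admissible K range [0, 6] by rejection (clipping offered as
an option, since published descriptions of such bounding are often
ambiguous between the two).

The sampler selects the Pearson type from (skewness², kurtosis) by the
standard criterion and samples each member on a standardized scale: types 0,
I, II, III and VII have closed-form parameterizations (normal, beta,
symmetric beta, gamma, scaled Student t) that match all four moments
exactly; type V (inverse gamma) solves its shape from the skewness
equation; type VI (beta prime) solves both shapes numerically; type IV,
which has no closed-form sampler, is drawn by inverse CDF on the arctan
transform, where the density `cos^{2m−2}θ · e^{−νθ}` is bounded and smooth
on (−π/2, π/2) and a 200,001-point quadrature grid inverts it accurately.

The hardest practical case — exercised directly by the tests — is a
near-boundary type I: the moment vector extrapolated from the reference
cohort's printed summaries (mean 5.243, SD 0.511, skewness −0.051, kurtosis
1.114) sits just above the feasibility bound kurt = skew² + 1 = 1.0026 and
maps to a U-shaped beta with shape parameters ≈ 0.09.  Its support,
[4.67, 5.78], lies inside [0, 6], so truncation is inert there, and the
pooled median stabilizes at 5.319 ± 0.004 across seeds (10,000 cohorts of
41).  Because the member's slight *negative* skew places its median at or
above its mean (5.243), no Pearson-consistent reconstruction from these
printed (rounded) summaries can produce a pooled median as low as the 5.03
reported for the original analysis; reproducing that value exactly would
require the unrounded data moments.  The package states the reconstruction
it actually computes.

## Bayesian correlation test

BF01 = f(r | ρ=0, n) / ∫ f(r | ρ, n) π_κ(ρ) dρ, with f the exact sampling
density of the Pearson correlation of a bivariate-normal sample (Hotelling's
single-hypergeometric form; for n > 200 a Fisher-z normal approximation is
substituted, and the two are cross-validated near the crossover) and π_κ a
symmetric beta(1/κ, 1/κ) stretched to (−1, 1).  κ defaults to 1/3 and is
fully configurable; the prior is two-sided since no directional hypothesis
is assumed.  Integration is adaptive quadrature at relative tolerance 1e−8.
The implementation is validated three ways: a frozen value from a 10⁶-node
Riemann oracle at (r=0, n=41, κ=1/3), agreement with an independent
closed-form implementation (pingouin's Ly method), and a simulation oracle
that estimates both marginal likelihoods by kernel density at the observed r.

Cohort sizing inverts the Fisher-z power relation using the standard mean
bias correction `atanh(r) + r/(2(n−1))`, searching for the smallest n whose
achieved power reaches the target (two-sided α = 0.05, power 0.8 defaults);
this yields n = 29 at r = 0.5 and brackets 19–46 over r ∈ [0.6, 0.4].

## Pipeline and reproducibility

`run_pipeline` executes simulate/ingest → exclusions → estimation →
validity/contrasts → extrapolation → correlation, with per-stage RNG streams
spawned from the master seed, so identical configurations reproduce outputs
bit-for-bit.  Reports are validated against a JSON schema shipped in the
package by a minimal structural validator (type/required/properties).
Practice trials (16 per task, when generated) are flagged and excluded from
analysis; block structure and task order are carried as metadata only —
analyses pool over blocks.

Problem sizes used in the shipped tests: 41-observer cohorts on the full
810-trial and 192-trial designs for parameter recovery; 200 replicates per ω
condition; 100 replicate cohorts per correlation scenario for the Bayes
factor majority property; 10⁵ draws for Pearson moment recovery; 10,000 × 41
for the set-size-6 simulation.  These match the study conditions where the
design prescribes them and are otherwise chosen to keep Monte-Carlo error
well below the tolerances being asserted.

## What the synthetic tests do not show

The generators implement exactly the assumptions of the estimators (discrete
slots with uniform item sampling, Gaussian log-numerosity noise, stationary
parameters across blocks).  Passing recovery tests therefore demonstrates
the internal consistency and numerical correctness of the chain, not that
real observers satisfy these assumptions: encoding variability, attention
fluctuations slower than a per-trial lapse, response biases in the dot task,
and retention-interval decay are all absent from the generators, and reaction
times are out of scope.  Validity and reliability checks on real data remain
empirical questions the pipeline can measure but not guarantee.
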