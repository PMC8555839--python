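# Methods

## Models

### Processing trees

Each experimental condition is a binary multinomial processing tree. A
direct question (DQ) has two categories: "true" with probability π and
"false" with probability 1−π. A crosswise (CWM) question pairs the
sensitive statement with an innocuous statement of known prevalence *p*;
the "both/none true" category collects the branches π·p and (1−π)(1−p), and
"exactly one true" the two cross branches. Branch probabilities are products
of parameters θ or complements 1−θ; category probabilities are sums of
branch probabilities and sum to one per tree for every parameter vector —
this is enforced structurally and checked by randomized property tests.

Counts per condition are product-multinomial. The log-likelihood is
maximized by the standard MPT expectation-maximization scheme: the E-step
distributes each category count over its branches proportionally to branch
probabilities, and the M-step sets each parameter to its expected
direct/(direct+complement) usage ratio. The likelihood is non-decreasing at
every EM step (asserted at run time). Goodness of fit is
G² = 2(ℓ_saturated − ℓ̂), asymptotically χ² with df = (independent
categories) − (free parameters); nested models are compared through
ΔG² with df equal to the number of restrictions and an upper-tail χ²
p-value. No multiplicity correction is applied across model comparisons
(only the Likert t-tests are Bonferroni-corrected, matching the analysis
the pipeline reproduces).

### Shrinkage (order-constraint) reparameterization

The instruction-by-technique interaction is tested by reparameterizing
π_fake = α·π_honest per technique and equating the α's. The substitution is
performed as an exact branch rewrite that keeps the model a binary MPT:
a factor α·π is two chained factors, and 1 − α·π splits into the two
branches (1−π) and π(1−α). EM then applies unchanged with α ∈ [0, 1].

When the fake-good estimate exceeds the honest one, the rewrite is mirrored
(π_honest = β·π_fake, β ∈ [0, 1]) and α = 1/β̂ is reported with a flag; the
reported value is capped at 2. This keeps the EM parameter space inside
[0, 1] while avoiding a hard cap at 1 that would bias the interaction test,
and makes the interaction ΔG² exactly invariant to relabeling which
condition is called "honest" (checked in the tests). The equal-α restricted
model is fitted in both orientations and the better likelihood kept.

### Standard errors

SEs come from the inverse observed Fisher information, computed as a
central-finite-difference Hessian of the log-likelihood at the MLE
(step 10⁻⁵, shrunk near bounds). For the just-identified single-tree
models this reproduces the delta-method closed forms
SE(π̂_DQ) = √(π̂(1−π̂)/n) and SE(π̂_CWM) = √(λ̂(1−λ̂)/n)/|2p−1| to four
decimals, and for the ratio parameters the usual delta-method ratio SE.
Estimates within 10⁻⁷ of a bound are flagged and their SE reported as
undefined rather than extrapolated; a singular information matrix is
flagged, never silently pseudo-inverted.

### Numerical choices

* EM convergence: absolute log-likelihood change < 10⁻¹⁰, at most 10,000
  iterations. Parameters are clipped to [10⁻⁸, 1−10⁻⁸] so E-step weights
  stay defined.
* Default initialization is 0.5 for every free parameter, with 20
  deterministically seeded random restarts on non-convergence. The study
  pipeline initializes at closed-form estimates (which are the exact MLEs
  of the just-identified trees), so its fits converge in a handful of
  iterations.
* EM converges very slowly along nearly flat ridges — typically a ratio
  parameter whose MLE sits at or near 1. A fit that has not converged is
  polished by a bounded L-BFGS-B step on the same likelihood and then
  *confirmed* by EM from the polished point; convergence is only declared
  by the EM criterion. Comparisons refuse unconverged fits.
* Closed-form CWM estimates falling outside [0, 1] are returned unclipped
  with a flag; the ML path stays inside bounds by construction. The two
  agree to 10⁻⁶ whenever the closed form is interior.

## Privacy analysis

For 0 < π, p, λ < 1 the posterior carrier probabilities are
Pr(carrier | both/none) = πp/λ and Pr(carrier | one) = π(1−p)/(1−λ), with
λ = 1−p+π(2p−1) derived from the model identity when not observed. Both lie
strictly in (0, 1) (response symmetry: no safe answer exists), they satisfy
the law of total probability exactly, and the lower-risk option is
"both/none" iff p < ½ (comparison of numerators p vs 1−p).

## Synthetic respondents

The generator emulates the data-generating process the analysis assumes.
Defaults are the study conditions: N = 1,946 split 2:1 crosswise:direct and
1:1 honest:fake-good by deterministic largest-remainder allocation
(reproducible group sizes; the published cell sizes can be set exactly via
`group_sizes`), p = .158, and true prevalence 0.4553 — the honest crosswise
estimate, taken as the best available stand-in for the unknown truth.

Strategies: *truthful* respondents answer the DQ with their carrier status
and the CWM with "both/none" iff carrier status equals the randomization
event; *fake-good* respondents always deny the DQ, while their CWM
behaviour is a configurable mixture over answer-as-if-honest (default
weight 1 — the headline finding is that respondents cannot identify a
self-protective crosswise answer), always-pick-the-less-risky-option, and
uniform random; *random* responders pick a category uniformly (default rate
0, with 5–14% a plausible range for exploration). Faking and
random-responding are modeled at the answer stage only; the generator does
not model item nonresponse, multi-item designs, or respondent-level
heterogeneity in understanding, so passing recovery tests demonstrate
correctness of the inferential machinery under the assumed process, not
robustness to real-world instruction non-adherence patterns beyond the
mixtures modeled.

Likert items are drawn from a latent normal per condition with the
published means as targets and SD reconstructed as SE·√n from the published
summary statistics (e.g. 0.12·√326 ≈ 2.17), then rounded and clamped to
1–7. Rounding/clamping biases the mean, so the latent location is
calibrated by root-finding so the discretized mean hits the target; the
real data's distributional shape beyond mean and SE is unknown, and this
reconstruction is a modeling choice. The published real-data means are
therefore *inputs* to the generator, recovered to within 0.05 by
construction — not independently reproduced results.

## Likert analyses

Each of the three experience items gets a 2×2 between-subjects ANOVA using
Type III sums of squares with sum-to-zero contrasts (appropriate for the
unbalanced design and matching the independent main/interaction framing of
the power analyses), plus the four predeclared pairwise comparisons as
Student (pooled-variance) t-tests — a Welch option is provided — with
p-values multiplied by 4 and capped at 1 (α_adj = .0125).

## Power and design

Sensitivity (minimum detectable effect size) and post-hoc power for
two-sample t-tests use the exact noncentral t distribution with
ncp = d/√(1/n₁+1/n₂); MDES is solved by root-finding to 10⁻⁶. ANOVA power
uses the noncentral F with ncp = f²·N. At the study's N = 1,946 the ANOVA
sensitivity computes to f ≈ .0635 (commonly rounded to .06); the computed
value is reported, not the rounded one. Power for detecting a nonzero
prevalence determines the exact rejection region of the one-sided Wald
statistic over the answer counts (binomial SE for DQ, crosswise
delta-method SE for CWM) and evaluates it by a continuity-corrected normal
approximation, with a Monte-Carlo mode as cross-check. The allocation
helper returns the square root of the per-respondent variance ratio
(Neyman-style); at π = .35, p = .158 it gives ≈ 1.5, which survey practice
rounds up to the 2:1 convention.

## The canonical count fixture

Raw answer frequencies are not part of the package's inputs; the built-in
table {DQ-honest 117/334, DQ-fake 51/326, CWM-honest 338/637, CWM-fake
360/649} was reconstructed by inverting the published percentage estimates
at the published group sizes and verifying neighbouring integers fail the
printed rounding. Three counts are unique; the CWM-honest count 338
computes to 45.52% where 45.53% was printed (a rounding artifact of the
inversion), so reports render the computed value and the instruction
contrast for the CWM (printed 0.75) reproduces as ≈ 0.75–0.76. No tuning is
applied to force digit-level agreement.

## Problem sizes in the test suite

The distributional acceptance checks use 500 replicates for parameter
recovery and coverage at the study's group sizes, 1,000 replicates for the
χ²₁ null calibration of the five comparison tests, 10⁵ draws for simulator
identities and Likert calibration, and 40–60 replicates for the Likert
power/null simulations — sizes chosen so Monte-Carlo error is well inside
the asserted bands while the whole suite stays fast.

## Known limitations

* Binary trees only; no S-ary categories, latent-class/hierarchical MPTs,
  or Bayesian estimation.
* The identifiability check is the counting condition (free parameters vs
  independent categories); structural non-identifiability beyond counting
  is not detected symbolically.
* Wald intervals and χ² asymptotics are used throughout, consistent with
  the reproduced analysis; small-sample exact methods are out of scope.
* The privacy profile conditions on truthful instruction-following; it does
  not model strategic answer choice feeding back into λ.
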