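# Methods

## Segmented logistic interrupted time series

The policy evaluation models a binary article-level outcome (has a
data-availability statement; is in-principle reusable) as

    logit P(y=1) = β₀ + β₁·t + β₂·post + β₃·t·post,

with `t` the submission date minus the policy date in units of 50 days
(negative pre-policy) and `post = 1(t ≥ 0)`. The time origin sits at the
policy date, so the model is equivalent to two period-specific lines:
intercepts β₀ and β₀+β₂, slopes β₁ and β₁+β₃. An article submitted exactly
on the policy date is post-policy — the mandate applied to submissions on
or after that date — and correspondingly the first half-open 50-day time
bin starts at day 0.

Estimation is maximum likelihood by iteratively reweighted least squares
(statsmodels GLM, binomial family), gradient tolerance 1e-8, at most 100
iterations; the covariance matrix is the inverse observed information at
the optimum. The fit refuses to return estimates when either period lacks
both outcome classes or the coefficients diverge (|β̂| > 30) — both signal
(quasi-)separation, under which the MLE does not exist; callers get an
explicit `SeparationError` rather than a misleadingly converged fit.

### Risk-ratio reporting and anchors

Effects are presented as risk ratios. The anchored conversion
`RR = OR / ((1−P₀) + P₀·OR)` is algebraically exact for the logistic
model's own probability ratio when OR = exp(Δη) and P₀ = expit(η₀): the
package tests this identity to 1e-12. Anchor choices (exposed as model
probabilities in each `EffectEstimate`):

* **level change** — OR exp(β₂), anchored at expit(β₀), the model
  probability immediately pre-policy; compares an article submitted just
  after the policy with one just before;
* **pre-policy trend** — OR exp(β₁), same anchor;
* **post-policy trend** — OR exp(β₁+β₃), anchored at expit(β₀+β₂), the
  probability immediately post-policy;
* **slope ratio** — the ratio of the converted post- and pre-trend risk
  ratios; its Wald p-value tests β₃ (on the odds scale the slope change
  and its test coincide there).

These anchors are the natural immediately-pre/immediately-post reading of
a level change at the intervention point; other anchors (e.g. period-mean
probabilities) are defensible and would move the converted numbers
slightly, which is why every estimate also carries its odds ratio.

Confidence intervals for risk ratios are delta-method intervals computed
on the log-RR scale and exponentiated, using the analytic gradient
`∂ log expit(η)/∂β = (1−expit(η))·x`. When the anchor probability is
near zero the RR collapses onto the OR and the interval onto the ordinary
Wald interval (tested).

### Trend decomposition

The joint effect of one 50-day interval plus the policy, relative to
immediately pre-policy, is decomposed additively on the excess-relative-
risk scale. Here the square-root approximation RR ≈ √OR is used instead of
the anchored conversion — the outcome is common in the post-period, and the
√OR transformation keeps the three components on a single comparable scale
without tying each to a different anchor. With

    rr_time = √exp(β₁),  rr_policy = √exp(β₂),  rr_joint = √exp(β₁+β₂+β₃),

the shares of the joint excess `rr_joint − 1` are

    share_baseline    = (rr_time − 1)   / (rr_joint − 1)
    share_policy      = (rr_policy − 1) / (rr_joint − 1)
    share_interaction = (rr_joint − rr_time − rr_policy + 1) / (rr_joint − 1)

whose numerator in the last line is the relative excess risk due to
interaction (RERI); the three shares sum to one identically. Standard
errors run the delta method through the full chain β → shares with the
analytic Jacobian (checked against central differences to 1e-6); p-values
are one-sided tests of each share against zero, matching how such
attribution shares are reported. The decomposition is undefined when
rr_joint ≤ 1 (there is no positive joint excess to attribute) and raises
rather than returning signed nonsense. Interval truncation to [0,1] for
the two sign-constrained shares is a display concern left to serialization.

## Interval procedures

* **Wilson, continuity-corrected** (binomial): Newcombe's closed-form
  score bounds; the lower bound is pinned to 0 at x=0 and the upper to 1
  at x=n, and both are truncated to [0,1]. Reported percentages round
  half away from zero to integers.
* **Sison–Glaz** (simultaneous multinomial): implemented from the
  conditional representation of the multinomial as independent Poissons
  given their sum. For integer half-width c, each Poisson(nᵢ) is
  truncated to [nᵢ−c, nᵢ+c]; its central moments are computed exactly
  from the pmf (the supports are tiny, so no factorial-moment recursion
  is needed); the probability that the truncated sum equals n is
  approximated by an Edgeworth expansion with the summed third and
  fourth cumulants; dividing by the exact Poisson(n) mass at n gives the
  coverage ν(c). The returned c is the smallest integer with
  ν(c) < level ≤ ν(c+1) (an exact tie resolves to the covering c with
  γ=0), γ interpolates linearly, and every cell gets the same pre-
  truncation bounds p̂ᵢ ± c/n (upper + 2γ/n). The implementation is
  cross-checked in the tests against statsmodels'
  `multinomial_proportions_confint(method="sison-glaz")` and against
  exhaustive-enumeration coverage (k ≤ 4, n ≤ 35), which lands between
  0.90 and 0.99 for the nominal 0.95.
* **Pearson χ² (2×2)**: no Yates correction — the uncorrected statistic
  is what the pipeline's reference comparisons print — delegated to
  scipy with `correction=False`.

## Reproducibility audit

Percentage error uses |reported| in the denominator so negative reported
values (effect sizes, differences) give positive PE, and the obtained
value is rounded half-away-from-zero to the reported value's printed
decimal places first, so floating-point tails never manufacture spurious
minor errors. Boundary conventions: PE exactly 10 is major; a reported
value of exactly 0 yields PE 0 if the obtained value rounds to 0 and is
otherwise flagged straight to major (relative error is undefined there).
For p-values the significance sides are p ≤ 0.05 versus p > 0.05; equality
on both sides is no decision error; a decision error takes precedence over
a numeric major, but the PE-based major flag is retained internally so
type-by-error tallies can count p-value majors as well. Inequality-form
reported values ("<0.001") never contribute numeric PE: they match when
the obtained value satisfies the bound and otherwise fall to the decision
rule (major when on the same side of 0.05).

Article classification evaluates each value at its final stage (after
assistance when requested; a value the assistance did not touch falls back
to its before-assistance result). Any remaining blocking error → not fully
reproducible (despite assistance, if requested); a clean final state is
reproducible, "with assistance" exactly when the before-assistance state
contained a blocking error. Counting articles whose *initial* check
contained a blocking error is the package's definition of "initially
non-reproducible"; minor-only articles count as initially reproducible,
the only reading under which the three outcome groups partition cleanly.

## Synthetic data

The corpus generator emulates the study conditions of a mid-2010s
psychology journal adopting a mandatory policy: 591 articles, submission
dates uniform in whole days over [−1915, +523] around the policy date,
DAS drawn from the segmented logistic model, and reusability fields drawn
down a conditional cascade (accessible | DAS) → (complete | accessible) →
(understandable | complete) with period-specific probabilities
(.96, .40, .57) pre and (.99, .72, .87) post, landing ≈22% and ≈62%
reusable-given-DAS. Default coefficients are obtained by *exactly*
inverting the anchored OR→RR conversion for risk ratios (trend 1.04,
level 1.53, slope ratio 1.14) at baseline anchor expit(β₀) = 0.35, the
approximate height of the pre-policy trajectory at the policy date.
A single root seed feeds named integer-indexed sub-streams (dates,
outcome, cascade, extras, injections), so adding a stream never perturbs
existing draws and identical parameters give byte-identical CSV output.

What the generator does **not** emulate: coder disagreement, the
editorial article-selection process, non-uniform submission-date density
(real corpora bunch near the policy date because sampling was by
publication date), or any correlation between reusability and article
content. Passing tests therefore demonstrate that the estimators recover
the generating process they assume — parameter recovery at n = 591 over
500 replicates (median risk ratios within 10% of truth, Wald CI coverage
0.90–0.98), not that the model is correctly specified for any real
journal.

The audit generator plants errors whose magnitudes land unambiguously
inside each PE band after printed-precision rounding (×1.03 → minor,
×1.25 → major; integer-printed degrees of freedom are drawn ≥ 34 so a 3%
shift still moves the rounded integer; injected p-values stay away from
0.05 so multiplicative errors never cross the boundary, and decision
errors are planted by explicit crossing). The deterministic
`reference_margin_fixture` reproduces the reference study's exact margins —
1324 values over 35 articles; 64/146/2/0 major/minor/insufficient/decision
errors; outcomes 11/11/13; 57 issues across five loci with 33 resolved
(24 specification clarifications, 8 data-file replacements, 1 original-
analysis correction) — with the seed varying only the cosmetic reported
values. Problem sizes throughout the suite (500 replicate fits, full
enumeration at n ≤ 35) were chosen as the smallest at which the checked
guarantees are sharp.

## Known limitations

* Wald inference throughout; profile-likelihood or robust intervals are
  out of scope, and the separation guard is a heuristic (coefficient
  magnitude), not a certificate.
* The Sison–Glaz coverage function is the standard Edgeworth
  approximation; for very small n or extremely skewed counts the attained
  simultaneous coverage can sit anywhere in the usual conservative band.
* The ITS assumes article-level independence; autocorrelated or
  overdispersed alternatives (segmented Poisson/GEE) are not provided.
* The audit engine classifies printed-versus-obtained values; it does not
  re-run any original analysis or parse statistics out of documents.
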