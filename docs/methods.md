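# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the test suite shows.

## The sampling model

The population is the set of screened, retained posts for one drug over
the surveillance window. It is partitioned into strata by 7-day week
(half-open blocks `[t, t+7d)` counted from the window start; the final
partial block is its own week) crossed with origin class (social media vs
blogs and forums). A week cell with fewer than 2 posts is folded forward
into the next cell of the same origin until the merged cell holds at
least 2; a deficient trailing cell folds backward. Folding keeps
intervals contiguous, and after it every stratum has `N_h ≥ 2` whenever
the drug's total does.

Within each stratum a simple random sample without replacement of size
`n_h` is drawn; every sampled post represents `w_h = N_h / n_h`
population posts. Allocation across strata is proportional to `N_h` with
largest-remainder rounding, a minimum of one per nonempty stratum, and a
cap at `N_h` with surplus redistributed by largest remainder (ties break
on stratum order).

### Sample size

The per-drug `n` is the smallest value for which, with
`K = round(p0·N)` population successes, the probability over
`k ~ Hypergeometric(N, K, n)` that the exact confidence interval attains
half-width `≤ d` is at least the required coverage. Defaults: expected
proportion `p0 = 0.05`, precision `d = 0.015`, coverage 0.95, CI level
95%. The exact CI is obtained by tail inversion: the lower bound is the
smallest `K/N` with upper-tail probability `P(X ≥ k) > α/2`, the upper
bound the largest `K/N` with `P(X ≤ k) > α/2`. A census (`n = N`) has
zero half-width, so a solution always exists.

Numerics: tail probabilities are computed from a cached log-factorial
table with windowed summation — terms more than 30 standard deviations
from the mean contribute less than 1e-100 and cannot affect a comparison
with `α/2`. Bounds are located by binary search (tails are monotone in
`K`). The solver scans `n` upward with a cheap rejection step: if the
half-width at the modal `k` exceeds `d` and the mode alone carries more
mass than the allowed failure rate, coverage cannot be met and full
enumeration is skipped. Support points with mass below 1e-12 are dropped
and counted as failures (a conservative truncation of order 1e-9).
Populations above a configurable threshold (default 10^6) switch to a
Wald half-width with finite-population correction; the exact and
approximate routes are compared on their overlap in tests.

### Estimation

Totals are Horvitz–Thompson expansions `Ŷ = Σ w_i y_i` with the
stratified variance `Σ_h N_h²(1−n_h/N_h) s²_h / n_h` written in the
equivalent per-group form `(1−n_g/N_g)·n_g/(n_g−1)·Σ(z_i−z̄_g)²` on the
weighted values `z_i = w_i y_i`. Strata with a single sampled unit have
no within-stratum variance estimate and are collapsed with the adjacent
stratum of the same origin for variance computation only; this is the
standard collapsed-stratum device and is mildly conservative when the
collapsed strata differ in mean, which is the main reason replicate CI
coverage sits at the upper half of the nominal band in the recovery
studies. CIs are normal-approximation at 95%, truncated at zero for
counts. The CI method on totals is a package choice (normal + FPC);
bootstrap or exact alternatives were not pursued.

Quarterly series report `10,000 × Ŷ_risk / N_quarter` where `N_quarter`
is the exact population size of the strata assigned to the quarter (the
weighted all-posts total is exact, so the ratio CI reduces to scaling the
numerator CI). Folded strata spanning a quarter boundary are assigned to
the quarter of their interval start — a distortion of at most one week.
Origin shares are ratio estimators with delta-method variance computed on
the residuals `w_i (b_i − R̂ r_i)`.

### Interrater reliability and origin contrasts

Three-way percent agreement is the fraction of items with unanimous
labels. Gwet AC1 uses the multi-rater form with `r = 3` raters and
`q = 2` categories: `Pa` is the mean over items of
`Σ_k r_ik(r_ik−1)/(r(r−1))` and `Pe = Σ_k π_k(1−π_k)/(q−1)`. For binary
categories `Pe ≤ 0.5`, so the denominator never degenerates. Results are
acceptable when agreement exceeds 90% and AC1 exceeds 0.60. Disagreements
are settled by an adjudicator, never by majority.

Origin contrasts fit a weighted logistic regression of the risk indicator
on a social-media indicator by IRLS (relative coefficient change below
1e-10 or 100 iterations). Because the sampling weights are design
weights, the SE is a weight-robust sandwich rather than the model-based
one. With one binary predictor the fitted OR is algebraically the
weighted 2×2 cross-product ratio; the implementation asserts this to
1e-8. A Haldane–Anscombe 0.5 correction is applied (with a logged
warning, and a Woolf-style SE on the corrected cells) only when a
weighted cell is zero; an empty origin margin is an error.

## The synthetic corpus

The generator emulates the structural features the analysis depends on:
weekly post volumes per drug and origin over 2015-01-01..2018-12-31; a
tenfold fentanyl volume step from 2017-10-01; key-risk prevalences per
analyzed post in the 0.5–2.5% band (defaults 2.0 / 0.7 / 2.3 / 1.5 /
2.1% for misuse / abuse / addiction / overdose / death); origin-dependent
risk odds planted as a log-odds shift for social-media posts relative to
a blogs/forums baseline, with the sign pattern seen in this kind of
surveillance (fentanyl
overdose and death skewed to social media, abuse and addiction to blogs
and forums); spam, non-English and non-US contaminants; threaded
replies; misspelled drug mentions (one random substitution, usually
outside the lexicon); and occasional secondary drug mentions. Weekly cell
counts are deterministic (`round(volume × multiplier)`), so the corpus
scale is exactly configurable; the default is ≈183k posts, a desk-scale
stand-in for the millions of posts a real crawl yields.

Latent labels are planted as marker phrases from a versioned phrasebook,
and the machine coder recovers them by exact phrase lookup. Misuse and
abuse are mutually exclusive on a post; the misuse draw is conditioned on
the abuse draw so both marginals equal their configured values. One RNG
stream is keyed per (drug, week) cell, so changing one cell's volume
never perturbs any other cell, and identical configurations produce
byte-identical corpora.

What the generator does **not** emulate: natural language (screening
cannot produce the false positives of real text), coder ambiguity (labels
are deterministic phrases; simulated raters flip them with independent
error rates), user-level longitudinal behaviour, and platform dynamics.
Passing tests therefore validate the sampling, estimation and inference
machinery on a population whose structure is known — they say nothing
about the accuracy of keyword screening or human coding on real posts.

## Screening choices

Matching is case-insensitive and whole-token (split on non-alphanumeric),
so "oxymoron" never hits "oxymorphone"; multi-word terms match as token
sequences. Lexicon misspellings can be generated with bounded-edit
Soundex variants (the variant set is finite and deterministic; American
Soundex is the chosen encoding). Exclusion rules run in a fixed order
(window, language, country, source class, then the phrase rules
off-context / spam / pharmacy-news-popculture / indeterminate); the first
match records the reason. The phrase rules are an explicit approximation
of manual screening — the package has no human in the loop. Exclusion
never cascades from an originating post to its replies; a reply matching
a phrase rule is retained when it has informative content, defined as a
drug flag plus a key-risk marker. Unknown domains default to social
media (configurable) with a warning; posts with no recovered drug flag
are excluded as off-context.

## Problem sizes in the validation studies

The replicate recovery studies use the default ≈183k-post corpus with
misspellings disabled (so the sampling frame coincides with the latent
population): 500 replicates for the weighted-total bias and CI-coverage
study, 1,000 simulated samples for the precision check at N = 50,000,
and 200 replicates for the odds-ratio recovery on a dedicated one-drug
corpus (104 weeks, 250 posts/week per origin, planted ln 5 death effect,
explicit n = 3,000). The odds-ratio study fixes its sample size
explicitly rather than using the solver because, at the paper-like origin
mix, the expected blogs-and-forums death cell at solver n is about two
posts and the contrast would be degenerate by construction. The
sample-size solver is checked against a full enumeration oracle at small
N and against independent (scipy) tail probabilities for boundary
minimality at N up to 5,000.

## Known limitations

- The normal CI on totals undercovers slightly when the number of
  positive sampled indicators is small (rare risks in small strata); the
  collapsed-stratum device pushes the other way. Both effects are visible
  as coverage in the 0.93–0.97 band rather than exactly 0.95.
- The planning model pins the success count to `K = round(p0·N)`; if the
  true proportion is far above `p0`, attained precision can fall short of
  the design target.
- Origin shares and ORs condition on the coded sample; risks with very
  few sampled positives yield wide or continuity-corrected intervals.
- The biweekly-fold quarter assignment misattributes at most one week of
  volume at quarter boundaries.
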