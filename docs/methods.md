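# Methods

## The evaluation design

A screening rule is a dichotomization of a simple risk score. All scores
here are oriented so lower = riskier, and positivity at cutoff *c* is
`score ≤ c`; the age rule is positive at `age ≥ threshold` (internally the
negated age serves as its score, preserving the direction convention). The
reference standard is the WHO T-score diagnosis: per site,
osteoporosis at T ≤ −2.5, normal at T ≥ −1.0, osteopenia strictly between —
both boundary assignments are inclusive as written, so the three categories
partition the line. The "any site" diagnosis uses the minimum (worst)
available T-score across lumbar spine, femoral neck and total hip; a
subject with at least one measured site is evaluable, and per-site analyses
simply drop subjects missing that site.

The OSTA index truncates `0.2 (weight − age)` toward zero (−2.1 → −2).
Sources describing the score say only that decimals are "truncated"; we
adopt truncation toward zero because it is the convention consistent with
the published score range of such cohorts (a raw minimum near −11.6
printed as −11, which flooring would print as −12). Flooring remains
available via `osta_index(..., rounding="floor")`.

KKOS-style scores are additive band lookups. The published coefficient
table is external, so the `ScoreTable` type treats it strictly as
configuration (JSON with half-open `[lower, upper)` bands, validated for
gaps and overlaps); the test suite uses a clearly-labelled synthetic toy
table and never imitates the real coefficients.

## Statistics

For each confusion matrix the package reports sensitivity, specificity,
PPV, NPV, LR⁺, Youden's J and the two-point AUC at full precision; display
rounding (percentages to 1 dp, AUC/Youden to 3, LR⁺ to 2) happens only in
the report layer. Two exact identities hold for every matrix and are
enforced by property tests: `J = 2·AUC − 1` (both are affine in
sens + spec) and Bayes consistency of PPV/NPV at the sample prevalence.
Degenerate denominators give NaN markers rather than failures, and LR⁺ at
specificity 1 is reported as `inf`, so scan reports keep a stable shape.

Proportion CIs are exact Clopper–Pearson intervals from Beta quantiles
(lower bound 0 at x = 0, upper bound 1 at x = n), with Wilson available as
an option. The exact method is the default because the published
small-sample interval bounds we reproduce (e.g. 28.4–99.5 for 4/5) are
Clopper–Pearson values and are not reproduced by Wald or Wilson intervals.
Exact coverage over an (n, p) grid, computed by binomial enumeration, is
never below the nominal 95%.

AUCs and their comparison use the DeLong approach via midrank structural
components, so tied scores (inevitable for dichotomous predictors) are
handled as in the tie-corrected Mann–Whitney statistic; the test suite
cross-checks against brute-force concordant/discordant pair counting. For
a single dichotomized rule the AUC reduces to (sens + spec)/2 and its
variance comes from the same structural components reconstructed from the
2×2 counts. The paired comparison returns a two-sided z test; when the
variance of the AUC difference is exactly zero (identical rankings) the
statistic is defined as 0 with p = 1. The comparison method for published
AUC contrasts is not stated in such tables; paired DeLong is the standard
choice for correlated ROC curves measured on one cohort, and point AUCs
are reproducible while published CI bounds and p-values (which depend on
the subject-level joint distribution) are not promised.

Youden-optimal cutoff selection breaks ties toward the higher, more
sensitive cutoff — a deliberate screening-context policy (missing cases is
the costlier error); it is a documented tie-break, not a statistical claim.

Buderer sample sizes use the exact normal quantile (1.959964 at 95%) and
ceiling rounding; with targets S = 0.84, Sp = 0.486, prevalence 0.126 and
margin 0.10 this gives 410 (sensitivity) and 110 (specificity), the
enrollment floor being their maximum.

## Recovering confusion matrices from printed tables

Published accuracy tables print percentages, not counts. Because every
percentage is a ratio of small integers with a shared per-site denominator
pair (cases, non-cases), the counts are recovered by exhaustive integer
search: candidate case counts must re-round every printed sensitivity in
the column, candidate non-case counts every specificity, and each row's
(TP, TN) must additionally re-round the printed PPV and NPV. Searched
jointly across the nine rows of a site column with the constraint
cases + non-cases ≤ n, the solution is unique in practice (31/396 femoral
neck, 10/417 total hip, 16/411 lumbar, 42/385 any site for the modelled
study, each summing to 427). When printed precision leaves the last unit
of a single row ambiguous, the candidate closest to the unrounded target
is taken; all candidates re-round identically, so recovered metrics agree
with the printed table at its own precision. A property test verifies the
round trip (print → recover → print) on random matrices.

One caveat found during verification: published Youden columns are often
computed from the *rounded* percentages (0.774 + 0.641 − 1 = 0.415 where
full precision gives 0.416). The package always computes J at full
precision; the headline values reproduced here agree under both
conventions.

## The synthetic cohort generator

The generator draws (age, weight, height, T_lumbar, T_fn, T_hip) from a
truncated six-dimensional Gaussian. This is the minimal-assumption choice:
the emulated population is summarised only by means, SDs, observed ranges
and a few pairwise correlations, and BMD T-scores in elderly cohorts are
close to Gaussian.

**Correlation anchoring.** The screening score's discrimination is driven
by corr(OSTA, T). Writing L = 0.2(weight − age) for the continuous score,
each T-score is constructed to load on the standardized L with coefficient
equal to its target correlation r (0.234 / 0.350 / 0.304) and to be
conditionally independent of (age, weight) given L; equivalently
corr(age, T) = r·corr(age, L) and corr(weight, T) = r·corr(weight, L),
which hits corr(L, T) = r exactly before truncation. Inter-site T
correlations (not published; default 0.55) and the age–weight correlation
(default −0.1) are set directly; the assembled 6×6 matrix is validated for
positive definiteness at model construction, with an error naming an
offending variable triple when the requested values are jointly
impossible. Height is generated uncorrelated with everything: no height
correlation is published and nothing downstream uses it.

**Truncation.** Age, weight and height are restricted to the published
observed ranges by rejection sampling. Since the published moments
describe the observed (bounded) sample, the pre-truncation (μ, σ) of each
bounded marginal are solved (scipy root-finding on the truncated-normal
moment equations) so that the post-truncation mean and SD match the
targets. Joint rejection perturbs the anchored correlations slightly and
integer truncation of the score slightly more; `diagnose()` measures both
(typically ≤ 0.005 at these parameters) rather than correcting them, and
the measured values stay within the ±0.01 tolerance used in the recovery
tests at n = 100 000.

**Prevalence calibration.** Any-site prevalence is tuned by a single joint
shift δ of the three T means: the worst T moves by exactly δ, so the δ
placing the target quantile of the worst-T distribution at −2.5 is exact
on the calibration draw (n = 200 000 by default, deterministic under the
model seed, monotone in δ by construction). Default marginals give ≈ 12.9%
any-site prevalence; calibrating to the 9.8% target shifts the T means by
about +0.18 SD.

**Measurement precision.** Weight is recorded to 0.1 kg and height to
1 cm (the stated precision of the emulated measurements), age to 0.1 y;
T-scores are kept at full precision so that prevalence calibration is not
quantised. All randomness flows through one seeded generator; the same
seed reproduces the cohort CSV byte-for-byte.

**What the generator does not emulate.** Real referral cohorts have
skewed weight distributions, digit preference in recorded age, site-wise
missingness patterns, and clinically structured (not random) exclusion
flags; none of these are modelled. Passing pipeline tests on synthetic
cohorts therefore demonstrates correctness of the statistical machinery
under the stated population model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Generator-recovery checks use n = 100 000 draws (moments within 1%
relative or 5 Monte-Carlo SEs; SDs within 1.5%; correlations within
±0.01; prevalence within ±0.5 pp), chosen so Monte-Carlo noise is well
below the tolerances while a full test run stays fast; the exclusion-flow
check uses the modelled study's 532 → 427 configuration exactly. Exact-CI
coverage is enumerated, not simulated. Brute-force AUC oracles run at
n ≤ 20 where enumeration is trivially exact. Ceiling in the sample-size
formulas guards against floating-point values epsilon above an integer.

## Known limitations

* Subject-level joint distributions of competing predictors are not
  recoverable from published marginal tables, so published paired p-values
  and AUC CI bounds cannot be reproduced — only point AUCs and marginal
  metrics.
* The per-site case counts recovered by integer search are unique for the
  modelled tables but uniqueness is not guaranteed for arbitrary printed
  tables; `recover_site` then returns the smallest consistent solution.
* The KKOS coefficient table must be supplied by the user; results with
  the toy table are exercises of the machinery, not clinical estimates.
* The Gaussian copula is an assumption; tail dependence between sites is
  not modelled, which mainly affects the any-site prevalence attributable
  to single-site extremes.
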