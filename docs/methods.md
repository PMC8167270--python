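# Methods

## The scoring model

The instrument is an unweighted multi-criteria scorecard. Nine attributes,
organized in five value domains (population health 3, health system 3,
economic 1, organizational 1, environmental 1), are each graded on a
four-level ordinal scale mapped to points A=5, B=4, C=2, D=1. The mapping
is deliberately non-equidistant: the gap between B and C (4 → 2) encodes
that a "low degree of responsibility" is qualitatively closer to "none"
than to "moderate". All attributes carry equal weight; the overall score is
the arithmetic mean of the points over *documented* attributes only
(an attribute is documented iff its grade is present), so missing
information neither inflates nor deflates the score — it instead erodes the
score's *meaningfulness*, which requires at least 7 of 9 attributes
documented and a mean best-source quality of at least 2 points. Source
quality is typed 1/2/3 (producer documentation, institutional reports,
peer-reviewed literature) with points equal to the type; when an attribute
cites several sources only the highest type counts.

Screening is a hard gate in principle (both inclusion criteria yes, both
exclusion criteria no) but the engine still rates excluded innovations and
reports the screening outcome alongside, because the instrument's
validation rated its full sample regardless of screening outcome, and
because the deliberative use of the tool benefits from seeing the score of
an excluded candidate.

### Numerical conventions

* **Rounding.** Overall score and quality mean are rounded half-up to one
  decimal. The published worked examples (41/9 → 4.6, 32/9 → 3.6,
  16/7 → 2.3) are consistent with both half-up and half-even, so the
  convention is a package choice, recorded in `ToolConfig.rounding`.
* **Interval classification** operates on the *rounded* score, so the four
  printed intervals (1.0–2.0, 2.1–3.0, 3.1–4.0, 4.1–5.0) partition the
  1-decimal grid exactly; a raw 2.05 rounds to 2.1 and is classified
  "Few…". Only 1-decimal scores are ever reported.
* **Quality gate on the rounded mean.** The quality-sufficiency flag
  compares the 1-decimal rounded quality mean against the threshold, the
  same convention as interval classification, keeping the printed value and
  the flag consistent (a raw 1.96 prints as 2.0 and passes).
* **Documented but unsourced attributes** count toward availability but are
  excluded from the quality mean (logged at info level). The two rating
  components are defined independently, and discarding a grade because its
  source went unrecorded would conflate them.
* All thresholds (7-of-9, quality 2, point maps, interval edges) live in
  `ToolConfig`; defaults are the canonical instrument and any override
  marks downstream reports non-canonical.

## Agreement statistics

For two raters on q ordered categories, with agreement weights
`w_kl ∈ [0,1]`, `w_kk = 1`:

* weighted percent agreement `p_a` = mean over items rated by both raters
  of `w(x_i1, x_i2)`;
* chance agreement `p_e = (T_w/(q(q−1))) Σ_k π_k(1−π_k)` with `T_w = Σ w_kl`
  and `π_k` the mean across items of the proportion of raters using
  category k;
* coefficient `γ = (p_a − p_e)/(1 − p_e)` — Gwet's AC1 under identity
  weights, AC2 under quadratic weights `1 − ((k−l)/(q−1))²`.

This chance model estimates the propensity of *random* rating from the
pooled category usage rather than from each rater's margin, which is what
makes the AC family resistant to the prevalence and marginal-homogeneity
paradoxes of kappa-type indices. Since `p_e ≤ T_w/q² ≤ 1` with equality
only when every weight is 1 (which forces `p_a = 1`), the estimator cannot
produce 0/0 on valid weight schemes; perfect agreement pins the
coefficient at 1.

**Missing data** are handled by pairwise deletion per attribute: only items
rated by both raters enter `p_a`, `π_k` and N, which is why a
per-attribute reliability table shows varying N.

**Variance.** The SE comes from the two-rater subject-level linearization:
with per-item agreement `a_i`, per-item chance `pe_i = c Σ_k s_ik(1−π_k)`
(`s_ik` the proportion of raters placing item i in k, `c = T_w/(q(q−1))`),
and `γ_i = (a_i − p_e)/(1 − p_e)`,

```
γ*_i = γ_i − 2(1 − γ̂)(pe_i − p_e)/(1 − p_e)
Var(γ̂) = Σ_i (γ*_i − γ̂)² / (n(n−1))
```

No finite-population correction is applied: the rated innovations are
treated as a sample from an unbounded universe of candidate innovations. A
delete-one jackknife implements an independent variance estimate; the two
agree within a few percent on study-sized tables and the test suite
enforces 10%. Confidence intervals are `γ̂ ± t_{1−α/2, n−1}·SE` clipped to
[−1, 1]; the p-value is a two-sided t test of γ = 0 (we had to choose a
sidedness; two-sided is the conservative default). Perfect agreement gives
SE 0 and the p-value is reported "n/a".

**Interpretation scales.** Landis–Koch bands (<0 Poor, 0–0.20 Slight,
0.21–0.40 Fair, 0.41–0.60 Moderate, 0.61–0.80 Substantial, 0.81–1.00
Almost perfect) are resolved on the 2-decimal rounded coefficient so the
printed bands partition. Pearson's r (scipy) is interpreted with the
Hinkle rule of thumb on |r| (0.90–1.00 very high, 0.70–0.90 high,
0.50–0.70 moderate, 0.30–0.50 low, below 0.30 negligible) with the sign
reported in the label.

**Sample-size planning** uses the worst-case normal approximation for a
proportion: the smallest n with `z_{1−α/2}·√(0.25/n) ≤ margin`. A margin of
±0.20 at 95% confidence plans for 25 subjects (⌈24.01⌉).

## Synthetic data generator

`simulate_pair` draws rater 1 i.i.d. from a category marginal; rater 2
copies rater 1 with probability `agreement_prob` and otherwise disagrees
by an `independent_redraw` from the marginal (nominal scales) or by an
`adjacent_category` slip of ±1 rank, reflected at the scale ends (ordinal
scales — raters plausibly err by one level). Cells are masked completely
at random at `missing_rate`, either per cell or per item (the item mode
mimics information being unavailable for an innovation as a whole, which
is how missingness arises in practice). Everything is reproducible from
the integer seed.

`simulate_scorecards` defaults to the validation study's conditions:
25 innovations; per-attribute grade marginals equal to the observed
grade distribution of that study's sample; per-attribute missingness
equal to 1 − documented/25 there (from 0 for health relevance to 0.56 for
eco-responsibility); inclusion criteria always met and each exclusion gate
tripping for 12% of innovations. The source-type mix is not published, so
the default (0.4, 0.3, 0.3) over types 1/2/3 was chosen once so that
roughly a third of simulated innovations clear the quality gate, matching
the reported rating-step distribution.

Because the generating process is fully specified, agreement statistics
have closed forms under it. `population_coefficient` evaluates γ at the
generator's exact joint distribution (the large-sample limit of the
estimator). `expected_coefficient` additionally corrects for finite-sample
bias of the *estimator* at n items, to O(1/n): the chance-agreement
estimator `c Σ_k π̂_k(1−π̂_k)` is biased down by exactly `c Σ_k Var(s_k)/n`,
and the ratio contributes second-order delta-method terms in the variance
of and covariance between the observed- and chance-agreement estimators
(all moments computed by enumeration over the q² joint outcomes, the
chance term linearized in the category propensities; with missingness, n
is replaced by the expected complete-pair count). At study size (n = 25)
this correction is up to ~0.011 — material against Monte-Carlo error at
hundreds of replicates — and the corrected expectation matches simulated
estimator means to within ~0.0006.

### What the generator does and does not emulate

It reproduces the study's scale, marginals, missingness pattern and a
tunable agreement level, so estimator properties (calibration, SE accuracy,
monotone recovery of designed agreement) are testable offline. It does not
model rater-specific bias or drift, correlation of grades across attributes
within an innovation, informative (non-random) missingness, or the shared
evidence base that coupled the real raters' judgments. Passing tests
therefore validate the *estimators and the engine*, not the instrument's
field reliability.

## Problem sizes in the test suite

Monte-Carlo checks use study-sized tables (25 items, 4 categories) with
500 replicates per designed agreement level for calibration tests, 100
random tables for the jackknife cross-check, and up to 2000 synthetic
scorecards for marginal-recovery checks; the whole suite runs in a few
seconds on one core.

## Known limitations

* Strictly two raters; the multi-rater generalizations of AC1/AC2 are out
  of scope, as are kappa-family alternatives.
* The published per-attribute reliability coefficients cannot be
  reproduced exactly because the raw two-rater data were not published;
  only the perfect-agreement rows, the worked scorecards and the
  estimator's distributional properties are checkable.
* Grades are inputs: the package does not appraise evidence, compute the
  burden-of-disease quartile behind the health-relevance grade, or weight
  attributes (the instrument argues explicitly for equal weights).
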