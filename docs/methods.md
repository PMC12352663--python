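# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limits of what the test suite demonstrates.

## Cohort model and inclusion filters

The analysis unit is a dog with six demographic predictors — age (years),
weight (lbs), breed background (purebred vs mixed), and a four-level
sex/sterilization status encoded as three dummies with spayed female as the
reference — plus a lifetime set of health conditions and owner-reported
onset dates for a subset of them.  Reference levels are immaterial for the
pipeline: any full-rank coding yields identical fitted probabilities, which
is all downstream stages consume.

Inclusion follows the survey-analysis convention: conditions reported by
fewer than 60 dogs are dropped (the one-in-ten rule — six predictors and an
intercept need on the order of 60+ events for a stable logistic fit), then
dogs left with no retained condition are dropped.  The condition filter
runs exactly once, on the full cohort; there is deliberately no re-filter
loop after dog removal, so a condition may sit below 60 in the final
cohort.  Month-precision onset dates (YYYY-MM) are imputed to day 15 —
deterministic and centered — and flagged; duplicate (dog, condition) events
are a hard error rather than silently merged, because surveys should not
produce them and silent repair hides upstream bugs.

## Individualized risks

One logistic regression per condition, fitted by maximum likelihood
(statsmodels) on internally z-scored age and weight for optimizer
stability; coefficients and their covariance are mapped back to the raw
scale before reporting, so the published table is in per-year and per-pound
log-odds units.  There is no age×weight interaction and no regularization
by default.  When plain MLE fails (perfect separation, non-convergence) the
model is refitted with a weak L2 penalty on the slopes only (λ = 1e-4,
scikit-learn, which leaves the intercept unpenalized) and flagged
`penalized`.  Wald standard errors and p-values are emitted; where a
likelihood-ratio test might disagree (rare events), the Wald choice is
documented rather than hidden.

A structural identity worth knowing: because every model contains an
intercept, the fitted probabilities of each condition sum exactly to its
observed event count.  This is what centers the downstream Poisson-binomial
means.

## The co-occurrence test

For a pair (y, z), each dog contributes an independent Bernoulli trial with
success probability P(y∈d)·P(z∈d); the observed number of dogs with both
conditions is compared to the upper tail of the resulting Poisson binomial
(mean Σp, variance Σp(1−p)).  The tail is one-sided: an edge always means
*more* co-occurrence than the covariate-adjusted chance level.  The normal
approximation with a half-unit continuity correction is used pipeline-wide;
the correction measurably improves small-count tail accuracy and can be
switched off for strict replication of a plain normal tail.

Accuracy of the approximation: against the exact dynamic-programming tail,
the worst absolute error over random trial sets (probabilities uniform on
[0.001, 0.3]) occurs near the distribution median and scales with the
skewness γ₁ ≈ 0.18·√(100/n): about 0.012 at n = 100 trials, under 0.005
once n exceeds roughly 600, and under 0.004 everywhere for n ≥ 1000.  In
the decision region that matters for Bonferroni-corrected edges (tail
probabilities below 0.05) the error is an order of magnitude smaller.  The
exact O(n²) tail is exposed (`poisson_binomial.exact_upper_tail`) for
verification at any size a test needs.

Multiplicity control is Bonferroni over the C(M, 2) pairs actually tested
(α = 0.001 for the unstratified network, 0.01 for stratified, both
configurable), and a pair is only flagged when its observed correlation is
positive.  The correlation operand is configurable: the default correlates
the observed binary indicator vectors (a genuine co-occurrence check); the
alternative correlates the two fitted-probability vectors, which measures
shared covariate effects instead — both are provided because the
verification step can be read either way, and the choice is surfaced
rather than buried.  Untestable pairs (degenerate null variance) are kept
in the output with p = 1 and a flag so result tables always have C(M, 2)
rows.

The covariate-blind baseline — joint probability as the product of the two
sample prevalences, tested against a binomial — is implemented alongside
for contrast.  On cohorts where both members of a pair are age-driven but
conditionally independent, the baseline rejects the null for the majority
of pairs while the adjusted test stays near its nominal level; this
contrast is exercised by the acceptance studies.

### Calibration and the plug-in effect

Two distinct null protocols appear in the tests:

1. **Fitted-model null** (parametric bootstrap): condition indicators are
   redrawn independently from the fitted per-dog probabilities, and the
   redrawn counts are tested against those same fitted moments.  Here the
   raw p-values are approximately uniform (KS ≈ 0.02 at 10,000 pair draws
   without the continuity correction) and the 0.05-level rejection rate
   sits near nominal.  This isolates the distributional accuracy of the
   test statistic itself.
2. **Full refit pipeline**: models are fitted on the same data that is then
   tested.  The plug-in expected count tracks the realized condition
   margins, which removes a share of the sampling variance of order
   p_y + p_z; the test is therefore *conservative* (rejection ≈ 0.02 at
   the simulated prevalences of 3–12%), never anti-conservative.  At
   survey-cohort prevalences (mostly below a few percent) the deficit is
   negligible — the same reason a delta-method variance adjustment is
   dispensable there.  Both rates are reported by `scripts/acceptance.py`.

## Directed tests

Ordered pairs are tested only within dogs that have both conditions with
dated onsets.  The null success probability per dog is the product of a
direction term P(y)/(P(y)+P(z)) and a window term: the chance that two
onsets placed independently and uniformly in the dog's medical-history span
fall within W of each other, which is (W/Span)(2 − W/Span) for Span > W and
1 otherwise (verified against a Monte-Carlo two-uniform oracle in the
tests).  Span is the full history (earliest to latest onset over *all*
conditions), W defaults to 12 months at 30.4375 days per month.

The observed success count enforces both the realized order and a realized
gap ≤ W, for internal consistency with the windowed null.  Ties — identical
onset dates, common under month-level reporting — count for neither
direction by default (a 0.5-split option exists); this is conservative.
Both directions of every pair are always computed, and Bonferroni runs over
the number of directional hypotheses actually evaluated (those with at
least one co-occurring dated dog and positive null variance).

A caveat the synthetic studies make visible: the window term models onsets
as exchangeably placed within the span.  Real (and default synthetic)
histories are not uniform — first onsets anchor the span, gaps cluster —
so directed p-values inherit some model misspecification beyond the
direction term itself.  The direction-recovery studies plant orderings
strong enough (90% compliance) that this does not affect conclusions, but
weak directed edges near the significance boundary deserve skepticism.

## Life-stage stratification

Dogs are assigned puppy / young adult / mature adult / senior by age within
their weight class; heavier dogs cross stage boundaries earlier.  The
packaged `life_stages.yaml` is a plausible default in the style of common
veterinary life-stage guidance and is explicitly **non-authoritative** — a
study should supply the table its cohort was curated under.  Intervals are
half-open with boundary ages resolving to the older stage; weight classes
partition (0, ∞).

Each stratum is re-analysed from scratch: the ≥60-dog condition filter is
re-applied within the stratum, risk models are refit (age still varies
within a stage, and per-stratum filters imply per-stratum models), and the
pair tests run at Bonferroni-adjusted α = 0.01.  Strata with fewer than two
qualifying conditions yield empty networks rather than errors — small
puppy strata routinely do.  Stratum networks are compared by an
edge-overlap matrix (shared undirected edges off-diagonal, per-network edge
counts on the diagonal).

## Network topology and degree distributions

Networks include only conditions with at least one significant edge by
default (isolated conditions can be added by flag; density denominators
change accordingly).  Topology reports edge density m/C(n,2), global
transitivity (closed triplets over connected triplets — a mean-local
clustering variant is available), and Freeman graph-level centralization of
degree and betweenness, each normalized by its star-graph maximum so all
four summaries are unit-free in [0, 1]; vertex-transitive graphs score 0,
stars score 1.

The scale-free question is answered by discrete maximum-likelihood fits of
a power law (Hurwitz-zeta normalization) and an exponential (geometric
tail) over degrees ≥ xmin, compared with a Vuong-style normalized
log-likelihood-ratio test with a two-sided normal p-value; ties in
log-likelihood give p = 1 and an inconclusive verdict.  xmin is chosen by
KS minimization for the power law and shared by both fits, with candidates
restricted to retain at least two thirds of the positive-degree
observations (never fewer than 10).  The restriction is a deliberate
numerical choice for small networks: unrestricted KS minimization tends to
truncate non-power-law data exactly where the power law fails, leaving the
likelihood-ratio test with no discriminating sample.  At 160 nodes this
recipe identifies geometric degree data as exponential in ≈97% of
replicates and never mislabels power-law data as exponential.

## Synthetic cohorts

The generator emulates a large owner-survey cohort with known ground truth:

- **Covariates.** Age from a gamma distribution (shape 2.2) scaled to
  median 7.75 years and truncated at 22; weight from a two-component
  lognormal mixture (medians ≈ 22 and 62 lbs, mixing weight 0.42) giving an
  overall median near 51 lbs; sex status at proportions 46.8 / 45.8 / 4.8 /
  2.6% (spayed female / neutered male / intact male / intact female); a
  50/50 purebred–mixed split.  The exact distributional forms are package
  choices; only the summary statistics they reproduce are externally
  constrained.
- **Conditions.** Per-condition logistic models with baseline prevalences
  log-uniform on a configurable range (default 0.004–0.15, the realistic
  lifetime-prevalence regime for a filtered survey catalog) and slope
  distributions centered on a mild positive age effect.  Intercepts are
  calibrated so the mean linear predictor hits the target prevalence.
- **Planted comorbidity.** A pair (y, z, m) increments z's log-odds by
  log m in dogs with y; generation is topologically ordered and cycles are
  rejected.  The one-directional increment keeps the true odds ratio
  analytic for generator self-checks (mean empirical OR within 25% of the
  planted value at cohort scale); a shared-latent-factor mode is not the
  default.
- **Onsets.** Per-dog histories anchor at a first-onset age (uniform below
  ~55% of current age) with exponential inter-onset gaps, truncated at the
  survey date; an alternative places onsets i.i.d. uniformly over the
  history (the exchangeable case that matches the windowed null exactly).
  Planted orderings overwrite the pair's dates at the stated compliance
  (default 90%, gaps uniform over 1–6 months), with non-compliant dogs
  reversed at comparable gaps.

Everything is driven by one integer seed and is bit-reproducible, including
the written CSV files.

What the generator does *not* emulate: real condition catalogs and their
category structure, breed-specific risks, reporting and recall biases,
missing or erroneous onset dates, correlated survey skip-logic, or
condition recurrence.  Passing tests demonstrate that the statistical
machinery recovers known structure under the generative assumptions — they
do not validate owner-reported data quality.

## Simulation study sizes

The validation studies use sizes chosen to exercise each claim at useful
power: calibration and confounding on 500 null cohorts of 2,000 dogs × 20
conditions (prevalences 0.03–0.12 so every condition clears the one-in-ten
rule; "age-confounded" pairs are those with both age slopes ≥ 0.15/yr);
pair power on 100 cohorts of 5,000 dogs with an odds-8 pair at 5%
prevalence; direction recovery on 100 cohorts of 5,000 dogs; coefficient
coverage on 100 fits at n = 20,000; degree-model selection on 200 sampled
degree sequences of 160 nodes; and one full-scale end-to-end run at 26,614
dogs × 160 conditions.  `scripts/acceptance.py` runs reduced-replicate
versions of the same studies.

## Known limitations

- The plug-in conservatism described above means borderline edges at high
  prevalence are under-called rather than over-called; a delta-method
  variance correction is deliberately out of scope.
- The plain normal tail is least accurate near the distribution median for
  small trial counts (error ~0.012 at 100 effective trials); conclusions
  at Bonferroni thresholds are unaffected, and the exact tail is available.
- Directed inference treats one onset per condition; recurring episodes
  and uncertainty in owner-recalled dates are not modelled.  Undated
  events count for co-occurrence but are excluded from temporal tests.
- The default life-stage table is a stand-in, not the guideline table any
  particular cohort was curated under.
- The ≥1-condition dog filter conditions the cohort on a union event, which
  induces a Berkson-type negative dependence between conditions.  With a
  realistic catalog (dozens to hundreds of conditions, nearly every
  surveyed dog qualifying) the effect is negligible, but on toy cohorts
  with a handful of conditions it visibly suppresses positive-association
  signals; synthetic studies in this package use catalogs large or
  prevalent enough that the filter retains most dogs.
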