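# Methods

## Model and estimation

The package fits a recursive generalized structural equation model over
categorical survey data: a directed acyclic system with one regression
equation per endogenous variable.  In the shipped cervical-cancer-screening
model the outcome (ever screened, binary logit) is regressed on age group,
BMI category, health-facility barriers, contraception use, number of
children, health-care autonomy, lifetime sex partners, STI awareness, years
of schooling, religion, and wealth quintile; the mediators have their own
equations — contraception use (3-level baseline-category logit on religion
and schooling), number of children (4-level baseline-category logit on wealth
and religion), and STI awareness (binary logit on schooling).  Published
reports of this model do not list any further covariates in the mediator
equations, so the shipped configuration uses exactly those predictors; the
choice is configurable through the YAML model file.

Because the system is recursive, every variable is observed, and the
equations' residuals are independently specified, the joint likelihood
factorizes into per-equation likelihoods: equation-by-equation maximum
likelihood *is* the joint MLE, and the system log-likelihood is the sum of
the per-equation values.  No joint optimizer is built.

Each equation is maximized by Newton–Raphson with step-halving:

* convergence when the score max-norm is ≤ 1e-8 **or** the relative
  log-likelihood change is ≤ 1e-10; hard cap 100 iterations, 20 halvings per
  step; the log-likelihood never decreases across accepted steps;
* covariance = inverse observed information (identical to expected
  information under the canonical logit link);
* any coefficient exceeding 15 in absolute value during iteration aborts
  with a separation error — far outside any plausible survey effect, this
  catches complete/quasi-complete separation early;
* rank-deficient designs abort naming the collinear columns (QR with column
  pivoting); multinomial categories observed zero times drop their contrast
  with a warning.

Missing data are handled by **per-equation complete cases** (listwise within
each equation, not across equations), so equations using variables collected
only in a survey subsample fit on far fewer rows than the mediator equations.
Survey design weights are deliberately not used; an optional frequency-weight
column is accepted for aggregated synthetic data only.

## Effect decomposition

Only two-edge exposure → mediator-level → outcome chains are supported;
diagrams with mediator-of-mediator edges are rejected at build time with an
"unsupported chain depth" error rather than silently truncated.  Indirect
effects use the product-of-coefficients rule with the first-order
(no-cross-term) delta-method variance b²Var(a) + a²Var(b); the exact product
variance adds the term Var(a)Var(b), negligible at survey scale, and is not
used for reported SEs.  Intervals are normal-based with z = 1.959964 and
two-sided normal p-values (the Wald test is assumed for products as well).

Total effects come in two conventions:

* **per-row** (default): within each mediator-level block, an exposure's
  total combines its direct effect, that block's indirect effect, and — when
  the exposure also feeds another mediator — one indirect effect per level of
  the other mediator, producing one total row per combination.  Totals are
  reported in the block of the exposure's first mediator (equation
  declaration order).  This matches the row structure of published
  decomposition tables for this model.
* **grand total**: direct + all enumerated indirect paths, one row per
  exposure term, matching the textbook definition of a total effect.

Variance of a total uses the full gradient of direct + Σ aᵢbᵢ: each
equation's coefficient block contributes g'Σg with its estimated
within-equation covariance; coefficients from *different* equations are
treated as uncorrelated.  The equations share no parameters, but fitting them
on overlapping records does induce some correlation that this approximation
ignores; the report footer states it.  When decomposing a published
coefficient table (SEs back-derived from printed 95% CIs), within-equation
covariances are unavailable and the covariance is diagonal.

## Descriptives

Cross-tabs use pairwise complete cases with declaration-order labels and
always row-wise percentages.  Tests: Pearson chi-squared without continuity
correction (general R×C survey tables); Wilcoxon–Mann–Whitney with mid-ranks
and the tie-corrected normal approximation, no continuity correction;
quantiles by linear interpolation ("type 7") — the convention is fixed and
documented because published tables rarely state one.

## Synthetic-data generator

The generator emulates the structure of the NFHS-4 women's file that the
analysis assumes:

* exogenous covariates drawn independently from the published category
  margins (wealth ≈ 19/21/21/20/19%, religion ≈ 74/14/7/5%, age 66/34%, …);
  schooling from a discrete three-mass-plus-uniform mixture on 0–17 years
  calibrated to median 7, IQR (0, 10);
* mediators and outcome drawn from their logit equations with the published
  path coefficients as generating truths (unlisted terms zero);
* intercepts are not published, so they are calibrated once at
  scenario-build time against a fixed internal covariate sample of 200,000
  draws (its own RNG stream, independent of the user's seed): bisection on
  the binary intercepts and a damped log-ratio fixed point on the
  multinomial intercepts, targeting screening prevalence ≈ 21% and the
  published mediator margins;
* autonomy and lifetime sex partners are missing *jointly* via one
  "detail-module administered" Bernoulli(0.118) indicator per row.  The
  published per-variable observation fractions (~12.4% each) and the outcome
  equation's complete-case fraction (82,533/699,686 ≈ 11.8%) are consistent
  only with co-missingness, not independent missingness, so the group
  structure is the default; per-variable independent missingness is also
  supported.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: dependence among exogenous covariates (wealth
and schooling are independent here, certainly not in any real survey),
two-stage cluster sampling, strata and design weights, geographic structure,
and any misreporting process.  Parameter-recovery results therefore validate
the estimator and decomposition arithmetic under the model's own assumptions,
not the substantive findings.

One seeded PCG64 stream drives a population; identical scenarios give
byte-identical CSVs.  The analysis scripts use n = 100,000 (seed 1) and the
test suite n = 20,000–200,000, sizes at which every generating coefficient of
magnitude ≥ 0.1 is recovered within 3 Wald SEs while the full pipeline runs
in seconds to a couple of minutes.

## Numerical and design notes

* Category labels match exactly after trimming surrounding whitespace; no
  fuzzy matching.  Missing markers: empty cell or `NA`.
* Reference levels default to the published contrasts (age 15–34, BMI
  underweight, facility "not a big problem", no contraception, no children,
  decides alone, one partner, STI-unaware, Hindu, poorest) and are
  configurable per variable.
* Reference ("Ref") rows report an effect of exactly 0 with SE 0 and an odds
  ratio of 1.00.
* Display rounding: 3 decimals for path coefficients and effects, 2 for odds
  ratios; unrounded variants are always written alongside.
* The shipped published coefficient set contains one internally inconsistent
  pair of cells (the schooling → contraception-others indirect effect and the
  total that includes it, where the printed value disagrees with the product
  of the printed factors by ~0.004); reconstruction checks exclude those two
  cells and treat the rest of the table at ±0.002.

## Known limitations

* Two-edge mediation chains only; no latent variables, ordinal/probit links,
  interaction terms, or counterfactual (natural-effect) definitions on the
  probability scale.
* No robust/clustered SEs, Firth correction, or survey-weighted estimation.
* Cross-equation covariance of coefficients is approximated as zero in total
  effect SEs.
* CSV is the only input format; conversion from native survey formats is out
  of scope.
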