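# Methods

## Model and estimators

All estimators address the same binomial-logit model
`logit Pr(Y=1|x) = beta' x` with an implicit intercept.  Records carry
nonnegative weights; a weight-w record is likelihood-identical to w
duplicated records, which lets 2×2 tables, grouped cohorts and
pseudo-records (data augmentation) share one code path.

**Maximum likelihood** uses Newton–Raphson with step-halving, a raw-step
cap of 5 per coordinate, tolerance 1e-8 on the score sup-norm and a cap
of 50 iterations.  A gradient-converged fit whose log-likelihood is
within 1e-3 of zero has fitted every outcome perfectly: that is monotone
likelihood (complete separation or a one-level outcome) and is flagged
`converged=False` with a "separation" note rather than raised.  A
converged fit with any non-intercept coefficient outside the odds-ratio
estimability window [1/999, 999] keeps its estimates but carries an
"out of range" note; the *replicate-level* convergence filter used in
simulations applies the window to the exposure coefficient, which is
the quantity the filter exists to police.  Partial (quasi-) separation
of a nuisance covariate therefore does not by itself discard a
replicate — deliberately, because the exposure estimate can remain
perfectly regular while a rare nuisance covariate has no events.

**Firth's method** maximizes `l(beta) + 0.5 log|I(beta)|` by Newton
iteration on the modified score (hat-diagonal form), sharing the ML
tolerances.  The determinant is evaluated by `slogdet`; a non-positive
sign aborts with an explicit error.  On any saturated 2×2 the estimate
reduces to the add-½ cross-product ratio, which the tests exploit as an
independent oracle.

**Exact conditional inference** builds the permutational distribution
of `T_j = sum y_i x_ij` given every other sufficient statistic
(including the intercept's event total) by forward dynamic programming
over records with exact integer counts.  Integer weights are treated as
group sizes via binomial transition coefficients, which is equal to the
record-by-record DP (verified against exhaustive 2^n enumeration).
States are pruned by remaining-capacity bounds when all covariates are
nonnegative; the live-state cap defaults to 5×10^7, beyond which a
capacity error names the cap — multivariate exact inference at large n
is out of scope by design and is *flagged*, never silently skipped, in
simulation summaries.  The conditional MLE solves the tilted-mean
equation by monotone bracketing + Brent; when the observed statistic
sits on the support boundary the median-unbiased estimate (tail
probability ½) is substituted and noted.  Exact and mid-P intervals
invert the tail equations to 1e-10; a boundary statistic yields an
open (infinite) bound on that side, serialized as ±inf.

**Bayesian posteriors.**  Two priors: independent N(0, 100) on every
coefficient, and the hyper-g prior `beta | g ~ N(0, g diag(1/2))` with
`f(g) = ((a-2)/2)(1+g)^(-a/2)`, a=4 — under which the shrinkage factor
g/(1+g) is uniform and F(g) = g/(1+g).  The sampler is an adaptive
random-walk Metropolis on beta (proposal covariance from the inverse of
likelihood-information-plus-prior-precision, scale tuned toward 0.3
acceptance during burn-in by Robbins–Monro and frozen afterwards) with
a stepping-out slice-sampler update of log g for the hyper-g prior.
The algorithm is a contract detail: any sampler passing the seeded
determinism, prior-recovery and two-seed agreement tests is
conforming.  Defaults are 4 chains × 10,000 retained draws after 2,000
burn-in (case studies); simulations use 1 × 2,000 after 500, trading
Monte-Carlo noise for runtime.  Summaries are the pooled posterior
median and equal-tailed 95% interval; effective sample sizes come from
the initial-positive-sequence autocorrelation estimator, and a summary
whose ESS falls below the configured floor is flagged, not hidden.
Both priors cover the full coefficient vector including the intercept
by default.  The alternative convention (flat prior on the intercept)
is implemented behind `include_intercept=False`; on the bundled
hydramnios table the full-vector convention reproduces the reference
posterior medians (hyper-g ≈ 9.6–10) while the intercept-excluded one
collapses the exposure OR toward 2, so the default is the full vector.

**Log F(m, m) priors** add `m b/2 − m log(1+e^b)` per penalized
coefficient (never the intercept; by default all others).  The same
posterior kernel is realized as pseudo-data — per coefficient, two
records with that covariate 1, everything else 0 (intercept column
included) and weights m/2 for one event and one non-event — and both
representations are implemented and asserted equal to 1e-10.  The point
estimate is the posterior mode (maximizer of the augmented likelihood)
and intervals are profile inversions of the augmented objective, which
reproduces the asymmetric published intervals; Wald intervals on the
augmented fit are available as an option.  Prior odds-ratio intervals
follow from F(m, m) quantiles: about (1/648, 648) for m=1 and
(1/39, 39) for m=2, shrinking as m grows.

**Profile intervals** for all likelihood-based fits invert the
(penalized) likelihood-ratio test: bracket expansion from the estimate
in units of the Wald SE, doubled geometrically, then Brent root-finding
on the profile deviance with endpoint tolerance 1e-6; the inner
constrained maximization reuses the Newton machinery with the profiled
coordinate frozen.  An endpoint that never crosses the chi-square
threshold before |beta| = 40 is reported as an open bound.

## Synthetic-data generator

Six covariate scenarios emulate sparse epidemiological designs: (1) a
lone exposure x1 ~ Bern(pi_x1) with pi_x1 in {0.05, 0.1, 0.2}; (2) an
added independent Bern(0.5) covariate; (3) the correlated pair
x1 | x2 ~ Bern(((x2+1)/2) pi_x1); (4) the pair plus Bern(0.3) and
Bern(0.1) covariates; (5) eight covariates including a three-level
multinomial; (6) a fixed eight-covariate cohort mimic with given
coefficient vector (intercept −6.40) and rare multi-level covariates.
Multi-level covariates are coded 0,1,2(,3) and entered as single
quantitative columns.  The exposure odds ratio is 1, 4 or 16; other
covariates carry OR 2 in scenarios 2–5.  The intercept for scenarios
1–5 is calibrated so the *expected* event count equals the target n_e,
by bisection on the exactly enumerated covariate support (tolerance
1e-10; the scenario-3 dependence is honored in the enumeration).
Replicates are streamed from one master seed with per-replicate
spawned substreams, so any single replicate is reproducible alone.
Degenerate replicates (zero events, constant covariate columns) are
passed through; the estimators and the convergence filter account for
them, mirroring how convergence rates are defined.

What the generator does *not* emulate: continuous covariates,
covariate measurement error, confounding structures beyond the built-in
x1–x2 correlation, or informative missingness.  Passing tests therefore
demonstrate correct estimator behavior under clean categorical
sparse-data conditions, not robustness to those real-data features.

Scenario 6's sample size is not pinned by the design description; the
default is n = 3,000 (nearest round number to the motivating cohort's
2,992 births), configurable.

## Evaluation

`summarize` computes, per method and design cell: exp(mean retained log
OR) ("average OR"), mean log-OR bias, 95%-interval coverage (an open
bound covers on its side), convergence rate, and the retained count.
Headline summaries restrict every method to the replicates where the
ML fit passed the convergence filter, so methods are compared on
identical data; unrestricted summaries are available.
`required_replications` sizes a comparison so the 95% CI of a
between-method difference in mean log OR is within ±log(ratio), given
a per-method variance and between-method correlation.

## Problem sizes used in the checked runs

The simulation reproduction runs the sparsest scenario-4 cell (n=100,
pi_x1=0.05, n_e=5; null and OR=4) at the full 1,000 replicates.  The
large-sample recovery check uses scenario 1 at n=100,000 with 100
expected events and 200 replicates, collapsing each replicate to its
four covariate-outcome groups so all eight estimators (including exact
conditional enumeration and MCMC) run in seconds per replicate.

## Known limitations

* Exact conditional inference is enumeration-based; multivariate
  problems at n in the thousands exceed the state cap and are refused
  with a capacity error rather than approximated (no Monte-Carlo
  network sampling).
* On ML-degenerate replicates — a nuisance covariate separates and the
  exposure has zero events, leaving the exposure coefficient
  unidentified while the reported value sits inside the estimability
  window — replicate-level averages of *any* estimator depend on
  optimizer internals.  The Firth average in the sparsest null cell is
  particularly sensitive, because the penalized-likelihood maximizer
  on such replicates is a strongly positive artifact mode (a known
  property of the Jeffreys penalty on near-degenerate tables): a
  faithful maximizer yields a larger cell average than iteration-
  truncated implementations report.
* The Bayesian sampler is a general-purpose Metropolis/slice scheme;
  very flat posteriors (tiny n with diffuse priors) mix slowly and
  should be run with longer chains than the simulation defaults.
* No dummy coding: multi-level covariates are treated as quantitative
  scores by design; no GLMs beyond the binomial-logit.
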