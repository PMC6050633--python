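# Methods

## Model and search

A balance between disjoint taxon groups X₊ (k₊ taxa) and X₋ (k₋ taxa) is
the normalised log-ratio of geometric means,
B = √(k₊k₋/(k₊+k₋)) · log(g(X₊)/g(X₋)), natural logarithms throughout.
Internally the search uses the proportional form
mean(log X₊) − mean(log X₋): the two differ by the constant
√(k₊k₋/(k₊+k₋)) only, which the regression slope absorbs, so every
criterion value is identical and the cheaper form wins.  Normalised scores
are used whenever balance values are reported.

The selection procedure is greedy forward:

1. **Pair step.** All k(k−1)/2 unordered two-taxon balances are fitted
   against the response (plus covariates) and the best criterion wins.
   Since B_ij = −B_ji carries the same association, orientation is fixed
   afterwards so that the fitted balance coefficient β₁ is positive.
2. **Extension steps.** For every taxon not yet in the balance, two
   candidates are formed — the taxon's log value averaged into the
   numerator group or into the denominator group — and all are fitted; the
   best candidate is accepted iff it improves the training criterion by
   more than `threshold` (the `th.imp` knob, default 0 = strictly better).
3. **Stopping.** The search ends on insufficient improvement, on reaching
   `max_components` taxa (default 20), or on running out of taxa.  Taxa are
   never removed once added.

Ties between candidates (criterion equal to within 1e-10) are broken
deterministically: candidates are enumerated in sorted-taxon-id order,
numerator placement before denominator, and only strict improvement
replaces the incumbent.  This makes the whole search a pure function of the
data and configuration.

## Regression fits and criteria

Continuous responses: ordinary least squares, criterion = mean squared
residual with the 1/n convention so models of equal n are comparable.
Dichotomous responses: maximum-likelihood logistic regression solved by a
small Newton/IRLS routine written for this package — the exhaustive scan
performs on the order of 10⁵ two-to-four-parameter fits per analysis, for
which general-purpose fitters carry too much overhead.  The routine is
validated against statsmodels OLS/Logit in the test suite (coefficients to
1e-6, log-likelihood to 1e-9).

When plain ML fails to converge — typically quasi-complete separation,
which small candidate balances meet routinely — the fit is retried with a
ridge penalty of 1e-4 on the slopes (intercept unpenalised) and flagged
`converged=False`; this keeps every candidate's criterion finite and
comparable without materially moving non-separable fits.

Criteria for dichotomous responses: AUC of the full model's fitted
probabilities (Mann–Whitney midrank form, ties counted half — the default),
McFadden's pseudo-R² (1 − ℓ_full/ℓ_null) as the explained-variance option,
and Tjur's discrimination coefficient (mean fitted probability in cases
minus controls, clipped to [0,1]).  The latter two are this package's
concrete readings of "explained variance" and "discrimination coefficient";
AUC remains the default and the one exercised everywhere.  AUC is always
computed from the full model (balance + covariates); a covariates-only
comparison mode is deliberately not provided.

## Zero replacement

Log-ratios require strictly positive parts.  All observed zeros are treated
as *rounded* zeros (taxa present but below the detection limit of the
realised depth); structural zeros are out of scope.  Replacement happens
once, on the full table, before any cross-validation split — the search
never sees the response at this stage, but the small information leakage
from using all rows to form the prior is acknowledged rather than patched.

- **add_one**: x → x + 1 for every cell.
- **GBM** (default): per row with total N and total prior mass
  S = `gbm_prior_strength` · k (default 0.5 per part, a Jeffreys-like
  weight), each zero cell j is imputed as N·S·t_j/(N+S), where t is the
  prior composition — the across-sample geometric mean of each taxon's
  observed nonzero proportions, normalised.  Nonzero cells are scaled by
  the single factor 1 − (imputed mass)/N, so the ratios between all
  originally nonzero parts and the row total are preserved exactly.  A row
  whose imputed mass would reach its observed mass raises a degenerate-
  prior error instead of silently distorting the sample.

The GBM literature admits several parameterisations; this one (geometric
column prior, strength 0.5/part) is fixed by an oracle test against an
independently hand-coded per-cell implementation, and no numeric parity
with any external implementation is claimed.

## Cross-validation and the 1se rule

M iterations (default 10) of K-fold CV (default 5).  Folds are stratified
by class for dichotomous responses — otherwise small studies routinely
produce single-class test folds on which AUC is undefined; continuous
responses use plain shuffled folds.  Per training set the greedy search
runs once up to C components; every prefix balance along its path, with its
training-fold coefficients, is scored on the held-out fold.  Folds whose
path stops early simply contribute nothing at the missing sizes, and
held-out values that are undefined (a test fold missing a class despite
stratification safeguards) are recorded as missing and excluded from the
means.

The number of components k_opt is the smallest c whose mean held-out
criterion is within one standard error of the best mean; the SE is the one
at the best-mean c, following the convention of cross-validated lasso.  An
`optimum` rule (argbest, smallest c on ties) is available.  The *global
balance* re-runs the search on all samples capped at k_opt; *cv accuracy*
is the mean held-out criterion at the size the global balance actually
reached.  Robustness tables report the relative frequencies of the distinct
size-k_opt CV balances (canonically oriented by their training-fold slope
sign) and each taxon's inclusion frequency with its modal side, rendered as
a +/−/· grid against the global balance.

## Dirichlet Monte Carlo

Each count row is one multinomial realisation of the sample's true
composition; with a Dirichlet(prior) prior (default 0.5 per part) the
posterior is Dirichlet(counts + prior).  Per draw, proportions are sampled
from that posterior and rescaled by the observed row total, giving
strictly positive tables (no zero replacement needed) that conserve each
sample's depth.  Draws are kept as positive reals — rounding back to
integers would re-introduce zeros and bias rare taxa.  The search re-runs
on each draw with the balance size held at k_opt (re-running the full CV
per draw would be quadratically expensive and answers a different
question), and the summary reports balance/taxon frequencies plus per-side
Jaccard agreement with a reference balance.  When no reference is supplied
the capped search on the posterior-mean table (a zero-free stand-in for the
observed table) provides one.

## Synthetic data generator

The generator emulates exactly the structure the model assumes, making
parameter recovery well-posed: latent log abundances w_ij = μ_j + N(0,
latent_sd²); the planted balance is computed on the latent (zero-free)
composition; the response follows the linear or logistic model on that
latent balance; observed counts are Multinomial(depth, softmax(w)).
Defaults define the standard test-bed used by the tests and the acceptance
script: 200 samples, 12 taxa with a 2-taxon balance planted among 10 noise
taxa, logistic effect β₁ = 2 on the normalised-balance scale, depth 10,000.
The baseline profile places planted taxa at the abundant end (μ = 0) and
spreads noise taxa down to μ = −6 natural-log units, so the rare end yields
rounded zeros at realistic depths and the zero-replacement stage is
genuinely exercised.  Optional knobs: a binary covariate acting on the
response and/or shifting the numerator taxa (confounding), per-sample depth
vectors, and extra zero-inflation.

What the generator does *not* emulate: taxon-taxon correlation structure,
phylogeny, overdispersion beyond the multinomial, batch effects, or
signatures that are not exactly balances.  Passing recovery tests therefore
demonstrates correctness of the machinery under the model's own
assumptions, not performance on real microbiome data.

## Problem sizes in the test and acceptance runs

Recovery is assessed over 50 seeds at the standard test-bed conditions with
the default CV (M = 10, K = 5); null calibration uses 100 seeds with a
single CV iteration (M = 1, K = 5) capped at pair balances, which already
yields 500 held-out folds; the acceptance script uses 25 seeds per block
and 50 Monte Carlo draws.  These sizes are the package's choice of a
statistically meaningful yet quick default; all are plain parameters of the
relevant functions.

## Numerical notes and limitations

- Logistic linear predictors are clipped at ±35 before the inverse-logit;
  Newton steps stop at 1e-9 and fall back to ridge after 50 iterations.
- Rank-deficient designs raise a collinearity error naming the dependent
  columns (QR with pivoting) rather than silently dropping them.
- The greedy search does not explore the whole balance space and can miss
  the global optimum; the CV robustness and Monte Carlo summaries are the
  intended evidence for (or against) the stability of its result.
- Samples with missing response or covariates are dropped with a warning at
  assembly; prevalence filtering and taxonomic agglomeration are assumed to
  have happened upstream.
- The training AUC of a fitted model is upward-biased under the null
  (it is max(A, 1−A) of the raw-score AUC); model-size decisions therefore
  rely exclusively on held-out values, which the tests show are unbiased.
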