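# Methods

## Response model

All computations build on the three-parameter logistic response function

    P(θ) = g + (1 − g) / (1 + exp(−D·a·(θ − b)))

for a correct response to a dichotomous item with discrimination a > 0,
difficulty b, and lower asymptote g ∈ [0, 1).  The 2PLM is the g = 0 case;
the 1PLM additionally shares one discrimination across all 1PLM items; the
`DRM` label is stored as given but evaluated as 3PLM everywhere.  The
scaling constant D defaults to 1.0 and is never changed implicitly; pass
D = 1.702 to work on the normal-ogive-aligned scale, as all worked
examples do.  Probabilities are floored/ceiled at 1e−12 inside
likelihoods; saturation-prone quantities (1 − P at large |z|) are computed
through `expit(−z)` to avoid cancellation.

## Marginal maximum likelihood via EM

Ability is integrated out over a *rectangular* quadrature: K equally
spaced nodes (default 49 on [−6, 6]) with weights proportional to the
standard-normal density, renormalized — the midpoint rule, not
Gauss–Hermite, so node listings match the conventional printed grids.

Each EM cycle:

1. **E-step.**  Per person, the posterior over nodes is proportional to
   w_k · Π_observed P^x (1 − P)^{1−x}; missing responses are simply
   skipped, and a person with no observed responses keeps the prior as
   posterior.  Expected per-node counts n̄_jk (responses) and r̄_jk
   (correct responses) accumulate per item; the marginal log-likelihood is
   Σ_i log Σ_k w_k L_ik.
2. **M-step.**  Each item's expected complete-data log-likelihood, plus
   the log-densities of any active priors, is maximized by L-BFGS-B with
   analytic gradients under the box constraints a ∈ (0.01, 10),
   b ∈ (−10, 10), g ∈ (1e−4, 0.5) (inner tolerances ftol 1e−12,
   gtol 1e−8).  All 1PLM items form one block in which the shared slope
   and all their difficulties are maximized jointly.  A failed optimizer
   retries from a neutral start; a still-failed or boundary solution flags
   the item and estimation continues.

Convergence is declared when the maximum absolute change over all free
item parameters between cycles falls below `Etol` (default 1e−4;
`MaxE` = 500 cycles).  Starting values: a = 1; b from a PROX-style logit
transform of the item's observed proportion-correct; g at the prior mode
((α−1)/(α+β−2) for a beta(α, β) prior) or 0.2.

**Priors.**  beta(α, β) on g, lognormal(meanlog, sdlog) on a,
normal(mean, sd) on b.  Priors penalize only the M-step objective; the
*reported* log-likelihood, −2LL, AIC and BIC always exclude prior terms,
so AIC = −2LL + 2p and BIC = −2LL + p·ln(N) hold exactly for the reported
numbers.  The per-cycle log-likelihood trace is exposed alongside the
final −2LL (evaluated by one extra E-step after the last M-step); the two
differ by whatever the final M-step gained.

**Escaping the 3PLM degeneracy.**  For very hard items the 3PLM marginal
likelihood has a spurious "all-guessing" mode (a and b drifting upward
together until the item is flat at g).  After EM converges, any 3PLM item
with a > 3 or |b| > 3 is re-fit against the current posterior from a grid
of dispersed starts (a ∈ {0.7, 1.2, 2}, b ∈ {±1.9, ±1, 0}), and EM resumes
if anything moved (at most two rescue rounds).  Because the refit can only
increase the M-step objective, the marginal likelihood keeps its monotone
ascent (up to ~1e−5 wobble from the prior-free reporting scale).

**Standard errors.**  The covariance matrix of the free item parameters is
the inverse of the empirical (cross-product/BHHH) information: per person,
the score of the *marginal* log-likelihood is the posterior-weighted
complete-data score (Fisher's identity); the information is the sum of
outer products.  The shared 1PLM slope's SE is reported once, on the first
1PLM row; fixed parameters have missing SEs.  The first-order convergence
test requires EM convergence plus a small marginal gradient — the maximum
absolute gradient component *per person* below 1e−3, a sample-size-free
criterion.  The second-order test is positive-definiteness (Cholesky) of
the information matrix.

**Empirical histogram.**  With `emp_hist` the latent weights are replaced
each cycle by the normalized posterior mass at the nodes.  In plain
calibration the histogram is standardized every cycle to mean 0, variance
1 — the N(0, 1) identification of the θ scale — by an affine transform of
the node positions whose mass is re-interpolated onto the fixed grid (the
transform is iterated so the discrete moments are (0, 1) to 1e−9, since
one interpolation pass alone inflates the variance by ~1%).  Whether the
reference implementations standardize per cycle or post hoc is not
documented; per cycle is this package's choice.

## Fixed-item-parameter calibration (FIPC)

Pretest items are calibrated with the operational items' parameters held
fixed, so the new estimates land on the operational scale with no
post-hoc linking.  The latent distribution is *not* standardized here —
the fixed items identify the scale — and its mean and variance are free:

* **OEM** (one EM cycle, no weight updating): a single E-step whose
  posterior uses the fixed items only, then a single M-step for the
  non-fixed items.  The reported group line is the descriptive first two
  moments of the final all-item posterior mass.
* **MEM**: cycle 1 equals OEM; from cycle 2 on, each E-step uses all
  items at current values, non-fixed items are re-estimated, and the
  latent distribution is updated concurrently — with `emp_hist` the
  weights become the normalized posterior mass on the fixed node grid;
  without it a normal distribution is re-fit by the mass's first two
  moments and re-evaluated at the (unchanged) nodes.  Nodes are never
  re-centered; only weights move.

Fixed rows are returned bit-identical to the input and carry no standard
errors.  The free-parameter count is the non-fixed item parameters plus 2
(mu, sigma2).  Group-parameter SEs come from a joint empirical information
matrix in which (mu, sigma2) enter through the normal log-weight
derivatives at the current scale, with sigma's SE by the delta method —
the reference outputs print these SEs without stating a method, so
agreement is expected only to loose tolerance.

## Fixed-ability-parameter calibration (FAPC, Stocking's Method A)

Each pretest item is estimated independently by maximizing its response
log-likelihood over (a, b, g), treating the supplied ability estimates as
known.  The same bounds, starts and priors as the M-step apply; the
reported −2LL (summed over items) again excludes prior terms.  Per-item
SEs come from the observed information (central differences of the
analytic gradient).  Items with zero observed responses are excluded and
counted; constant-response items run to a bound and are flagged.  The
group line is purely descriptive: the mean and SD (ddof = 1) of the
supplied scores.  In the intended pipeline the scores are ML estimates
from the operational items, which inflates their SD above 1 — that is a
property of ML scoring, not of the item estimates.

## Ability estimation

All methods skip missing responses person-wise; default range (−5, 5) for
the bounded methods.

* **ML** — bounded likelihood maximization with five-segment multi-start
  (the 3PLM likelihood can be multimodal); SE = 1/√TIF(θ̂).
  All-correct/all-incorrect patterns clamp to a range bound and are
  flagged; zero-response persons get missing values.
* **MLF** — ML after appending two virtual 2PLM fence items with a = 3.0
  at b = lo (answered correctly) and b = hi (answered incorrectly),
  pulling extreme patterns inward.  Fence parameters are configurable;
  the convention here is this package's own default.
* **WL** — Warm's weighted likelihood for the general 3PLM: the root of
  S(θ) + J(θ)/(2I(θ)) with J = Σ_j P′_j P″_j/(P_j Q_j), found by sign
  scan plus Brent; validated through the score-equation residual.
* **MAP** — posterior mode under a normal prior;
  SE = 1/√(TIF + 1/σ₀²).
* **EAP** — posterior mean/SD over `nquad` equally spaced nodes spanning
  prior mean ± 6 prior SD, density-weighted (consistent with the
  calibration grid).  An empty response pattern returns the prior
  moments.
* **EAP summed scoring** — the summed-score likelihood at each node comes
  from the Lord–Wingersky recursion
  dist_j(s) = dist_{j−1}(s)·Q_j + dist_{j−1}(s−1)·P_j; identical summed
  scores map to identical estimates, and the score-to-θ conversion table
  is returned.
* **Inverse TCC** — solves TCC(θ) = s by bisection to 1e−8 after checking
  monotonicity on a 401-point grid.  Scores at or below TCC(lo) —
  including sub-guessing scores below Σg — clamp to lo, mirroring hi;
  SE = 1/√TIF(θ̂).

## Curves

`traceline`/`info` evaluate ICC/TCC and IIF/TIF on a user grid; TCC and
TIF are exact column sums of the per-item curves.  For dichotomous items
the expected-score curve equals the ICC, so the score-curve flag only
relabels.  Plots are simple matplotlib line charts; the numeric series
(tidy CSV: item_or_test, theta, value, kind) are the tested artifact.

## Response simulator and what it covers

`simulate_responses` draws θ_i from the stated normal (or takes an
explicit vector) and responses as Bernoulli(P_j(θ_i)), using numpy's
PCG64 with explicit seeds.  Two canned designs reproduce the study
conditions used throughout the tests:

* `fixture_simdat30` — 2,000 × 30 complete matrix, abilities N(0, 1);
* `fixture_simdat60` — 2,000 × 60; 50 operational items answered by all,
  10 pretest items of which each examinee is assigned a uniform random 5
  (≈1,000 responses per pretest item; the rest missing).

Generating item parameters are drawn once per seed from documented
ranges: a ~ lognormal(0.2, 0.25) (≈0.8–2.0), b ~ N(0, 1) clipped to
±1.75, g ~ beta(5, 16) truncated at 0.35 — the windows operational pools
of this kind occupy; harder items would leave the 3PLM's all-guessing
mode empirically supported, which real banks avoid by design.  The
fixtures are synthetic, statistically equivalent stand-ins for externally
distributed example datasets of the same design (those files' exact item
draws and RNG state are not public), so tests against the fixtures
demonstrate recovery under the design, not byte-level reproduction.  The
simulator draws independent Bernoulli responses from the fitted model
family itself: passing recovery tests shows the estimation machinery is
correct and calibrated for data of this size and missingness pattern, not
that real response data (with misfit, dependence, speededness) would be
recovered equally well.

## Numerical and design choices (summary)

* Metadata: fixed columns id, cats, model, par.1–par.3; auto ids V1..Vn;
  missing written as "NA"; "NA"/""/"NaN" accepted on read.  A stray g on
  a 1PLM/2PLM row warns and coerces to missing.  Where a printed metadata
  table and its generating code transcript disagree on model labels, the
  code transcript is taken as authoritative.
* Optimizer bounds a ∈ (0.01, 10), b ∈ (−10, 10), g ∈ (1e−4, 0.5);
  degenerate items (all correct/incorrect) run to a bound and are
  flagged, never a crash.
* The quadrature constructor requires at least 3 nodes; the "calibration
  = weighted logistic regression at known θ" reduction is exercised
  through the exact-expected-count M-step oracle and the FAPC/GLM
  equivalence instead of a 1-node grid.
* EAP.SUM and INV.TCC compute each person's summed score over observed
  responses; they are intended for complete response matrices.
* CLI exit codes: 2 missing input file, 3 validation failure; every run
  writes a config echo for bit-for-bit reproducibility.

## Problem sizes

The test suite and the acceptance script run the full designs (N = 2,000;
30 or 60 items; 49 quadrature points), the Monte-Carlo SE check at 20
replicates of N = 2,000 × 4 items, and the EM-monotonicity sweep at 20
random datasets of 60–120 persons — sizes chosen so the entire suite
completes in a few minutes on one CPU while keeping every estimate in the
regime the methods are designed for.

## Known limitations

* Polytomous models, multiple-group calibration, item-fit statistics,
  DIF, and classification indices are out of scope.
* The empirical cross-product information can understate SEs in small
  samples; the Monte-Carlo test bounds the discrepancy at the reference
  sample size only.
* WL for the 3PLM is validated via its score equation, not against an
  external implementation.
* FIPC group-parameter SEs use a normal-score approximation even under
  the empirical histogram.
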