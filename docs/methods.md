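# Methods

## Model

The latent disease course of patient *n* is a continuous-time Markov
chain on ordered states `1..M` with patient-specific generator
`Q(beta, Z_n)`: for every allowed edge `(i, j)`,
`log Q_ij = beta_ij' Z_n`, where `Z_n` is the patient's static covariate
vector with a trailing intercept coordinate fixed to 1.  The default
transition graph is forward-only with jumps of at most `max_hop = 2`
states; with `M = 9` this yields 15 allowed transitions, and the final
state is absorbing.  Whether backward transitions are truly impossible or
merely negligible in the disease is not something this package decides:
the graph is configuration (`allowed_edges(n_states, max_hop)`), and the
forward two-hop default reflects the staging analyses this model is built
for.

Observations occur at the visit times only.  Given the state at a visit,
the `K` clinical features are independent Gaussians
`X_k | S = s ~ N(mu_sk, sigma_sk^2)`.  The emission model is usually
imported from an established staging analysis and frozen
(`EmissionParams.frozen`), so EM re-estimates only the transition model
and the initial distribution; unfrozen emission updates
(posterior-weighted moments, missing features skipped) are also
implemented.  Missing features are `NaN` in memory, `"NA"` on disk, and
contribute nothing to the likelihood of their visit; an all-missing row
has likelihood 1 by the empty-product convention.

## Inference

EM alternates between:

* **E-step.**  Per patient, forward–backward smoothing in log space over
  the interval transition matrices `A(delta_t) = expm(delta_t Q)` yields
  the observed-data log-likelihood, visit-state posteriors and pairwise
  posteriors.  Expected dwell times and jump counts on each inter-visit
  interval conditioned on its endpoint states come from the Van Loan
  construction: the integral
  `int_0^d expm(uQ) E expm((d-u)Q) du` is the (1,2) block of
  `expm(d [[Q, E], [0, Q]])`, equivalently the Fréchet derivative of the
  matrix exponential at `dQ` in direction `dE`, which is how the fallback
  computes it (`scipy.linalg.expm_frechet`, one call per interval for the
  whole endpoint-weighted count table).  When the generator's eigenvalues
  are separated by more than `1e-6` (relative) and the eigenvector matrix
  has condition number below `1e8`, a spectral form of the same integral
  (divided-difference kernel) is used instead, which is much faster and
  lets per-covariate-group results be cached; the two routes agree to
  numerical precision and the fallback covers defective generators such
  as intercept-only models with tied exit rates.
* **Hard vs soft.**  The default `hard` mode conditions each interval on
  its Viterbi-decoded endpoints (ties broken toward the lower state); the
  `soft` mode weights all endpoint pairs by the pairwise posteriors and
  carries the classical EM guarantee — the log-likelihood trace is
  non-decreasing, which the tests assert to `1e-8` relative.  With the
  well-separated emission models used here the two modes give nearly
  identical fits; `hard` is noticeably cheaper.
* **M-step.**  `pi` is the normalized sum of first-visit posteriors.
  The expected complete-data transition objective separates across edges,
  `sum_n [ N_nij (beta_ij' Z_n) - D_ni exp(beta_ij' Z_n) ]`, and each
  edge's block is concave; it is maximized by damped Newton–Raphson
  (step-halving line search, at most 20 halvings, `1e-8` ridge on
  near-singular Hessians, gradient-ascent fallback), converged at
  gradient infinity-norm `1e-8`.  With an intercept-only model this
  reproduces the closed-form occupancy estimator `N_ij / D_i` exactly,
  which the tests assert to `1e-8`.  Patients with a single visit inform
  only `pi`, the emissions and the likelihood.

Numerical guards: the linear predictor is clipped to `[-30, 10]` before
exponentiation; emission variances are floored at `1e-6`; the closed-form
generator update uses a rate floor of `1e-10` for edges with no expected
events (keeping the support intact for the next E-step); `expm` results
have sub-`1e-8` negative round-off clipped and rows renormalized, larger
violations raise.  Convergence of the outer loop is a relative
log-likelihood change below `tol` (default `1e-6`, `max_iter = 200`).

Initialization follows two strategies: `random` draws standard-normal
coefficients per restart, runs a short EM burn-in (default 10
iterations), and keeps the highest-likelihood candidate; `two_step` fits
one single-covariate model per covariate and assembles the full
coefficient matrix from the per-covariate fits (intercepts averaged),
which presumes approximately independent covariates.

## Significance and downstream analyses

`bootstrap_fit` draws `B` (default 100) patient-level training cohorts of
80% size, refits on each (warm-started from the point estimate), records
the coefficient matrix and the log-likelihood of the patients outside the
training draw, and reports percentile intervals at the configured level
(default 95%).  Two resampling schemes are exposed.  The default draws
the training patients *with replacement*: the replicate scatter then
matches the estimator's sampling variability and the percentile intervals
are calibrated (verified by simulation — replicate SD within a few
percent of `sqrt(1/0.8)` times the measured estimator SD).  The
alternative `subsample` scheme is the literal repeated 80/20 split
without replacement; its replicate scatter is only
`sqrt(n/m - 1) = sqrt(1/0.8 - 1) = 0.5` times the full-sample sampling
SD, so its percentile intervals undercover badly and it is kept only for
protocol fidelity.  Percentile intervals were chosen because
they need no distributional assumption and read directly off the
replicate matrix; resampling is always by patient, never by visit,
because repeated visits of a patient are strongly dependent.  The
replicate count is exposed as a parameter since reasonable protocols
vary.  No multiple-testing
correction is applied across the edge-by-covariate grid; intervals are
reported raw and flagged as such.  `classify_effects` calls an effect
accelerating (decelerating) when the point estimate is at least +2 (at
most −2) and the interval excludes zero.

`group_transition_matrices` sweeps a covariate grid — by default raw CAG
values {40, 42, 43, 45, 50} mapped through the same `(CAG - 40)/10`
scaling used at fit time, all other covariates held at cohort means — and
reports `A(1 year)` per group, with a display-only truncation of entries
below 0.005.  `cluster_beta_patterns` arranges per-covariate effect
vectors over the allowed transitions (intercept excluded), centers
columns (standardization optional; centering-only is the default), takes
the first two principal components, and clusters the scores by
average-linkage agglomerative clustering, cut at 2 clusters by default or
at a configurable height.

## Synthetic cohorts

The simulator emulates the observational registry data the model targets:
SNP dosages `Binomial(2, MAF)`, integer CAG repeats uniform on [40, 50]
scaled as `(CAG - 40)/10`, optional binary or standard-normal covariates,
and configurable missingness (missing covariates are cohort-mean imputed
before generator evaluation).  Latent paths are Gillespie-simulated under
each patient's own generator; visits start at `t = 0` with
Gamma-distributed gaps (mean 1 year, shape 4, so roughly annual with the
irregularity of real registry follow-up); visit counts are uniform on
[4, 14] by default; features are Gaussian draws from the state occupied
at each visit.  Enrollment (the simulation initial distribution) is
spread over all transient states with extra weight on early states — the
weights were chosen to maximize the minimum per-edge event count under
the default rates, so that every one of the 15 transitions is estimable
from a cohort of a few hundred patients.  Default baseline rates are
0.4/year for adjacent-state transitions and 0.2/year for two-hop jumps.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs (covariates are drawn independently), informative visit schedules
(gap lengths are independent of disease state), cohort effects across
pooled studies, and non-Gaussian feature noise.  Passing the recovery and
coverage tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation in real registry data.

## Simulation-study design and problem sizes

Two properties of the design matter for parameter recovery and are easy
to get wrong:

* **Edge traffic.**  Coefficients of a rarely traversed transition are
  weakly identified; the per-coefficient sampling standard deviation
  scales like the inverse square root of the per-group event count.  The
  front-loaded enrollment above keeps the minimum per-edge, per-genotype
  event count near 15–20 at 300 patients.
* **Two-hop identifiability.**  With strictly annual visits a direct
  `i -> i+2` jump is nearly indistinguishable from two quick one-hop
  jumps, producing a flat likelihood ridge; gap jitter (shape-4 Gamma)
  and two-hop rates comparable to one-hop rates keep the ridge curved
  enough to estimate both.  The recovery study therefore uses a shared
  baseline rate of 0.3/year on all edges with a +0.5 binary-covariate
  effect.

Study sizes used by the test suite and the acceptance script: recovery —
20 replicates of 300 patients, 9 states, frozen true emissions, hard-mode
EM (|bias| and RMSE per coefficient at most 0.5); bootstrap calibration —
a reduced 4-state chain model (the chain isolates interval calibration
from the multi-hop identifiability issue above), 200 patients, 100 outer
replications of B = 40 with-replacement refits (coverage between 88% and
99% per coefficient); conditional-statistics validation — rejection-sampled
endpoint-conditioned Gillespie paths (50 000 accepted) against the
augmented-exponential expectations within 3 Monte-Carlo standard errors;
decoding/likelihood — 100 random 3-state instances against exhaustive
path enumeration at `1e-10`.

## Known limitations

* Hard (Viterbi-conditioned) EM does not guarantee a monotone likelihood
  trace; the guarantee holds in soft mode, and the default was chosen for
  fidelity to the staged-decoding procedure the model family uses plus
  speed, not for the guarantee.
* Multi-hop rates remain weakly identified when visit gaps are long
  relative to state holding times; estimates on sparse edges should be
  read together with their bootstrap intervals.
* The bootstrap refits inherit the point estimate as initialization; with
  very few EM iterations per replicate the intervals collapse toward the
  point estimate, so replicate fits are run to convergence criteria, not
  a fixed tiny iteration budget.
* Covariates are treated as time-invariant by construction; emission
  families other than the Gaussian are out of scope.
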