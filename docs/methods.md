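# Methods

## The model and its assumptions

`sgtlm` fits a latent-variable binary mixed model.  Each observation's
binary outcome is the sign indicator of a latent continuous variable whose
conditional distribution — and whose cluster-level random effects — follow
skew generalized t (SGT) laws built from a shared scale-mixture
representation:

    Z = mu + U^{-1/2} (delta * |V| + X),   X ~ N(0, Omega_bar),
    V ~ N(0, 1),   U ~ Gamma(nu/2, nu0/2),

with working shape `delta`, `Omega = Omega_bar + delta delta'`, and
`c = sqrt(2/pi)` (the half-normal mean) entering all moment formulas.
Key structural assumptions:

* one scale-mixing variable `U_i` and one half-normal variable `V_i` are
  **shared** by the latent outcomes and the random effects of a cluster —
  this is what makes every marginal and conditional law stay in the skew-t
  family and the EM tractable.  A consequence: given the random effects the
  latent outcomes are *correlated* whenever the link is skewed;
* the latent scale is standardized by
  `ups0 = [U2 + (U2 - c^2 U1^2) d_eps^2]^{-1/2}` (with
  `U_t = E{U^{-t/2}}`), so `Var{Z_ij | b_i} = 1` and fixed effects are
  directly comparable with probit coefficients;
* identifiability requires `nu0` fixed relative to `nu` (the package works
  throughout on the skew-t scale `nu0 = nu`, folding any `nu0/nu` ratio
  into the scale matrix), and design-dependent restrictions on the
  skewness parameters (below).

Special cases: probit (`d_eps = delta = 0`, `nu -> inf`), skew probit
(`nu -> inf`), t link / robit (`d_eps = delta = 0`), skew-t link.  The
Gaussian limits are implemented as genuine normal-kernel paths, not as a
large finite `nu`.

## Identifiability restrictions

Two data structures make skewness parameters unidentifiable and the
fitter refuses to free them silently (`check_identifiability`):

* binary-only fixed covariates: the conditional skew-probit model is not
  identified, so the link skewness `d_eps` is pinned at 0;
* a random intercept: only `d_eps + delta_0` enters the marginal law, so
  one of them must be pinned.  The default restriction is `delta_0 = 0`
  (the success probability may be skewed irrespective of random effects;
  the alternative restrictions `d_eps = 0` or `d_eps = delta_0` are
  selectable through the same flags).

## Truncated-moment engine

The E-step needs the first two moments of truncated multivariate skew-t
vectors and joint moments against `U` and `V`.  Everything is assembled on
the *augmented* `(p+1)`-variate symmetric t vector whose extra coordinate
carries the skewness: the truncated-ST normalizer, first-moment terms
(marginal pdf x conditional cdf at a degree shift) and second-moment terms
(bivariate pdf x conditional cdf at two degree shifts).  The truncated
multivariate *t* moments needed for the V-channel are the `delta = 0`
special case of the same assembly; a brute-force rejection oracle validates
the reduction in the tests.  Joint moments `E{U^{r/2} g(Z)}` are tilted
truncated-ST moments at degrees `nu + r`, which is why second moments need
`nu + r > 4`: the E-step uses `r = 2`, so any `nu > 2` is fittable, and the
selection grid `2.5:15` matches that domain.

Degenerate truncation regions (pattern probability below `1e-12`) raise a
`DegenerateRegionError` naming the offending cluster rather than returning
garbage.

## The cdf integrator and its accuracy knob

No installed routine evaluates batches of multivariate t cdfs fast enough
for EM, so `sgtlm.mvt` implements the classical separation-of-variables
integrator (sequential conditioning after Cholesky, smallest-limit-first
variable ordering) on scrambled Sobol points, vectorized across both
integration points and problems; `df = inf` switches the kernel to the
normal case.  All randomization derives from a fixed internal seed, so
every cdf value — and hence every fit — is deterministic and a smooth
function of its inputs.

The point budget is the accuracy knob (`MvtOptions(points, shifts)`), and
EM stability depends on it, so it is exposed on `FitControl`:

| context                | default          | typical abs. error |
|------------------------|------------------|--------------------|
| direct cdf calls       | 512 x 6          | ~1e-5              |
| EM moment work         | 128 x 3          | ~1e-4              |
| scaled-down study fits | 64 x 2           | ~3e-4              |
| oracle tests           | 2048 x 8 and up  | ~1e-6              |

A uniform 1e-8 target is achievable (~2.5e5 points) but makes the EM about
fifty times slower than any reasonable test budget; the tests that assert
1e-6..1e-8-level identities buy that accuracy locally.

## Estimation procedure

Per the six-step scheme: (1) E-step; (2) parameter-expanded M-step with a
q x q working scale `alpha` on the random effects, solved jointly with
`beta` (the `delta_eps` update precedes the `beta` update, which references
it); (3) PX phase ends when the dominant eigenvalue of `alpha - I` falls
below 1e-2; (4-6) plain EM until the relative marginal log-likelihood
change falls below 1e-6; (7) terminal rescaling `beta <- ups0 beta`,
`delta <- ups0 delta`, `D_bar <- ups0^2 D_bar` (likelihood-invariant).  The
whole iteration runs at `ups0 = 1`.  Initialization: zeros for `beta`,
`d_eps`, `delta`; identity for `D_bar`.

Numerical choices:

* **Restricted updates.** With `delta_0` frozen the closed-form joint
  (delta, D_bar) maximizer no longer applies; the package uses a
  conditional-maximization pair (GLS solve for the free shape elements
  given `D_bar`, then the general `D_bar` update), which preserves the EM
  ascent property.  Under parameter expansion `alpha` is restricted to keep
  the first coordinate axis invariant so the reduction `alpha delta*`
  preserves the restriction.
* **Boundary safeguard.** When `D_bar` degenerates (a variance component on
  the boundary) the PX working scale need not approach the identity even
  though the observed-data model has stabilized; a stalled log-likelihood
  for three consecutive PX iterations forces the switch to plain EM.  At
  such boundary solutions the "alpha ~ I at the ML" diagnostic is *not*
  expected to hold.
* `D_bar` updates are symmetrized with an eigenvalue floor of 1e-8.
* Cluster probabilities are floored at 1e-300 before logs; floored clusters
  are counted and reported, never silently dropped.
* Degrees of freedom are selected on a grid (default `2.5:15` by 0.1) with
  warm starts, not by profile maximization inside EM: the profiled
  likelihood of pure t links can be unbounded as `nu` decreases, which the
  grid search detects and flags (`nu_at_edge`) instead of chasing.  Because
  grid selection never needs `E{log U | y}` (which has no closed form), no
  approximation for it is implemented.
* Cluster size is capped at 10 by default — the documented accuracy
  envelope of the cdf integrator — and overridable.

## Inference

* Standard errors: empirical observed information `sum_i g_i g_i'` from the
  per-cluster scores of the expected complete-data log-likelihood at the
  estimate, computed on the working `ups0 = 1` scale and mapped to the
  reported scale through the (finite-difference) Jacobian of the rescaling,
  which depends on `d_eps` through `ups0`.  vech derivatives use the
  symmetric-matrix convention with off-diagonal duplication factor 2.
* Variance-component SEs by the delta method on the entries of `Sigma_b`.
* AIC / BIC / HQ count beta + free skewness entries + q(q+1)/2 scale
  parameters; `nu` is **not** counted when grid-selected (this bookkeeping
  reproduces the published application's criterion values; a flag includes
  it for sensitivity analysis).
* Empirical Bayes: `E{b_i | y_i}` via moment chains at orders
  r in {0, 1, -1} of the conditional truncated skew-t law, on the reported
  scale with `ups0` explicit; `E{U_i | y_i}` (order r = 2) is the cluster
  weight, with values below 1 flagging outlying clusters.

## Synthetic-data generator

`simstudy.SimDesign` encodes two mechanisms with fixed truths: a probit
mechanism (`U = 1`, no skewness) and a skewed heavy-tailed mechanism
(`d_eps = -2`, `delta_1 = 2`, `nu = 5`, hence `ups0 = 0.4598` and marginal
random-effect variances 0.83 / 0.42 / 4.73).  Both share: n clusters of 6
observations; a cluster-level Bernoulli(0.5) covariate and an
observation-level standard-normal covariate; true fixed effects (-1, 1);
`D_bar = [[0.5, 0.25], [0.25, 1.0]]`; covariates drawn once per
(mechanism, n) and reused across replicates; per-replicate outcome seeds
`master_seed + rep_index`.  The sign convention for the true fixed effects
follows the published performance tables (intercept -1, slope +1), where
the accompanying text prints the opposite signs; the tables are
self-consistent with the reported biases, the text is not.

What the generator does *not* emulate: covariate measurement error,
missing visits / informative dropout, cluster-size variation, or any
misspecification outside the two stated mechanisms.  A green recovery test
therefore establishes internal correctness of the estimator under its own
sampling assumptions, not robustness to real-data artifacts.

The full published experiment (250 replicates, n up to 1000, four fitters)
is runnable through `run_study` / `sgtlm study`; the default replication in
the test suite is much smaller (6-12 replicates at n = 100-200) purely for
runtime, and each scaled-down configuration is stated in the test
docstrings.  One consequence is accepted rather than hidden: the published
intercept bias of the heavy-tailed fit is itself outside the +-10% band at
n <= 500 (-17% at n = 100, -11% at n = 500, -2% only at n = 1000), so the
scaled-down bias check on the intercept reproduces that finite-sample bias
rather than the n = 1000 regime.

## Likelihood geometry of the skewness channel

On data generated from this model with strong link skewness and heavy tails,
the marginal likelihood is *bimodal* in the skewness channel: one mode near
the generating parameters, and a second, genuinely stationary mode (verified
by a near-zero score at high cdf accuracy) with `d_eps` near zero and
inflated scale parameters whose likelihood is only ~1 unit lower at n = 100.
Plain EM — and PX-EM — started from the standard zero initialization cannot
cross the valley between them and converges to the near-symmetric mode.
`fit(..., skew_starts=(0.0, -2.0, 2.0))` provides a deterministic
multi-start over link-skewness initializations and returns the
highest-likelihood solution; it is opt-in because it multiplies the fit cost
by the number of starts.

A related structural point: because one half-normal draw is shared between
the latent noise and the random effects, a negative link skewness combined
with a positive slope skewness induces a *negative* effective intercept-slope
covariance at the latent scale (the cross term
`ups0 d_eps (U2 - c^2 U1^2)(J delta' W' + W delta J')` of the marginal
covariance).  Symmetric fitters (probit/t link) applied to such data
therefore estimate inflated variances with a negative covariance — that is
the correct maximum-likelihood response to this model's data, and the
package's misspecification tests assert against what the model itself
implies rather than against intuitions formed under independent skewness
draws.

## Known limitations

* Degrees of freedom below 2 (and second moments below `nu + r = 4`) are
  outside the moment formulas used here; very small `nu` needs different
  truncated-moment expressions and is not supported.
* The empirical-information SEs assume a correctly specified model and an
  interior optimum; on variance-component boundaries the information matrix
  is near-singular and a pseudo-inverse (with a warning path) is used.
* Cdf accuracy, not statistics, caps the practical cluster size (~10) and
  random-effect dimension.
* The sklearn facade exposes marginal predictions only; conditional
  (cluster-specific) predictions are available by combining
  `eb_random_effects` with `success_prob`.
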