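# sgtlm — skew generalized t-link mixed models for clustered binary outcomes

`sgtlm` fits generalized linear mixed models for correlated binary data —
longitudinal clinical measurements, repeated diagnostic calls on the same
patient, grouped success/failure outcomes — in which **both** the link
function and the random-effects distribution come from the skew generalized
t (SGT) family.  The probit GLMM assumes a symmetric, thin-tailed latent
scale; when the latent mechanism is skewed or heavy-tailed that assumption
biases fixed effects and collapses variance components.  The SGT link adds
two kinds of flexibility with two extra parameters: a skewness parameter
and a degrees-of-freedom parameter, nesting the probit, skew-probit, t-link
(robit) and skew-t-link models as special cases.

## Model

For cluster *i* with binary outcomes `Y_ij = 1{Z_ij > 0}`:

    Z_i | b_i, U_i, V_i ~ N(X_i β + W_i b_i + (V_i U_i^{-1/2} − c·Ũ₁) υ₀ δ_ε 1,
                             υ₀² U_i^{-1} I)
    b_i | U_i, V_i      ~ N((V_i U_i^{-1/2} − c·Ũ₁) δ,  U_i^{-1} D̄)
    U_i ~ Gamma(ν/2, ν/2),   V_i ~ half-normal(0, 1)

with `c = √(2/π)`, `Ũ_t = E{U^{-t/2}}`, link skewness `δ_ε`, random-effects
working shape `δ`, scale matrix `D̄` (so `Σ_b = Ũ₂ D̄ + (Ũ₂ − c²Ũ₁²) δδᵀ`),
and the scaling constant `υ₀ = [Ũ₂ + (Ũ₂ − c²Ũ₁²) δ_ε²]^{-1/2}` which forces
`Var{Z_ij | b_i} = 1` so that β keeps its probit-scale interpretation.
`δ_ε = δ = 0` with `ν → ∞` recovers the probit GLMM; finite ν with zero
skewness is the t-link model; `ν → ∞` alone the skew-probit model.

Marginally each cluster's latent vector is skew-t, so the likelihood of an
outcome pattern is a single n_i-dimensional skew-t cdf.  Fitting is maximum
likelihood via a parameter-expanded EM algorithm whose E-step consists of
closed-form moments of *truncated* multivariate skew-t distributions
(evaluated through low-dimensional Student-t cdfs on a vectorized
quasi-Monte-Carlo integrator).  Standard errors are empirical-information
based; per-cluster empirical-Bayes estimates of the random effects and of
the mixing weights `E{U_i | y_i}` (values below 1 flag outlying clusters)
support cluster-level inference.

## Worked example

```python
import numpy as np
from sgtlm import FitControl, MvtOptions, fit, random_effects_cov
from sgtlm.inference import attach_inference
from sgtlm.simstudy import SimDesign, simulate_dataset

# 100 clusters x 6 visits from the skewed heavy-tailed mechanism
# (beta = (-1, 1), delta_eps = -2, delta1 = 2, nu = 5)
panel, b_true = simulate_dataset(SimDesign(mechanism="sgt", n_clusters=100,
                                           seed=5), 0)
ctrl = FitControl(loglik_rtol=1e-5,
                  moment_options=MvtOptions(points=64, shifts=2))
res = fit(panel, nu=5.0, fix_delta0=True, control=ctrl)
res = attach_inference(res, panel)
print("beta      :", np.round(res.theta.beta, 3))
print("delta_eps :", round(res.theta.delta_eps, 3))
print("delta     :", np.round(res.theta.delta, 3))
print("Sigma_b   :", np.round(random_effects_cov(res.theta), 3))
print("loglik    :", round(res.loglik, 2), " AIC:", round(res.ic["aic"], 2))
print("mean weight:", round(float(res.eb["u2"].mean()), 3),
      " outlying clusters:", int((res.eb["u2"] < 1).sum()))
```

prints (this exact run):

```
beta      : [-1.043  1.438]
delta_eps : -0.231
delta     : [0.    2.668]
Sigma_b   : [[ 2.003 -2.538]
 [-2.538 11.999]]
loglik    : -271.64  AIC: 557.29
mean weight: 1.022  outlying clusters: 43
```

Read: the fixed effects land near the truth (−1, 1).  The skewness
parameters (δ̂_ε, δ̂₁) and the implied random-effects covariance `Σ_b` are a
single replicate's maximum-likelihood estimate of *weakly identified*
quantities: their likelihood surface is a flat ridge, and their
replicate-to-replicate spread is large (the published experiment averages
250 replicates before these stabilize near their truths 0.83/0.42/4.73).
`res.eb["u2"]` holds the per-cluster heaviness weights `E{U_i | y_i}` —
values below 1 flag clusters whose response pattern the model explains by
a heavy-tail draw — and `res.eb["b"]` the empirical-Bayes intercepts and
slopes.

The same fit through the scikit-learn facade:

```python
from sgtlm import SGTLinkMixedModel
model = SGTLinkMixedModel(link="skew-t", nu=5.0, random_slopes=(1,))
# model.fit(X_long, y, groups=ids); model.predict_proba(X_long)
```

A command-line interface mirrors the library: `sgtlm fit data.csv --config
schema.yaml`, `sgtlm simulate`, `sgtlm study --config study.yaml`,
`sgtlm fixtures` (long CSV in, JSON/CSV reports out).

## Acceptance script

`scripts/acceptance.py` recomputes, directly from the package's moment
formulas, the scaling constant υ₀ of the heavy-tailed simulation design and
the three marginal random-effects (co)variances it implies, and writes them
to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
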