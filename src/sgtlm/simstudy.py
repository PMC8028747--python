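"""Synthetic-data generation and the Monte-Carlo performance experiment.

Two data mechanisms are implemented, matching the performance experiment the
package is designed to reproduce:

* ``probit``: U = 1, no skewness (delta_eps = delta1 = 0) — a plain probit
  GLMM with correlated random intercept and slope;
* ``sgt``: gamma mixing with nu = 5 and strong skewness delta_eps = -2,
  delta1 = 2 (upsilon0 = 0.4598), i.e. data that are both skewed and heavy
  tailed at the latent scale.

Shared structure: n clusters of n_i = 6 observations, eta_ij = beta0 +
beta1*X1_i + b0_i + b1_i*W1_ij with a cluster-level Bernoulli(0.5) covariate
X1 and an observation-level standard-normal covariate W1; true fixed effects
(beta0, beta1) = (-1, 1); D_bar = [[0.5, 0.25], [0.25, 1.0]].  Covariates are
generated once per (mechanism, n) and reused across replicates; outcome
randomness is seeded per replicate as master_seed + rep_index.

Four fitters are compared: PM (probit), SPM (skew probit), GTLM (t link) and
SGTLM (skew generalized t link, nu treated as known = 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClusterData, Panel
from .em import FitControl, fit
from .inference import attach_inference, delta_method_varcomp
from .model import Theta, upsilon0
from .sgt_core import HALF_NORMAL_MEAN, MixingSpec, mixing_moment

__all__ = ["SimDesign", "FITTERS", "simulate_dataset", "performance_summary",
           "run_study", "fitter_restrictions"]

_C = HALF_NORMAL_MEAN

#: fitting models of the four-way comparison -> (nu, restriction kwargs)
FITTERS = {
    "PM": dict(nu=np.inf, fix_delta_eps=True, fix_delta_all=True),
    "SPM": dict(nu=np.inf, fix_delta0=True),
    "GTLM": dict(nu=5.0, fix_delta_eps=True, fix_delta_all=True),
    "SGTLM": dict(nu=5.0, fix_delta0=True),
}


def fitter_restrictions(name: str) -> dict:
    try:
        return dict(FITTERS[name])
    except KeyError:
        raise ValueError(f"unknown fitter {name!r}; choose from {sorted(FITTERS)}")


@dataclass
class SimDesign:
    """Configuration of one simulation setting (a stated world, not a dial)."""

    mechanism: str = "sgt"
    n_clusters: int = 100
    ni: int = 6
    beta: tuple = (-1.0, 1.0)
    d_bar: np.ndarray = field(default_factory=lambda: np.array([[0.5, 0.25],
                                                                [0.25, 1.0]]))
    delta_eps: float | None = None
    delta1: float | None = None
    nu: float | None = None
    n_reps: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("probit", "sgt"):
            raise ValueError("mechanism must be 'probit' or 'sgt'")
        if self.mechanism == "probit":
            self.delta_eps = 0.0 if self.delta_eps is None else self.delta_eps
            self.delta1 = 0.0 if self.delta1 is None else self.delta1
            self.nu = np.inf if self.nu is None else self.nu
            if self.delta_eps != 0.0 or self.delta1 != 0.0 or not np.isinf(self.nu):
                raise ValueError("probit mechanism fixes delta_eps = delta1 = 0, U = 1")
        else:
            self.delta_eps = -2.0 if self.delta_eps is None else self.delta_eps
            self.delta1 = 2.0 if self.delta1 is None else self.delta1
            self.nu = 5.0 if self.nu is None else self.nu
        self.d_bar = np.asarray(self.d_bar, dtype=float)

    @property
    def delta(self) -> np.ndarray:
        # null random-intercept skewness ensures identifiability
        return np.array([0.0, float(self.delta1)])

    @property
    def upsilon0(self) -> float:
        return upsilon0(self.delta_eps, self.nu)

    def true_theta(self) -> Theta:
        return Theta(beta=np.asarray(self.beta, float), delta_eps=self.delta_eps,
                     delta=self.delta, d_bar=self.d_bar, nu=self.nu,
                     upsilon0=self.upsilon0,
                     fix_delta_eps=self.mechanism == "probit",
                     fix_delta0=True, fix_delta_all=self.mechanism == "probit")

    def covariates(self):
        """Cluster covariate X1 and occasion covariates W1, fixed per design."""
        tag = 0 if self.mechanism == "probit" else 1
        rng = np.random.default_rng([self.seed % (2 ** 31), tag,
                                     self.n_clusters, self.ni])
        x1 = rng.binomial(1, 0.5, size=self.n_clusters).astype(float)
        w1 = rng.standard_normal((self.n_clusters, self.ni))
        return x1, w1


def simulate_dataset(design: SimDesign, rep_index: int = 0):
    """One replicate: returns (panel, true random effects b (n, 2)).

    Deterministic given (design.seed, rep_index); the latent hierarchy is
    b_i | U_i, V_i ~ N((V U^{-1/2} - c U1) delta, U^{-1} D_bar) and
    Z_i | b_i, U_i, V_i ~ N(eta_i + (V U^{-1/2} - c U1) u0 deps J,
    u0^2 U^{-1} I), with Y = 1{Z > 0}.
    """
    x1, w1 = design.covariates()
    n, ni = design.n_clusters, design.ni
    rng = np.random.default_rng([(design.seed + rep_index) % (2 ** 31), 97])
    mix = (MixingSpec.normal_limit() if np.isinf(design.nu)
           else MixingSpec.skew_t(design.nu))
    u1m = mixing_moment(1, mix)
    u0 = design.upsilon0
    beta0, beta1 = design.beta
    L = np.linalg.cholesky(design.d_bar)
    if mix.is_normal_limit:
        u = np.ones(n)
    else:
        u = rng.gamma(design.nu / 2.0, 2.0 / design.nu, size=n)
    v = np.abs(rng.standard_normal(n))
    shift = v / np.sqrt(u) - _C * u1m
    b = shift[:, None] * design.delta + (rng.standard_normal((n, 2)) @ L.T) / np.sqrt(u)[:, None]
    clusters = []
    for i in range(n):
        eta = beta0 + beta1 * x1[i] + b[i, 0] + b[i, 1] * w1[i]
        z = (eta + shift[i] * u0 * design.delta_eps
             + u0 / math.sqrt(u[i]) * rng.standard_normal(ni))
        y = (z > 0).astype(int)
        X = np.column_stack([np.ones(ni), np.full(ni, x1[i])])
        W = np.column_stack([np.ones(ni), w1[i]])
        clusters.append(ClusterData(y=y, X=X, W=W, id=i))
    panel = Panel(clusters=clusters, fixed_names=["intercept", "x1"],
                  random_names=["intercept", "w1"], outcome_name="y",
                  id_name="cluster")
    return panel, b


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

def performance_summary(estimates, truths, se_list=None, ci_list=None,
                        eb_pairs=None, ic_list=None,
                        labels=None) -> pd.DataFrame:
    """Monte-Carlo performance table over replicates.

    estimates : (R, k) per-replicate estimates; truths : (k,).
    se_list : optional (R, k) standard errors; ci_list : optional (R, k, 2)
    confidence intervals; eb_pairs : optional list of (b_true, b_hat) pairs
    per replicate; ic_list : optional list of {aic, bic, hq} dicts.

    Columns per parameter: mean, pct_bias (100 (mean - truth)/|truth|), rmse,
    sd (divisor R-1), se_bar (quadratic mean of SEs), cp (CI coverage).
    R-squared rows (mean squared Pearson correlation between simulated and
    empirical-Bayes random effects) and mean information criteria are
    appended as extra rows.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    R, k = est.shape
    if R < 2:
        raise ValueError("performance summary needs at least two replicates")
    truths = np.asarray(truths, dtype=float)
    labels = list(labels) if labels is not None else [f"par{j}" for j in range(k)]
    mean = est.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_bias = 100.0 * (mean - truths) / np.abs(truths)
    rmse = np.sqrt(np.mean((est - truths) ** 2, axis=0))
    sd = est.std(axis=0, ddof=1)
    rows = {"mean": mean, "truth": truths, "pct_bias": pct_bias,
            "rmse": rmse, "sd": sd}
    if se_list is not None:
        se = np.atleast_2d(np.asarray(se_list, dtype=float))
        rows["se_bar"] = np.sqrt(np.mean(se ** 2, axis=0))
    if ci_list is not None:
        ci = np.asarray(ci_list, dtype=float)
        rows["cp"] = np.mean((ci[:, :, 0] <= truths) & (truths <= ci[:, :, 1]),
                             axis=0)
    table = pd.DataFrame(rows, index=labels)
    extra = {}
    if eb_pairs is not None:
        qq = eb_pairs[0][0].shape[1]
        r2 = np.zeros((len(eb_pairs), qq))
        for r_i, (bt, bh) in enumerate(eb_pairs):
            for l in range(qq):
                c = np.corrcoef(bt[:, l], bh[:, l])[0, 1]
                r2[r_i, l] = c ** 2
        for l in range(qq):
            extra[f"r2_b{l}"] = r2[:, l].mean()
    if ic_list is not None:
        for key in ("aic", "bic", "hq"):
            extra[f"mean_{key}"] = float(np.mean([d[key] for d in ic_list]))
    table.attrs["extras"] = extra
    return table


def _true_values(design: SimDesign, fitter: str):
    """Truths aligned with the fitter's free-parameter labels plus Sigma_b."""
    from .model import random_effects_cov
    th = design.true_theta()
    sigma_b = random_effects_cov(th)
    vals = {"beta0": design.beta[0], "beta1": design.beta[1],
            "delta_eps": design.delta_eps, "delta1": design.delta1,
            "sigma11": sigma_b[0, 0], "sigma12": sigma_b[0, 1],
            "sigma22": sigma_b[1, 1]}
    return vals


def run_study(designs, fitters=("PM", "SPM", "GTLM", "SGTLM"),
              control: FitControl | None = None, compute_eb: bool = True,
              n_jobs: int = 1, verbose: bool = False) -> dict:
    """Run the replicate x fitter comparison for one or more designs.

    Returns ``{(mechanism, n, fitter): {"table": DataFrame, "n_failed": int}}``
    shaped like the published performance tables.  Individual fit failures
    are logged and excluded with a count.
    """
    if isinstance(designs, SimDesign):
        designs = [designs]
    out = {}
    for design in designs:
        if design.n_reps < 1:
            raise ValueError("a study needs at least one replicate")
        reps = []
        for r in range(design.n_reps):
            reps.append(simulate_dataset(design, r))
        for name in fitters:
            spec = fitter_restrictions(name)
            recs, failures = [], 0
            for r, (panel, b_true) in enumerate(reps):
                try:
                    recs.append(_fit_one(panel, b_true, spec, control,
                                         compute_eb))
                except Exception as exc:  # noqa: BLE001 - robustness by design
                    failures += 1
                    if verbose:
                        print(f"[study] {name} rep {r} failed: {exc}")
            if not recs:
                raise RuntimeError(f"all replicates failed for fitter {name}")
            truths = _true_values(design, name)
            labels = sorted(recs[0]["est"].keys(),
                            key=list(recs[0]["est"].keys()).index)
            est = np.array([[rec["est"][l] for l in labels] for rec in recs])
            ses = np.array([[rec["se"][l] for l in labels] for rec in recs])
            cis = np.stack([np.array([rec["ci"][l] for l in labels])
                            for rec in recs])
            tab = performance_summary(
                est, [truths.get(l, np.nan) for l in labels], ses, cis,
                eb_pairs=[rec["eb"] for rec in recs] if compute_eb else None,
                ic_list=[rec["ic"] for rec in recs], labels=labels)
            out[(design.mechanism, design.n_clusters, name)] = {
                "table": tab, "n_failed": failures}
    return out


def _fit_one(panel: Panel, b_true, spec: dict, control, compute_eb) -> dict:
    spec = dict(spec)
    nu = spec.pop("nu")
    res = fit(panel, nu=nu, control=control, **spec)
    res = attach_inference(res, panel, compute_eb=compute_eb)
    est, se = {}, {}
    for lbl, e, s in zip(res.free_labels, _flatten_theta(res.theta), res.se):
        est[lbl], se[lbl] = e, s
    vc = delta_method_varcomp(res.theta, res.vcov)
    for key, d in vc.items():
        est[key], se[key] = d["estimate"], d["se"]
    ci = {l: (est[l] - 1.96 * se[l], est[l] + 1.96 * se[l]) for l in est}
    rec = {"est": est, "se": se, "ci": ci, "ic": res.ic,
           "loglik": res.loglik, "converged": res.converged}
    if compute_eb:
        rec["eb"] = (b_true, res.eb["b"])
    return rec


def _flatten_theta(theta: Theta) -> np.ndarray:
    from .inference import pack_free
    return pack_free(theta)
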