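"""scikit-learn style estimator facade for the SGT-link mixed model.

``SGTLinkMixedModel`` wraps the EM fitter in the familiar fit/predict API so
the model composes with sklearn model-selection utilities: ``fit(X, y,
groups=...)`` takes long-format arrays, ``predict_proba`` returns marginal
success probabilities, and all fitted quantities are exposed as trailing-
underscore attributes.  The library modules (model, em, inference, simstudy)
remain the full-control surface underneath.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import Panel
from .em import FitControl, fit, select_nu
from .inference import attach_inference
from .model import check_identifiability, random_effects_cov, success_prob
from .mvt import MvtOptions

__all__ = ["SGTLinkMixedModel"]

_LINKS = {
    "probit": dict(nu=np.inf, fix_delta_eps=True, fix_delta_all=True),
    "skew-probit": dict(nu=np.inf),
    "t": dict(fix_delta_eps=True, fix_delta_all=True),
    "skew-t": dict(),
}


class SGTLinkMixedModel(ClassifierMixin, BaseEstimator):
    """Clustered binary regression with a skew generalized t link.

    Parameters
    ----------
    link : {"probit", "skew-probit", "t", "skew-t"}
        Link family; "probit"/"skew-probit" are the normal limits, "t" and
        "skew-t" use gamma scale mixing with ``nu`` degrees of freedom.
    nu : float or None
        Degrees of freedom; ignored by the normal-limit links.  ``None``
        selects nu on ``nu_grid`` by profile likelihood.
    nu_grid : array-like or None
        Grid for the profile search (default 2.5:15 by 0.1).
    random_slopes : sequence of int
        Column indices of X whose coefficients get cluster-level random
        slopes (in addition to the random intercept when
        ``random_intercept``).
    fit_intercept, random_intercept : bool
        Include fixed / random intercept columns.
    fix_delta0 : bool or "auto"
        Pin the random-intercept skewness to zero; "auto" applies the
        restriction whenever a random intercept is present.
    fix_delta_eps : bool or "auto"
        Pin the link skewness; "auto" applies it when every fixed covariate
        is binary (the design-driven identifiability restriction).
    max_iter, tol : EM iteration cap and relative log-likelihood tolerance.
    cdf_points : accuracy knob of the internal t-cdf integrator.
    include_nu_in_ic : count nu as an estimated parameter in AIC/BIC/HQ.

    Attributes
    ----------
    beta_, delta_eps_, delta_, d_bar_, sigma_b_, nu_, upsilon0_ : estimates
    se_, vcov_, free_labels_ : inference on the free parameters
    loglik_, ic_, converged_, n_iter_ : fit metadata
    random_effects_, weights_ : per-cluster empirical-Bayes predictions
    """

    def __init__(self, link="skew-t", nu=5.0, nu_grid=None, random_slopes=(),
                 fit_intercept=True, random_intercept=True, fix_delta0="auto",
                 fix_delta_eps="auto", max_iter=500, tol=1e-6, cdf_points=128,
                 skew_starts=None, include_nu_in_ic=False, compute_eb=True,
                 verbose=False):
        self.link = link
        self.nu = nu
        self.nu_grid = nu_grid
        self.random_slopes = random_slopes
        self.fit_intercept = fit_intercept
        self.random_intercept = random_intercept
        self.fix_delta0 = fix_delta0
        self.fix_delta_eps = fix_delta_eps
        self.max_iter = max_iter
        self.tol = tol
        self.cdf_points = cdf_points
        self.skew_starts = skew_starts
        self.include_nu_in_ic = include_nu_in_ic
        self.compute_eb = compute_eb
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------
    def _designs(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xd = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        cols = [np.asarray(X[:, j], float) for j in self.random_slopes]
        if self.random_intercept:
            cols = [np.ones(len(X))] + cols
        if not cols:
            raise ValueError("the model needs at least one random-effect column")
        return Xd, np.column_stack(cols)

    def fit(self, X, y, groups=None):
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if groups is None:
            raise ValueError("clustered model requires groups= in fit")
        y = np.asarray(y)
        Xd, Wd = self._designs(X)
        panel = Panel.from_arrays(y, Xd, Wd, np.asarray(groups))
        spec = dict(_LINKS[self.link])
        nu = spec.pop("nu", self.nu)
        fde = spec.get("fix_delta_eps", False)
        fda = spec.get("fix_delta_all", False)
        fd0 = False
        required = check_identifiability(panel, fix_delta_eps=fde)
        if not fda:
            if self.fix_delta_eps is True or (
                    self.fix_delta_eps == "auto" and "fix_delta_eps" in required):
                fde = True
            required = check_identifiability(panel, fix_delta_eps=fde)
            if self.fix_delta0 is True or (
                    self.fix_delta0 == "auto" and "fix_delta0" in required):
                fd0 = True
        ctrl = FitControl(max_iter=self.max_iter, loglik_rtol=self.tol,
                          moment_options=MvtOptions(points=self.cdf_points,
                                                    shifts=3),
                          verbose=self.verbose)
        restr = dict(fix_delta_eps=fde, fix_delta0=fd0, fix_delta_all=fda)
        if nu is None:
            self.nu_, res = select_nu(panel, self.nu_grid, ctrl, **restr)
        else:
            res = fit(panel, nu=float(nu), control=ctrl,
                      skew_starts=self.skew_starts, **restr)
            self.nu_ = float(nu)
        res = attach_inference(res, panel, include_nu=self.include_nu_in_ic,
                               compute_eb=self.compute_eb)
        th = res.theta
        self.result_ = res
        self.panel_ = panel
        self.theta_ = th
        self.beta_ = th.beta
        self.coef_ = th.beta
        self.delta_eps_ = th.delta_eps
        self.delta_ = th.delta
        self.d_bar_ = th.d_bar
        self.sigma_b_ = random_effects_cov(th)
        self.upsilon0_ = th.upsilon0
        self.loglik_ = res.loglik
        self.se_ = res.se
        self.vcov_ = res.vcov
        self.free_labels_ = res.free_labels
        self.ic_ = res.ic
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        if res.eb is not None:
            self.random_effects_ = res.eb["b"]
            self.weights_ = res.eb["u2"]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        """Marginal success probabilities (random effects integrated out)."""
        check_is_fitted(self, "theta_")
        Xd, Wd = self._designs(X)
        p1 = np.array([success_prob(self.theta_, xr, wr)
                       for xr, wr in zip(Xd, Wd)])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y, groups=None):
        """Mean predictive log-likelihood per observation (marginal)."""
        proba = self.predict_proba(X)[:, 1]
        y = np.asarray(y)
        eps = 1e-12
        return float(np.mean(np.where(y == 1, np.log(proba + eps),
                                      np.log(1 - proba + eps))))
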