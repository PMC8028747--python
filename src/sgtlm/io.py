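"""Long-format CSV ingestion, fit reports and synthetic fixtures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClusterData, Panel

__all__ = ["PanelSchema", "read_long_csv", "write_long_csv", "make_fixture",
           "fit_report"]


@dataclass
class PanelSchema:
    """Column roles of a long-format clustered binary dataset.

    ``fixed`` / ``random`` entries name covariate columns; the literal "1"
    denotes an intercept pseudo-column of ones.
    """

    outcome: str = "y"
    cluster: str = "id"
    fixed: list[str] = field(default_factory=lambda: ["1"])
    random: list[str] = field(default_factory=lambda: ["1"])


def _design(df: pd.DataFrame, cols: list[str], role: str) -> np.ndarray:
    parts = []
    for c in cols:
        if c == "1":
            parts.append(np.ones(len(df)))
        else:
            if c not in df.columns:
                raise ValueError(f"missing {role} covariate column {c!r}")
            parts.append(df[c].to_numpy(dtype=float))
    return np.column_stack(parts)


def read_long_csv(path, schema: PanelSchema | None = None) -> Panel:
    """Read a long CSV (one row per observation) into a Panel.

    Validates the presence of all named columns, a strictly 0/1 outcome and
    the absence of missing values; clusters keep file order.
    """
    schema = schema or PanelSchema()
    df = pd.read_csv(path)
    used = [schema.outcome, schema.cluster] + \
        [c for c in schema.fixed + schema.random if c != "1"]
    used = list(dict.fromkeys(used))
    for col in used:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    sub = df[used]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    y = df[schema.outcome].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"outcome column {schema.outcome!r} must be binary 0/1")
    X = _design(df, schema.fixed, "fixed")
    W = _design(df, schema.random, "random")
    return Panel.from_arrays(
        y, X, W, df[schema.cluster].to_numpy(),
        fixed_names=list(schema.fixed), random_names=list(schema.random),
        outcome_name=schema.outcome, id_name=schema.cluster)


def write_long_csv(panel: Panel, path) -> None:
    """Inverse of read_long_csv for panels with plain covariate columns."""
    rows = []
    for c in panel.clusters:
        for j in range(c.n):
            row = {panel.id_name: c.id, panel.outcome_name: c.y[j]}
            for name, val in zip(panel.fixed_names, c.X[j]):
                if name != "1":
                    row[name] = val
            for name, val in zip(panel.random_names, c.W[j]):
                if name != "1":
                    row[name] = val
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def make_fixture(kind: str, seed: int = 0, path=None, theta=None):
    """Generate a synthetic panel fixture.

    ``respiratory_like``: 111 patients x 4 visits with binary covariates
    (center, baseline, sex, treat), a sex x treat interaction, and
    median-centered age as the random-slope covariate — the structure of a
    two-center respiratory-illness trial, with outcomes simulated from a
    user-set or default parameter vector (the real data are not bundled).
    ``simdesign``: delegates to the simulation-study generator.
    """
    from .model import Theta, cluster_marginal_params
    from .sgt_core import MixingSpec
    rng = np.random.default_rng([seed % (2 ** 31), 1311])
    if kind == "simdesign":
        from .simstudy import SimDesign, simulate_dataset
        panel, _ = simulate_dataset(SimDesign(mechanism="sgt", seed=seed), 0)
    elif kind == "respiratory_like":
        n, visits = 111, 4
        if theta is None:
            theta = Theta(beta=[0.5, 0.6, 1.6, -1.0, -2.0, 1.3],
                          delta_eps=0.0, delta=[0.03], d_bar=[[0.012]],
                          nu=3.7, fix_delta_eps=True).finalize_scale()
        center = rng.binomial(1, 0.5, n)
        sex = rng.binomial(1, 0.79, n)          # mostly male, as in the trial
        treat = rng.binomial(1, 0.5, n)
        baseline = rng.binomial(1, 0.45, n)
        age = rng.integers(18, 70, n).astype(float)
        age_c = age - np.median(age)
        clusters = []
        for i in range(n):
            X = np.column_stack([
                np.ones(visits), np.full(visits, center[i]),
                np.full(visits, baseline[i]), np.full(visits, sex[i]),
                np.full(visits, 1 - treat[i]),
                np.full(visits, sex[i] * (1 - treat[i]))])
            W = np.full((visits, 1), age_c[i])
            y = _simulate_outcomes(theta, X, W, rng)
            clusters.append(ClusterData(y=y, X=X, W=W, id=i))
        panel = Panel(clusters,
                      fixed_names=["1", "center", "baseline", "sex", "placebo",
                                   "sex_x_placebo"],
                      random_names=["age_c"], outcome_name="y", id_name="patient")
    else:
        raise ValueError("kind must be 'respiratory_like' or 'simdesign'")
    if path is not None:
        write_long_csv(panel, path)
    return panel


def _simulate_outcomes(theta, X, W, rng) -> np.ndarray:
    """Draw one cluster's outcomes from the latent hierarchy."""
    from .sgt_core import mixing_moment
    import math
    from .sgt_core import HALF_NORMAL_MEAN as c0
    mix = theta.mixing
    u1 = mixing_moment(1, mix)
    ni = X.shape[0]
    u = 1.0 if mix.is_normal_limit else rng.gamma(theta.nu / 2, 2 / theta.nu)
    v = abs(rng.standard_normal())
    shift = v / math.sqrt(u) - c0 * u1
    L = np.linalg.cholesky(theta.d_bar)
    b = shift * theta.delta + (L @ rng.standard_normal(theta.q)) / math.sqrt(u)
    u0 = theta.upsilon0
    z = (X @ theta.beta + W @ b + shift * u0 * theta.delta_eps
         + u0 / math.sqrt(u) * rng.standard_normal(ni))
    return (z > 0).astype(int)


def fit_report(res, panel: Panel) -> dict:
    """JSON-serializable fit summary (estimates / se / z, IC, EB extremes)."""
    from .inference import delta_method_varcomp, pack_free
    est = pack_free(res.theta)
    out = {
        "loglik": res.loglik,
        "converged": bool(res.converged),
        "n_iter": int(res.n_iter),
        "n_px_iter": int(res.n_px_iter),
        "nu": res.theta.nu if np.isfinite(res.theta.nu) else "inf",
        "upsilon0": res.theta.upsilon0,
        "n_clusters": panel.n_clusters,
        "n_obs": panel.n_obs,
    }
    if res.free_labels is not None:
        rows = []
        for lbl, e, s in zip(res.free_labels, est, res.se):
            rows.append({"parameter": lbl, "estimate": float(e),
                         "se": float(s),
                         "z_value": float(e / s) if s > 0 else None})
        out["parameters"] = rows
        out["varcomp"] = delta_method_varcomp(res.theta, res.vcov)
        out["ic"] = res.ic
    if res.eb is not None:
        w = res.eb["u2"]
        out["eb_weights"] = {"mean": float(np.mean(w)),
                             "n_outlying": int(np.sum(w < 1.0))}
    if res.nu_profile is not None:
        out["nu_profile"] = [[float(a), float(b)] for a, b in res.nu_profile]
        out["nu_at_lower_edge"] = bool(res.nu_at_edge)
    return out
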