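"""Shared fixtures: accuracy presets, small panels, rejection oracles."""

import numpy as np
import pytest

from sgtlm import MixingSpec, MvtOptions, SgtParams, TruncRegion, sgt_rvs
from sgtlm.sgt_core import lambda_to_delta


@pytest.fixture(scope="session")
def hi_opts():
    """High-accuracy cdf options for oracle comparisons."""
    return MvtOptions(points=2048, shifts=8)


@pytest.fixture(scope="session")
def med_opts():
    return MvtOptions(points=512, shifts=4)


@pytest.fixture(scope="session")
def probit_panel_small():
    """Probit-mechanism panel, 40 clusters x 6 observations."""
    from sgtlm.simstudy import SimDesign, simulate_dataset
    return simulate_dataset(SimDesign(mechanism="probit", n_clusters=40, seed=7), 0)


@pytest.fixture(scope="session")
def sgt_panel_small():
    """SGT-mechanism panel, 40 clusters x 6 observations."""
    from sgtlm.simstudy import SimDesign, simulate_dataset
    return simulate_dataset(SimDesign(mechanism="sgt", n_clusters=40, seed=7), 0)


def rejection_sample(params: SgtParams, region: TruncRegion, n_draw: int,
                     seed: int) -> np.ndarray:
    """Draws of Z from the truncated law by rejection on the full sample."""
    z = sgt_rvs(params, n_draw, seed=seed)
    keep = np.ones(n_draw, dtype=bool)
    for k in range(region.dim):
        if region.orient[k] > 0:
            keep &= z[:, k] <= region.a[k]
        else:
            keep &= z[:, k] > region.a[k]
    return z[keep]


def joint_rejection_sample(params: SgtParams, region: TruncRegion, n_draw: int,
                           seed: int):
    """(u, v, z) draws from the joint latent representation, kept in-region."""
    rng = np.random.default_rng(seed)
    mix = params.mixing
    ws = lambda_to_delta(params.lam, mix.scale_ratio * params.omega)
    p = params.dim
    if mix.is_normal_limit:
        u = np.ones(n_draw)
    else:
        # on the rescaled ST form the mixing is Gamma(nu/2, nu/2)
        u = rng.gamma(mix.nu / 2, 2.0 / mix.nu, size=n_draw)
    v = np.abs(rng.standard_normal(n_draw))
    x = rng.multivariate_normal(np.zeros(p), ws.omega_bar, size=n_draw,
                                method="eigh")
    z = params.mu + (v[:, None] * ws.delta + x) / np.sqrt(u)[:, None]
    keep = np.ones(n_draw, dtype=bool)
    for k in range(p):
        if region.orient[k] > 0:
            keep &= z[:, k] <= region.a[k]
        else:
            keep &= z[:, k] > region.a[k]
    return u[keep], v[keep], z[keep]
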