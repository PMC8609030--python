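"""Shared fixtures: synthetic cohorts and data helpers reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coexdyn as cd
from coexdyn.network import NetworkConfig, build_reference_network

SIGMA = 0.4  # log2-scale residual SD used by most fixtures


def one_factor_groups(seed, n_genes, n_per_group, r_case, r_ctrl, noise_sd=1.0,
                      case_loadings=None):
    """Two independent one-factor expression groups (genes x samples frames).

    Population within-module correlation is r_case / r_ctrl respectively;
    ``case_loadings`` optionally overrides the per-gene case loading vector.
    """
    rng = np.random.default_rng(seed)
    lam_case = cd.loading_for_correlation(r_case, noise_sd)
    lam_ctrl = cd.loading_for_correlation(r_ctrl, noise_sd)
    lc = np.full(n_genes, lam_case) if case_loadings is None else np.asarray(case_loadings)
    f1 = rng.normal(size=n_per_group)
    f2 = rng.normal(size=n_per_group)
    xc = lc[:, None] * f1[None, :] + rng.normal(0, noise_sd, (n_genes, n_per_group))
    xt = lam_ctrl * f2[None, :] + rng.normal(0, noise_sd, (n_genes, n_per_group))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    ec = pd.DataFrame(xc, index=genes, columns=[f"case{j}" for j in range(n_per_group)])
    et = pd.DataFrame(xt, index=genes, columns=[f"ctrl{j}" for j in range(n_per_group)])
    return ec, et


def exact_correlation_data(corr, n_samples, seed=0):
    """samples x genes data whose *empirical* correlation equals ``corr``
    exactly (whitening construction); used for model-exact oracles."""
    g = corr.shape[0]
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_samples, g))
    x = x - x.mean(axis=0)
    # whiten empirically, then colour by the target correlation
    cov = x.T @ x / (n_samples - 1)
    li = np.linalg.inv(np.linalg.cholesky(cov))
    z = x @ li.T  # empirical covariance = I
    l = np.linalg.cholesky(corr)
    y = z @ l.T
    return y


@pytest.fixture(scope="session")
def make_one_factor_groups():
    return one_factor_groups


@pytest.fixture(scope="session")
def two_module_cohort():
    """Time-constant cohort with two planted 50-gene modules (r = 0.6),
    100 background genes and 100 subjects per group."""
    mods = (
        cd.PlantedModule("m1", 50, cd.loading_for_correlation(0.6, SIGMA)),
        cd.PlantedModule("m2", 50, cd.loading_for_correlation(0.6, SIGMA)),
    )
    cfg = cd.SyntheticConfig(
        n_cases=100, n_controls=100, n_background_genes=100,
        modules=mods, sampling_interval_days=90.0, noise_sd=SIGMA, seed=3,
    )
    expr, samples, truth = cd.generate_cohort(cfg)
    return expr, samples, truth, cfg


@pytest.fixture(scope="session")
def reference_partition(two_module_cohort):
    expr, samples, _, _ = two_module_cohort
    return build_reference_network(expr, samples, config=NetworkConfig(), seed=3)
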