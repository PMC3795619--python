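"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from raygrowth import SizeAtAgeRecord, SpeciesTemplate, generate_sample


@pytest.fixture
def vbgf2_records():
    """Noise-free two-parameter von Bertalanffy data (w_inf=100, k=0.2, w0=20)."""
    ages = np.arange(1.0, 16.0)
    sizes = 100.0 - (100.0 - 20.0) * np.exp(-0.2 * ages)
    return [SizeAtAgeRecord("sim", float(a), float(s)) for a, s in zip(ages, sizes)]


@pytest.fixture
def small_noisy_dataset():
    """Eight noisy records used by the grid-oracle equivalence checks."""
    tpl = SpeciesTemplate(
        "grid", w_inf=100.0, k=0.2, w0=20.0, age_min=1.0, age_max=15.0, n=8, noise_sd=5.0
    )
    return generate_sample(tpl, seed=11)


def grid_posterior_medians(records, w0, priors, w_grid, k_grid, v_grid):
    """Brute-force grid-integration posterior medians of (w_inf, k).

    Independent of the MH sampler: evaluates prior x likelihood on a dense
    lattice (scipy.stats densities), integrates numerically (log-spaced
    variance axis carries a d(log v) weight), and reads medians off the
    marginal CDFs.
    """
    ages = np.array([r.age for r in records])
    sizes = np.array([r.disc_width for r in records])
    n = len(ages)
    scale = np.exp(
        np.log(priors.w_inf_mean)
        - (0.0 if priors.log_location_mean else 0.5 * priors.w_inf_log_sd**2)
    )
    lp_w = stats.lognorm.logpdf(w_grid, s=priors.w_inf_log_sd, scale=scale)
    lp_k = stats.beta.logpdf(k_grid, priors.k_alpha, priors.k_beta)
    lp_v = stats.invgamma.logpdf(v_grid, priors.var_shape, scale=priors.var_rate)
    pred = w_grid[:, None, None] - (w_grid[:, None, None] - w0) * np.exp(
        -k_grid[None, :, None] * ages[None, None, :]
    )
    rss = ((sizes - pred) ** 2).sum(axis=-1)
    ll = -0.5 * n * np.log(2 * np.pi * v_grid[None, None, :]) - rss[:, :, None] / (
        2 * v_grid[None, None, :]
    )
    lpost = ll + lp_w[:, None, None] + lp_k[None, :, None] + lp_v[None, None, :]
    post = np.exp(lpost - lpost.max()) * v_grid[None, None, :]  # log-spaced v weight

    def median(axis_vals, marginal):
        c = np.cumsum(marginal) / marginal.sum()
        return float(np.interp(0.5, c, axis_vals))

    return (
        median(w_grid, post.sum(axis=(1, 2))),
        median(k_grid, post.sum(axis=(0, 2))),
    )
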