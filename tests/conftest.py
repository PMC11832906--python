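"""Shared fixtures and independent oracles for the test suite.

The brute-force likelihood oracle here deliberately avoids every shortcut
the package takes (no log-sum-exp, no vectorization, no shared code): it
enumerates latent community states and multiplies probabilities directly,
so agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ctmsom as cm


def brute_force_site_likelihood(y_site, f_single, f_pair, p_site):
    """Probability-domain enumeration of one site's marginal likelihood.

    y_site : (K, S) in {0, 1, nan}; f_single : (S,); f_pair : dict
    {(i, j): value} with i < j; p_site : (K, S) detection probabilities.
    """
    K, S = y_site.shape
    weights, states = [], []
    for z in itertools.product((0, 1), repeat=S):
        e = sum(f_single[i] * z[i] for i in range(S))
        for (i, j), val in f_pair.items():
            e += val * z[i] * z[j]
        states.append(z)
        weights.append(math.exp(e))
    total_w = sum(weights)
    like = 0.0
    for z, w in zip(states, weights):
        prod = w / total_w
        for i in range(S):
            if z[i] == 1:
                for k in range(K):
                    y = y_site[k, i]
                    if math.isnan(y):
                        continue
                    prod *= p_site[k, i] if y == 1 else (1.0 - p_site[k, i])
            else:
                if np.nansum(y_site[:, i]) > 0:
                    prod = 0.0
        like += prod
    return like


def brute_force_loglik(Y, F_single, F_pair, P):
    """Dataset-level oracle: sum of log site likelihoods.

    F_single : (J, S); F_pair : dict {(i, j): (J,)}; P : (J, K, S).
    """
    total = 0.0
    for j in range(Y.shape[0]):
        pairs_j = {key: vals[j] for key, vals in F_pair.items()}
        total += math.log(
            brute_force_site_likelihood(Y[j], F_single[j], pairs_j, P[j]))
    return total


@pytest.fixture(scope="session")
def study_world():
    """One synthetic dataset from the default (study-like) configuration."""
    return cm.simulate(cm.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_fit():
    """A fast, converged fit of the generating model on a small world."""
    sim = cm.simulate(cm.SimConfig(
        n_sites=150, study_start="2022-01-01", study_end="2022-02-09",
        deployment="full", simulate_images=False, seed=9))
    res = cm.fit(sim.spec, sim.model_data(), n_starts=1, seed=9)
    return sim, res


def single_species_array(histories):
    """DetectionArray for one species from a list of 0/1/nan site histories."""
    vals = np.asarray(histories, dtype=float)[:, :, None]
    J, K = vals.shape[:2]
    return cm.DetectionArray(
        vals, [f"S{j}" for j in range(J)],
        pd.date_range("2022-01-01", periods=K), ["sp"])


def intercept_only_data(array):
    """ModelData with no covariates beyond the intercept."""
    site_df = pd.DataFrame(index=array.site_ids)
    return cm.ModelData(array=array, site_covariates=site_df)
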