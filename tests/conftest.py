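"""Shared fixtures: survey vectors, synthetic mixtures and fitted PMF models."""

from itertools import permutations

import numpy as np
import pytest

from pahrisk import pmf, registry, synthetic


@pytest.fixture(scope="session")
def survey_means():
    return registry.survey_mean_vector()


@pytest.fixture(scope="session")
def carc_params():
    return registry.default_exposure("carcinogenic")


@pytest.fixture(scope="session")
def mixture_200():
    """Four-source mixture at the standard recovery settings (n=200, noise 0.1)."""
    return synthetic.generate_mixture(200, noise_cv=0.1, seed=7)


@pytest.fixture(scope="session")
def recovery_model(mixture_200):
    conc, unc, _ = mixture_200
    return pmf.fit_pmf(conc, unc, 4, n_starts=20, seed=7)


@pytest.fixture(scope="session")
def diagnostics_model():
    """Low-noise fit used for the r²/residual diagnostics checks."""
    conc, unc, truth = synthetic.generate_mixture(200, noise_cv=0.05, seed=7)
    model = pmf.fit_pmf(conc, unc, 4, n_starts=20, seed=7)
    return model, truth


def match_factors(estimated: np.ndarray, truth: np.ndarray):
    """Best permutation matching of profile rows by summed cosine similarity.

    Returns (permutation, cosine similarities) where ``permutation[h]`` is the
    true factor index matched to estimated factor h.
    """

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    k = estimated.shape[0]
    best = max(
        (sum(cos(estimated[h], truth[p[h]]) for h in range(k)), p)
        for p in permutations(range(k))
    )
    perm = best[1]
    return perm, [cos(estimated[h], truth[perm[h]]) for h in range(k)]
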