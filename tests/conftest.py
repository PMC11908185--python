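"""Shared fixtures: seeded generators, small Gibbs chains, constructed chains.

``build_permuted_chain`` fabricates a chain directly in the GibbsChain
container: each sample places K' well-separated (log rate, log weight)
centroids -- with small jitter -- at randomly permuted component slots,
with the remaining slots holding negligible weight.  This reproduces
the label-switching structure of a real chain while keeping the true
partition known, so post-processing can be checked against a
nearest-centroid oracle without running the sampler.
"""

import numpy as np
import pytest

from restime.gibbs import GibbsChain, GibbsConfig, run_gibbs
from restime.synthetic import SCENARIOS, sample_hyperexponential


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def build_permuted_chain(w=200, omega=200, K=6,
                         lam_centroids=(5.0, 0.5, 0.05),
                         pi_centroids=(0.6, 0.25, 0.15),
                         jitter=0.03, seed=0, cluster_of_event=None):
    """Chain with known clusters, label-switched uniformly per sample."""
    rng = np.random.default_rng(seed)
    lam_c = np.asarray(lam_centroids, float)
    pi_c = np.asarray(pi_centroids, float)
    kp = lam_c.size
    if cluster_of_event is None:
        cluster_of_event = np.arange(omega) % kp
    cluster_of_event = np.asarray(cluster_of_event)

    weights = np.empty((w, K))
    rates = np.empty((w, K))
    z = np.empty((w, omega), dtype=np.int16)
    for i in range(w):
        slots = rng.permutation(K)[:kp]
        lam = np.exp(np.log(lam_c) + jitter * rng.normal(size=kp))
        pi = np.exp(np.log(pi_c) + jitter * rng.normal(size=kp))
        full_pi = np.full(K, 1e-9)
        full_lam = np.exp(rng.uniform(np.log(1e-2), np.log(10), K))
        full_pi[slots] = pi
        full_lam[slots] = lam
        weights[i] = full_pi / full_pi.sum()
        rates[i] = full_lam
        z[i] = slots[cluster_of_event]

    durations = rng.exponential(1.0 / lam_c[cluster_of_event])
    config = GibbsConfig(n_iter=100 + w * 10, burn_in=100, thin=10,
                         seed=seed, K=K)
    chain = GibbsChain(weights=weights, rates=rates, indicators=z,
                       durations=durations, config=config)
    return chain, cluster_of_event, lam_c, pi_c


def permute_chain_labels(chain, seed=0):
    """Uniformly permute component indices within every kept sample."""
    rng = np.random.default_rng(seed)
    K = chain.weights.shape[1]
    weights = chain.weights.copy()
    rates = chain.rates.copy()
    z = chain.indicators.copy()
    for i in range(chain.w):
        perm = rng.permutation(K)  # new index of old component k is perm[k]
        inv = np.empty(K, dtype=int)
        inv[perm] = np.arange(K)
        weights[i] = chain.weights[i][inv]
        rates[i] = chain.rates[i][inv]
        z[i] = perm[chain.indicators[i]]
    return GibbsChain(weights=weights, rates=rates, indicators=z,
                      durations=chain.durations, config=chain.config)


@pytest.fixture(scope="session")
def two_comp_chain():
    """A real (sampled) chain on two well-separated components."""
    truth = SCENARIOS["two_component"](n=3000, seed=7)
    t, _ = sample_hyperexponential(truth)
    cfg = GibbsConfig(n_iter=4000, burn_in=1000, thin=6, seed=7, K=10)
    return run_gibbs(t, cfg, log_every=0), truth
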