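"""Label-switching correction, noise removal, MAP/CI estimation."""

import dataclasses

import numpy as np
import pytest

from restime.postprocess import (MembershipMatrix, correct_labels,
                                 filter_weights, fingerprint, map_estimate,
                                 membership_matrix, mode_component_count,
                                 remove_noise, tau_posterior)
from restime.model import MixtureState

from conftest import build_permuted_chain, permute_chain_labels


def simplex(vals):
    v = np.asarray(vals, float)
    return v / v.sum()


class TestFilterWeights:
    def test_below_threshold_dropped(self):
        st = MixtureState(weights=simplex([0.995, 0.005]), rates=[1.0, 2.0])
        assert filter_weights(st, omega=1000).tolist() == [0]

    def test_boundary_inclusive(self):
        st = MixtureState(weights=simplex([0.99, 0.01]), rates=[1.0, 2.0])
        assert filter_weights(st, omega=1000).tolist() == [0, 1]

    def test_three_survivors(self):
        w = np.array([0.5, 0.3995, 0.1, 0.0004, 0.0001])
        st = MixtureState(weights=w, rates=np.ones(5))
        assert filter_weights(st, omega=100).tolist() == [0, 1, 2]


class TestModeComponentCount:
    @staticmethod
    def chain_with_counts(counts, K=6, omega=1000):
        """Each entry of counts gives the survivor count of one sample."""
        from restime.gibbs import GibbsChain, GibbsConfig
        w = len(counts)
        weights = np.full((w, K), 1e-6)
        for i, c in enumerate(counts):
            weights[i, :c] = (1 - (K - c) * 1e-6) / c
        rates = np.ones((w, K))
        z = np.zeros((w, omega), np.int16)
        cfg = GibbsConfig(n_iter=100 + w, burn_in=100, thin=1, seed=0, K=K)
        return GibbsChain(weights=weights, rates=rates, indicators=z,
                          durations=np.ones(omega), config=cfg)

    def test_unanimous(self):
        assert mode_component_count(self.chain_with_counts([3] * 10)) == 3

    def test_plain_mode(self):
        counts = [3] * 600 + [4] * 300 + [5] * 100
        assert mode_component_count(self.chain_with_counts(counts)) == 3

    def test_tie_broken_upward(self):
        counts = [3] * 500 + [4] * 500
        assert mode_component_count(self.chain_with_counts(counts)) == 4


class TestCorrectLabels:
    def test_recovers_centroid_partition(self):
        """GMM assignment matches a nearest-centroid oracle exactly."""
        chain, cluster_of_event, lam_c, pi_c = build_permuted_chain(seed=3)
        model = correct_labels(chain)
        assert model.k_prime == 3
        mask = model.assignment >= 0
        logx = np.column_stack([np.log(chain.rates[mask]),
                                np.log(chain.weights[mask])])
        cents = np.column_stack([np.log(lam_c), np.log(pi_c)])
        oracle = np.argmin(((logx[:, None, :] - cents) ** 2).sum(-1), axis=1)
        # clusters are ordered by decreasing rate; centroids already are
        np.testing.assert_array_equal(model.assignment[mask], oracle)

    def test_every_cluster_has_w_members_under_permutation_symmetry(self):
        chain, *_ = build_permuted_chain(w=150, jitter=0.0, seed=5)
        model = correct_labels(chain)
        for c in model.clusters:
            assert c.n_samples == 150

    def test_conservation_each_survivor_in_exactly_one_cluster(self):
        chain, *_ = build_permuted_chain(seed=8)
        model = correct_labels(chain)
        mask = chain.weights >= 10.0 / chain.omega
        assert ((model.assignment >= 0) == mask).all()
        total = sum(c.n_samples for c in model.clusters)
        assert total == int(mask.sum())

    def test_clusters_ordered_fastest_first(self):
        chain, *_ = build_permuted_chain(seed=2)
        model = correct_labels(chain)
        rates = [c.map_lambda.value for c in model.clusters]
        assert rates == sorted(rates, reverse=True)

    def test_no_training_samples_is_an_error(self):
        chain, *_ = build_permuted_chain(seed=1)
        with pytest.raises(ValueError, match="inspect the chain"):
            correct_labels(chain, k_prime=5)


class TestLabelSwitchingInvariance:
    def test_outputs_invariant_under_per_sample_permutation(self):
        chain, *_ = build_permuted_chain(seed=13)
        shuffled = permute_chain_labels(chain, seed=99)

        def summary(ch):
            model = correct_labels(ch)
            mm = membership_matrix(ch, model)
            model = remove_noise(model, mm)
            return (model.k_prime, model.noise_flags.tolist(),
                    [(c.map_tau.value, c.map_tau.ci) for c in model.clusters],
                    mm.probabilities)

        k_a, flags_a, taus_a, P_a = summary(chain)
        k_b, flags_b, taus_b, P_b = summary(shuffled)
        assert k_a == k_b
        assert flags_a == flags_b
        assert taus_a == taus_b
        np.testing.assert_array_equal(P_a, P_b)


class TestMembershipMatrix:
    def test_matches_naive_counting_loop(self):
        chain, *_ = build_permuted_chain(w=20, omega=5, K=4,
                                         lam_centroids=(3.0, 0.03),
                                         pi_centroids=(0.7, 0.3), seed=4)
        # with only 5 events the default filter (10 expected events)
        # would drop everything; require 1 expected event instead
        model = correct_labels(chain, numerator=1.0)
        mm = membership_matrix(chain, model)
        for n in range(5):
            for c in range(model.k_prime):
                hits = sum(
                    1 for i in range(20)
                    if model.assignment[i, chain.indicators[i, n]] == c)
                assert mm.probabilities[n, c] == pytest.approx(hits / 20)

    def test_single_sample_single_cluster(self):
        chain, *_ = build_permuted_chain(w=1, omega=30, K=3,
                                         lam_centroids=(1.0,),
                                         pi_centroids=(1.0,), seed=6)
        model = correct_labels(chain)
        mm = membership_matrix(chain, model)
        np.testing.assert_allclose(mm.probabilities[:, 0], 1.0)

    def test_unassigned_mass_reported_not_renormalized(self):
        chain, *_ = build_permuted_chain(w=50, omega=100, seed=9)
        # force one event's indicator to a filtered (tiny-weight) slot
        for i in range(25):
            chain.indicators[i, 0] = int(np.argmin(chain.weights[i]))
        model = correct_labels(chain)
        mm = membership_matrix(chain, model)
        assert mm.unassigned[0] == pytest.approx(0.5)
        assert mm.probabilities[0].sum() == pytest.approx(0.5)


class TestRemoveNoise:
    @staticmethod
    def with_col_max(maxima):
        """Membership matrix whose per-cluster column maxima are given."""
        P = np.zeros((4, len(maxima)))
        for c, m in enumerate(maxima):
            P[c % 4, c] = m
        return MembershipMatrix(probabilities=P,
                                unassigned=1 - P.sum(axis=1))

    @staticmethod
    def model_with(k):
        chain, *_ = build_permuted_chain(
            w=30, omega=200, K=6,
            lam_centroids=tuple(5.0 * 0.1 ** i for i in range(k)),
            pi_centroids=tuple(simplex(np.arange(1, k + 1.0))), seed=7)
        return correct_labels(chain)

    def test_boundary_noise_rule(self):
        model = self.model_with(3)
        mm = self.with_col_max([0.39, 0.41, 0.9])
        flags = remove_noise(model, mm).noise_flags
        assert flags.tolist() == [True, False, False]

    def test_all_noise_is_an_error(self):
        model = self.model_with(2)
        with pytest.raises(ValueError, match="noise"):
            remove_noise(model, self.with_col_max([0.1, 0.2]))

    def test_monotone_in_threshold(self):
        model = self.model_with(3)
        mm = self.with_col_max([0.35, 0.45, 0.8])
        lo = remove_noise(model, mm, threshold=0.3).noise_flags
        hi = remove_noise(model, mm, threshold=0.5).noise_flags
        assert (~lo | hi).all()  # raising the threshold never un-flags
        assert lo.sum() <= hi.sum()


class TestMapEstimate:
    def test_degenerate_constant_samples(self):
        est = map_estimate(np.full(30, 2.0))
        assert est.value == 2.0 and est.ci == (2.0, 2.0)

    def test_gamma_mode_within_bin_width(self, rng):
        shape, rate = 101.0, 53.0
        x = rng.gamma(shape, 1.0 / rate, size=20_000)
        est = map_estimate(x)
        q75, q25 = np.percentile(x, [75, 25])
        width = 2 * (q75 - q25) / x.size ** (1 / 3)
        assert abs(est.value - (shape - 1) / rate) < width
        lo, hi = est.ci
        assert lo < (shape - 1) / rate < hi

    def test_bimodal_flagged(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 5000), rng.normal(3, 0.1, 5000)])
        assert map_estimate(x).multimodal
        assert not map_estimate(rng.normal(0, 1, 5000)).multimodal

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="longer chain"):
            map_estimate(np.arange(10.0))


class TestTauPosterior:
    def test_constant_rates(self):
        est = tau_posterior(np.full(30, 2.0))
        assert est.value == pytest.approx(0.5)

    def test_inverse_gamma_mode(self, rng):
        """Reciprocals of Gamma(a, b) rates follow InverseGamma(a, b) with
        mode b / (a + 1)."""
        a, b = 8.0, 40.0
        lam = rng.gamma(a, 1.0 / b, size=50_000)
        est = tau_posterior(lam)
        tau = 1.0 / lam
        q75, q25 = np.percentile(tau, [75, 25])
        width = 2 * (q75 - q25) / tau.size ** (1 / 3)
        assert abs(est.value - b / (a + 1)) < width

    def test_ci_is_reciprocal_of_swapped_rate_ci(self, rng):
        lam = rng.gamma(5.0, 2.0, size=1000)
        est = tau_posterior(lam)
        lo, hi = np.percentile(lam, [2.5, 97.5])
        assert est.ci == (pytest.approx(1 / hi), pytest.approx(1 / lo))

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            tau_posterior(np.array([1.0, 0.0]))


class TestFingerprint:
    @staticmethod
    def model_with_taus(taus, omega=100):
        from restime.postprocess import (ClusterModel, KineticCluster,
                                         MapEstimate)
        clusters = [
            KineticCluster(index=i, rates=np.full(30, 1 / t),
                           weights=np.full(30, 1.0 / len(taus)),
                           map_lambda=MapEstimate(1 / t, (1 / t, 1 / t)),
                           map_tau=MapEstimate(t, (0.8 * t, 1.2 * t)),
                           map_weight=MapEstimate(0.5, (0.4, 0.6)))
            for i, t in enumerate(sorted(taus))
        ]
        return ClusterModel(k_prime=len(taus), clusters=clusters,
                            assignment=np.zeros((30, 3), np.int16),
                            omega=omega)

    def test_slowest_cluster_wins(self):
        df = fingerprint({1: self.model_with_taus([0.2, 1.2, 300.0])})
        assert df.loc[0, "tau_ns"] == 300.0
        assert df.loc[0, "n_clusters"] == 3

    def test_single_residue_mean_equals_tau(self):
        df = fingerprint({7: self.model_with_taus([5.0])})
        assert df["tau_ns"].mean() == df.loc[0, "tau_ns"]
        assert not bool(df.loc[0, "flagged"])  # tau < 4 * tau

    def test_flag_threshold_arithmetic(self):
        models = {i: self.model_with_taus([t])
                  for i, t in enumerate([1.0, 1.0, 1.0, 1.0, 10.0])}
        df = fingerprint(models)
        assert not df["flagged"].any()  # mean 2.8 -> threshold 11.2
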