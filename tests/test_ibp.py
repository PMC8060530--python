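from itertools import combinations_with_replacement, product

import numpy as np
import pytest

from emarisk import ibp


SX, SA = 0.3, 0.8


def enumerate_posterior(X, alpha, sigma_x, sigma_a, k_max=5):
    """Brute-force posterior over unordered feature matrices, truncated at k_max.

    States are multisets of nonzero ownership columns; each is scored with the
    exchangeable IBP pmf times the collapsed (A-integrated) likelihood. Returns
    (states, probs, prior_mass_within_truncation).
    """
    N = X.shape[0]
    patterns = [np.array(bits) for bits in product((0, 1), repeat=N) if any(bits)]
    states, logws, logpriors = [], [], []
    for k in range(k_max + 1):
        for cols in combinations_with_replacement(range(len(patterns)), k):
            Z = (np.stack([patterns[c] for c in cols], axis=1)
                 if k else np.zeros((N, 0), dtype=int))
            lp = ibp.ibp_log_prior(Z, alpha)
            logpriors.append(lp)
            logws.append(lp + ibp.collapsed_log_likelihood(Z, X, sigma_x, sigma_a))
            states.append(Z)
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    return states, w / w.sum(), float(np.sum(np.exp(logpriors)))


class TestPrior:
    @pytest.mark.parametrize(
        "counts,i,expected",
        [(np.ones(10), 9, 0.9), ([1, 0, 0, 0], 3, 0.25)],
    )
    def test_existing_prob_is_m_over_n(self, counts, i, expected):
        # column 0 owned by every row except possibly i
        Z = np.zeros((len(list(counts)), 1), dtype=int)
        Z[:, 0] = np.asarray(counts, dtype=int)
        Z[i, 0] = 0
        assert ibp.ibp_prior_existing_prob(0, i, Z) == pytest.approx(expected)

    def test_retired_column_rejected(self):
        Z = np.zeros((4, 1), dtype=int)
        Z[2, 0] = 1
        with pytest.raises(ValueError, match="retired"):
            ibp.ibp_prior_existing_prob(0, 2, Z)

    def test_pmf_normalises_over_truncation(self):
        # total prior mass over all unordered Z with K<=6 is ~1 for small alpha
        N, alpha = 3, 0.5
        patterns = [np.array(b) for b in product((0, 1), repeat=N) if any(b)]
        total = 0.0
        for k in range(7):
            for cols in combinations_with_replacement(range(len(patterns)), k):
                Z = (np.stack([patterns[c] for c in cols], axis=1)
                     if k else np.zeros((N, 0), dtype=int))
                total += np.exp(ibp.ibp_log_prior(Z, alpha))
        assert total == pytest.approx(1.0, abs=1e-3)


class TestCollapsedLikelihood:
    def test_no_feature_limit_is_iid_gaussian(self, rng):
        X = rng.normal(size=(4, 3))
        Z = np.zeros((4, 0), dtype=int)
        expected = -0.5 * np.sum(X**2) / SX**2 - X.size * (0.5 * np.log(2 * np.pi) + np.log(SX))
        assert ibp.collapsed_log_likelihood(Z, X, SX, SA) == pytest.approx(expected)

    def test_column_permutation_invariance(self, rng):
        X = rng.normal(size=(5, 4))
        Z = (rng.random((5, 3)) < 0.5).astype(int)
        Z[0] = 1  # no dead columns
        base = ibp.collapsed_log_likelihood(Z, X, SX, SA)
        for perm in ([2, 0, 1], [1, 2, 0]):
            assert ibp.collapsed_log_likelihood(Z[:, perm], X, SX, SA) == pytest.approx(base)

    def test_masked_input_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        mask = np.ones_like(X, dtype=bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="complete"):
            ibp.collapsed_log_likelihood(np.ones((3, 1), dtype=int), X, SX, SA, mask=mask)


class TestSampleWeights:
    def test_prior_fallback_without_observations(self, rng):
        Z = np.ones((6, 2), dtype=int)
        st = ibp.FeatureModelState(Z, np.zeros((2, 3)), 1.0, SX, 2.0)
        X = np.zeros((6, 3))
        mask = np.zeros_like(X, dtype=bool)
        draws = np.stack([ibp.sample_weights(st, X, mask, rng) for _ in range(400)])
        assert abs(draws.mean()) < 0.3
        assert draws.std() == pytest.approx(2.0, rel=0.15)

    def test_flat_prior_limit_is_least_squares(self, rng):
        Z = (rng.random((40, 2)) < 0.5).astype(int)
        Z[:, 0] |= 1 - Z[:, 1]  # ensure full column rank usage
        A_true = rng.normal(size=(2, 3))
        X = Z @ A_true + 0.01 * rng.normal(size=(40, 3))
        st = ibp.FeatureModelState(Z, A_true, 1.0, 0.01, 1e6)
        mask = np.ones_like(X, dtype=bool)
        draws = np.stack([ibp.sample_weights(st, X, mask, rng) for _ in range(50)])
        lstsq = np.linalg.lstsq(Z, X, rcond=None)[0]
        np.testing.assert_allclose(draws.mean(axis=0), lstsq, atol=0.02)

    def test_conjugate_posterior_recovers_weights(self, rng):
        Z = (rng.random((120, 3)) < 0.5).astype(int)
        A_true = rng.normal(size=(3, 5))
        X = Z @ A_true + SX * rng.normal(size=(120, 5))
        st = ibp.FeatureModelState(Z, A_true, 1.0, SX, SA)
        mask = np.ones_like(X, dtype=bool)
        draws = np.stack([ibp.sample_weights(st, X, mask, rng) for _ in range(500)])
        zscores = np.abs(draws.mean(0) - A_true) / draws.std(0)
        assert np.mean(zscores < 3) >= 0.95
        assert zscores.max() < 5


class TestResampleAlpha:
    def test_k0_n1_is_gamma_1_2(self, rng):
        st = ibp.FeatureModelState(np.zeros((1, 0), int), np.zeros((0, 2)), 1.0, SX, SA)
        draws = np.array([ibp.resample_alpha(st, rng, 1.0, 1.0) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(0.5, rel=0.05)   # Gamma(1, 2) mean
        assert draws.var() == pytest.approx(0.25, rel=0.1)

    def test_posterior_mean_monotone_in_k(self, rng):
        means = []
        for K in (0, 3, 8):
            Z = np.ones((20, K), dtype=int)
            st = ibp.FeatureModelState(Z, np.zeros((K, 2)), 1.0, SX, SA)
            means.append(np.mean([ibp.resample_alpha(st, rng) for _ in range(4000)]))
        assert means[0] < means[1] < means[2]


class TestSampleRow:
    def test_flat_likelihood_reduces_to_prior(self, rng):
        # huge sigma_x: acceptance of z_ik=1 approaches m_{-i,k}/N
        N = 8
        Z = np.ones((N, 1), dtype=int)
        Z[0, 0] = 0
        m_over_n = 7 / 8
        X = rng.normal(size=(N, 2))
        ones = 0
        reps = 4000
        for _ in range(reps):
            st = ibp.FeatureModelState(Z.copy(), np.zeros((1, 2)), 1e-9, 1e6, SA)
            new = ibp.sample_row(0, st, X[0], np.ones(2, bool), rng)
            ones += int(new.Z.shape[1] == 1 and new.Z[0, 0] == 1)
        assert ones / reps == pytest.approx(m_over_n, abs=0.02)

    def test_unobserved_row_sampled_from_prior(self, rng):
        N = 6
        Z = np.ones((N, 1), dtype=int)
        Z[1, 0] = 0
        st = ibp.FeatureModelState(Z, np.zeros((1, 3)), 1e-9, SX, SA)
        ones = sum(
            ibp.sample_row(1, st, np.zeros(3), np.zeros(3, bool), rng).Z[1, 0]
            for _ in range(4000)
        )
        assert ones / 4000 == pytest.approx(5 / 6, abs=0.02)


class TestRunGibbs:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(12, 4))
        cfg = ibp.GibbsConfig(n_iterations=40, burn_in=10, thin=2, seed=3)
        s1 = ibp.run_gibbs(X, None, cfg)
        s2 = ibp.run_gibbs(X, None, cfg)
        np.testing.assert_array_equal(s1.map_state.Z, s2.map_state.Z)
        np.testing.assert_allclose(s1.logp_trace, s2.logp_trace)

    def test_all_zero_data_yields_no_features(self):
        X = np.zeros((20, 4))
        cfg = ibp.GibbsConfig(n_iterations=60, burn_in=20, thin=2, seed=0,
                              sigma_x=0.05, resample_alpha=False, alpha=0.5)
        summary = ibp.run_gibbs(X, None, cfg)
        assert summary.map_state.K == 0
        assert np.isfinite(summary.logp_trace).all()

    def test_recovers_feature_count_on_separated_data(self, rng):
        # 3 well-separated additive sources on the unit score scale, observed
        # through a sparse turn-over mask (3 of 32 items per row) — the regime
        # the model is built for
        A_true = np.zeros((3, 32))
        A_true[0, :12], A_true[1, 12:22], A_true[2, 22:] = 0.5, 0.45, 0.4
        Z_true = (rng.random((600, 3)) < 0.4).astype(int)
        X = Z_true @ A_true + 0.15 * rng.normal(size=(600, 32))
        mask = np.zeros_like(X, dtype=bool)
        for i in range(600):
            mask[i, rng.choice(32, size=3, replace=False)] = True
        cfg = ibp.GibbsConfig(n_iterations=150, burn_in=75, thin=5, seed=1,
                              init_features=5)
        summary = ibp.run_gibbs(X, mask, cfg)
        assert summary.map_state.K in (2, 3, 4)
        assert np.isfinite(summary.logp_trace).all()

    def test_map_logp_is_max_over_samples(self, rng):
        X = rng.normal(size=(15, 3))
        summary = ibp.run_gibbs(X, None, ibp.GibbsConfig(n_iterations=30, burn_in=10, thin=2, seed=2))
        mask = np.ones_like(X, dtype=bool)
        recomputed = max(ibp.joint_log_prob(s, X, mask) for s in summary.samples)
        assert summary.map_logp == pytest.approx(recomputed)


class TestCanonicalize:
    def test_row_permutation_changes_only_labelling(self, rng):
        # permuting rows may relabel columns, but the multiset of ownership
        # patterns (after undoing the row permutation) is unchanged
        Z = (rng.random((10, 4)) < 0.5).astype(int)
        Z[:, Z.sum(0) == 0] = 1
        perm = rng.permutation(10)
        Zc1, _, _ = ibp.canonicalize(Z)
        Zc2, _, _ = ibp.canonicalize(Z[perm])
        cols1 = sorted(map(tuple, Zc1[perm].T))
        cols2 = sorted(map(tuple, Zc2.T))
        assert cols1 == cols2

    def test_ordering_by_count_then_value(self):
        Z = np.array([[0, 1, 1], [0, 1, 0], [1, 0, 0]])
        Zc, _, order = ibp.canonicalize(Z)
        counts = Zc.sum(0)
        assert list(counts) == sorted(counts, reverse=True)
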