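"""Slice-sampler kernels: sticks, conjugate updates, allocations, alpha,
label-switching moves and whole-chain behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from devtraj.dpmm import (
    DPMMPriors,
    DirichletProcessMixture,
    MixtureState,
    _log_accept_swap_adjacent,
    _log_accept_swap_any,
    _sample_invwishart,
    allocation_probabilities,
    label_switch_moves,
    niw_posterior,
    run_chain,
    sample_alpha,
    sample_component_params,
    sample_slice_and_labels,
    sample_sticks,
    stick_posterior_params,
    stick_weights,
)
from devtraj.simulate import classification_accuracy, generate_gaussian_clusters


def toy_priors(p=2):
    return DPMMPriors(b0=np.zeros(p), N0=0.1, c0=p + 1.0, C0=np.eye(p))


class TestStickWeights:
    @pytest.mark.parametrize(
        "V, expected",
        [
            ([0.5, 0.5, 0.5], [0.5, 0.25, 0.125]),
            ([1.0], [1.0]),
            ([0.2, 0.3], [0.2, 0.24]),
        ],
    )
    def test_examples(self, V, expected):
        np.testing.assert_allclose(stick_weights(V), expected, rtol=1e-15)

    def test_partial_sums_bounded(self, rng):
        V = rng.uniform(0.01, 0.99, size=25)
        C = stick_weights(V)
        assert np.all(C >= 0)
        assert np.all(np.cumsum(C) <= 1 + 1e-12)

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            stick_weights([0.5, 1.2])


class TestStickPosteriors:
    def test_counting(self):
        a, b = stick_posterior_params(np.array([0, 0, 1]), alpha=1.0, K_rep=2)
        np.testing.assert_allclose(a, [3, 2])
        np.testing.assert_allclose(b, [2, 1])

    def test_empty_gives_prior(self):
        a, b = stick_posterior_params(np.array([], dtype=int), alpha=2.5, K_rep=3)
        np.testing.assert_allclose(a, [1, 1, 1])
        np.testing.assert_allclose(b, [2.5, 2.5, 2.5])

    def test_single_component_posterior(self, rng):
        n = 40
        a, b = stick_posterior_params(np.zeros(n, dtype=int), alpha=1.5, K_rep=1)
        assert (a[0], b[0]) == (1 + n, 1.5)
        draws = np.array([sample_sticks(np.zeros(n, dtype=int), 1.5, 1, rng)[0]
                          for _ in range(4000)])
        expected = stats.beta(1 + n, 1.5).mean()
        assert draws.mean() == pytest.approx(expected, rel=0.02)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            stick_posterior_params(np.array([0]), alpha=0.0, K_rep=1)


class TestConjugateUpdate:
    def oracle(self, y_k, priors):
        """Independent normal-inverse-Wishart update using the uncentred
        sufficient-statistic form of the scale update."""
        y_k = np.atleast_2d(y_k)
        n = y_k.shape[0]
        N_n = priors.N0 + n
        b_n = (priors.N0 * priors.b0 + y_k.sum(axis=0)) / N_n
        C_n = (
            priors.C0
            + y_k.T @ y_k
            + priors.N0 * np.outer(priors.b0, priors.b0)
            - N_n * np.outer(b_n, b_n)
        )
        return b_n, N_n, priors.c0 + n, C_n

    def test_matches_independent_oracle(self, rng):
        priors = DPMMPriors(b0=rng.normal(size=3), N0=0.4, c0=5.0,
                            C0=np.diag([1.0, 2.0, 0.5]))
        y_k = rng.normal(size=(7, 3))
        got = niw_posterior(y_k, priors)
        want = self.oracle(y_k, priors)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-10)

    def test_empty_component_returns_prior(self):
        priors = toy_priors()
        b_n, N_n, c_n, C_n = niw_posterior(np.empty((0, 2)), priors)
        np.testing.assert_array_equal(b_n, priors.b0)
        assert (N_n, c_n) == (priors.N0, priors.c0)
        np.testing.assert_array_equal(C_n, priors.C0)

    def test_single_point_at_prior_mean_is_fixed_point(self):
        priors = toy_priors()
        b_n, N_n, c_n, C_n = niw_posterior(priors.b0[None, :], priors)
        np.testing.assert_allclose(b_n, priors.b0, atol=1e-14)
        assert c_n == priors.c0 + 1
        np.testing.assert_allclose(C_n, priors.C0, atol=1e-14)

    def test_invwishart_moments(self, rng):
        scale = np.array([[2.0, 0.3], [0.3, 1.0]])
        df = 10.0
        draws = np.mean([_sample_invwishart(df, scale, rng) for _ in range(6000)], axis=0)
        np.testing.assert_allclose(draws, stats.invwishart(df, scale).mean(), rtol=0.05)

    def test_component_draws_center_on_posterior_mean(self, rng):
        priors = toy_priors()
        y = rng.normal(loc=[3.0, -2.0], size=(30, 2))
        z = np.zeros(30, dtype=int)
        mus = np.array([sample_component_params(y, z, 0, priors, rng)[0] for _ in range(3000)])
        b_n, N_n, c_n, C_n = niw_posterior(y, priors)
        np.testing.assert_allclose(mus.mean(axis=0), b_n, atol=0.05)


class TestSliceAndLabels:
    def test_allocation_probabilities_match_enumeration(self, rng):
        """Brute-force evaluation of the slice full conditional on 4 points."""
        y = rng.normal(size=(4, 2))
        mus = np.array([[0.0, 0.0], [2.0, 1.0]])
        Sigmas = np.array([np.eye(2), 2 * np.eye(2)])
        C = np.array([0.4, 0.35])
        u = np.array([0.05, 0.38, 0.2, 0.01])
        probs = allocation_probabilities(y, C, mus, Sigmas, u)
        for i in range(4):
            dens = np.array(
                [
                    stats.multivariate_normal(mus[k], Sigmas[k]).pdf(y[i]) * (C[k] > u[i])
                    for k in range(2)
                ]
            )
            np.testing.assert_allclose(probs[i], dens / dens.sum(), rtol=1e-10)

    def test_equal_components_give_half_half(self):
        y = np.array([[0.0, 0.0]])
        mus = np.zeros((2, 2))
        Sigmas = np.array([np.eye(2), np.eye(2)])
        probs = allocation_probabilities(y, np.array([0.5, 0.5]), mus, Sigmas,
                                         np.array([0.1]))
        np.testing.assert_allclose(probs[0], [0.5, 0.5])

    def test_slice_keeps_observation_coverage(self, rng):
        priors = toy_priors()
        y = rng.normal(size=(12, 2))
        state = MixtureState(
            z=np.zeros(12, dtype=int),
            V=np.array([0.6]),
            mus=np.zeros((1, 2)),
            Sigmas=np.eye(2)[None],
            alpha=1.0,
        )
        new = sample_slice_and_labels(y, state, priors, rng)
        assert new.z.min() >= 0
        assert new.z.max() < new.K_rep
        C = new.weights
        assert np.all(C[new.z] > new.u)


class TestSampleAlpha:
    def quadrature_mean(self, K, n, e1, e2):
        grid = np.linspace(1e-8, 40, 400_001)
        logp = (e1 - 1 + K) * np.log(grid) - e2 * grid + gammaln(grid) - gammaln(grid + n)
        p = np.exp(logp - logp.max())
        p /= np.trapezoid(p, grid)
        return np.trapezoid(grid * p, grid)

    @pytest.mark.parametrize("K, n", [(4, 150), (2, 30), (9, 79)])
    def test_long_run_mean_matches_quadrature(self, K, n, rng):
        a, draws = 1.0, []
        for _ in range(60_000):
            a = sample_alpha(a, K, n, 1.0, 1.0, rng)
            draws.append(a)
        assert np.mean(draws[2000:]) == pytest.approx(
            self.quadrature_mean(K, n, 1.0, 1.0), rel=0.02
        )

    def test_stochastically_larger_for_more_clusters(self, rng):
        n = 50

        def mean_for(K):
            a, acc = 1.0, 0.0
            for _ in range(20_000):
                a = sample_alpha(a, K, n, 1.0, 1.0, rng)
                acc += a
            return acc / 20_000

        assert mean_for(n) > mean_for(1)

    def test_large_rate_shrinks_alpha_toward_zero(self, rng):
        draws = [sample_alpha(0.5, 2, 20, 1.0, 500.0, rng) for _ in range(2000)]
        assert np.mean(draws) < 0.05

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            sample_alpha(1.0, 0, 10, 1.0, 1.0, rng)
        with pytest.raises(ValueError):
            sample_alpha(-1.0, 2, 10, 1.0, 1.0, rng)


class TestLabelSwitchMoves:
    def joint_log_weight_term(self, V, z):
        """The only factor of the joint posterior that the moves change is
        the allocation-weight product prod_i C_{z_i} (stick priors and
        likelihood terms travel with the swapped parameters)."""
        C = stick_weights(V)
        return np.sum(np.log(C[z]))

    def test_swap_any_ratio_matches_joint_density(self, rng):
        for _ in range(200):
            K = rng.integers(2, 6)
            V = rng.uniform(0.05, 0.9, size=K)
            z = rng.integers(0, K, size=12)
            counts = np.bincount(z, minlength=K)
            k, l = rng.choice(K, size=2, replace=False)
            z_new = z.copy()
            z_new[z == k], z_new[z == l] = l, k
            want = self.joint_log_weight_term(V, z_new) - self.joint_log_weight_term(V, z)
            got = _log_accept_swap_any(stick_weights(V), counts, k, l)
            assert got == pytest.approx(want, abs=1e-10)

    def test_swap_adjacent_ratio_matches_joint_density(self, rng):
        for _ in range(200):
            K = rng.integers(2, 6)
            V = rng.uniform(0.05, 0.9, size=K)
            z = rng.integers(0, K, size=12)
            counts = np.bincount(z, minlength=K)
            k = rng.integers(0, K - 1)
            V_new = V.copy()
            V_new[[k, k + 1]] = V_new[[k + 1, k]]
            z_new = z.copy()
            z_new[z == k], z_new[z == k + 1] = k + 1, k
            want = self.joint_log_weight_term(V_new, z_new) - self.joint_log_weight_term(V, z)
            got = _log_accept_swap_adjacent(V, counts, k)
            assert got == pytest.approx(want, abs=1e-10)

    def test_symmetric_state_always_accepts(self, rng):
        """Equal weights with equal occupancy give a move-1 acceptance
        probability of one."""
        V = np.array([0.5, 0.5])  # equal sticks: both move ratios vanish
        counts = np.array([1, 1])  # equal occupancy
        assert _log_accept_swap_any(stick_weights(V), counts, 0, 1) == pytest.approx(0.0)
        state = MixtureState(
            z=np.array([0, 1]),
            V=V,
            mus=np.array([[0.0, 0.0], [1.0, 1.0]]),
            Sigmas=np.array([np.eye(2), np.eye(2)]),
            alpha=1.0,
        )
        for _ in range(5):
            state, accepted = label_switch_moves(state, rng)
            assert accepted[0]

    def test_single_component_is_a_noop(self, rng):
        state = MixtureState(
            z=np.zeros(3, dtype=int),
            V=np.array([0.9]),
            mus=np.zeros((1, 2)),
            Sigmas=np.eye(2)[None],
            alpha=1.0,
        )
        _, accepted = label_switch_moves(state, rng)
        assert accepted == (False, False)

    def test_detailed_balance_on_toy_posterior(self, rng):
        """Empirical transition frequencies of the label moves on a discrete
        toy state space satisfy detailed balance w.r.t. the enumerated joint
        density."""
        y = np.array([[0.0, 0.0], [2.0, 0.0]])
        thetas = (np.array([0.0, 0.0]), np.array([2.0, 0.0]))
        v_vals = (0.6, 0.3)

        def state_key(st):
            perm = 0 if np.allclose(st.mus[0], thetas[0]) else 1
            vord = 0 if np.isclose(st.V[0], v_vals[0]) else 1
            return (vord, perm, tuple(st.z))

        def log_joint(key):
            vord, perm, z = key
            V = np.array([v_vals[vord], v_vals[1 - vord]])
            C = stick_weights(V)
            mus = [thetas[perm], thetas[1 - perm]]
            ll = sum(
                stats.multivariate_normal(mus[zi], np.eye(2)).logpdf(y[i])
                for i, zi in enumerate(z)
            )
            return np.sum(np.log(C[list(z)])) + ll

        state = MixtureState(
            z=np.array([0, 1]),
            V=np.array(v_vals),
            mus=np.array(thetas),
            Sigmas=np.array([np.eye(2), np.eye(2)]),
            alpha=1.0,
        )
        transitions = {}
        prev = state_key(state)
        for _ in range(40_000):
            state, _ = label_switch_moves(state, rng)
            if state.K_rep < 2:  # trimming dropped an empty trailing component
                state.V = np.append(state.V, v_vals[1] if np.isclose(state.V[0], v_vals[0]) else v_vals[0])
                state.mus = np.vstack([state.mus, thetas[1] if np.allclose(state.mus[0], thetas[0]) else thetas[0]])
                state.Sigmas = np.array([np.eye(2), np.eye(2)])
            cur = state_key(state)
            transitions[(prev, cur)] = transitions.get((prev, cur), 0) + 1
            prev = cur
        for (a, b), n_ab in transitions.items():
            if a == b:
                continue
            n_ba = transitions.get((b, a), 0)
            # detailed balance: pi(a) P(a->b) = pi(b) P(b->a), so the flow
            # counts in the two directions agree up to Monte-Carlo error
            assert n_ba > 0
            assert abs(n_ab - n_ba) / np.sqrt(n_ab + n_ba) < 5.0


class TestRunChain:
    def test_fixed_seed_is_bit_reproducible(self):
        y, _ = generate_gaussian_clusters("separated", seed=3, n_per_cluster=10)
        priors = DPMMPriors.from_data(y)
        t1 = run_chain(y, priors, n_iter=200, init_K=3, seed=11)
        t2 = run_chain(y, priors, n_iter=200, init_K=3, seed=11)
        np.testing.assert_array_equal(t1.K, t2.K)
        np.testing.assert_array_equal(t1.alpha, t2.alpha)
        np.testing.assert_array_equal(t1.allocations, t2.allocations)

    def test_two_near_identical_points_collapse_to_one_cluster(self):
        y = np.array([[0.0, 0.0], [1e-3, 0.0]])
        priors = DPMMPriors(b0=np.zeros(2), N0=0.1, c0=3.0, C0=np.eye(2))
        trace = run_chain(y, priors, n_iter=1500, init_K=2, seed=4)
        counts = np.bincount(trace.K[500:])
        assert counts.argmax() == 1

    def test_separated_clusters_recovered(self, separated_clusters):
        y, labels = separated_clusters
        priors = DPMMPriors.from_data(y)
        trace = run_chain(y, priors, n_iter=2500, init_K=5, seed=5)
        ks = trace.K[1000:]
        assert np.bincount(ks).argmax() == 3
        # the modal partition matches the simulated clusters
        from devtraj.postprocess import psm, select_clustering

        res = select_clustering(psm([trace], 0.5), k_min=2, k_max=6)
        assert res.k == 3
        assert classification_accuracy(labels, res.assignment) == 100.0

    def test_component_means_recover_truth(self, separated_clusters):
        """Posterior draws of occupied component means fall within three
        posterior standard deviations of the simulated means."""
        y, labels = separated_clusters
        priors = DPMMPriors.from_data(y)
        rng = np.random.default_rng(17)
        trace = run_chain(y, priors, n_iter=800, init_K=3, seed=17)
        state = trace.final_state
        for j in range(3):
            members = np.flatnonzero(labels == j)
            comp = np.bincount(state.z[members]).argmax()
            b_n, N_n, c_n, C_n = niw_posterior(y[state.z == comp], priors)
            post_sd = np.sqrt(np.diag(C_n / (c_n - y.shape[1] - 1)) / N_n)
            assert np.all(np.abs(state.mus[comp] - y[labels == j].mean(axis=0))
                          <= 3 * post_sd + 0.3)

    def test_label_moves_do_not_change_posterior_of_K(self, separated_clusters):
        y, _ = separated_clusters
        priors = DPMMPriors.from_data(y)
        with_moves = run_chain(y, priors, n_iter=2000, init_K=5, seed=21)
        without = run_chain(y, priors, n_iter=2000, init_K=5, seed=22, label_switch=False)
        m1, m2 = with_moves.K[800:].mean(), without.K[800:].mean()
        assert abs(m1 - m2) < 0.5

    def test_segment_and_resume_round_trips_through_checkpoint(self, tmp_path):
        """A chain can be run in segments, checkpointing the state to disk
        between them; the resumed segment continues from the saved state."""
        from devtraj.dpmm import load_state, save_state

        y, _ = generate_gaussian_clusters("separated", seed=3, n_per_cluster=8)
        priors = DPMMPriors.from_data(y)
        seg1 = run_chain(y, priors, n_iter=100, init_K=3, seed=11)
        save_state(seg1.final_state, tmp_path / "ckpt.npz")
        restored = load_state(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(restored.z, seg1.final_state.z)
        np.testing.assert_allclose(restored.Sigmas, seg1.final_state.Sigmas)
        seg2 = run_chain(y, priors, n_iter=100, seed=12, init_state=restored)
        assert len(seg2.K) == 100
        assert seg2.final_state.K_occupied >= 1

    def test_init_K_reduced_with_warning(self):
        y = np.array([[0.0, 0.0], [5.0, 5.0], [0.1, 0.1]])
        priors = DPMMPriors(b0=np.zeros(2), N0=0.1, c0=3.0, C0=np.eye(2))
        with pytest.warns(UserWarning, match="reducing"):
            run_chain(y, priors, n_iter=5, init_K=10, seed=0)

    def test_prior_reproduction_with_likelihood_off(self):
        """Geweke-style check: with constant densities the sampler's
        stationary laws of alpha and V_1 match the prior."""
        rng = np.random.default_rng(31)
        y = rng.normal(size=(20, 2))
        priors = DPMMPriors(b0=np.zeros(2), N0=0.1, c0=3.0, C0=np.eye(2))
        trace = run_chain(y, priors, n_iter=6000, init_K=3, seed=31,
                          likelihood_off=True, label_switch=False)
        alphas = trace.alpha[1000:]
        # alpha ~ Gamma(1, 1): mean 1, sd 1
        assert alphas.mean() == pytest.approx(1.0, abs=0.1)
        assert alphas.std() == pytest.approx(1.0, abs=0.15)
        # occupied K matches the Chinese-restaurant prior marginal simulated
        # independently under alpha ~ Gamma(1, 1)
        prior_K = []
        for _ in range(4000):
            a = rng.gamma(1.0, 1.0)
            tables = []
            for i in range(20):
                probs = np.array(tables + [a], dtype=float)
                pick = rng.choice(len(probs), p=probs / probs.sum())
                if pick == len(tables):
                    tables.append(1)
                else:
                    tables[pick] += 1
            prior_K.append(len(tables))
        assert trace.K[1000:].mean() == pytest.approx(np.mean(prior_K), rel=0.12)


class TestModelObjects:
    def test_exchangeability_of_rows(self, separated_clusters):
        """Permuting observations permutes the consensus partition."""
        y, _ = separated_clusters
        perm = np.random.default_rng(2).permutation(len(y))
        res1 = DirichletProcessMixture(y).fit(n_iter=1200, init_K=[4], seed=9)
        res2 = DirichletProcessMixture(y[perm]).fit(n_iter=1200, init_K=[4], seed=9)
        c1 = res1.consensus(k_max=6).assignment
        c2 = res2.consensus(k_max=6).assignment
        assert classification_accuracy(c1[perm], c2) == 100.0

    def test_priors_validation(self):
        with pytest.raises(ValueError):
            DPMMPriors(b0=np.zeros(2), N0=0.1, c0=1.0, C0=np.eye(2))  # c0 <= p-1
        with pytest.raises(ValueError):
            DPMMPriors(b0=np.zeros(2), N0=-1.0, c0=3.0, C0=np.eye(2))
        with pytest.raises(ValueError):
            DPMMPriors(b0=np.zeros(2), N0=0.1, c0=3.0, C0=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_summary_mentions_convergence(self, separated_clusters):
        y, _ = separated_clusters
        res = DirichletProcessMixture(y).fit(n_iter=400, init_K=[2, 3], seed=1)
        text = res.summary()
        assert "Gelman-Rubin" in text and "Consensus clustering" in text

    def test_plots_render(self, separated_clusters):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        y, _ = separated_clusters
        res = DirichletProcessMixture(y).fit(n_iter=300, init_K=[3], seed=2)
        res.plot_trace()
        res.plot_similarity()
        plt.close("all")
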