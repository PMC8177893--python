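"""Variational HMM: exact-inference oracles, conjugate closed forms,
parameter recovery and free-energy behaviour."""

import itertools

import numpy as np
import pytest

from tdehmm.hmm import VBGaussianHMM, forward_backward, viterbi
from tdehmm.synthetic import generate_state_sequence


def brute_force_posteriors(ll, A, pi):
    """Exhaustive path-sum oracle for small T, K."""
    T, K = ll.shape
    tot = 0.0
    marg = np.zeros((T, K))
    xi = np.zeros((T - 1, K, K))
    best_p, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * np.exp(ll[0, path[0]])
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * np.exp(ll[t, path[t]])
        tot += p
        for t in range(T):
            marg[t, path[t]] += p
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += p
        if p > best_p:
            best_p, best_path = p, path
    return marg / tot, xi / tot, np.log(tot), np.array(best_path)


def two_regime_data(rng, T=30_000, dim=4, stay=0.992):
    P = np.array([[stay, 1 - stay], [1 - stay, stay]])
    seq = generate_state_sequence(P, T, seed=rng.integers(2**31 - 1))
    M1 = rng.standard_normal((dim, dim))
    M2 = rng.standard_normal((dim, dim))
    chols = [np.linalg.cholesky(M @ M.T + np.eye(dim)) for M in (M1, M2)]
    z = rng.standard_normal((T, dim))
    X = np.empty((T, dim))
    for k in (0, 1):
        X[seq == k] = z[seq == k] @ chols[k].T
    return X, seq


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        T, K = 6, 2
        ll = rng.standard_normal((T, K))
        A = rng.random((K, K))
        A /= A.sum(axis=1, keepdims=True)
        pi = np.array([0.4, 0.6])
        g, xi, le = forward_backward(ll, A, pi, return_full_xi=True)
        g0, xi0, le0, _ = brute_force_posteriors(ll, A, pi)
        np.testing.assert_allclose(g, g0, atol=1e-10)
        np.testing.assert_allclose(xi, xi0, atol=1e-10)
        assert abs(le - le0) < 1e-10

    def test_uniform_likelihoods_give_chain_marginals(self):
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        pi = np.array([0.9, 0.1])
        ll = np.zeros((8, 2))
        g, _, _ = forward_backward(ll, A, pi)
        mu = pi.copy()
        for t in range(8):
            np.testing.assert_allclose(g[t], mu, atol=1e-12)
            mu = mu @ A

    def test_single_state_gamma_all_ones(self, rng):
        g, _, _ = forward_backward(rng.standard_normal((10, 1)), np.ones((1, 1)), np.ones(1))
        np.testing.assert_allclose(g, 1.0)

    def test_zero_likelihood_row_rejected(self):
        ll = np.full((3, 2), -np.inf)
        with pytest.raises(ValueError, match="zero likelihood"):
            forward_backward(ll, np.eye(2), np.ones(2) / 2)


class TestViterbi:
    def test_matches_brute_force(self, rng):
        T, K = 6, 2
        ll = rng.standard_normal((T, K))
        A = rng.random((K, K))
        A /= A.sum(axis=1, keepdims=True)
        pi = np.array([0.5, 0.5])
        _, _, _, best = brute_force_posteriors(ll, A, pi)
        np.testing.assert_array_equal(viterbi(ll, A, pi), best)

    def test_single_state_constant_path(self, rng):
        path = viterbi(rng.standard_normal((5, 1)), np.ones((1, 1)), np.ones(1))
        assert np.all(path == 0)

    def test_dominant_state_wins_throughout(self):
        ll = np.tile([0.0, -50.0], (20, 1))
        A = np.full((2, 2), 0.5)
        assert np.all(viterbi(ll, A, np.ones(2) / 2) == 0)


class TestFit:
    def test_single_state_matches_conjugate_closed_form(self, rng):
        # K=1: inverse-Wishart posterior has scale S0 + X^T X, dof nu0 + T
        X = rng.standard_normal((2000, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        m = VBGaussianHMM(n_states=1, n_iter=5).fit(X)
        emp = X.T @ X / 2000
        S0 = emp + 1e-10 * np.trace(emp) / 4 * np.eye(4)
        expected = (S0 + X.T @ X) / (4 + 2 + 2000 - 4 - 1)
        np.testing.assert_allclose(m.covariances_[0], expected, rtol=1e-10)

    def test_single_state_free_energy_equals_exact_marginal_likelihood(self, rng):
        # for K=1 the variational bound is tight: -F = log p(X) with
        # log p(X) = -TP/2 log pi + log Gamma_P((nu0+T)/2) - log Gamma_P(nu0/2)
        #            + nu0/2 log|S0| - (nu0+T)/2 log|S0 + X^T X|
        from scipy.special import multigammaln

        T, P = 300, 3
        X = rng.standard_normal((T, P)) @ np.diag([1.0, 0.6, 1.4])
        m = VBGaussianHMM(n_states=1, n_iter=3).fit(X)
        S = X.T @ X
        emp = S / T
        S0 = emp + 1e-10 * np.trace(emp) / P * np.eye(P)
        nu0 = P + 2.0
        log_px = (
            -T * P / 2.0 * np.log(np.pi)
            + multigammaln((nu0 + T) / 2.0, P) - multigammaln(nu0 / 2.0, P)
            + nu0 / 2.0 * np.linalg.slogdet(S0)[1]
            - (nu0 + T) / 2.0 * np.linalg.slogdet(S0 + S)[1]
        )
        assert m.free_energy(X) == pytest.approx(-log_px, rel=1e-10)

    def test_two_regime_frame_accuracy(self, rng):
        X, seq = two_regime_data(rng)
        m = VBGaussianHMM(n_states=2, n_init=3, n_iter=25, random_state=0).fit(X)
        hard = m.posterior_.gamma.argmax(axis=1)
        acc = max(np.mean(hard == seq), np.mean(hard == 1 - seq))
        assert acc > 0.9

    def test_duplicated_subjects_leave_states_unchanged(self, rng):
        X, _ = two_regime_data(rng, T=8000)
        m1 = VBGaussianHMM(n_states=2, n_init=2, n_iter=25, random_state=1).fit(X)
        X2 = np.vstack([X, X])
        m2 = VBGaussianHMM(n_states=2, n_init=2, n_iter=25, random_state=1).fit(
            X2, lengths=[8000, 8000])
        # align labels by covariance similarity, then compare
        d = np.array([[np.linalg.norm(a - b) for b in m2.covariances_]
                      for a in m1.covariances_])
        perm = d.argmin(axis=1)
        assert set(perm) == {0, 1}
        for a, b in zip(m1.covariances_, m2.covariances_[perm]):
            np.testing.assert_allclose(a, b, rtol=0.05, atol=0.05)

    def test_free_energy_monotone_and_converged(self, rng):
        X, _ = two_regime_data(rng, T=10_000)
        m = VBGaussianHMM(n_states=2, n_init=2, n_iter=40, random_state=0).fit(X)
        fe = m.free_energy_trace_
        assert np.all(np.diff(fe) <= 1e-6 * np.abs(fe[:-1]))
        assert abs(fe[-1] - fe[-2]) < 1e-5 * abs(fe[-1])
        assert fe[-1] <= fe[0]

    def test_deterministic_under_seed(self, rng):
        X, _ = two_regime_data(rng, T=6000)
        m1 = VBGaussianHMM(n_states=2, n_init=2, n_iter=10, random_state=3).fit(X)
        m2 = VBGaussianHMM(n_states=2, n_init=2, n_iter=10, random_state=3).fit(X)
        np.testing.assert_array_equal(m1.covariances_, m2.covariances_)
        np.testing.assert_array_equal(m1.posterior_.gamma, m2.posterior_.gamma)

    @pytest.mark.parametrize("k_true", [2, 3])
    def test_parameter_recovery(self, k_true):
        # FO and self-transition probabilities recovered within +/- 0.05
        rng = np.random.default_rng(100 + k_true)
        T, dim, stay = 40_000, 4, 0.99
        P = np.full((k_true, k_true), (1 - stay) / (k_true - 1))
        np.fill_diagonal(P, stay)
        seq = generate_state_sequence(P, T, seed=7)
        chols = []
        for _ in range(k_true):
            M = rng.standard_normal((dim, dim))
            chols.append(np.linalg.cholesky(M @ M.T + 0.5 * np.eye(dim)))
        z = rng.standard_normal((T, dim))
        X = np.empty((T, dim))
        for k in range(k_true):
            X[seq == k] = z[seq == k] @ chols[k].T
        m = VBGaussianHMM(n_states=k_true, n_init=3, n_iter=30, random_state=0).fit(X)
        hard = m.posterior_.gamma.argmax(axis=1)
        accs = {p: np.mean(np.array(p)[hard] == seq)
                for p in itertools.permutations(range(k_true))}
        perm = max(accs, key=accs.get)
        assert accs[perm] > 0.9
        fo_true = np.bincount(seq, minlength=k_true) / T
        fo_est = np.bincount(np.array(perm)[hard], minlength=k_true) / T
        np.testing.assert_allclose(fo_est, fo_true, atol=0.05)
        inv = np.argsort(perm)
        trans = m.transmat_[np.ix_(inv, inv)]
        np.testing.assert_allclose(np.diag(trans), stay, atol=0.05)

    def test_label_permutation_equivariance(self, rng):
        # permuting the initial responsibilities permutes the recovered
        # states and leaves the free energy unchanged
        X, _ = two_regime_data(rng, T=6000)
        m = VBGaussianHMM(n_states=2)
        T, P_dim = X.shape
        emp = X.T @ X / T
        m._nu0 = P_dim + 2.0
        m._S0 = emp + 1e-10 * np.trace(emp) / P_dim * np.eye(P_dim)
        from tdehmm.hmm import _safe_cholesky
        m._S0_chol = _safe_cholesky(m._S0)
        m._trans_alpha0 = np.ones((2, 2)) + 9.0 * np.eye(2)
        m._init_alpha0 = np.ones(2)
        segs = [(0, T)]
        gamma = rng.random((T, 2))
        gamma /= gamma.sum(axis=1, keepdims=True)

        def run(g):
            Nk, sc = m._m_step_stats(X, g)
            state = m._update_global(Nk, sc, np.full((2, 2), T / 4), g.mean(0))
            for _ in range(4):
                state, fe = m._vb_sweep(X, segs, state)
            return state, fe

        s1, fe1 = run(gamma)
        s2, fe2 = run(gamma[:, ::-1])
        assert abs(fe1 - fe2) < 1e-6 * abs(fe1)
        np.testing.assert_allclose(s1[0][0].S, s2[0][1].S, rtol=1e-8)

    def test_stochastic_matches_batch_free_energy(self, rng):
        X, _ = two_regime_data(rng, T=12_000)
        lengths = [3000] * 4
        mb = VBGaussianHMM(n_states=2, n_init=2, n_iter=30, random_state=0).fit(X, lengths)
        ms = VBGaussianHMM(n_states=2, n_init=2, n_iter=15, stochastic=True,
                           sv_iter=30, batch_size=2, random_state=0).fit(X, lengths)
        fb, fs = mb.free_energy_trace_[-1], ms.free_energy_trace_[-1]
        assert abs(fs - fb) < 5e-3 * abs(fb)

    def test_cross_check_against_em_baseline(self, rng):
        # hmmlearn's EM point estimate agrees with the VB posterior mean on
        # well-separated regimes (independent implementation)
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        X, seq = two_regime_data(rng, T=15_000)
        m = VBGaussianHMM(n_states=2, n_init=2, n_iter=25, random_state=0).fit(X)
        em = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                  n_iter=50, random_state=0).fit(X)
        d = np.array([[np.linalg.norm(a - b) for b in em.covars_] for a in m.covariances_])
        perm = d.argmin(axis=1)
        assert set(perm) == {0, 1}
        for a, b in zip(m.covariances_, em.covars_[perm]):
            assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.1
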