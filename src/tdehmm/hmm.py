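"""Variational-Bayes Gaussian hidden Markov model with zero-mean states.

Each state is a zero-mean multivariate Gaussian over the embedded observation
space, so a state's full covariance encodes cross-channel, cross-lag structure
— i.e. frequency-resolved power and phase coupling.  Conjugate priors are used
throughout: inverse-Wishart on the state covariances (equivalently Wishart on
the precisions) and Dirichlet on the transition-matrix rows and the initial
distribution.  Inference alternates an exact forward–backward E-step (using
exponentiated expected log-parameters) with conjugate M-step updates; the
negative evidence lower bound ("free energy") is exact for this family and is
non-increasing across batch iterations.

A stochastic variational option updates the global posteriors from
subject-level minibatches with a Robbins–Monro step size, for cohorts too
long for batch sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import digamma, gammaln

__all__ = ["VBGaussianHMM", "StatePosterior", "forward_backward", "viterbi", "fit_hmm"]


def _fb_core(B: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled alpha/beta recursions; the O(T K^2) inner loop."""
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for j in range(K):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(K):
        alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = a * B[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    for j in range(K):
        beta[T - 1, j] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
    return alpha, beta, c


try:  # the jitted recursion is ~100x faster on long recordings
    from numba import njit

    _fb_core = njit(cache=False, fastmath=False)(_fb_core)
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# exact inference on a chain
# ---------------------------------------------------------------------------

def forward_backward(
    log_likelihoods: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
    return_full_xi: bool = False,
):
    """Scaled forward–backward recursion.

    Parameters
    ----------
    log_likelihoods : (T, K) array
        Per-sample log observation densities (may be unnormalised).
    transition, initial : arrays
        Non-negative weights; need not be normalised (expected-log-parameter
        surrogates from variational posteriors are sub-stochastic).

    Returns
    -------
    gamma : (T, K) posterior state probabilities, rows summing to 1
    xi : (K, K) summed pairwise posteriors (or (T-1, K, K) if requested)
    log_evidence : float
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    T, K = ll.shape
    A = np.asarray(transition, dtype=float)
    pi = np.asarray(initial, dtype=float)
    row_max = ll.max(axis=1)
    if not np.all(np.isfinite(row_max)):
        bad = int(np.flatnonzero(~np.isfinite(row_max))[0])
        raise ValueError(f"all-state zero likelihood at sample {bad}")
    B = np.exp(ll - row_max[:, None])

    alpha, beta, c = _fb_core(
        np.ascontiguousarray(B), np.ascontiguousarray(A, dtype=float),
        np.ascontiguousarray(pi, dtype=float),
    )
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # pairwise posteriors: xi_t = alpha_t (x) A B_{t+1} beta_{t+1} / c_{t+1};
    # each slice already sums to 1 under the scaled recursion
    W = B[1:] * beta[1:] / c[1:, None]
    if return_full_xi:
        xi = alpha[:-1, :, None] * A[None] * W[:, None, :]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = A * (alpha[:-1].T @ W)

    log_evidence = float(np.sum(np.log(c)) + np.sum(row_max))
    return gamma, xi, log_evidence


def viterbi(log_likelihoods: np.ndarray, transition: np.ndarray, initial: np.ndarray) -> np.ndarray:
    """Most probable state path; ties resolve toward the lower state index."""
    ll = np.asarray(log_likelihoods, dtype=float)
    T, K = ll.shape
    if not np.all(np.isfinite(ll.max(axis=1))):
        raise ValueError("a sample has zero likelihood under every state")
    with np.errstate(divide="ignore"):
        logA = np.log(np.asarray(transition, dtype=float))
        logpi = np.log(np.asarray(initial, dtype=float))
    delta = logpi + ll[0]
    back = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)  # argmax -> first (lowest) index on ties
        delta = cand[back[t], np.arange(K)] + ll[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class StatePosterior:
    """Per-sample state beliefs for a fitted model.

    ``gamma`` rows sum to one; ``xi`` holds summed pairwise transition
    posteriors; ``boundaries`` gives each subject's (start, stop) slice of
    the concatenated time axis.
    """

    gamma: np.ndarray
    xi: np.ndarray
    viterbi_path: np.ndarray
    boundaries: list[tuple[int, int]] = field(default_factory=list)

    def subject_gamma(self, s: int) -> np.ndarray:
        a, b = self.boundaries[s]
        return self.gamma[a:b]

    def subject_path(self, s: int) -> np.ndarray:
        a, b = self.boundaries[s]
        return self.viterbi_path[a:b]


def _dirichlet_kl(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    aq, ap = np.asarray(alpha_q, float), np.asarray(alpha_p, float)
    a0q, a0p = aq.sum(), ap.sum()
    return float(
        gammaln(a0q) - gammaln(a0p)
        - np.sum(gammaln(aq) - gammaln(ap))
        + np.sum((aq - ap) * (digamma(aq) - digamma(a0q)))
    )


def _multigammaln(a: float, p: int) -> float:
    i = np.arange(1, p + 1)
    return float(p * (p - 1) / 4.0 * np.log(np.pi) + np.sum(gammaln(a + (1 - i) / 2.0)))


class _WishartPosterior:
    """Wishart posterior on a state's precision: W(Lambda | V, nu) with
    V = S^{-1} held via the Cholesky factor of the (inverse-Wishart) scale S."""

    def __init__(self, S: np.ndarray, nu: float):
        self.S = S
        self.nu = float(nu)
        self._chol = None

    @property
    def chol(self) -> np.ndarray:
        if self._chol is None:
            self._chol = _safe_cholesky(self.S)
        return self._chol

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def logdet_S(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))

    def e_logdet_precision(self) -> float:
        p, nu = self.p, self.nu
        return float(np.sum(digamma((nu - np.arange(p)) / 2.0)) + p * np.log(2.0) - self.logdet_S())

    def e_precision_quad(self, X: np.ndarray) -> np.ndarray:
        """nu * x^T S^{-1} x for each row of X."""
        Z = linalg.solve_triangular(self.chol, X.T, lower=True)
        return self.nu * np.einsum("ij,ij->j", Z, Z)

    def mean_covariance(self) -> np.ndarray:
        return self.S / (self.nu - self.p - 1.0)

    def kl_from_prior(self, S0_chol: np.ndarray, nu0: float) -> float:
        """KL(q || p) between Wishart posteriors on the precision."""
        p, nu = self.p, self.nu
        logdet_Sq = self.logdet_S()
        logdet_Sp = 2.0 * float(np.sum(np.log(np.diag(S0_chol))))
        e_logdet = self.e_logdet_precision()
        # tr(S0 S_q^{-1}) via triangular solves
        M = linalg.solve_triangular(self.chol, S0_chol @ S0_chol.T, lower=True)
        M = linalg.solve_triangular(self.chol, M.T, lower=True)
        tr_term = self.nu * float(np.trace(M))
        log_z_q = nu * p / 2.0 * np.log(2.0) - nu / 2.0 * logdet_Sq + _multigammaln(nu / 2.0, p)
        log_z_p = nu0 * p / 2.0 * np.log(2.0) - nu0 / 2.0 * logdet_Sp + _multigammaln(nu0 / 2.0, p)
        return float((nu - nu0) / 2.0 * e_logdet - nu * p / 2.0 + tr_term / 2.0 - log_z_q + log_z_p)


def _safe_cholesky(S: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Cholesky with an eigenvalue floor at ``floor_frac`` of the mean trace."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        floor = floor_frac * np.trace(S) / S.shape[0]
        w = np.maximum(w, floor)
        return np.linalg.cholesky((V * w) @ V.T)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class VBGaussianHMM:
    """Variational-Bayes HMM with zero-mean full-covariance Gaussian states.

    Follows the scikit-learn estimator protocol: ``fit(X, lengths=None)`` with
    ``X`` of shape (n_samples, n_features); per-subject segmentation is given
    by ``lengths`` as in ``hmmlearn``.

    Parameters
    ----------
    n_states : int
        Number of hidden states K.
    transition_prior_diag : float, default 10
        Dirichlet prior count on the transition-matrix diagonal
        (off-diagonal counts are 1), encouraging temporal persistence.
    prior_dof_offset : float, default 2
        Inverse-Wishart prior degrees of freedom = n_features + offset; the
        prior scale is the empirical covariance of the data.
    n_iter, tol : batch VB stopping rule (relative free-energy change).
    n_init : number of seeded k-means restarts; the restart with the best
        free energy after ``init_iter`` VB sweeps is continued to convergence.
    stochastic : bool
        Use subject-minibatch stochastic variational inference with step
        size ``(t + sv_delay)**(-sv_kappa)``.
    random_state : seed for initialisation (and minibatch order).

    Attributes (after fit)
    ----------------------
    covariances_ : (K, P, P) posterior-mean state covariances
    transmat_ : (K, K) posterior-mean transition matrix
    startprob_ : (K,) posterior-mean initial distribution
    free_energy_trace_ : per-iteration negative ELBO (non-increasing in
        batch mode)
    posterior_ : :class:`StatePosterior` for the training data
    """

    def __init__(
        self,
        n_states: int = 6,
        transition_prior_diag: float = 10.0,
        prior_dof_offset: float = 2.0,
        n_iter: int = 50,
        tol: float = 1e-6,
        n_init: int = 5,
        init_iter: int = 3,
        stochastic: bool = False,
        batch_size: int = 1,
        sv_kappa: float = 0.6,
        sv_delay: float = 5.0,
        sv_iter: int = 50,
        random_state: int | None = 0,
    ):
        self.n_states = n_states
        self.transition_prior_diag = transition_prior_diag
        self.prior_dof_offset = prior_dof_offset
        self.n_iter = n_iter
        self.tol = tol
        self.n_init = n_init
        self.init_iter = init_iter
        self.stochastic = stochastic
        self.batch_size = batch_size
        self.sv_kappa = sv_kappa
        self.sv_delay = sv_delay
        self.sv_iter = sv_iter
        self.random_state = random_state

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_states", "transition_prior_diag", "prior_dof_offset", "n_iter", "tol",
            "n_init", "init_iter", "stochastic", "batch_size", "sv_kappa", "sv_delay",
            "sv_iter", "random_state",
        )}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------
    def _segments(self, T: int, lengths) -> list[tuple[int, int]]:
        if lengths is None:
            return [(0, T)]
        lengths = list(lengths)
        if sum(lengths) != T:
            raise ValueError("lengths must sum to n_samples")
        out, t = [], 0
        for n in lengths:
            out.append((t, t + n))
            t += n
        return out

    def _expected_log_lik(self, X: np.ndarray, states: list[_WishartPosterior]) -> np.ndarray:
        T, P = X.shape
        ll = np.empty((T, len(states)))
        for k, st in enumerate(states):
            ll[:, k] = 0.5 * st.e_logdet_precision() - 0.5 * st.e_precision_quad(X) \
                - 0.5 * P * np.log(2.0 * np.pi)
        return ll

    def _e_step(self, X, segments, states, trans_alpha, init_alpha):
        K = self.n_states
        elog_t = digamma(trans_alpha) - digamma(trans_alpha.sum(axis=1, keepdims=True))
        elog_pi = digamma(init_alpha) - digamma(init_alpha.sum())
        A, pi = np.exp(elog_t), np.exp(elog_pi)
        ll = self._expected_log_lik(X, states)
        gamma = np.empty((X.shape[0], K))
        xi = np.zeros((K, K))
        gamma0 = np.zeros(K)
        log_ev = 0.0
        for a, b in segments:
            g, x, le = forward_backward(ll[a:b], A, pi)
            gamma[a:b] = g
            xi += x
            gamma0 += g[0]
            log_ev += le
        return gamma, xi, gamma0, log_ev, ll

    def _m_step_stats(self, X, gamma):
        """Per-state counts and scatter matrices Sum_t gamma_tk x x^T."""
        K = gamma.shape[1]
        Nk = gamma.sum(axis=0)
        scatter = np.empty((K, X.shape[1], X.shape[1]))
        for k in range(K):
            Xw = X * gamma[:, k, None]
            scatter[k] = Xw.T @ X
        return Nk, scatter

    def _free_energy(self, log_ev, states, trans_alpha, init_alpha):
        kl = _dirichlet_kl(init_alpha, self._init_alpha0)
        for k in range(self.n_states):
            kl += _dirichlet_kl(trans_alpha[k], self._trans_alpha0[k])
            kl += states[k].kl_from_prior(self._S0_chol, self._nu0)
        return -(log_ev - kl)  # negative ELBO

    def _init_gamma(self, X, segments, rng):
        """k-means on log second-moment features of short windows."""
        from sklearn.cluster import KMeans

        T, P = X.shape
        win = max(25, min(250, T // (20 * self.n_states) or 25))
        feats, spans = [], []
        for a, b in segments:
            for s in range(a, b - win + 1, win):
                w = X[s : s + win]
                feats.append(np.log(np.mean(w * w, axis=0) + 1e-12))
                spans.append((s, s + win))
        F = np.asarray(feats)
        F = (F - F.mean(0)) / (F.std(0) + 1e-12)
        km = KMeans(self.n_states, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(F)
        gamma = np.full((T, self.n_states), 0.1 / max(self.n_states - 1, 1))
        for (s, e), l in zip(spans, lab):
            gamma[s:e, :] = 0.1 / max(self.n_states - 1, 1)
            gamma[s:e, l] = 0.9
        gamma /= gamma.sum(axis=1, keepdims=True)
        return gamma

    def _update_global(self, Nk, scatter, xi, gamma0):
        states = [_WishartPosterior(self._S0 + scatter[k], self._nu0 + Nk[k])
                  for k in range(self.n_states)]
        trans_alpha = self._trans_alpha0 + xi
        init_alpha = self._init_alpha0 + gamma0
        return states, trans_alpha, init_alpha

    # -- fitting ------------------------------------------------------------
    def fit(self, X: np.ndarray, lengths=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        T, P = X.shape
        K = self.n_states
        if K < 1:
            raise ValueError("n_states must be >= 1")
        if P >= T:
            raise ValueError("need more samples than features")
        segments = self._segments(T, lengths)
        rng = np.random.default_rng(self.random_state)

        emp_cov = X.T @ X / T
        self._nu0 = P + self.prior_dof_offset
        self._S0 = emp_cov + 1e-10 * np.trace(emp_cov) / P * np.eye(P)
        self._S0_chol = _safe_cholesky(self._S0)
        self._trans_alpha0 = np.ones((K, K)) + (self.transition_prior_diag - 1.0) * np.eye(K)
        self._init_alpha0 = np.ones(K)

        best = None
        n_restarts = max(1, self.n_init) if K > 1 else 1
        for _ in range(n_restarts):
            if K == 1:
                gamma = np.ones((T, 1))
            else:
                gamma = self._init_gamma(X, segments, rng)
            Nk, scatter = self._m_step_stats(X, gamma)
            # transition counts from hard init labels: keeps the persistence
            # implied by the init (a uniform or smoothed-outer-product count
            # starts the chain in a fast-switching basin it rarely escapes)
            hard = gamma.argmax(axis=1)
            xi0 = np.zeros((K, K))
            for a, b in segments:
                np.add.at(xi0, (hard[a : b - 1], hard[a + 1 : b]), 1.0)
            state = self._update_global(Nk, scatter, xi0, gamma.mean(0))
            trace = []
            for _ in range(self.init_iter):
                state, fe = self._vb_sweep(X, segments, state)
                trace.append(fe)
            if best is None or trace[-1] < best[1]:
                best = (state, trace[-1], trace)
        state, _, trace = best

        if self.stochastic and len(segments) > 1:
            state, trace = self._fit_stochastic(X, segments, state, trace, rng)
        prev = trace[-1] if trace else np.inf
        for _ in range(self.n_iter):
            state, fe = self._vb_sweep(X, segments, state)
            trace.append(fe)
            if np.isfinite(prev) and abs(prev - fe) <= self.tol * abs(fe):
                prev = fe
                break
            prev = fe

        states, trans_alpha, init_alpha = state
        gamma, xi, gamma0, log_ev, ll = self._e_step(X, segments, states, trans_alpha, init_alpha)
        self.states_ = states
        self.trans_alpha_ = trans_alpha
        self.init_alpha_ = init_alpha
        self.covariances_ = np.stack([s.mean_covariance() for s in states])
        self.transmat_ = trans_alpha / trans_alpha.sum(axis=1, keepdims=True)
        self.startprob_ = init_alpha / init_alpha.sum()
        self.free_energy_trace_ = np.asarray(trace + [self._free_energy(log_ev, states, trans_alpha, init_alpha)])
        elog_t = digamma(trans_alpha) - digamma(trans_alpha.sum(axis=1, keepdims=True))
        elog_pi = digamma(init_alpha) - digamma(init_alpha.sum())
        path = np.concatenate([
            viterbi(ll[a:b], np.exp(elog_t), np.exp(elog_pi)) for a, b in segments
        ])
        self.posterior_ = StatePosterior(gamma=gamma, xi=xi, viterbi_path=path, boundaries=segments)
        self.n_features_in_ = P
        return self

    def _vb_sweep(self, X, segments, state):
        states, trans_alpha, init_alpha = state
        gamma, xi, gamma0, log_ev, _ = self._e_step(X, segments, states, trans_alpha, init_alpha)
        fe = self._free_energy(log_ev, states, trans_alpha, init_alpha)
        Nk, scatter = self._m_step_stats(X, gamma)
        return self._update_global(Nk, scatter, xi, gamma0), fe

    def _fit_stochastic(self, X, segments, state, trace, rng):
        states, trans_alpha, init_alpha = state
        n_seg = len(segments)
        S = [st.S.copy() for st in states]
        nu = [st.nu for st in states]
        t_len = {i: b - a for i, (a, b) in enumerate(segments)}
        T = X.shape[0]
        for it in range(self.sv_iter):
            rho = (it + 1 + self.sv_delay) ** (-self.sv_kappa)
            batch = rng.choice(n_seg, size=min(self.batch_size, n_seg), replace=False)
            segs = [segments[i] for i in batch]
            scale = T / sum(t_len[i] for i in batch)
            n_starts = n_seg / len(batch)
            cur = [_WishartPosterior(S[k], nu[k]) for k in range(self.n_states)]
            gamma_parts, xi_b, g0_b = [], np.zeros_like(trans_alpha), np.zeros(self.n_states)
            elog_t = digamma(trans_alpha) - digamma(trans_alpha.sum(axis=1, keepdims=True))
            elog_pi = digamma(init_alpha) - digamma(init_alpha.sum())
            for a, b in segs:
                ll = self._expected_log_lik(X[a:b], cur)
                g, x, _ = forward_backward(ll, np.exp(elog_t), np.exp(elog_pi))
                gamma_parts.append((a, b, g))
                xi_b += x
                g0_b += g[0]
            Nk = np.zeros(self.n_states)
            scat = np.zeros((self.n_states, X.shape[1], X.shape[1]))
            for a, b, g in gamma_parts:
                Nk += g.sum(0)
                for k in range(self.n_states):
                    Xw = X[a:b] * g[:, k, None]
                    scat[k] += Xw.T @ X[a:b]
            for k in range(self.n_states):
                S_hat = self._S0 + scale * scat[k]
                nu_hat = self._nu0 + scale * Nk[k]
                S[k] = (1 - rho) * S[k] + rho * S_hat
                nu[k] = (1 - rho) * nu[k] + rho * nu_hat
            trans_alpha = (1 - rho) * trans_alpha + rho * (self._trans_alpha0 + scale * xi_b)
            init_alpha = (1 - rho) * init_alpha + rho * (self._init_alpha0 + n_starts * g0_b)
        states = [_WishartPosterior(S[k], nu[k]) for k in range(self.n_states)]
        return (states, trans_alpha, init_alpha), trace

    # -- prediction ---------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "states_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X: np.ndarray, lengths=None) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        segments = self._segments(X.shape[0], lengths)
        gamma, _, _, _, _ = self._e_step(X, segments, self.states_, self.trans_alpha_, self.init_alpha_)
        return gamma

    def predict(self, X: np.ndarray, lengths=None) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        segments = self._segments(X.shape[0], lengths)
        ll = self._expected_log_lik(X, self.states_)
        elog_t = digamma(self.trans_alpha_) - digamma(self.trans_alpha_.sum(axis=1, keepdims=True))
        elog_pi = digamma(self.init_alpha_) - digamma(self.init_alpha_.sum())
        return np.concatenate([viterbi(ll[a:b], np.exp(elog_t), np.exp(elog_pi)) for a, b in segments])

    def free_energy(self, X: np.ndarray, lengths=None) -> float:
        """Negative evidence lower bound on held data under the current
        global posteriors (lower is better)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        segments = self._segments(X.shape[0], lengths)
        _, _, _, log_ev, _ = self._e_step(X, segments, self.states_, self.trans_alpha_, self.init_alpha_)
        return self._free_energy(log_ev, self.states_, self.trans_alpha_, self.init_alpha_)


def fit_hmm(X: np.ndarray, n_states: int, lengths=None, **kwargs) -> tuple[VBGaussianHMM, StatePosterior]:
    """Convenience wrapper: fit a :class:`VBGaussianHMM` and return the model
    together with its training-data posterior."""
    model = VBGaussianHMM(n_states=n_states, **kwargs).fit(X, lengths=lengths)
    return model, model.posterior_
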