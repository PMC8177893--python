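"""Pairing states across independently fitted HMMs by covariance geometry.

Two models fitted on different datasets (e.g. two medication conditions)
have no shared state labelling.  States are paired by computing the
affine-invariant Riemannian distance between their covariance matrices and
solving the resulting K x K linear assignment problem (Munkres algorithm).
Because each model lives in its own PCA subspace, covariances are first
mapped back to a common channel space (the lag-0 block by default) where the
metric is well defined across fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from .embedding import covariance_to_channel_space

__all__ = ["StateMatch", "riemannian_distance", "match_states", "match_models", "spd_repair"]


@dataclass
class StateMatch:
    """A bijective pairing of two models' states.

    ``pairing[a]`` is the model-B state matched to model-A state ``a``;
    ``total_distance`` is the sum of matched distance-matrix entries, minimal
    over all permutations.
    """

    distance_matrix: np.ndarray
    pairing: np.ndarray
    total_distance: float


def spd_repair(A: np.ndarray, floor_frac: float = 1e-10) -> np.ndarray:
    """Symmetrise and floor eigenvalues at ``floor_frac`` of the trace."""
    A = (A + A.T) / 2.0
    w, V = np.linalg.eigh(A)
    floor = floor_frac * max(np.trace(A), np.finfo(float).tiny)
    if w[0] < floor:
        warnings.warn(
            f"SPD repair triggered: min eigenvalue {w[0]:.3e} floored to {floor:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.maximum(w, floor)
        A = (V * w) @ V.T
    return A


def riemannian_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between SPD matrices.

    ``d(A, B) = sqrt(sum_i log^2 lambda_i)`` over the generalised
    eigenvalues of ``(A, B)``.  Symmetric, zero iff ``A == B`` and invariant
    under congruence ``A -> M A M^T, B -> M B M^T`` for invertible ``M``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    for name, M in (("A", A), ("B", B)):
        w_min = float(np.linalg.eigvalsh((M + M.T) / 2.0)[0])
        if w_min <= 0:
            raise ValueError(f"matrix {name} is not positive definite (min eigenvalue {w_min:.3e})")
    w = linalg.eigh(A, B, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def match_states(covs_A: np.ndarray, covs_B: np.ndarray, repair: bool = False) -> StateMatch:
    """Minimal-total-distance bijection between two K-state covariance sets.

    Solves the linear assignment problem on the K x K Riemannian distance
    matrix; for K <= 8 this equals the brute-force minimum over all K!
    permutations.
    """
    covs_A = np.asarray(covs_A, dtype=float)
    covs_B = np.asarray(covs_B, dtype=float)
    if covs_A.shape != covs_B.shape or covs_A.ndim != 3:
        raise ValueError("need two equal-shaped stacks of K covariance matrices")
    K = covs_A.shape[0]
    if repair:
        covs_A = np.stack([spd_repair(c) for c in covs_A])
        covs_B = np.stack([spd_repair(c) for c in covs_B])
    D = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            D[a, b] = riemannian_distance(covs_A[a], covs_B[b])
    rows, cols = linear_sum_assignment(D)
    pairing = np.empty(K, dtype=int)
    pairing[rows] = cols
    return StateMatch(distance_matrix=D, pairing=pairing, total_distance=float(D[rows, cols].sum()))


def match_models(model_A, embedding_A, model_B, embedding_B, full_lag_space: bool = False) -> StateMatch:
    """Match two fitted HMMs whose covariances live in different PCA spaces.

    Each model's state covariances are mapped back to channel space through
    its own projection (lag-0 block by default; ``full_lag_space=True`` uses
    the whole channel x lag space, which is rank-deficient and relies on the
    SPD repair floor).
    """
    def to_common(model, emb):
        return np.stack([
            covariance_to_channel_space(
                c, emb.projection, emb.n_channels, emb.n_lags, full=full_lag_space
            )
            for c in model.covariances_
        ])

    return match_states(to_common(model_A, embedding_A), to_common(model_B, embedding_B), repair=True)
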