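"""Region-level preprocessing: PC reduction, leakage correction, sign alignment.

Pipeline order (fixed): per-region first-PC reduction -> symmetric
orthogonalisation of the cortical block -> per-subject z-scoring -> stacking
with the STN contacts -> temporal concatenation across subjects -> sign-flip
correction.  STN channels bypass the orthogonalisation: intracranial contacts
do not suffer source-leakage mixing, and orthogonalising them against the
cortex would destroy genuine STN-cortex zero-lag structure.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .datatypes import ConcatenatedDataset, RegionTimeSeries

__all__ = [
    "reduce_region_to_first_pc",
    "symmetric_orthogonalise",
    "sign_flip_correct",
    "standardise_and_concatenate",
    "preprocess_cohort",
]


def reduce_region_to_first_pc(vertex_series: np.ndarray) -> np.ndarray:
    """Collapse a vertices x samples matrix to its first principal component.

    Returns the PC score series (length ``n_samples``), sign-fixed to
    correlate positively with the mean vertex series.  Raises on constant
    input, where the principal direction is undefined.
    """
    V = np.atleast_2d(np.asarray(vertex_series, dtype=float))
    if V.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    Vc = V - V.mean(axis=1, keepdims=True)
    if not np.any(Vc):
        raise ValueError("degenerate region: all vertex series are constant")
    # SVD of the demeaned matrix; left vector = loading, score = s * v
    u, s, vt = np.linalg.svd(Vc, full_matrices=False)
    score = s[0] * vt[0]
    ref = Vc.mean(axis=0)
    if np.dot(score, ref) < 0:
        score = -score
    return score


def symmetric_orthogonalise(data: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Closest matrix (Frobenius) with mutually orthogonal rows.

    Alternates a Procrustes step (orthonormal row basis via polar
    decomposition) with per-row magnitude updates, the standard construction
    for removing zero-lag correlation ("leakage") among reconstructed
    sources while staying as close as possible to the input.  Rows are
    demeaned first so orthogonality equals zero sample correlation.

    Raises if the rows are not linearly independent (naming the channels
    that appear redundant).
    """
    D = np.asarray(data, dtype=float)
    n, t = D.shape
    if t < n:
        raise ValueError(f"need at least as many samples ({t}) as channels ({n})")
    D = D - D.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(D, compute_uv=False)
    if sv[-1] <= max(n, t) * np.finfo(float).eps * sv[0]:
        # name likely offenders via pivoted QR of the transposed data
        _, _, piv = linalg.qr(D.T, mode="economic", pivoting=True)
        rank = int(np.sum(sv > max(n, t) * np.finfo(float).eps * sv[0]))
        raise ValueError(
            "rank-deficient input; redundant channel indices: " f"{sorted(piv[rank:].tolist())}"
        )

    d = np.linalg.norm(D, axis=1)
    prev = np.inf
    for _ in range(max_iter):
        A = d[:, None] * D
        W, _, Vt = np.linalg.svd(A, full_matrices=False)
        U = W @ Vt  # orthonormal rows closest to A
        d = np.einsum("ij,ij->i", D, U)
        err = np.linalg.norm(D - d[:, None] * U)
        if abs(prev - err) <= tol * max(err, 1.0):
            break
        prev = err
    return d[:, None] * U


def _lagged_autocov(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Cross-covariance stack C[l] = cov(x_t, x_{t+l}), l = 0..n_lags-1."""
    x = x - x.mean(axis=1, keepdims=True)
    n, t = x.shape
    out = np.empty((n_lags, n, n))
    for lag in range(n_lags):
        out[lag] = x[:, : t - lag] @ x[:, lag:].T / (t - lag)
    return out


def sign_flip_correct(
    matrices: list[np.ndarray], n_lags: int = 15, max_sweeps: int = 20, seed: int | None = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Resolve per-channel sign ambiguity across subjects.

    Source-reconstructed MEG (and bipolar LFP montages) leave each channel's
    polarity arbitrary per subject.  A greedy coordinate search flips signs
    to maximise cross-subject agreement of the lagged autocovariance
    structure: with ``F_s`` the sign-adjusted off-diagonal lagged
    autocovariance stack of subject ``s``, the objective is
    ``sum_{a != b} <F_a, F_b>``, non-decreasing over accepted moves.

    Returns ``(sign_vectors, flipped_matrices)``.
    """
    S = len(matrices)
    if S == 0:
        raise ValueError("no subjects")
    n = matrices[0].shape[0]
    if any(m.shape[0] != n for m in matrices):
        raise ValueError("all subjects must share the channel count")
    signs = [np.ones(n) for _ in range(S)]
    if S == 1:
        return signs, [m.copy() for m in matrices]

    C = [_lagged_autocov(np.asarray(m, dtype=float), n_lags) for m in matrices]
    for c in C:  # off-diagonal structure only; diagonals are sign-invariant
        idx = np.arange(n)
        c[:, idx, idx] = 0.0
    F = [c.copy() for c in C]
    rng = np.random.default_rng(seed)

    for _ in range(max_sweeps):
        improved = False
        order = [(a, i) for a in range(S) for i in range(n)]
        rng.shuffle(order)
        G = np.sum(F, axis=0)
        for a, i in order:
            # flipping s_a[i] negates row i and column i of F_a
            delta_f = np.zeros_like(F[a])
            delta_f[:, i, :] = -2.0 * F[a][:, i, :]
            delta_f[:, :, i] = -2.0 * F[a][:, :, i]
            delta_f[:, i, i] = 0.0
            gain = 2.0 * np.sum((G - F[a]) * delta_f)
            if gain > 1e-9:
                signs[a][i] *= -1.0
                F[a] = F[a] + delta_f
                G = G + delta_f
                improved = True
        if not improved:
            break
    return signs, [s[:, None] * m for s, m in zip(signs, matrices)]


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd.ravel() <= 0).tolist()
        raise ValueError(f"constant channels cannot be standardised: {bad}")
    return (x - mu) / sd


def standardise_and_concatenate(subjects: list[RegionTimeSeries]) -> ConcatenatedDataset:
    """Z-score each subject's channels, then concatenate along time."""
    if not subjects:
        raise ValueError("no subjects")
    ref = subjects[0]
    for s in subjects[1:]:
        if s.labels != ref.labels or s.groups != ref.groups or s.fs != ref.fs:
            raise ValueError(f"subject {s.subject_id} metadata mismatch")
    blocks, boundaries, t = [], [], 0
    for s in subjects:
        blocks.append(_zscore_rows(s.data))
        boundaries.append((t, t + s.n_samples))
        t += s.n_samples
    return ConcatenatedDataset(
        data=np.concatenate(blocks, axis=1),
        fs=ref.fs,
        boundaries=boundaries,
        labels=list(ref.labels),
        groups=list(ref.groups),
        subject_ids=[s.subject_id for s in subjects],
        condition=ref.condition,
    )


def preprocess_cohort(
    subjects: list[RegionTimeSeries],
    orthogonalise: bool = True,
    sign_flip: bool = True,
    n_lags: int = 15,
    seed: int | None = 0,
) -> ConcatenatedDataset:
    """Full preprocessing chain for one condition's cohort.

    Orthogonalises each subject's cortical block (STN contacts bypass),
    z-scores per subject and channel, concatenates across subjects, and
    finally applies the cross-subject sign-flip correction.
    """
    processed = []
    for s in subjects:
        x = s.data.copy()
        cort = s.cortical_indices
        if orthogonalise and cort.size > 1:
            x[cort] = symmetric_orthogonalise(x[cort])
        processed.append(
            RegionTimeSeries(x, s.fs, list(s.labels), list(s.groups), s.subject_id, s.condition)
        )
    ds = standardise_and_concatenate(processed)
    if sign_flip and len(subjects) > 1:
        mats = [ds.subject_data(i) for i in range(ds.n_subjects)]
        signs, flipped = sign_flip_correct(mats, n_lags=n_lags, seed=seed)
        ds.data = np.concatenate(flipped, axis=1)
    return ds
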