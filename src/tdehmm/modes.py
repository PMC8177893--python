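"""Data-driven spectral frequency modes via robust non-negative matrix
factorisation, and projection of coherence onto them.

Canonical band definitions weight every bin of a band equally for every
subject, which blurs individually varying spectral peaks at the group level.
Instead, the group-level STN-cortex cross-coherence (frequency bins x
[6 STN x 42 cortical x n_states] columns) is factorised into a small number
of non-negative spectral modes; three typically align with the canonical
delta/theta, alpha and beta bands and one absorbs the broadband noise floor.
Robustness: the multiplicative-update factorisation is restarted from many
seeds and the lowest-error restart is kept among those whose modes agree
(matched correlation above threshold) with the consensus of the restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .spectra import StateSpectra

__all__ = [
    "FrequencyModeSet",
    "ProjectedCoherence",
    "build_group_coherence",
    "RobustNMF",
    "nnmf_frequency_modes",
    "project_onto_modes",
    "CANONICAL_BANDS",
]

CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta_theta": (1.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}


@dataclass
class FrequencyModeSet:
    """Non-negative spectral modes on a fixed frequency grid.

    ``modes`` is M x F with each row normalised to unit 1-norm; ``labels``
    assigns each mode a canonical band name or ``"residual"``.
    """

    modes: np.ndarray
    freqs: np.ndarray
    labels: list[str]
    reconstruction_error: float = np.nan
    restart_stability: float = np.nan
    n_restarts: int = 0

    def band_mass(self, mode_index: int, band: tuple[float, float]) -> float:
        """Fraction of a mode's 1-norm mass inside ``band`` (Hz)."""
        m = self.modes[mode_index]
        inside = (self.freqs >= band[0]) & (self.freqs <= band[1])
        return float(m[inside].sum() / m.sum())


@dataclass
class ProjectedCoherence:
    """Coherence projected onto frequency modes.

    ``subject``: (n_subjects, n_states, M, N, N); ``group``:
    (n_states, M, N, N) — the subject average.
    """

    subject: np.ndarray
    group: np.ndarray
    labels: list[str] = field(default_factory=list)


def build_group_coherence(
    spectra: StateSpectra,
    stn_indices: np.ndarray,
    cortical_indices: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """STN-cortex cross-coherence matrices for mode discovery.

    Per subject, each state's (F, |STN|, |cortical|) coherence block is
    vectorised to F x (|STN| * |cortical|) and states are concatenated along
    columns; the group matrix is the subject average (ignoring subjects that
    never visited a state).  Returns ``(subject_matrices, group_matrix)`` of
    shapes (S, F, B*K) and (F, B*K) with B = |STN| * |cortical|.
    """
    stn = np.asarray(stn_indices, dtype=int)
    cort = np.asarray(cortical_indices, dtype=int)
    if stn.size == 0 or cort.size == 0:
        raise ValueError("channel group tags must identify STN and cortical channels")
    S, K, F = spectra.n_subjects, spectra.n_states, spectra.freqs.size
    B = stn.size * cort.size
    subj = np.full((S, F, B * K), np.nan)
    for s in range(S):
        for k in range(K):
            block = spectra.coherence[s, k][:, stn[:, None], cort[None, :]]
            subj[s, :, k * B : (k + 1) * B] = block.reshape(F, B)
    with np.errstate(invalid="ignore"):
        group = np.nanmean(subj, axis=0)
    if np.isnan(group).any():
        raise ValueError("a state was never visited by any subject")
    return subj, group


class RobustNMF:
    """Multiplicative-update NMF with seeded restarts and a consensus filter.

    sklearn-style transformer on a non-negative matrix X (n_samples x
    n_features), factorised as ``X ~ W H`` with ``n_components`` columns in
    W.  Restarts are matched to each other by column correlation (linear
    assignment); the returned factorisation is the lowest-error restart
    among those agreeing with the consensus above ``corr_threshold``.

    Attributes after fit: ``components_`` (H), ``W_``, ``reconstruction_err_``,
    ``stability_`` (mean matched correlation of restarts to the winner).
    """

    def __init__(self, n_components: int = 4, n_restarts: int = 10,
                 corr_threshold: float = 0.9, max_iter: int = 2000,
                 tol: float = 1e-6, random_state: int | None = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.corr_threshold = corr_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_components", "n_restarts", "corr_threshold", "max_iter", "tol", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _matched_corr(W_a: np.ndarray, W_b: np.ndarray) -> float:
        """Mean column correlation after optimal one-to-one matching."""
        def norm(W):
            Wc = W - W.mean(axis=0)
            s = np.linalg.norm(Wc, axis=0)
            return Wc / np.where(s > 0, s, 1.0)
        C = norm(W_a).T @ norm(W_b)
        r, c = linear_sum_assignment(-C)
        return float(C[r, c].mean())

    def fit(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("NMF input must be non-negative")
        rng = np.random.default_rng(self.random_state)
        runs = []
        for _ in range(max(1, self.n_restarts)):
            seed = int(rng.integers(2**31 - 1))
            nmf = NMF(
                n_components=self.n_components, solver="mu", init="random",
                max_iter=self.max_iter, tol=self.tol, random_state=seed,
            )
            W = nmf.fit_transform(X)
            runs.append((nmf.reconstruction_err_, W, nmf.components_))
        runs.sort(key=lambda r: r[0])
        best_err, best_W, best_H = runs[0]
        corrs = np.array([self._matched_corr(best_W, W) for _, W, _ in runs])
        stable = corrs >= self.corr_threshold
        # winner: lowest error inside the consensus cluster (the best-error
        # restart always agrees with itself, so the set is non-empty)
        for err, W, H in runs:
            if self._matched_corr(best_W, W) >= self.corr_threshold:
                best_err, best_W, best_H = err, W, H
                break
        self.W_ = best_W
        self.components_ = best_H
        self.reconstruction_err_ = float(best_err)
        self.stability_ = float(corrs.mean())
        self.n_restarts_ = len(runs)
        return self

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).W_


def _label_modes(modes: np.ndarray, freqs: np.ndarray) -> list[str]:
    """Assign canonical band names by mass-in-band, greedily by fraction."""
    labels = ["residual"] * modes.shape[0]
    frac = np.zeros((len(CANONICAL_BANDS), modes.shape[0]))
    for bi, (lo, hi) in enumerate(CANONICAL_BANDS.values()):
        inside = (freqs >= lo) & (freqs <= hi)
        frac[bi] = modes[:, inside].sum(axis=1) / modes.sum(axis=1)
    names = list(CANONICAL_BANDS)
    used: set[int] = set()
    for bi, mi in sorted(
        ((b, m) for b in range(frac.shape[0]) for m in range(modes.shape[0])),
        key=lambda t: -frac[t],
    ):
        if names[bi] in labels or mi in used:
            continue
        labels[mi] = names[bi]
        used.add(mi)
    return labels


def nnmf_frequency_modes(
    group_matrix: np.ndarray,
    freqs: np.ndarray,
    n_modes: int = 4,
    n_restarts: int = 10,
    seed: int | None = 0,
) -> FrequencyModeSet:
    """Factorise a group coherence matrix (F x columns) into spectral modes.

    The spectral factor W (F x M) is extracted, its columns normalised to
    unit 1-norm, and each mode labelled with the canonical band holding most
    of its mass (unmatched modes are labelled "residual").
    """
    model = RobustNMF(n_components=n_modes, n_restarts=n_restarts, random_state=seed)
    W = model.fit_transform(np.asarray(group_matrix, dtype=float))
    norms = W.sum(axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    modes = (W / norms).T
    return FrequencyModeSet(
        modes=modes,
        freqs=np.asarray(freqs, dtype=float),
        labels=_label_modes(modes, np.asarray(freqs)),
        reconstruction_error=model.reconstruction_err_,
        restart_stability=model.stability_,
        n_restarts=model.n_restarts_,
    )


def project_onto_modes(spectra: StateSpectra, mode_set: FrequencyModeSet) -> ProjectedCoherence:
    """Inner product of coherence with each frequency mode.

    Linear in the coherence: with a one-hot mode the projection equals the
    coherence at the selected bin, and the group projection is the subject
    average of the subject projections.
    """
    if spectra.freqs.size != mode_set.freqs.size or not np.allclose(
        spectra.freqs, mode_set.freqs
    ):
        raise ValueError("frequency grids of spectra and modes do not match")
    proj = np.einsum("skfij,mf->skmij", spectra.coherence, mode_set.modes)
    with np.errstate(invalid="ignore"):
        group = np.nanmean(proj, axis=0)
    return ProjectedCoherence(subject=proj, group=group, labels=list(mode_set.labels))
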