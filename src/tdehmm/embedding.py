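"""Time-delay embedding and PCA reduction of multichannel time series.

Embedding a channels x samples matrix with ``L`` lags stacks, for each lag
offset in a symmetric window around zero, a delayed copy of every channel.
The covariance of the embedded data then carries cross-channel *and*
cross-lag second moments, so Gaussian states fitted on it encode spectral
power and phase coupling.  A PCA step (default retention: 2 x n_channels
components) keeps the state covariances tractable; the stored projection maps
state covariances back to channel space (lag-0 block) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ConcatenatedDataset

__all__ = [
    "window_to_lags",
    "embed",
    "pca_reduce",
    "EmbeddedData",
    "TimeDelayEmbedding",
    "embed_dataset",
    "covariance_to_channel_space",
]


def window_to_lags(window_ms: float, fs: float) -> int:
    """Number of lags spanned by ``window_ms`` at sampling rate ``fs``
    (60 ms at 250 Hz -> 15 lags)."""
    L = int(round(window_ms * fs / 1000.0))
    if L < 1:
        raise ValueError(f"window {window_ms} ms spans no samples at fs={fs}")
    return L


def lag_offsets(n_lags: int) -> np.ndarray:
    """Symmetric lag window centred on zero: offsets -floor(L/2) .. L-1-floor(L/2)."""
    return np.arange(n_lags) - n_lags // 2


def embed(data: np.ndarray, n_lags: int) -> np.ndarray:
    """Lag-embed a channels x samples matrix.

    Returns an ``(N*L) x (T-L+1)`` matrix whose row block ``l`` (rows
    ``l*N .. l*N+N``) holds the channels delayed by the ``l``-th offset of the
    symmetric window; column ``tau`` corresponds to original centre sample
    ``tau + L//2``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    N, T = X.shape
    if T <= n_lags:
        raise ValueError(f"need more than {n_lags} samples, got {T}")
    Tp = T - n_lags + 1
    out = np.empty((N * n_lags, Tp))
    for l in range(n_lags):
        out[l * N : (l + 1) * N] = X[:, l : l + Tp]
    return out


@dataclass
class EmbeddedData:
    """PCA-reduced embedded data plus everything needed to map back.

    ``data`` is P x T' in principal-component space; ``projection`` (P x N*L,
    orthonormal rows) and ``mean`` reconstruct the embedded space;
    ``boundaries`` are per-subject (start, stop) pairs on the embedded time
    axis.  ``eigenvalues`` holds the full embedded-covariance spectrum so
    reconstruction-error identities can be checked.
    """

    data: np.ndarray
    n_lags: int
    projection: np.ndarray
    mean: np.ndarray
    explained_variance: np.ndarray
    eigenvalues: np.ndarray
    n_channels: int
    fs: float
    boundaries: list[tuple[int, int]]

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def sample_offset(self) -> int:
        """Offset of embedded column 0 relative to the raw time axis."""
        return self.n_lags // 2


def pca_reduce(embedded: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on an embedded matrix (rows = N*L dims, columns = time).

    Returns ``(scores, projection, eigenvalues)``: scores are
    ``n_components x T`` (projection of the demeaned data), projection rows
    are orthonormal eigenvectors ordered by decreasing eigenvalue, and
    ``eigenvalues`` is the full non-increasing spectrum.
    """
    E = np.asarray(embedded, dtype=float)
    d, T = E.shape
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds embedded dimension {d}")
    mean = E.mean(axis=1)
    Ec = E - mean[:, None]
    C = Ec @ Ec.T / T
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    proj = V[:, :n_components].T
    return proj @ Ec, proj, w


class TimeDelayEmbedding:
    """Transformer: lag-embed and PCA-reduce multichannel data.

    scikit-learn style with ``X`` of shape (n_samples, n_channels) and an
    optional ``lengths`` argument to avoid embedding across subject
    boundaries.  ``n_components=None`` applies the default retention rule of
    2 x n_channels.
    """

    def __init__(self, window_ms: float = 60.0, fs: float = 250.0,
                 n_components: int | None = None, chunk_size: int = 30000):
        self.window_ms = window_ms
        self.fs = fs
        self.n_components = n_components
        self.chunk_size = chunk_size

    def get_params(self, deep: bool = True) -> dict:
        return {"window_ms": self.window_ms, "fs": self.fs,
                "n_components": self.n_components, "chunk_size": self.chunk_size}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _segments(self, T, lengths):
        if lengths is None:
            return [(0, T)]
        if sum(lengths) != T:
            raise ValueError("lengths must sum to n_samples")
        out, t = [], 0
        for n in lengths:
            out.append((t, t + n))
            t += n
        return out

    def fit(self, X: np.ndarray, lengths=None):
        X = np.asarray(X, dtype=float)
        T, N = X.shape
        L = window_to_lags(self.window_ms, self.fs)
        d = N * L
        segments = self._segments(T, lengths)
        # accumulate first/second moments of the embedded data chunk-wise
        s1 = np.zeros(d)
        s2 = np.zeros((d, d))
        n_tot = 0
        for a, b in segments:
            for c0 in range(a, b - L + 1, self.chunk_size):
                c1 = min(c0 + self.chunk_size, b - L + 1)
                E = embed(X[c0 : c1 + L - 1].T, L)
                s1 += E.sum(axis=1)
                s2 += E @ E.T
                n_tot += E.shape[1]
        mean = s1 / n_tot
        C = s2 / n_tot - np.outer(mean, mean)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        P = self.n_components if self.n_components is not None else 2 * N
        if P > d:
            raise ValueError(f"n_components={P} exceeds embedded dimension {d}")
        self.n_lags_ = L
        self.n_channels_ = N
        self.mean_ = mean
        self.components_ = V[:, :P].T
        self.eigenvalues_ = w
        self.explained_variance_ = w[:P]
        return self

    def transform(self, X: np.ndarray, lengths=None) -> np.ndarray:
        """Embedded PC scores, shape (sum(T_s - L + 1), n_components)."""
        if not hasattr(self, "components_"):
            raise RuntimeError("not fitted")
        X = np.asarray(X, dtype=float)
        L = self.n_lags_
        segments = self._segments(X.shape[0], lengths)
        parts = []
        for a, b in segments:
            for c0 in range(a, b - L + 1, self.chunk_size):
                c1 = min(c0 + self.chunk_size, b - L + 1)
                E = embed(X[c0 : c1 + L - 1].T, L)
                parts.append((self.components_ @ (E - self.mean_[:, None])).T)
        return np.concatenate(parts, axis=0)

    def fit_transform(self, X: np.ndarray, lengths=None) -> np.ndarray:
        return self.fit(X, lengths).transform(X, lengths)


def embed_dataset(ds: ConcatenatedDataset, window_ms: float = 60.0,
                  n_components: int | None = None) -> EmbeddedData:
    """Embed a concatenated dataset, respecting subject boundaries."""
    lengths = [b - a for a, b in ds.boundaries]
    tde = TimeDelayEmbedding(window_ms=window_ms, fs=ds.fs, n_components=n_components)
    scores = tde.fit_transform(ds.data.T, lengths=lengths)
    emb_bounds, t = [], 0
    for n in lengths:
        emb_bounds.append((t, t + n - tde.n_lags_ + 1))
        t += n - tde.n_lags_ + 1
    return EmbeddedData(
        data=scores.T,
        n_lags=tde.n_lags_,
        projection=tde.components_,
        mean=tde.mean_,
        explained_variance=tde.explained_variance_,
        eigenvalues=tde.eigenvalues_,
        n_channels=ds.n_channels,
        fs=ds.fs,
        boundaries=emb_bounds,
    )


def covariance_to_channel_space(
    sigma: np.ndarray, projection: np.ndarray, n_channels: int, n_lags: int,
    full: bool = False,
) -> np.ndarray:
    """Map a P x P state covariance from PC space back to channel space.

    The back-projection ``projection^T @ sigma @ projection`` lives in the
    N*L embedded space; by default the lag-0 block (an N x N symmetric PSD
    matrix) is returned, with ``full=True`` the whole embedded-space matrix.
    """
    back = projection.T @ sigma @ projection
    if full:
        return (back + back.T) / 2.0
    l0 = n_lags // 2
    block = back[l0 * n_channels : (l0 + 1) * n_channels, l0 * n_channels : (l0 + 1) * n_channels]
    return (block + block.T) / 2.0
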