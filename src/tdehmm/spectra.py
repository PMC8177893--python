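"""State-resolved multitaper power and coherence estimation.

State visits (maximal runs where one state's posterior probability exceeds
all others) are extracted from the concatenated data, band-passed 1-45 Hz,
and their spectra estimated with Slepian (DPSS) multitapers: 7 tapers at
time-bandwidth product 4, on windows zero-padded to a 0.5 Hz frequency grid.
Long visits are tiled into full-length windows; a visit shorter than one
window is treated as a single window of its own length (the short-segment
multitaper regime).  Cross-spectra are averaged over tapers and windows with
duration weighting, and coherence is reported as the normalised cross-
spectral magnitude ``|S_ij| / sqrt(S_ii S_jj)`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .datatypes import ConcatenatedDataset

__all__ = [
    "StateSpectra",
    "extract_state_segments",
    "multitaper_spectra",
    "compute_state_spectra",
    "coherence_bias_floor",
]


@dataclass
class StateSpectra:
    """Per subject x state spectral estimates.

    ``psd``: (n_subjects, n_states, n_freqs, N); ``coherence``:
    (n_subjects, n_states, n_freqs, N, N) with unit diagonal and symmetric
    (i, j).  Entries are NaN for states a subject never visited.
    """

    psd: np.ndarray
    coherence: np.ndarray
    freqs: np.ndarray
    fs: float
    n_tapers: int = 7
    time_bandwidth: float = 4.0

    @property
    def n_subjects(self) -> int:
        return self.psd.shape[0]

    @property
    def n_states(self) -> int:
        return self.psd.shape[1]

    def coherence_long_frame(self):
        """Coherence in long format: (subject, state, f, i, j, value) rows
        over the upper triangle, dropping never-visited states."""
        import pandas as pd

        N = self.psd.shape[3]
        iu = np.triu_indices(N, k=1)
        rows = []
        for s in range(self.n_subjects):
            for k in range(self.n_states):
                block = self.coherence[s, k]
                if np.isnan(block).all():
                    continue
                for fi, f in enumerate(self.freqs):
                    vals = block[fi, iu[0], iu[1]]
                    rows.append(pd.DataFrame({
                        "subject": s, "state": k, "f": f,
                        "i": iu[0], "j": iu[1], "value": vals,
                    }))
        return pd.concat(rows, ignore_index=True)


def _argmax_runs(gamma: np.ndarray, state: int) -> list[tuple[int, int]]:
    hard = np.argmax(gamma, axis=1)
    mask = hard == state
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def bandpass(data: np.ndarray, fs: float, lo: float = 1.0, hi: float = 45.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def extract_state_segments(
    timeseries: np.ndarray,
    gamma: np.ndarray,
    state: int,
    fs: float,
    min_len: int = 10,
    sample_offset: int = 0,
    band: tuple[float, float] | None = (1.0, 45.0),
) -> list[np.ndarray]:
    """Band-passed data segments for one state's visits.

    ``gamma`` is the (possibly embedding-shortened) T' x K posterior aligned
    to raw sample ``t + sample_offset``; a visit is a maximal argmax run.
    The band-pass is applied to the full series before slicing so every
    segment sees the same zero-phase filter.  Returns possibly empty list.
    """
    X = np.asarray(timeseries, dtype=float)
    if band is not None:
        X = bandpass(X, fs, *band)
    segs = []
    for a, b in _argmax_runs(np.asarray(gamma), state):
        ra, rb = a + sample_offset, b + sample_offset
        if rb - ra >= min_len:
            segs.append(X[:, ra:rb])
    return segs


@lru_cache(maxsize=256)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)


def coherence_bias_floor(n_taper_windows: int) -> float:
    """Expected coherence magnitude between independent signals when
    averaging ``n`` taper-windows: approximately ``sqrt(pi / (4 n))``
    (Rayleigh mean of an average of ``n`` independent unit phasors)."""
    return float(np.sqrt(np.pi / (4.0 * n_taper_windows)))


def multitaper_spectra(
    segments: list[np.ndarray],
    fs: float,
    n_tapers: int = 7,
    time_bandwidth: float = 4.0,
    resolution_hz: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 45.0,
    state_label: str | int = "?",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Duration-weighted multitaper PSD and coherence over a list of segments.

    Returns ``(freqs, psd, coherence)`` with ``psd`` of shape (F, N) and
    ``coherence`` (F, N, N).  The FFT length is ``fs / resolution_hz``;
    segments longer than that are tiled into non-overlapping full windows
    (a trailing remainder of at least a quarter window is kept), shorter
    segments form a single window.  Raises if no segment is usable.
    """
    nfft = int(round(fs / resolution_hz))
    min_win = 2 * n_tapers + 2  # DPSS needs more samples than tapers
    windows: list[np.ndarray] = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        t = seg.shape[1]
        if t < min_win:
            continue
        if t <= nfft:
            windows.append(seg)
        else:
            n_full = t // nfft
            for w in range(n_full):
                windows.append(seg[:, w * nfft : (w + 1) * nfft])
            rem = t - n_full * nfft
            if rem >= max(nfft // 4, min_win):
                windows.append(seg[:, n_full * nfft :])
    if not windows:
        raise ValueError(f"state {state_label}: no segment long enough for spectral estimation")

    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = (freqs >= fmin) & (freqs <= fmax)
    N = windows[0].shape[0]
    S = np.zeros((keep.sum(), N, N), dtype=complex)
    total_w = 0.0
    for w in windows:
        t = w.shape[1]
        tapers = _dpss_cached(t, time_bandwidth, n_tapers)  # unit-energy rows
        # (tapers, channels, freqs)
        tx = np.fft.rfft(tapers[:, None, :] * w[None, :, :], n=nfft, axis=-1)[..., keep]
        cross = np.einsum("kif,kjf->fij", tx, np.conj(tx), optimize=True) / n_tapers
        S += t * cross
        total_w += t
    S /= total_w * fs  # one-sided up to a factor irrelevant for coherence
    S *= 2.0

    psd = np.real(np.einsum("fii->fi", S)).copy()
    denom = np.sqrt(psd[:, :, None] * psd[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(S) / denom
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    idx = np.arange(N)
    coh[:, idx, idx] = 1.0
    return freqs[keep], psd, coh


def compute_state_spectra(
    ds: ConcatenatedDataset,
    gamma: np.ndarray,
    emb_boundaries: list[tuple[int, int]],
    n_states: int,
    sample_offset: int,
    n_tapers: int = 7,
    time_bandwidth: float = 4.0,
    resolution_hz: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 45.0,
    min_len: int = 10,
) -> StateSpectra:
    """Subject x state multitaper spectra from a fitted posterior.

    ``gamma`` spans the concatenated embedded time axis with per-subject
    slices ``emb_boundaries``; ``sample_offset`` realigns it to raw samples
    (the embedding trims L-1 samples per subject).
    """
    nfft = int(round(ds.fs / resolution_hz))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / ds.fs)
    keep = (freqs >= fmin) & (freqs <= fmax)
    F = int(keep.sum())
    N = ds.n_channels
    psd = np.full((ds.n_subjects, n_states, F, N), np.nan)
    coh = np.full((ds.n_subjects, n_states, F, N, N), np.nan)
    fgrid = freqs[keep]
    for s in range(ds.n_subjects):
        a, b = emb_boundaries[s]
        g = gamma[a:b]
        raw = bandpass(ds.subject_data(s), ds.fs, fmin, fmax)
        for k in range(n_states):
            segs = [
                raw[:, r0 + sample_offset : r1 + sample_offset]
                for r0, r1 in _argmax_runs(g, k)
                if r1 - r0 >= min_len
            ]
            if not segs:
                continue
            try:
                fg, p, c = multitaper_spectra(
                    segs, ds.fs, n_tapers, time_bandwidth, resolution_hz,
                    fmin, fmax, state_label=k,
                )
            except ValueError:
                continue
            psd[s, k], coh[s, k] = p, c
    return StateSpectra(psd=psd, coherence=coh, freqs=fgrid, fs=ds.fs,
                        n_tapers=n_tapers, time_bandwidth=time_bandwidth)
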