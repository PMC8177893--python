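"""Synthetic Markov-switching multichannel oscillation cohorts.

Stands in for resting-state MEG + STN-LFP recordings, which are not publicly
available for this kind of study.  Each latent regime ("state") carries its
own band-limited coherence graph: every edge shares a narrow-band Gaussian
latent oscillation between its two channels, mixed with independent channel
noise so that the spectral coherence magnitude at the edge's centre frequency
hits a prescribed target.  The mixing gain has a closed form: with shared
signal power ``a^2 S_z(f0)`` and noise floor ``S_n(f0)`` the coherence
magnitude at the centre frequency is ``a^2 S_z / (a^2 S_z + S_n)``, so a
target ``c`` fixes ``a^2 = c/(1-c) * S_n/S_z``.

The latent state sequence is a first-order Markov chain, optionally made
semi-Markov by enforcing a minimum dwell (the dwell is then
``min_dwell + Geometric(1 - p_stay)``, which preserves the geometric tail).

Ground truth (state sequences, closed-form per-edge coherence, temporal
statistics) is recorded so that recovery by the estimation pipeline can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .datatypes import RegionTimeSeries

__all__ = [
    "StateSpec",
    "ConditionSpec",
    "CohortSpec",
    "GroundTruth",
    "stationary_distribution",
    "generate_state_sequence",
    "generate_coherent_timeseries",
    "generate_cohort",
    "default_channel_groups",
    "demo_state_specs",
    "demo_cohort_spec",
]

#: default spectral width (Hz) of an edge's shared latent oscillation
DEFAULT_EDGE_BANDWIDTH = 4.0


@dataclass
class StateSpec:
    """Spectral-connectivity blueprint of one latent state.

    ``edges`` holds ``(i, j, centre_hz, coherence_target)`` tuples, optionally
    extended with a fifth element giving the latent bandwidth in Hz.
    ``psd_background`` is the white-noise variance per channel (scalar or
    length-``n_channels`` array).
    """

    state_id: int
    edges: list[tuple] = field(default_factory=list)
    psd_background: float | np.ndarray = 1.0

    def validate(self, n_channels: int, fs: float) -> None:
        for e in self.edges:
            i, j, f0, c = e[:4]
            if not (0 <= i < n_channels and 0 <= j < n_channels):
                raise ValueError(f"edge ({i},{j}) has channel index outside [0,{n_channels})")
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coherence_target {c} outside [0, 1]")
            if not 0.0 < f0 < fs / 2:
                raise ValueError(f"centre frequency {f0} outside (0, {fs / 2})")

    def edge_bandwidth(self, k: int) -> float:
        e = self.edges[k]
        return float(e[4]) if len(e) > 4 else DEFAULT_EDGE_BANDWIDTH


@dataclass
class ConditionSpec:
    """Per-condition perturbation: a nominal state-label permutation and
    amplitude multipliers on selected edges, keyed ``(state_id, edge_index)``."""

    permutation: list[int] | None = None
    edge_scale: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class CohortSpec:
    n_subjects: int = 4
    n_channels: int = 48
    n_stn: int = 6
    fs: float = 250.0
    duration_s: float = 300.0
    transition_matrix: np.ndarray = None
    min_dwell_samples: int = 0
    condition_map: dict[str, ConditionSpec] = field(default_factory=lambda: {"A": ConditionSpec()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = np.full((1, 1), 1.0)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        _check_stochastic(self.transition_matrix)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.min_dwell_samples < 0:
            raise ValueError("min_dwell_samples must be >= 0")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring recovery.

    ``sequences[condition][s]`` is subject ``s``'s latent state sequence (base
    state identities).  ``coherence_edges[condition][k]`` lists the effective
    ``(i, j, centre_hz, coherence)`` of state ``k``'s edges after condition
    scaling.  ``permutations[condition]`` records the nominal label
    permutation attached to the condition.
    """

    n_states: int
    fs: float
    sequences: dict[str, list[np.ndarray]]
    coherence_edges: dict[str, dict[int, list[tuple]]]
    permutations: dict[str, list[int]]

    def fractional_occupancy(self, condition: str) -> np.ndarray:
        """Per-subject FO matrix, shape (n_subjects, n_states); rows sum to 1."""
        seqs = self.sequences[condition]
        fo = np.zeros((len(seqs), self.n_states))
        for s, seq in enumerate(seqs):
            counts = np.bincount(seq, minlength=self.n_states)
            fo[s] = counts / seq.size
        return fo

    def mean_lifetimes_ms(self, condition: str) -> np.ndarray:
        """Mean dwell per state in milliseconds, pooled over subjects."""
        sums = np.zeros(self.n_states)
        counts = np.zeros(self.n_states)
        for seq in self.sequences[condition]:
            vals, lengths = _run_lengths(seq)
            for v, n in zip(vals, lengths):
                sums[v] += n
                counts[v] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / counts, np.nan) * 1000.0 / self.fs


def _check_stochastic(P: np.ndarray, tol: float = 1e-12) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < -tol):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [seq.size]))
    return seq[starts], ends - starts


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalised to sum 1)."""
    _check_stochastic(P)
    w, v = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_state_sequence(
    transition_matrix: np.ndarray,
    n_samples: int,
    min_dwell_samples: int = 0,
    seed: int | np.random.Generator | None = None,
    initial_state: int | None = None,
) -> np.ndarray:
    """Sample a latent state sequence from a (semi-)Markov chain.

    With ``min_dwell_samples == 0`` this is a plain first-order Markov chain.
    Otherwise each visit's dwell is drawn as ``min_dwell + Geometric(1-p_kk)``
    (support starting at 0 extra samples), after which the chain jumps to a
    different state with the conditional probabilities ``p_kj / (1 - p_kk)``.
    The final run may be truncated by the end of the sequence.
    """
    P = np.asarray(transition_matrix, dtype=float)
    _check_stochastic(P)
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = P.shape[0]
    if initial_state is None:
        state = int(rng.choice(K, p=stationary_distribution(P)))
    else:
        state = int(initial_state)

    seq = np.empty(n_samples, dtype=np.int64)
    if min_dwell_samples == 0:
        seq[0] = state
        # vectorised would need inverse-cdf per row; chain loop is fine here
        u = rng.random(n_samples - 1)
        cdf = np.cumsum(P, axis=1)
        for t in range(1, n_samples):
            state = int(np.searchsorted(cdf[state], u[t - 1], side="right"))
            seq[t] = min(state, K - 1)
            state = seq[t]
        return seq

    t = 0
    while t < n_samples:
        p_stay = P[state, state]
        if p_stay >= 1.0:
            dwell = n_samples - t
        else:
            dwell = min_dwell_samples + rng.geometric(1.0 - p_stay) - 1
            dwell = max(dwell, 1)
        end = min(t + dwell, n_samples)
        seq[t:end] = state
        t = end
        if t < n_samples:
            if p_stay >= 1.0:  # absorbing; cannot leave
                continue
            probs = P[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(K, p=probs))
    return seq


def _edge_latent_gain(f0: float, bandwidth: float, fs: float, noise_var: float, target: float):
    """Band-pass filter and mixing gain hitting ``target`` coherence at f0.

    Returns ``(sos, gain)`` where the latent is unit-variance filtered white
    noise and ``gain`` multiplies it before adding to a channel with white
    noise of variance ``noise_var``.
    """
    lo = max(f0 - bandwidth / 2.0, 0.1)
    hi = min(f0 + bandwidth / 2.0, fs / 2.0 - 0.1)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    freqs = np.linspace(0.0, fs / 2.0, 4097)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    h2 = np.abs(h) ** 2
    df = freqs[1] - freqs[0]
    h2_int = np.trapezoid(h2, dx=df)
    h2_f0 = np.interp(f0, freqs, h2)
    # unit-variance latent: S_z(f0) = |H(f0)|^2 / integral(|H|^2 df)
    s_z = h2_f0 / h2_int
    s_n = 2.0 * noise_var / fs  # one-sided white-noise PSD
    target = min(float(target), 0.999)
    gain2 = target / (1.0 - target) * s_n / s_z
    return sos, np.sqrt(gain2)


def generate_coherent_timeseries(
    state_specs: list[StateSpec],
    state_sequence: np.ndarray,
    fs: float,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
    groups: list[str] | None = None,
    n_channels: int | None = None,
    edge_scale: dict[tuple[int, int], float] | None = None,
    subject_id: str = "s0",
    condition: str = "A",
) -> RegionTimeSeries:
    """Emit a channels x samples matrix following a latent state sequence.

    For every state a full-length stationary realisation is generated from
    its spec; the output switches between these realisations according to
    ``state_sequence``, so within any single-state run the signal is exactly
    the stationary process of that state.
    """
    seq = np.asarray(state_sequence, dtype=int)
    T = seq.size
    specs = {sp.state_id: sp for sp in state_specs}
    missing = set(np.unique(seq)) - set(specs)
    if missing:
        raise ValueError(f"state sequence visits states without specs: {sorted(missing)}")
    if n_channels is None:
        n_channels = max((max(e[0], e[1]) for sp in state_specs for e in sp.edges), default=0) + 1
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_scale = edge_scale or {}

    out = np.zeros((n_channels, T))
    for sid, sp in specs.items():
        sp.validate(n_channels, fs)
        mask = seq == sid
        if not mask.any():
            continue
        bg = np.broadcast_to(np.atleast_1d(np.asarray(sp.psd_background, dtype=float)), (n_channels,))
        if np.any(bg <= 0):
            raise ValueError("psd_background must be positive")
        x = rng.standard_normal((n_channels, T)) * np.sqrt(bg)[:, None]
        for k, e in enumerate(sp.edges):
            i, j, f0, c = e[:4]
            bw = sp.edge_bandwidth(k)
            scale = edge_scale.get((sid, k), 1.0)
            white = rng.standard_normal(T)
            sos_i, gain_i = _edge_latent_gain(f0, bw, fs, bg[i], c)
            _, gain_j = _edge_latent_gain(f0, bw, fs, bg[j], c)
            z = sps.sosfilt(sos_i, white)
            z /= z.std()
            x[i] += scale * gain_i * z
            x[j] += scale * gain_j * z
        out[:, mask] = x[:, mask]

    return RegionTimeSeries(
        data=out, fs=fs, labels=labels or [], groups=groups or [],
        subject_id=subject_id, condition=condition,
    )


def effective_coherence(target: float, amplitude_scale: float) -> float:
    """Closed-form coherence after scaling the mixing amplitude by ``m``:
    with ``r = c/(1-c)``, the scaled edge reaches ``m^2 r / (m^2 r + 1)``."""
    r = target / (1.0 - min(target, 0.999))
    r *= amplitude_scale**2
    return r / (r + 1.0)


def state_effective_coherences(spec: StateSpec, edge_scale: dict | None = None) -> list[tuple]:
    """Closed-form per-edge coherence of one state, accounting for channels
    that carry several latents.

    A channel touched by ``k`` edges accumulates their latent powers in its
    auto-spectrum, so an edge with signal-to-noise ratio ``r = c/(1-c)``
    (scaled by ``m^2``) reaches
    ``m^2 r / sqrt((1 + sum_i) (1 + sum_j))`` at its centre frequency, where
    ``sum_i`` is the total scaled ``r`` of all edges at channel ``i`` whose
    latent bands overlap this edge's centre frequency.  For disjoint
    channels this reduces to ``m^2 r / (m^2 r + 1)``.
    """
    edge_scale = edge_scale or {}
    r_edges = []
    for k, e in enumerate(spec.edges):
        m = edge_scale.get((spec.state_id, k), 1.0)
        c = min(e[3], 0.999)
        r_edges.append(m**2 * c / (1.0 - c))

    def band(k):
        e = spec.edges[k]
        bw = spec.edge_bandwidth(k)
        return e[2] - bw / 2.0, e[2] + bw / 2.0

    out = []
    for k, e in enumerate(spec.edges):
        i, j, f0 = e[0], e[1], e[2]
        denom = []
        for ch in (i, j):
            s = 0.0
            for k2, e2 in enumerate(spec.edges):
                if ch in (e2[0], e2[1]):
                    lo, hi = band(k2)
                    if lo <= f0 <= hi:
                        s += r_edges[k2]
            denom.append(1.0 + s)
        out.append((i, j, f0, r_edges[k] / np.sqrt(denom[0] * denom[1])))
    return out


def default_channel_groups(n_channels: int = 48, n_stn: int = 6) -> tuple[list[str], list[str]]:
    """Default geometry: first ``n_stn`` channels are STN contacts, the rest
    cortical regions split into rough anatomical clusters."""
    clusters = ["frontal", "medial_pfc", "temporal", "sensorimotor", "parietal", "visual"]
    labels, groups = [], []
    for i in range(n_stn):
        labels.append(f"STN{i}")
        groups.append(f"STN{i % 2}")  # alternate right/left contacts
    n_cort = n_channels - n_stn
    for i in range(n_cort):
        cl = clusters[int(i * len(clusters) / max(n_cort, 1))]
        labels.append(f"ctx{i:02d}")
        groups.append(cl)
    return labels, groups


def generate_cohort(
    cohort_spec: CohortSpec, state_specs: list[StateSpec]
) -> tuple[dict[str, list[RegionTimeSeries]], GroundTruth]:
    """Generate a multi-subject, multi-condition cohort plus its ground truth.

    Reproducible: identical ``(cohort_spec, state_specs)`` including the seed
    give bit-identical output.  Conditions share the chain parameters but use
    independent realisations; state identities in the returned ground truth
    are always base-state ids, with the nominal per-condition label
    permutation recorded separately.
    """
    for sp in state_specs:
        sp.validate(cohort_spec.n_channels, cohort_spec.fs)
    if {sp.state_id for sp in state_specs} != set(range(cohort_spec.n_states)):
        raise ValueError("state specs must cover states 0..K-1 of the transition matrix")
    labels, groups = default_channel_groups(cohort_spec.n_channels, cohort_spec.n_stn)

    root = np.random.SeedSequence(cohort_spec.seed)
    cond_names = list(cohort_spec.condition_map)
    streams = root.spawn(len(cond_names) * cohort_spec.n_subjects)

    data: dict[str, list[RegionTimeSeries]] = {}
    sequences: dict[str, list[np.ndarray]] = {}
    coh_edges: dict[str, dict[int, list[tuple]]] = {}
    perms: dict[str, list[int]] = {}
    idx = 0
    for cname in cond_names:
        cspec = cohort_spec.condition_map[cname]
        perms[cname] = list(cspec.permutation) if cspec.permutation is not None else list(
            range(cohort_spec.n_states)
        )
        coh_edges[cname] = {
            sp.state_id: state_effective_coherences(sp, cspec.edge_scale)
            for sp in state_specs
        }
        data[cname], sequences[cname] = [], []
        for s in range(cohort_spec.n_subjects):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            seq = generate_state_sequence(
                cohort_spec.transition_matrix,
                cohort_spec.n_samples,
                cohort_spec.min_dwell_samples,
                seed=rng,
            )
            ts = generate_coherent_timeseries(
                state_specs, seq, cohort_spec.fs, seed=rng,
                labels=labels, groups=groups, n_channels=cohort_spec.n_channels,
                edge_scale=cspec.edge_scale,
                subject_id=f"sub{s:02d}", condition=cname,
            )
            data[cname].append(ts)
            sequences[cname].append(seq)

    gt = GroundTruth(
        n_states=cohort_spec.n_states,
        fs=cohort_spec.fs,
        sequences=sequences,
        coherence_edges=coh_edges,
        permutations=perms,
    )
    return data, gt


def demo_state_specs(n_channels: int = 48, n_stn: int = 6, coherence: float = 0.8,
                     n_stn_edges: int = 10) -> list[StateSpec]:
    """Three-state blueprint with band-specific STN-cortex coherence graphs.

    State 0 lives in the delta/theta range (centre 4.5 Hz), state 1 in alpha
    (10 Hz), state 2 in beta (13-30 Hz, centre 21 Hz).  Each state couples
    the STN contacts to ``n_stn_edges`` distinct cortical regions (so the
    networks are dense, as in real STN-cortex coupling) plus one
    cortico-cortical edge.  Cortical endpoints are disjoint within and
    across states; STN contacts are reused, which lowers the realised
    coherence below the nominal target in a way the ground truth records
    exactly (:func:`state_effective_coherences`).
    """
    if n_channels < 24 or n_stn < 4:
        raise ValueError("demo specs need >= 24 channels and >= 4 STN contacts")
    n_cort = n_channels - n_stn
    if 3 * n_stn_edges + 6 > n_cort:
        raise ValueError("too many STN edges for the cortical channel count")
    # latent bandwidths sized so that, after the +/-2 Hz multitaper smearing
    # of 2-s windows, each edge's spectral footprint stays inside its
    # canonical band (alpha rhythms in particular are narrowband)
    bands = [(0, 4.5, 3.0), (1, 10.0, 2.0), (2, 21.0, 6.0)]
    specs = []
    for sid, f0, bw in bands:
        edges = [
            (k % n_stn, n_stn + n_stn_edges * sid + k, f0, coherence, bw)
            for k in range(n_stn_edges)
        ]
        edges.append((n_stn + 3 * n_stn_edges + 2 * sid, n_stn + 3 * n_stn_edges + 2 * sid + 1,
                      f0, coherence, bw))
        specs.append(StateSpec(state_id=sid, edges=edges, psd_background=1.0))
    return specs


def demo_cohort_spec(
    n_subjects: int = 4,
    duration_s: float = 300.0,
    seed: int = 0,
    two_conditions: bool = False,
    scaled_edge: tuple[int, int] | None = None,
    edge_scale: float = 0.5,
) -> CohortSpec:
    """Cohort mirroring the study geometry: 48 channels (6 STN contacts),
    250 Hz, 3 states with mean dwell around 2 s (min dwell 1 s).

    With ``two_conditions`` a second condition "B" is added carrying the
    nominal label permutation (0,1,2)->(2,0,1) and, optionally, an amplitude
    scaling on one edge given as ``(state_id, edge_index)``.
    """
    K = 3
    stay = 0.996
    P = np.full((K, K), (1 - stay) / (K - 1))
    np.fill_diagonal(P, stay)
    cmap = {"A": ConditionSpec()}
    if two_conditions:
        scale = {scaled_edge: edge_scale} if scaled_edge is not None else {}
        cmap["B"] = ConditionSpec(permutation=[2, 0, 1], edge_scale=scale)
    return CohortSpec(
        n_subjects=n_subjects,
        n_channels=48,
        n_stn=6,
        fs=250.0,
        duration_s=duration_s,
        transition_matrix=P,
        min_dwell_samples=250,
        condition_map=cmap,
        seed=seed,
    )
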