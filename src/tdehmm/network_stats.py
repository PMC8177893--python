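"""Edge significance within a condition and cluster-pair tests across
conditions.

Within a condition ("IntraMed"-style), the group-level mode-projected
coherence of each state is normalised by subtracting each edge's mean across
states, and a two-component one-dimensional Gaussian mixture with unit
variances — one component for background noise, one for genuine connections —
is fitted to the absolute normalised values.  An edge's p-value is its upper
tail probability under the noise component; edges surviving multiple-
comparison correction at ``alpha`` are flagged.

Across conditions ("InterMed"-style), matched states are compared per
cluster pair (anatomical channel groups, STN contacts pooled into one
cluster) and frequency mode with two-sided independent-sample t-tests on
subject-level mean coherence, corrected over the family of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import is_stn_group
from .modes import ProjectedCoherence

__all__ = [
    "NetworkResult",
    "ClusterComparison",
    "fixed_variance_gmm",
    "gmm_threshold",
    "intermed_ttests",
]


@dataclass
class NetworkResult:
    """Per state x mode edge significance.

    ``edges`` lists (i, j) channel index pairs; ``values`` (K, M, E) are the
    group projected coherences, ``normalised`` the across-state demeaned
    values, ``pvalues``/``significant`` the GMM noise-tail inference.
    ``offsets`` (M, E) holds the per-edge across-state means.
    """

    edges: list[tuple[int, int]]
    values: np.ndarray
    normalised: np.ndarray
    offsets: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    correction: str = "fdr_bh"

    def significant_edges(self, state: int, mode: int) -> list[tuple[int, int]]:
        return [self.edges[e] for e in np.flatnonzero(self.significant[state, mode])]

    def to_frame(self):
        """Long-format table: state, mode, i, j, value, normalised, p, significant."""
        import pandas as pd

        K, M, E = self.values.shape
        idx = np.indices((K, M, E)).reshape(3, -1)
        ii = np.array([self.edges[e][0] for e in idx[2]])
        jj = np.array([self.edges[e][1] for e in idx[2]])
        return pd.DataFrame({
            "state": idx[0], "mode": idx[1], "i": ii, "j": jj,
            "value": self.values.ravel(), "normalised": self.normalised.ravel(),
            "p": self.pvalues.ravel(), "significant": self.significant.ravel(),
        })

    def edge_list_json(self, groups: list[str]) -> dict:
        """Circular-graph-ready significant edge lists with cluster tags."""
        out = {"clusters": groups, "states": []}
        K, M, _ = self.values.shape
        for k in range(K):
            for m in range(M):
                out["states"].append({
                    "state": k, "mode": m,
                    "edges": [[int(i), int(j)] for i, j in self.significant_edges(k, m)],
                })
        return out


def fixed_variance_gmm(
    x: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """EM fit of a two-component 1-D Gaussian mixture with unit variances.

    Only the means and weights are free; the values are expected to be
    standardised by the caller.  Deterministic: means initialise at the 25th
    and 90th percentiles.  Returns ``(means, weights)`` with the first
    component the smaller-mean ("noise") one.
    """
    x = np.asarray(x, dtype=float).ravel()
    mu = np.percentile(x, [25.0, 90.0]).astype(float)
    if mu[1] - mu[0] < 1e-12:
        mu[1] = mu[0] + 1.0
    w = np.array([0.5, 0.5])
    prev = np.inf
    for _ in range(max_iter):
        logp = stats.norm.logpdf(x[:, None], loc=mu[None, :]) + np.log(w)[None, :]
        m = logp.max(axis=1, keepdims=True)
        r = np.exp(logp - m)
        tot = r.sum(axis=1, keepdims=True)
        ll = float(np.sum(np.log(tot) + m.ravel()[:, None]))
        r /= tot
        nk = r.sum(axis=0) + 1e-300
        mu = (r * x[:, None]).sum(axis=0) / nk
        w = nk / x.size
        if abs(prev - ll) < tol * (abs(ll) + 1.0):
            break
        prev = ll
    order = np.argsort(mu)
    return mu[order], w[order]


def gmm_threshold(
    projected: ProjectedCoherence | np.ndarray,
    edges: list[tuple[int, int]] | None = None,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> NetworkResult:
    """Significance-threshold edges of group-level projected coherence.

    Accepts either a :class:`ProjectedCoherence` (all upper-triangle channel
    pairs become edges) or a raw (K, M, E) array with an explicit edge list.
    Needs at least 2 states, since normalisation demeans each edge across
    states.  P-values are upper-tail probabilities of the absolute
    normalised value under the noise component, corrected per state x mode
    family across edges.
    """
    if isinstance(projected, ProjectedCoherence):
        K, M, N = projected.group.shape[0], projected.group.shape[1], projected.group.shape[2]
        iu = np.triu_indices(N, k=1)
        edges = list(zip(iu[0].tolist(), iu[1].tolist()))
        values = projected.group[:, :, iu[0], iu[1]]
    else:
        values = np.asarray(projected, dtype=float)
        if edges is None or values.ndim != 3:
            raise ValueError("raw input needs a (K, M, E) array and an edge list")
    K, M, E = values.shape
    if K < 2:
        raise ValueError("demeaning across states needs at least 2 states")
    if not np.all(np.isfinite(values)):
        raise ValueError("projected coherence contains non-finite values")

    offsets = values.mean(axis=0)  # (M, E) per-edge mean across states
    normalised = values - offsets[None]
    pvals = np.ones_like(values)
    sig = np.zeros_like(values, dtype=bool)
    for m in range(M):
        for k in range(K):
            v = np.abs(normalised[k, m])
            sd = v.std()
            if sd <= 0:
                warnings.warn(
                    f"state {k}, mode {m}: degenerate (all-equal) values; nothing flagged",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            z = v / sd
            mu, _ = fixed_variance_gmm(z)
            pvals[k, m] = stats.norm.sf(z, loc=mu[0])
            rej, _, _, _ = multipletests(pvals[k, m], alpha=alpha, method=correction)
            sig[k, m] = rej
    return NetworkResult(
        edges=edges, values=values, normalised=normalised, offsets=offsets,
        pvalues=pvals, significant=sig, alpha=alpha, correction=correction,
    )


@dataclass
class ClusterComparison:
    """Cluster-pair t-tests between conditions for matched states.

    Arrays are (K, M, C, C) over matched state pairs, modes and cluster
    pairs (symmetric in the last two axes).  ``direction`` holds +1 where
    condition A > condition B on significant pairs, -1 for the reverse,
    0 otherwise.
    """

    clusters: list[str]
    t_stats: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    direction: np.ndarray
    alpha: float = 0.05
    correction: str = "bonferroni"
    mode_labels: list[str] = field(default_factory=list)

    def to_frame(self):
        """Long-format table over state pair x mode x cluster pair."""
        import pandas as pd

        K, M, C, _ = self.t_stats.shape
        rows = []
        for k in range(K):
            for m in range(M):
                for ci in range(C):
                    for cj in range(ci, C):
                        rows.append((k, m, self.clusters[ci], self.clusters[cj],
                                     self.t_stats[k, m, ci, cj], self.pvalues[k, m, ci, cj],
                                     bool(self.significant[k, m, ci, cj]),
                                     self.direction[k, m, ci, cj]))
        return pd.DataFrame(rows, columns=["state", "mode", "cluster_a", "cluster_b",
                                           "t", "p", "significant", "direction"])


def _cluster_of(groups: list[str]) -> tuple[list[str], np.ndarray]:
    names = []
    for g in groups:
        top = "STN" if is_stn_group(g) else g
        if top not in names:
            names.append(top)
    assign = np.array([names.index("STN" if is_stn_group(g) else g) for g in groups])
    return names, assign


def intermed_ttests(
    proj_A: ProjectedCoherence,
    proj_B: ProjectedCoherence,
    groups: list[str],
    pairing: np.ndarray | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    family: str = "global",
) -> ClusterComparison:
    """Two-sided independent-sample t-tests on cluster-pair coherence.

    For matched state pair ``(k, pairing[k])`` and each mode, every subject's
    mean projected coherence over the edges between two channel clusters is
    computed and the two conditions compared.  Correction defaults to the
    total number of comparisons performed (all cluster pairs x modes x
    matched state pairs); ``family="per_state"`` corrects within each
    matched state pair instead.
    """
    A, B = proj_A.subject, proj_B.subject
    SA, K, M, N, _ = A.shape
    SB = B.shape[0]
    if SA < 2 or SB < 2:
        raise ValueError("need at least 2 subjects per condition")
    if pairing is None:
        pairing = np.arange(K)
    clusters, assign = _cluster_of(groups)
    C = len(clusters)
    masks = []
    for ci in range(C):
        for cj in range(ci, C):
            mi = np.outer(assign == ci, assign == cj)
            mask = mi | mi.T
            np.fill_diagonal(mask, False)
            masks.append(((ci, cj), mask))

    t_stats = np.full((K, M, C, C), np.nan)
    pvals = np.full((K, M, C, C), np.nan)
    for k in range(K):
        kb = int(pairing[k])
        for m in range(M):
            for (ci, cj), mask in masks:
                if not mask.any():
                    warnings.warn(
                        f"cluster pair ({clusters[ci]}, {clusters[cj]}) has no edges; skipped",
                        RuntimeWarning, stacklevel=2,
                    )
                    continue
                a_vals = np.array([A[s, k, m][mask].mean() for s in range(SA)])
                b_vals = np.array([B[s, kb, m][mask].mean() for s in range(SB)])
                if np.isnan(a_vals).all() or np.isnan(b_vals).all():
                    continue
                t, p = stats.ttest_ind(
                    a_vals[~np.isnan(a_vals)], b_vals[~np.isnan(b_vals)]
                )
                for x, y in ((ci, cj), (cj, ci)):
                    t_stats[k, m, x, y] = t
                    pvals[k, m, x, y] = p

    sig = np.zeros_like(pvals, dtype=bool)
    iu = [(ci, cj) for ci in range(C) for cj in range(ci, C)]
    if family == "global":
        flat = np.array([pvals[k, m, ci, cj] for k in range(K) for m in range(M) for ci, cj in iu])
        ok = ~np.isnan(flat)
        rej = np.zeros(flat.size, dtype=bool)
        if ok.any():
            rej[ok], _, _, _ = multipletests(flat[ok], alpha=alpha, method=correction)
        idx = 0
        for k in range(K):
            for m in range(M):
                for ci, cj in iu:
                    sig[k, m, ci, cj] = sig[k, m, cj, ci] = rej[idx]
                    idx += 1
    else:
        for k in range(K):
            flat = np.array([pvals[k, m, ci, cj] for m in range(M) for ci, cj in iu])
            ok = ~np.isnan(flat)
            rej = np.zeros(flat.size, dtype=bool)
            if ok.any():
                rej[ok], _, _, _ = multipletests(flat[ok], alpha=alpha, method=correction)
            idx = 0
            for m in range(M):
                for ci, cj in iu:
                    sig[k, m, ci, cj] = sig[k, m, cj, ci] = rej[idx]
                    idx += 1

    direction = np.zeros_like(t_stats)
    with np.errstate(invalid="ignore"):
        direction[sig & (t_stats > 0)] = 1.0
        direction[sig & (t_stats < 0)] = -1.0
    return ClusterComparison(
        clusters=clusters, t_stats=t_stats, pvalues=pvals, significant=sig,
        direction=direction, alpha=alpha, correction=correction,
        mode_labels=list(proj_A.labels),
    )
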