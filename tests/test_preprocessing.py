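"""Leakage correction, sign alignment and standardisation."""

import numpy as np
import pytest

from tdehmm.datatypes import RegionTimeSeries
from tdehmm.preprocessing import (
    preprocess_cohort,
    reduce_region_to_first_pc,
    sign_flip_correct,
    standardise_and_concatenate,
    symmetric_orthogonalise,
)


class TestFirstPC:
    def test_single_vertex_returns_same_waveform(self, rng):
        v = rng.standard_normal((1, 200))
        pc = reduce_region_to_first_pc(v)
        r = np.corrcoef(pc, v[0])[0, 1]
        assert r > 0.999999

    def test_identical_vertices_return_same_waveform(self, rng):
        v = rng.standard_normal(300)
        pc = reduce_region_to_first_pc(np.vstack([v, v]))
        assert np.corrcoef(pc, v)[0, 1] > 0.999999

    def test_beats_random_projections(self, rng):
        # the first PC explains at least as much variance as any of 1000
        # random unit projections
        V = rng.standard_normal((5, 400)) * np.array([3.0, 1.0, 1.0, 0.5, 0.2])[:, None]
        Vc = V - V.mean(axis=1, keepdims=True)
        pc = reduce_region_to_first_pc(V)
        for _ in range(1000):
            w = rng.standard_normal(5)
            w /= np.linalg.norm(w)
            assert np.var(w @ Vc) <= np.var(pc) + 1e-9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            reduce_region_to_first_pc(np.ones((3, 100)))


class TestSymmetricOrthogonalise:
    def test_orthogonal_input_unchanged(self, rng):
        # orthogonal zero-mean rows are a fixed point
        D = np.vstack([np.sin(np.linspace(0, 20 * np.pi, 1000)),
                       np.cos(np.linspace(0, 20 * np.pi, 1000))])
        D -= D.mean(axis=1, keepdims=True)
        O = symmetric_orthogonalise(D)
        np.testing.assert_allclose(O, D, atol=1e-8)

    def test_rows_exactly_uncorrelated(self, rng):
        O = symmetric_orthogonalise(rng.standard_normal((5, 800)))
        C = np.corrcoef(O)
        off = C[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_closer_than_gram_schmidt(self, rng):
        # Gram-Schmidt oracle: sequential projection, order-dependent
        D = rng.standard_normal((3, 1000))
        Dc = D - D.mean(axis=1, keepdims=True)
        O = symmetric_orthogonalise(D)
        G = Dc.copy()
        for i in range(3):
            for j in range(i):
                G[i] -= (G[i] @ G[j]) / (G[j] @ G[j]) * G[j]
        assert np.linalg.norm(Dc - O) <= np.linalg.norm(Dc - G) + 1e-9

    def test_rank_deficient_names_channels(self, rng):
        x = rng.standard_normal(500)
        D = np.vstack([x, 2 * x, rng.standard_normal(500)])
        with pytest.raises(ValueError, match="redundant channel"):
            symmetric_orthogonalise(D)


class TestSignFlip:
    def test_single_subject_identity(self, rng):
        signs, flipped = sign_flip_correct([rng.standard_normal((4, 500))])
        np.testing.assert_array_equal(signs[0], 1.0)

    def test_recovers_negated_channel(self, rng):
        base = rng.standard_normal((5, 3)) @ rng.standard_normal((3, 2000))
        base += 0.1 * rng.standard_normal(base.shape)
        other = base.copy()
        other[3] *= -1.0
        signs, flipped = sign_flip_correct([base, other], n_lags=15)
        # relative signs matter, and only up to a global flip per subject
        # (flipping every channel leaves the covariance objective unchanged)
        rel = signs[0] * signs[1]
        assert np.all(np.delete(rel, 3) == rel[0])
        assert rel[3] == -rel[0]

    def test_aligned_cohort_is_fixed_point(self, rng):
        base = rng.standard_normal((4, 3)) @ rng.standard_normal((3, 1500))
        subs = [base + 0.05 * rng.standard_normal(base.shape) for _ in range(3)]
        signs, _ = sign_flip_correct(subs, n_lags=15)
        for s in signs:
            np.testing.assert_array_equal(s, np.ones(4))


class TestStandardise:
    def _ts(self, rng, t, sid):
        return RegionTimeSeries(rng.standard_normal((3, t)) * 4 + 2, fs=100.0,
                                labels=["a", "b", "c"], groups=["g", "g", "g"],
                                subject_id=sid)

    def test_zero_mean_unit_sd_and_boundaries(self, rng):
        ds = standardise_and_concatenate([self._ts(rng, 1000, "s0"), self._ts(rng, 2000, "s1")])
        assert ds.boundaries == [(0, 1000), (1000, 3000)]
        assert ds.data.shape == (3, 3000)
        for s in range(2):
            x = ds.subject_data(s)
            np.testing.assert_allclose(x.mean(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(x.std(axis=1), 1.0, atol=1e-12)

    def test_zscore_idempotent(self, rng):
        ts = self._ts(rng, 500, "s0")
        once = standardise_and_concatenate([ts]).data
        twice = standardise_and_concatenate(
            [RegionTimeSeries(once, 100.0, ts.labels, ts.groups)]).data
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_mismatched_labels_rejected(self, rng):
        a = self._ts(rng, 100, "s0")
        b = RegionTimeSeries(rng.standard_normal((3, 100)), 100.0,
                             labels=["x", "y", "z"], groups=["g"] * 3)
        with pytest.raises(ValueError, match="mismatch"):
            standardise_and_concatenate([a, b])


class TestPipelineOrder:
    def test_stn_channels_bypass_orthogonalisation(self, rng):
        # cortical rows end up mutually uncorrelated, but genuine
        # STN-cortex zero-lag correlation survives
        shared = rng.standard_normal(3000)
        data = rng.standard_normal((5, 3000))
        data[0] = shared + 0.5 * rng.standard_normal(3000)     # STN contact
        data[2] = shared + 0.5 * rng.standard_normal(3000)     # cortical
        data[3] = data[2] * 0.7 + rng.standard_normal(3000)    # leaked cortical
        ts = RegionTimeSeries(data, 250.0, labels=[f"c{i}" for i in range(5)],
                              groups=["STN0", "STN1", "ctx", "ctx", "ctx"])
        ds = preprocess_cohort([ts], sign_flip=False)
        C = np.corrcoef(ds.data)
        cort = [2, 3, 4]
        off = C[np.ix_(cort, cort)][~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6
        assert abs(C[0, 2]) > 0.3
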