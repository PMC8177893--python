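"""Generator behaviour: chain statistics, closed-form coherence targets,
cohort bookkeeping and determinism."""

import numpy as np
import pytest

from tdehmm.spectra import multitaper_spectra
from tdehmm.synthetic import (
    CohortSpec,
    ConditionSpec,
    StateSpec,
    demo_cohort_spec,
    demo_state_specs,
    effective_coherence,
    generate_cohort,
    generate_coherent_timeseries,
    generate_state_sequence,
    stationary_distribution,
)


class TestStateSequence:
    def test_absorbing_chain_stays_constant(self):
        P = np.eye(2)
        seq = generate_state_sequence(P, 500, seed=0, initial_state=0)
        assert np.all(seq == 0)

    def test_mean_dwell_matches_geometric(self):
        # self-transition 0.9 -> geometric dwell with mean 1/(1-p) = 10
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = generate_state_sequence(P, 200_000, seed=1)
        change = np.flatnonzero(np.diff(seq)) + 1
        runs = np.diff(np.concatenate(([0], change, [seq.size])))
        assert abs(runs.mean() - 10.0) / 10.0 < 0.05

    def test_occupancy_matches_stationary_distribution(self):
        # eigen-decomposition oracle for the stationary distribution
        P = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        pi = stationary_distribution(P)
        np.testing.assert_allclose(pi, 1 / 3, atol=1e-12)
        seq = generate_state_sequence(P, 300_000, seed=2)
        fo = np.bincount(seq, minlength=3) / seq.size
        np.testing.assert_allclose(fo, pi, atol=0.02 / 3 * 3)

    def test_asymmetric_chain_occupancy(self):
        P = np.array([[0.95, 0.05], [0.02, 0.98]])
        pi = stationary_distribution(P)
        seq = generate_state_sequence(P, 400_000, seed=3)
        fo = np.bincount(seq, minlength=2) / seq.size
        np.testing.assert_allclose(fo, pi, atol=0.02)

    def test_min_dwell_enforced(self):
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        seq = generate_state_sequence(P, 50_000, min_dwell_samples=20, seed=4)
        change = np.flatnonzero(np.diff(seq)) + 1
        runs = np.diff(np.concatenate(([0], change, [seq.size])))
        assert np.all(runs[:-1] >= 20)  # final run may be truncated

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_state_sequence(np.array([[0.5, 0.6], [0.5, 0.5]]), 100, seed=0)

    def test_deterministic_under_seed(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        a = generate_state_sequence(P, 10_000, seed=9)
        b = generate_state_sequence(P, 10_000, seed=9)
        assert np.array_equal(a, b)


class TestCoherentTimeseries:
    def test_single_edge_hits_coherence_target(self):
        # closed form: coherence = a^2 S_z / (a^2 S_z + S_n) fixes the gain
        spec = StateSpec(0, edges=[(0, 1, 20.0, 0.9)])
        ts = generate_coherent_timeseries([spec], np.zeros(30_000, dtype=int),
                                          250.0, seed=2, n_channels=2)
        f, _, coh = multitaper_spectra([ts.data], 250.0)
        est = coh[np.argmin(np.abs(f - 20.0)), 0, 1]
        assert 0.8 <= est <= 0.95

    def test_independent_noise_sits_at_bias_floor(self):
        # magnitude-squared coherence of independent signals averages to
        # ~1/n over n averaged taper-windows
        spec = StateSpec(0)
        ts = generate_coherent_timeseries([spec], np.zeros(30_000, dtype=int),
                                          250.0, seed=3, n_channels=3)
        f, _, coh = multitaper_spectra([ts.data], 250.0)
        iu = np.triu_indices(3, 1)
        n_tw = 7 * (30_000 // 500)
        assert np.mean(coh[:, iu[0], iu[1]] ** 2) < 2.0 / n_tw

    def test_invalid_target_rejected(self):
        spec = StateSpec(0, edges=[(0, 1, 20.0, 1.5)])
        with pytest.raises(ValueError, match="coherence_target"):
            generate_coherent_timeseries([spec], np.zeros(100, dtype=int),
                                         250.0, seed=0, n_channels=2)

    def test_edge_scale_lowers_coherence(self):
        # amplitude scale m gives closed-form coherence m^2 r / (m^2 r + 1)
        assert effective_coherence(0.6, 1.0) == pytest.approx(0.6, abs=1e-9)
        assert effective_coherence(0.6, 0.5) == pytest.approx(0.2727, abs=1e-3)
        spec = StateSpec(0, edges=[(0, 1, 20.0, 0.6)])
        seq = np.zeros(30_000, dtype=int)
        a = generate_coherent_timeseries([spec], seq, 250.0, seed=5, n_channels=2)
        b = generate_coherent_timeseries([spec], seq, 250.0, seed=5, n_channels=2,
                                         edge_scale={(0, 0): 0.5})
        f, _, ca = multitaper_spectra([a.data], 250.0)
        _, _, cb = multitaper_spectra([b.data], 250.0)
        i = np.argmin(np.abs(f - 20.0))
        assert cb[i, 0, 1] < ca[i, 0, 1]
        assert cb[i, 0, 1] == pytest.approx(effective_coherence(0.6, 0.5), abs=0.08)


class TestCohort:
    def test_single_state_full_occupancy(self):
        spec = CohortSpec(n_subjects=1, n_channels=4, n_stn=2, fs=100.0, duration_s=5.0,
                          transition_matrix=np.ones((1, 1)), seed=0)
        _, gt = generate_cohort(spec, [StateSpec(0)])
        np.testing.assert_allclose(gt.fractional_occupancy("A"), [[1.0]])

    def test_permutation_recorded(self):
        spec = demo_cohort_spec(n_subjects=1, duration_s=4.0, seed=0, two_conditions=True)
        _, gt = generate_cohort(spec, demo_state_specs())
        assert gt.permutations["B"] == [2, 0, 1]
        assert gt.permutations["A"] == [0, 1, 2]

    def test_ground_truth_consistent_with_sequences(self):
        spec = demo_cohort_spec(n_subjects=2, duration_s=20.0, seed=1)
        data, gt = generate_cohort(spec, demo_state_specs())
        fo = gt.fractional_occupancy("A")
        np.testing.assert_allclose(fo.sum(axis=1), 1.0, atol=1e-12)
        assert len(data["A"]) == 2
        assert data["A"][0].data.shape == (48, 5000)
        assert len(data["A"][0].stn_indices) == 6

    def test_bit_identical_under_seed(self):
        spec = demo_cohort_spec(n_subjects=1, duration_s=5.0, seed=42)
        d1, g1 = generate_cohort(spec, demo_state_specs())
        spec2 = demo_cohort_spec(n_subjects=1, duration_s=5.0, seed=42)
        d2, g2 = generate_cohort(spec2, demo_state_specs())
        assert np.array_equal(d1["A"][0].data, d2["A"][0].data)
        assert np.array_equal(g1.sequences["A"][0], g2.sequences["A"][0])

    def test_condition_scaling_recorded_in_truth(self):
        spec = demo_cohort_spec(n_subjects=1, duration_s=4.0, seed=0,
                                two_conditions=True, scaled_edge=(2, 0), edge_scale=0.5)
        _, gt = generate_cohort(spec, demo_state_specs())
        cA = gt.coherence_edges["A"][2][0][3]
        cB = gt.coherence_edges["B"][2][0][3]
        assert cB < cA

    def test_channel_reuse_lowers_effective_coherence(self):
        from tdehmm.synthetic import StateSpec, state_effective_coherences

        # disjoint edge: closed form c = r/(r+1); shared channel: r/sqrt((1+2r)(1+r))
        lone = StateSpec(0, edges=[(0, 1, 10.0, 0.8)])
        assert state_effective_coherences(lone)[0][3] == pytest.approx(0.8, abs=1e-9)
        shared = StateSpec(0, edges=[(0, 1, 10.0, 0.8), (0, 2, 10.0, 0.8)])
        r = 4.0
        expected = r / np.sqrt((1 + 2 * r) * (1 + r))
        for e in state_effective_coherences(shared):
            assert e[3] == pytest.approx(expected, abs=1e-9)
        # an edge in a different band does not load this edge's denominator
        far = StateSpec(0, edges=[(0, 1, 10.0, 0.8), (0, 2, 25.0, 0.8)])
        assert state_effective_coherences(far)[0][3] == pytest.approx(0.8, abs=1e-9)
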