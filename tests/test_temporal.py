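"""Fractional occupancy, lifetimes, intervals and the two-way ANOVA."""

import numpy as np
import pytest

from tdehmm.synthetic import generate_state_sequence
from tdehmm.temporal import TemporalMetrics, anova_temporal, compute_temporal_metrics


def metrics_from_lifetimes(lifetimes_by_state, subject_id, condition, fs=250.0):
    K = len(lifetimes_by_state)
    return TemporalMetrics(
        fs=fs, n_states=K,
        fractional_occupancy=np.full(K, 1.0 / K),
        lifetimes_ms=[np.asarray(l, dtype=float) for l in lifetimes_by_state],
        filtered_lifetimes_ms=[np.asarray(l, dtype=float) for l in lifetimes_by_state],
        intervals_ms=[np.asarray(l, dtype=float) for l in lifetimes_by_state],
        n_visits=np.array([len(l) for l in lifetimes_by_state]),
        subject_id=subject_id, condition=condition,
    )


class TestMetrics:
    def test_hand_countable_toy_path(self):
        m = compute_temporal_metrics(np.array([0, 0, 0, 1, 1, 0, 0]), fs=1000.0)
        np.testing.assert_allclose(m.fractional_occupancy, [5 / 7, 2 / 7])
        np.testing.assert_array_equal(m.lifetimes_ms[0], [3.0, 2.0])
        np.testing.assert_array_equal(m.lifetimes_ms[1], [2.0])
        np.testing.assert_array_equal(m.intervals_ms[0], [2.0])
        assert m.intervals_ms[1].size == 0

    def test_constant_path(self):
        m = compute_temporal_metrics(np.zeros(500, dtype=int), fs=250.0)
        assert m.fractional_occupancy[0] == 1.0
        np.testing.assert_array_equal(m.lifetimes_ms[0], [2000.0])
        assert m.intervals_ms[0].size == 0

    def test_lifetime_filter_excludes_exactly_subthreshold_runs(self):
        # runs of 20, 30 and 10 samples at 250 Hz = 80, 120 and 40 ms
        path = np.concatenate([np.zeros(20), np.ones(5), np.zeros(30),
                               np.ones(5), np.zeros(10), np.ones(5)]).astype(int)
        m = compute_temporal_metrics(path, fs=250.0, min_lifetime_ms=100.0)
        np.testing.assert_array_equal(m.lifetimes_ms[0], [80.0, 120.0, 40.0])
        np.testing.assert_array_equal(m.filtered_lifetimes_ms[0], [120.0])

    def test_total_lifetime_equals_duration(self, rng):
        path = rng.integers(0, 3, size=2000)
        m = compute_temporal_metrics(path, fs=250.0)
        total = sum(l.sum() for l in m.lifetimes_ms)
        assert total == pytest.approx(2000 / 250.0 * 1000.0)

    def test_mean_lifetime_matches_geometric_dwell(self):
        # self-transition 0.99 at 250 Hz -> mean dwell 100 samples = 400 ms
        P = np.array([[0.99, 0.01], [0.01, 0.99]])
        seq = generate_state_sequence(P, 400_000, seed=11)
        m = compute_temporal_metrics(seq, fs=250.0)
        for k in range(2):
            mean_lt = m.lifetimes_ms[k].mean()
            assert abs(mean_lt - 400.0) / 400.0 < 0.1

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_temporal_metrics(np.array([], dtype=int), fs=250.0)


class TestAnova:
    def test_visit_level_f_matches_sums_of_squares_oracle(self, rng):
        # balanced 2x2 table, explicit sums-of-squares computation
        cells = {}
        for cond in ("A", "B"):
            for k in (0, 1):
                cells[(cond, k)] = rng.normal(300 + 40 * k + (15 if cond == "B" else 0),
                                              25, size=12)
        mA = [metrics_from_lifetimes([cells[("A", 0)], cells[("A", 1)]], "s0", "A")]
        mB = [metrics_from_lifetimes([cells[("B", 0)], cells[("B", 1)]], "s0", "B")]
        res = anova_temporal(mA, mB, metric="lifetime")

        y = np.concatenate([cells[c] for c in cells])
        n = 12
        grand = y.mean()
        m_state = {k: np.concatenate([cells[("A", k)], cells[("B", k)]]).mean() for k in (0, 1)}
        m_cond = {c: np.concatenate([cells[(c, 0)], cells[(c, 1)]]).mean() for c in ("A", "B")}
        ss_state = 2 * n * sum((m_state[k] - grand) ** 2 for k in (0, 1))
        ss_cond = 2 * n * sum((m_cond[c] - grand) ** 2 for c in ("A", "B"))
        ss_int = n * sum(
            (cells[(c, k)].mean() - m_state[k] - m_cond[c] + grand) ** 2
            for c in ("A", "B") for k in (0, 1)
        )
        ss_err = sum(((cells[c] - cells[c].mean()) ** 2).sum() for c in cells)
        df_err = 4 * (n - 1)
        f_state = ss_state / 1 / (ss_err / df_err)
        f_cond = ss_cond / 1 / (ss_err / df_err)
        f_int = ss_int / 1 / (ss_err / df_err)
        assert res.f_statistic("state") == pytest.approx(f_state, rel=1e-8)
        assert res.f_statistic("condition") == pytest.approx(f_cond, rel=1e-8)
        assert res.f_statistic("state:condition") == pytest.approx(f_int, rel=1e-8)

    def test_state_dependent_dwell_detected(self):
        # 300 vs 150 ms generator dwell: state main effect found reliably
        found = 0
        for seed in range(20):
            r = np.random.default_rng(3000 + seed)
            mA, mB = [], []
            for cond, bucket in (("A", mA), ("B", mB)):
                for s in range(17):
                    lts = [r.exponential(300.0, size=60), r.exponential(150.0, size=60)]
                    bucket.append(metrics_from_lifetimes(lts, f"s{s}", cond))
            res = anova_temporal(mA, mB, metric="lifetime", post_hoc="none")
            found += res.p_value("state") < 0.05
        assert found / 20 > 0.9

    def test_null_type_one_rate_calibrated(self):
        # no-effect visit tables: each main effect rejects at ~alpha
        rej_state, rej_cond = 0, 0
        n_rep = 500
        for seed in range(n_rep):
            r = np.random.default_rng(4000 + seed)
            mA = [metrics_from_lifetimes([r.exponential(200, 100), r.exponential(200, 100)],
                                         "s0", "A")]
            mB = [metrics_from_lifetimes([r.exponential(200, 100), r.exponential(200, 100)],
                                         "s0", "B")]
            res = anova_temporal(mA, mB, metric="interval", post_hoc="none")
            rej_state += res.p_value("state") < 0.05
            rej_cond += res.p_value("condition") < 0.05
        assert abs(rej_state / n_rep - 0.05) <= 0.02
        assert abs(rej_cond / n_rep - 0.05) <= 0.02

    def test_fo_repeated_measures_dfs(self, rng):
        mA, mB = [], []
        for s in range(8):
            for cond, bucket in (("A", mA), ("B", mB)):
                path = rng.integers(0, 3, size=500)
                bucket.append(compute_temporal_metrics(path, 250.0, 3,
                                                       subject_id=f"s{s}", condition=cond))
        res = anova_temporal(mA, mB, metric="fo")
        assert res.table.loc["state", "Num DF"] == 2
        assert res.table.loc["state", "Den DF"] == 14
        assert res.table.loc["condition", "Num DF"] == 1

    def test_state_without_visits_excluded_with_warning(self, rng):
        mA = [metrics_from_lifetimes([rng.exponential(200, 20), np.array([])],
                                     "s0", "A")]
        mB = [metrics_from_lifetimes([rng.exponential(200, 20), rng.exponential(200, 20)],
                                     "s0", "B")]
        mA.append(metrics_from_lifetimes([rng.exponential(200, 20), rng.exponential(150, 20)],
                                         "s1", "A"))
        mB.append(metrics_from_lifetimes([rng.exponential(200, 20), rng.exponential(150, 20)],
                                         "s1", "B"))
        res = anova_temporal(mA, mB, metric="lifetime", post_hoc="none")
        assert res.excluded_states == []  # state 1 has visits in both conditions overall
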