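import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import halotrace as ht


class TestDerivePrePost:
    def test_definition(self):
        table = ht.EpochTable.from_records(
            [("meeting", 100.0, 100.0), ("intromission", 150.0, 200.0),
             ("ejaculation", 480.0, 500.0)])
        out = ht.derive_pre_post(table, recording_span=700.0)
        assert out.bouts("pre").tolist() == [[0.0, 100.0]]
        assert out.bouts("post").tolist() == [[500.0, 600.0]]

    def test_post_clipped_with_warning(self):
        table = ht.EpochTable.from_records(
            [("meeting", 300.0, 300.0), ("ejaculation", 480.0, 500.0)])
        with pytest.warns(UserWarning, match="clipped"):
            out = ht.derive_pre_post(table, recording_span=600.0)
        assert out.bouts("post").tolist() == [[500.0, 600.0]]

    def test_no_ejaculation_no_post(self):
        table = ht.EpochTable.from_records([("chasing", 50.0, 60.0)])
        out = ht.derive_pre_post(table, recording_span=200.0)
        assert out.bouts("pre").tolist() == [[0.0, 50.0]]
        assert len(out.bouts("post")) == 0

    def test_missing_marker_errors(self):
        with pytest.raises(ValueError, match="meeting"):
            ht.derive_pre_post(ht.EpochTable(), recording_span=100.0)


def zscored(values, frame_rate=10.0):
    return ht.TraceMatrix(np.asarray(values, dtype=float), stage="zscored",
                          frame_rate=frame_rate)


class TestEpochStats:
    def test_constant_trace_stats(self):
        vals = np.zeros((1, 100))
        vals[0, 20:40] = 2.0
        epochs = ht.EpochTable.from_records([("AT", 2.0, 4.0)],
                                            timeline="imaging")
        stats = ht.epoch_stats(zscored(vals), epochs)
        assert stats.means.loc[0, "AT"] == pytest.approx(2.0)
        assert stats.stds.loc[0, "AT"] == pytest.approx(0.0)

    def test_bouts_pooled(self):
        vals = np.zeros((1, 100))
        vals[0, 10:20] = 1.0
        vals[0, 50:60] = 3.0
        epochs = ht.EpochTable.from_records(
            [("AT", 1.0, 2.0), ("AT", 5.0, 6.0)], timeline="imaging")
        stats = ht.epoch_stats(zscored(vals), epochs)
        assert stats.means.loc[0, "AT"] == pytest.approx(2.0)

    def test_short_label_dropped_with_warning(self):
        epochs = ht.EpochTable.from_records(
            [("blip", 1.0, 1.05), ("AT", 2.0, 4.0)], timeline="imaging")
        with pytest.warns(UserWarning, match="blip"):
            stats = ht.epoch_stats(zscored(np.random.default_rng(0)
                                           .uniform(size=(2, 100))), epochs)
        assert "blip" not in stats.labels and "AT" in stats.labels

    def test_empty_table_empty_stats(self):
        stats = ht.epoch_stats(zscored(np.ones((2, 10))), ht.EpochTable())
        assert stats.means.empty


class TestPopulationCorrelation:
    def _stats(self, columns):
        means = pd.DataFrame(columns)
        return ht.EpochStats(means=means, stds=means * 0)

    def test_identical_vectors(self):
        stats = self._stats({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        corr = ht.population_correlation(stats, ["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_sign_flip(self):
        stats = self._stats({"a": [1.0, -2, 3], "b": [-1.0, 2, -3]})
        corr = ht.population_correlation(stats, ["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        stats = self._stats({"a": [1.0, 2, 3], "b": [1.0, 2, 4]})
        corr = ht.population_correlation(stats, ["a", "b"])
        # r = 1.5 / (1 * sqrt(7/3)) = 0.981980...
        assert corr.loc["a", "b"] == pytest.approx(0.9819805061, abs=1e-9)

    def test_zero_variance_vector_marked(self):
        stats = self._stats({"a": [1.0, 2, 3], "b": [2.0, 2, 2]})
        with pytest.warns(UserWarning, match="zero variance"):
            corr = ht.population_correlation(stats, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"]) and corr.loc["b", "b"] == 1.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_symmetric_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        means = pd.DataFrame(rng.normal(size=(5, 4)),
                             columns=["a", "b", "c", "d"])
        corr = ht.population_correlation(
            ht.EpochStats(means=means, stds=means * 0))
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestMeanR2:
    def test_single_pair(self):
        corr = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]],
                            index=["AT", "intromission"],
                            columns=["AT", "intromission"])
        assert ht.mean_r2(corr, "AT") == pytest.approx(0.25)
        assert ht.mean_r2(corr, "intromission") == pytest.approx(0.25)

    def test_perfect_correlations(self):
        labels = ["intromission", "AT", "ejaculation"]
        corr = pd.DataFrame([[1.0, -1, 1], [-1, 1.0, -1], [1, -1, 1.0]],
                            index=labels, columns=labels)
        assert ht.mean_r2(corr, "intromission") == pytest.approx(1.0)

    def test_matches_direct_recomputation(self):
        labels = ["intromission", "AT", "ejaculation"]
        rng = np.random.default_rng(8)
        means = pd.DataFrame(rng.normal(size=(6, 3)), columns=labels)
        corr = ht.population_correlation(ht.EpochStats(means, means * 0))
        expected = np.mean([corr.loc["AT", "intromission"] ** 2,
                            corr.loc["AT", "ejaculation"] ** 2])
        assert ht.mean_r2(corr, "AT") == pytest.approx(expected)

    def test_pre_post_excluded_and_errors(self):
        labels = ["intromission", "pre", "post"]
        corr = pd.DataFrame(np.eye(3), index=labels, columns=labels)
        with pytest.raises(ValueError, match="mating"):
            ht.mean_r2(corr, "intromission")


class TestSortCells:
    def test_descending_order(self):
        means = pd.DataFrame({"intromission": [0.2, 0.9, -0.1]})
        stats = ht.EpochStats(means=means, stds=means * 0)
        assert ht.sort_cells(stats, "intromission") == [1, 0, 2]

    def test_ties_broken_by_id(self):
        means = pd.DataFrame({"AT": [0.5, 0.5, 0.5]})
        stats = ht.EpochStats(means=means, stds=means * 0)
        assert ht.sort_cells(stats, "AT") == [0, 1, 2]

    def test_singleton(self):
        means = pd.DataFrame({"AT": [1.0]})
        assert ht.sort_cells(ht.EpochStats(means, means * 0), "AT") == [0]


class TestBoutStatistics:
    @pytest.fixture
    def preset(self):
        return ht.generate_epoch_script(ht.SimConfig(), preset="male_day10")

    def test_printed_at_statistics(self, preset):
        """AT bouts of 2.4, 4.6, 1.1 s give 2.7 +/- 1.8 s (1 d.p.)."""
        row = ht.bout_statistics(preset).table.loc["AT"]
        assert round(row["mean_s"], 1) == 2.7
        assert round(row["std_s"], 1) == 1.8

    def test_printed_intromission_cumulative(self, preset):
        row = ht.bout_statistics(preset).table.loc["intromission"]
        assert row["count"] == 2
        assert row["cumulative_s"] == pytest.approx(73.1)

    def test_single_bout_std_undefined(self):
        table = ht.EpochTable.from_records([("ejaculation", 10.0, 15.0)])
        row = ht.bout_statistics(table).table.loc["ejaculation"]
        assert np.isnan(row["std_s"])
        assert row["cumulative_s"] == pytest.approx(5.0)

    def test_cumulative_equals_sum_exactly(self):
        rng = np.random.default_rng(9)
        t = 0.0
        rows = []
        for _ in range(20):
            t += rng.uniform(0.5, 3)
            d = rng.uniform(0.1, 10)
            rows.append(("AT", t, t + d))
            t += d
        summary = ht.bout_statistics(ht.EpochTable.from_records(rows))
        assert summary.table.loc["AT", "cumulative_s"] == \
            summary.durations["AT"].sum()

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ht.bout_statistics(ht.EpochTable())


class TestTwoSampleTtest:
    def test_identical_groups(self):
        t, df, p = ht.two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_printed_bout_comparison(self):
        """AT (2.4, 4.6, 1.1) vs intromission (41.6, 31.5) durations."""
        t, df, p = ht.two_sample_ttest([2.4, 4.6, 1.1], [41.6, 31.5])
        assert df == 3
        assert t == pytest.approx(-8.488, abs=0.005)
        assert p == pytest.approx(0.0034, abs=0.0002)

    def test_degenerate_zero_variance(self):
        t, df, p = ht.two_sample_ttest([2.0, 2.0], [5.0, 5.0])
        assert np.isinf(t) and t < 0 and p == 0.0
        t2, _, p2 = ht.two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert t2 == 0.0 and p2 == 1.0

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ht.two_sample_ttest([1.0], [2.0, 3.0])


class TestPipelineCorrelationStructure:
    def test_mating_correlation_signs(self):
        """Intromission anticorrelates with AT and correlates with
        ejaculation when cells carry that modulation structure."""
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            s = ht.run_mating_session(seed=seed, n_cells=8,
                                      image_shape=(48, 48))
            corr = s.behavior_correlation(list(ht.MATING_LABELS))
            hits += (corr.loc["intromission", "AT"] < 0
                     and corr.loc["intromission", "ejaculation"] > 0)
        assert hits / n_runs >= 0.95
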