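import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import halotrace as ht


def tm(values, stage="raw_roi", frame_rate=10.0, **kw):
    return ht.TraceMatrix(np.asarray(values, dtype=float), stage=stage,
                          frame_rate=frame_rate, **kw)


class TestLowpass:
    def test_constant_unchanged(self):
        out = ht.lowpass_moving_average(tm(np.full((2, 10), 4.0)), 3)
        assert (out.values == 4.0).all()
        assert out.stage == "lowpassed"

    def test_truncated_edge_windows(self):
        out = ht.lowpass_moving_average(tm([[0.0, 3.0, 0.0]]), 3)
        assert out.values[0] == pytest.approx([1.5, 1.0, 1.5])

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).uniform(size=(3, 20))
        out = ht.lowpass_moving_average(tm(x), 1)
        assert np.array_equal(out.values, x)

    def test_width_longer_than_trace_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            ht.lowpass_moving_average(tm([[1.0, 2.0]]), 5)


class TestSubtractNeuropil:
    def test_roi_equals_halo_gives_zero(self):
        x = np.random.default_rng(1).uniform(size=(2, 30))
        roi = ht.lowpass_moving_average(tm(x), 1)
        halo = ht.lowpass_moving_average(tm(x.copy(), stage="raw_halo"), 1)
        out = ht.subtract_neuropil(roi, halo)
        assert (out.values == 0).all()
        assert out.stage == "neuropil_subtracted"

    def test_recovers_cell_signal_exactly(self, small_session):
        """roi = s + n, halo = n: subtraction returns s when noise is off."""
        cfg, _, movie, truth = small_session
        rois = ht.compute_halo(ht.RoiSet(truth.footprints))
        raw_roi, raw_halo = ht.extract_traces(movie, rois)
        sub = ht.subtract_neuropil(ht.lowpass_moving_average(raw_roi, 1),
                                   ht.lowpass_moving_average(raw_halo, 1))
        expected = truth.bleach_curve[None] * truth.cell_fluor
        assert sub.values == pytest.approx(expected)

    def test_empty_halo_passthrough(self):
        x = np.random.default_rng(2).uniform(1, 2, size=(2, 10))
        h = np.random.default_rng(3).uniform(size=(2, 10))
        flags = np.array([True, False])
        roi = ht.lowpass_moving_average(tm(x, empty_halo=flags), 1)
        halo = ht.lowpass_moving_average(
            tm(h, stage="raw_halo", empty_halo=flags), 1)
        out = ht.subtract_neuropil(roi, halo)
        assert np.array_equal(out.values[0], x[0])
        assert out.values[1] == pytest.approx(x[1] - h[1])
        assert out.empty_halo[0]

    def test_shape_mismatch_errors(self):
        roi = ht.lowpass_moving_average(tm(np.ones((2, 10))), 1)
        halo = ht.lowpass_moving_average(tm(np.ones((2, 8)), stage="raw_halo"), 1)
        with pytest.raises(ValueError, match="shape"):
            ht.subtract_neuropil(roi, halo)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        out = ht.compute_dff(tm(np.full((1, 100), 5.0),
                                stage="neuropil_subtracted"))
        assert (out.values == 0).all()
        assert out.stage == "dff"

    def test_two_frame_window_covering_trace(self):
        out = ht.compute_dff(tm([[2.0, 4.0]], stage="neuropil_subtracted"),
                             window_s=120.0)
        assert out.values[0] == pytest.approx([-1 / 3, 1 / 3])

    def test_slow_exponential_bleach_bound(self):
        """For tau >> window, residual |dff| stays well under window/tau."""
        fs, tau, window = 10.0, 2400.0, 120.0
        t = np.arange(6000) / fs
        trace = tm(np.exp(-t / tau)[None], stage="neuropil_subtracted",
                   frame_rate=fs)
        out = ht.compute_dff(trace, window_s=window)
        assert np.abs(out.values).max() < window / tau

    def test_zero_f0_names_cell_and_frame(self):
        vals = np.ones((2, 50))
        vals[1, 9:12] = [1.0, 0.0, -1.0]  # 3-frame window at frame 10 sums to 0
        with pytest.raises(ZeroDivisionError, match="cell 1.*frame 10"):
            ht.compute_dff(tm(vals, stage="neuropil_subtracted"), window_s=0.3)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError, match="longer"):
            ht.compute_dff(tm([[1.0]], stage="neuropil_subtracted"))


class TestZscore:
    def test_mean_zero_std_one(self):
        x = np.random.default_rng(4).uniform(size=(3, 200))
        out = ht.zscore(tm(x, stage="dff"))
        assert out.values.mean(axis=1) == pytest.approx(np.zeros(3), abs=1e-12)
        assert out.values.std(axis=1, ddof=1) == pytest.approx(np.ones(3))
        assert out.stage == "zscored"

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(5).uniform(size=(2, 64))
        z1 = ht.zscore(tm(x, stage="dff")).values
        z2 = ht.zscore(tm(a * x + b, stage="dff")).values
        assert z2 == pytest.approx(z1)

    def test_two_point_trace(self):
        out = ht.zscore(tm([[1.0, 3.0]], stage="dff"))
        assert out.values[0] == pytest.approx([-np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_zero_variance_names_cell(self):
        vals = np.vstack([np.random.default_rng(6).uniform(size=20),
                          np.full(20, 2.0)])
        with pytest.raises(ValueError, match="cell 1"):
            ht.zscore(tm(vals, stage="dff"))


class TestTraceCsv:
    def test_round_trip_preserves_stage_and_values(self, tmp_path):
        vals = np.random.default_rng(7).uniform(size=(3, 40))
        traces = tm(vals, stage="dff")
        p = tmp_path / "traces.csv"
        traces.to_csv(p)
        back = ht.TraceMatrix.from_csv(p)
        assert back.stage == "dff" and back.frame_rate == 10.0
        assert back.values == pytest.approx(vals)


class TestPipelineInvariances:
    def test_scale_and_offset_invariance_end_to_end(self, small_session):
        """z-scored output is identical under movie -> c*movie + b."""
        cfg, _, movie, truth = small_session
        rois = ht.compute_halo(ht.RoiSet(truth.footprints))

        def run(frames):
            m = ht.MovieStack(frames, frame_rate=cfg.imaging_rate)
            roi_tr, halo_tr = ht.extract_traces(m, rois)
            return ht.process_traces(roi_tr, halo_tr).values

        z1 = run(movie.frames)
        z2 = run(2.7 * movie.frames + 40.0)
        assert z2 == pytest.approx(z1, abs=1e-8)

    def test_bleach_removal(self):
        """Bleach-on vs bleach-off z-scored traces agree to < 0.1 z."""
        def run(bleach_tau, seed=21):
            s = ht.run_mating_session(seed=seed, n_cells=6,
                                      image_shape=(48, 48), noise_sd=0.0,
                                      bleach_tau=bleach_tau)
            return s.zscored.values
        diff = np.abs(run(600.0) - run(None)).max()
        assert diff < 0.1

    def test_modulated_cells_rank_above_unmodulated(self):
        """Cells rate-modulated in an epoch score higher z there (>=95%)."""
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            mod = {"intromission": np.array([3.0, 3.0, 1.0, 1.0])}
            s = ht.run_mating_session(seed=seed, n_cells=4,
                                      image_shape=(48, 48),
                                      modulation_map=mod)
            stats = s.epoch_statistics()
            m = stats.means["intromission"].to_numpy()
            hits += m[:2].mean() > m[2:].mean()
        assert hits / n_runs >= 0.95
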