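"""Generator correctness: event logs, spike statistics, forward model."""

import numpy as np
import pytest
from scipy import stats

from honpipe import synthgen
from honpipe.core import GcampKernel, GroundTruth, ParameterError, SubtypeTemplate, make_bout_table
from honpipe.locomotion import detect_bouts


class TestGenLocomotion:
    def test_zero_bout_rate_gives_still_recording(self):
        speed, bouts = synthgen.gen_locomotion(100, rate=10, bout_rate=0, seed=1)
        assert np.all(speed.values == 0)
        assert len(bouts) == 0

    def test_bout_log_matches_rendered_speed(self):
        speed, bouts = synthgen.gen_locomotion(600, rate=10, bout_rate=1, seed=1)
        assert len(bouts) > 0
        # plateau speed above the locomotion threshold for every bout
        assert (bouts["mean_speed"] > 1.0).all()
        # the logged onset is the first supra-threshold sample of each bout
        detected = detect_bouts(speed, threshold=1.0, min_duration=0.0, merge_gap=0.0)
        np.testing.assert_allclose(detected["onset"], bouts["onset"], atol=1e-9)
        np.testing.assert_allclose(detected["offset"], bouts["offset"], atol=1e-9)

    def test_refractory_gap_respected(self):
        speed, bouts = synthgen.gen_locomotion(3000, rate=10, bout_rate=2, refractory=20, seed=2)
        gaps = bouts["onset"].to_numpy()[1:] - bouts["offset"].to_numpy()[:-1]
        assert (gaps >= 19.0).all()

    def test_deterministic_under_seed(self):
        a = synthgen.gen_locomotion(300, rate=10, bout_rate=1, seed=5)
        b = synthgen.gen_locomotion(300, rate=10, bout_rate=1, seed=5)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1].equals(b[1])

    @pytest.mark.parametrize("duration,rate", [(-1, 10), (100, 0)])
    def test_invalid_parameters(self, duration, rate):
        with pytest.raises(ParameterError):
            synthgen.gen_locomotion(duration, rate=rate, bout_rate=1)


class TestGenStimuli:
    def test_block_structure_and_counts(self):
        stim = synthgen.gen_stimuli(3, modalities=("a", "b", "c", "null"), seed=0)
        assert len(stim) == 12
        assert (stim["modality"].value_counts() == 3).all()

    def test_interval_bounds(self):
        stim = synthgen.gen_stimuli(10, base_interval=15, jitter_max=15, seed=1)
        iv = np.diff(np.concatenate([[0.0], stim["time"].to_numpy()]))
        assert (iv >= 15.1 - 1e-12).all() and (iv <= 30.0).all()

    def test_deterministic_under_seed(self):
        a = synthgen.gen_stimuli(4, seed=3)
        b = synthgen.gen_stimuli(4, seed=3)
        assert a.equals(b)


class TestGenSpikes:
    def test_invalid_mixture_rejected(self):
        bouts = make_bout_table([10], [15])
        with pytest.raises(ParameterError):
            synthgen.gen_spikes(bouts, None, duration=100, n_cells=5, proportions={"ON": 0.5}, seed=0)

    def test_non_mod_is_homogeneous_poisson(self):
        """Peri-bout spike counts of a non-modulated cell pass a chi-square
        test against the homogeneous Poisson expectation."""
        speed, bouts = synthgen.gen_locomotion(4000, rate=10, bout_rate=1, seed=3)
        gt = synthgen.gen_spikes(
            bouts, None, duration=4000, n_cells=30, proportions={"non_mod": 1.0}, seed=4
        )
        rate = gt.templates["non_mod"].baseline_rate
        win = 10.0  # seconds around each bout onset
        counts = []
        for spikes in gt.spike_trains:
            for on in bouts["onset"]:
                counts.append(np.sum((spikes >= on - win / 2) & (spikes < on + win / 2)))
        counts = np.array(counts)
        mu = rate * win
        # bin the Poisson distribution and chi-square observed vs expected
        edges = np.arange(int(mu - 4 * np.sqrt(mu)), int(mu + 4 * np.sqrt(mu)))
        obs = np.histogram(counts, bins=edges)[0]
        exp = stats.poisson(mu).pmf(edges[:-1]) * counts.size
        keep = exp > 5
        chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
        p = stats.chi2(keep.sum() - 1).sf(chi2)
        assert p > 0.01

    def test_on_cells_reach_peak_rate_in_bouts(self):
        """Mean in-bout firing of ON cells matches the template peak rate
        within Poisson counting error over >100 bouts."""
        speed, bouts = synthgen.gen_locomotion(9000, rate=10, bout_rate=1, seed=5)
        assert len(bouts) >= 100
        gt = synthgen.gen_spikes(bouts, None, duration=9000, n_cells=10, proportions={"ON": 1.0}, seed=6)
        total, tspan = 0, 0.0
        for spikes in gt.spike_trains:
            for _, b in bouts.iterrows():
                total += np.sum((spikes >= b.onset + 0.5) & (spikes < b.offset))
                tspan += b.offset - b.onset - 0.5
        est = total / tspan
        peak = gt.templates["ON"].peak_rate
        assert abs(est - peak) < 4 * np.sqrt(total) / tspan

    def test_zero_sensory_gain_leaves_baseline(self):
        stim = synthgen.gen_stimuli(20, seed=1)
        dur = float(stim["time"].max() + 30)
        gt = synthgen.gen_spikes(
            make_bout_table([], []), stim, duration=dur, n_cells=20,
            proportions={"non_mod": 1.0},
            sensory_gain={m: 0.0 for m in ("visual", "tactile", "olfactory_food")},
            p_responsive=1.0, seed=2,
        )
        base = gt.templates["non_mod"].baseline_rate
        post = sum(
            np.sum((sp >= t) & (sp < t + 2)) for sp in gt.spike_trains for t in stim["time"]
        )
        n_win = 20 * len(stim)
        assert abs(post / (n_win * 2.0) - base) < 4 * np.sqrt(post) / (n_win * 2.0)

    def test_null_stimulus_never_flagged_responsive(self):
        stim = synthgen.gen_stimuli(5, seed=1)
        gt = synthgen.gen_spikes(
            make_bout_table([], []), stim, duration=700, n_cells=10, p_responsive=1.0, seed=2
        )
        assert "null" not in gt.sensory_responsive.columns


class TestKernelAndFluor:
    def test_kernel_peaks_after_report_delay(self):
        k = GcampKernel()
        t = np.linspace(0, 10, 20001)
        assert t[np.argmax(k.evaluate(t))] >= k.report_delay
        np.testing.assert_allclose(t[np.argmax(k.evaluate(t))], k.peak_time, atol=1e-3)

    def _single_cell_gt(self, spikes, kernel=None, noise=0.0, bleach=np.inf, dur=60.0):
        return GroundTruth(
            cell_labels=["ON"], spike_trains=[np.asarray(spikes, float)],
            true_onsets=np.zeros((1, 0)), kernel=kernel or GcampKernel(),
            noise_sd=noise, bleach_tau=bleach, neuropil_gain=0.0, duration=dur,
        )

    def test_no_spikes_no_noise_gives_flat_baseline(self):
        fl = synthgen.spikes_to_fluor(self._single_cell_gt([]), rate=10, f_base=50.0)
        np.testing.assert_allclose(fl.traces.values, 50.0)

    def test_single_spike_peaks_after_delay(self):
        fl = synthgen.spikes_to_fluor(self._single_cell_gt([10.0]), rate=100)
        t_peak = np.argmax(fl.traces.values[0]) / 100
        assert t_peak >= 10.0 + GcampKernel().report_delay
        np.testing.assert_allclose(t_peak, 10.0 + GcampKernel().peak_time, atol=0.02)

    def test_amplitude_linearity(self):
        """Doubling the per-spike amplitude doubles the deviation from the
        bleach-only baseline (convolution is linear)."""
        spikes = [5.0, 8.0, 8.3]
        f1 = synthgen.spikes_to_fluor(
            self._single_cell_gt(spikes, GcampKernel(amplitude_per_spike=0.1)), rate=20, f_base=100
        )
        f2 = synthgen.spikes_to_fluor(
            self._single_cell_gt(spikes, GcampKernel(amplitude_per_spike=0.2)), rate=20, f_base=100
        )
        np.testing.assert_allclose(f2.traces.values - 100, 2 * (f1.traces.values - 100), atol=1e-9)

    def test_peak_fluorescence_linear_in_firing_rate(self):
        """Constant-rate trains at 1-15 Hz: noiseless peak fluorescence is
        monotone and nearly linear in rate (R^2 >= 0.95)."""
        rates = np.array([1, 3, 6, 9, 12, 15], float)
        peaks = []
        for r in rates:
            spikes = np.arange(0.0, 20.0, 1.0 / r)  # regular train, 20 s
            fl = synthgen.spikes_to_fluor(self._single_cell_gt(spikes, dur=30.0), rate=50)
            peaks.append(fl.traces.values[0].max())
        peaks = np.array(peaks)
        assert np.all(np.diff(peaks) > 0)
        r2 = stats.linregress(rates, peaks).rvalue ** 2
        assert r2 >= 0.95


class TestRenderStack:
    def test_single_cell_roundtrip(self, rng):
        from honpipe.core import TraceMatrix

        tr = TraceMatrix(100 + 5 * rng.standard_normal((1, 40)), rate=10)
        stack, rois = synthgen.render_stack(tr, frame_shape=(32, 32), noise_sd=0.0)
        roi_mean = stack[:, rois.masks[0]].mean(axis=1)
        np.testing.assert_allclose(roi_mean, tr.values[0])

    def test_two_cells_map_to_their_own_traces(self, rng):
        from honpipe.core import TraceMatrix

        vals = 100 + 5 * rng.standard_normal((2, 60))
        tr = TraceMatrix(vals, rate=10)
        stack, rois = synthgen.render_stack(tr, frame_shape=(64, 64), noise_sd=0.1, seed=1)
        for i in range(2):
            m = stack[:, rois.masks[i]].mean(axis=1)
            own = np.corrcoef(m, vals[i])[0, 1]
            other = np.corrcoef(m, vals[1 - i])[0, 1]
            assert own > 0.99 and own > other

    def test_background_carries_common_signal(self, rng):
        from honpipe.core import TraceMatrix

        common = rng.standard_normal(30)
        tr = TraceMatrix(np.full((1, 30), 100.0), rate=10)
        stack, rois = synthgen.render_stack(tr, frame_shape=(32, 32), neuropil_level=common)
        bg = ~rois.masks.any(axis=0)
        assert np.allclose(stack[:, bg] - common[:, None], 0.0)

    def test_overcrowded_layout_rejected(self):
        from honpipe.core import TraceMatrix

        tr = TraceMatrix(np.zeros((100, 5)), rate=10)
        with pytest.raises(synthgen.LayoutError):
            synthgen.render_stack(tr, frame_shape=(32, 32), roi_radius=6)

    def test_session_determinism(self):
        a = synthgen.simulate_session(duration=150, n_cells=5, seed=9)
        b = synthgen.simulate_session(duration=150, n_cells=5, seed=9)
        np.testing.assert_array_equal(a.traces.values, b.traces.values)
        assert a.bouts.equals(b.bouts)
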