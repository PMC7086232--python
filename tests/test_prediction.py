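"""Movement prediction: predictor-cell selection, online variable,
decoding with permutation chance, ROC time courses."""

import numpy as np
import pandas as pd
import pytest

from honpipe.core import ParameterError, PeriEventTensor, TraceMatrix, make_bout_table
from honpipe.prediction import (
    DecoderConfig,
    detection_metrics,
    draw_epochs,
    prediction_variable,
    roc_auc_timecourse,
    select_predictor_cells,
    svm_decode,
)


def feature_tensors(rng, n_cells=10, n_epochs=16, n_samples=200, separation=0.0):
    """Movement/stationary epoch tensors with optional class separation."""
    mov = rng.standard_normal((n_cells, n_epochs, n_samples)) + separation
    sta = rng.standard_normal((n_cells, n_epochs, n_samples))
    w = (-10.0, 10.0)
    return (
        PeriEventTensor(mov, rate=10, window=w, alignment="bout_onset"),
        PeriEventTensor(sta, rate=10, window=w, alignment="stationary"),
    )


class TestSelectPredictorCells:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "subtype": ["ON", "ON", "OFF", "up_down"],
                "onset_time": [-2.0, 1.0, -3.0, -2.5],
                "active_move_fraction": [0.95, 0.99, 0.95, 0.99],
            }
        )

    def test_only_early_movement_locked_on_cells(self):
        np.testing.assert_array_equal(select_predictor_cells(self.table()), [0])

    def test_impossible_fraction_gives_empty(self):
        assert select_predictor_cells(self.table(), move_fraction_min=1.01).size == 0

    def test_up_down_optionally_included(self):
        idx = select_predictor_cells(self.table(), include_up_down=True)
        np.testing.assert_array_equal(idx, [0, 3])


class TestPredictionVariable:
    def test_constant_cell_never_crosses(self):
        tm = TraceMatrix(np.zeros((1, 100)), rate=10, kind="z")
        var, crossings, thr = prediction_variable(tm, [0])
        assert crossings.size == 0

    def test_step_crossing_within_trailing_window(self, rng):
        x = 0.1 * rng.standard_normal((1, 300))
        x[0, 150:170] += 3.0  # sparse excursion, as for real movement
        tm = TraceMatrix(x, rate=10, kind="z")
        _, crossings, _ = prediction_variable(tm, [0], n_frames=3)
        assert crossings.size >= 1
        assert 15.0 <= crossings[0] <= 15.0 + 3 / 10

    def test_empty_cell_set_rejected(self):
        tm = TraceMatrix(np.zeros((1, 100)), rate=10, kind="z")
        with pytest.raises(ParameterError):
            prediction_variable(tm, [])


class TestDetectionMetrics:
    def test_perfect_indicator(self):
        rate = 10.0
        bouts = make_bout_table([20.0, 60.0], [30.0, 70.0])
        times = np.arange(1000) / rate
        move = np.zeros(1000, bool)
        for _, b in bouts.iterrows():
            move |= (times >= b.onset - 3) & (times < b.offset + 3)
        out = detection_metrics(move, rate, bouts)
        assert out["frame_detection_rate"] == 1.0
        assert out["false_positive_rate"] == 0.0

    def test_always_on_has_unit_false_positive_rate(self):
        bouts = make_bout_table([20.0], [30.0])
        out = detection_metrics(np.ones(500, bool), 10.0, bouts)
        assert out["frame_detection_rate"] == 1.0
        assert out["false_positive_rate"] == 1.0

    def test_random_variable_detection_matches_duty_cycle(self, rng):
        duty = 0.3
        bouts = make_bout_table([100.0], [140.0])
        supra = rng.random(4000) < duty
        out = detection_metrics(supra, 10.0, bouts)
        assert out["frame_detection_rate"] == pytest.approx(duty, abs=0.07)
        assert out["false_positive_rate"] == pytest.approx(duty, abs=0.05)

    def test_pre_onset_crossing_counts_as_predicted_bout(self):
        rate = 10.0
        bouts = make_bout_table([50.0], [60.0])
        supra = np.zeros(1000, bool)
        supra[480:] = True  # crossing at 48 s, 2 s before onset
        out = detection_metrics(supra, rate, bouts)
        assert out["n_bouts_predicted"] == 1
        assert out["bout_lead_times"][0] == pytest.approx(2.0)

    def test_no_bouts_returns_none(self):
        assert detection_metrics(np.zeros(10, bool), 10.0, make_bout_table([], [])) is None


class TestSvmDecode:
    def test_separable_features_decode_perfectly(self, rng):
        mov, sta = feature_tensors(rng, separation=5.0)
        res = svm_decode(mov, sta, permute=False, seed=0, eval_windows=[(-1.0, 2.0)])
        assert res.accuracy[0] == 1.0

    def test_identical_class_distributions_at_chance(self, rng):
        mov, sta = feature_tensors(rng, n_epochs=30, separation=0.0)
        res = svm_decode(mov, sta, permute=False, seed=0, eval_windows=[(-1.0, 2.0)])
        assert abs(res.accuracy[0] - 0.5) < 0.12

    def test_permuted_labels_at_chance_even_when_separable(self, rng):
        """Label permutation nulls out even perfectly separable data:
        the 80-analysis mean sits within 5 points of 50 %."""
        mov, sta = feature_tensors(rng, n_epochs=30, separation=5.0)
        res = svm_decode(mov, sta, permute=True, seed=1, eval_windows=[(-1.0, 2.0)])
        assert abs(res.accuracy[0] - 0.5) < 0.05

    def test_class_imbalance_rejected(self, rng):
        mov, sta = feature_tensors(rng)
        sta = PeriEventTensor(sta.values[:, :10], rate=10, window=sta.window)
        with pytest.raises(ParameterError):
            svm_decode(mov, sta)

    def test_fewer_epochs_than_folds_rejected(self, rng):
        mov, sta = feature_tensors(rng, n_epochs=5)
        with pytest.raises(ParameterError):
            svm_decode(mov, sta)

    def test_deterministic_given_seed(self, rng):
        mov, sta = feature_tensors(rng, separation=0.5)
        a = svm_decode(mov, sta, seed=3, eval_windows=[(-1.0, 2.0)])
        b = svm_decode(mov, sta, seed=3, eval_windows=[(-1.0, 2.0)])
        np.testing.assert_array_equal(a.accuracy, b.accuracy)


class TestDrawEpochs:
    def test_stationary_epochs_avoid_locomotion(self, medium_session, medium_z):
        cfg = DecoderConfig()
        mov, sta = draw_epochs(medium_z, medium_session.bouts, cfg, seed=0)
        assert mov.values.shape[1] == sta.values.shape[1] >= cfg.n_folds
        # movement epochs carry more ON-cell activity at their centre
        # than the matched stationary epochs
        labels = np.array(medium_session.ground_truth.cell_labels)
        on_cells = labels == "ON"
        t = mov.rel_times
        mid = (t >= 0) & (t < 2)
        m = np.nanmean(mov.values[on_cells][:, :, mid])
        s = np.nanmean(sta.values[on_cells][:, :, mid])
        assert m > s + 0.5

    def test_on_cells_carry_the_pre_onset_information(self, medium_session, medium_z):
        """Only ON cells fire before bout onset in the generator, so
        pre-onset decoding from ON cells beats OFF cells and chance;
        after onset every modulated subtype decodes above chance."""
        labels = np.array(medium_session.ground_truth.cell_labels)
        cfg = DecoderConfig()
        mov, sta = draw_epochs(medium_z, medium_session.bouts, cfg, seed=0)

        def subset(t, cells):
            return PeriEventTensor(t.values[cells], rate=t.rate, window=t.window, truncated=t.truncated)

        acc = {}
        for lab in ("ON", "OFF", "up_down", "down_up"):
            cells = np.flatnonzero(labels == lab)
            pre = svm_decode(subset(mov, cells), subset(sta, cells), cfg, seed=1,
                             eval_windows=[(-cfg.window, cfg.window)]).accuracy[0]
            post = svm_decode(subset(mov, cells), subset(sta, cells), cfg, seed=2,
                              eval_windows=[(1.0, cfg.window)]).accuracy[0]
            acc[lab] = (pre, post)
        assert acc["ON"][0] > acc["OFF"][0]
        assert acc["ON"][0] > 0.65
        assert all(post > 0.7 for _, post in acc.values())

    def test_real_decoding_beats_chance_pre_onset(self, medium_session, medium_z):
        cfg = DecoderConfig()
        mov, sta = draw_epochs(medium_z, medium_session.bouts, cfg, seed=0)
        win = [(-cfg.window, cfg.window)]
        real = svm_decode(mov, sta, cfg, permute=False, seed=1, eval_windows=win)
        chance = svm_decode(mov, sta, cfg, permute=True, seed=2, eval_windows=win)
        assert real.accuracy[0] > chance.accuracy[0] + 0.15
        assert abs(chance.accuracy[0] - 0.5) < 0.1


class TestRocAucTimecourse:
    def _tensor(self, values):
        return PeriEventTensor(values, rate=10, window=(0.0, values.shape[2] / 10), alignment="stimulus")

    def test_outcome_indicator_gives_unit_auc(self, rng):
        moved = np.array([True] * 5 + [False] * 5)
        vals = np.broadcast_to(moved[None, :, None].astype(float), (3, 10, 20)).copy()
        df = roc_auc_timecourse(self._tensor(vals), moved, ["ON"] * 3)
        np.testing.assert_allclose(df["ON"], 1.0)

    def test_negated_predictor_mirrors_auc(self, rng):
        vals = rng.standard_normal((4, 20, 15))
        moved = rng.random(20) < 0.5
        moved[:2], moved[-2:] = True, False
        a = roc_auc_timecourse(self._tensor(vals), moved, ["ON"] * 4)
        b = roc_auc_timecourse(self._tensor(-vals), moved, ["ON"] * 4)
        np.testing.assert_allclose(a["ON"].to_numpy() + b["ON"].to_numpy(), 1.0, atol=1e-12)

    def test_independent_predictor_near_half_at_200_trials(self, rng):
        vals = rng.standard_normal((5, 200, 10))
        moved = np.arange(200) < 100
        df = roc_auc_timecourse(self._tensor(vals), moved, ["ON"] * 5)
        assert np.all((df["ON"] >= 0.4) & (df["ON"] <= 0.6))

    def test_censoring_removes_post_onset_movement_trials(self, rng):
        vals = rng.standard_normal((2, 10, 30))
        moved = np.array([True] * 5 + [False] * 5)
        censor = np.array([0.5] * 5 + [np.nan] * 5)
        df = roc_auc_timecourse(
            self._tensor(vals), moved, ["ON"] * 2, censor_times=censor, censor_post_onset=True
        )
        # all movement trials censored from 0.5 s on -> one-class bins are NaN
        assert df.loc[df["time"] >= 0.5, "ON"].isna().all()
        assert df.loc[df["time"] < 0.5, "ON"].notna().all()

    def test_too_few_trials_rejected(self, rng):
        vals = rng.standard_normal((2, 3, 5))
        with pytest.raises(ParameterError):
            roc_auc_timecourse(self._tensor(vals), np.array([True, True, False]), ["ON"] * 2)
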