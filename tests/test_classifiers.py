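"""Thresholding, featurization, SVMs, and onset detection."""

import numpy as np
import pytest

import nirsbci as nb
from nirsbci.classifiers import n_samples_in

from conftest import make_recording

RATE = 6.25


def _diff_recording(diff, rate=RATE):
    """Recording whose L-R HbO difference equals ``diff`` (R all zero)."""
    n = len(diff)
    return make_recording(
        {"L": (np.asarray(diff, float), np.zeros(n)),
         "R": (np.zeros(n), np.zeros(n))},
        rate=rate,
    )


class TestDiffSeries:
    def test_identical_channels_give_zero(self):
        x = np.arange(5.0)
        rec = make_recording({"L": (x, x), "R": (x, x)})
        np.testing.assert_array_equal(nb.diff_series(rec), 0)

    def test_common_offset_cancels(self):
        rng = np.random.default_rng(0)
        l = rng.normal(0, 1, 20)
        r = rng.normal(0, 1, 20)
        rec1 = make_recording({"L": (l, l), "R": (r, r)})
        rec2 = make_recording({"L": (l + 5.0, l), "R": (r + 5.0, r)})
        np.testing.assert_allclose(nb.diff_series(rec1),
                                   nb.diff_series(rec2), atol=1e-12)

    def test_elementwise_arithmetic(self):
        rec = make_recording({
            "L": (np.array([1.0, 2.0]), np.zeros(2)),
            "R": (np.array([0.5, 0.5]), np.zeros(2)),
        })
        np.testing.assert_array_equal(nb.diff_series(rec), [0.5, 1.5])

    def test_missing_channel_error(self):
        rec = make_recording({"L": (np.zeros(5), np.zeros(5))})
        with pytest.raises(KeyError, match="R"):
            nb.diff_series(rec)


class TestThreshold:
    def test_baseline_is_mean_of_rest_trial_maxima(self):
        # rest trials hold diff maxima 0.3 and 0.5 -> baseline 0.4
        diff = np.zeros(40)
        diff[2] = 0.3
        diff[12] = 0.5
        rec = _diff_recording(diff, rate=1.0)
        trials = nb.TrialTable([nb.Trial(0, 10, "rest"),
                                nb.Trial(10, 10, "rest"),
                                nb.Trial(20, 10, "task")])
        model = nb.fit_threshold(rec, trials)
        assert model.baseline == pytest.approx(0.4)

    def test_single_constant_rest_trial(self):
        rec = _diff_recording(np.full(10, 0.2), rate=1.0)
        trials = nb.TrialTable([nb.Trial(0, 10, "rest")])
        assert nb.fit_threshold(rec, trials).baseline == pytest.approx(0.2)

    def test_all_zero_diff_gives_zero_baseline(self):
        rec = _diff_recording(np.zeros(10), rate=1.0)
        trials = nb.TrialTable([nb.Trial(0, 10, "rest")])
        assert nb.fit_threshold(rec, trials).baseline == 0.0

    def test_no_rest_trials_error(self):
        rec = _diff_recording(np.zeros(10), rate=1.0)
        with pytest.raises(ValueError, match="rest"):
            nb.fit_threshold(rec, nb.TrialTable([nb.Trial(0, 10, "task")]))

    def test_strict_exceedance_rule(self):
        model = nb.ThresholdModel(baseline=0.4)
        rec = _diff_recording(np.array([0.2, 0.5]), rate=1.0)
        pred = nb.predict_threshold(model, rec)
        assert list(pred.labels) == ["rest", "task"]
        # ties are rest
        rec_tie = _diff_recording(np.full(4, 0.4), rate=1.0)
        assert all(nb.predict_threshold(model, rec_tie).labels == "rest")

    def test_negative_baseline_flags_positive_diff(self):
        model = nb.ThresholdModel(baseline=-1.0)
        rec = _diff_recording(np.full(4, 0.1), rate=1.0)
        assert all(nb.predict_threshold(model, rec).labels == "task")


class TestDetectOnset:
    def _pred(self, first_task_idx, n=100, rate=RATE):
        labels = np.array(["rest"] * n, object)
        if first_task_idx is not None:
            labels[first_task_idx:] = "task"
        return nb.PredictionSeries(times=np.arange(n) / rate, labels=labels)

    def test_latency_in_seconds(self):
        pred = self._pred(20)
        assert nb.detect_onset(pred, (0.0, 30.0)) == pytest.approx(3.2)

    def test_no_crossing_returns_none(self):
        assert nb.detect_onset(self._pred(None), (0.0, 10.0)) is None

    def test_crossing_at_onset_sample(self):
        assert nb.detect_onset(self._pred(0), (0.0, 10.0)) == 0.0

    def test_malformed_span_rejected(self):
        with pytest.raises(ValueError):
            nb.detect_onset(self._pred(0), (0.0, -5.0))


class TestFeaturize:
    def test_pointwise_sample_count_30s_trial(self):
        n = int(35 * RATE) + 1
        rec = make_recording({"L": (np.zeros(n), np.zeros(n)),
                              "R": (np.zeros(n), np.zeros(n))})
        trials = nb.TrialTable([nb.Trial(0.0, 30.0, "task")])
        samples = nb.featurize_pointwise(rec, trials)
        assert samples.n == 187  # floor(30 x 6.25)
        assert samples.design.shape[1] == 4

    def test_pointwise_empty_trials_distinct_from_error(self):
        rec = make_recording({"L": (np.zeros(10), np.zeros(10)),
                              "R": (np.zeros(10), np.zeros(10))})
        samples = nb.featurize_pointwise(rec, nb.TrialTable([]))
        assert samples.n == 0

    def test_pointwise_feature_order(self):
        rec = make_recording({
            "L": (np.array([1.0, 0]), np.array([2.0, 0])),
            "R": (np.array([3.0, 0]), np.array([4.0, 0])),
        })
        trials = nb.TrialTable([nb.Trial(0.0, 1 / RATE, "task")])
        samples = nb.featurize_pointwise(rec, trials)
        np.testing.assert_array_equal(samples.design[0], [1.0, 2.0, 3.0, 4.0])

    def test_window_dim_default_geometry(self):
        """30 s window, 2 channels x 2 chromophores -> 187*4 = 748."""
        n = int(35 * RATE) + 1
        rec = make_recording({"L": (np.zeros(n), np.zeros(n)),
                              "R": (np.zeros(n), np.zeros(n))})
        trials = nb.TrialTable([nb.Trial(0.0, 30.0, "task")])
        samples = nb.featurize_window(rec, trials, 30.0)
        assert samples.design.shape == (1, 748)

    def test_window_dim_eight_signal_montage_is_4000(self):
        """40 s at 6.25 Hz over 8 optode signals x 2 chromophores."""
        n = int(45 * RATE) + 1
        rec = make_recording({
            f"C{i}": (np.zeros(n), np.zeros(n)) for i in range(8)
        })
        trials = nb.TrialTable([nb.Trial(0.0, 40.0, "task")])
        samples = nb.featurize_window(rec, trials, 40.0)
        assert samples.design.shape == (1, 4000)

    def test_window_zero_length_rejected(self):
        rec = make_recording({"L": (np.zeros(10), np.zeros(10))})
        with pytest.raises(ValueError):
            nb.featurize_window(rec, nb.TrialTable([]), 0.0)

    def test_short_trial_errors_unless_truncate(self):
        n = int(70 * RATE)
        rec = make_recording({"L": (np.zeros(n), np.zeros(n))})
        trials = nb.TrialTable([nb.Trial(0.0, 20.0, "task"),
                                nb.Trial(30.0, 30.0, "rest")])
        with pytest.raises(ValueError, match="shorter"):
            nb.featurize_window(rec, trials, 30.0)
        samples = nb.featurize_window(rec, trials, 30.0, truncate=True)
        assert samples.design.shape[1] == n_samples_in(20.0, RATE) * 2

    def test_trial_exceeding_recording_rejected(self):
        rec = make_recording({"L": (np.zeros(10), np.zeros(10))})
        with pytest.raises(ValueError, match="exceeds"):
            nb.featurize_pointwise(
                rec, nb.TrialTable([nb.Trial(0.0, 60.0, "task")]))


def _separable_samples(n=40, d=4, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, d))
    y = np.array(["task" if i % 2 else "rest" for i in range(n)], object)
    X[y == "task", 0] += gap
    import pandas as pd

    return nb.LabeledSamples(design=X, labels=y,
                             meta=pd.DataFrame(index=range(n)))


class TestSvm:
    def test_two_point_toy_separates(self):
        import pandas as pd

        samples = nb.LabeledSamples(
            design=np.array([[0.0, 0.0], [1.0, 1.0]]),
            labels=np.array(["rest", "task"], object),
            meta=pd.DataFrame(index=range(2)),
        )
        model = nb.fit_svm(samples, "pointwise", channels=["L"])
        np.testing.assert_array_equal(
            model.svm.predict(samples.design), samples.labels)

    def test_single_class_rejected(self):
        import pandas as pd

        samples = nb.LabeledSamples(
            design=np.zeros((3, 2)),
            labels=np.array(["rest"] * 3, object),
            meta=pd.DataFrame(index=range(3)),
        )
        with pytest.raises(ValueError, match="both classes"):
            nb.fit_svm(samples, "pointwise", channels=["L"])

    def test_duplicated_rows_leave_decision_unchanged(self):
        """Regression check on a well-separated set (box constraints stay
        inactive, so duplicating both classes equally is a no-op; with
        bound support vectors duplication doubles the effective C)."""
        import pandas as pd

        X = np.array([[0, 0], [0.2, 0.1], [-0.1, 0.2],
                      [3, 3], [3.2, 2.9], [2.9, 3.1]], float)
        y = np.array(["rest"] * 3 + ["task"] * 3, object)
        samples = nb.LabeledSamples(X, y, pd.DataFrame(index=range(6)))
        dup = nb.LabeledSamples(
            design=np.vstack([samples.design, samples.design]),
            labels=np.concatenate([samples.labels, samples.labels]),
            meta=pd.DataFrame(index=range(2 * samples.n)),
        )
        m1 = nb.fit_svm(samples, "pointwise", channels=["L", "R"])
        m2 = nb.fit_svm(dup, "pointwise", channels=["L", "R"])
        np.testing.assert_allclose(m1.svm.weights, m2.svm.weights, atol=1e-6)
        assert m1.svm.intercept == pytest.approx(m2.svm.intercept, abs=1e-6)

    def test_permuted_labels_near_chance(self):
        """Random labels on pure-noise features: held-out accuracy ~0.5."""
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            import pandas as pd

            X = rng.normal(0, 1, (120, 4))
            y = np.array(["task", "rest"] * 60, object)
            rng.shuffle(y)
            train = nb.LabeledSamples(X[:80], y[:80],
                                      pd.DataFrame(index=range(80)))
            model = nb.fit_svm(train, "pointwise", channels=["L", "R"])
            accs.append(np.mean(model.svm.predict(X[80:]) == y[80:]))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_fit_deterministic(self):
        samples = _separable_samples(seed=1)
        m1 = nb.fit_svm(samples, "pointwise", channels=["L", "R"])
        m2 = nb.fit_svm(samples, "pointwise", channels=["L", "R"])
        np.testing.assert_array_equal(m1.svm.weights, m2.svm.weights)


class TestPredictSvm:
    def test_noise_free_training_recording_scores_high(self):
        """Separable noise-free simulation: only the hemodynamic rise and
        decay around trial edges is ambiguous, so with 60 s trials the
        pointwise SVM recovers >= 95% of training labels."""
        table = nb.generate_paradigm("training_block", 4, 4, 60.0, 60.0,
                                     seed=2)
        ds = nb.generate_participant({"b": table},
                                     noise=nb.NoiseParams.silent(), seed=3)
        rec = ds.recordings["b"]
        model = nb.fit_model("svm-point", rec, table)
        pred = nb.predict_svm(model, rec, table)
        samples = nb.featurize_pointwise(rec, table)
        acc = np.mean(pred.labels == samples.labels)
        assert acc >= 0.95

    def test_geometry_mismatch_error(self, clean_participant,
                                     training_table):
        rec = clean_participant.recordings["restricted"]
        model = nb.fit_model("svm-point", rec, training_table)
        n = rec.n_samples
        rec3 = make_recording({
            ch: (np.zeros(n), np.zeros(n)) for ch in ("A", "B", "C")
        })
        with pytest.raises(ValueError, match="channels"):
            nb.predict_svm(model, rec3)

    def test_empty_trial_table_empty_predictions(self, clean_participant,
                                                 training_table):
        rec = clean_participant.recordings["restricted"]
        model = nb.fit_model("svm-window", rec, training_table)
        pred = nb.predict_svm(model, rec, nb.TrialTable([]))
        assert len(pred.times) == 0

    def test_window_model_748_features_18_rows(self, clean_participant,
                                               training_table):
        rec = clean_participant.recordings["restricted"]
        samples = nb.featurize_window(rec, training_table, 30.0)
        assert samples.design.shape == (18, 748)
        model = nb.fit_svm(samples, "window", rec.channels, rate=rec.rate,
                           window_duration=30.0)
        assert model.expected_dim == 748
        p1 = nb.predict_svm(model, rec, training_table)
        p2 = nb.predict_svm(model, rec, training_table)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_all_models_emit_prediction_series(self, clean_participant,
                                               training_table):
        """Interface conformance: one evaluation path consumes all three."""
        rec = clean_participant.recordings["restricted"]
        for kind in ("threshold", "svm-point", "svm-window"):
            model = nb.fit_model(kind, rec, training_table)
            pred = nb.predict_model(model, rec, training_table)
            assert isinstance(pred, nb.PredictionSeries)
            assert set(pred.labels) <= {"task", "rest"}

    def test_threshold_invariant_to_common_offset_not_scale(
            self, noisy_participant, training_table):
        # noisy world: nonzero baseline, so rescaling moves labels
        rec = noisy_participant.recordings["restricted"]
        model = nb.fit_model("threshold", rec, training_table)
        shifted = rec.copy()
        for ch in shifted.channels:
            shifted.series[ch]["HbO"] = shifted.series[ch]["HbO"] + 7.0
        np.testing.assert_array_equal(
            nb.predict_threshold(model, rec).labels,
            nb.predict_threshold(model, shifted).labels,
        )
        scaled = rec.copy()
        for ch in scaled.channels:
            scaled.series[ch]["HbO"] = scaled.series[ch]["HbO"] * 0.1
        assert not np.array_equal(
            nb.predict_threshold(model, rec).labels,
            nb.predict_threshold(model, scaled).labels,
        )
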