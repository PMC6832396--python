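"""IMU pipeline: differencing, thresholds, onsets, RMS features, PCA classifier."""

import numpy as np
import pytest

import handpilot as hp
from handpilot import imu
from handpilot.fsm import HandState, MovementClass
from handpilot.synth import IMU_ACTION_CLASS

from conftest import make_burst_stream


def stream_from_matrix(values, timestamps=None):
    """Build an ImuStream from an (n, 6) array (accel then gyro columns)."""
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = np.arange(values.shape[0]) / 47.0
    return hp.ImuStream(timestamps, values[:, :3], values[:, 3:])


def diff_signal(values, dt=1.0 / 47.0):
    values = np.asarray(values, dtype=float)
    ts = np.arange(values.shape[0]) * dt
    return imu.differentiate(stream_from_matrix(values, ts))


class TestDifferentiate:
    def test_constant_channels_give_zero(self):
        d = diff_signal(np.full((10, 6), 3.7))
        assert np.all(d.X == 0.0)
        assert d.X.shape == (9, 6)

    def test_unit_ramp_gives_ones(self):
        vals = np.outer(np.arange(8.0), np.ones(6))
        assert np.all(diff_signal(vals).X == 1.0)

    def test_fixture_matches_hand_computed_differences(self):
        col = np.array([0.0, 1.5, -2.0, 3.25, 3.25, -1.0, 0.5, 2.0, -0.75, 0.25])
        expected = [1.5, -3.5, 5.25, 0.0, -4.25, 1.5, 1.5, -2.75, 1.0]
        d = diff_signal(np.tile(col[:, None], (1, 6)))
        assert d.X[:, 0] == pytest.approx(expected)

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            imu.differentiate(stream_from_matrix(np.zeros((1, 6))))


class TestThresholds:
    def test_symmetric_extremes_give_half_max(self):
        """Extreme differences of +-4.0 on an axis give a threshold of 2.0."""
        d = hp.DiffSignal(np.vstack([[4, 1, 1, 1, 1, 1], [-4, 1, 1, 1, 1, 1]]),
                          np.array([0.0, 1.0]))
        alpha = hp.compute_thresholds(d)
        assert alpha.alpha[0] == pytest.approx(2.0)
        assert alpha.alpha[1] == pytest.approx(0.5)

    def test_all_zero_channel_warns(self):
        X = np.ones((5, 6))
        X[:, 3] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            alpha = hp.compute_thresholds(hp.DiffSignal(X, np.arange(5.0)))
        assert alpha.alpha[3] == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 6))
        alpha = hp.compute_thresholds(hp.DiffSignal(X, np.arange(200.0)))
        # independent oracle: explicit scan over samples and axes
        for i in range(6):
            best = 0.0
            for k in range(200):
                best = max(best, abs(X[k, i]))
            assert alpha.alpha[i] == pytest.approx(best / 2.0)


class TestDetect:
    def test_quiet_stream_has_no_onsets(self):
        rng = np.random.default_rng(0)
        X = 0.01 * rng.normal(size=(500, 6))
        alpha = hp.ActivationThresholds(np.full(6, 1.0))
        assert hp.detect_movement(hp.DiffSignal(X, np.arange(500) / 47.0), alpha) == []

    def test_single_burst_one_onset_at_start(self, imu_config):
        stream, truth = make_burst_stream([2.0], [1], duration=6.0, config=imu_config)
        d = hp.differentiate(stream)
        calib, calib_truth = hp.synth_imu_calibration(imu_config)
        alpha = hp.compute_thresholds(hp.differentiate(calib))
        onsets = hp.detect_movement(d, alpha)
        assert len(onsets) == 1
        # onset within the burst (instruction at 2.0 s, 0.4 s long)
        assert 1.9 <= d.timestamps[onsets[0]] <= 2.5

    def test_two_bursts_two_onsets(self, imu_config):
        stream, _ = make_burst_stream([2.0, 5.0], [1, 2], duration=9.0,
                                      config=imu_config)
        calib, _ = hp.synth_imu_calibration(imu_config)
        alpha = hp.compute_thresholds(hp.differentiate(calib))
        assert len(hp.detect_movement(hp.differentiate(stream), alpha)) == 2


class TestFeature:
    def test_constant_window_rms_is_abs_value(self):
        X = np.full((100, 6), -2.5)
        d = hp.DiffSignal(X, np.arange(100) / 10.0)
        feat = hp.extract_feature(d, 50)
        assert feat.theta == pytest.approx(np.full(6, 2.5))

    def test_small_window_matches_hand_computed_rms(self):
        """At a realized 2 Hz rate the centered window spans 3 samples;
        axis values {3, 4, 5} give RMS sqrt(50/3)."""
        X = np.zeros((7, 6))
        X[:, 0] = [9, 9, 3, 4, 5, 9, 9]
        d = hp.DiffSignal(X, np.arange(7) / 2.0)
        feat = hp.extract_feature(d, 3)
        assert feat.window_samples == 2
        assert feat.theta[0] == pytest.approx(np.sqrt((9 + 16 + 25) / 3))

    def test_window_tracks_realized_rate_with_drops(self):
        """10% dropped samples -> N follows the realized ~42 Hz local rate."""
        cfg = hp.ImuSynthConfig(seed=3, drop_prob=0.1)
        stream, _ = make_burst_stream([3.0], [1], duration=8.0, config=cfg, seed=3)
        d = hp.differentiate(stream)
        k = int(np.searchsorted(d.timestamps, 3.2))
        feat = hp.extract_feature(d, k)
        assert feat.local_rate == pytest.approx(0.9 * 47.0, rel=0.12)
        assert feat.window_samples == round(feat.local_rate)

    def test_decision_lags_onset_by_half_window(self, imu_config):
        """Centered 1 s RMS window -> decision ~0.5 s after the onset."""
        stream, _ = make_burst_stream([2.0], [1], duration=6.0, config=imu_config)
        d = hp.differentiate(stream)
        k = int(np.searchsorted(d.timestamps, 2.1))
        feat = hp.extract_feature(d, k)
        assert feat.decision_time - feat.onset_time == pytest.approx(0.5, abs=0.05)

    def test_truncated_window_deferred_or_warned(self):
        X = np.ones((50, 6))
        d = hp.DiffSignal(X, np.arange(50) / 47.0)
        with pytest.raises(ValueError):
            hp.extract_feature(d, 45)
        with pytest.warns(UserWarning, match="truncated"):
            hp.extract_feature(d, 45, allow_truncated=True)


class TestClassifier:
    @staticmethod
    def clustered_features(n_per_class=10, noise=0.05, seed=5):
        rng = np.random.default_rng(seed)
        c1 = np.array([2.0, 0.1, 0.1, 2.0, 0.1, 0.1])
        c2 = np.array([0.1, 2.0, 0.1, 0.1, 2.0, 0.1])
        feats = np.vstack(
            [c1 + noise * rng.normal(size=(n_per_class, 6)),
             c2 + noise * rng.normal(size=(n_per_class, 6))]
        )
        labels = [1] * n_per_class + [2] * n_per_class
        return feats, labels

    def test_projection_is_orthonormal(self):
        feats, labels = self.clustered_features()
        model = hp.fit_classifier(feats, labels)
        assert np.allclose(model.components @ model.components.T, np.eye(2),
                           atol=1e-10)

    def test_exact_low_rank_structure_recovered(self):
        """Features spanning a 2-D plane in 6-D are reconstructed exactly."""
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(12, 2))
        basis = np.zeros((2, 6))
        basis[0, 0], basis[1, 3] = 1.0, 1.0  # plane = axes 0 and 3
        feats = coords @ basis
        model = hp.fit_classifier(feats, [1] * 6 + [2] * 6)
        recon = (feats - model.mean) @ model.components.T @ model.components
        assert np.allclose(recon, feats - model.mean, atol=1e-10)

    def test_matches_brute_force_covariance_eigendecomposition(self):
        """PCA equals the eigenvectors of the explicit covariance matrix
        (up to sign); projected coordinates agree within 1e-8."""
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = int(rng.integers(5, 20))
            feats = rng.normal(size=(n, 6)) * rng.uniform(0.5, 3.0, size=6)
            labels = [1, 1, 2, 2] + [int(rng.integers(1, 3)) for _ in range(n - 4)]
            model = hp.fit_classifier(feats, labels)
            centered = feats - feats.mean(axis=0)
            evals, evecs = np.linalg.eigh(centered.T @ centered / len(feats))
            oracle = evecs[:, np.argsort(evals)[::-1][:2]].T
            for row, orow in zip(model.components, oracle):
                sign = np.sign(row @ orow)
                assert np.allclose(row, sign * orow, atol=1e-8)
            proj = centered @ model.components.T
            oproj = centered @ oracle.T
            assert np.allclose(np.abs(proj), np.abs(oproj), atol=1e-8)

    def test_centroids_are_class_means_and_separated(self):
        feats, labels = self.clustered_features()
        model = hp.fit_classifier(feats, labels)
        proj = (feats - model.mean) @ model.components.T
        assert model.centroids[0] == pytest.approx(proj[:10].mean(axis=0))
        assert model.centroids[1] == pytest.approx(proj[10:].mean(axis=0))
        between = np.linalg.norm(model.centroids[0] - model.centroids[1])
        within = max(
            np.linalg.norm(proj[:10] - model.centroids[0], axis=1).max(),
            np.linalg.norm(proj[10:] - model.centroids[1], axis=1).max(),
        )
        assert within < between

    def test_too_few_examples_rejected(self):
        feats = np.eye(3, 6)
        with pytest.raises(hp.CalibrationError):
            hp.fit_classifier(feats, [1, 1, 2])  # class 2 has one example
        with pytest.raises(hp.CalibrationError):
            hp.fit_classifier(feats[:2], [1, 2])

    def test_training_point_recall_and_tie_rule(self):
        feats, labels = self.clustered_features(noise=0.01)
        model = hp.fit_classifier(feats, labels)
        assert hp.classify(feats[0], model).label is MovementClass.CLASS1
        assert hp.classify(feats[-1], model).label is MovementClass.CLASS2
        # symmetric two-point classes: the midpoint is exactly equidistant
        # from both centroids and falls to class 1 by the tie rule
        a = np.array([2.0, 0, 0, 0, 0, 0])
        b = np.array([0, 2.0, 0, 0, 0, 0])
        e = np.array([0, 0, 0.1, 0, 0, 0])
        sym = hp.fit_classifier([a + e, a - e, b + e, b - e], [1, 1, 2, 2])
        res = hp.classify((a + b) / 2, sym)
        assert res.distances[0] == pytest.approx(res.distances[1], abs=1e-12)
        assert res.label is MovementClass.CLASS1

    def test_high_snr_label_recovery(self):
        feats, labels = self.clustered_features(n_per_class=50, noise=0.05, seed=13)
        model = hp.fit_classifier(feats[::2], list(labels[::2]))
        predicted = [int(hp.classify(f, model).label) for f in feats[1::2]]
        assert predicted == list(labels[1::2])


class TestDecode:
    def test_scripted_movements_fold_through_fsm(self, imu_config, imu_calibrated):
        alpha, model = imu_calibrated
        stream, _ = make_burst_stream([2.0, 6.0, 10.0], [2, 1, 2], duration=14.0,
                                      config=imu_config)
        events = hp.decode_imu(stream, model, alpha)
        assert [(e.from_state, e.to_state) for e in events] == [
            (HandState.RS, HandState.HC),
            (HandState.HC, HandState.RS),
            (HandState.RS, HandState.HC),
        ]
        assert all("point" in e.trigger and "distances" in e.trigger for e in events)

    def test_movement_free_stream_is_silent(self, imu_config, imu_calibrated):
        alpha, model = imu_calibrated
        stream, _ = make_burst_stream([], [], duration=6.0, config=imu_config)
        assert hp.decode_imu(stream, model, alpha) == []

    def test_open_close_pair(self, imu_config, imu_calibrated):
        alpha, model = imu_calibrated
        stream, _ = make_burst_stream([2.0, 6.0], [1, 1], duration=10.0,
                                      config=imu_config)
        events = hp.decode_imu(stream, model, alpha)
        assert [(e.from_state, e.to_state) for e in events] == [
            (HandState.RS, HandState.HO),
            (HandState.HO, HandState.RS),
        ]


class TestProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_no_missed_or_spurious_onsets(self, seed, imu_config, imu_calibrated):
        """Every scripted movement yields exactly one onset and no onset
        falls outside a scripted movement, across seeds."""
        alpha, _ = imu_calibrated
        times = [2.0, 5.0, 8.0, 11.0]
        stream, truth = make_burst_stream(times, [1, 2, 1, 2], duration=15.0,
                                          config=imu_config, seed=seed)
        d = hp.differentiate(stream)
        onsets = hp.detect_movement(d, alpha)
        assert len(onsets) == len(times)
        for k, gt in zip(onsets, truth):
            assert abs(d.timestamps[k] - gt.time) < 0.5

    def test_accuracy_non_increasing_in_signature_noise(self):
        """Held-out classification accuracy cannot improve as the per-
        movement signature angle noise grows (3-point grid)."""
        grid = [0.0, 0.6, 1.2]
        accs = []
        for noise in grid:
            correct = total = 0
            for seed in (21, 22, 23):
                cfg = hp.ImuSynthConfig(seed=seed, signature_angle_noise=noise)
                calib_stream, calib_truth = hp.synth_imu_calibration(cfg)
                alpha, model = hp.calibrate_imu(
                    calib_stream,
                    [g.time for g in calib_truth],
                    [int(IMU_ACTION_CLASS[g.action]) for g in calib_truth],
                )
                times = [2.0 + 2.0 * i for i in range(12)]
                classes = [1, 2] * 6
                stream, _ = make_burst_stream(
                    times, classes, duration=times[-1] + 3.0,
                    config=cfg, seed=seed + 100,
                )
                d = hp.differentiate(stream)
                for k, cls in zip(hp.detect_movement(d, alpha), classes):
                    feat = hp.extract_feature(d, k, allow_truncated=True)
                    correct += int(hp.classify(feat, model).label) == cls
                    total += 1
            accs.append(correct / total)
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]
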