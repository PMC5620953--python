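import numpy as np
import pytest

from actitag import preprocess as pp


def _static_segments(bias=np.zeros(3), scale=np.ones(3), n=9, rng=None):
    """Static recordings whose calibrated means are unit gravity vectors."""
    dirs = []
    for ax in range(3):
        for sgn in (1, -1):
            v = np.zeros(3)
            v[ax] = sgn
            dirs.append(v)
    extra = np.array([[1, 1, 1], [1, -1, 1], [-1, 1, -1]]) / np.sqrt(3)
    dirs = np.vstack([dirs, extra])[:n]
    segs = []
    for d in dirs:
        raw = d / scale + bias  # invert scale*(x - bias) = d
        seg = np.tile(raw, (50, 1))
        if rng is not None:
            seg = seg + rng.normal(0, 1e-4, seg.shape)
        segs.append(seg)
    return segs


class TestCalibrate:
    def test_identity_solution_for_calibrated_statics(self):
        params = pp.calibrate(_static_segments())
        np.testing.assert_allclose(params.bias, 0.0, atol=1e-6)
        np.testing.assert_allclose(params.scale, 1.0, atol=1e-6)

    def test_recovers_known_bias_and_scale(self):
        bias = np.array([0.05, -0.02, 0.01])
        scale = np.array([1.1, 0.9, 1.0])
        params = pp.calibrate(_static_segments(bias, scale, rng=np.random.default_rng(0)))
        np.testing.assert_allclose(params.bias, bias, atol=1e-3)
        np.testing.assert_allclose(params.scale, scale, atol=1e-3)
        cal = pp.apply_calibration(np.vstack([s.mean(0) for s in _static_segments(bias, scale)]), params)
        np.testing.assert_allclose(np.linalg.norm(cal, axis=1), 1.0, atol=1e-3)

    def test_rejects_fewer_than_nine_segments(self):
        with pytest.raises(ValueError, match="9 static segments"):
            pp.calibrate(_static_segments()[:8])

    def test_rejects_moving_segment(self):
        segs = _static_segments()
        segs[0] = segs[0] + np.linspace(0, 1, 50)[:, None]
        with pytest.raises(ValueError, match="not static"):
            pp.calibrate(segs)


class TestDenoise:
    def test_constant_signal_unchanged(self):
        x = np.ones((20, 3))
        np.testing.assert_array_equal(pp.denoise(x), x)

    def test_single_sample_spike_removed(self):
        x = np.zeros((5, 3))
        x[2, 1] = 10.0
        assert pp.denoise(x)[2, 1] == 0.0

    def test_monotone_ramp_interior_unchanged(self):
        x = np.linspace(0, 1, 30)[:, None] * np.ones(3)
        np.testing.assert_allclose(pp.denoise(x)[1:-1], x[1:-1])

    def test_too_short(self):
        with pytest.raises(ValueError):
            pp.denoise(np.zeros((2, 3)))


class TestRemoveGravity:
    fs = 100.0

    def test_static_dc_removed(self):
        x = np.tile([0.0, 0.0, 1.0], (1000, 1))
        body = pp.remove_gravity(x, self.fs)
        assert np.abs(np.linalg.norm(body, axis=1)).max() < 0.02

    def test_5hz_passband_gain(self):
        t = np.arange(2000) / self.fs
        x = np.zeros((2000, 3))
        x[:, 0] = 0.3 * np.sin(2 * np.pi * 5 * t)
        out = pp.remove_gravity(x, self.fs)[:, 0]
        amp = np.abs(out[500:1500]).max()
        assert 0.9 * 0.3 <= amp <= 1.1 * 0.3

    def test_superposition_dc_plus_sine(self):
        t = np.arange(2000) / self.fs
        x = np.zeros((2000, 3))
        x[:, 2] = 1.0 + 0.3 * np.sin(2 * np.pi * 5 * t)
        out = pp.remove_gravity(x, self.fs)[:, 2]
        sine = 0.3 * np.sin(2 * np.pi * 5 * t)
        assert np.abs(out[500:1500] - sine[500:1500]).max() < 0.02 + 0.1 * 0.3

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            pp.remove_gravity(np.zeros((100, 3)), fs=2.0)


class TestOrientation:
    def test_axis_aligned_closed_forms(self):
        o = pp.estimate_orientation(np.array([[0.0, 0.0, 1.0]]), 100.0)
        roll, pitch, tilt = o[0]
        assert roll == pytest.approx(0.0, abs=1e-12)
        assert pitch == pytest.approx(0.0, abs=1e-12)
        assert tilt == pytest.approx(45.0, abs=1e-9)  # atan(1/1)

    def test_roll_regularizer_on_x_gravity(self):
        o = pp.estimate_orientation(np.array([[1.0, 0.0, 0.0]]), 100.0)
        expected = np.degrees(np.arctan2(1.0, 0.01))
        assert o[0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(89.4271, abs=1e-3)

    def test_negative_z_uses_sign_convention(self):
        o = pp.estimate_orientation(np.array([[0.5, 0.0, -0.8]]), 100.0)
        expected = np.degrees(np.arctan2(0.5, 0.8 + 0.01 * 0.25))
        assert o[0, 0] == pytest.approx(expected)

    def test_zero_magnitude_tilt_is_zero(self):
        o = pp.estimate_orientation(np.zeros((3, 3)), 100.0)
        assert (o[:, 2] == 0).all()

    @pytest.mark.parametrize("vec", [(0, 0, 1), (0, 0, -1), (0, 1, 0), (1, 0, 0), (-1, 0, 0)])
    def test_matches_hand_formula_for_unit_vectors(self, vec):
        ax, ay, az = vec
        o = pp.estimate_orientation(np.array([vec], dtype=float), 100.0)
        sign_z = 1.0 if az >= 0 else -1.0
        roll = np.degrees(np.arctan2(ax, sign_z * az + 0.01 * ax**2))
        pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
        tilt = np.degrees(np.arctan(az / 1.0))
        np.testing.assert_allclose(o[0], [roll, pitch, tilt], atol=1e-9)


class TestWindowing:
    def _frame(self, n, fs=100.0):
        z = np.zeros((n, 3))
        return pp.SignalFrame(
            time=np.arange(n) / fs, acc=z, body_acc=z, orientation=z, fs=fs
        )

    def test_ten_seconds_gives_four_windows(self):
        wins = pp.window(self._frame(1000))
        assert len(wins) == 4
        assert [w.start_s for w in wins] == [0.0, 2.0, 4.0, 6.0]

    def test_exactly_one_window(self):
        assert len(pp.window(self._frame(300))) == 1

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            pp.window(self._frame(290))

    def test_window_duration_and_overlap(self):
        wins = pp.window(self._frame(1000))
        for w in wins:
            assert w.end_s - w.start_s == pytest.approx(3.0)
        for a, b in zip(wins, wins[1:]):
            assert a.end_s - b.start_s == pytest.approx(1.0)

    def test_zero_overlap_rewindowing_reproduces_boundaries(self):
        frame = self._frame(1200)
        wins = pp.window(frame, win_s=3, overlap_s=0)
        assert [w.start_s for w in wins] == [0.0, 3.0, 6.0, 9.0]


def test_pipeline_produces_consistent_frame():
    rng = np.random.default_rng(0)
    acc = np.tile([0.0, 0.0, 1.0], (600, 1)) + rng.normal(0, 0.01, (600, 3))
    frame = pp.preprocess(acc, 100.0)
    assert len(frame) == 600
    # static signal: body acceleration small, orientation near (0, 0, 45)
    assert np.abs(frame.body_acc).mean() < 0.02
    assert abs(frame.orientation[:, 2].mean() - 45.0) < 2.0


def test_orientation_source_switch_changes_static_orientation():
    acc = np.tile([0.0, 0.0, 1.0], (600, 1))
    default = pp.preprocess(acc, 100.0)
    literal = pp.preprocess(acc, 100.0, orientation_source="bandpassed")
    # band-passing removes DC, destroying the static posture reading
    assert abs(default.orientation[300, 2] - 45.0) < 1.0
    assert not np.allclose(default.orientation, literal.orientation, atol=1.0)
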