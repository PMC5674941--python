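"""Spiral sampling and windowed amplitude/frequency scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_window_stats
from biofilmq import complexity as cx
from biofilmq import image_io, synthetic
from biofilmq.errors import ValidationError

signals = st.lists(st.floats(0, 255), min_size=25, max_size=120).map(np.array)


class TestSpiralPath:
    def test_default_contract(self):
        path = cx.spiral_path((200, 200))
        assert path.n_samples == 2000
        spacing = np.hypot(*np.diff(path.samples, axis=0).T)
        assert spacing.min() >= 0.9 and spacing.max() <= 1.1
        assert (np.diff(path.radii) >= -1e-9).all()

    def test_starts_at_center(self):
        path = cx.spiral_path((37.5, 12.0), n_samples=1)
        np.testing.assert_allclose(path.samples, [[37.5, 12.0]])

    @pytest.mark.parametrize("pitch", [2.0, 4.0, 8.0])
    def test_max_radius_matches_arc_length_prediction(self, pitch):
        path = cx.spiral_path((300, 300), n_samples=2000, pitch=pitch)
        predicted = cx.spiral_max_radius(2000, pitch)
        assert path.radii.max() == pytest.approx(predicted, rel=0.10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            cx.spiral_path((0, 0), n_samples=0)
        with pytest.raises(ValidationError):
            cx.spiral_path((0, 0), pitch=0)


class TestSampleSignal:
    def test_constant_image(self):
        img = np.full((200, 200), 99.0)
        path = cx.spiral_path(image_io.image_center(img.shape), n_samples=500)
        np.testing.assert_allclose(cx.sample_signal(img, path), 99.0)

    def test_bilinear_midpoint_between_halves(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 255.0
        path = cx.SpiralPath(samples=np.array([[1.5, 1.0]]), center=(1.5, 1.0), pitch=4.0)
        assert cx.sample_signal(img, path)[0] == pytest.approx(127.5)

    def test_radial_gradient_recovers_path_radius(self):
        shape = (201, 201)
        c = image_io.image_center(shape)
        ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.hypot(xs - c[0], ys - c[1])
        path = cx.spiral_path(c, n_samples=1500)
        signal = cx.sample_signal(img, path)
        assert np.abs(signal - path.radii).max() <= 0.75

    def test_path_leaving_image_rejected_with_index(self):
        img = np.zeros((20, 20))
        path = cx.spiral_path((10, 10), n_samples=500)
        with pytest.raises(ValidationError, match="spiral sample"):
            cx.sample_signal(img, path)


class TestWindowedScores:
    def test_constant_signal_scores_zero(self):
        sig = np.full(100, 42.0)
        assert cx.windowed_amplitude(sig) == 0.0
        assert cx.windowed_frequency(sig) == 0.0

    def test_alternating_signal_closed_forms(self):
        sig = np.tile([0.0, 255.0], 50)
        assert cx.windowed_amplitude(sig, 20) == 255.0
        assert cx.windowed_frequency(sig, 20) == pytest.approx(16256.25, abs=1e-9)

    def test_unit_ramp_amplitude(self):
        sig = np.arange(100, dtype=float)
        assert cx.windowed_amplitude(sig, 20) == pytest.approx(19.0, abs=1e-12)

    def test_window_count_is_length_minus_window_plus_one(self):
        sig = np.arange(30, dtype=float)
        # 11 windows of a slope-1 ramp, each spanning 19 units
        assert cx.windowed_amplitude(sig, 20) == 19.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            cx.windowed_amplitude(np.zeros(10), 20)

    @given(signals)
    @settings(deadline=None, max_examples=60)
    def test_matches_naive_per_window_loop(self, sig):
        amp_o, freq_o = naive_window_stats(sig, 20)
        assert cx.windowed_amplitude(sig, 20) == pytest.approx(amp_o, abs=1e-9)
        assert cx.windowed_frequency(sig, 20) == pytest.approx(freq_o, abs=1e-9)

    @given(signals, st.floats(-20, 20))
    @settings(deadline=None, max_examples=60)
    def test_intensity_shift_invariance(self, sig, c):
        assert cx.windowed_amplitude(sig + c, 20) == pytest.approx(cx.windowed_amplitude(sig, 20), abs=1e-9)
        assert cx.windowed_frequency(sig + c, 20) == pytest.approx(cx.windowed_frequency(sig, 20), abs=1e-6)

    @given(signals, st.floats(0.1, 3.0))
    @settings(deadline=None, max_examples=60)
    def test_contrast_scaling_is_exact(self, sig, c):
        centered = c * (sig - sig.mean()) + sig.mean()
        assert cx.windowed_amplitude(centered, 20) == pytest.approx(
            c * cx.windowed_amplitude(sig, 20), rel=1e-9, abs=1e-9
        )
        assert cx.windowed_frequency(centered, 20) == pytest.approx(
            c**2 * cx.windowed_frequency(sig, 20), rel=1e-9, abs=1e-9
        )

    @given(signals)
    @settings(deadline=None, max_examples=60)
    def test_frequency_bounded_by_quarter_squared_range(self, sig):
        # per-window variance of a bounded signal cannot exceed (range/2)^2
        max_range = sig.max() - sig.min()
        assert cx.windowed_frequency(sig, 20) <= max_range**2 / 4 + 1e-9


class TestComplexityScore:
    def test_uniform_core_scores_zero_without_noise(self):
        spec = synthetic.lb_preset(noise_sd=0.0, core_intensity_trend=1.0)
        img, _ = synthetic.generate_day_image(spec, 1)
        gray = image_io.to_grayscale(img)
        score = cx.complexity_score(gray, image_io.image_center(gray.shape))
        # zero up to the rounding of bilinear interpolation weights
        assert score.amplitude == pytest.approx(0.0, abs=1e-9)
        assert score.frequency == pytest.approx(0.0, abs=1e-9)

    def test_noise_floor_bounded_by_twice_noise_sd(self):
        spec = synthetic.lb_preset(noise_sd=3.0, core_intensity_trend=1.0)
        img, _ = synthetic.generate_day_image(spec, 1)
        gray = image_io.to_grayscale(img)
        score = cx.complexity_score(gray, image_io.image_center(gray.shape))
        # range of ~20 iid noise samples is a few sigma; amplitude stays near it
        assert 0 < score.amplitude <= 2 * 3.0 * 3.7

    def test_wrinkled_core_outscores_smooth_at_equal_mean(self):
        smooth = synthetic.lb_preset(rng_seed=2, core_base_intensity=150.0, core_intensity_trend=1.0)
        wrinkled = synthetic.lbgm_preset(
            rng_seed=2, core_base_intensity=150.0, core_intensity_trend=1.0,
            outer_expansion=1.64, core_expansion=1.04,
        )
        scores = {}
        for name, spec in (("smooth", smooth), ("wrinkled", wrinkled)):
            img, _ = synthetic.generate_day_image(spec, 2)
            gray = image_io.to_grayscale(img)
            scores[name] = cx.complexity_score(gray, image_io.image_center(gray.shape))
        assert scores["wrinkled"].amplitude > scores["smooth"].amplitude
        assert scores["wrinkled"].frequency > scores["smooth"].frequency

    def test_rotation_changes_scores_only_marginally(self):
        spec = synthetic.lbgm_preset(rng_seed=3, noise_sd=0.0)
        img, _ = synthetic.generate_day_image(spec, 3)
        gray = image_io.to_grayscale(img)
        c = image_io.image_center(gray.shape)
        s1 = cx.complexity_score(gray, c)
        s2 = cx.complexity_score(np.rot90(gray), c)
        assert s2.amplitude == pytest.approx(s1.amplitude, rel=0.05)
        assert s2.frequency == pytest.approx(s1.frequency, rel=0.05)


class TestMaxComplexity:
    def test_coordinate_wise_maximum(self):
        scores = [cx.ComplexityScore(1, 10), cx.ComplexityScore(3, 5)]
        assert cx.max_complexity(scores) == (3, 10)

    def test_single_timepoint(self):
        assert cx.max_complexity([cx.ComplexityScore(2, 7)]) == (2, 7)

    def test_joint_mode_picks_one_day(self):
        scores = [cx.ComplexityScore(1, 10), cx.ComplexityScore(3, 5)]
        assert cx.max_complexity(scores, joint=True) == (1, 10)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cx.max_complexity([])
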