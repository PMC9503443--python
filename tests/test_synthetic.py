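import numpy as np
import pytest
from scipy import stats

import chromahr as ch
from chromahr.filtering import moving_average
from chromahr.synthetic import face_box_for_shape, forehead_rect_for_shape


class TestHRRamp:
    def test_protocol_ceiling_arithmetic(self):
        # age 20: max HR 208 - 0.7*20 = 194, ceiling 0.85*194 = 164.9
        assert ch.protocol_max_hr(20) == pytest.approx(194.0)
        assert ch.ramp_ceiling(20) == pytest.approx(164.9)

    def test_series_length_is_duration_seconds(self):
        scen = ch.SyntheticScenario(duration=600, seed=1)
        assert len(ch.generate_hr_ramp(scen)) == 600

    def test_series_starts_at_initial_hr(self):
        scen = ch.SyntheticScenario(age=22, initial_hr=93, duration=120, seed=2)
        hr = ch.generate_hr_ramp(scen)
        assert hr.hr[0] == pytest.approx(93.0)

    def test_ceiling_never_exceeded(self):
        for seed in range(5):
            scen = ch.SyntheticScenario(age=30, duration=300, seed=seed)
            hr = ch.generate_hr_ramp(scen)
            assert hr.hr.max() <= ch.ramp_ceiling(30) + 1e-12

    def test_smoothed_trend_is_monotone(self):
        scen = ch.SyntheticScenario(duration=400, seed=3)
        hr = ch.generate_hr_ramp(scen)
        trend = moving_average(hr.hr, 60)
        assert np.all(np.diff(trend) > -0.5)

    def test_initial_hr_at_ceiling_rejected(self):
        scen = ch.SyntheticScenario(age=25, initial_hr=170, seed=0)
        with pytest.raises(ValueError, match="161.9"):
            ch.generate_hr_ramp(scen)


class TestChannelSignals:
    def test_zero_coupling_zero_noise_gives_constant_baseline(self):
        scen = ch.SyntheticScenario(
            coupling=(0, 0, 0), noise_sd=0.0, duration=50, seed=0
        )
        hr = ch.generate_hr_ramp(scen)
        sig = ch.generate_channel_signals(hr, scen)
        np.testing.assert_allclose(sig, np.tile(scen.baseline_color, (len(hr), 1)))

    def test_negative_red_coupling_decreases_with_intensity(self):
        scen = ch.SyntheticScenario(
            coupling=(-0.5, 0, 0), noise_sd=0.0, hr_jitter_sd=0.0, duration=60, seed=0
        )
        hr = ch.generate_hr_ramp(scen)
        sig = ch.generate_channel_signals(hr, scen)
        rising = np.diff(hr.hr) > 0
        assert np.all(np.diff(sig[:, 0])[rising] < 0)

    def test_ols_recovers_coupling_within_three_se(self):
        # 3-SE coverage is ~99.7% per channel; over 5 seeds x 3 channels
        # allow at most one excursion
        hits = 0
        for seed in range(5):
            scen = ch.SyntheticScenario(duration=600, noise_sd=2.0, seed=seed)
            hr = ch.generate_hr_ramp(scen)
            sig = ch.generate_channel_signals(hr, scen)
            pct = ch.max_hr_percent(hr.hr, scen.age)
            for c in range(3):
                res = stats.linregress(pct, sig[:, c])
                hits += abs(res.slope - scen.coupling[c]) < 3 * res.stderr
        assert hits >= 14


class TestRenderFrames:
    def test_clean_render_forehead_matches_ground_truth(self, clean_recording):
        scen, hr, rgb, frames = clean_recording
        fx, fy, fw, fh = frames[0].metadata["forehead_rect"]
        for sec in (0, len(rgb) - 1):
            frame = frames[sec * 25]
            region = frame.pixels[fy : fy + fh, fx : fx + fw].astype(float)
            np.testing.assert_allclose(
                region.mean(axis=(0, 1)), rgb[sec], atol=0.5
            )

    def test_blur_fraction_one_flags_every_frame(self):
        scen = ch.SyntheticScenario(
            duration=2, frame_shape=(120, 160), blur_fraction=1.0, seed=4
        )
        hr = ch.generate_hr_ramp(scen)
        rgb = ch.generate_channel_signals(hr, scen)
        assert all(f.metadata["blurred"] for f in ch.render_frames(rgb, scen))

    def test_flicker_brightness_cv_matches_sinusoid(self):
        # CV of a full-cycle sinusoidal gain sampled 25x is amplitude/sqrt(2)
        amp = 0.05
        scen = ch.SyntheticScenario(
            duration=3, frame_shape=(120, 160), noise_sd=0.0,
            flicker_amplitude=amp, blur_fraction=0.0, seed=6,
        )
        hr = ch.generate_hr_ramp(scen)
        rgb = ch.generate_channel_signals(hr, scen)
        frames = list(ch.render_frames(rgb, scen))
        fx, fy, fw, fh = frames[0].metadata["forehead_rect"]
        means = np.array(
            [f.pixels[fy : fy + fh, fx : fx + fw].mean() for f in frames[25:50]]
        )
        cv = means.std() / means.mean()
        assert cv == pytest.approx(amp / np.sqrt(2), rel=0.1)

    def test_frame_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            face_box_for_shape((20, 30))

    def test_forehead_rect_inside_face_box(self):
        bx, by, bw, bh = face_box_for_shape((360, 640))
        fx, fy, fw, fh = forehead_rect_for_shape((360, 640))
        assert bx <= fx and fx + fw <= bx + bw
        assert by <= fy and fy + fh <= by + bh


class TestDeterminism:
    def test_identical_scenarios_give_bit_identical_outputs(self):
        scen = ch.SyntheticScenario(duration=3, frame_shape=(120, 160), seed=77)
        runs = []
        for _ in range(2):
            hr = ch.generate_hr_ramp(scen)
            rgb = ch.generate_channel_signals(hr, scen)
            first = next(iter(ch.render_frames(rgb, scen)))
            runs.append((hr.hr.tobytes(), rgb.tobytes(), first.pixels.tobytes()))
        assert runs[0] == runs[1]

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            ch.SyntheticScenario(duration=-1)
        with pytest.raises(ValueError):
            ch.SyntheticScenario(blur_fraction=1.5)
        with pytest.raises(ValueError):
            ch.SyntheticScenario(baseline_color=(0, 120, 120))
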