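import numpy as np
import pytest

import chromahr as ch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scenario():
    """Corruption-free scenario: no noise, no flicker, no blur."""
    return ch.SyntheticScenario(
        duration=6,
        frame_shape=(120, 160),
        noise_sd=0.0,
        flicker_amplitude=0.0,
        blur_fraction=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_scenario):
    """(scenario, hr, true 1 Hz RGB, rendered frames) with corruptions off."""
    hr = ch.generate_hr_ramp(clean_scenario)
    rgb = ch.generate_channel_signals(hr, clean_scenario)
    frames = list(ch.render_frames(rgb, clean_scenario))
    return clean_scenario, hr, rgb, frames


@pytest.fixture(scope="session")
def detector_frame():
    """One 360x640 rendered frame, big enough for the cascade detector."""
    scen = ch.SyntheticScenario(
        duration=1, frame_shape=(360, 640), noise_sd=1.0,
        flicker_amplitude=0.0, blur_fraction=0.0, seed=5,
    )
    hr = ch.generate_hr_ramp(scen)
    rgb = ch.generate_channel_signals(hr, scen)
    return next(iter(ch.render_frames(rgb, scen)))


@pytest.fixture
def gt_box_config():
    """Pipeline config that bypasses detection via ground-truth boxes."""
    cfg = ch.PipelineConfig()
    return cfg.model_copy(
        update={"face": cfg.face.model_copy(update={"box_policy": "ground_truth"})}
    )
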