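"""Synthetic exercise recordings with known heart-rate/color coupling.

Emulates a submaximal ramp test on a cycle ergometer: heart rate climbs
from a resting/warm-up value toward 85% of the age-predicted maximum
(208 − 0.7·age) while the facial skin color drifts linearly with the
percentage of maximum heart rate. Frames carry the face as a flat-shaded
ellipse with dark eye/brow/mouth blobs — enough structure for a frontal
cascade detector — plus the corruptions that plague real recordings:
mains-lamp brightness flicker, sensor noise, and occasional motion blur.

Every stochastic element is driven by ``scenario.seed``; identical
scenarios produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy import ndimage

from .preprocessing import FrameImage, motion_psf

__all__ = [
    "SyntheticScenario",
    "HRSeries",
    "REFERENCE_COHORT",
    "protocol_max_hr",
    "ramp_ceiling",
    "generate_hr_ramp",
    "generate_channel_signals",
    "render_frames",
]

#: Cohort records of the nine-rider reference study population
#: (sex, age [y], weight [kg], height [cm], HR at exercise start and end
#: [bpm], ramp duration [s]). Used for cohort summaries and as realistic
#: parameter sets for synthetic scenarios.
REFERENCE_COHORT: list[dict] = [
    {"id": "P1", "sex": "M", "age": 22, "weight": 64.2, "height": 172, "initial_hr": 93, "final_hr": 191, "duration": 570},
    {"id": "P2", "sex": "M", "age": 33, "weight": 66.9, "height": 177, "initial_hr": 70, "final_hr": 180, "duration": 960},
    {"id": "P3", "sex": "F", "age": 19, "weight": 64.2, "height": 177, "initial_hr": 87, "final_hr": 191, "duration": 545},
    {"id": "P4", "sex": "M", "age": 36, "weight": 83.2, "height": 182, "initial_hr": 91, "final_hr": 191, "duration": 900},
    {"id": "P5", "sex": "F", "age": 24, "weight": 66.6, "height": 170, "initial_hr": 97, "final_hr": 184, "duration": 560},
    {"id": "P6", "sex": "F", "age": 29, "weight": 47.0, "height": 157, "initial_hr": 114, "final_hr": 193, "duration": 480},
    {"id": "P7", "sex": "M", "age": 33, "weight": 83.0, "height": 186, "initial_hr": 101, "final_hr": 180, "duration": 960},
    {"id": "P8", "sex": "M", "age": 22, "weight": 90.7, "height": 195, "initial_hr": 101, "final_hr": 201, "duration": 720},
    {"id": "P9", "sex": "M", "age": 24, "weight": 87.3, "height": 194, "initial_hr": 115, "final_hr": 188, "duration": 660},
]


def protocol_max_hr(age: float) -> float:
    """Age-predicted maximal HR used by the ramp protocol: 208 − 0.7·age."""
    return 208.0 - 0.7 * age


def ramp_ceiling(age: float) -> float:
    """Test-termination HR: 85% of the protocol's age-predicted maximum."""
    return 0.85 * protocol_max_hr(age)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth configuration of one synthetic ramp recording.

    ``coupling`` is the signed slope of each rendered color channel
    (R, G, B, 8-bit units) per percentage point of maxHR%. The defaults sum
    to zero so that chromaticity normalization downstream preserves each
    channel's trend direction. ``noise_sd`` serves both as the 1 Hz
    channel-signal noise and the per-pixel sensor noise of rendered frames.
    ``flicker_freq`` is the apparent (aliased) frequency of the lamp
    ripple at the camera's frame clock.
    """

    age: float = 25.0
    initial_hr: float = 95.0
    frame_rate: float = 25.0
    duration: float = 360.0
    coupling: tuple[float, float, float] = (-0.35, 0.25, 0.10)
    baseline_color: tuple[float, float, float] = (185.0, 135.0, 115.0)
    noise_sd: float = 2.0
    flicker_amplitude: float = 0.02
    flicker_freq: float = 1.0
    blur_fraction: float = 0.1
    blur_length: int = 9
    frame_shape: tuple[int, int] = (360, 640)
    hr_jitter_ar: float = 0.9
    hr_jitter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 <= self.blur_fraction <= 1.0:
            raise ValueError("blur_fraction must lie in [0, 1]")
        if len(self.coupling) != 3:
            raise ValueError("coupling must have 3 components")
        if len(self.baseline_color) != 3 or not all(
            0 < c < 255 for c in self.baseline_color
        ):
            raise ValueError("baseline_color components must lie in (0, 255)")
        if self.noise_sd < 0 or self.flicker_amplitude < 0:
            raise ValueError("noise_sd and flicker_amplitude must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible substream keyed on (seed, stream)."""
        return np.random.default_rng([self.seed, stream])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HRSeries:
    """Per-second heart rate (bpm) with the participant's age."""

    hr: np.ndarray
    age: float
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=np.float64)
        if self.t is None:
            self.t = np.arange(len(self.hr), dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if len(self.hr) != len(self.t):
            raise ValueError("hr and t must have equal length")
        if np.any(self.hr <= 0):
            raise ValueError("heart rates must be positive")
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("t must increase in 1 s steps")

    def __len__(self) -> int:
        return len(self.hr)


def generate_hr_ramp(scenario: SyntheticScenario) -> HRSeries:
    """Monotone HR ramp saturating at 85% of the protocol maximum.

    The underlying trend rises linearly from ``initial_hr`` to the ceiling
    over the scenario duration; beat-to-beat variability is added as a
    seeded AR(1) perturbation and the series is clipped to the ceiling.
    """
    ceiling = ramp_ceiling(scenario.age)
    if scenario.initial_hr >= ceiling:
        raise ValueError(
            f"initial_hr {scenario.initial_hr} must be below the ramp "
            f"ceiling {ceiling:.1f} bpm (85% of {protocol_max_hr(scenario.age):.1f})"
        )
    n = int(round(scenario.duration))
    trend = np.linspace(scenario.initial_hr, ceiling, n)
    rng = scenario.rng(1)
    jitter = np.empty(n)
    x = 0.0
    for i in range(n):
        x = scenario.hr_jitter_ar * x + rng.normal(0.0, scenario.hr_jitter_sd)
        jitter[i] = x
    hr = np.clip(trend + jitter, 1.0, ceiling)
    hr[0] = scenario.initial_hr  # the recorded start value is the anchor
    return HRSeries(hr=hr, age=scenario.age)


def _maxhr_pct(hr: np.ndarray, age: float) -> np.ndarray:
    return hr * 100.0 / (220.0 - age)


def generate_channel_signals(
    hr: HRSeries, scenario: SyntheticScenario
) -> np.ndarray:
    """Ground-truth 1 Hz R, G, B color signals, shape (n, 3).

    channel_c(t) = baseline_c + coupling_c × maxHR%(t) + N(0, noise_sd),
    clipped to the 8-bit range.
    """
    if len(scenario.coupling) != 3:
        raise ValueError("coupling must have 3 components")
    pct = _maxhr_pct(hr.hr, hr.age)
    base = np.asarray(scenario.baseline_color, dtype=np.float64)
    coup = np.asarray(scenario.coupling, dtype=np.float64)
    sig = base[None, :] + coup[None, :] * pct[:, None]
    if scenario.noise_sd > 0:
        sig = sig + scenario.rng(2).normal(0.0, scenario.noise_sd, sig.shape)
    return np.clip(sig, 0.0, 255.0)


# ---------------------------------------------------------------------------
# frame rendering

_BG_COLOR = np.array([70.0, 75.0, 85.0])
_DARK = np.array([40.0, 30.0, 30.0])
_MOUTH = np.array([120.0, 60.0, 60.0])

#: Face-box geometry as fractions of the frame: the box is centered
#: horizontally, its top sits at 0.22·H, height 0.5·H, width 0.78·height.
_FACE_TOP_FRAC = 0.22
_FACE_HEIGHT_FRAC = 0.50
_FACE_ASPECT = 0.78  # width / height

#: Forehead rectangle within the face box (fractions of box width/height).
#: Lies inside the face ellipse and above the brows, so it is flat-shaded.
FOREHEAD_RECT_FRAC = (0.35, 0.08, 0.30, 0.22)  # x, y, w, h


def face_box_for_shape(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Ground-truth face box (x, y, w, h) for a frame of the given shape."""
    H, W = shape
    bh = int(round(_FACE_HEIGHT_FRAC * H))
    bw = int(round(_FACE_ASPECT * bh))
    y0 = int(round(_FACE_TOP_FRAC * H))
    x0 = (W - bw) // 2
    if bw < 24 or bh < 24 or x0 < 0 or y0 + bh > H:
        raise ValueError(
            f"frame shape {shape} too small to contain the synthetic face"
        )
    return x0, y0, bw, bh


def _face_masks(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Boolean masks for the face ellipse and its dark features."""
    H, W = shape
    x0, y0, bw, bh = face_box_for_shape(shape)
    cy, cx = y0 + bh / 2.0, x0 + bw / 2.0
    yy, xx = np.mgrid[0:H, 0:W]

    def ellipse(ecy, ecx, ry, rx):
        return ((xx - ecx) / rx) ** 2 + ((yy - ecy) / ry) ** 2 <= 1.0

    face = ellipse(cy, cx, bh / 2.0, bw / 2.0)
    features = np.zeros((H, W), dtype=bool)
    for s in (-1.0, 1.0):
        ex = cx + s * 0.18 * bw
        ey = y0 + 0.42 * bh
        features |= ellipse(ey, ex, 0.045 * bh, 0.09 * bw)  # eye
        features |= ellipse(ey - 0.09 * bh, ex, 0.018 * bh, 0.11 * bw)  # brow
    mouth = ellipse(y0 + 0.72 * bh, cx, 0.035 * bh, 0.16 * bw)
    return {"face": face, "features": features, "mouth": mouth}


def forehead_rect_for_shape(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Ground-truth forehead rectangle (x, y, w, h) in frame coordinates."""
    x0, y0, bw, bh = face_box_for_shape(shape)
    fx, fy, fw, fh = FOREHEAD_RECT_FRAC
    return (
        x0 + int(round(fx * bw)),
        y0 + int(round(fy * bh)),
        int(round(fw * bw)),
        int(round(fh * bh)),
    )


def render_frames(
    signals: np.ndarray,
    scenario: SyntheticScenario,
) -> Iterator[FrameImage]:
    """Stream frames at ``scenario.frame_rate`` realizing the 1 Hz signals.

    Per frame, in order: the face ellipse is painted with that second's
    ground-truth color (features over-painted below the forehead), the whole
    frame is scaled by the sinusoidal lamp flicker, per-pixel Gaussian
    sensor noise is added, and a seeded subset of frames is convolved with
    a linear-motion kernel. Frame metadata records the true face box,
    forehead rectangle, and blur flag.
    """
    signals = np.asarray(signals, dtype=np.float64)
    n_sec = signals.shape[0]
    fps = int(round(scenario.frame_rate))
    n_frames = n_sec * fps
    if n_frames < 1:
        raise ValueError("signals do not cover any full frame interval")
    shape = tuple(scenario.frame_shape)
    box = face_box_for_shape(shape)  # raises if the frame is too small
    rect = forehead_rect_for_shape(shape)
    masks = _face_masks(shape)
    base = np.empty(shape + (3,), dtype=np.float64)
    base[:] = _BG_COLOR

    rng = scenario.rng(3)
    blurred_flags = rng.random(n_frames) < scenario.blur_fraction
    psf = motion_psf(scenario.blur_length)

    for k in range(n_frames):
        t = k / fps
        sec = k // fps
        frame = base.copy()
        frame[masks["face"]] = signals[sec]
        frame[masks["features"]] = _DARK
        frame[masks["mouth"]] = _MOUTH
        if scenario.flicker_amplitude > 0:
            gain = 1.0 + scenario.flicker_amplitude * np.sin(
                2.0 * np.pi * scenario.flicker_freq * t
            )
            frame *= gain
        if scenario.noise_sd > 0:
            frame += rng.normal(0.0, scenario.noise_sd, frame.shape)
        if blurred_flags[k]:
            for c in range(3):
                frame[:, :, c] = ndimage.convolve(
                    frame[:, :, c], psf, mode="reflect"
                )
        frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        yield FrameImage(
            frame,
            t=t,
            index=k,
            metadata={
                "face_box": box,
                "forehead_rect": rect,
                "blurred": bool(blurred_flags[k]),
            },
        )
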