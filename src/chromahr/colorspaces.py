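"""Chromaticity normalization, color-model conversion, and patch averaging.

Each pixel's R, G, B components are divided by their sum, removing the
brightness factor contributed by lamp flicker and exposure changes and
leaving relative color (the per-pixel components then sum to exactly 1).
The normalized image is converted to each of five color models — RGB, HSV,
YCbCr, Lab, YUV — and the forehead patch is spatially averaged per channel,
yielding one sample per channel per frame.

Conversion standards: HSV by the hexcone model; YCbCr and YUV per ITU-R
BT.601 (8-bit studio offset, chroma centered at 128, for YCbCr); Lab via
sRGB → XYZ with D65 white. These are the defaults of mainstream imaging
libraries and are delegated to ``skimage.color``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

__all__ = [
    "NormalizedImage",
    "ColorSignalSet",
    "COLOR_MODELS",
    "MODEL_CHANNELS",
    "normalize_rgb",
    "convert_color",
    "patch_average",
    "combined_intensity",
    "signals_from_colors",
    "signals_from_frames",
]

COLOR_MODELS = ("RGB", "HSV", "YCbCr", "Lab", "YUV")

#: Channel names per model. Ambiguous single letters (Y vs Y, b vs B) are
#: disambiguated by model-qualified names ("Lab.b", "YUV.Y") in outputs.
MODEL_CHANNELS: dict[str, tuple[str, str, str]] = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H", "S", "V"),
    "YCbCr": ("Y", "Cb", "Cr"),
    "Lab": ("L", "a", "b"),
    "YUV": ("Y", "U", "V"),
}


@dataclass
class NormalizedImage:
    """Chromaticity image: per-pixel components are nonnegative and sum
    to 1 (black pixels are mapped to the neutral point (1/3, 1/3, 1/3))."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("normalized image must be H x W x 3")
        self.pixels = px


@dataclass
class ColorSignalSet:
    """Three named 1 Hz channel series for one color model."""

    model: str
    channels: dict[str, np.ndarray]
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model not in COLOR_MODELS:
            raise ValueError(f"unknown color model {self.model!r}")
        expected = MODEL_CHANNELS[self.model]
        if tuple(self.channels) != expected:
            raise ValueError(
                f"channel names {tuple(self.channels)} do not match "
                f"{self.model} channels {expected}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("channel vectors must have equal length")
        (n,) = lengths
        if self.t is None:
            self.t = np.arange(n, dtype=np.float64)
        if len(self.t) != n:
            raise ValueError("t must match channel length")

    def __len__(self) -> int:
        return len(self.t)

    def as_matrix(self) -> np.ndarray:
        """Channels stacked as columns, shape (n, 3)."""
        return np.column_stack(list(self.channels.values()))

    def qualified_names(self) -> list[str]:
        return [f"{self.model}.{c}" for c in self.channels]


def normalize_rgb(image) -> NormalizedImage:
    """Divide each pixel by its component sum (chromaticity normalization).

    Scale-invariant by construction — normalize(k·p) = normalize(p) for any
    k > 0 — which is what removes multiplicative brightness variation.
    Zero-sum (black) pixels get the neutral sentinel (1/3, 1/3, 1/3).
    """
    px = getattr(image, "pixels", image)
    px = np.asarray(px, dtype=np.float64)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    s = px.sum(axis=2, keepdims=True)
    zero = s[:, :, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = px / s
    out[zero] = 1.0 / 3.0
    return NormalizedImage(out)


def convert_color(norm: NormalizedImage, model: str) -> np.ndarray:
    """Convert a chromaticity image to the target model, shape H x W x 3.

    The chromaticity values (which lie in [0, 1]) are interpreted on the
    8-bit scale for the RGB model (×255); the other models consume the
    [0, 1] domain their converters expect, which is numerically identical
    to rescaling to 8-bit and back. Output units: RGB on [0, 255]; HSV with
    H in degrees [0, 360) and S, V in [0, 1]; YCbCr 8-bit studio range
    (chroma centered at 128); Lab with L in [0, 100]; YUV with Y in [0, 1]
    and signed U, V.
    """
    px = norm.pixels
    if model == "RGB":
        return px * 255.0
    if model == "HSV":
        hsv = skcolor.rgb2hsv(px)
        hsv = hsv.copy()
        hsv[:, :, 0] *= 360.0
        return hsv
    if model == "YCbCr":
        return skcolor.rgb2ycbcr(px)
    if model == "Lab":
        return skcolor.rgb2lab(px)
    if model == "YUV":
        return skcolor.rgb2yuv(px)
    raise ValueError(f"unknown color model {model!r}")


def patch_average(patch_channel: np.ndarray) -> float:
    """Spatial mean of one channel over the patch (one sample per frame)."""
    arr = np.asarray(patch_channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot average an empty patch")
    return float(arr.mean())


def combined_intensity(r: float, g: float, b: float) -> float:
    """Luma-weighted combined intensity as a percentage of full scale:
    I = ((0.21·R + 0.72·G + 0.07·B) / 255) · 100, inputs on [0, 255]."""
    return (0.21 * np.asarray(r) + 0.72 * np.asarray(g) + 0.07 * np.asarray(b)) / 255.0 * 100.0


def signals_from_colors(rgb: np.ndarray, t: np.ndarray | None = None) -> dict[str, ColorSignalSet]:
    """Run 1 Hz R, G, B color vectors (n x 3, 8-bit scale) through the same
    normalization and conversions as the frame pipeline.

    Each second's color is treated as a uniform patch, so patch averaging
    is the identity; this is the ground-truth oracle path for synthetic
    signals and the signal-level simulation path for cohort studies.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("rgb must be n x 3")
    norm = normalize_rgb(rgb[:, None, :])
    if t is None:
        t = np.arange(rgb.shape[0], dtype=np.float64)
    out: dict[str, ColorSignalSet] = {}
    for model in COLOR_MODELS:
        conv = convert_color(norm, model)[:, 0, :]
        names = MODEL_CHANNELS[model]
        out[model] = ColorSignalSet(
            model=model,
            channels={names[c]: conv[:, c].copy() for c in range(3)},
            t=np.asarray(t, dtype=np.float64),
        )
    return out


def signals_from_frames(frames, config=None, models=COLOR_MODELS):
    """Per-frame extraction chain ending in 1 Hz ColorSignalSets; see
    :func:`chromahr.pipeline.signals_from_frames`."""
    from .pipeline import signals_from_frames as _impl

    return _impl(frames, config=config, models=models)
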