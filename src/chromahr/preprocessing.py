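"""Per-frame de-blurring and denoising.

Exercise videos recorded from a bike ergometer show intermittent motion
blur from head movement. Each frame is screened with a sharpness statistic;
frames below threshold are restored by Wiener-Hunt deconvolution with a
linear-motion point-spread function, and every frame is then denoised with
a small Gaussian kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import restoration

__all__ = [
    "FrameImage",
    "is_blurred",
    "sharpness",
    "motion_psf",
    "wiener_deblur",
    "gaussian_denoise",
]


@dataclass
class FrameImage:
    """One video frame: H x W x 3 pixel array on the 8-bit scale.

    ``metadata`` carries optional provenance from the synthetic renderer
    (ground-truth face box, forehead rectangle, blur flag) and is never
    required by the processing stages.
    """

    pixels: np.ndarray
    t: float = 0.0
    index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame has zero spatial extent")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("frame values must lie in [0, 255]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _as_float(frame: FrameImage | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, FrameImage) else np.asarray(frame)
    return px.astype(np.float64, copy=False)


def _like(frame: FrameImage | np.ndarray, pixels: np.ndarray) -> FrameImage:
    pixels = np.clip(pixels, 0.0, 255.0)
    if isinstance(frame, FrameImage):
        if frame.pixels.dtype == np.uint8:
            out = np.rint(pixels).astype(np.uint8)
        else:
            out = pixels
        return FrameImage(out, t=frame.t, index=frame.index, metadata=dict(frame.metadata))
    return FrameImage(pixels)


def sharpness(frame: FrameImage | np.ndarray, statistic: str = "laplacian") -> float:
    """Sharpness statistic of a frame.

    ``laplacian`` (default) is the variance of the Laplacian of the
    grayscale frame, the standard focus/blur measure: blur attenuates high
    spatial frequencies, collapsing the Laplacian response.
    ``pixel_variance`` is the raw grayscale pixel variance, kept as a
    configurable alternative reading of a variance-based blur screen.
    """
    gray = _as_float(frame).mean(axis=2)
    if statistic == "laplacian":
        return float(ndimage.laplace(gray).var())
    if statistic == "pixel_variance":
        return float(gray.var())
    raise ValueError(f"unknown sharpness statistic {statistic!r}")


def is_blurred(
    frame: FrameImage | np.ndarray,
    threshold: float = 100.0,
    statistic: str = "laplacian",
) -> bool:
    """True iff the frame's sharpness statistic falls below ``threshold``."""
    if threshold <= 0:
        raise ValueError("blur threshold must be > 0")
    return sharpness(frame, statistic) < threshold


def motion_psf(length: int = 9, angle_deg: float = 0.0) -> np.ndarray:
    """Linear-motion point-spread function: a normalized line of ``length``
    pixels at ``angle_deg`` (0 = horizontal), rasterized on a square grid."""
    if length < 1:
        raise ValueError("psf length must be >= 1")
    if length == 1:
        return np.ones((1, 1))
    theta = np.deg2rad(angle_deg)
    # sample the segment finely and bin onto the pixel grid
    ts = np.linspace(-(length - 1) / 2, (length - 1) / 2, 8 * length)
    xs = np.round(ts * np.cos(theta)).astype(int)
    ys = np.round(ts * np.sin(theta)).astype(int)
    half = (length - 1) // 2 + 1
    size = 2 * half + 1
    psf = np.zeros((size, size))
    np.add.at(psf, (ys + half, xs + half), 1.0)
    # trim empty border rows/cols so the kernel stays compact
    rows = np.flatnonzero(psf.any(axis=1))
    cols = np.flatnonzero(psf.any(axis=0))
    psf = psf[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return psf / psf.sum()


def wiener_deblur(
    frame: FrameImage | np.ndarray,
    psf: np.ndarray,
    nsr: float = 0.01,
) -> FrameImage:
    """Wiener-Hunt deconvolution applied per channel.

    ``nsr`` is the regularization weight (noise-to-signal balance); 0 gives
    the unregularized inverse filter, large values shrink the restoration
    toward a flat image.
    """
    psf = np.asarray(psf, dtype=np.float64)
    if psf.ndim != 2:
        raise ValueError("psf must be 2-D")
    if np.any(psf < 0):
        raise ValueError("psf must be nonnegative")
    if not np.isclose(psf.sum(), 1.0, atol=1e-8):
        raise ValueError("psf must sum to 1")
    if nsr < 0:
        raise ValueError("nsr must be >= 0")
    px = _as_float(frame)
    if psf.shape[0] > px.shape[0] or psf.shape[1] > px.shape[1]:
        raise ValueError(
            f"psf {psf.shape} larger than frame {px.shape[:2]}"
        )
    out = np.empty_like(px)
    for c in range(3):
        out[:, :, c] = restoration.wiener(px[:, :, c] / 255.0, psf, balance=nsr, clip=False)
    return _like(frame, out * 255.0)


def gaussian_denoise(frame: FrameImage | np.ndarray, sigma: float) -> FrameImage:
    """Per-channel Gaussian smoothing with reflective borders; sigma=0 is
    the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    px = _as_float(frame)
    if sigma == 0:
        return _like(frame, px)
    out = ndimage.gaussian_filter(px, sigma=(sigma, sigma, 0), mode="reflect")
    return _like(frame, out)
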