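"""Face localization, the 400x400 face crop, and the forehead patch.

Detection uses a boosted LBP frontal-face cascade (the Viola-Jones family
of detectors). The analysis region is a small square patch on the lower
forehead of the normalized 400x400 face crop — the skin region reported to
give the most reliable remote pulse/color signal.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass

import numpy as np
import skimage.data
from skimage.feature import Cascade
from skimage.transform import resize

from .preprocessing import FrameImage

__all__ = [
    "FaceBox",
    "PatchSpec",
    "NoFaceError",
    "detect_face",
    "crop_resize_face",
    "extract_forehead_patch",
    "FACE_CROP_SIZE",
]

FACE_CROP_SIZE = 400


class NoFaceError(RuntimeError):
    """Raised when no face is detected in a frame."""

    def __init__(self, frame_index: int):
        self.frame_index = frame_index
        super().__init__(f"no face detected in frame {frame_index}")


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box; 0-based, half-open pixel coords."""

    x: int
    y: int
    w: int
    h: int
    source: str = "detected"  # "detected" | "ground_truth" | "manual"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("face box must have positive size")

    def clipped_to(self, shape: tuple[int, int]) -> "FaceBox":
        H, W = shape
        x = max(0, min(self.x, W - 1))
        y = max(0, min(self.y, H - 1))
        w = min(self.w, W - x)
        h = min(self.h, H - y)
        return FaceBox(x, y, w, h, self.source)

    def iou(self, other: "FaceBox") -> float:
        ix = max(0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        union = self.w * self.h + other.w * other.h - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class PatchSpec:
    """Forehead-patch placement on the 400x400 face crop.

    The patch center sits at fractional crop coordinates (cx_frac, cy_frac);
    cy_frac defaults to 0.18, just above the brow line of a frontal crop,
    on the lower forehead.
    """

    cx_frac: float = 0.5
    cy_frac: float = 0.18
    size: int = 16

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("patch size must be >= 1")
        if not (0.0 <= self.cx_frac <= 1.0 and 0.0 <= self.cy_frac <= 1.0):
            raise ValueError("patch center fractions must lie in [0, 1]")


_cascade_lock = threading.Lock()
_cascade: Cascade | None = None


def _get_cascade() -> Cascade:
    global _cascade
    with _cascade_lock:
        if _cascade is None:
            _cascade = Cascade(skimage.data.lbp_frontal_face_cascade_filename())
    return _cascade


def detect_face(
    frame: FrameImage,
    *,
    use_ground_truth: bool = False,
    min_size: int = 60,
    max_size: int | None = None,
    scale_factor: float = 1.2,
) -> FaceBox:
    """Locate the face in a frame.

    With ``use_ground_truth`` the box recorded by the synthetic renderer is
    returned verbatim (source="ground_truth"), bypassing detection for
    deterministic tests. Otherwise the cascade detector runs and the
    largest detection wins; ties break topmost-then-leftmost.
    """
    if use_ground_truth:
        meta = frame.metadata.get("face_box")
        if meta is None:
            raise ValueError("frame metadata carries no ground-truth face box")
        x, y, w, h = meta
        return FaceBox(int(x), int(y), int(w), int(h), source="ground_truth")

    px = frame.pixels
    if max_size is None:
        max_size = min(px.shape[0], px.shape[1])
    detections = _get_cascade().detect_multi_scale(
        img=px,
        scale_factor=scale_factor,
        step_ratio=1,
        min_size=(min_size, min_size),
        max_size=(max_size, max_size),
    )
    if not detections:
        raise NoFaceError(frame.index)
    best = max(
        detections,
        key=lambda d: (d["width"] * d["height"], -d["r"], -d["c"]),
    )
    box = FaceBox(
        int(best["c"]), int(best["r"]), int(best["width"]), int(best["height"])
    )
    return box.clipped_to(px.shape[:2])


def crop_resize_face(frame: FrameImage, box: FaceBox) -> FrameImage:
    """Crop the face box and bilinearly resize it to 400x400, regardless of
    the box's aspect ratio."""
    H, W = frame.pixels.shape[:2]
    if box.x < 0 or box.y < 0 or box.x + box.w > W or box.y + box.h > H:
        raise ValueError(f"face box {box} lies outside the {H}x{W} frame")
    crop = frame.pixels[box.y : box.y + box.h, box.x : box.x + box.w]
    if crop.shape[:2] == (FACE_CROP_SIZE, FACE_CROP_SIZE):
        out = crop.astype(np.float64)
    else:
        out = resize(
            crop.astype(np.float64),
            (FACE_CROP_SIZE, FACE_CROP_SIZE),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return FrameImage(out, t=frame.t, index=frame.index, metadata=dict(frame.metadata))


def extract_forehead_patch(face: FrameImage, spec: PatchSpec = PatchSpec()) -> FrameImage:
    """Axis-aligned size x size crop centered (integer-floored) at the
    spec's fractional coordinates of the face crop."""
    H, W = face.pixels.shape[:2]
    cx = int(spec.cx_frac * W)
    cy = int(spec.cy_frac * H)
    x0 = cx - spec.size // 2
    y0 = cy - spec.size // 2
    if x0 < 0 or y0 < 0 or x0 + spec.size > W or y0 + spec.size > H:
        raise ValueError(
            f"patch ({spec.size}px at {cx},{cy}) exceeds the {H}x{W} crop"
        )
    patch = face.pixels[y0 : y0 + spec.size, x0 : x0 + spec.size]
    return FrameImage(patch, t=face.t, index=face.index, metadata=dict(face.metadata))


def sample_patch(frame: FrameImage, box: FaceBox, spec: PatchSpec = PatchSpec()) -> np.ndarray:
    """Forehead-patch pixels sampled directly from the frame.

    Numerically equivalent to ``extract_forehead_patch(crop_resize_face(
    frame, box), spec)`` — the bilinear 400x400 resize evaluates each
    output pixel independently, so only the patch's pixels need
    interpolating. Returns a size x size x 3 float array.
    """
    H, W = frame.pixels.shape[:2]
    if box.x < 0 or box.y < 0 or box.x + box.w > W or box.y + box.h > H:
        raise ValueError(f"face box {box} lies outside the {H}x{W} frame")
    S = FACE_CROP_SIZE
    cx = int(spec.cx_frac * S)
    cy = int(spec.cy_frac * S)
    x0 = cx - spec.size // 2
    y0 = cy - spec.size // 2
    if x0 < 0 or y0 < 0 or x0 + spec.size > S or y0 + spec.size > S:
        raise ValueError(f"patch ({spec.size}px at {cx},{cy}) exceeds the {S}x{S} crop")
    # crop-relative sample coordinates of the bilinear resize, edge-clamped
    ys = np.clip((np.arange(y0, y0 + spec.size) + 0.5) * box.h / S - 0.5, 0, box.h - 1)
    xs = np.clip((np.arange(x0, x0 + spec.size) + 0.5) * box.w / S - 0.5, 0, box.w - 1)
    yf = np.floor(ys).astype(int)
    xf = np.floor(xs).astype(int)
    yc = np.minimum(yf + 1, box.h - 1)
    xc = np.minimum(xf + 1, box.w - 1)
    wy = (ys - yf)[:, None, None]
    wx = (xs - xf)[None, :, None]
    crop = frame.pixels[box.y : box.y + box.h, box.x : box.x + box.w].astype(np.float64)
    p00 = crop[np.ix_(yf, xf)]
    p01 = crop[np.ix_(yf, xc)]
    p10 = crop[np.ix_(yc, xf)]
    p11 = crop[np.ix_(yc, xc)]
    return (
        p00 * (1 - wy) * (1 - wx)
        + p01 * (1 - wy) * wx
        + p10 * wy * (1 - wx)
        + p11 * wy * wx
    )
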