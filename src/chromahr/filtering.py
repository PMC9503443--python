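"""Temporal resampling and the two-stage smoothing of the 1 Hz signals.

Patch-average series are noisy; a long median filter removes spikes and a
short causal moving average smooths the residual steps. Both stages
preserve series length; endpoints are handled by signal reflection plus
edge replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Signal1D",
    "resample_to_1hz",
    "median_smooth",
    "moving_average",
    "minmax_normalize",
]

log = logging.getLogger(__name__)


@dataclass
class Signal1D:
    """A finite real-valued series sampled at ``rate`` Hz from ``t0`` s."""

    values: np.ndarray
    rate: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")


def _values(x) -> np.ndarray:
    v = x.values if isinstance(x, Signal1D) else np.asarray(x, dtype=np.float64)
    return v


def resample_to_1hz(signal, rate: int = 25) -> np.ndarray:
    """Blockwise mean over each whole second; a trailing partial second is
    dropped."""
    v = _values(signal)
    if isinstance(signal, Signal1D):
        rate = int(round(signal.rate))
    if v.size == 0:
        raise ValueError("cannot resample an empty signal")
    if rate < 1:
        raise ValueError("rate must be >= 1")
    n_sec = len(v) // rate
    if n_sec == 0:
        raise ValueError(f"signal shorter than one second at {rate} Hz")
    return v[: n_sec * rate].reshape(n_sec, rate).mean(axis=1)


def _reflect_extend(v: np.ndarray, halfwin: int, pad: int) -> np.ndarray:
    """Extend both ends by ``halfwin`` samples: mirror-reflect the first/last
    ``pad`` interior samples, then replicate the outermost reflected value
    for any remaining shortfall."""
    pad = min(pad, len(v) - 1)
    left = v[1 : pad + 1][::-1]
    right = v[-pad - 1 : -1][::-1]
    if halfwin > pad:
        extra = halfwin - pad
        lfill = np.full(extra, left[0] if len(left) else v[0])
        rfill = np.full(extra, right[-1] if len(right) else v[-1])
        left = np.concatenate([lfill, left])
        right = np.concatenate([right, rfill])
    else:
        left = left[len(left) - halfwin :] if halfwin else left[:0]
        right = right[:halfwin]
    return np.concatenate([left, v, right])


def median_smooth(signal, window: int = 201, pad: int = 40) -> np.ndarray:
    """Sliding-window median, length-preserving.

    Endpoints are handled by reflecting ``pad`` samples at each end and
    edge-replicating any remaining shortfall up to the half-window. If the
    series is shorter than the window, the window shrinks to the largest
    odd number that fits (logged).
    """
    v = _values(signal)
    if v.size == 0:
        raise ValueError("cannot smooth an empty signal")
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    if window > len(v):
        window = len(v) if len(v) % 2 == 1 else len(v) - 1
        window = max(window, 1)
        log.info("median window shrunk to %d for a length-%d signal", window, len(v))
    if window == 1:
        return v.copy()
    halfwin = (window - 1) // 2
    ext = _reflect_extend(v, halfwin, pad)
    sw = np.lib.stride_tricks.sliding_window_view(ext, window)
    return np.median(sw, axis=1)


def moving_average(signal, ws: int = 21) -> np.ndarray:
    """Causal moving average: y(n) = mean(x(n), x(n−1), …, x(n−ws+1)).

    The first ws−1 outputs are computed on a mirror-reflected prefix so the
    output has the input's length.
    """
    v = _values(signal)
    if ws < 1:
        raise ValueError("ws must be >= 1")
    if ws > len(v):
        raise ValueError(f"ws={ws} exceeds signal length {len(v)}")
    if ws == 1:
        return v.copy()
    prefix = v[1:ws][::-1]
    ext = np.concatenate([prefix, v])
    kernel = np.full(ws, 1.0 / ws)
    return np.convolve(ext, kernel, mode="valid")


def minmax_normalize(v) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant vector maps to all 0.5."""
    v = _values(v)
    if v.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)
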