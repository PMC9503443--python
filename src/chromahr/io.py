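"""Standard-format I/O: PNG frame directories (or video containers where a
reader is available), tidy signal CSVs, HR CSVs, scenario YAML, reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .colorspaces import MODEL_CHANNELS, ColorSignalSet
from .preprocessing import FrameImage
from .synthetic import SyntheticScenario

__all__ = [
    "DataError",
    "write_frames",
    "iter_frames",
    "write_signals_csv",
    "read_signals_csv",
    "read_hr_csv",
    "write_ground_truth_csv",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "write_json",
]


class DataError(Exception):
    """Unreadable, malformed, or missing input data."""


def write_frames(frames: Iterable[FrameImage], outdir) -> int:
    """Write frames as numbered PNGs (frame_000000.png, …); returns count."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = 0
    for frame in frames:
        iio.imwrite(outdir / f"frame_{frame.index:06d}.png", frame.pixels)
        n += 1
    return n


def iter_frames(path, frame_rate: float = 25.0) -> Iterator[FrameImage]:
    """Stream frames from a PNG directory (sorted by name) or a video file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise DataError(f"no PNG frames found in {path}")
        for k, f in enumerate(files):
            px = iio.imread(f)
            if px.ndim == 2:
                px = np.repeat(px[:, :, None], 3, axis=2)
            yield FrameImage(px[:, :, :3], t=k / frame_rate, index=k)
        return
    if not path.exists():
        raise DataError(f"input {path} does not exist")
    try:
        for k, px in enumerate(iio.imiter(path)):
            yield FrameImage(np.asarray(px)[:, :, :3], t=k / frame_rate, index=k)
    except Exception as exc:  # no plugin for this container in this install
        raise DataError(f"cannot read video {path}: {exc}") from exc


def write_signals_csv(signals: dict[str, ColorSignalSet], path) -> None:
    """Tidy long format: columns t, model, channel, value."""
    rows = []
    for model, sig in signals.items():
        for name, v in sig.channels.items():
            rows.append(
                pd.DataFrame(
                    {"t": sig.t, "model": model, "channel": name, "value": v}
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_signals_csv(path) -> dict[str, ColorSignalSet]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read signals CSV {path}: {exc}") from exc
    required = {"t", "model", "channel", "value"}
    if not required.issubset(df.columns):
        raise DataError(
            f"signals CSV {path} must have columns {sorted(required)}"
        )
    out = {}
    for model, g in df.groupby("model", sort=False):
        names = MODEL_CHANNELS.get(str(model))
        if names is None:
            raise DataError(f"unknown color model {model!r} in {path}")
        chans = {}
        t = None
        for name in names:
            gc = g[g["channel"] == name].sort_values("t")
            if gc.empty:
                raise DataError(f"model {model} missing channel {name} in {path}")
            chans[name] = gc["value"].to_numpy(dtype=float)
            t = gc["t"].to_numpy(dtype=float)
        out[str(model)] = ColorSignalSet(model=str(model), channels=chans, t=t)
    return out


def read_hr_csv(path) -> pd.DataFrame:
    """HR CSV dialect: header "t,hr", seconds from exercise start, bpm."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read HR CSV {path}: {exc}") from exc
    if not {"t", "hr"}.issubset(df.columns):
        raise DataError(f"HR CSV {path} must have columns t,hr")
    if (df["hr"] <= 0).any():
        raise DataError(f"HR CSV {path} contains non-positive heart rates")
    return df[["t", "hr"]]


def write_ground_truth_csv(path, hr_series, maxhr_pct, rgb) -> None:
    pd.DataFrame(
        {
            "t": hr_series.t,
            "hr": hr_series.hr,
            "maxhr_pct": maxhr_pct,
            "R": rgb[:, 0],
            "G": rgb[:, 1],
            "B": rgb[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)


def scenario_from_yaml(path) -> SyntheticScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("coupling", "baseline_color", "frame_shape"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return SyntheticScenario(**data)
    except TypeError as exc:
        raise DataError(f"invalid scenario YAML {path}: {exc}") from exc


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
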