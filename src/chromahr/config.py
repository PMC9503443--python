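"""Validated pipeline configuration (one schema covering every stage)."""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field


class PreprocessConfig(BaseModel):
    blur_threshold: float = Field(100.0, gt=0)
    blur_statistic: Literal["laplacian", "pixel_variance"] = "laplacian"
    deblur: Literal["conditional", "always", "off"] = "conditional"
    psf_length: int = Field(9, ge=1)
    psf_angle: float = 0.0
    nsr: float = Field(0.01, ge=0)
    gaussian_sigma: float = Field(1.0, ge=0)


class FaceConfig(BaseModel):
    patch_cx_frac: float = Field(0.5, ge=0, le=1)
    patch_cy_frac: float = Field(0.18, ge=0, le=1)
    patch_size: int = Field(16, ge=1)
    face_min_size: int = Field(60, ge=8)
    #: run the detector every N frames, holding the last box in between
    detect_interval: int = Field(25, ge=1)
    box_policy: Literal["detect", "ground_truth", "manual"] = "detect"
    manual_box: Optional[tuple[int, int, int, int]] = None


class FilterConfig(BaseModel):
    median_window: int = Field(201, ge=1)
    median_pad: int = Field(40, ge=0)
    ma_window: int = Field(21, ge=1)


class RegressionConfig(BaseModel):
    normalize_y: bool = False
    degree: int = Field(3, ge=1)
    estimator: Literal["ridge", "svr"] = "ridge"
    alpha: float = Field(1e-6, ge=0)
    epsilon: float = Field(0.1, ge=0)
    C: float = Field(1.0, gt=0)
    adf_alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    """Top-level configuration; validates before any stage runs."""

    preprocessing: PreprocessConfig = PreprocessConfig()
    face: FaceConfig = FaceConfig()
    filtering: FilterConfig = FilterConfig()
    regression: RegressionConfig = RegressionConfig()
    frame_rate: float = Field(25.0, gt=0)
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
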