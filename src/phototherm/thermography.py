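"""Thermogram stacks: ROI time series and thermal-contrast metrics.

An infrared camera yields a time-ordered stack of 2-D temperature images.
This module reduces a stack to the per-frame temperature of a region of
interest (producing a :class:`~phototherm.lumped.ThermalTrace` that feeds
the efficiency pipeline) and computes contrast/dissipation metrics between
a "tumor" region and the surrounding "healthy" region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .lumped import ThermalTrace

__all__ = [
    "ThermogramStack",
    "RoiMask",
    "roi_timeseries",
    "thermal_contrast_map",
    "dissipation_metrics",
]


@dataclass
class ThermogramStack:
    """An ordered set of temperature frames with timestamps.

    ``frames`` has shape (n_frames, ny, nx) in degC; ``timestamps`` are
    seconds, strictly increasing; ``pixel_pitch_mm`` is the physical size of
    one pixel.  ``ambient_temp`` may be provided by the recording metadata;
    when absent, consumers fall back to a scene-based estimate.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_pitch_mm: float = 1.0
    ambient_temp: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n, ny, nx) array with n >= 1")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("timestamps length must match number of frames")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RoiMask:
    """A boolean pixel mask naming a region of interest."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one true pixel")

    @classmethod
    def rect(
        cls, shape: tuple[int, int], row0: int, row1: int, col0: int, col1: int,
        label: str = "",
    ) -> "RoiMask":
        """Rectangular ROI covering rows [row0, row1) and cols [col0, col1)."""
        m = np.zeros(shape, dtype=bool)
        m[row0:row1, col0:col1] = True
        return cls(m, label)


def roi_timeseries(
    stack: ThermogramStack, roi: RoiMask, reducer: str = "max"
) -> ThermalTrace:
    """Per-frame ROI temperature as a thermal trace.

    ``reducer`` is ``"max"`` (hotspot convention, the default — camera
    readouts report peak temperatures) or ``"mean"``.  The trace's ambient
    reference is the stack's recorded ambient temperature when available,
    otherwise the mean of the ROI complement in the first frame.  Laser
    on/off times are copied from stack metadata keys ``laser_on_s`` /
    ``laser_off_s`` when present.
    """
    if roi.mask.shape != stack.frame_shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match frames {stack.frame_shape}"
        )
    if reducer not in ("max", "mean"):
        raise ValueError(f"reducer must be 'max' or 'mean', got {reducer!r}")
    pixels = stack.frames[:, roi.mask]
    temps = pixels.max(axis=1) if reducer == "max" else pixels.mean(axis=1)

    if stack.ambient_temp is not None:
        ambient = float(stack.ambient_temp)
    else:
        complement = ~roi.mask
        ambient = (
            float(stack.frames[0][complement].mean())
            if complement.any()
            else float(stack.frames[0].mean())
        )

    return ThermalTrace(
        times=stack.timestamps,
        temps=temps,
        ambient_temp=ambient,
        laser_on_time=float(stack.metadata.get("laser_on_s", 0.0)),
        laser_off_time=stack.metadata.get("laser_off_s"),
        metadata={"roi": roi.label, "reducer": reducer},
    )


def thermal_contrast_map(
    stack: ThermogramStack, baseline_index: int = 0
) -> np.ndarray:
    """Elementwise temperature change: last frame minus the baseline frame."""
    n = stack.frames.shape[0]
    if not -n <= baseline_index < n:
        raise ValueError(f"baseline_index {baseline_index} out of range for {n} frames")
    return stack.frames[-1] - stack.frames[baseline_index]


def dissipation_metrics(
    contrast: np.ndarray, tumor: RoiMask, healthy: RoiMask
) -> tuple[float, float]:
    """Peak temperature change inside the tumor and healthy regions.

    Quantifies heat confinement: a selective photothermal agent shows a
    large tumor rise with the surrounding healthy region nearly unchanged.
    Masks must be disjoint.
    """
    contrast = np.asarray(contrast, dtype=float)
    if tumor.mask.shape != contrast.shape or healthy.mask.shape != contrast.shape:
        raise ValueError("mask shapes must match the contrast map")
    if (tumor.mask & healthy.mask).any():
        raise ValueError("tumor and healthy masks overlap")
    return float(contrast[tumor.mask].max()), float(contrast[healthy.mask].max())
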