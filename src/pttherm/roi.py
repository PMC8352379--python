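"""Hotspot ROI location and per-frame reduction of thermograph stacks.

The analysis fixes one circular ROI per tumor (30-pixel diameter by default),
placed to encompass the maximum temperature values, and reduces each frame to
the ROI mean ± SD. ROI placement is determinized as the global spatiotemporal
maximum at or after laser-on; ties break to the first pixel in (frame, row,
col) order. If the maximum sits closer than one radius to the frame edge the
center is shifted minimally inward so the full circle fits, keeping the
member-pixel count identical across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pttherm.io import TemperatureTrace, ThermalFrameStack


@dataclass
class ROISpec:
    """A circular pixel set: all pixels whose centers lie within diameter/2 of center."""

    center: tuple[int, int]
    diameter: float = 30.0
    member_pixels: np.ndarray = field(default=None, repr=False)  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.member_pixels is None:
            self.member_pixels = circle_pixels(self.center, self.diameter)

    @property
    def n_pixels(self) -> int:
        return len(self.member_pixels)


def circle_pixels(center: tuple[int, int], diameter: float) -> np.ndarray:
    """All integer (row, col) pixels with center at Euclidean distance ≤ diameter/2.

    Membership uses pixel-center distance with inclusive boundary.
    """
    r = diameter / 2.0
    cr, cc = center
    span = int(np.floor(r))
    rows, cols = np.mgrid[cr - span:cr + span + 1, cc - span:cc + span + 1]
    dist2 = (rows - cr) ** 2 + (cols - cc) ** 2
    keep = dist2 <= r * r + 1e-12
    return np.column_stack([rows[keep], cols[keep]])


def _fit_center_inside(center: tuple[int, int], diameter: float,
                       shape: tuple[int, int]) -> tuple[int, int]:
    """Shift center minimally inward so the full circle fits in the frame."""
    span = int(np.floor(diameter / 2.0))
    h, w = shape
    if h < 2 * span + 1 or w < 2 * span + 1:
        raise ValueError(
            f"frame of shape {shape} cannot contain a circle of diameter {diameter} "
            f"(needs at least {2 * span + 1} pixels per side)"
        )
    cr = min(max(center[0], span), h - 1 - span)
    cc = min(max(center[1], span), w - 1 - span)
    return int(cr), int(cc)


def locate_roi(stack: ThermalFrameStack, diameter_px: float = 30.0) -> ROISpec:
    """Place the ROI at the hottest pixel over all frames at/after laser-on.

    Returns an ROISpec centered on the global spatiotemporal maximum
    (first in (frame, row, col) order on ties), shifted inward if needed so
    the circle fits inside the frame.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    heated = stack.frames[stack.laser_on_index:]
    # np.argmax returns the first maximum in C order = (frame, row, col) lexicographic
    flat = int(np.argmax(heated))
    _, row, col = np.unravel_index(flat, heated.shape)
    center = _fit_center_inside((int(row), int(col)), diameter_px, stack.shape)
    return ROISpec(center=center, diameter=diameter_px)


def roi_trace(stack: ThermalFrameStack, roi: ROISpec) -> TemperatureTrace:
    """Reduce each frame to the ROI mean and population SD.

    Times are relative to laser-on, from the stack's frame period and
    laser-on index.
    """
    if roi.n_pixels == 0:
        raise ValueError("ROI has no member pixels")
    rows = roi.member_pixels[:, 0]
    cols = roi.member_pixels[:, 1]
    h, w = stack.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError(f"ROI at {roi.center} (diameter {roi.diameter}) exceeds frame bounds {stack.shape}")
    values = stack.frames[:, rows, cols]  # (n_frames, n_pixels)
    return TemperatureTrace(
        times=stack.times,
        temp_mean=values.mean(axis=1),
        temp_sd=values.std(axis=1, ddof=0),
        animal_id=stack.source_id,
        meta={"roi_center": roi.center, "roi_diameter": roi.diameter,
              "roi_n_pixels": roi.n_pixels,
              "roi_placement": "global spatiotemporal maximum"},
    )
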