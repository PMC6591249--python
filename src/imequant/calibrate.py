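"""Camera calibration: dark-current estimation and dynamic-range assessment.

Dark current is estimated as the per-pixel median over a stack of frames
acquired with no light; the estimate is subtracted from every experimental
frame before any quantification.  The linear dynamic range of the camera is
assessed from a dilution series: levels driven into sensor saturation are
excluded outright, then the highest remaining level is dropped greedily
until a least-squares line fits the survivors with r-squared above a strict
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .frames import ImageFrame
from .simcam import DarkCurrentMap

__all__ = [
    "LinearityError",
    "LinearityReport",
    "estimate_dark_current",
    "correct_frame",
    "assess_linearity",
]


class LinearityError(ValueError):
    """Raised when no linear range can be identified in a dilution series."""


@dataclass(frozen=True)
class LinearityReport:
    """Result of fitting the linear dynamic range of a dilution series.

    ``linear_levels`` is the maximal contiguous run of concentration levels
    classified linear; ``fold_range`` is the ratio of its highest to lowest
    concentration; ``r_squared`` is computed on those levels only.
    """

    slope: float
    intercept: float
    r_squared: float
    linear_levels: tuple[float, ...]
    fold_range: float


def estimate_dark_current(dark_frames: Sequence[ImageFrame]) -> DarkCurrentMap:
    """Per-pixel median over a stack of dark frames.

    For an even number of frames the lower of the two middle order
    statistics is taken (integer-preserving), rather than their average.
    """
    if len(dark_frames) == 0:
        raise ValueError("at least one dark frame is required")
    shape = dark_frames[0].shape
    for f in dark_frames:
        if f.shape != shape:
            raise ValueError(f"dark frame shapes differ: {f.shape} vs {shape}")
    stack = np.stack([np.asarray(f.pixels) for f in dark_frames])
    n = stack.shape[0]
    stack.sort(axis=0)
    return DarkCurrentMap(offsets=stack[(n - 1) // 2].astype(float))


def correct_frame(frame: ImageFrame, dark: DarkCurrentMap) -> ImageFrame:
    """Subtract the dark-current map pixelwise; negatives are preserved."""
    if frame.shape != dark.shape:
        raise ValueError(f"frame shape {frame.shape} != dark map shape {dark.shape}")
    corrected = np.asarray(frame.pixels, dtype=float) - dark.offsets
    return frame.with_pixels(corrected)


def assess_linearity(
    level_means: Sequence[tuple[float, float]],
    r2_min: float = 0.99,
    saturation: float = 2**16 - 1,
    raw_level_means: Sequence[float] | None = None,
) -> LinearityReport:
    """Identify the linear dynamic range of a dilution series.

    Parameters
    ----------
    level_means:
        ``(concentration, mean corrected masked ADU)`` pairs, concentrations
        strictly increasing.
    r2_min:
        Minimum r-squared for the surviving levels to count as linear.
    saturation:
        Sensor saturation in ADU; levels whose *raw* mean exceeds
        ``0.95 * saturation`` are excluded before fitting.
    raw_level_means:
        Raw (uncorrected) mean ADU per level, used for the saturation guard.
        When omitted the corrected means stand in, which only matters within
        one dark-offset of the guard.
    """
    if len(level_means) < 3:
        raise ValueError("at least 3 concentration levels are required")
    conc = np.array([c for c, _ in level_means], dtype=float)
    mean_adu = np.array([m for _, m in level_means], dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    raw = mean_adu if raw_level_means is None else np.asarray(raw_level_means, float)
    if raw.shape != conc.shape:
        raise ValueError("raw_level_means length mismatch")

    keep = raw <= 0.95 * saturation
    conc, mean_adu = conc[keep], mean_adu[keep]

    while len(conc) >= 3:
        fit = stats.linregress(conc, mean_adu)
        r2 = fit.rvalue**2
        if r2 >= r2_min:
            return LinearityReport(
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(r2),
                linear_levels=tuple(conc),
                fold_range=float(conc[-1] / conc[0]),
            )
        conc, mean_adu = conc[:-1], mean_adu[:-1]
    raise LinearityError(
        f"no linear range: fewer than 3 levels satisfy r^2 >= {r2_min} "
        "below the saturation guard"
    )
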