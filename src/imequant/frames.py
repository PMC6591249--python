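"""Single-channel image frames and TIFF input/output.

The whole pipeline operates on :class:`ImageFrame`, a thin container around
a 2-D pixel array plus the two pieces of metadata the analysis needs: the
lateral pixel size in micrometers and the camera bit depth.  Raw frames hold
unsigned integers; dark-corrected frames hold signed floats (subtraction may
legitimately go below zero and is never clamped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

#: lateral sampling of the default instrument geometry, micrometers / pixel
DEFAULT_PIXEL_SIZE_UM = 2.7


@dataclass(frozen=True)
class ImageFrame:
    """A single-channel 2-D image with acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D array, row-major, origin at the top-left, indexed (row, col).
    pixel_size_um:
        Lateral size of one pixel in micrometers.
    bit_depth:
        ADC bit depth of the source camera (16 for the default model).
        Retained on corrected (float) frames so saturation can still be
        reasoned about downstream.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {px.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        """Return a copy carrying new pixel data but the same metadata."""
        return replace(self, pixels=pixels)


def write_tiff(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as a single-image grayscale TIFF.

    Integer frames are stored as 16-bit unsigned, corrected frames as 32-bit
    float, with the pixel size recorded in the TIFF resolution tags.
    """
    px = frame.pixels
    if np.issubdtype(px.dtype, np.integer):
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float32)
    px_per_cm = 1e4 / frame.pixel_size_um
    tifffile.imwrite(
        Path(path), data, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
    )


def read_tiff(path: str | Path, bit_depth: int = 16) -> ImageFrame:
    """Read a single-image grayscale TIFF written by :func:`write_tiff`."""
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        pixel_size = DEFAULT_PIXEL_SIZE_UM
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None and unit.value == 3:  # centimeter
            num, den = res.value
            if num > 0:
                pixel_size = 1e4 * den / num
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale TIFF")
    return ImageFrame(pixels=data, pixel_size_um=pixel_size, bit_depth=bit_depth)
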