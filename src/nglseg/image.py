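"""Scene containers and raster I/O.

A scene is a small multi-channel raster (RGB UAV orthomosaic crop or a
synthetic stand-in) together with a declared value range, either 8-bit
integer (``"uint8"``, values 0..255) or unit float (``"unit"``, values in
[0, 1]).  Binary ground-truth masks use 0 = background, 1 = target.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

VALUE_RANGES = ("uint8", "unit")


def _validate_pixels(pixels: np.ndarray, value_range: str) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = pixels[:, :, None]
    if pixels.ndim != 3:
        raise ValueError(f"scene pixels must be HxWxC, got shape {pixels.shape}")
    if pixels.shape[2] not in (1, 3):
        raise ValueError(f"channel count must be 1 or 3, got {pixels.shape[2]}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("scene contains non-finite values")
    if value_range not in VALUE_RANGES:
        raise ValueError(f"value_range must be one of {VALUE_RANGES}")
    if value_range == "uint8":
        if pixels.min() < 0 or pixels.max() > 255:
            raise ValueError("uint8 scene has values outside [0, 255]")
    else:
        if pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9:
            raise ValueError("unit scene has values outside [0, 1]")
    return pixels


@dataclass
class SceneImage:
    """A height x width x channels intensity grid with range metadata."""

    pixels: np.ndarray
    value_range: str = "unit"

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels, self.value_range)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def range_bounds(self) -> tuple[float, float]:
        return (0.0, 255.0) if self.value_range == "uint8" else (0.0, 1.0)

    def as_unit_float(self) -> np.ndarray:
        """Pixels rescaled to float64 in [0, 1] (network input convention)."""
        x = self.pixels.astype(np.float64)
        if self.value_range == "uint8":
            x = x / 255.0
        return x

    def channel(self, c: int) -> np.ndarray:
        """One channel as a 2-D float matrix (the matrix P of the decomposition)."""
        return np.asarray(self.pixels[:, :, c], dtype=np.float64)


@dataclass
class EnhancedImage:
    """Result of sparse enhancement: clip(P + S) with per-channel diagnostics."""

    pixels: np.ndarray
    value_range: str
    kernel_used: str
    per_channel_results: list = field(default_factory=list)

    def scene(self) -> SceneImage:
        return SceneImage(self.pixels, self.value_range)


# ---------------------------------------------------------------------------
# raster I/O — PNG through imageio, TIFF through tifffile


def read_image(path: str | os.PathLike) -> SceneImage:
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        return SceneImage(arr.astype(np.float64), "uint8")
    return SceneImage(arr.astype(np.float64), "unit")


def write_image(scene: SceneImage, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if scene.value_range == "uint8":
        arr = np.clip(np.rint(scene.pixels), 0, 255).astype(np.uint8)
    else:
        arr = np.clip(scene.pixels, 0.0, 1.0)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr if arr.ndim == 3 and arr.shape[2] == 3 else arr[:, :, 0])
        return
    import imageio.v3 as iio

    if scene.value_range == "unit":
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr if arr.shape[2] == 3 else arr[:, :, 0])


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Binary mask from PNG; tolerant of {0,1} and {0,255} encodings."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(os.fspath(path)))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > arr.max() / 2).astype(np.uint8) if arr.max() > 1 else arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    import imageio.v3 as iio

    mask = np.asarray(mask)
    iio.imwrite(os.fspath(path), (mask > 0).astype(np.uint8) * 255)
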