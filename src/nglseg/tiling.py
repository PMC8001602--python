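"""Sliding-window patch extraction and full-scene reassembly.

Coordinates are 0-based, row-major; windows are half-open
[row, row + h) x [col, col + w).  Border remainders that do not admit a
full window are dropped, so the patch count is
(floor((W - w)/sx) + 1) * (floor((H - h)/sy) + 1).

On the study geometry (1300 px wide x 1000 px tall, 260 x 200 windows)
this yields 289 overlapping training patches at strides (65, 50) and 25
non-overlapping test patches at strides (260, 200).  Window sizes are
given width x height; that is the only reading consistent with both patch
counts on the study scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import SceneImage


@dataclass(frozen=True)
class TileSpec:
    window_w: int
    window_h: int
    stride_x: int
    stride_y: int

    def __post_init__(self) -> None:
        if min(self.window_w, self.window_h, self.stride_x, self.stride_y) <= 0:
            raise ValueError("window dims and strides must be positive")

    @property
    def non_overlapping(self) -> bool:
        return self.stride_x >= self.window_w and self.stride_y >= self.window_h

    def origins(self, height: int, width: int) -> list[tuple[int, int]]:
        """Row-major list of admissible (row, col) window origins."""
        if self.window_w > width or self.window_h > height:
            raise ValueError(
                f"window {self.window_w}x{self.window_h} exceeds image "
                f"extent {width}x{height}")
        rows = range(0, height - self.window_h + 1, self.stride_y)
        cols = range(0, width - self.window_w + 1, self.stride_x)
        return [(r, c) for r in rows for c in cols]

    def count(self, height: int, width: int) -> int:
        if self.window_w > width or self.window_h > height:
            raise ValueError("window exceeds image extent")
        return ((width - self.window_w) // self.stride_x + 1) * \
               ((height - self.window_h) // self.stride_y + 1)


@dataclass
class PatchSet:
    """Co-registered image/mask windows with their origins.

    images: (N, h, w, C) float array; masks: (N, h, w) uint8 (may be None
    when tiling a scene without ground truth).
    """

    origins: list[tuple[int, int]]
    images: np.ndarray
    masks: np.ndarray | None
    spec: TileSpec
    image_extent: tuple[int, int]

    def __len__(self) -> int:
        return len(self.origins)


def extract_patches(image: SceneImage, mask: np.ndarray | None,
                    spec: TileSpec) -> PatchSet:
    """Slide a window over the scene, dropping partial border windows."""
    H, W = image.height, image.width
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != (H, W):
            raise ValueError(f"mask shape {mask.shape} != image extent {(H, W)}")
    origins = spec.origins(H, W)
    h, w = spec.window_h, spec.window_w
    images = np.stack([image.pixels[r:r + h, c:c + w] for r, c in origins])
    masks = None
    if mask is not None:
        masks = np.stack([mask[r:r + h, c:c + w] for r, c in origins]).astype(np.uint8)
    return PatchSet(origins=origins, images=images, masks=masks, spec=spec,
                    image_extent=(H, W))


def stitch_predictions(origins: list[tuple[int, int]], patches: np.ndarray,
                       image_extent: tuple[int, int], spec: TileSpec
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble per-patch score grids into a full-scene grid.

    Requires a non-overlapping spec. Returns (scores, covered) where
    ``covered`` flags pixels written by some window; uncovered pixels hold
    NaN and must be excluded from metrics.
    """
    if not spec.non_overlapping:
        raise ValueError("stitching requires a non-overlapping TileSpec "
                         "(stride >= window in both axes)")
    H, W = image_extent
    patches = np.asarray(patches, dtype=np.float64)
    if patches.shape[0] != len(origins):
        raise ValueError("number of patch grids != number of origins")
    h, w = spec.window_h, spec.window_w
    full = np.full((H, W), np.nan)
    covered = np.zeros((H, W), dtype=bool)
    for (r, c), patch in zip(origins, patches):
        if patch.shape != (h, w):
            raise ValueError(f"patch shape {patch.shape} != window {(h, w)}")
        full[r:r + h, c:c + w] = patch
        covered[r:r + h, c:c + w] = True
    return full, covered


# study geometry defaults (width x height window; train/test strides)
STUDY_WINDOW = (260, 200)
STUDY_TRAIN_SPEC = TileSpec(window_w=260, window_h=200, stride_x=65, stride_y=50)
STUDY_TEST_SPEC = TileSpec(window_w=260, window_h=200, stride_x=260, stride_y=200)
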