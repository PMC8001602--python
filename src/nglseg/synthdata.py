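"""Seeded synthetic canopy scenes with planted sparse targets.

Real flight scenes of the kind this method targets are rarely deposited,
so every pipeline stage is exercised on generated scenes that reproduce
the statistical structure the method assumes:

* a smooth low-rank background — per channel a sum of at most
  ``background_rank`` separable (outer-product) smooth fields around a
  canopy-green base color, plus Gaussian texture noise;
* sparse, clustered, bright light-green targets — disc-shaped blob
  clusters covering ~3-4% of the pixels, receiving an additive
  per-channel color shift dominated by the green band;
* an exact planted-target indicator mask.

Scenes are float images in [0, 1] ("unit" range).  The generator is fully
driven by one integer seed: identical config + seed gives bit-identical
output.  What it deliberately does NOT model: leaf-scale texture of the
targets, atmospheric/radiometric effects, photorealistic canopy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk

from .image import SceneImage

DEFAULT_BASE_COLOR = (0.16, 0.34, 0.12)  # muted canopy green
DEFAULT_TARGET_SHIFT = (0.08, 0.20, 0.03)  # bright light-green offset
LOW_CONTRAST_TARGET_SHIFT = (0.03, 0.08, 0.012)


@dataclass(frozen=True)
class SyntheticSceneConfig:
    height: int = 512
    width: int = 512
    channels: int = 3
    background_rank: int = 3
    background_noise_sd: float = 0.02
    n_target_clusters: int = 12
    cluster_radius_px: tuple[int, int] = (4, 24)
    target_prevalence: float = 0.035
    target_color_shift: tuple[float, ...] = DEFAULT_TARGET_SHIFT
    base_color: tuple[float, ...] = DEFAULT_BASE_COLOR
    distractor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 0.5:
            raise ValueError("target_prevalence must be in (0, 0.5)")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.background_rank < 1:
            raise ValueError("background_rank must be >= 1")
        r_lo, r_hi = self.cluster_radius_px
        if not 0 < r_lo <= r_hi:
            raise ValueError("cluster_radius_px must be a positive (lo, hi) range")
        if len(self.target_color_shift) != self.channels:
            raise ValueError("target_color_shift length must match channels")

    def low_contrast(self) -> "SyntheticSceneConfig":
        """Same geometry with a weak target color shift (hard scenes)."""
        shift = LOW_CONTRAST_TARGET_SHIFT[: self.channels]
        return replace(self, target_color_shift=shift)


def _smooth_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth zero-mean 1-D field, unit max amplitude."""
    raw = gaussian_filter1d(rng.normal(size=n), sigma=max(4.0, n / 8.0))
    raw -= raw.mean()
    amp = np.abs(raw).max()
    return raw / amp if amp > 0 else raw


def background_field(cfg: SyntheticSceneConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Noise-free low-rank background, (H, W, C); per-channel rank is at
    most cfg.background_rank (one constant plus rank-1 smooth modes)."""
    H, W, C = cfg.height, cfg.width, cfg.channels
    bg = np.empty((H, W, C))
    modes = [(_smooth_profile(rng, H), _smooth_profile(rng, W))
             for _ in range(cfg.background_rank - 1)]
    for c in range(C):
        field = np.full((H, W), cfg.base_color[c])
        for u, v in modes:
            field = field + rng.uniform(0.02, 0.06) * np.outer(u, v)
        bg[:, :, c] = field
    return bg


def _plant_clusters(cfg: SyntheticSceneConfig,
                    rng: np.random.Generator) -> np.ndarray:
    H, W = cfg.height, cfg.width
    target_px = cfg.target_prevalence * H * W
    n = cfg.n_target_clusters
    r_lo, r_hi = cfg.cluster_radius_px

    # feasibility: clusters can over-paint ~3x a single disc while growing
    if n * np.pi * r_hi ** 2 * 3.0 < 0.8 * target_px:
        raise ValueError("target_prevalence unreachable: clusters too small/few")
    if n * np.pi * r_lo ** 2 > 1.2 * target_px:
        raise ValueError("target_prevalence unreachable: clusters too large/many")

    quota = target_px / n
    r0 = float(np.clip(np.sqrt(quota / np.pi), r_lo, r_hi))
    margin = int(np.ceil(r0)) + 2
    mask = np.zeros((H, W), dtype=np.uint8)
    centers = np.column_stack([
        rng.integers(margin, H - margin, size=n),
        rng.integers(margin, W - margin, size=n),
    ])
    for cy, cx in centers:
        rr, cc = disk((cy, cx), r0, shape=(H, W))
        mask[rr, cc] = 1
    # grow clusters with jittered sub-discs until the planted count is
    # close to the requested prevalence (hard stop well inside +-20%)
    guard = 0
    while mask.sum() < 0.92 * target_px and guard < 200 * n:
        guard += 1
        cy, cx = centers[rng.integers(0, n)]
        dy, dx = rng.integers(-int(r0), int(r0) + 1, size=2)
        rr, cc = disk((int(cy + dy), int(cx + dx)), max(r_lo, r0 / 2),
                      shape=(H, W))
        mask[rr, cc] = 1
    realized = mask.sum() / (H * W)
    if not (0.8 * cfg.target_prevalence <= realized <= 1.2 * cfg.target_prevalence):
        raise ValueError(
            f"target_prevalence unreachable with given cluster geometry: "
            f"requested {cfg.target_prevalence:.4f}, realized {realized:.4f}")
    return mask


def _paint_distractor(scene: np.ndarray, rng: np.random.Generator) -> None:
    """Bright non-target texture in the lower-right corner (false-alarm
    bait; carries no mask labels)."""
    H, W, C = scene.shape
    r0, c0 = 3 * H // 4, 3 * W // 4
    region = scene[r0:, c0:]
    region += rng.normal(0.0, 0.05, size=region.shape)
    shift = np.array([0.18, 0.12, 0.02][:C])  # bright but yellow-brown
    for _ in range(4):
        cy = rng.integers(r0 + 8, H - 8)
        cx = rng.integers(c0 + 8, W - 8)
        rr, cc = disk((cy, cx), rng.integers(4, 10), shape=(H, W))
        scene[rr, cc] += shift


def generate_scene(cfg: SyntheticSceneConfig) -> tuple[SceneImage, np.ndarray]:
    """One scene + exact target mask, deterministically from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    scene = background_field(cfg, rng)
    scene += rng.normal(0.0, cfg.background_noise_sd, size=scene.shape)
    if cfg.n_target_clusters > 0:
        mask = _plant_clusters(cfg, rng)
        shift = np.asarray(cfg.target_color_shift)
        scene[mask.astype(bool)] += shift
    else:
        mask = np.zeros((cfg.height, cfg.width), dtype=np.uint8)
    if cfg.distractor:
        _paint_distractor(scene, rng)
    np.clip(scene, 0.0, 1.0, out=scene)
    return SceneImage(scene, "unit"), mask


@dataclass
class ScenePair:
    image: SceneImage
    mask: np.ndarray
    role: str
    config: SyntheticSceneConfig


def generate_paired_areas(cfg_train: SyntheticSceneConfig,
                          cfg_test: SyntheticSceneConfig | None = None
                          ) -> tuple[ScenePair, ScenePair]:
    """Two independent scenes for the cross-area protocol (train on one
    area, test on the other).  If cfg_test is omitted, the train config is
    reused with a decorrelated seed."""
    if cfg_test is None:
        cfg_test = replace(cfg_train, seed=cfg_train.seed + 104729)
    if cfg_train.channels != cfg_test.channels:
        raise ValueError("train and test scenes must share a channel count")
    if cfg_train.seed == cfg_test.seed:
        cfg_test = replace(cfg_test, seed=cfg_test.seed + 104729)
    img_tr, mask_tr = generate_scene(cfg_train)
    img_te, mask_te = generate_scene(cfg_test)
    return (ScenePair(img_tr, mask_tr, "train", cfg_train),
            ScenePair(img_te, mask_te, "test", cfg_test))
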