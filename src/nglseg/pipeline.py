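"""End-to-end orchestration: enhance -> tile -> train -> predict -> stitch
-> evaluate, plus the beta-sweep and kernel-sweep experiment runners.

A run is described by a :class:`RunConfig`; one global integer seed fans
out deterministically to scene generation, weight initialisation, and
batch shuffling, so identical configs reproduce identical report rows on
one device.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .enhance import sparse_enhance
from .image import SceneImage, write_image, write_mask
from .losses import LossConfig
from .metrics import EvaluationReport, evaluate, render_result_map
from .models import SegmentationNetwork, TrainConfig, build_model, fit_network
from .rpca import RpcaConfig
from .synthdata import ScenePair, SyntheticSceneConfig, generate_paired_areas
from .tiling import PatchSet, TileSpec, extract_patches, stitch_predictions

_SEED_MOD = 2**31


@dataclass
class RunConfig:
    """Everything one experiment run needs.

    Desk-scale defaults: 128x96 training windows with quarter-window
    strides on a 512x512 scene, the shallow skip-connection model, and the
    positively-weighted balanced cross-entropy at beta = 0.99.
    """

    model: str = "3l_usn"
    loss: LossConfig = field(default_factory=LossConfig)
    enhance: bool = True
    rpca: RpcaConfig = field(default_factory=RpcaConfig)
    train_spec: TileSpec = field(
        default_factory=lambda: TileSpec(window_w=128, window_h=96,
                                         stride_x=32, stride_y=24))
    test_spec: TileSpec = field(
        default_factory=lambda: TileSpec(window_w=128, window_h=96,
                                         stride_x=128, stride_y=96))
    train: TrainConfig = field(default_factory=TrainConfig)
    width_scale: float = 1.0
    threshold: float = 0.5
    max_train_patches: int | None = None
    seed: int = 0

    def child_seed(self, k: int) -> int:
        return (self.seed * 7919 + k) % _SEED_MOD


def train_model(network: SegmentationNetwork, patches: PatchSet,
                loss: LossConfig, train_cfg: TrainConfig) -> tuple[SegmentationNetwork, list[dict]]:
    """Train a network on a PatchSet; returns it with the best-loss
    parameters restored, plus the per-epoch loss history."""
    if patches.masks is None:
        raise ValueError("training requires mask windows in the PatchSet")
    history = fit_network(network, patches.images, patches.masks, loss, train_cfg)
    return network, history


def predict_scene(network: SegmentationNetwork, scene: SceneImage,
                  spec: TileSpec, batch_size: int = 8
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Tile the scene (non-overlapping), run the network per patch, and
    stitch the score grids back.  Returns (scores, covered)."""
    patches = extract_patches(scene, None, spec)
    X = patches.images.astype(np.float32)
    if scene.value_range == "uint8":
        X = X / 255.0
    preds = np.empty(X.shape[:3], dtype=np.float64)
    for start in range(0, len(X), batch_size):
        preds[start:start + batch_size] = network.forward(X[start:start + batch_size])
    return stitch_predictions(patches.origins, preds, patches.image_extent, spec)


def _config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(cfg: RunConfig, train_pair: ScenePair, test_pair: ScenePair,
                   out_dir: str | None = None) -> dict:
    """One full run on a train/test scene pair; returns a report row."""
    train_img, test_img = train_pair.image, test_pair.image
    kernel = "none"
    if cfg.enhance:
        kernel = cfg.rpca.kernel
        train_img = sparse_enhance(train_img, cfg.rpca).scene()
        test_img = sparse_enhance(test_img, cfg.rpca).scene()

    patches = extract_patches(train_img, train_pair.mask, cfg.train_spec)
    X = patches.images.astype(np.float32)
    if train_img.value_range == "uint8":
        X = X / 255.0
    y = patches.masks
    if cfg.max_train_patches is not None and len(X) > cfg.max_train_patches:
        rng = np.random.default_rng(cfg.child_seed(3))
        sel = rng.choice(len(X), size=cfg.max_train_patches, replace=False)
        X, y = X[sel], y[sel]

    _, network = build_model(cfg.model, input_channels=train_img.channels,
                             seed=cfg.child_seed(1), width_scale=cfg.width_scale)
    train_cfg = replace(cfg.train, seed=cfg.child_seed(2))
    history = fit_network(network, X, y, cfg.loss, train_cfg)

    scores, covered = predict_scene(network, test_img, cfg.test_spec,
                                    batch_size=cfg.train.batch_size)
    report = evaluate(scores[covered], test_pair.mask[covered], cfg.threshold)
    row = {
        "model": cfg.model, "kernel": kernel,
        "loss": cfg.loss.kind, "beta": cfg.loss.beta,
        "auc": report.auc, "tpr": report.tpr, "fpr": report.fpr,
        "acc": report.acc, "kappa": report.kappa,
        "epochs_run": len(history), "seed": cfg.seed,
    }
    if out_dir is not None:
        _write_artifacts(out_dir, cfg, row, test_img, test_pair.mask,
                         scores, covered, network)
    return row


def _write_artifacts(out_dir: str, cfg: RunConfig, row: dict,
                     test_img: SceneImage, truth: np.ndarray,
                     scores: np.ndarray, covered: np.ndarray,
                     network: SegmentationNetwork) -> None:
    import imageio.v3 as iio
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    write_image(test_img, os.path.join(out_dir, "test_scene.png"))
    write_mask(truth, os.path.join(out_dir, "test_mask.png"))
    pred = np.where(covered, scores >= cfg.threshold, 0).astype(np.uint8)
    tri = render_result_map(pred, truth, source=test_img.as_unit_float())
    iio.imwrite(os.path.join(out_dir, "result_map.png"), tri)
    network.save(os.path.join(out_dir, "model.npz"))
    pd.DataFrame([row]).to_csv(os.path.join(out_dir, "report.csv"), index=False)
    manifest = {"config": dataclasses.asdict(cfg), "config_hash": _config_digest(cfg),
                "seed": cfg.seed}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def run_synthetic_experiment(cfg: RunConfig,
                             scene_cfg: SyntheticSceneConfig | None = None,
                             out_dir: str | None = None) -> dict:
    """Generate a train/test scene pair from the run seed, then run."""
    scene_cfg = scene_cfg or SyntheticSceneConfig()
    scene_cfg = replace(scene_cfg, seed=cfg.child_seed(10))
    pair_tr, pair_te = generate_paired_areas(scene_cfg)
    return run_experiment(cfg, pair_tr, pair_te, out_dir=out_dir)


def sweep_beta(base: RunConfig, betas: list[float], train_pair: ScenePair,
               test_pair: ScenePair) -> list[dict]:
    """One row per beta (balanced cross-entropy weight), same scenes/seed."""
    rows = []
    for beta in betas:
        cfg = replace(base, loss=LossConfig(kind="bce", beta=beta))
        rows.append(run_experiment(cfg, train_pair, test_pair))
    return rows


def sweep_kernels(base: RunConfig, kernels: list[str], train_pair: ScenePair,
                  test_pair: ScenePair) -> list[dict]:
    """One row per enhancement kernel; 'none' disables enhancement and
    serves as the ablation baseline."""
    rows = []
    for kernel in kernels:
        if kernel == "none":
            cfg = replace(base, enhance=False)
        else:
            cfg = replace(base, enhance=True,
                          rpca=replace(base.rpca, kernel=kernel))
        rows.append(run_experiment(cfg, train_pair, test_pair))
    return rows
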