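"""Sparse enhancement: E = P + S.

Each channel of the scene is decomposed into low-rank background plus a
sparse residual, and the sparse part is added back onto the original
pixels, amplifying rare bright anomalies (candidate new-leaf patches)
while leaving the smooth canopy essentially untouched.  The sum is clipped
to the scene's declared value range.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image import EnhancedImage, SceneImage
from .rpca import RpcaConfig, decompose


class SparseEnhancer(BaseEstimator, TransformerMixin):
    """Per-channel RPCA sparse enhancement as a stateless transformer.

    The decomposition runs independently on every channel so that
    E_c = clip(P_c + S_c) holds exactly per channel.  ``transform`` accepts
    an (H, W, C) array in the declared value range and returns the enhanced
    array; :meth:`enhance` keeps the full diagnostics.
    """

    def __init__(self, kernel: str = "godec", rank: int = 2,
                 cardinality: Optional[int] = None,
                 lambda_reg: Optional[float] = None,
                 max_iter: int = 100, tol: float = 1e-6,
                 value_range: str = "unit"):
        self.kernel = kernel
        self.rank = rank
        self.cardinality = cardinality
        self.lambda_reg = lambda_reg
        self.max_iter = max_iter
        self.tol = tol
        self.value_range = value_range

    def _config(self) -> RpcaConfig:
        return RpcaConfig(kernel=self.kernel, rank_bound=self.rank,
                          cardinality_bound=self.cardinality,
                          lambda_reg=self.lambda_reg,
                          max_iter=self.max_iter, tol=self.tol)

    def fit(self, X, y=None):
        self._config()  # validate hyperparameters
        return self

    def transform(self, X) -> np.ndarray:
        return self.enhance(SceneImage(np.asarray(X, dtype=np.float64),
                                       self.value_range)).pixels

    def enhance(self, image: SceneImage) -> EnhancedImage:
        cfg = self._config()
        lo, hi = image.range_bounds()
        out = np.empty_like(image.pixels, dtype=np.float64)
        results = []
        for c in range(image.channels):
            P = image.channel(c)
            res = decompose(P, cfg)
            out[:, :, c] = np.clip(P + res.S, lo, hi)
            results.append(res)
        return EnhancedImage(pixels=out, value_range=image.value_range,
                             kernel_used=cfg.kernel, per_channel_results=results)


def sparse_enhance(image: SceneImage, cfg: RpcaConfig) -> EnhancedImage:
    """Functional form of :class:`SparseEnhancer` driven by an RpcaConfig."""
    enh = SparseEnhancer(kernel=cfg.kernel, rank=cfg.rank_bound,
                         cardinality=cfg.cardinality_bound,
                         lambda_reg=cfg.lambda_reg, max_iter=cfg.max_iter,
                         tol=cfg.tol, value_range=image.value_range)
    return enh.enhance(image)
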