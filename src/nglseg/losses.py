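"""Binary cross-entropy losses for the imbalanced two-class problem.

With ground truth p in {0,1} and predicted probability p_hat in (0,1):

  ce(p, p_hat)        = mean of -[ p log p_hat + (1-p) log(1-p_hat) ]
  wce(p, p_hat, beta) = mean of -[ beta p log p_hat + (1-p) log(1-p_hat) ],
                        beta in (1, 2): up-weights the rare positive class
  bce(p, p_hat, beta) = mean of -[ beta p log p_hat
                                   + (1-beta)(1-p) log(1-p_hat) ],
                        beta in (0, 1): up-weights positives AND suppresses
                        the background term; at beta = 0.99 the
                        positive/negative gradient-weight ratio is 99.

Natural logarithm throughout; predictions are clamped to
[EPS, 1 - EPS] before the logs.  The two betas share a symbol in the
literature but have incompatible ranges and are treated as distinct
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7


def _check(p, p_hat) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if p.shape != p_hat.shape:
        raise ValueError(f"shape mismatch: truth {p.shape} vs prediction {p_hat.shape}")
    return p, np.clip(p_hat, EPS, 1.0 - EPS)


def binary_ce(p, p_hat) -> float:
    p, q = _check(p, p_hat)
    return float(np.mean(-(p * np.log(q) + (1.0 - p) * np.log(1.0 - q))))


def weighted_ce(p, p_hat, beta: float) -> float:
    if not 1.0 < beta < 2.0:
        raise ValueError(f"weighted CE requires beta in (1, 2), got {beta}")
    p, q = _check(p, p_hat)
    return float(np.mean(-(beta * p * np.log(q) + (1.0 - p) * np.log(1.0 - q))))


def balanced_ce(p, p_hat, beta: float) -> float:
    if not 0.0 < beta < 1.0:
        raise ValueError(f"balanced CE requires beta in (0, 1), got {beta}")
    p, q = _check(p, p_hat)
    return float(np.mean(-(beta * p * np.log(q)
                           + (1.0 - beta) * (1.0 - p) * np.log(1.0 - q))))


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: kind in {ce, wce, bce}; beta validated per kind."""

    kind: str = "bce"
    beta: float = 0.99

    def __post_init__(self) -> None:
        if self.kind not in ("ce", "wce", "bce"):
            raise ValueError(f"loss kind must be ce|wce|bce, got {self.kind!r}")
        if self.kind == "wce" and not 1.0 < self.beta < 2.0:
            raise ValueError("wce requires beta in (1, 2)")
        if self.kind == "bce" and not 0.0 < self.beta < 1.0:
            raise ValueError("bce requires beta in (0, 1)")

    def value(self, p, p_hat) -> float:
        if self.kind == "ce":
            return binary_ce(p, p_hat)
        if self.kind == "wce":
            return weighted_ce(p, p_hat, self.beta)
        return balanced_ce(p, p_hat, self.beta)

    def pixel_weights(self) -> tuple[float, float]:
        """(positive, negative) per-pixel log-term weights."""
        if self.kind == "ce":
            return 1.0, 1.0
        if self.kind == "wce":
            return self.beta, 1.0
        return self.beta, 1.0 - self.beta

    def grad_logits(self, p, p_hat) -> np.ndarray:
        """dLoss/dz with p_hat = sigmoid(z), per pixel, before the mean.

        For all three losses: w_pos * p * (p_hat - 1) + w_neg * (1-p) * p_hat.
        """
        p, q = _check(p, p_hat)
        w_pos, w_neg = self.pixel_weights()
        return w_pos * p * (q - 1.0) + w_neg * (1.0 - p) * q
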