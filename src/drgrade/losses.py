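"""Classification losses for long-tailed grade distributions.

Besides plain cross entropy and a focal-loss baseline, this module
implements the complement-entropy family.  For a sample with true class g
and predicted distribution ŷ over K classes, the complement entropy is the
Shannon entropy of the predictions restricted to the *incorrect* classes,

    C = −(1/N) Σ_i Σ_{j≠g} p_ij · log p_ij,     p_ij = ŷ_i[j] / (1 − ŷ_i[g]),

averaged over the mini-batch.  Flattening the incorrect-class mass makes the
true class — including rare classes — stand out, so training that *raises*
C counteracts the dominance of the majority grade.  The combined objective

    L = H(y, ŷ) + γ/(K−1) · C

uses the balance coefficient 1/(K−1) to put the two terms on the same scale
and an adjustment factor γ; the default γ = −1 means minimising L maximises
the complement entropy.  Positive γ is accepted for the literal additive
form.

Every loss exists in two forms: a plain-numpy function of a
:class:`LabeledBatch` (the reference surface), and a differentiable builder
(:func:`make_training_loss`) operating on probability tensors from
:mod:`drgrade.autodiff` for use in the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "LossConfig",
    "LabeledBatch",
    "cross_entropy",
    "complement_entropy",
    "balanced_complement_entropy",
    "cce_loss",
    "focal_loss",
    "make_training_loss",
    "LOSS_NAMES",
]

_TINY = 1e-300  # p·log p continuation point; well below any reachable probability

LOSS_NAMES = ("ce", "focal", "cce")


@dataclass
class LossConfig:
    """Shared numerical and shape parameters of all losses.

    gamma        adjustment factor γ of the combined objective (default −1,
                 i.e. the complement term is maximised)
    epsilon      clamp applied to probabilities before logs and to 1−ŷ[g];
                 must lie in (0, 1e−3]
    focal_gamma  focusing exponent of the focal baseline (≥ 0)
    focal_alpha  scalar weight of the focal baseline
    """

    gamma: float = -1.0
    epsilon: float = 1e-7
    focal_gamma: float = 2.0
    focal_alpha: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.epsilon <= 1e-3):
            raise ValueError(f"epsilon must be in (0, 1e-3], got {self.epsilon}")


@dataclass
class LabeledBatch:
    """Per-sample predicted distributions plus integer grade labels."""

    probs: np.ndarray      # (N, K), rows on the simplex
    labels: np.ndarray     # (N,), values in [0, K)

    def __post_init__(self):
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=np.float64))
        self.labels = np.atleast_1d(np.asarray(self.labels, dtype=np.intp))
        n, k = self.probs.shape
        if n < 1:
            raise ValueError("batch must contain at least one sample")
        if self.labels.shape != (n,):
            raise ValueError(
                f"got {self.labels.shape[0]} labels for {n} probability rows"
            )
        if np.any(self.probs < -1e-9):
            raise ValueError("probabilities must be nonnegative")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
        if np.any(self.labels < 0) or np.any(self.labels >= k):
            raise IndexError(f"labels must lie in [0, {k})")

    @property
    def num_classes(self) -> int:
        return self.probs.shape[1]


def _target_probs(batch: LabeledBatch) -> np.ndarray:
    return batch.probs[np.arange(len(batch.labels)), batch.labels]


def cross_entropy(batch: LabeledBatch, cfg: LossConfig | None = None) -> float:
    """Mean −log ŷ[g] over the batch (natural logarithm, clamped)."""
    cfg = cfg or LossConfig()
    pg = np.clip(_target_probs(batch), cfg.epsilon, 1.0)
    return float(-np.mean(np.log(pg)))


def complement_entropy(batch: LabeledBatch, cfg: LossConfig | None = None) -> float:
    """Mean entropy of the renormalised incorrect-class distribution.

    Samples whose target probability is (numerically) 1 have no incorrect-
    class mass and contribute 0.  The result lies in [0, log(K−1)].
    """
    cfg = cfg or LossConfig()
    k = batch.num_classes
    if k < 2:
        raise ValueError("complement entropy requires at least 2 classes")
    pg = _target_probs(batch)
    denom = 1.0 - np.clip(pg, 0.0, 1.0 - cfg.epsilon)
    ratios = batch.probs / denom[:, None]
    ratios[np.arange(len(batch.labels)), batch.labels] = 0.0
    # degenerate samples: all non-target mass vanished
    ratios[pg >= 1.0 - cfg.epsilon] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(ratios > 0.0, ratios * np.log(ratios), 0.0)
    return float(-plogp.sum() / len(batch.labels))


def balanced_complement_entropy(batch: LabeledBatch,
                                cfg: LossConfig | None = None) -> float:
    """Complement entropy divided by the balance coefficient's K−1."""
    return complement_entropy(batch, cfg) / (batch.num_classes - 1)


def cce_loss(batch: LabeledBatch, cfg: LossConfig | None = None) -> float:
    """Combined objective H + γ/(K−1)·C."""
    cfg = cfg or LossConfig()
    gamma_term = cfg.gamma / (batch.num_classes - 1)
    return cross_entropy(batch, cfg) + gamma_term * complement_entropy(batch, cfg)


def focal_loss(batch: LabeledBatch, cfg: LossConfig | None = None) -> float:
    """−mean α·(1−ŷ[g])^γ_f · log ŷ[g]; reduces to CE at γ_f = 0, α = 1."""
    cfg = cfg or LossConfig()
    if cfg.focal_gamma < 0:
        raise ValueError(f"focal_gamma must be >= 0, got {cfg.focal_gamma}")
    pg_raw = _target_probs(batch)
    pg = np.clip(pg_raw, cfg.epsilon, 1.0)
    modulation = (1.0 - pg_raw) ** cfg.focal_gamma
    return float(-np.mean(cfg.focal_alpha * modulation * np.log(pg)))


# ---------------------------------------------------------------------------
# differentiable versions (probability tensors -> scalar Tensor)
# ---------------------------------------------------------------------------

def _ce_t(probs: ad.Tensor, labels: np.ndarray, cfg: LossConfig) -> ad.Tensor:
    pg = ad.gather_rows(probs, labels)
    return -ad.reduce_mean(ad.log(ad.clip(pg, cfg.epsilon, 1.0)))


def _complement_t(probs: ad.Tensor, labels: np.ndarray, cfg: LossConfig) -> ad.Tensor:
    n, k = probs.shape
    if k < 2:
        raise ValueError("complement entropy requires at least 2 classes")
    mask = np.ones((n, k))
    mask[np.arange(n), labels] = 0.0
    pg = ad.gather_rows(probs, labels)
    denom = 1.0 - ad.clip(pg, 0.0, 1.0 - cfg.epsilon)
    ratios = probs * ad.Tensor(mask) / ad.reshape(denom, (n, 1))
    plogp = ratios * ad.log(ad.clip(ratios, _TINY, 1.0))
    return -ad.reduce_sum(plogp) * ad.Tensor(1.0 / n)


def _cce_t(probs: ad.Tensor, labels: np.ndarray, cfg: LossConfig) -> ad.Tensor:
    gamma_term = cfg.gamma / (probs.shape[1] - 1)
    return _ce_t(probs, labels, cfg) + ad.Tensor(gamma_term) * _complement_t(probs, labels, cfg)


def _focal_t(probs: ad.Tensor, labels: np.ndarray, cfg: LossConfig) -> ad.Tensor:
    if cfg.focal_gamma < 0:
        raise ValueError(f"focal_gamma must be >= 0, got {cfg.focal_gamma}")
    pg = ad.gather_rows(probs, labels)
    one_minus = ad.clip(1.0 - pg, _TINY, 1.0)
    modulation = ad.exp(ad.Tensor(cfg.focal_gamma) * ad.log(one_minus))
    logp = ad.log(ad.clip(pg, cfg.epsilon, 1.0))
    return -ad.reduce_mean(ad.Tensor(cfg.focal_alpha) * modulation * logp)


def make_training_loss(name: str, cfg: LossConfig | None = None):
    """Return a callable (probs Tensor, labels array) -> scalar loss Tensor."""
    cfg = cfg or LossConfig()
    table = {"ce": _ce_t, "cce": _cce_t, "focal": _focal_t}
    if name not in table:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(table)}")
    fn = table[name]

    def loss(probs: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
        return fn(probs, np.asarray(labels, dtype=np.intp), cfg)

    return loss
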