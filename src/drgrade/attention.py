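"""Squeeze-and-excitation channel attention.

A feature map is first squeezed by global average pooling into a per-channel
summary v, then excited through a two-layer bottleneck gate

    y = σ(W2 · ReLU(W1 · v))

whose sigmoid output reweights the channels of the original map.  The gate
learns which channels carry lesion-discriminative signal; its weights live
in the open interval (0, 1).  A simple heatmap export visualises where the
attended channels respond on the image plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ExcitationParams",
    "make_excitation_params",
    "global_average_pool",
    "excitation",
    "apply_attention",
    "attention_heatmap",
]

DEFAULT_REDUCTION_RATIO = 16


@dataclass
class ExcitationParams:
    """Bottleneck gate weights: W1 maps C → ⌊C/r⌋ (at least 1), W2 maps back."""

    w1: np.ndarray            # (hidden, C)
    w2: np.ndarray            # (C, hidden)
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden(self) -> int:
        return self.w1.shape[0]


def make_excitation_params(channels: int, reduction_ratio: int = DEFAULT_REDUCTION_RATIO,
                           seed: int = 0, bias: bool = True) -> ExcitationParams:
    """He-style random initialisation of the gate for a C-channel map."""
    if channels < 1:
        raise ValueError("channels must be >= 1")
    if reduction_ratio < 1:
        raise ValueError("reduction ratio must be >= 1")
    hidden = max(1, channels // reduction_ratio)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), channels, reduction_ratio]))
    w1 = rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels))
    w2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden))
    b1 = np.zeros(hidden) if bias else None
    b2 = np.zeros(channels) if bias else None
    return ExcitationParams(w1=w1, w2=w2, b1=b1, b2=b2)


def global_average_pool(fm: np.ndarray) -> np.ndarray:
    """Squeeze: v[c] = mean over the H×W plane of channel c."""
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3 or fm.shape[0] < 1 or fm.shape[1] < 1:
        raise ValueError(f"feature map must be nonempty H×W×C, got {fm.shape}")
    return fm.mean(axis=(0, 1))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def excitation(v: np.ndarray, params: ExcitationParams) -> np.ndarray:
    """Excite: σ(W2·ReLU(W1·v)); every output strictly inside (0, 1)."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != params.channels:
        raise ValueError(
            f"vector length {v.shape[-1]} does not match gate channels {params.channels}"
        )
    hidden = v @ params.w1.T
    if params.b1 is not None:
        hidden = hidden + params.b1
    hidden = np.maximum(hidden, 0.0)
    logits = hidden @ params.w2.T
    if params.b2 is not None:
        logits = logits + params.b2
    return _sigmoid(logits)


def apply_attention(fm: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Rescale each channel of the map by its attention weight."""
    fm = np.asarray(fm, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if fm.ndim != 3 or weights.ndim != 1 or fm.shape[2] != weights.shape[0]:
        raise ValueError(
            f"channel counts differ: map {fm.shape}, weights {weights.shape}"
        )
    return fm * weights[None, None, :]


def attention_heatmap(fm: np.ndarray, weights: np.ndarray,
                      out_size: tuple[int, int]) -> np.ndarray:
    """Weighted channel sum, bilinearly resized and min-max scaled to [0, 1].

    A constant map (no spatial contrast) yields an all-zero heatmap.
    """
    oh, ow = out_size
    if oh < 1 or ow < 1:
        raise ValueError(f"output size must be positive, got {out_size}")
    weighted = apply_attention(fm, weights).sum(axis=2)
    h, w = weighted.shape
    if (h, w) != (oh, ow):
        weighted = ndimage.zoom(weighted, (oh / h, ow / w), order=1,
                                grid_mode=True, mode="nearest")
    lo, hi = weighted.min(), weighted.max()
    if hi - lo <= 0:
        return np.zeros((oh, ow))
    return (weighted - lo) / (hi - lo)
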