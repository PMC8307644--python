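"""Bilinear pooling and its Tensor-Sketch compact approximation.

Full bilinear pooling forms the global descriptor

    B(X) = Σ_s  x_s · y_sᵀ

over all spatial positions *s* of two feature streams — a C1×C2 matrix whose
inner products realise the second-order polynomial kernel:

    ⟨B(X), B(Y)⟩ = Σ_s Σ_u ⟨x_s, y_u⟩².

Because c² is typically 10⁵–10⁶ dimensional, the compact variant replaces
each outer product with a randomized projection φ(x, y) ∈ R^d (Count Sketch
of each vector followed by circular convolution — the Tensor Sketch) such
that  E⟨φ(x,y), φ(x',y')⟩ = ⟨x,x'⟩·⟨y,y'⟩, giving a d-dimensional pooled
descriptor C(X) = Σ_s φ(x_s, y_s) with d in the low thousands.

The functions here are plain numpy and serve both as the library surface and
as the exact oracle against which the differentiable pooling layer used in
training (see :mod:`drgrade.model`) is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SketchProjection",
    "make_sketch_projection",
    "bilinear_pool",
    "bilinear_inner_product",
    "count_sketch",
    "tensor_sketch",
    "compact_bilinear_pool",
    "normalize_descriptor",
]

DEFAULT_SKETCH_DIM = 8192


def _check_feature_map(fm: np.ndarray, name: str) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError(f"{name} must be H×W×C, got shape {fm.shape}")
    if min(fm.shape) < 1:
        raise ValueError(f"{name} has an empty dimension: {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError(f"{name} contains non-finite entries")
    return fm


@dataclass(frozen=True)
class SketchProjection:
    """Frozen random hash/sign tables defining the Tensor-Sketch map φ.

    Regenerating with the same ``(input_dims, output_dim, seed)`` reproduces
    bit-identical tables, so only those three values need to be stored with
    a model; the tables themselves are derived state.
    """

    input_dims: tuple[int, int]
    output_dim: int
    seed: int
    hash_tables: tuple[np.ndarray, np.ndarray] = field(repr=False)
    sign_tables: tuple[np.ndarray, np.ndarray] = field(repr=False)

    def sketch_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (C, d) matrices M with M[i, h[i]] = s[i]; x @ M is the Count Sketch."""
        mats = []
        for c, h, s in zip(self.input_dims, self.hash_tables, self.sign_tables):
            m = np.zeros((c, self.output_dim))
            m[np.arange(c), h] = s
            mats.append(m)
        return mats[0], mats[1]

    def save(self, path: str | Path) -> None:
        record = {
            "input_dims": list(self.input_dims),
            "output_dim": self.output_dim,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(record) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SketchProjection":
        record = json.loads(Path(path).read_text())
        return make_sketch_projection(
            record["input_dims"][0],
            record["input_dims"][1],
            record["output_dim"],
            record["seed"],
        )


def make_sketch_projection(c1: int, c2: int, d: int, seed: int) -> SketchProjection:
    """Draw the two hash tables (uniform over [0, d)) and sign tables (±1)."""
    if d < 1:
        raise ValueError(f"sketch dimension must be >= 1, got {d}")
    if c1 < 1 or c2 < 1:
        raise ValueError(f"channel counts must be >= 1, got ({c1}, {c2})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), c1, c2, d]))
    h1 = rng.integers(0, d, size=c1)
    h2 = rng.integers(0, d, size=c2)
    s1 = rng.choice(np.array([-1.0, 1.0]), size=c1)
    s2 = rng.choice(np.array([-1.0, 1.0]), size=c2)
    return SketchProjection(
        input_dims=(c1, c2),
        output_dim=d,
        seed=int(seed),
        hash_tables=(h1, h2),
        sign_tables=(s1, s2),
    )


def bilinear_pool(fm_a: np.ndarray, fm_b: np.ndarray) -> np.ndarray:
    """Exact bilinear descriptor: sum of per-position outer products.

    Returns the C1×C2 matrix  B[i, j] = Σ_s fm_a[s, i] · fm_b[s, j].
    When both streams are the same feature map the result is symmetric PSD.
    """
    fm_a = _check_feature_map(fm_a, "fm_a")
    fm_b = _check_feature_map(fm_b, "fm_b")
    if fm_a.shape[:2] != fm_b.shape[:2]:
        raise ValueError(
            f"spatial shapes differ: {fm_a.shape[:2]} vs {fm_b.shape[:2]}"
        )
    xa = fm_a.reshape(-1, fm_a.shape[2])
    xb = fm_b.reshape(-1, fm_b.shape[2])
    return xa.T @ xb


def bilinear_inner_product(fm_a, fm_b, fm_c, fm_d) -> float:
    """⟨B(X), B(Y)⟩ with B(X) from (fm_a, fm_b) and B(Y) from (fm_c, fm_d)."""
    bx = bilinear_pool(fm_a, fm_b)
    by = bilinear_pool(fm_c, fm_d)
    if bx.shape != by.shape:
        raise ValueError(f"descriptor shapes differ: {bx.shape} vs {by.shape}")
    return float((bx * by).sum())


def count_sketch(v: np.ndarray, hash_table: np.ndarray, sign_table: np.ndarray,
                 d: int) -> np.ndarray:
    """out[k] = Σ_{i : h[i]=k} s[i]·v[i]  — the basic hashed projection."""
    v = np.asarray(v, dtype=np.float64)
    hash_table = np.asarray(hash_table)
    sign_table = np.asarray(sign_table)
    if v.shape[-1] != hash_table.shape[0] or v.shape[-1] != sign_table.shape[0]:
        raise ValueError(
            f"vector length {v.shape[-1]} does not match table length "
            f"{hash_table.shape[0]}"
        )
    out = np.zeros(v.shape[:-1] + (d,))
    np.add.at(out, (..., hash_table), sign_table * v)
    return out


def tensor_sketch(x: np.ndarray, y: np.ndarray, proj: SketchProjection) -> np.ndarray:
    """φ(x, y): circular convolution of the two Count Sketches (via FFT)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    c1, c2 = proj.input_dims
    if x.shape[-1] != c1 or y.shape[-1] != c2:
        raise ValueError(
            f"input dims ({x.shape[-1]}, {y.shape[-1]}) do not match projection "
            f"{proj.input_dims}"
        )
    d = proj.output_dim
    s1 = count_sketch(x, proj.hash_tables[0], proj.sign_tables[0], d)
    s2 = count_sketch(y, proj.hash_tables[1], proj.sign_tables[1], d)
    return np.fft.irfft(np.fft.rfft(s1, axis=-1) * np.fft.rfft(s2, axis=-1),
                        n=d, axis=-1)


def compact_bilinear_pool(fm_a: np.ndarray, fm_b: np.ndarray,
                          proj: SketchProjection) -> np.ndarray:
    """Compact descriptor C(X) = Σ_s φ(x_s, y_s) of length proj.output_dim."""
    fm_a = _check_feature_map(fm_a, "fm_a")
    fm_b = _check_feature_map(fm_b, "fm_b")
    if fm_a.shape[:2] != fm_b.shape[:2]:
        raise ValueError(
            f"spatial shapes differ: {fm_a.shape[:2]} vs {fm_b.shape[:2]}"
        )
    xa = fm_a.reshape(-1, fm_a.shape[2])
    xb = fm_b.reshape(-1, fm_b.shape[2])
    return tensor_sketch(xa, xb, proj).sum(axis=0)


def normalize_descriptor(desc: np.ndarray) -> np.ndarray:
    """Signed square root followed by L2 normalisation; zero maps to zero."""
    desc = np.asarray(desc, dtype=np.float64)
    if not np.all(np.isfinite(desc)):
        raise ValueError("descriptor contains non-finite entries")
    rooted = np.sign(desc) * np.sqrt(np.abs(desc))
    norm = np.linalg.norm(rooted)
    if norm == 0.0:
        return rooted
    return rooted / norm
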