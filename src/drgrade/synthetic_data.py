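"""Seeded generator of fundus-like images with ordinal 5-grade labels.

Real diabetic-retinopathy screening sets are severely long-tailed: healthy
eyes (grade 0) dominate and proliferative disease (grade 4) is rare.  The
generator reproduces that structure so the full training pipeline — and in
particular the imbalance behaviour of the losses — can be exercised without
any external download.

Each image is a dark circular retinal field with a bright optic disc and a
few curved vessel strokes; disease grade is encoded purely in the *density*
of three lesion archetypes drawn on top:

  * small dark dots      (microaneurysm-like)
  * irregular dark blobs (haemorrhage-like, random-walk unions of disks)
  * bright patches       (exudate-like)

Per-grade archetype counts are Poisson around grade-monotone means, with
grade 0 at exactly zero, so the mean total lesion count strictly increases
with grade and grade 0 is lesion-free.  Rendering uses simple parametric
primitives; photorealism is a non-goal, the grade-monotone statistics are
the point.

Determinism: image i of a dataset is drawn from a generator seeded with
``SeedSequence([dataset_seed, i])``, so images do not depend on generation
order and two runs with the same spec are pixel-identical.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "LesionParams",
    "SyntheticDatasetSpec",
    "LabeledImageSet",
    "sample_lesion_counts",
    "generate_fundus_image",
    "generate_dataset",
    "train_test_split",
    "save_dataset",
    "load_image_dir",
]


@dataclass(frozen=True)
class LesionParams:
    """Mean archetype counts and radius ranges (pixels) for one grade."""

    dot_mean: float
    blob_mean: float
    patch_mean: float
    dot_radius: tuple[float, float] = (0.6, 1.1)
    blob_radius: tuple[float, float] = (1.0, 1.8)
    patch_radius: tuple[float, float] = (1.0, 1.9)

    @property
    def total_mean(self) -> float:
        return self.dot_mean + self.blob_mean + self.patch_mean


#: Grade-monotone default archetype means; grade 0 is lesion-free.
DEFAULT_GRADE_PARAMS: tuple[LesionParams, ...] = (
    LesionParams(0.0, 0.0, 0.0),
    LesionParams(2.0, 0.5, 0.5),
    LesionParams(5.0, 2.0, 2.0),
    LesionParams(9.0, 4.0, 4.0),
    LesionParams(14.0, 7.0, 7.0),
)

#: Long-tailed class profile (65:6:13:2:2 per 88) at total size 1900,
#: so the default stratified split leaves ~1500 train / ~400 test images.
DEFAULT_CLASS_COUNTS: tuple[int, ...] = (1403, 130, 281, 43, 43)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    num_classes: int = 5
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    image_size: tuple[int, int] = (32, 32)
    grade_params: tuple[LesionParams, ...] = DEFAULT_GRADE_PARAMS
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.class_counts) != self.num_classes:
            raise ValueError("class_counts length must equal num_classes")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("every class count must be strictly positive")
        if len(self.grade_params) != self.num_classes:
            raise ValueError("grade_params length must equal num_classes")
        totals = [p.total_mean for p in self.grade_params]
        if totals[0] != 0.0:
            raise ValueError("grade 0 must have zero mean lesion count")
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise ValueError("mean total lesion count must increase with grade")

    def to_json(self) -> str:
        rec = asdict(self)
        rec["grade_params"] = [asdict(p) for p in self.grade_params]
        return json.dumps(rec, indent=2)

    @classmethod
    def from_dict(cls, rec: dict) -> "SyntheticDatasetSpec":
        rec = dict(rec)
        if "grade_params" in rec:
            rec["grade_params"] = tuple(
                LesionParams(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in p.items()})
                for p in rec["grade_params"]
            )
        for key in ("class_counts", "image_size"):
            if key in rec and isinstance(rec[key], list):
                rec[key] = tuple(rec[key])
        return cls(**rec)


@dataclass
class LabeledImageSet:
    """Images in [0,1] (N, H, W, 3) plus grades and generation provenance."""

    images: np.ndarray
    labels: np.ndarray
    spec: SyntheticDatasetSpec | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.images[idx], self.labels[idx], self.spec)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _random_point_in_field(rng, h, w, field_r, margin=1.5):
    # polar sampling with sqrt radius -> uniform over the disc interior
    r = (field_r - margin) * np.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return h / 2 + r * np.sin(theta), w / 2 + r * np.cos(theta)


def _paint(img, mask, color, alpha=1.0):
    img[mask] = (1 - alpha) * img[mask] + alpha * np.asarray(color)


def sample_lesion_counts(grade: int, spec: SyntheticDatasetSpec,
                         rng: np.random.Generator) -> tuple[int, int, int]:
    """Poisson draws of (dots, blobs, patches) around the grade's means."""
    p = spec.grade_params[grade]
    return (int(rng.poisson(p.dot_mean)),
            int(rng.poisson(p.blob_mean)),
            int(rng.poisson(p.patch_mean)))


def generate_fundus_image(grade: int, spec: SyntheticDatasetSpec,
                          stream_seed) -> np.ndarray:
    """Render one fundus-like image for the given grade.

    `stream_seed` may be an int or a ``numpy.random.SeedSequence``.
    """
    if not 0 <= grade < spec.num_classes:
        raise IndexError(f"grade {grade} outside [0, {spec.num_classes})")
    rng = np.random.default_rng(stream_seed)
    h, w = spec.image_size
    scale = min(h, w) / 32.0     # lesion radii are calibrated at 32 px

    img = np.zeros((h, w, 3))
    img[:] = (0.02, 0.02, 0.02)
    field_r = 0.48 * min(h, w)
    field = _disk_mask(h, w, h / 2, w / 2, field_r)
    _paint(img, field, (0.55, 0.22, 0.12))

    # optic disc: bright circle offset from centre
    disc_theta = rng.uniform(0.0, 2.0 * np.pi)
    disc_r = 0.55 * field_r
    dcy = h / 2 + disc_r * np.sin(disc_theta)
    dcx = w / 2 + disc_r * np.cos(disc_theta)
    _paint(img, _disk_mask(h, w, dcy, dcx, 2.8 * scale) & field, (0.95, 0.85, 0.55))

    # vessels: quadratic Bezier strokes from the disc toward the rim
    for _ in range(rng.integers(2, 5)):
        end_theta = rng.uniform(0.0, 2.0 * np.pi)
        ey = h / 2 + 0.92 * field_r * np.sin(end_theta)
        ex = w / 2 + 0.92 * field_r * np.cos(end_theta)
        my = (dcy + ey) / 2 + rng.normal(0, 0.15 * min(h, w))
        mx = (dcx + ex) / 2 + rng.normal(0, 0.15 * min(h, w))
        t = np.linspace(0.0, 1.0, 40)
        py = (1 - t) ** 2 * dcy + 2 * (1 - t) * t * my + t ** 2 * ey
        px = (1 - t) ** 2 * dcx + 2 * (1 - t) * t * mx + t ** 2 * ex
        stroke = np.zeros((h, w), dtype=bool)
        for cy, cx in zip(py, px):
            stroke |= _disk_mask(h, w, cy, cx, 0.7 * scale)
        _paint(img, stroke & field, (0.30, 0.07, 0.05), alpha=0.85)

    n_dots, n_blobs, n_patches = sample_lesion_counts(grade, spec, rng)
    p = spec.grade_params[grade]

    for _ in range(n_dots):
        cy, cx = _random_point_in_field(rng, h, w, field_r)
        r = rng.uniform(*p.dot_radius) * scale
        _paint(img, _disk_mask(h, w, cy, cx, r) & field, (0.12, 0.02, 0.02))

    for _ in range(n_blobs):
        cy, cx = _random_point_in_field(rng, h, w, field_r)
        blob = np.zeros((h, w), dtype=bool)
        for _ in range(rng.integers(3, 6)):      # random-walk union of disks
            r = rng.uniform(*p.blob_radius) * scale
            blob |= _disk_mask(h, w, cy, cx, r)
            cy += rng.normal(0, 1.2 * scale)
            cx += rng.normal(0, 1.2 * scale)
        _paint(img, blob & field, (0.16, 0.03, 0.03), alpha=0.9)

    for _ in range(n_patches):
        cy, cx = _random_point_in_field(rng, h, w, field_r)
        r = rng.uniform(*p.patch_radius) * scale
        _paint(img, _disk_mask(h, w, cy, cx, r) & field, (0.97, 0.92, 0.55))

    img += rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticDatasetSpec) -> LabeledImageSet:
    """Render exactly class_counts[g] images per grade, deterministically."""
    labels = np.concatenate([
        np.full(c, g, dtype=np.intp) for g, c in enumerate(spec.class_counts)
    ])
    h, w = spec.image_size
    images = np.empty((len(labels), h, w, 3))
    for i, g in enumerate(labels):
        stream = np.random.SeedSequence([int(spec.seed), int(i)])
        images[i] = generate_fundus_image(int(g), spec, stream)
    return LabeledImageSet(images, labels, spec)


def train_test_split(ds: LabeledImageSet, test_fraction: float,
                     seed: int) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified split; every grade lands in both halves when counts permit."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), len(ds)]))
    train_idx, test_idx = [], []
    for g in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == g)
        if len(idx) == 1:
            warnings.warn(
                f"grade {g} has a single image; assigning it to training",
                stacklevel=2,
            )
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=np.intp)
    return ds.subset(train_idx), ds.subset(test_idx)


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_dataset(ds: LabeledImageSet, out_dir: str | Path) -> Path:
    """Write PNGs plus a (filename, grade) CSV and the spec as JSON."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, g) in enumerate(zip(ds.images, ds.labels)):
        name = f"img_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / name)
        rows.append((name, int(g)))
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "grade"])
        writer.writerows(rows)
    if ds.spec is not None:
        (out_dir / "spec.json").write_text(ds.spec.to_json() + "\n")
    return out_dir


def load_image_dir(directory: str | Path,
                   labels_csv: str | None = None) -> LabeledImageSet:
    """Load a user-supplied image directory with a (filename, grade) CSV."""
    from PIL import Image

    directory = Path(directory)
    csv_path = Path(labels_csv) if labels_csv else directory / "labels.csv"
    images, labels = [], []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(
                Image.open(directory / row["filename"]).convert("RGB"),
                dtype=np.float64,
            ) / 255.0
            images.append(arr)
            labels.append(int(row["grade"]))
    spec = None
    spec_path = directory / "spec.json"
    if spec_path.exists():
        spec = SyntheticDatasetSpec.from_dict(json.loads(spec_path.read_text()))
    return LabeledImageSet(np.stack(images), np.asarray(labels), spec)
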