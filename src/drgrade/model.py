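"""Two-stream non-homologous bilinear classifier.

Architecture, per sample:

    image ──► backbone A ──► channel attention ──┐
                                                 ├─► align grids ─► compact
    image ──► backbone B ──► channel attention ──┘    bilinear pooling (d)
                                                        │
                              signed √ + L2 ◄───────────┘
                                                        │
                              affine d → K ─► softmax ─► grade probabilities

"Non-homologous" means the two streams are architecturally different
networks, so they extract complementary features; a homologous/shared
configuration (one backbone feeding both streams) is available for
ablations.  Three backbone families exist, all built on the package's
autodiff engine:

  * ``tiny``        — a short seeded convolutional stack, the default for
                      CPU-scale experiments and tests;
  * ``resnet50``    — a residual-style stack (identity shortcuts), sized
                      for CPU;
  * ``densenet121`` — a densely-connected stack (feature concatenation),
                      sized for CPU.

No pretrained weights are distributed; requesting ``pretrained=True``
raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .attention import ExcitationParams
from .sketch_pooling import SketchProjection, make_sketch_projection

__all__ = [
    "BackboneSpec",
    "TwoStreamModel",
    "build_model",
    "align_streams",
    "save_model",
    "load_model",
    "BACKBONE_FAMILIES",
]

BACKBONE_FAMILIES = ("tiny", "resnet50", "densenet121")


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone family plus its final channel count.

    ``output_channels`` defaults per family (tiny 16, resnet50 32,
    densenet121 24).  ``width`` scales internal channel counts of the
    residual/dense families.
    """

    family: str = "tiny"
    output_channels: int | None = None
    pretrained: bool = False
    width: int | None = None

    def resolved_channels(self) -> int:
        defaults = {"tiny": 16, "resnet50": 32, "densenet121": 24}
        if self.family not in defaults:
            raise ValueError(
                f"unknown backbone family {self.family!r}; "
                f"choose from {BACKBONE_FAMILIES}"
            )
        return self.output_channels or defaults[self.family]


class _Conv:
    def __init__(self, rng, params, name, cin, cout, k=3, stride=1, padding=1):
        w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
        self.w = ad.tensor(w, requires_grad=True)
        self.b = ad.tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding = stride, padding
        params[f"{name}.w"] = self.w
        params[f"{name}.b"] = self.b

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class _Backbone:
    """Base: owns a params dict and reports its output channel count."""

    def __init__(self):
        self.params: dict[str, ad.Tensor] = {}
        self.out_channels: int = 0

    def __call__(self, x: ad.Tensor) -> ad.Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class TinyBackbone(_Backbone):
    """3-layer strided conv stack; 32×32 input → 8×8 feature grid."""

    def __init__(self, rng, out_channels=16, width=None):
        super().__init__()
        w = width or 8
        self.c1 = _Conv(rng, self.params, "c1", 3, w, stride=2)
        self.c2 = _Conv(rng, self.params, "c2", w, int(1.5 * w), stride=2)
        self.c3 = _Conv(rng, self.params, "c3", int(1.5 * w), out_channels, stride=1)
        self.out_channels = out_channels

    def __call__(self, x):
        x = ad.relu(self.c1(x))
        x = ad.relu(self.c2(x))
        return ad.relu(self.c3(x))


class ResidualBackbone(_Backbone):
    """Residual-style stack: stem then two stages of identity-shortcut blocks."""

    def __init__(self, rng, out_channels=32, width=None):
        super().__init__()
        w = width or max(8, out_channels // 2)
        self.stem = _Conv(rng, self.params, "stem", 3, w, stride=2)
        self.blocks: list[tuple] = []
        widths = [w, out_channels]
        cin = w
        for si, cout in enumerate(widths):
            stride = 1 if si == 0 else 2
            conv1 = _Conv(rng, self.params, f"s{si}.conv1", cin, cout, stride=stride)
            conv2 = _Conv(rng, self.params, f"s{si}.conv2", cout, cout, stride=1)
            proj = None
            if stride != 1 or cin != cout:
                proj = _Conv(rng, self.params, f"s{si}.proj", cin, cout,
                             k=1, stride=stride, padding=0)
            self.blocks.append((conv1, conv2, proj))
            cin = cout
        self.out_channels = out_channels

    def __call__(self, x):
        x = ad.relu(self.stem(x))
        for conv1, conv2, proj in self.blocks:
            identity = proj(x) if proj is not None else x
            y = conv2(ad.relu(conv1(x)))
            x = ad.relu(y + identity)
        return x


class DenseBackbone(_Backbone):
    """Densely-connected stack: each layer's output is concatenated onto its input."""

    def __init__(self, rng, out_channels=24, width=None, num_layers=4, growth=6):
        super().__init__()
        w = width or 8
        self.stem = _Conv(rng, self.params, "stem", 3, w, stride=2)
        self.layers = []
        cin = w
        for li in range(num_layers):
            self.layers.append(_Conv(rng, self.params, f"d{li}", cin, growth))
            cin += growth
        self.transition = _Conv(rng, self.params, "trans", cin, out_channels,
                                k=1, padding=0)
        self.out_channels = out_channels

    def __call__(self, x):
        x = ad.relu(self.stem(x))
        for layer in self.layers:
            x = ad.concat([x, ad.relu(layer(x))], axis=1)
        x = ad.relu(self.transition(x))
        n, c, h, w = x.shape
        return ad.adaptive_avg_pool2d(x, (max(1, h // 2), max(1, w // 2)))


def _make_backbone(spec: BackboneSpec, rng) -> _Backbone:
    if spec.pretrained:
        raise ValueError(
            "no pretrained weights are distributed with this package; "
            "set pretrained=False"
        )
    cout = spec.resolved_channels()
    if spec.family == "tiny":
        return TinyBackbone(rng, cout, spec.width)
    if spec.family == "resnet50":
        return ResidualBackbone(rng, cout, spec.width)
    if spec.family == "densenet121":
        return DenseBackbone(rng, cout, spec.width)
    raise ValueError(f"unknown backbone family {spec.family!r}")


class _AttentionGate:
    """Engine-side squeeze-excite gate; layouts: w1 (C, hidden), w2 (hidden, C)."""

    def __init__(self, rng, params, name, channels, reduction_ratio, bias=True):
        hidden = max(1, channels // reduction_ratio)
        self.w1 = ad.tensor(rng.normal(0.0, np.sqrt(2.0 / channels),
                                       size=(channels, hidden)), requires_grad=True)
        self.w2 = ad.tensor(rng.normal(0.0, np.sqrt(2.0 / hidden),
                                       size=(hidden, channels)), requires_grad=True)
        params[f"{name}.w1"] = self.w1
        params[f"{name}.w2"] = self.w2
        self.b1 = self.b2 = None
        if bias:
            self.b1 = ad.tensor(np.zeros(hidden), requires_grad=True)
            self.b2 = ad.tensor(np.zeros(channels), requires_grad=True)
            params[f"{name}.b1"] = self.b1
            params[f"{name}.b2"] = self.b2

    def __call__(self, f: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor]:
        n, c = f.shape[0], f.shape[1]
        v = ad.reduce_mean(f, axis=(2, 3))
        hidden = v @ self.w1
        if self.b1 is not None:
            hidden = hidden + self.b1
        logits = ad.relu(hidden) @ self.w2
        if self.b2 is not None:
            logits = logits + self.b2
        w = ad.sigmoid(logits)
        return f * ad.reshape(w, (n, c, 1, 1)), w

    def as_excitation_params(self) -> ExcitationParams:
        return ExcitationParams(
            w1=self.w1.data.T.copy(),
            w2=self.w2.data.T.copy(),
            b1=None if self.b1 is None else self.b1.data.copy(),
            b2=None if self.b2 is None else self.b2.data.copy(),
        )


def align_streams(fm_a: np.ndarray, fm_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adaptively average-pool two H×W×C maps to their common coarser grid."""
    fm_a = np.asarray(fm_a, dtype=np.float64)
    fm_b = np.asarray(fm_b, dtype=np.float64)
    if fm_a.ndim != 3 or fm_b.ndim != 3:
        raise ValueError("feature maps must be H×W×C")
    target = (min(fm_a.shape[0], fm_b.shape[0]), min(fm_a.shape[1], fm_b.shape[1]))

    def pool(fm):
        if fm.shape[:2] == target:
            return fm
        t = ad.tensor(fm.transpose(2, 0, 1)[None])
        out = ad.adaptive_avg_pool2d(t, target)
        return out.data[0].transpose(1, 2, 0)

    return pool(fm_a), pool(fm_b)


class TwoStreamModel:
    """Assembled classifier; construct via :func:`build_model`."""

    def __init__(self, spec_a, spec_b, d, num_classes, reduction_ratio, seed,
                 shared=False, mode="bilinear", normalize=True,
                 input_size=(32, 32)):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        if d < 1:
            raise ValueError("sketch dimension must be >= 1")
        if mode not in ("bilinear", "single"):
            raise ValueError(f"unknown mode {mode!r}")
        self.build_args = dict(
            spec_a=spec_a, spec_b=spec_b, d=d, num_classes=num_classes,
            reduction_ratio=reduction_ratio, seed=seed, shared=shared,
            mode=mode, normalize=normalize, input_size=tuple(input_size),
        )
        self.num_classes = num_classes
        self.d = d
        self.seed = seed
        self.shared = shared
        self.mode = mode
        self.normalize = normalize
        self.input_size = tuple(input_size)

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
        self.params: dict[str, ad.Tensor] = {}
        self.stream_a = _make_backbone(spec_a, rng)
        self._register("a", self.stream_a.params)
        if shared:
            self.stream_b = self.stream_a
        else:
            self.stream_b = _make_backbone(spec_b, rng)
            self._register("b", self.stream_b.params)

        ca, cb = self.stream_a.out_channels, self.stream_b.out_channels
        self.gate_a = _AttentionGate(rng, self.params, "att_a", ca, reduction_ratio)
        if shared:
            self.gate_b = self.gate_a
        else:
            self.gate_b = _AttentionGate(rng, self.params, "att_b", cb, reduction_ratio)

        self.projection: SketchProjection = make_sketch_projection(ca, cb, d, seed)
        m1, m2 = self.projection.sketch_matrices()
        self._m1, self._m2 = ad.tensor(m1), ad.tensor(m2)

        feat_dim = d if mode == "bilinear" else ca
        self.classifier_w = ad.tensor(
            rng.normal(0.0, np.sqrt(1.0 / feat_dim), size=(feat_dim, num_classes)),
            requires_grad=True,
        )
        self.classifier_b = ad.tensor(np.zeros(num_classes), requires_grad=True)
        self.params["clf.w"] = self.classifier_w
        self.params["clf.b"] = self.classifier_b

    def _register(self, prefix, sub):
        for k, v in sub.items():
            self.params[f"{prefix}.{k}"] = v

    # ------------------------------------------------------------------
    def _check_input(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[3] != 3 or \
                images.shape[1:3] != self.input_size:
            raise ValueError(
                f"expected (N, {self.input_size[0]}, {self.input_size[1]}, 3) "
                f"images, got {images.shape}"
            )
        return images

    def _preprocess(self, images: np.ndarray) -> ad.Tensor:
        # zero-center: all-positive inputs make first-layer features strongly
        # correlated and trap SGD in the predict-the-majority solution
        images = self._check_input(images)
        return ad.tensor(images.transpose(0, 3, 1, 2) - 0.5)

    def forward_tensor(self, images: np.ndarray) -> ad.Tensor:
        """Differentiable forward pass: images (N,H,W,3) → probs Tensor (N,K)."""
        x = self._preprocess(images)
        fa = self.stream_a(x)
        fa, _ = self.gate_a(fa)
        if self.mode == "single":
            v = ad.reduce_mean(fa, axis=(2, 3))
            logits = v @ self.classifier_w + self.classifier_b
            return ad.softmax(logits)

        if self.shared:
            fb = fa
        else:
            fb = self.stream_b(x)
            fb, _ = self.gate_b(fb)
        target = (min(fa.shape[2], fb.shape[2]), min(fa.shape[3], fb.shape[3]))
        fa = ad.adaptive_avg_pool2d(fa, target)
        fb = ad.adaptive_avg_pool2d(fb, target)

        n = fa.shape[0]
        p = target[0] * target[1]
        fa = ad.transpose(ad.reshape(fa, (n, fa.shape[1], p)), (0, 2, 1))
        fb = ad.transpose(ad.reshape(fb, (n, fb.shape[1], p)), (0, 2, 1))
        desc = ad.circular_conv_pool(fa @ self._m1, fb @ self._m2)
        if self.normalize:
            desc = ad.l2_normalize(ad.signed_sqrt(desc))
        logits = desc @ self.classifier_w + self.classifier_b
        return ad.softmax(logits)

    def predict_proba(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        images = self._check_input(images)
        out = [
            self.forward_tensor(images[i:i + batch_size]).data
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        # ties broken toward the lowest class index (np.argmax convention)
        return np.argmax(self.predict_proba(images, batch_size), axis=1)

    # ------------------------------------------------------------------
    def stream_state(self, images: np.ndarray, stream: str = "a"):
        """Feature map (H×W×C) and attention weights for one image, one stream."""
        x = self._preprocess(self._check_input(images)[:1])
        backbone = self.stream_a if stream == "a" else self.stream_b
        gate = self.gate_a if stream == "a" else self.gate_b
        f = backbone(x)
        _, w = gate(f)
        return f.data[0].transpose(1, 2, 0), w.data[0]

    @property
    def attention_a(self) -> ExcitationParams:
        return self.gate_a.as_excitation_params()

    @property
    def attention_b(self) -> ExcitationParams:
        return self.gate_b.as_excitation_params()

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in arrays:
                raise KeyError(f"checkpoint is missing parameter {k!r}")
            if arrays[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            v.data = np.asarray(arrays[k], dtype=np.float64)


def build_model(spec_a: BackboneSpec, spec_b: BackboneSpec, d: int = 256,
                num_classes: int = 5, reduction_ratio: int = 16, seed: int = 0,
                shared: bool = False, mode: str = "bilinear",
                normalize: bool = True,
                input_size: tuple[int, int] = (32, 32)) -> TwoStreamModel:
    """Deterministically construct the two-stream model from its specs."""
    return TwoStreamModel(spec_a, spec_b, d, num_classes, reduction_ratio,
                          seed, shared=shared, mode=mode, normalize=normalize,
                          input_size=input_size)


# ---------------------------------------------------------------------------
# checkpointing: parameter archive + JSON sidecar with the build arguments
# ---------------------------------------------------------------------------

def save_model(model: TwoStreamModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    args = dict(model.build_args)
    for key in ("spec_a", "spec_b"):
        s = args[key]
        args[key] = dict(family=s.family, output_channels=s.output_channels,
                         pretrained=s.pretrained, width=s.width)
    path.with_suffix(".json").write_text(json.dumps(args, indent=2) + "\n")


def load_model(path: str | Path) -> TwoStreamModel:
    path = Path(path)
    args = json.loads(path.with_suffix(".json").read_text())
    for key in ("spec_a", "spec_b"):
        args[key] = BackboneSpec(**args[key])
    args["input_size"] = tuple(args["input_size"])
    model = build_model(**args)
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_arrays({k: npz[k] for k in npz.files})
    return model
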