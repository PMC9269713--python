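"""Frozen deep-feature extraction behind a uniform adapter contract.

The pipeline treats a pretrained CNN purely as a fixed feature extractor: the
classification head is discarded and the penultimate representation (the last
fully-connected hidden layer for AlexNet/VGG16, the 1024-wide global-average
pool for GoogLeNet) becomes the feature vector.  The feature widths —
4096 / 1024 / 4096 — and the architecture sizes — roughly 61 M parameters for
AlexNet, 7 M for GoogLeNet, 138 M for VGG16 — are part of the adapter's
verifiable contract, computed here from explicit layer-shape tables of the
standard architectures, so no deep-learning framework is needed to check
them.

A deterministic ``fallback`` extractor (seeded random orthonormal projection
of downsampled pixels) makes every downstream stage testable fully offline.
Running the real CNNs requires the optional torch/torchvision extra.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import transform as _sktransform

from .roi_prep import PseudoColorImage

#: Downsampling grid (per channel) used by the fallback extractor.
FALLBACK_GRID = 24
#: Default fallback feature width (matches the GoogLeNet tap width).
FALLBACK_DIM = 1024


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_side: int
    feature_dim: int
    param_count_millions: int | None  # None for the fallback (no fixed net)


@dataclass(frozen=True)
class FeatureMatrix:
    """n_samples x feature_dim deep-feature table with sample bookkeeping."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    backbone: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got {vals.shape}")
        if vals.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


# --------------------------------------------------------------------------
# Architecture layer tables
# --------------------------------------------------------------------------
# Each entry is ("conv", in_ch, out_ch, k) or ("linear", n_in, n_out); biases
# are included.  These are the standard ImageNet architectures.

_ALEXNET_LAYERS: list[tuple] = [
    ("conv", 3, 64, 11),
    ("conv", 64, 192, 5),
    ("conv", 192, 384, 3),
    ("conv", 384, 256, 3),
    ("conv", 256, 256, 3),
    ("linear", 256 * 6 * 6, 4096),
    ("linear", 4096, 4096),
    ("linear", 4096, 1000),
]

_VGG16_LAYERS: list[tuple] = [
    ("conv", 3, 64, 3), ("conv", 64, 64, 3),
    ("conv", 64, 128, 3), ("conv", 128, 128, 3),
    ("conv", 128, 256, 3), ("conv", 256, 256, 3), ("conv", 256, 256, 3),
    ("conv", 256, 512, 3), ("conv", 512, 512, 3), ("conv", 512, 512, 3),
    ("conv", 512, 512, 3), ("conv", 512, 512, 3), ("conv", 512, 512, 3),
    ("linear", 512 * 7 * 7, 4096),
    ("linear", 4096, 4096),
    ("linear", 4096, 1000),
]


def _inception(in_ch, c1, c3r, c3, c5r, c5, cp) -> list[tuple]:
    return [
        ("conv", in_ch, c1, 1),
        ("conv", in_ch, c3r, 1), ("conv", c3r, c3, 3),
        ("conv", in_ch, c5r, 1), ("conv", c5r, c5, 5),
        ("conv", in_ch, cp, 1),
    ]


_GOOGLENET_LAYERS: list[tuple] = (
    [("conv", 3, 64, 7), ("conv", 64, 64, 1), ("conv", 64, 192, 3)]
    + _inception(192, 64, 96, 128, 16, 32, 32)      # 3a -> 256
    + _inception(256, 128, 128, 192, 32, 96, 64)    # 3b -> 480
    + _inception(480, 192, 96, 208, 16, 48, 64)     # 4a -> 512
    + _inception(512, 160, 112, 224, 24, 64, 64)    # 4b
    + _inception(512, 128, 128, 256, 24, 64, 64)    # 4c
    + _inception(512, 112, 144, 288, 32, 64, 64)    # 4d -> 528
    + _inception(528, 256, 160, 320, 32, 128, 128)  # 4e -> 832
    + _inception(832, 256, 160, 320, 32, 128, 128)  # 5a
    + _inception(832, 384, 192, 384, 48, 128, 128)  # 5b -> 1024
    + [("linear", 1024, 1000)]
)

_ARCHITECTURES: dict[str, list[tuple]] = {
    "alexnet": _ALEXNET_LAYERS,
    "vgg16": _VGG16_LAYERS,
    "googlenet": _GOOGLENET_LAYERS,
}

_SPECS: dict[str, BackboneSpec] = {
    "alexnet": BackboneSpec("alexnet", 227, 4096, 61),
    "googlenet": BackboneSpec("googlenet", 224, 1024, 7),
    "vgg16": BackboneSpec("vgg16", 224, 4096, 138),
    "fallback": BackboneSpec("fallback", 32, FALLBACK_DIM, None),
}


def registry() -> list[BackboneSpec]:
    """All supported backbones with their contract metadata."""
    return list(_SPECS.values())


def get_spec(name: str) -> BackboneSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; known: {sorted(_SPECS)}"
        ) from None


def _layer_params(layer: tuple) -> int:
    if layer[0] == "conv":
        _, cin, cout, k = layer
        return cout * cin * k * k + cout
    if layer[0] == "linear":
        _, nin, nout = layer
        return nout * nin + nout
    raise ValueError(f"unknown layer kind {layer[0]!r}")


def count_parameters(backbone: str) -> int:
    """Total trainable parameters of the standard architecture, in millions.

    Summed over the explicit layer-shape table (weights + biases, main
    branch only for GoogLeNet — auxiliary classifiers are training-time
    scaffolding and vary across implementations) and rounded to the nearest
    million.
    """
    if backbone == "fallback":
        raise ValueError("fallback extractor has no fixed architecture")
    if backbone not in _ARCHITECTURES:
        raise KeyError(f"unknown backbone {backbone!r}")
    total = sum(_layer_params(l) for l in _ARCHITECTURES[backbone])
    return int(round(total / 1e6))


def count_parameters_exact(backbone: str) -> int:
    """Exact parameter count of the layer table (not rounded)."""
    if backbone not in _ARCHITECTURES:
        raise KeyError(f"unknown backbone {backbone!r}")
    return sum(_layer_params(l) for l in _ARCHITECTURES[backbone])


# --------------------------------------------------------------------------
# Feature extraction
# --------------------------------------------------------------------------

def extract_features(
    images: Sequence[PseudoColorImage],
    backbone: str,
    weights_source: str = "pretrained",
    seed: int = 0,
) -> FeatureMatrix:
    """Run a batch of pseudo-color stacks through a frozen backbone.

    Rows follow input order; the column count always equals the registry
    ``feature_dim`` for the named backbone.  ``weights_source`` is
    ``pretrained`` (ImageNet weights, requires torchvision with local or
    fetchable weights) or ``random_seeded`` (seeded random initialization,
    for shape/determinism checks without any download).  The ``fallback``
    backbone ignores ``weights_source`` and uses the deterministic seeded
    projection extractor.
    """
    spec = get_spec(backbone)
    if backbone == "fallback":
        return fallback_extract(images, dim=spec.feature_dim, seed=seed)

    for i, img in enumerate(images):
        if img.shape != (spec.input_side, spec.input_side):
            raise ValueError(
                f"image {i} has shape {img.shape}; {backbone} expects "
                f"{spec.input_side}x{spec.input_side} "
                "(use roi_prep.resize_for_backbone)"
            )
    if weights_source not in ("pretrained", "random_seeded"):
        raise ValueError(f"unknown weights_source {weights_source!r}")
    return _torch_extract(images, spec, weights_source, seed)


def _torch_extract(images, spec, weights_source, seed) -> FeatureMatrix:
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:
        raise ImportError(
            f"backbone {spec.name!r} needs the optional torch/torchvision "
            "extra; for offline tests use backbone='fallback' (or "
            "weights_source='random_seeded' once torch is installed)"
        ) from exc

    torch.manual_seed(seed)
    pretrained = weights_source == "pretrained"
    try:
        if spec.name == "alexnet":
            net = tvm.alexnet(weights=tvm.AlexNet_Weights.IMAGENET1K_V1 if pretrained else None)
            net.classifier = torch.nn.Sequential(*list(net.classifier.children())[:-1])
        elif spec.name == "vgg16":
            net = tvm.vgg16(weights=tvm.VGG16_Weights.IMAGENET1K_V1 if pretrained else None)
            net.classifier = torch.nn.Sequential(*list(net.classifier.children())[:-1])
        elif spec.name == "googlenet":
            net = tvm.googlenet(
                weights=tvm.GoogLeNet_Weights.IMAGENET1K_V1 if pretrained else None,
                init_weights=not pretrained,
            )
            net.fc = torch.nn.Identity()  # tap the 1024-wide GAP output
        else:  # pragma: no cover
            raise KeyError(spec.name)
    except Exception as exc:  # missing weight files, no network, ...
        raise RuntimeError(
            f"could not build {spec.name} with {weights_source} weights "
            f"({exc}); for offline use pass backbone='fallback'"
        ) from exc

    net.eval()
    mean = np.array([0.485, 0.456, 0.406])[:, None, None]
    std = np.array([0.229, 0.224, 0.225])[:, None, None]
    rows = []
    with torch.no_grad():
        for img in images:
            x = (img.channels - mean) / std
            t = torch.from_numpy(x[None].astype(np.float32))
            rows.append(net(t).numpy().ravel())
    values = np.stack(rows) if rows else np.empty((0, spec.feature_dim))
    return FeatureMatrix(
        values=values,
        sample_ids=tuple(f"s{i:05d}" for i in range(len(images))),
        backbone=spec.name,
    )


def fallback_extract(
    images: Sequence[PseudoColorImage],
    dim: int = FALLBACK_DIM,
    seed: int = 0,
    grid: int = FALLBACK_GRID,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Deterministic offline feature extractor.

    Each stack is downsampled to a fixed ``grid x grid`` raster per channel,
    flattened, and projected by a seeded random matrix with orthonormal
    columns to ``dim`` features.  Same seed + inputs give bit-identical
    output, and the orthonormal projection preserves distinctions between
    inputs (injective on the downsampled space).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    flat_dim = 3 * grid * grid
    if dim > flat_dim:
        raise ValueError(
            f"dim={dim} exceeds the flattened grid size {flat_dim}; "
            "enlarge `grid`"
        )
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((flat_dim, dim)))

    rows = []
    for img in images:
        if img.shape == (grid, grid):
            small = img.channels
        else:
            small = np.stack(
                [
                    _sktransform.resize(
                        ch, (grid, grid), order=1, anti_aliasing=True,
                        mode="reflect",
                    )
                    for ch in img.channels
                ]
            )
        rows.append(small.ravel() @ Q)
    values = np.stack(rows) if rows else np.empty((0, dim))
    if sample_ids is None:
        sample_ids = tuple(f"s{i:05d}" for i in range(len(images)))
    return FeatureMatrix(values=values, sample_ids=sample_ids, backbone="fallback")


# --------------------------------------------------------------------------
# Persistence: TSV with a one-line header + JSON sidecar
# --------------------------------------------------------------------------

def write_features(
    fm: FeatureMatrix,
    path: str | os.PathLike,
    weights_source: str = "fallback",
    seed: int | None = None,
) -> None:
    width = len(str(max(fm.feature_dim, 1)))
    header = "sample_id\t" + "\t".join(
        f"f{i + 1:0{max(4, width)}d}" for i in range(fm.feature_dim)
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    sidecar = {"backbone": fm.backbone, "weights_source": weights_source, "seed": seed}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_features(path: str | os.PathLike) -> FeatureMatrix:
    backbone = "fallback"
    sidecar = str(path) + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            backbone = json.load(fh).get("backbone", backbone)
    ids, rows = [], []
    with open(path) as fh:
        fh.readline()
        for ln in fh:
            tok = ln.rstrip("\n").split("\t")
            if len(tok) < 2:
                continue
            ids.append(tok[0])
            rows.append([float(v) for v in tok[1:]])
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float), sample_ids=tuple(ids), backbone=backbone
    )
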