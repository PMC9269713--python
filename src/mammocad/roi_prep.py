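"""Region-of-interest preparation for mammogram lesion classification.

Takes annotated grayscale mammograms and produces the small square patches
the rest of the pipeline consumes: parse circle/box lesion annotations,
extract non-overlapping 32x32 tiles (or a whole-box resized crop), augment by
exact 90-degree rotations (optionally flips), and synthesize the three-channel
pseudo-color stack — original intensities, CLAHE-enhanced, and 1%/1%
percentile-stretched — that replaces naive grayscale channel replication at
the CNN input.

All pixel data is carried as float arrays in [0, 1]; 8-bit quantization
happens only on write.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from skimage import exposure, transform

logger = logging.getLogger("mammocad")

#: Default ROI side in pixels.
DEFAULT_SIDE = 32
#: Default percentile saturation (bottom / top percent of pixel values).
DEFAULT_STRETCH = (1.0, 1.0)
#: Default CLAHE settings: 8x8 tile grid, normalized clip limit 0.01.
DEFAULT_CLAHE_TILES = (8, 8)
DEFAULT_CLAHE_CLIP = 0.01


class LesionClass(str, Enum):
    NORMAL = "normal"
    BENIGN = "benign"
    MALIGNANT = "malignant"


class CoordinateOrigin(str, Enum):
    TOP_LEFT = "top_left"
    BOTTOM_LEFT = "bottom_left"


@dataclass(frozen=True)
class CircleGeometry:
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"circle radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class BoxGeometry:
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"box must satisfy x0 < x1 and y0 < y1, got "
                f"({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )


@dataclass(frozen=True)
class LesionAnnotation:
    """One annotated lesion (or normal-tissue marker) on a mammogram."""

    image_id: str
    lesion_class: LesionClass
    geometry: CircleGeometry | BoxGeometry | None
    coordinate_origin: CoordinateOrigin = CoordinateOrigin.TOP_LEFT


@dataclass(frozen=True)
class GrayROI:
    """A square grayscale patch with label and provenance.

    ``source`` is ``(image_id, offset, augmentation_tag)`` where offset is the
    (row, col) of the patch's top-left corner in the source raster (or a
    descriptive token for resized crops) and the tag names the transform
    applied ("orig", "rot90", "rot90+fliplr", ...).
    """

    pixels: np.ndarray
    label: LesionClass
    source: tuple[str, tuple[int, int] | str, str]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"ROI must be square 2-D, got shape {px.shape}")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ValueError("ROI intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PseudoColorImage:
    """Three-channel stack: (original, CLAHE, percentile-stretched)."""

    channels: np.ndarray  # (3, H, W) in [0, 1]
    channel_roles: tuple[str, str, str] = ("original", "clahe", "stretched")

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) channels, got {ch.shape}")
        if ch.min() < -1e-12 or ch.max() > 1 + 1e-12:
            raise ValueError("pseudo-color values must lie in [0, 1]")
        object.__setattr__(self, "channels", np.clip(ch, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


class AnnotationParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


# --------------------------------------------------------------------------
# Annotation parsing
# --------------------------------------------------------------------------

_MINIMIAS_SEVERITY = {"B": LesionClass.BENIGN, "M": LesionClass.MALIGNANT}


def parse_annotations(path: str | os.PathLike, dialect: str) -> list[LesionAnnotation]:
    """Parse a lesion-annotation file.

    Two dialects are supported:

    ``minimias_info``
        Whitespace-delimited lines ``id tissue abnormality [severity x y r]``
        as distributed with the mini-MIAS database.  Lines without
        coordinates describe normal tissue.  Coordinates use a bottom-left
        origin (converted to raster top-left at ROI extraction).

    ``bbox_csv``
        CSV with header ``image_id,class,x0,y0,x1,y1`` giving top-left-origin
        bounding boxes, as used for INbreast-style exports.
    """
    if dialect == "minimias_info":
        return _parse_minimias(path)
    if dialect == "bbox_csv":
        return _parse_bbox_csv(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _parse_minimias(path: str | os.PathLike) -> list[LesionAnnotation]:
    out: list[LesionAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) == 3:
                # id, tissue code, NORM and nothing else: normal tissue.
                if tok[2].upper() != "NORM":
                    raise AnnotationParseError(
                        f"line {lineno}: abnormality {tok[2]!r} without "
                        f"severity and coordinates: {line!r}"
                    )
                out.append(
                    LesionAnnotation(
                        image_id=tok[0],
                        lesion_class=LesionClass.NORMAL,
                        geometry=None,
                        coordinate_origin=CoordinateOrigin.BOTTOM_LEFT,
                    )
                )
                continue
            if len(tok) != 7:
                raise AnnotationParseError(
                    f"line {lineno}: expected 3 or 7 fields, got {len(tok)}: {line!r}"
                )
            severity = tok[3].upper()
            if severity not in _MINIMIAS_SEVERITY:
                raise AnnotationParseError(
                    f"line {lineno}: unknown severity code {tok[3]!r}"
                )
            try:
                x, y, r = float(tok[4]), float(tok[5]), float(tok[6])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-numeric geometry in {line!r}"
                ) from exc
            out.append(
                LesionAnnotation(
                    image_id=tok[0],
                    lesion_class=_MINIMIAS_SEVERITY[severity],
                    geometry=CircleGeometry(x, y, r),
                    coordinate_origin=CoordinateOrigin.BOTTOM_LEFT,
                )
            )
    return out


_BBOX_CLASSES = {c.value: c for c in LesionClass}


def _parse_bbox_csv(path: str | os.PathLike) -> list[LesionAnnotation]:
    out: list[LesionAnnotation] = []
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        expected = ["image_id", "class", "x0", "y0", "x1", "y1"]
        if [h.strip() for h in header] != expected:
            raise AnnotationParseError(
                f"line 1: expected header {','.join(expected)!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            tok = [t.strip() for t in line.split(",")]
            if len(tok) != 6:
                raise AnnotationParseError(
                    f"line {lineno}: expected 6 fields, got {len(tok)}"
                )
            cls = tok[1].lower()
            if cls not in _BBOX_CLASSES:
                raise AnnotationParseError(
                    f"line {lineno}: unknown class {tok[1]!r}"
                )
            try:
                x0, y0, x1, y1 = (float(v) for v in tok[2:])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-numeric box in {line!r}"
                ) from exc
            try:
                geom = BoxGeometry(x0, y0, x1, y1)
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            out.append(
                LesionAnnotation(
                    image_id=tok[0],
                    lesion_class=_BBOX_CLASSES[cls],
                    geometry=geom,
                )
            )
    return out


# --------------------------------------------------------------------------
# ROI extraction
# --------------------------------------------------------------------------

def extract_rois(
    image: np.ndarray,
    ann: LesionAnnotation,
    mode: str,
    side: int = DEFAULT_SIDE,
) -> list[GrayROI]:
    """Cut square ROIs out of ``image`` for one annotation.

    ``tile_nonoverlap`` (circle lesions): every ``side``-square on the
    row-major grid anchored at the top-left of the circle's bounding square
    whose four corners all lie inside the circle.  Grid squares never overlap
    by construction; tiles that would leave the image are dropped (never
    padded) and logged.  A lesion too small to hold one tile yields an empty
    list.

    ``whole_box_resize`` (box lesions): the box crop, resized to
    ``side x side`` with anti-aliased bilinear interpolation — the INbreast
    convention of using the whole mass as one sample.
    """
    img = _as_unit_float(image)
    H, W = img.shape
    geom = ann.geometry
    if geom is None:
        raise ValueError("annotation has no geometry; cannot extract an ROI")

    if mode == "tile_nonoverlap":
        if not isinstance(geom, CircleGeometry):
            raise ValueError("tile_nonoverlap requires a circle annotation")
        cx, cy, r = geom.center_x, geom.center_y, geom.radius
        if ann.coordinate_origin is CoordinateOrigin.BOTTOM_LEFT:
            cy = (H - 1) - cy
        if not (0 <= cx < W and 0 <= cy < H):
            raise ValueError(
                f"circle center ({cx}, {cy}) outside {W}x{H} image after "
                "origin conversion"
            )
        rois: list[GrayROI] = []
        # Row-major grid over the bounding square of the circle.
        y_anchor = int(np.floor(cy - r))
        x_anchor = int(np.floor(cx - r))
        n_steps = int(np.ceil(2 * r / side)) + 1
        for iy in range(n_steps):
            for ix in range(n_steps):
                y0 = y_anchor + iy * side
                x0 = x_anchor + ix * side
                corners = [
                    (x0, y0),
                    (x0 + side - 1, y0),
                    (x0, y0 + side - 1),
                    (x0 + side - 1, y0 + side - 1),
                ]
                if any((px - cx) ** 2 + (py - cy) ** 2 > r**2 for px, py in corners):
                    continue
                if y0 < 0 or x0 < 0 or y0 + side > H or x0 + side > W:
                    logger.info(
                        "dropping out-of-bounds tile at (%d, %d) for %s",
                        y0, x0, ann.image_id,
                    )
                    continue
                rois.append(
                    GrayROI(
                        pixels=img[y0 : y0 + side, x0 : x0 + side].copy(),
                        label=ann.lesion_class,
                        source=(ann.image_id, (y0, x0), "orig"),
                    )
                )
        return rois

    if mode == "whole_box_resize":
        if not isinstance(geom, BoxGeometry):
            raise ValueError("whole_box_resize requires a box annotation")
        y0, y1 = geom.y0, geom.y1
        if ann.coordinate_origin is CoordinateOrigin.BOTTOM_LEFT:
            y0, y1 = (H - 1) - geom.y1, (H - 1) - geom.y0
        x0 = int(np.clip(np.floor(geom.x0), 0, W - 1))
        x1 = int(np.clip(np.ceil(geom.x1), x0 + 1, W))
        yy0 = int(np.clip(np.floor(y0), 0, H - 1))
        yy1 = int(np.clip(np.ceil(y1), yy0 + 1, H))
        crop = img[yy0:yy1, x0:x1]
        resized = transform.resize(
            crop, (side, side), order=1, anti_aliasing=True, mode="reflect"
        )
        return [
            GrayROI(
                pixels=np.clip(resized, 0.0, 1.0),
                label=ann.lesion_class,
                source=(ann.image_id, f"box({x0},{yy0},{x1},{yy1})", "orig"),
            )
        ]

    raise ValueError(f"unknown extraction mode: {mode!r}")


def extract_normal_rois(
    image: np.ndarray,
    ann: LesionAnnotation,
    side: int = DEFAULT_SIDE,
    n: int = 1,
    seed: int = 0,
    margin_frac: float = 0.25,
) -> list[GrayROI]:
    """Sample ``n`` normal-tissue tiles from an image annotated as normal.

    Tiles are drawn uniformly (seeded) from the central region of the image,
    keeping a ``margin_frac`` border away from the edges where film
    background dominates.
    """
    img = _as_unit_float(image)
    H, W = img.shape
    rng = np.random.default_rng(seed)
    my, mx = int(H * margin_frac), int(W * margin_frac)
    y_hi, x_hi = H - my - side, W - mx - side
    if y_hi <= my or x_hi <= mx:
        return []
    out = []
    for k in range(n):
        y0 = int(rng.integers(my, y_hi))
        x0 = int(rng.integers(mx, x_hi))
        out.append(
            GrayROI(
                pixels=img[y0 : y0 + side, x0 : x0 + side].copy(),
                label=LesionClass.NORMAL,
                source=(ann.image_id, (y0, x0), "orig"),
            )
        )
    return out


# --------------------------------------------------------------------------
# Augmentation
# --------------------------------------------------------------------------

def augment(
    roi: GrayROI,
    rotations: Sequence[int] = (0, 90, 180, 270),
    flips: bool = False,
) -> list[GrayROI]:
    """Rotate (and optionally flip) one ROI; exact pixel permutations only.

    Each requested rotation is a multiple of 90 degrees and is applied with
    ``np.rot90`` — no interpolation, so the pixel multiset is preserved
    bit-exactly.  With ``flips`` on, each rotation additionally yields a
    left-right and an up-down flipped variant (3 outputs per rotation).
    """
    out: list[GrayROI] = []
    for angle in rotations:
        if angle % 90 != 0:
            raise ValueError(
                f"rotation {angle} is not a multiple of 90 degrees; "
                "augmentation is interpolation-free"
            )
        k = (angle // 90) % 4
        rot = np.rot90(roi.pixels, k=k) if k else roi.pixels.copy()
        tag = "orig" if angle % 360 == 0 else f"rot{angle % 360}"
        img_id, offset, base = roi.source
        base_prefix = "" if base == "orig" else base + "+"
        out.append(replace(roi, pixels=rot, source=(img_id, offset, base_prefix + tag)))
        if flips:
            out.append(
                replace(
                    roi,
                    pixels=np.fliplr(rot),
                    source=(img_id, offset, base_prefix + tag + "+fliplr"),
                )
            )
            out.append(
                replace(
                    roi,
                    pixels=np.flipud(rot),
                    source=(img_id, offset, base_prefix + tag + "+flipud"),
                )
            )
    return out


# --------------------------------------------------------------------------
# Pseudo-color channel synthesis
# --------------------------------------------------------------------------

def clahe_channel(
    roi: GrayROI | np.ndarray,
    clip_limit: float = DEFAULT_CLAHE_CLIP,
    tiles: tuple[int, int] = DEFAULT_CLAHE_TILES,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one patch.

    Local histogram equalization over a ``tiles`` grid with the normalized
    clip limit bounding noise amplification.  Constant inputs pass through
    unchanged (a single-level histogram has nothing to equalize).
    """
    px = roi.pixels if isinstance(roi, GrayROI) else _as_unit_float(roi)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    rows, cols = tiles
    if rows < 1 or cols < 1:
        raise ValueError("tile grid must be at least 1x1")
    if rows > px.shape[0] or cols > px.shape[1]:
        raise ValueError(
            f"tile grid {tiles} larger than image {px.shape}"
        )
    if px.size == 0 or np.ptp(px) == 0:
        return px.copy()
    kernel = (
        max(1, px.shape[0] // rows),
        max(1, px.shape[1] // cols),
    )
    out = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def percentile_stretch(
    roi: GrayROI | np.ndarray,
    low: float = DEFAULT_STRETCH[0],
    high: float = DEFAULT_STRETCH[1],
) -> np.ndarray:
    """Linear intensity stretch saturating the bottom/top percentiles.

    Values at or below the ``low``-th percentile map to 0, at or above the
    ``(100-high)``-th percentile map to 1, linear in between (percentiles by
    linear interpolation between order statistics).  If the two percentile
    values coincide — e.g. a constant patch — the input is returned
    unchanged.
    """
    px = roi.pixels if isinstance(roi, GrayROI) else _as_unit_float(roi)
    if low + high >= 100:
        raise ValueError("low + high percentiles must be < 100")
    lo, hi = np.percentile(px, [low, 100.0 - high])
    if hi <= lo:
        return px.copy()
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


def to_pseudo_color(
    roi: GrayROI,
    clahe_params: dict | None = None,
    stretch_params: dict | None = None,
) -> PseudoColorImage:
    """Build the three-channel pseudo-color stack from one grayscale ROI.

    Channel 0 carries the original intensities bit-exactly; channel 1 the
    CLAHE enhancement; channel 2 the percentile stretch.  This replaces the
    usual grayscale-replicated-three-times input of pretrained CNNs with
    channels that each add global contrast information.
    """
    clahe_params = clahe_params or {}
    stretch_params = stretch_params or {}
    return PseudoColorImage(
        channels=np.stack(
            [
                roi.pixels,
                clahe_channel(roi, **clahe_params),
                percentile_stretch(roi, **stretch_params),
            ]
        )
    )


def resize_for_backbone(img: PseudoColorImage, target: int) -> PseudoColorImage:
    """Resize a pseudo-color stack to ``target x target`` per channel.

    Anti-aliased bilinear interpolation, matching how small lesion patches
    are upsampled to a CNN's fixed input resolution (227 for AlexNet, 224
    for VGG16/GoogLeNet).  No-op when already at the target size.
    """
    if target <= 0:
        raise ValueError("target side must be positive")
    if img.shape == (target, target):
        return img
    resized = np.stack(
        [
            transform.resize(
                ch, (target, target), order=1, anti_aliasing=True, mode="reflect"
            )
            for ch in img.channels
        ]
    )
    return PseudoColorImage(channels=np.clip(resized, 0.0, 1.0))


# --------------------------------------------------------------------------
# Image / manifest I/O
# --------------------------------------------------------------------------

def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit grayscale PGM (raw or ASCII) or PNG into [0, 1] floats."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def write_pseudo_color_png(img: PseudoColorImage, path: str | os.PathLike) -> None:
    """Write a pseudo-color stack as an RGB PNG (round-half-up to 8 bits)."""
    arr = np.floor(img.channels * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(np.moveaxis(arr, 0, -1), mode="RGB").save(path)


def write_gray_png(pixels: np.ndarray, path: str | os.PathLike) -> None:
    arr = np.floor(np.clip(pixels, 0, 1) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_manifest(
    rows: Iterable[tuple[str, str, str, str]], path: str | os.PathLike
) -> None:
    """Write a sample manifest: sample_id, label, source, transform (TSV)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\tsource\ttransform\n")
        for sample_id, label, source, tag in rows:
            fh.write(f"{sample_id}\t{label}\t{source}\t{tag}\n")


def read_manifest(path: str | os.PathLike) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, ln.rstrip("\n").split("\t"))) for ln in fh if ln.strip()]


def _as_unit_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.size and img.max() > 1.0:  # 8-bit input
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)
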