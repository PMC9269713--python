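"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Two generators make every stage testable without downloading any mammography
benchmark:

*  ``gen_roi_dataset`` — mammogram-like 32x32 patches: a smoothed-noise
   background in a mid-gray band plus a centered radial Gaussian lesion.
   The class cues mirror real radiological ones: malignant lesions are
   larger, higher-contrast and spiculated (sinusoidal rim perturbation)
   than benign ones, and per-lesion contrast jitter supplies the
   within-class variability that class-wise PCA needs to represent the
   lesion-intensity direction at all.  Additive pixel noise on top.  This
   is a class-separable stand-in for lesion ROIs, not a realistic phantom.

*  ``gen_feature_table`` — a low-rank latent-factor feature table emulating
   correlated deep features: latent factors load onto disjoint feature
   groups (planting multicollinearity), labels follow a logistic model on a
   known informative subset of factors, and the ground-truth informative
   directions are returned for recovery tests.

The default label effect size (beta 21 per informative factor) puts the
Bayes accuracy of the label model near 98.5%, the regime the benchmark
pipelines report operating in.  Everything is deterministic per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .roi_prep import GrayROI, LesionClass, write_gray_png, write_manifest


@dataclass(frozen=True)
class RoiSimConfig:
    n_per_class: int = 200
    side: int = 32
    background_sigma: float = 4.0       # px, smoothing of the background noise
    background_band: tuple[float, float] = (0.42, 0.58)
    contrast: dict = field(
        default_factory=lambda: {"benign": 0.15, "malignant": 0.40}
    )
    radius_frac: dict = field(          # lesion scale relative to side
        default_factory=lambda: {"benign": 0.25, "malignant": 0.42}
    )
    contrast_jitter: float = 0.15       # relative sd of per-lesion contrast
    spiculation_amplitude: float = 5.0  # px, malignant only
    spiculation_frequency: int = 6      # lobes around the lesion rim
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sigma <= 0 or self.noise_sigma <= 0:
            raise ValueError("all sigmas must be positive")
        vals = self.contrast
        if "malignant" in vals and "benign" in vals:
            if not vals["malignant"] >= vals["benign"] >= 0:
                raise ValueError("need contrast: malignant >= benign >= 0")


@dataclass(frozen=True)
class FeatureSimConfig:
    n: int = 400
    p: int = 200
    rank: int = 10                      # latent factors
    n_informative: int = 3
    beta_true: float = 21.0             # per informative factor
    collinearity_load: float = 1.0      # base factor loading within a group
    spectrum_top: float = 1.5           # leading factor's load multiplier
    spectrum_ratio: float = 0.8         # geometric decay of load multipliers
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_informative <= self.rank <= self.p):
            raise ValueError("need 0 < n_informative <= rank <= p")
        if self.n <= self.rank:
            raise ValueError("need n > rank")


def _lesion_field(side: int, radius: float, rng: np.random.Generator,
                  spic_amp: float, spic_freq: int) -> np.ndarray:
    """Unit-amplitude radial Gaussian bump, optionally with a spiculated rim."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    c = (side - 1) / 2.0
    dy, dx = yy - c, xx - c
    rr = np.hypot(dy, dx)
    if spic_amp > 0:
        theta = np.arctan2(dy, dx)
        phase = rng.uniform(0, 2 * np.pi)
        radius_local = radius + spic_amp * np.sin(spic_freq * theta + phase)
        radius_local = np.clip(radius_local, radius * 0.3, None)
    else:
        radius_local = radius
    return np.exp(-0.5 * (rr / radius_local) ** 2)


def gen_roi_dataset(
    cfg: RoiSimConfig,
) -> tuple[list[GrayROI], list[str], list[tuple[str, str, str, str]]]:
    """Generate labeled synthetic lesion ROIs.

    Returns ``(rois, labels, manifest_rows)`` where manifest rows follow the
    (sample_id, label, source, transform) layout written by the ROI
    preparation stage, so downstream stages cannot tell synthetic from real
    origin.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.background_band
    rois: list[GrayROI] = []
    labels: list[str] = []
    manifest: list[tuple[str, str, str, str]] = []
    for cls, delta in sorted(cfg.contrast.items()):
        radius = cfg.radius_frac.get(cls, 0.35) * cfg.side
        for i in range(cfg.n_per_class):
            bg = rng.standard_normal((cfg.side, cfg.side))
            bg = ndimage.gaussian_filter(bg, cfg.background_sigma)
            span = np.ptp(bg)
            bg = lo + (hi - lo) * ((bg - bg.min()) / span if span > 0 else 0.5)
            spic = cfg.spiculation_amplitude if cls == "malignant" else 0.0
            jit = max(0.2, 1.0 + cfg.contrast_jitter * rng.standard_normal())
            img = bg + delta * jit * _lesion_field(
                cfg.side, radius, rng, spic, cfg.spiculation_frequency
            )
            img = img + cfg.noise_sigma * rng.standard_normal(img.shape)
            img = np.clip(img, 0.0, 1.0)
            sid = f"sim_{cls}_{i:04d}"
            rois.append(
                GrayROI(
                    pixels=img,
                    label=LesionClass(cls) if cls in LesionClass._value2member_map_
                    else LesionClass.NORMAL,
                    source=(sid, (0, 0), "orig"),
                )
            )
            labels.append(cls)
            manifest.append((sid, cls, f"{sid}@(0,0)", "orig"))
    return rois, labels, manifest


def gen_feature_table(
    cfg: FeatureSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a correlated feature table with a planted informative subspace.

    Latent ``Z ~ N(0, I)`` (n x rank); factor ``j`` loads onto its own
    contiguous group of ``p // rank`` features with weight
    ``collinearity_load * spectrum_top * spectrum_ratio**j``.  The geometric
    decay mirrors the decaying covariance spectra of real deep features and
    keeps relative eigenvalue gaps large against sampling noise, so group
    directions stay identifiable.  ``X = Z W + noise_sigma * E``.  Labels are
    ``y ~ Bernoulli(sigmoid(Z[:, :n_informative] @ beta))`` with equal
    ``beta_true`` per informative factor.  Returns ``(X, y, directions)``
    where ``directions`` holds the unit-norm informative group directions in
    feature space (rows), the ground truth for subspace-recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p, r = cfg.n, cfg.p, cfg.rank
    Z = rng.standard_normal((n, r))
    W = np.zeros((r, p))
    group = max(1, p // r)
    mults = cfg.spectrum_top * cfg.spectrum_ratio ** np.arange(r)
    for j in range(r):
        start = j * group
        stop = p if j == r - 1 else min(p, start + group)
        W[j, start:stop] = cfg.collinearity_load * mults[j]
    X = Z @ W + cfg.noise_sigma * rng.standard_normal((n, p))
    eta = Z[:, : cfg.n_informative] @ np.full(cfg.n_informative, cfg.beta_true)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    norms = np.linalg.norm(W[: cfg.n_informative], axis=1, keepdims=True)
    directions = W[: cfg.n_informative] / np.where(norms > 0, norms, 1.0)
    return X, y, directions


def write_roi_dataset(
    cfg: RoiSimConfig, out_dir: str | os.PathLike
) -> tuple[list[GrayROI], list[str]]:
    """Materialize a synthetic ROI dataset in the prepare-stage layout
    (grayscale PNGs plus a TSV manifest)."""
    os.makedirs(out_dir, exist_ok=True)
    rois, labels, manifest = gen_roi_dataset(cfg)
    for (sid, _, _, _), roi in zip(manifest, rois):
        write_gray_png(roi.pixels, os.path.join(out_dir, sid + ".png"))
    write_manifest(manifest, os.path.join(out_dir, "manifest.tsv"))
    return rois, labels
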