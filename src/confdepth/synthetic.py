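"""Seeded generator of stereo-style supervision with realistic failure modes.

Real stereo supervision from a surgical scene fails in structured ways:

* a band along the left image border has no counterpart in the right
  image, is never matched, and arrives with confidence exactly 0;
* compact regions hit by droplets, smoke or specular bleed-through carry
  *gross* disparity errors and conspicuously low confidence;
* everywhere else the matcher is accurate up to small noise and reports
  high confidence.

The generator reproduces exactly this joint structure on top of a smooth
random polynomial inverse-depth surface, so the link between confidence
and supervision quality — the premise a confidence-weighted loss relies
on — holds *by construction* and every downstream claim about it is
testable without any dataset download.

Default geometry mirrors a stereo-laparoscope test split (384 x 192
frames); magnitudes of the corruption are free parameters chosen so that
confidence-blind and confidence-aware training visibly diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .maps_io import (
    ConfidenceMap,
    InverseDepthMap,
    SupervisionFrame,
    build_validity_mask,
    read_pfm,
    read_png16,
    write_pfm,
    write_png16,
)

__all__ = [
    "SceneConfig",
    "CorruptionConfig",
    "generate_truth",
    "corrupt",
    "generate_dataset",
    "load_dataset",
    "CONFIDENCE_PNG_SCALE",
]

#: quantisation scale for confidence maps written as 16-bit PNG
CONFIDENCE_PNG_SCALE = 65535.0


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of the true inverse-depth surface.

    The surface is a random polynomial in normalised image coordinates,
    rescaled into ``inv_depth_range`` (units: arbitrary inverse depth).
    """

    height: int = 192
    width: int = 384
    surface_order: int = 2
    inv_depth_range: tuple[float, float] = (0.25, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("scene must be at least 2x2")
        if self.surface_order < 0:
            raise ValueError("surface_order must be >= 0")
        low, high = self.inv_depth_range
        if not (0 < low < high):
            raise ValueError("inv_depth_range must satisfy 0 < low < high")


@dataclass(frozen=True)
class CorruptionConfig:
    """How supervision departs from the truth.

    occlusion_border_cols: width of the confidence-0 left band.
    blob_count / blob_radius_range: number and size (pixels) of low
        confidence disk artefacts carrying gross outliers.
    outlier_magnitude: scale of the gross disparity error inside blobs.
    inlier_noise_sd: Gaussian noise sd on trusted pixels.
    conf_high_range / conf_low_range: confidence intervals of trusted
        and artefact pixels; the low interval must sit entirely below
        the high one.
    """

    occlusion_border_cols: int = 32
    blob_count: int = 6
    blob_radius_range: tuple[int, int] = (8, 24)
    outlier_magnitude: float = 5.0
    inlier_noise_sd: float = 0.01
    conf_high_range: tuple[float, float] = (0.7, 1.0)
    conf_low_range: tuple[float, float] = (0.05, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occlusion_border_cols < 0 or self.blob_count < 0:
            raise ValueError("occlusion_border_cols and blob_count must be >= 0")
        rmin, rmax = self.blob_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("blob_radius_range must satisfy 0 < min <= max")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be > 0")
        if self.inlier_noise_sd < 0:
            raise ValueError("inlier_noise_sd must be >= 0")
        for lo, hi in (self.conf_high_range, self.conf_low_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("confidence ranges must be sub-intervals of [0, 1]")
        if self.conf_low_range[1] >= self.conf_high_range[0]:
            raise ValueError(
                "conf_low_range must lie entirely below conf_high_range"
            )


def generate_truth(cfg: SceneConfig) -> InverseDepthMap:
    """Smooth random polynomial inverse-depth surface, clipped into range."""
    rng = np.random.default_rng(cfg.seed)
    ys, xs = np.meshgrid(
        np.linspace(-1.0, 1.0, cfg.height),
        np.linspace(-1.0, 1.0, cfg.width),
        indexing="ij",
    )
    surface = np.zeros((cfg.height, cfg.width))
    for i in range(cfg.surface_order + 1):
        for j in range(cfg.surface_order + 1 - i):
            surface += rng.normal() * (xs**j) * (ys**i)
    low, high = cfg.inv_depth_range
    smin, smax = float(surface.min()), float(surface.max())
    if smax - smin < 1e-12:
        # degenerate (e.g. order 0): park at mid-range
        surface = np.full_like(surface, 0.5 * (low + high))
    else:
        surface = low + (surface - smin) * (high - low) / (smax - smin)
    return InverseDepthMap(np.clip(surface, low, high))


def _blob_mask(
    shape: tuple[int, int], rng: np.random.Generator, cfg: CorruptionConfig
) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    ys, xs = np.mgrid[0:h, 0:w]
    rmin, rmax = cfg.blob_radius_range
    for _ in range(cfg.blob_count):
        cy = rng.integers(0, h)
        cx = rng.integers(cfg.occlusion_border_cols, w)
        radius = rng.integers(rmin, rmax + 1)
        mask |= (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
    return mask


def corrupt(truth: InverseDepthMap, cfg: CorruptionConfig) -> SupervisionFrame:
    """Produce a supervision frame with occlusion band, blobs, and noise.

    Blob pixels get disparity = truth + gross error of ~outlier_magnitude
    with random sign, and low confidence; the left border gets confidence
    0 with invalid (NaN) disparity; all remaining pixels get small
    Gaussian noise and high confidence.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = truth.shape
    if cfg.occlusion_border_cols >= w:
        raise ConfigError("occlusion band covers the entire image width")

    border = np.zeros((h, w), dtype=bool)
    border[:, : cfg.occlusion_border_cols] = True
    blobs = _blob_mask((h, w), rng, cfg) & ~border
    clean = ~border & ~blobs
    if not clean.any():
        raise ConfigError("corruption blobs cover every non-occluded pixel")

    disparity = truth.values.copy()
    confidence = np.zeros((h, w))

    # trusted pixels: small noise, high confidence
    disparity[clean] += rng.normal(0.0, cfg.inlier_noise_sd, clean.sum())
    confidence[clean] = rng.uniform(*cfg.conf_high_range, clean.sum())

    # artefact pixels: gross, signed outliers, low confidence
    n_blob = int(blobs.sum())
    if n_blob:
        sign = rng.choice([-1.0, 1.0], n_blob)
        magnitude = cfg.outlier_magnitude * rng.uniform(0.5, 1.5, n_blob)
        disparity[blobs] += sign * magnitude
        confidence[blobs] = rng.uniform(*cfg.conf_low_range, n_blob)

    # occlusion band: no estimate at all
    disparity[border] = np.nan
    confidence[border] = 0.0

    disp = InverseDepthMap(disparity)
    conf = ConfidenceMap(confidence)
    return SupervisionFrame(disp, conf, build_validity_mask(disp, conf))


def _frame_stats(truth: InverseDepthMap, frame: SupervisionFrame) -> dict[str, float]:
    q = frame.confidence.values
    n = q.size
    low = (q > 0) & (q < 0.5)
    return {
        "occluded_fraction": float((q == 0).mean()),
        "outlier_fraction": float(low.mean()),
        "mean_abs_error_valid": float(
            np.nanmean(np.abs(frame.disparity.values - truth.values)[frame.mask.flags])
        ),
        "pixels": n,
    }


def generate_dataset(
    n: int,
    scene: SceneConfig,
    corr: CorruptionConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write ``n`` (truth, supervision) groups to disk plus a CSV manifest.

    Per-image randomness is derived from ``(seed, image index)`` with a
    SeedSequence, so any single image can be regenerated independently.
    Truth and supervisory disparity are PFM; confidence is 16-bit PNG at
    scale :data:`CONFIDENCE_PNG_SCALE`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx in range(n):
        scene_seed, corr_seed = (
        int(s) for s in np.random.SeedSequence([scene.seed, idx]).generate_state(2) % (2**31)
        )
        scfg = SceneConfig(
            scene.height, scene.width, scene.surface_order,
            scene.inv_depth_range, scene_seed,
        )
        ccfg = CorruptionConfig(
            corr.occlusion_border_cols, corr.blob_count, corr.blob_radius_range,
            corr.outlier_magnitude, corr.inlier_noise_sd,
            corr.conf_high_range, corr.conf_low_range, corr_seed,
        )
        truth = generate_truth(scfg)
        frame = corrupt(truth, ccfg)
        names = {
            "truth": f"img{idx:04d}_truth.pfm",
            "disparity": f"img{idx:04d}_disparity.pfm",
            "confidence": f"img{idx:04d}_confidence.png",
        }
        write_pfm(truth, out / names["truth"])
        write_pfm(frame.disparity, out / names["disparity"])
        write_png16(
            InverseDepthMap(np.where(frame.confidence.values > 0,
                                     frame.confidence.values, np.nan)),
            out / names["confidence"],
            CONFIDENCE_PNG_SCALE,
        )
        rows.append(
            {"index": idx, "scene_seed": scene_seed, "corruption_seed": corr_seed,
             **names, **_frame_stats(truth, frame)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(out_dir: str | Path) -> list[tuple[InverseDepthMap, SupervisionFrame]]:
    """Read back a generated dataset via its manifest."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    groups = []
    for _, row in manifest.iterrows():
        truth = read_pfm(out / row["truth"])
        disp = read_pfm(out / row["disparity"])
        conf_raw = read_png16(out / row["confidence"], CONFIDENCE_PNG_SCALE)
        conf = ConfidenceMap(np.nan_to_num(conf_raw.values, nan=0.0))
        groups.append((truth, SupervisionFrame(disp, conf)))
    return groups
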