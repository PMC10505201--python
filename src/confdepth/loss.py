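"""Confidence-weighted scale-and-shift-invariant loss.

Stereo self-supervision in surgical video is contaminated: smoke, blood,
droplets and occlusions make the matcher's disparity grossly wrong exactly
where its confidence ``q`` is low.  The loss therefore weights every pixel
by a function of its confidence before comparing the (affine-aligned)
prediction with the supervisory disparity:

* data term   L_data = (1 / 2M) * sum_i w(q_i) * (dhat_i - dstar_i)^2
* gradient    L_grad = (1 / M)  * sum_k sum_i w(q_i) * (|dx R_i^k| + |dy R_i^k|)
* per image   L = L_data + alpha * L_grad
* batch       mean of per-image L over the training set

where ``R^k`` is the aligned residual at pyramid level ``k`` (resolution
halved per level, K levels) and ``M`` counts *valid* pixels — pixels whose
weight happens to be zero stay in the denominator.

Weight functions (``theta`` is the confidence threshold, ``lam`` the
soft-mask sharpness):

* hard mask   w(q) = 1 if q >= theta else 0
* soft mask   w(q) = exp(lam * (q - 1)) if q >= theta else 0
* uniform     w(q) = 1   (the confidence-blind baseline)

Zero-weight pixels are excluded from the internal affine alignment and
from every pyramid level (residuals are pooled by weighted block means and
a pixel participates in a forward difference only where its weight is
positive), so a gross outlier at a masked pixel cannot leak into the loss
through the alignment or through coarse-scale averaging.  This is what
makes the hard-mask objective exactly the objective of training on the
trusted subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import AffineParams, _solve_lsq, apply_affine
from .errors import (
    DegenerateInputError,
    DimensionError,
    DomainError,
    EmptyBatchError,
    EmptyImageError,
)
from .maps_io import ConfidenceMap, InverseDepthMap, SupervisionFrame, ValidityMask

__all__ = [
    "WeightConfig",
    "LossConfig",
    "LossBreakdown",
    "ScalePyramid",
    "weight_of",
    "cw_ssi_mse",
    "build_pyramid",
    "cw_gradient_term",
    "image_loss",
    "batch_loss",
]

logger = logging.getLogger(__name__)

MASK_KINDS = ("hard", "soft", "uniform")


@dataclass(frozen=True)
class WeightConfig:
    """Confidence-to-weight mapping.

    mask_kind: "hard", "soft" or "uniform".
    threshold: theta, confidence below which supervision is ignored.
    sharpness: lam, soft-mask exponent steepness (lam = 0 degenerates the
        soft mask to the hard mask).
    """

    mask_kind: str = "soft"
    threshold: float = 0.5
    sharpness: float = 10.0

    def __post_init__(self) -> None:
        if self.mask_kind not in MASK_KINDS:
            raise ValueError(f"mask_kind must be one of {MASK_KINDS}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.sharpness < 0:
            raise ValueError(f"sharpness must be >= 0, got {self.sharpness}")


@dataclass(frozen=True)
class LossConfig:
    """Full loss configuration: alpha, K and the weight function."""

    gradient_weight: float = 0.5
    scale_levels: int = 4
    weight: WeightConfig = field(default_factory=WeightConfig)

    def __post_init__(self) -> None:
        if self.gradient_weight < 0:
            raise ValueError("gradient_weight must be >= 0")
        if self.scale_levels < 1:
            raise ValueError("scale_levels must be >= 1")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-image loss decomposition."""

    data_term: float
    gradient_term: float
    total: float
    effective_pixels: int  # pixels with positive weight


@dataclass
class ScalePyramid:
    """Residual/weight/validity grids at successively halved resolution.

    ``levels[k]`` holds ``(residual, weights, valid)`` for level k+1;
    ``m_full`` is the full-resolution valid-pixel count used as the single
    normaliser of the gradient term.
    """

    levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    m_full: int


def weight_of(q, cfg: WeightConfig):
    """Evaluate the confidence weight; scalar in, scalar out (arrays OK)."""
    arr = np.asarray(q, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError(f"confidence outside [0, 1]: {arr[(arr < 0) | (arr > 1)][:3]}")
    if cfg.mask_kind == "uniform":
        w = np.ones_like(arr)
    elif cfg.mask_kind == "hard":
        w = np.where(arr >= cfg.threshold, 1.0, 0.0)
    else:  # soft
        w = np.where(arr >= cfg.threshold, np.exp(cfg.sharpness * (arr - 1.0)), 0.0)
    return w if arr.ndim else float(w)


def cw_ssi_mse(
    pred_aligned: InverseDepthMap,
    gt: InverseDepthMap,
    conf: ConfidenceMap,
    mask: ValidityMask,
    cfg: WeightConfig,
) -> float:
    """Weighted mean squared residual, normalised by 2M (M = valid pixels)."""
    if not (pred_aligned.shape == gt.shape == conf.shape == mask.shape):
        raise DimensionError("pred/gt/conf/mask shapes differ")
    flags = mask.flags
    m = int(flags.sum())
    if m == 0:
        raise EmptyImageError("no valid pixels: the data term is undefined")
    w = weight_of(conf.values[flags], cfg)
    r = pred_aligned.values[flags] - gt.values[flags]
    return float(np.sum(w * r * r) / (2.0 * m))


def _pool2(a: np.ndarray, pad_value: float) -> np.ndarray:
    """Split into 2x2 blocks (ceil semantics, edge blocks padded)."""
    h, w = a.shape
    hp, wp = -(-h // 2) * 2, -(-w // 2) * 2
    padded = np.full((hp, wp), pad_value, dtype=a.dtype)
    padded[:h, :w] = a
    return padded.reshape(hp // 2, 2, wp // 2, 2)


def build_pyramid(
    pred_aligned: InverseDepthMap,
    gt: InverseDepthMap,
    conf_weights: np.ndarray,
    mask: ValidityMask,
    levels: int,
) -> ScalePyramid:
    """Residual pyramid for the multi-scale gradient term.

    Level 1 is the full-resolution residual.  Each subsequent level pools
    2x2 blocks: weights by plain averaging, residuals by weight-weighted
    averaging (plain mean when the block weight is zero), validity by the
    all-four-children-valid rule.  Levels that would shrink below the
    image's dyadic budget are dropped with a warning rather than raising.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = pred_aligned.shape
    max_levels = int(np.floor(np.log2(min(h, w)))) + 1
    if levels > max_levels:
        warnings.warn(
            f"image {h}x{w} supports only {max_levels} pyramid levels; "
            f"requested {levels}, truncating",
            stacklevel=2,
        )
        levels = max_levels

    resid = np.where(mask.flags, pred_aligned.values - gt.values, 0.0)
    wgt = np.where(mask.flags, np.asarray(conf_weights, dtype=np.float64), 0.0)
    valid = mask.flags.copy()
    m_full = int(valid.sum())

    out: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(resid, wgt, valid)]
    for _ in range(levels - 1):
        rb = _pool2(resid, 0.0)
        wb = _pool2(wgt, 0.0)
        vb = _pool2(valid.astype(np.float64), 0.0)
        wsum = wb.sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_weighted = (wb * rb).sum(axis=(1, 3)) / wsum
        r_plain = rb.mean(axis=(1, 3))
        resid = np.where(wsum > 0, np.nan_to_num(r_weighted), r_plain)
        wgt = wb.mean(axis=(1, 3))
        valid = vb.sum(axis=(1, 3)) == 4
        out.append((resid, wgt, valid))
    return ScalePyramid(levels=out, m_full=m_full)


def cw_gradient_term(pyramid: ScalePyramid) -> float:
    """Sum of weighted forward-difference magnitudes across levels, / M.

    A difference contributes only where both participating pixels are
    valid and carry positive weight; the contribution is weighted by the
    mean of the two pixels' (pooled) weights, so the term is exactly
    symmetric under horizontal/vertical flips.
    """
    if pyramid.m_full == 0:
        return 0.0
    total = 0.0
    for resid, wgt, valid in pyramid.levels:
        eff = valid & (wgt > 0)
        # x direction (columns)
        both = eff[:, :-1] & eff[:, 1:]
        dx = np.abs(resid[:, 1:] - resid[:, :-1])
        wx = 0.5 * (wgt[:, :-1] + wgt[:, 1:])
        total += float(np.sum(wx[both] * dx[both]))
        # y direction (rows)
        both = eff[:-1, :] & eff[1:, :]
        dy = np.abs(resid[1:, :] - resid[:-1, :])
        wy = 0.5 * (wgt[:-1, :] + wgt[1:, :])
        total += float(np.sum(wy[both] * dy[both]))
    return total / pyramid.m_full


def image_loss(
    pred: InverseDepthMap, sup: SupervisionFrame, cfg: LossConfig = LossConfig()
) -> LossBreakdown:
    """Full per-image loss: align, residual data term, gradient pyramid.

    Degenerate images — everything masked out, fewer than two weighted
    pixels, a singular alignment, or a non-positive fitted scale —
    contribute zero loss (logged), so a bad frame never poisons a batch.
    """
    if pred.shape != sup.shape:
        raise DimensionError(f"pred {pred.shape} vs supervision {sup.shape}")
    w_full = np.zeros(pred.shape, dtype=np.float64)
    flags = sup.mask.flags & np.isfinite(pred.values)
    w_full[flags] = weight_of(sup.confidence.values[flags], cfg.weight)

    fit_flags = flags & (w_full > 0)
    n_eff = int(fit_flags.sum())
    if n_eff < 2:
        logger.warning("image fully masked (%d weighted pixels): zero loss", n_eff)
        return LossBreakdown(0.0, 0.0, 0.0, 0)
    x = pred.values[fit_flags]
    y = sup.disparity.values[fit_flags]
    try:
        params = _solve_lsq(x, y)
    except DegenerateInputError:
        logger.warning("degenerate alignment (constant prediction): zero loss")
        return LossBreakdown(0.0, 0.0, 0.0, 0)
    if params.s <= 0:
        logger.warning("non-positive fitted scale s=%.3g: zero loss", params.s)
        return LossBreakdown(0.0, 0.0, 0.0, 0)

    aligned = apply_affine(pred, AffineParams(params.s, params.t))
    mask = ValidityMask(flags)
    conf = ConfidenceMap(sup.confidence.values)
    data = cw_ssi_mse(aligned, sup.disparity, conf, mask, cfg.weight)
    pyr = build_pyramid(aligned, sup.disparity, w_full, mask, cfg.scale_levels)
    grad = cw_gradient_term(pyr)
    return LossBreakdown(
        data_term=data,
        gradient_term=grad,
        total=data + cfg.gradient_weight * grad,
        effective_pixels=n_eff,
    )


def batch_loss(
    preds: list[InverseDepthMap],
    sups: list[SupervisionFrame],
    cfg: LossConfig = LossConfig(),
) -> tuple[float, list[LossBreakdown]]:
    """Mean per-image total over the batch; degenerate images count in N."""
    if not preds or not sups:
        raise EmptyBatchError("batch_loss requires non-empty lists")
    if len(preds) != len(sups):
        raise DimensionError(
            f"{len(preds)} predictions vs {len(sups)} supervision frames"
        )
    breakdowns = [image_loss(p, s, cfg) for p, s in zip(preds, sups)]
    total = float(np.mean([b.total for b in breakdowns]))
    return total, breakdowns
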