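"""Scale-shift-invariant evaluation of depth predictions.

Protocol: align the predicted inverse depth onto the reference inverse
depth with the robust IRLS-biweight aligner (so supervisory outliers do
not skew the affine fit), convert both to depth by reciprocal, then score

* Abs. Rel. = mean |d - d*| / d*
* delta_k   = fraction of pixels with max(d/d*, d*/d) strictly below
  1.25, 1.25^2, 1.25^3

over pixels that remain valid after alignment (aligned inverse depth must
exceed a small floor eps before the reciprocal; pixels at or below the
floor are dropped and reported via ``pixels_evaluated``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import IRLSConfig, align_irls, apply_affine
from .errors import (
    ConfdepthError,
    DimensionError,
    DomainError,
    EmptyBatchError,
    EvaluationError,
)
from .maps_io import ConfidenceMap, InverseDepthMap, ValidityMask, build_validity_mask

__all__ = [
    "MetricsReport",
    "abs_rel",
    "threshold_accuracy",
    "evaluate_pair",
    "evaluate_set",
    "DELTA_THRESHOLDS",
]

DELTA_THRESHOLDS = (1.25, 1.25**2, 1.25**3)

#: floor on aligned inverse depth before taking the reciprocal
EPS_INVERSE_DEPTH = 1e-8


@dataclass(frozen=True)
class MetricsReport:
    abs_rel: float
    delta1: float
    delta2: float
    delta3: float
    pixels_evaluated: int

    def as_dict(self) -> dict[str, float]:
        return {
            "abs_rel": self.abs_rel,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "delta3": self.delta3,
            "pixels_evaluated": self.pixels_evaluated,
        }


def _valid_depths(
    pred_depth: np.ndarray, gt_depth: np.ndarray, mask: ValidityMask
) -> tuple[np.ndarray, np.ndarray]:
    pred_depth = np.asarray(pred_depth, dtype=np.float64)
    gt_depth = np.asarray(gt_depth, dtype=np.float64)
    if pred_depth.shape != gt_depth.shape or pred_depth.shape != mask.shape:
        raise DimensionError("depth/mask shape mismatch")
    p = pred_depth[mask.flags]
    g = gt_depth[mask.flags]
    if np.any(g <= 0):
        raise DomainError("ground-truth depth must be strictly positive on valid pixels")
    return p, g


def abs_rel(pred_depth, gt_depth, mask: ValidityMask) -> float:
    """Mean absolute relative depth error over valid pixels."""
    p, g = _valid_depths(pred_depth, gt_depth, mask)
    if p.size == 0:
        raise DomainError("no valid pixels to evaluate")
    return float(np.mean(np.abs(p - g) / g))


def threshold_accuracy(pred_depth, gt_depth, mask: ValidityMask, t: float) -> float:
    """Fraction of valid pixels with max(d/d*, d*/d) strictly below t."""
    if t <= 1:
        raise DomainError(f"threshold must exceed 1, got {t}")
    p, g = _valid_depths(pred_depth, gt_depth, mask)
    if np.any(p <= 0):
        raise DomainError("predicted depth must be strictly positive on valid pixels")
    if p.size == 0:
        raise DomainError("no valid pixels to evaluate")
    ratio = np.maximum(p / g, g / p)
    return float(np.mean(ratio < t))


def evaluate_pair(
    pred_inv: InverseDepthMap,
    gt_inv: InverseDepthMap,
    conf: ConfidenceMap | None = None,
    irls: IRLSConfig = IRLSConfig(),
) -> MetricsReport:
    """Robustly align in inverse-depth space, then score in depth space.

    ``conf`` restricts the valid population (pixels with q = 0 are
    excluded); pass None to treat every finite pixel as valid.
    """
    if conf is None:
        conf = ConfidenceMap(np.ones(gt_inv.shape))
    mask = build_validity_mask(gt_inv, conf)
    mask = ValidityMask(mask.flags & np.isfinite(pred_inv.values))
    try:
        params = align_irls(pred_inv, gt_inv, mask, irls)
    except ConfdepthError as exc:
        raise EvaluationError(f"degenerate alignment: {exc}") from exc
    aligned = apply_affine(pred_inv, params)

    ok = (
        mask.flags
        & (aligned.values > EPS_INVERSE_DEPTH)
        & (gt_inv.values > EPS_INVERSE_DEPTH)
    )
    eval_mask = ValidityMask(ok)
    if eval_mask.count_valid == 0:
        raise EvaluationError("no pixels with valid depth after alignment")
    with np.errstate(divide="ignore"):
        pred_depth = np.where(ok, 1.0 / np.where(ok, aligned.values, 1.0), np.nan)
        gt_depth = np.where(ok, 1.0 / np.where(ok, gt_inv.values, 1.0), np.nan)
    d1, d2, d3 = (
        threshold_accuracy(pred_depth, gt_depth, eval_mask, t) for t in DELTA_THRESHOLDS
    )
    return MetricsReport(
        abs_rel=abs_rel(pred_depth, gt_depth, eval_mask),
        delta1=d1,
        delta2=d2,
        delta3=d3,
        pixels_evaluated=eval_mask.count_valid,
    )


def evaluate_set(
    pairs: list[tuple[InverseDepthMap, InverseDepthMap, ConfidenceMap | None]],
    irls: IRLSConfig = IRLSConfig(),
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Per-image reports plus their unweighted mean across images."""
    if not pairs:
        raise EmptyBatchError("evaluate_set requires a non-empty list of pairs")
    reports = [evaluate_pair(p, g, c, irls) for p, g, c in pairs]
    agg = MetricsReport(
        abs_rel=float(np.mean([r.abs_rel for r in reports])),
        delta1=float(np.mean([r.delta1 for r in reports])),
        delta2=float(np.mean([r.delta2 for r in reports])),
        delta3=float(np.mean([r.delta3 for r in reports])),
        pixels_evaluated=int(sum(r.pixels_evaluated for r in reports)),
    )
    return agg, reports
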