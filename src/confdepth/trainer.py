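"""Desk-scale training loop for the confidence-aware loss.

The full-scale system trains a dense transformer predictor against stereo
supervision; everything the loss claims, however, is a statement about
*pixels and weights*, not about the predictor's architecture.  The
trainer therefore fits a deliberately small parametric predictor — a
low-order 2-D polynomial surface over normalised image coordinates — by
gradient descent on the batch loss, which is enough to test the central
claim: under contaminated supervision, confidence-weighted training
(hard or soft mask) recovers the true surface better than
confidence-blind (uniform) training.

The optimiser is plain finite-difference gradient descent with a
backtracking halving line search and a per-pass step decay (default
0.95), tracking the best parameters seen.  Optional augmentations mirror
the usual recipe at reduced scale: horizontal/vertical flips with 50%
probability (supervision and predicted map flipped together) and additive
Gaussian noise on the supervisory disparity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import align_lsq, apply_affine
from .errors import DivergenceError, EmptyBatchError, ConfdepthError
from .loss import LossConfig, WeightConfig, batch_loss
from .maps_io import (
    ConfidenceMap,
    InverseDepthMap,
    SupervisionFrame,
    ValidityMask,
)
from .synthetic import CorruptionConfig, SceneConfig, corrupt, generate_truth

__all__ = [
    "PredictorParams",
    "TrainConfig",
    "ArmResult",
    "ExperimentReport",
    "predict_surface",
    "fit",
    "run_comparison",
]


@dataclass
class PredictorParams:
    """Coefficients of a 2-D polynomial inverse-depth surface.

    ``coefficients[k]`` multiplies ``x^j * y^i`` with terms enumerated in
    row-major order over ``i + j <= order``; x, y are image coordinates
    normalised to [-1, 1].
    """

    coefficients: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        expected = n_terms(self.order)
        if self.coefficients.shape != (expected,):
            raise ValueError(
                f"order {self.order} needs {expected} coefficients, "
                f"got shape {self.coefficients.shape}"
            )


def n_terms(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _design_matrix(height: int, width: int, order: int) -> np.ndarray:
    ys, xs = np.meshgrid(
        np.linspace(-1.0, 1.0, height),
        np.linspace(-1.0, 1.0, width),
        indexing="ij",
    )
    cols = [
        (xs**j) * (ys**i)
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.stack([c.ravel() for c in cols], axis=1)


def predict_surface(params: PredictorParams, height: int, width: int) -> InverseDepthMap:
    """Evaluate the polynomial predictor on an image grid."""
    design = _design_matrix(height, width, params.order)
    return InverseDepthMap((design @ params.coefficients).reshape(height, width))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and augmentation switches.

    step_decay mirrors the usual exponential learning-rate attenuation
    (factor per full pass over the data); augmentations default off.
    """

    loss: LossConfig = field(default_factory=LossConfig)
    predictor_order: int = 2
    max_steps: int = 150
    step_size: float = 0.2
    step_decay: float = 0.95
    augment_flips: bool = False
    augment_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.step_decay <= 1:
            raise ValueError("step_decay must be in (0, 1]")
        if self.augment_noise_sd < 0:
            raise ValueError("augment_noise_sd must be >= 0")


@dataclass
class FitResult:
    params: PredictorParams
    trajectory: list[float]  # best-so-far batch loss per step
    final_loss: float


def _flip_frame(frame: SupervisionFrame, axis: int) -> SupervisionFrame:
    return SupervisionFrame(
        InverseDepthMap(np.flip(frame.disparity.values, axis=axis).copy()),
        ConfidenceMap(np.flip(frame.confidence.values, axis=axis).copy()),
        ValidityMask(np.flip(frame.mask.flags, axis=axis).copy()),
    )


def _augmented_batch(
    dataset: list[SupervisionFrame],
    preds: list[InverseDepthMap],
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[list[InverseDepthMap], list[SupervisionFrame]]:
    out_p, out_s = [], []
    for pred, sup in zip(preds, dataset):
        if cfg.augment_noise_sd > 0:
            noisy = sup.disparity.values + rng.normal(
                0.0, cfg.augment_noise_sd, sup.shape
            )
            sup = SupervisionFrame(
                InverseDepthMap(noisy), sup.confidence, sup.mask
            )
        if cfg.augment_flips:
            for axis in (0, 1):
                if rng.random() < 0.5:
                    sup = _flip_frame(sup, axis)
                    pred = InverseDepthMap(np.flip(pred.values, axis=axis).copy())
        out_p.append(pred)
        out_s.append(sup)
    return out_p, out_s


def fit(dataset: list[SupervisionFrame], cfg: TrainConfig = TrainConfig()) -> FitResult:
    """Fit the polynomial predictor by finite-difference gradient descent.

    Deterministic given ``cfg.seed``.  The returned parameters are the
    best seen, so the final batch loss never exceeds the initial one.
    """
    if not dataset:
        raise EmptyBatchError("fit requires a non-empty dataset")
    shape = dataset[0].shape
    rng = np.random.default_rng(cfg.seed)
    k = n_terms(cfg.predictor_order)
    design = _design_matrix(*shape, cfg.predictor_order)

    # warm start: unweighted least-squares fit of the surface to the pooled
    # valid supervision (identical for every weight function), plus a tiny
    # seeded jitter so the start is never exactly degenerate
    rows, targets = [], []
    for sup in dataset:
        flags = sup.mask.flags.ravel()
        rows.append(design[flags])
        targets.append(sup.disparity.values.ravel()[flags])
    a = np.concatenate(rows)
    b = np.concatenate(targets)
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    coeffs = coeffs + 1e-9 * rng.standard_normal(k)

    augmenting = cfg.augment_flips or cfg.augment_noise_sd > 0

    def evaluate(c: np.ndarray) -> float:
        pred = InverseDepthMap((design @ c).reshape(shape))
        preds = [pred] * len(dataset)
        if augmenting:
            preds, sups = _augmented_batch(dataset, preds, cfg, rng)
        else:
            sups = dataset
        total, _ = batch_loss(preds, sups, cfg.loss)
        return total

    step = cfg.step_size
    current = evaluate(coeffs)
    if not np.isfinite(current):
        raise DivergenceError("non-finite loss at initialisation", 0, step)
    best_c, best_loss = coeffs.copy(), current
    trajectory = [best_loss]
    h = 1e-6
    for it in range(1, cfg.max_steps + 1):
        grad = np.empty(k)
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            grad[j] = (evaluate(coeffs + e) - evaluate(coeffs - e)) / (2 * h)
        gnorm = float(np.linalg.norm(grad))
        if not np.isfinite(gnorm):
            raise DivergenceError(
                f"non-finite gradient at step {it}", it, step
            )
        if gnorm < 1e-14:
            trajectory.append(best_loss)
            break
        direction = grad / gnorm
        # backtracking halving line search from the decayed base step
        trial_step = step
        accepted = False
        for _ in range(12):
            cand = coeffs - trial_step * direction
            val = evaluate(cand)
            if np.isfinite(val) and val < current:
                coeffs, current = cand, val
                accepted = True
                break
            trial_step *= 0.5
        if not np.isfinite(current):
            raise DivergenceError(f"non-finite loss at step {it}", it, trial_step)
        if current < best_loss:
            best_loss, best_c = current, coeffs.copy()
        trajectory.append(best_loss)
        if not accepted and not augmenting:
            # no descent direction at any step length: converged
            break
        step *= cfg.step_decay
    return FitResult(
        params=PredictorParams(best_c, cfg.predictor_order),
        trajectory=trajectory,
        final_loss=best_loss,
    )


@dataclass(frozen=True)
class ArmResult:
    mask_kind: str
    recovery_error: float
    final_loss: float
    initial_loss: float
    diverged: bool = False


@dataclass(frozen=True)
class ExperimentReport:
    """Outcome of the uniform / hard / soft comparison."""

    arms: dict[str, ArmResult]
    win_margin: float  # uniform recovery error minus soft recovery error


def recovery_error(
    params: PredictorParams, truth: InverseDepthMap
) -> float:
    """Mean |predicted - true| inverse depth after affine alignment.

    The predictor is only identified up to scale/shift, so it is aligned
    to the clean truth by least squares before the comparison.
    """
    pred = predict_surface(params, *truth.shape)
    mask = ValidityMask(np.isfinite(truth.values))
    aff = align_lsq(pred, truth, mask)
    aligned = apply_affine(pred, aff)
    return float(np.mean(np.abs(aligned.values - truth.values)[mask.flags]))


def run_comparison(
    scene: SceneConfig,
    corr: CorruptionConfig,
    base: TrainConfig = TrainConfig(),
    n_images: int = 4,
) -> ExperimentReport:
    """Train uniform / hard / soft arms on one contaminated scene.

    All arms share the dataset (``n_images`` corrupted observations of a
    single truth surface, per-image corruption streams derived from the
    corruption seed) and the initialisation; they differ only in the
    weight function.  Recovery error is measured against the clean truth.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    truth = generate_truth(scene)
    dataset = []
    for idx in range(n_images):
        sub = int(np.random.SeedSequence([corr.seed, idx]).generate_state(1)[0] % (2**31))
        dataset.append(corrupt(truth, replace(corr, seed=sub)))

    arms: dict[str, ArmResult] = {}
    for kind in ("uniform", "hard", "soft"):
        wcfg = WeightConfig(
            mask_kind=kind,
            threshold=base.loss.weight.threshold,
            sharpness=base.loss.weight.sharpness,
        )
        cfg = replace(base, loss=replace(base.loss, weight=wcfg))
        try:
            result = fit(dataset, cfg)
            arms[kind] = ArmResult(
                mask_kind=kind,
                recovery_error=recovery_error(result.params, truth),
                final_loss=result.final_loss,
                initial_loss=result.trajectory[0],
            )
        except ConfdepthError:
            arms[kind] = ArmResult(
                mask_kind=kind,
                recovery_error=float("nan"),
                final_loss=float("nan"),
                initial_loss=float("nan"),
                diverged=True,
            )
    margin = arms["uniform"].recovery_error - arms["soft"].recovery_error
    return ExperimentReport(arms=arms, win_margin=float(margin))
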