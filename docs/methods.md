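# Methods

This note records the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## Setting and assumptions

A monocular predictor emits per-pixel inverse depth `d` defined only up
to an affine transform `s·d + t` with `s > 0`. Supervision comes from a
stereo matcher as a disparity map `d*` (also inverse-depth-like) plus a
confidence map `q ∈ [0, 1]`. The framework assumes:

- supervision error is *heteroscedastic and confidence-linked*: pixels
  with high `q` carry small, roughly Gaussian error; pixels with low `q`
  may carry gross, bounded-support outliers; `q = 0` pixels carry no
  estimate at all (left-border occlusion band of a rectified pair);
- the affine ambiguity is global per image (no spatially varying scale);
- depth is strictly positive wherever it is evaluated.

## The loss, precisely

Per image, with `M` = number of *valid* pixels (finite disparity and
`q > 0`):

1. **Alignment.** `(s, t)` solves the 2×2 normal equations of
   `min Σ (s·dᵢ + t − d*ᵢ)²` over the pixels that are valid *and* carry
   positive weight `w(qᵢ) > 0`. Restricting the fit to weighted pixels
   (rather than all valid pixels) is a deliberate design choice: it makes
   the masked losses *exactly* independent of whatever values sit at
   masked pixels, so the hard-mask objective coincides with training on
   the trusted subset. The fit itself is unweighted within that set.
2. **Data term.** `(1/2M) Σ w(qᵢ)(d̂ᵢ − d*ᵢ)²`. The denominator counts
   all valid pixels, not only weighted ones — masking a pixel removes its
   numerator contribution but does not renormalise the image.
3. **Gradient term.** Residual `R = d̂ − d*` is put through a `K`-level
   pyramid (resolution halved per level, ceil semantics). Weights are
   pooled by plain 2×2 averaging; residuals by *weight-weighted* block
   means (plain mean when the block weight is zero); a coarse cell is
   valid only if all four children are valid. Forward differences are
   accumulated where both participating pixels are valid with positive
   weight, each difference weighted by the mean of its two pixels'
   weights, summed over levels, divided by the full-resolution `M` once
   (no per-level renormalisation). The symmetric edge weight makes the
   term exactly invariant under horizontal/vertical flips applied
   consistently to prediction and supervision; the weighted residual
   pooling prevents masked outliers from leaking into coarse levels.
4. **Total.** `data + α·gradient` per image; a batch is the plain mean of
   per-image totals. Degenerate images (all masked, constant prediction,
   or fitted `s ≤ 0`) contribute zero with a logged warning and still
   count in the batch size, so one bad frame cannot poison a batch.

Defaults: `θ = 0.5`, `λ = 10`, `α = 0.5`, `K = 4`. `λ = 0` reduces the
soft mask to the hard mask identically, which the tests exploit as an
exact degeneracy check. Images smaller than `2^(K−1)` in a dimension get
a truncated pyramid with a warning rather than an error.

## Robust evaluation

Evaluation aligns prediction to reference in inverse-depth space with
IRLS using Tukey's biweight `w(u) = (1 − (u/c)²)²`, `|u| < c`, `c =
4.685`:

- residual scale: median absolute residual about **zero** divided by
  0.6745, recomputed each sweep; mean absolute residual as the zero-MAD
  fallback. Centring at zero rather than at the residual median matters:
  with an outlier-biased initial fit the median-centred MAD can collapse
  and zero every weight.
- initialisation from the closed-form least-squares fit; stop when the
  relative change of `(s, t)` drops below 1e-8 or after 50 sweeps.

Both maps are then converted to depth by reciprocal — pixels whose
aligned inverse depth falls at or below 1e-8 are dropped (and surface in
`pixels_evaluated`) — and scored with Abs. Rel. and the three δ
accuracies using strict `<`. Aggregation over a set is the unweighted
mean of per-image metrics, matching the per-image alignment convention.

The choice `c = 4.685` trades robustness against efficiency: the
`simulate_biweight_efficiency` experiment measures the variance ratio of
OLS to IRLS slopes over independent clean-Gaussian regressions and lands
near 0.95, the classical value for this constant; an aggressive constant
(c = 1) is visibly less efficient, a huge constant recovers OLS exactly.

## Synthetic supervision generator

The generator emulates the joint structure of matcher output on surgical
frames, so that the confidence–error link holds by construction:

- **truth**: a random polynomial surface (order 2 by default) over
  normalised coordinates, rescaled into inverse-depth range
  [0.25, 1.0] (arbitrary units; roughly 1–4 depth units);
- **occlusion band**: the leftmost columns (32 of 384 by default, ~8%)
  get `q = 0` and NaN disparity;
- **artefact blobs**: 6 random disks (radius 8–24 px at 384×192),
  emulating droplets/smoke, get confidence drawn from [0.05, 0.45] and
  disparity displaced by ±`outlier_magnitude`·U(0.5, 1.5) with
  `outlier_magnitude = 5` — several times the whole signal range, as
  matcher failures are;
- **everywhere else**: confidence from [0.7, 1.0] and Gaussian noise with
  sd 0.01 on the disparity.

Default frame geometry (384×192) mirrors a stereo-laparoscope test
split. No quantitative noise model for real matcher failures is
available, so the magnitudes are free parameters chosen once to make the
confidence-blind/confidence-aware contrast visible; the low/high
confidence intervals are kept disjoint around the θ = 0.5 threshold.
Per-image randomness derives from `(seed, image index)` so any image can
be regenerated independently.

What the generator does **not** emulate: photometric content, spatially
correlated inlier noise, confidence miscalibration (low-confidence pixels
that are actually fine and vice versa), and non-affine disparity
distortions. Passing tests therefore establish the mechanics of the loss
(exact masking, invariances, robust alignment) and the *direction* of the
training benefit under the assumed confidence–error link — not its
magnitude on real surgical data.

## Desk-scale trainer

The trainer fits a low-order 2-D polynomial surface (6 coefficients at
order 2) instead of a neural predictor: every claim made about the loss
is a statement about pixels and weights, not architecture, and a tiny
parametric predictor keeps the experiment seconds-long and fully
deterministic. Optimisation is finite-difference gradient descent with a
backtracking halving line search, base step 0.2 decayed by 0.95 per pass,
initialised from the unweighted least-squares fit of the surface to the
pooled valid supervision (identical across weight functions, which keeps
the hard/soft-λ=0 trajectories bit-for-bit equal). Best-seen parameters
are returned, so the loss trajectory is monotone non-increasing. Optional
augmentations (50% horizontal/vertical flips applied to supervision and
prediction together, Gaussian supervision noise) are off by default: they
add variance, not coverage, at this scale.

The comparison experiment trains three arms (uniform / hard / soft) on
`n_images` corrupted observations of a *single* truth surface — one truth,
several corruption draws — so the recovered surface is a well-posed common
estimand. Reported `recovery_error` is the mean absolute inverse-depth
error against the clean truth after affine alignment (the predictor is
only identified up to `(s, t)`). Problem sizes used by the test suite:
48×64 frames, 4 images, ≤150 optimisation passes, 5 scene seeds.

## Known limitations

- The closed-form alignment may return `s ≤ 0` on adversarial inputs;
  the loss treats such images as degenerate (zero contribution, logged)
  rather than constraining the solve.
- Whether Abs. Rel. should be computed in depth or disparity space after
  alignment is convention-dependent; depth space is the default here,
  and gross reference outliers therefore dominate image-wide Abs. Rel.
  through their reciprocal. The δ accuracies are the more interpretable
  summary under contamination.
- Absolute-scale recovery is out of scope: all outputs are relative.
- The IRLS stopping rule, scale estimator and initialisation are
  package choices (documented above), not properties of the biweight.
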