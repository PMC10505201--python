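# confdepth

Confidence-weighted scale-and-shift-invariant losses and robust evaluation
for self-supervised monocular depth estimation.

## The problem

Dense monocular depth predictors for surgical endoscopy are commonly
trained against *stereo self-supervision*: a stereo matcher run on the
left/right laparoscope images produces a per-pixel disparity map that
serves as an indirect ground truth. Two complications make this brittle:

1. **Affine ambiguity.** Monocular inverse depth (and stereo disparity)
   are only defined up to an unknown scale `s > 0` and shift `t`, which
   vary with camera, optics and working distance. Losses and metrics must
   therefore be *scale-shift invariant*.
2. **Contaminated supervision.** In vivo frames contain smoke, blood,
   droplets and occlusions. Where the matcher fails, it fails *grossly* —
   and modern matchers report exactly where, as a per-pixel confidence
   `q ∈ [0, 1]` (with `q = 0` on the unmatched left-border occlusion
   band).

`confdepth` implements the training loss that exploits this confidence
signal, the robust evaluation protocol, a synthetic supervision generator
with the same failure structure, and a small trainer that demonstrates the
robustness benefit end-to-end — all without any dataset download.

## The loss

For one image with `M` valid pixels, prediction `d`, supervisory
disparity `d*` and confidence `q`, the prediction is first aligned by
least squares,

    (s, t) = argmin Σᵢ (s·dᵢ + t − d*ᵢ)²,     d̂ᵢ = s·dᵢ + t,

and the loss is

    L = (1/2M) Σᵢ w(qᵢ) (d̂ᵢ − d*ᵢ)²
      + α · (1/M) Σₖ Σᵢ w(qᵢ) (|∇ₓRᵢᵏ| + |∇ᵧRᵢᵏ|),

where `Rᵏ = d̂ − d*` at pyramid level `k` (resolution halved per level,
`K = 4` levels) and the weight function is one of

    hard mask:    w(q) = 1[q ≥ θ]
    soft mask:    w(q) = exp(λ(q − 1)) · 1[q ≥ θ]
    uniform:      w(q) = 1        (confidence-blind baseline)

with defaults `θ = 0.5`, `λ = 10`, `α = 0.5`. Zero-weight pixels are
excluded from the internal alignment and from every pyramid level, so a
gross outlier at a masked pixel cannot move the loss at all.

For **evaluation**, predictions are aligned to the reference in
inverse-depth space by IRLS with the Tukey biweight
`w(u) = (1 − (u/c)²)²` at `c = 4.685` (≈95% Gaussian efficiency), then
scored in depth space with Abs. Rel. and δ-threshold accuracies
(`δ < 1.25, 1.25², 1.25³`, strict inequality).

## Worked example

Run the desk-scale comparison — three predictors trained on the same
contaminated synthetic supervision, differing only in the weight
function:

```bash
confdepth demo-train --out report.csv --seed 2
```

```
mask_kind  recovery_error  initial_loss  final_loss  diverged
  uniform        0.017258      2.485874    2.485623     False
     hard        0.000395      0.011970    0.011005     False
     soft        0.000325      0.003820    0.003527     False
win_margin (uniform - soft recovery error): 0.0169328
```

`recovery_error` is the mean absolute inverse-depth error against the
*clean* truth surface after affine alignment. The confidence-blind
(uniform) arm absorbs the gross outliers hiding in low-confidence blobs
and lands ~50× farther from the truth than the hard/soft confidence-
weighted arms; the soft mask, which up-weights the most trustworthy
pixels, edges out the hard mask.

Other entry points: `confdepth simulate` (generate a synthetic dataset:
PFM disparity/truth + 16-bit PNG confidence + CSV manifest),
`confdepth align` (closed-form or robust scale/shift fit),
`confdepth loss` (per-image loss breakdown), `confdepth evaluate`
(per-image and aggregate metrics CSV). The same functionality is
available as a library: see `confdepth.loss`, `confdepth.alignment`,
`confdepth.metrics`, `confdepth.synthetic`, `confdepth.trainer`.

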