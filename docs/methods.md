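# Methods

## Problem setting

Unpaired sequence-to-sequence translation between two visual domains `A`
and `B` (e.g. two cataract-surgery video datasets recorded with different
cameras and palettes).  Frame-wise image translators leave the temporal
dimension unconstrained, which produces flicker, disappearing instruments
and mode-collapsed static output when applied to video.  This package
implements a translator with explicit spatio-temporal constraints, the
evaluation metrics to quantify temporal consistency, and a synthetic
two-domain video generator that provides exact optical-flow and
foreground-mask ground truth for testing.

## Model

### Shared-latent backbone

Per-domain encoders `E_A`, `E_B` and decoders `G_A`, `G_B` form a VAE-GAN
whose innermost residual blocks are shared between domains, so
corresponding content maps to a common Gaussian latent (the shared-latent
assumption).  Cross-domain translation is `f_B(a) = G_B(E_A(a))` and
symmetrically for `f_A`.  Multi-scale patch discriminators `D_A`, `D_B`
score realism per domain with the least-squares adversarial objective.
The backbone loss combines, per domain: an adversarial term (weights
`λ0 = λ5 = 10`), a KL penalty toward the unit Gaussian on latent means
(`λ1 = λ3 = 0.1`) and L1 reconstruction plus cycle-reconstruction through
the other domain (`λ2 = λ4 = 100`).  The adversarial form (least squares)
and the λ-to-term assignment follow the standard shared-latent translation
recipe; both are exposed in configuration.

### Motion translation

For consecutive source frames `a_t, a_{t+1}` with source optical flow
`F_A` (an input: exact flow for synthetic scenes, a classical or learned
estimator otherwise), a U-Net `M_AB` maps the 11-channel stack
`(a_t, a_{t+1}, sg(b̂_t), F_A)` — where `b̂_t = f_B(a_t)` and `sg` is the
stop-gradient — to a 2-channel backward-convention flow field `F̂_B` for
the target domain.  `M_AB` and `M_BA` are independent modules.  Two losses
ride on the translated flow:

* motion cycle: `L_MT = δ_MT · ‖ sg(b̂_{t+1}) − f̃(b̂_t, F̂_B) ‖₁`, with
  `f̃` the bilinear backward warp and `δ_MT = 10`;
* structural consistency:
  `L_MS-SSIM = −δ_SSIM · MS-SSIM(b̂_t, sg(f̃(b̂_t, F̂_B)))`, `δ_SSIM = 10`.

Gradient routing: the successor frame `b̂_{t+1}` and the MT-module input
`b̂_t` are always gradient-stopped, so generators and MT modules train
jointly in a single optimisation step.  The warped frame inside `L_MT` is
*not* stopped by default (`mt_routing="flow_and_frame"`): the motion-cycle
term then constrains the generator to produce motion-consistent
consecutive translations as well as teaching the MT module.  The
alternative reading, in which the warped frame is also stopped and the
motion-cycle term updates only the MT module, is available as
`mt_routing="flow_only"`; in desk-scale experiments it leaves the
generator without a usable temporal signal (the structural term is nearly
saturated early in training), and the consistency advantage over the
ablation disappears.

### Flow conventions

Grids are row-major with the origin top-left, `x` = column, `y` = row;
flow channels are `(dx, dy)` in pixels.  A *forward* field holds the
displacement of content from frame `t` to `t+1`; warping uses *backward*
fields, where `out(p) = frame(p + flow(p))` via bilinear sampling with
border clamping.  Negating a forward field yields the backward field that
predicts frame `t+1` from frame `t`; this is exact for rigid motion away
from occlusion boundaries and is the direction used by the motion-cycle
loss and the warping-error metric.  The MT modules output backward fields
directly (the convention is self-consistent for a learned module).  Pixel
centres sit at integer coordinates, making zero-flow warping bit-exact.

## Training schedule

Adam (`β = (0.5, 0.999)`), L2 weight decay `1e-4` on all parameter groups,
learning rate `2e-4` held for the first half of training and decayed
linearly to zero afterwards (default: constant to epoch 100, zero at
epoch 200).  Batch size defaults to 8 at 192×192 for full-scale runs;
desk-scale experiments use batch 1 at 64×64.  Each step performs one
discriminator update on real vs. freshly translated frames, then one
joint generator+MT update.  All parameters are Xavier-initialised from a
seed; the MT-module output head starts at zero so the predicted flow is
exactly zero at initialisation (a stable warm start in which both
temporal terms sit at their fixed points).  Every source of randomness
(initialisation, latent noise, batch order) flows from the config seed,
making checkpoints bit-reproducible and training resumable.

## Evaluation metrics

* **Mask temporal consistency** — over all ordered frame pairs `t ≠ t'`:
  `M_TC^d = 1/(T(T−1)) Σ d(|fg(a_t) − fg(a_{t'})|, |fg(b̂_t) − fg(b̂_{t'})|)`
  with `d` = RMSE (lower better) or single-scale SSIM (higher better).
  The `t = t'` diagonal compares two all-zero images and is excluded; with
  the printed normalisation the SSIM variant is exactly 1 for a perfectly
  consistent translation.  Foreground masks come from an oracle (synthetic
  data) or temporal-median background subtraction (threshold 0.1 on
  grayscale deviation, one binary opening).
* **tOF** — mean absolute difference between estimated flow fields of the
  source and translated sequences.
* **tLP** — mean absolute difference of consecutive-frame perceptual
  distances; the default embedder is a seeded random-projection CNN
  (three fixed random conv/ReLU/pool stages, mean+std pooling) and any
  trained perceptual embedder can be plugged in through the same
  protocol.
* **Warping error** — mean absolute error of flow-warped frame
  predictions in the target domain, restricted to validity masks where
  available.
* **FID / KID / diversity** — Fréchet distance between Gaussian fits
  (symmetric matrix square root, `εI` regularisation at `ε = 1e-6` for
  near-singular covariances), unbiased squared MMD with the cubic
  polynomial kernel `(x·y/d + 1)³` over seeded subsets (the cross-term
  diagonal is excluded, keeping the estimator unbiased for independent
  sets and exactly zero for identical ones), and mean pairwise embedder
  distance over seeded random frame pairs.

## Synthetic data

The generator emulates the shared-content / distinct-style structure of
two surgical video datasets: a static circular iris/pupil-like background
whose palette, radial gradient and noise texture define the domain style,
plus 1–2 rigid elongated tool sprites (rectangle or capsule) translating
with known per-frame velocities.  Sprites are rasterised on the integer
pixel grid and the emitted forward/backward flows are the rasterised
displacements, so warping closures are exact on the accompanying validity
mask (the XOR band of consecutive footprints marks occlusion and
disocclusion).  Masks are exactly binary (no anti-aliasing).  Controlled
corruptions emulate the failure modes the metrics must detect:
`drop_tool` (disappearing instruments), `flicker` (per-frame style
jitter) and `static_collapse` (mode collapse onto the first frame).

What this does *not* emulate: camera motion, deformable instruments,
specular highlights, photometric drift and compression artifacts of real
surgical video.  Passing the synthetic batteries therefore shows the
operators and metrics are implemented correctly and respond in the right
direction, not that translation quality transfers to real recordings.

## Desk-scale study conditions

The end-to-end direction check trains the full model and its
`δ_MT = δ_SSIM = 0` ablation on 64×64 scenes — 200 consecutive-frame
pairs per domain (20 scenes of 11 frames), 300 steps, batch 1, oracle
source flow, base width 8 everywhere — and compares mean tOF (iLK
estimator) on six held-out sequences per seed, for three seeds.  These
sizes were chosen once for single-CPU runtimes; training is far from
convergence there, so the check asserts only the *sign* of the
MT-vs-ablation difference on a majority of seeds, never magnitudes.

## Numerical choices

* All network code runs on an `autograd`-based reverse-mode engine over
  numpy (float32), with custom gradients for convolution (im2col matmul
  forward, transposed-convolution backward), separable Gaussian blur,
  bilinear warping, instance normalisation and leaky ReLU.  Gradients of
  every custom operator are verified against central finite differences
  in the test suite.
* MS-SSIM uses the canonical five-scale exponent weights, an 11-pixel
  Gaussian window (σ = 1.5) and valid-mode convolution; the scale count
  is capped by image size (weights renormalised) and requesting more
  scales than feasible is an error that names the maximum.  Contrast
  terms are clamped at `1e-8` before exponentiation.  `MS-SSIM(x, x)` is
  exactly 1.
* Bilinear warping clamps sample coordinates to the image border; flow
  gradients vanish where the clamp is active.
* The discriminator and generator losses are averaged per element, so
  loss magnitudes are resolution-independent.
* Middlebury `.flo` I/O is exact at 32-bit precision.

## Known limitations

* The classical flow estimator (iLK/TV-L1 via scikit-image) is adequate
  for rigid synthetic motion but far weaker than learned estimators on
  real video; the estimator interface accepts an external backend.
* The published full-scale setting (192×192, batch 8, 200 epochs) is
  supported by the same code paths but is not exercised by the test
  suite, which runs at 32–64 px.
* Mask temporal consistency is reported as the normalised per-sequence
  value in `[−1, 1]` (SSIM variant); published tables built on other
  aggregations of the same quantity are not directly comparable.
* The temporal-median foreground extractor assumes each pixel is
  background for most of the sequence; slow, large instruments violate
  this and need the oracle or an external segmenter.
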