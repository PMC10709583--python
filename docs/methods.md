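# Methods

## Problem and pipeline

A single-slice cine CMR acquisition images the ascending (AAo) and
descending (DAo) thoracic aorta perpendicular to the vessel at the level
of the pulmonary artery bifurcation, reconstructing 30–40 phases of one
cardiac cycle (typical matrix 256×186–256, in-plane pixel 1.1–1.9 mm).
The pipeline segments both lumens in every frame, converts the label maps
to per-frame cross-sectional areas `A(t) = n_pixels(t) · row_mm · col_mm`,
and computes the aortic distensibility

    AD = (A_max − A_min) / (A_min · PP)   [mmHg⁻¹],

with `A_max`, `A_min` the frame-wise extrema over the cycle and `PP` the
brachial pulse pressure.  `A_max`/`A_min` are taken as raw extrema with no
temporal smoothing: the predicted extrema need not coincide with the
nominal systolic/diastolic phases, and the formula uses them regardless.
An optional cyclic moving-average smoother exists on `AreaCurve` but is
off by default.

## Segmentation network

A time-distributed U-Net over the frame sequence:

* **Encoder** — four steps of two 3×3 convolutions with ReLU, batch
  normalisation, and 2×2 max-pooling; dropout (0.5) before the BN layer in
  the last two steps; filter widths `[16, 32, 64, 128, 256]`.
* **Bottleneck** — a densely connected convolutional block: internal
  layer *i* is a pair of 3×3 convolutions whose input is the channel
  concatenation of the block input and all *i−1* previous layer outputs
  (1 layer by default; 3 in the unpruned variant).
* **Decoder** — four steps of nearest-neighbour 2× up-sampling followed by
  a 2×2 convolution ("up-conv"), a skip merge, and two 3×3 convolutions
  with ReLU; the final decode step has five convolutions, the last one
  mapping to a single channel with a sigmoid.
* **BConvLSTM skip merge** — at decoder level 2 (the second up-sampling
  step) the up-sampled features and the encoder skip are stacked
  channel-wise per frame and fed, over the cine's T frames, to a
  bidirectional ConvLSTM with zero initial states.  Gate equations per
  direction:

      I_t = σ(W_xi∗X_t + W_hi∗H_{t−1} + b_i)
      F_t = σ(W_xf∗X_t + W_hf∗H_{t−1} + b_f)
      C_t = F_t ∘ C_{t−1} + I_t ∘ tanh(W_xc∗X_t + W_hc∗H_{t−1} + b_c)
      O_t = σ(W_xo∗X_t + W_ho∗H_{t−1} + b_o)
      H_t = O_t ∘ tanh(C_t)

  and the full output sequence `Y_t = tanh(W_f∗H→_t + W_b∗H←_t) + b` is
  returned (one map per frame, not just the last step).  All other levels
  merge by plain channel concatenation.

Configuration toggles express the unpruned ancestor and the ablations:
`filter_multiplier=4` (4× filters), `dense_blocks_final_encode=3`,
`bconvlstm_levels={1,2,3}`, `merge_mode="concat"` (no non-linear merge),
and `loss_kind="dice"` (no focal Tversky).

Design choices where the architecture description left room:

* **Single-channel head + component labelling.**  The decoder ends in one
  sigmoid channel ("aorta vs background").  AAo/DAo separation happens
  after thresholding (default 0.5): connected components of the
  temporal-mean binary map give two persistent footprints, per-frame
  components are assigned to the footprint they overlap most, and the
  footprint with the larger mean area is labelled AAo (AAo cross-sections
  exceed DAo cross-sections in this imaging plane).  Fewer than two
  footprints produces a warning and a single-vessel labelling.
* **Up-sampling interpolant**: nearest-neighbour before the 2×2
  convolution.
* **Even-kernel padding**: 2×2 convolutions pad one row/column at the
  bottom/right ("same" output size).
* **BatchNorm inference** uses running statistics accumulated during
  training (EMA momentum 0.9).
* **Initial recurrent states**: zeros in both directions.

## Loss

Focal Tversky loss `(1 − TI)^γ` with

    TI = (Σ p₀g₀ + ε) / (Σ p₀g₀ + α Σ p₀g₁ + β Σ p₁g₀ + ε),

α = β = 0.8 (deliberately not the α+β = 1 convention), γ = 1, ε = 10⁻⁶.
The smoothing ε is an implementation addition: it makes the empty-mask
case well defined (both empty → TI = 1, loss 0).  The loss is reduced at
sequence level — all T×H×W pixels of one study jointly, matching the
end-to-end (whole-cycle) learning — and averaged over the sequences of a
batch.  `dice_loss` (1 − soft Dice) is the ablation alternative and equals
the Tversky loss at α = β = 0.5, γ = 1 on binary inputs.

## Training protocol

Reference protocol: random patient-level split 272/68/84 of 424 studies
(largest-remainder apportionment reproduces those sizes exactly), Adam at
constant lr 0.001 for 250 epochs, batch ≈120 frames (≈4 sequences at
30–40 phases — batching is implemented per sequence, with the equivalent
frames-per-batch logged), He-normal initialisation, dropout 0.5, online
augmentation drawing one rotation in [−30°, +30°] and one integer
translation in [−20, +20] px per axis per sample, independently
(bilinear for images, nearest-neighbour for masks, zero fill).  Model
selection is the best validation Dice at threshold 0.5 — "validation
accuracy" made concrete.

**Desk preset** (the scale used by the test suite and the reproduction
script): 64×64 grid, T = 12, filter widths `[4, 8, 16, 32, 64]`, batch of
4 sequences, 60 epochs, translations capped at 5 px (scaled to the
smaller grid).  60 epochs was chosen because on 20-phantom cohorts the
validation Dice is still climbing at 20 epochs and plateaus around 50–60
— the protocol trains to plateau.  A desk run takes ~5 minutes on one CPU
core.

## The autodiff engine

The network runs on a small reverse-mode automatic-differentiation engine
over numpy arrays (`aortacine.nn.engine`) implementing exactly the
operations the architecture needs (convolution via im2col/matmul,
pooling, up-sampling, batch norm, dropout, the elementwise gates, and the
structural ops that unroll sequences over time).  Gradients of every
primitive are verified against finite differences in the test suite.
Dtypes follow the inputs: training uses float32 parameters for speed; the
closed-form unit checks build float64 graphs and match hand arithmetic to
1e−12.  With a single CPU core a desk-scale batch (4 sequences × 12
frames at 64×64) takes ~2 s forward+backward.

## Synthetic phantoms

The generator emulates the statistical structure of the clinical inputs,
not their anatomy or MR physics:

* two bright elliptical lumens on a darker, smoothly modulated
  thorax-like background; intra-lumen brightness heterogeneity (a smooth
  sinusoidal field, amplitude 0.15 of the lumen intensity) stands in for
  flow-related signal variation; additive Gaussian noise (σ 0.01–0.04 of
  the intensity range across the cohort);
* baseline areas sampled lognormally (σ = 0.18, clipped at ±2σ) around
  the cohort means 679 mm² (AAo) and 371 mm² (DAo), random aspect ratio
  (0.72–0.95), orientation, and small centre jitter;
* both semi-axes scale by `1 + δ·p(t)` with an asymmetric raised-sine
  profile `p(t)` (fast systolic upstroke over 35% of the cycle, slower
  diastolic decay) and a small DAo phase delay; the radius pulsatility δ
  is drawn from 0.05–0.15, spanning distensibilities ≈2–7×10⁻³ mmHg⁻¹ at
  the cohort pulse pressure of 48 ± 10 mmHg (from systolic 127 /
  diastolic 79 mmHg means);
* the default 64×64 grid uses a 2.5 mm pixel so real-world areas are
  preserved at desk scale; draws whose maximal-dilation footprint would
  exceed 5% of the grid (or whose vessels would touch) are rejected and
  resampled, keeping the severe class-imbalance regime the focal Tversky
  loss targets.

Ground truth is exact: rasterized label maps (pixel-centre test of the
ellipse inequality), analytic area curves `π a(t) b(t) · mm²/px`, and the
AD implied by the stored extrema and PP.

**What passing tests do and do not show.**  Phantom experiments validate
the mechanics of the pipeline — that the architecture can learn
spatiotemporal boundaries under class imbalance, and that areas and AD
are recovered end to end — but bright ellipses with smooth backgrounds
are far easier than clinical SSFP images (no surrounding structures with
similar intensity, no flow voids or banding, no shape pathology), so
phantom Dice values do not predict clinical performance.

Rasterization bounds the agreement between mask-derived and analytic
areas: |A_pix − A_true| ≤ perimeter·(pixel diagonal)/2.  Propagated
through the AD formula this band is wide at 64² (the per-frame area swing
is a few pixels), which is why AD accuracy is always assessed against the
ground-truth *masks* (as a clinical study is assessed against the expert
reader), while the analytic truth is used for convergence checks: the
mask-vs-analytic AD error strictly decreases from 64² to 128² grids.

## Evaluation statistics

* **Dice** over the full T×H×W stack per vessel; both-empty = 1,
  empty-vs-nonempty = 0.
* **Absolute area error**: mean over frames of |A_pred(t) − A_true(t)|.
* **Bland-Altman**: bias = mean difference, limits of agreement
  bias ± 1.96 · sample SD; computed for A_max, A_min and AD, pooling both
  vessels.
* **Curve distances** between predicted and reference time-area curves as
  (frame index, area mm²) point sequences with no axis rescaling
  (configurable): discrete Fréchet (coupling minimax), symmetric
  Hausdorff (set-level max-min; computed via scipy's directed routine),
  and DTW (symmetric step pattern, no window, unnormalized total cost).
  All three are validated against exhaustive path/coupling enumeration on
  short sequences; Fréchet ≥ Hausdorff holds on every pair.
* **Wilcoxon signed-rank**, two-sided, zeros dropped, mid-ranks for ties;
  exact null distribution for ≤25 non-zero pairs (validated against 2ⁿ
  sign-pattern enumeration), normal approximation with continuity
  correction otherwise; Bonferroni adjustment `min(1, m·p)` with m = 6 by
  default (the six metric columns of a typical comparison table).

## I/O conventions

NIfTI volumes (time on the last axis; pulse pressure, study id and pad
offsets in a `.meta.json` sidecar), DICOM series (frames ordered by
trigger time when present, else instance number), and lossless frame
stacks (TIFF for float data, PNG accepted for integers) with a `meta.json`
sidecar.  Studies are zero-padded to the 256×256 network grid (any
multiple of 16 works), content centred with ties toward the top-left and
the placement recorded so cropping inverts it exactly; intensities are
min-max normalised to [0, 1] per study (constant studies map to zero) —
chosen for scanner-agnostic behaviour across multi-vendor inputs.
Coordinates are row-major and 0-based throughout; areas never depend on
the convention.

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` run the desk preset: 20
phantom studies (64×64, T = 12) split 13/3/4, 60 epochs, ~5 minutes on
one CPU core.  Held-out performance at seed 1: mean Dice ≈0.98 (AAo) and
≈0.96 (DAo), mean relative AD error ≈10% per vessel.

## Known limitations

* No MR physics (SSFP banding, flow artefacts) or anatomical context in
  the phantoms; no multi-slice support (single plane only); no isotropic
  resampling or DICOM de-identification.
* The AAo/DAo assignment by component area fails if the vessels'
  footprints merge at the threshold or if the DAo appears larger than the
  AAo (a two-channel head is available as a non-default configuration).
* The engine is CPU-only and single-device; the full clinical protocol
  (256×256, T = 30–40, 250 epochs, 424 studies) is expressible but slow
  without hardware acceleration.
* Energy/carbon accounting is exposed only as an optional training hook
  (`--track-energy`) and nothing in the package asserts on its output.
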