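# Methods

## The segmentation model

FlyNet 2.0+ is a U-shaped encoder–decoder over video clips. Input is a
`(T, 128, 128)` clip (default `T = 32`), normalized to zero mean and
unit standard deviation per video; output is a per-pixel heart
probability for every frame.

Encoder block *i* (of `n_levels = 4`, filters `16·2^i`):

```
temporal conv -> batch norm -> per-frame 3x3 conv -> batch norm
              -> leaky ReLU (slope 0.2) -> 2x2 max pool
```

where *temporal conv* is a forward-in-time convolutional LSTM for the
first `n_spatiotemporal = 2` blocks and a plain per-frame 3×3
convolution afterwards. The skip connection is taken before pooling.
Decoder blocks mirror this with a stride-2 2×2 transposed convolution,
skip concatenation, conv, batch norm, leaky ReLU — no pooling and no
recurrence, so they run on all frames in parallel. A 1×1 convolution
and sigmoid produce the output. The same builder with
`n_spatiotemporal = 0` yields the purely spatial network used for
coarse heart localization.

The ConvLSTM computes its four gates as one 3×3 convolution of
`concat(x_t, h_{t-1})`; the forget-gate bias starts at 1. Recurrence is
forward-only — segmentation of frame *t* may use frames before it, not
after.

Filter counts, depth, kernel size, leaky slope and the Dice smoothing
constant are exposed in `ModelConfig`; the defaults are sized for
desk-scale training and can be raised on better hardware.

### Loss

`log_cosh_dice_loss` pools all frames of a sample's sequence into one
Dice coefficient

```
Dice = (2 Σ p·t + ε) / (Σ p + Σ t + ε),   ε = 1 by default
```

and returns `ln cosh(1 − Dice)` averaged over the batch. The loss is
zero iff Dice is 1 (at ε = 0) and monotone decreasing in Dice;
sequence-level pooling matches sequence-level optimization, and the
smoothing keeps empty-vs-empty well defined. The analytic gradient is
propagated directly into the network.

### Numerical engine

All layers (conv via im2col/GEMM, ConvLSTM with backpropagation through
time, batch norm, max pool with first-element tie-breaking, transposed
conv, sigmoid) carry hand-written backward passes on numpy, float32 by
default. Correctness is established by central-difference gradient
checks of every layer and of the whole network through the loss in
float64 (worst relative error ~1e-6). Adam follows the standard
bias-corrected update. One seed controls weight initialization; a
separate training seed controls the data split, batch order and crop
augmentation. Bitwise reproducibility of training holds on a fixed
BLAS; it is not promised across numerical backends.

### Training procedure

Training samples are full-size video+mask pairs. Per epoch, every
`seq_len`-frame sequence receives a fresh crop: the bounding box of the
mask union over the clip, dilated by `margin` (4 px), squared by
padding the short side (shifting inward at frame edges), then shifted
by a uniform integer jitter capped at the margin — so the heart is
guaranteed inside every augmented crop. Images are resized bilinearly,
masks by nearest neighbour, and each clip is normalized. Adam runs at
lr 0.001. The 80/10/10 sample split is applied when no explicit
validation set is given.

The coarse localizer trains on whole frames resized
(aspect-distorted) to its input size, without cropping, for a short
schedule — its contract is only a bounding box.

## Inference cascade

`segment_video` chains: coarse localization (downsample → predict →
upsample → threshold 0.5 → squared bounding box with margin 8 over the
foreground union of all frames) → crop/resize → normalization → fine
segmentation in `seq_len` chunks (short tails padded by repeating the
last frame and trimmed after) → per-frame cleanup → inverse mapping to
full size (bilinear resize of the binary mask to the box extent,
re-threshold at 0.5, paste). One crop box serves the whole video,
matching the dataset's single `resize_parameters.txt` per sample.
Cleanup keeps the largest 4-connected component and fills enclosed
holes, with no temporal smoothing: corrections are purely spatial, and
a temporal filter would risk smearing genuine fast systolic motion.

## Cardiac analysis

Heart area per frame is the mask pixel count times the pixel area from
the calibration (defaults 3.3 µm axial × 2.3 µm lateral at 125 fps —
documentation defaults; calibrate per system). Beat detection smooths
the trace with a moving average (~0.1 s window, odd length) and takes
local maxima with prominence ≥ 20% of the trace range and separation ≥
one beat period at a 12 Hz ceiling as end-diastoles; the minimum
*on the raw trace* between consecutive diastoles is end-systole (the
smoothed trace would shallow out the brief systolic dip at high heart
rates). When the first pass finds beats shorter than four smoothing
windows, detection runs a second pass with the window shrunk to a
quarter of the measured beat interval — at 5–6 Hz a beat spans only
~21 frames, and a 0.1 s window would otherwise erase the diastolic
plateau entirely. Diastolic holds appear as plateaus; beat intervals
are measured between sub-frame plateau midpoints, which reduces the
frame-quantization error of fast rhythms, and a plateau longer than
twice the median plateau is treated as a heart stop and yields no
beat.
Boundary beats cannot form interior maxima, so an N-beat recording
yields about N − 2 measurable intervals.

Derived parameters: per-beat HR = 1/interval with the median reported;
EDA/ESA as the median area over diastolic/systolic frames (medians
resist occasional missed or spurious events), with equivalent diameters
`2·sqrt(A/π)` also reported since the field often quotes EDD/ESD;
FS = 100·(EDA − ESA)/EDA — the end-diastolic denominator is the field
convention; AI = sd(per-beat HR)/median(per-beat HR) with the sample
(n−1) standard deviation by default and the population flavour as an
option. Both-empty frames score IOU 1 by convention and are flagged so
callers can exclude them.

## The phantom generator

The phantom emulates the statistical structure of OCM heart videos: an
elliptical lumen (the ground-truth "heart region" is the lumen only —
a deliberate, documented convention) inside a bright wall annulus, a
speckled background, exponential depth attenuation, and a beat-driven
area modulation. Beat intervals are `1/rate · (1 + jitter)` with
jitter ~ Normal(0, cv) truncated at ±3σ; pause windows exclude beats
and hold the area at the diastolic level; pacing segments override the
base rate. Each beat's contraction is a raised cosine occupying 40% of
the interval, dipping from relative area 1 to `systolic_fraction` —
smooth, band-limited, and analytically integrable where the real
traces are only empirical. Both semi-axes scale by the square root of
the relative area so lumen area tracks the waveform exactly up to
pixelation. Speckle is multiplicative exponential noise (a first-order
approximation of fully developed coherent speckle) blended by
`speckle_scale`, followed by a Gaussian blur. One master seed drives
all randomness. Full-size samples embed the 128×128 phantom at a
random depth offset in a 600×128 frame and record the box in
`resize_parameters.txt` convention, so phantoms are drop-in dataset
samples.

True parameters accompany every phantom: FS truth is
`100·(1 − systolic_fraction)` by construction; HR and AI truth are
computed from the realized beat schedule (excluding pause-spanning
intervals).

What the phantom does *not* model: wave-optics of OCT image formation,
3-D heart-tube geometry, larval body-motion artifacts, occlusions, and
stage-dependent anatomy. Passing the phantom suite therefore
demonstrates that the pipeline's geometry, training loop and analysis
are correct and self-consistent — not that any particular accuracy
carries over to real recordings, which have harder appearance
variation.

## Study conditions for tests and the acceptance script

Training runs use a deliberately small problem so a full train fits on
one CPU core: model space 64×64, 8-frame sequences, 8 base filters,
4 levels (2 spatiotemporal); six noiseless training phantoms of
32 frames (96×96 heart region embedded in 140×96 frames, 25 fps,
2.5 Hz, systolic fractions 0.4–0.6), 15 epochs, plus two held-out
phantoms. Parameter-recovery phantoms use the full 125 fps timing:
1000–2000 frames, rates 1–6 Hz, systolic fractions 0.3–0.8, zero beat
jitter for the HR/FS bands, and jitter CVs {0, 0.15, 0.3} across five
seeds for the arrhythmia-index monotonicity check. The coarse
localizer trains for 5 epochs. These sizes are the package's reference
conditions; they are not tuned per run.

## Known limitations

- Training throughput is CPU-bound and far below a GPU implementation;
  the architecture defaults here are correspondingly small.
- The beat detector assumes a dominant single rhythm; heavily
  arrhythmic traces bias the plateau-based pause heuristic.
- The reader accepts any full-frame height (published materials are
  inconsistent between 600 and 701 rows); the validator reports actual
  shapes rather than enforcing one.
- Mask auto-detection treats an all-zero stack as a mask; callers can
  override by declaring the kind explicitly.
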