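# Methods

## Problem and model

Remote photoplethysmography (rPPG) estimates the cardiac pulse from the tiny
periodic color changes that blood volume induces in facial skin.  The heart
rate is the dominant frequency of the blood-volume-pulse (BVP) waveform,
physiologically confined to 0.8–4.0 Hz (48–240 bpm).  The package implements
MDAR, a dual-branch convolutional network that regresses the per-frame BVP
waveform from video chunks and reads the heart rate off the waveform's power
spectrum.

**Dual branches.**  The *static* branch (stages r1–r5, 3×3 convolutions with
tanh activations, 2×2 average pooling after stages 2 and 4) extracts
time-independent appearance features — where the skin is and how it reflects
light.  Because those features are stable over a chunk by definition, the
branch runs on the chunk's temporal-mean frame, in the spirit of
appearance-averaging in multi-task temporal-shift rPPG networks; this also
removes per-frame redundancy.  The *dynamic* branch (stages d1–d6) sees
diff-normalized frames and carries all temporal information.

**Alternating time shift (ATSM).**  Before the convolutions of dynamic
stages 1–4, channel segments are shifted along time: a fraction α₁ of the
channels one frame backward (`out[t] = in[t+1]`), α₁ one frame forward, α₂
two frames backward and α₂ two frames forward; the rest are untouched, and
vacated frames are zero-filled (no wrap-around).  Segment sizes use
`floor(α·C)` with the remainder assigned to the unchanged segment, since the
tuned fractions (α₁ = 1/4, α₂ = 1/12) rarely divide the channel count.  With
α₂ = 0 the operator reduces exactly to the classic single-frame temporal
shift (TSM).  Note that at stage 1 the input has only three channels, so
`floor(α·3) = 0` and that shift is an identity; the temporal receptive field
is built up by the stage-2–4 shifts (verified by a perturbation test).

**Dynamic–static feature fusion (DSFFM).**  At stages 2 and 5 the static
features gate the dynamic ones: `g = SiLU(conv1×1(r_n))`, normalized by its
per-sample mean magnitude (a single scalar per chunk, making the gate O(1)),
then `out = a ⊙ d_n · β` with β = 0.2 (the value that minimized validation
error in the original tuning).  The gate depends only on the static branch,
so the fusion is exactly linear in the dynamic features and in β — both are
tested invariants.  The fused product replaces the dynamic feature map
feeding the next stage; the static branch continues unfused.  Whether the
normalizing "one-dimensional value" is per-sample, per-channel or global is
an open design point; per-sample is implemented.

**Multiscale fusion and head.**  The dynamic stage outputs d2 (shallow, full
resolution), d5 and d6 (deep, quarter resolution) are merged: d2 and d5 are
bilinearly interpolated to twice d6's spatial size, 2×2 average-pooled down
to d6's size, and concatenated along channels.  A spatial average, dropout
(0.25 after fusion, 0.5 before the head) and a single dense layer produce
one waveform value per frame.

## Training

Waveform regression with mean squared error on diff-normalized labels
(negative Pearson correlation is a config alternative).  Optimizer: AdamW
(decoupled weight decay) with a one-cycle cosine schedule peaking at the
configured rate — the toolbox convention in this model family.  Defaults:
batch 4, 30 epochs, peak lr 0.01, weight decay 9e-3, gradient-norm clipping
at 1.0 to stabilize the small-batch regime.  Data are split 80/20 into
training and validation *by clip*, never by chunk, so no clip leaks across
the split; the best-validation-loss parameters are restored after training.

The network and optimizer are implemented on a small reverse-mode autodiff
core written for this package (numpy + numba); the 3×3 convolutions are
direct numba kernels over a channel-first layout, and every operator's
gradient is checked against finite differences or a float64 closed form in
the test suite.  Training is deterministic for a fixed seed on a fixed
numeric backend (single-threaded float32).

## Preprocessing

* Static input: per-chunk, per-channel standardization `(x − µ)/(σ + ε)`.
* Dynamic input: `d(t) = (x(t+1) − x(t)) / (x(t+1) + x(t) + ε)`, scaled by
  its global standard deviation, final frame zero-padded.  The ratio form
  cancels multiplicative illumination gain exactly (tested to 1e-6).
* Labels: first difference of the BVP, std-scaled, zero-padded — matching
  the dynamic input convention (raw labels are a config switch).
* Chunking: non-overlapping fixed-length windows (default 180 frames);
  trailing remainders are dropped.  ε = 1e-7 everywhere.
* Resizing uses separable bilinear interpolation matrices (half-pixel
  centers), default target 72×72, 36×36 for the half-width configuration.

Chunk length, input resolution and label convention are not pinned by the
architecture; all three are exposed in `PreprocessConfig`.

## Synthetic data

The generator stands in for real facial video so the whole pipeline is
testable without datasets.  One clip is: a skin-toned frame
(base RGB (0.78, 0.60, 0.50)) with a centered ellipse covering ~60% of the
frame as the "face"; inside it the BVP modulates the pixel values with
chromatic weights 0.5/1.0/0.3 (R/G/B; green strongest, as in real rPPG) at
amplitude 0.05; plus iid Gaussian pixel noise (σ = 0.02), a slow sinusoidal
illumination drift (amplitude 0.05 at 0.05–0.2 Hz, below the heart-rate band
so bandpassing can reject it), and an integer-pixel random-walk translation
reflected at ±1 px.  The BVP is a unit-variance sinusoid at the target rate
plus a 0.3-weight second harmonic (the skewed systolic shape of real PPG).
Defaults: 30 fps, 6 s clips (one standard 180-frame chunk), heart rates
uniform in 60–120 bpm.  Every output is a pure function of (config, seed).

What the generator does **not** emulate: real facial texture and its motion,
3-D head pose, specular highlights, sensor compression artifacts, skin-tone
population variation, or non-stationary heart rates.  Passing tests
therefore demonstrate that the architecture, optimization and spectral
read-out work as specified — not that the model reaches any particular
accuracy on real subjects.

## Heart-rate read-out and metrics

Heart rate = 60 × the argmax frequency of a Hann-windowed periodogram of the
predicted waveform, zero-padded to ≥2048 bins for sub-bpm peak resolution,
restricted to 0.8–4.0 Hz.  Per clip, chunk predictions are stitched in order
and one rate is estimated from the whole stitched waveform.  Accuracy is
MAE = mean |ŷ − y| (bpm) and MAPE = 100 · mean |ŷ − y|/y (%).

The improvement table reports `100 · (other − mdar)/other` per train/test
combination and per-method means over the four combinations, recomputed
unrounded from the packaged published benchmark errors.  Comparisons with
the published one-decimal cells use a ±0.2-point band (the published cells
mix rounding and truncation and were evidently computed from unrounded
internal metrics); the per-method means are compared at ±0.1.  One published
cell is internally inconsistent with its benchmark values (PhysNet,
UBFC-rPPG→MMPD MAE improvement: printed −15.9%, recomputed −12.1%) and is
flagged as a documented discrepancy rather than matched; the corresponding
per-method MAE mean inherits the offset.

## Problem sizes and numerical choices

The end-to-end check trains the half-width configuration (stages
16/16/32/32/32/32, 36×36 input, 120-frame chunks) on 40 six-second clips
(32 train / 8 validation after the clip-level split) for the full 30 epochs
at batch 4, then scores 10 unseen clips.  These sizes are the package's
desk-scale study conditions; the full-width 72×72 configuration is the
shipped default for real use.  Degenerate inputs are handled explicitly:
constant videos standardize to zeros with a warning, constant labels
diff-normalize to zeros, constant waveforms raise on heart-rate estimation,
and a clip shorter than one chunk yields no chunks with a warning.
Saturated-pixel fractions are reported by the generator (<1% under
defaults; a warning above 50%).

## Known limitations

* The exact stage widths, pooling positions, head depth, optimizer and loss
  of the original network are not fully recoverable from its description;
  the choices above are documented defaults, all config-exposed.
* The static branch's chunk-mean input assumes appearance is stable within a
  chunk; fast pose changes violate this.
* Double-frame shifts discard two boundary frames per direction; very short
  chunks (T ≤ 2) turn those segments into zeros.
* The autodiff core implements exactly the operators this architecture
  needs; it is not a general-purpose framework.
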