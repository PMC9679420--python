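# Methods

`bspmaf` implements an end-to-end pipeline that predicts recurrence of atrial
fibrillation (AF) after ablation from 128-lead body-surface potential maps
(BSPMs): multichannel recordings are conditioned, rendered into 3D
isopotential sequence maps, and classified by a 3D convolutional network with
a temporal-attention block.  Because clinical BSPM datasets of AF patients
are not publicly available, the package ships a synthetic cohort generator
that emulates the statistical structure the pipeline assumes; every stage is
testable end to end without any download.

## Synthetic data

**Torso and vest.** The torso is a parametric elliptic cylinder (default
36 × 24 × 60 cm) with squashed spherical caps, exported/imported as Wavefront
OBJ.  The vest places 74 anterior and 54 posterior electrodes in vertical
columns with exactly 3.5 cm between same-column neighbours, plus a
three-electrode Wilson-central-terminal (WCT) reference triangle.  The
channel map is a fixed convention: labels 29/93/37 form a near-equilateral
chest triangle whose differences approximate Einthoven leads I
(left − right, ~0°) and III (lower-left − upper-left, ~120°), and labels
93, 112, 3, 5, 25, 36 lie along the default cardiac-axis direction so the
activation-sequence analysis has a canonical ordering.

**Forward model.** The ventricular complex is a traveling wavefront in a
uniform lead field: electrode *e* sees a Gaussian QRS-like deflection with
amplitude proportional to the projection of its displacement from the heart
centre onto the frontal-plane axis direction (angle α, 0° = patient's left,
+90° = down), arriving with delay = projection / 10 m s⁻¹.  We deliberately
do not sample a near-field point dipole for this component: at electrode
distances of ~15 cm the 1/r² warping makes the bipolar chest-lead geometry
inconsistent with the Einthoven construction (the recovered axis is biased
by tens of degrees) and the peak timing of a translating dipole is biphasic
and unstable.  The linear lead field is the simplest model that produces
both the sweeping isopotential wavefront and lead projections from which the
configured axis is recoverable (round-trip error ≲ 5°, asserted at ±10°).
The reference electrodes carry no ventricular pickup, emulating the
approximately-zero Wilson terminal.

AF-like recordings superimpose an irregular atrial oscillator: a rotating
current dipole in the atrial region (near-field p·r/|r|³ sampling), with
instantaneous frequency = dominant rate + band-limited jitter and ±20 %
amplitude modulation.  The two outcome classes differ in dominant atrial
rate, jitter bandwidth ("organization") and f-wave amplitude:

| class | rate (Hz) | jitter SD (Hz) | amplitude (mV) |
|---|---|---|---|
| non-recurrence | 4.5 | 0.3 | 0.25 |
| recurrence | 7.0 | 1.2 | 0.30 |

These defaults encode the association of higher dominant frequency and lower
atrial organization with post-ablation recurrence; they are the package's
study conditions, not fitted quantities.  Patient-level variability (heart
rate, axis angle ±3°, rate ±0.15 Hz, amplitude ±10 %, independent
sub-seeds derived from the master seed) makes inter-patient splits face real
between-subject differences.  What the generator does **not** emulate:
anatomically realistic heart–torso geometry, bidomain propagation, ectopy,
electrode motion artefacts, or any within-class overlap structure between
outcomes — so passing tests demonstrate that the pipeline extracts the
spatio-temporal structure it was designed for, not clinical performance.

## Preprocessing

Channels are referenced against the WCT (mean of the three reference
traces, then dropped), band-pass filtered at 1–40 Hz with a zero-phase
4th-order Butterworth (zero phase preserves the activation timing used by
the lead analyses), and cut into 2-s windows (0-based, half-open).  The
minority (recurrence) class is augmented with 175-sample-stride overlapping
windows, pooled and evenly subsampled so the class counts balance; the
minority never exceeds the majority count.  Baseline wander at a configurable
SNR (default 12 dB, measured over the whole recording) is synthesized as an
exactly band-limited (< 0.5 Hz) Fourier-domain process — filter-based
synthesis at a 10⁻³ normalized cutoff suffers edge transients.  Segments are
normalized by a global per-segment min–max map to [0, 1] over all channels
jointly; per-channel scaling would destroy the inter-channel topography that
the isopotential map encodes.  Constant segments map to 0.5.

## Isopotential sequence maps

Each time sample becomes a grayscale frame: the 74 anterior electrode values
are spread over a raster (default 64 × 64) by Shepard inverse-distance
weighting, f(q) = Σ dᵢ⁻ᵘ zᵢ / Σ dᵢ⁻ᵘ with u = 2; an exact hit returns the
electrode value; output is a convex combination of inputs, hence bounded.
The raster mask is the convex hull of the anterior electrode pixels dilated
by one pixel; electrodes are orthographically projected onto the frontal
plane (the posterior surface is ignored).  Grayscale intensity is the
normalized voltage itself — no colormap round-trip, since composing a color
scale with a luma conversion is neither invertible nor better for a CNN.
Stacking all L samples gives the H × W × T sequence (2-s window at 1 kHz →
K = 2000 frames at Δt = 1 ms).  Sequences are resized by bilinear spatial
resampling plus stride-averaged temporal subsampling (temporal upsampling is
refused); both operations preserve the [0, 1] range.

## Classifier

Input (N, 1, T, H, W), channels first.  Contracting path: five 3×3×3
convolutions (three of them stride 2), channel schedule c–2c–4c–8c–8c; batch
normalization then a rectifier after every convolution.  The fifth
convolution's output is fusion tap F1 and hosts the temporal-attention
block.  Expansive path: three 2×2×2 stride-2 up-convolutions, each halving
the channel count relative to its input and concatenating the matching
contracting map (U-Net skips); the concatenated maps are taps F2–F4.  The
taps are global-average-pooled, concatenated, passed through dropout
(rate 0.5) and three fully connected layers (Dense 256 → 32 → 2) with a
softmax — eight convolutional and three fully connected layers in total.
Exact kernel sizes and the pooling rule for the taps are not uniquely
determined by the architecture's published description; 3×3×3 kernels and
global average pooling are the package's choices.

**Temporal attention.** The deep feature map is squeezed to one channel by a
1×1×1 convolution; per-frame statistics are taken by spatial average and max
pooling, **mean-centered across frames**, passed through a shared bias-free
two-layer perceptron (hidden width T/r, r = 4, rectifier), summed, and a
sigmoid yields the gate M_T ∈ (0,1)^T that multiplies the input frame-wise.
Centering is a deliberate design choice: the gate then measures a frame's
salience *relative to the rest of the window*, and a time-constant input
receives the neutral uniform gate σ(0) = 0.5 for any weights — without
centering, a fully connected excitation cannot satisfy that symmetry.  The
gate multiplies the original C-channel map directly (squeeze-excitation
convention), so the block reduces exactly to frame-wise rescaling.  Variants:
A1 uses the max statistic only; A2/A3 replace the 1×1×1 squeeze by
concatenating per-channel statistics (max; average + max).  The hidden width
is max(1, ⌊T/r⌋) so tiny test shapes survive.

**Loss and optimization.** Focal loss on the recurrence probability,
−α(1−p)^γ log p for positives and −(1−α)p^γ log(1−p) for negatives, with
γ = 2, α = 0.25 (γ = 0, α = 0.5 reduces to half the binary cross-entropy);
probabilities are clamped to [10⁻⁷, 1−10⁻⁷].  Training uses Adam with
1/t decay (lr_t = lr₀/(1 + decay·t), defaults lr₀ = 10⁻³, decay = 10⁻⁴ —
the decay constant and epoch budget are free choices), mini-batches of 16,
and keeps the best-validation-accuracy checkpoint.  The whole network runs
on a small tape-based reverse-mode autodiff core over numpy (im2col turns
3D convolution into a matrix product; the up-convolution is expressed with
reshape/transpose/matmul), in float64, CPU-only.  All initialization,
shuffling and dropout are seed-driven, so training is bit-reproducible.

## Evaluation

Intra-patient: segments pooled, shuffled, split 7:2:1 (largest-remainder
rounding).  Inter-patient: patients partitioned into five folds
(sizes differing by at most one); the scarce recurrent patients are dealt
round-robin so no test fold holds more than one of them and every training
partition keeps at least one; validation segments are held out from the
training patients only.  Metrics: SE = TP/(TP+FN), SP = TN/(TN+FP),
PPV = TP/(TP+FP), ACC = (TP+TN)/(TP+TN+FP+FN), each ×100 %, with undefined
ratios reported as NaN plus a warning; AUC by the rank (Mann–Whitney)
formulation with midrank ties.  In a fold whose test patients are all
non-recurrent, SE/PPV/AUC are undefined; the cross-validation mean AUC
averages the folds where it exists.

## Scaled-down experiment sizes

The end-to-end experiments run at desk scale, chosen once: 14 patients
(4 recurrent) at 24 s each (12 two-second segments per patient before
augmentation), sequences rendered at 64 × 64 and resized to 16 × 16 × 32,
base channel width 4 (schedule 4–8–16–32, a quarter of the full-size
default 16–32–64–128), 12 training epochs.  At these sizes the full
inter-patient five-fold cross-validation plus the intra-patient split runs
in a few minutes on one CPU core.  These are scaled-down analogues of the
clinical study design; their accuracy figures characterize the synthetic
task only.

## Numerical notes and limitations

* IDW exact hits use a 10⁻¹² distance threshold; coincident electrodes with
  conflicting values raise an ambiguity error.
* Ties in activation arrival are broken by position in the reference-channel
  list; the per-beat delay is the largest pairwise arrival inversion against
  the canonical order, binned as {0, 1–3, >3 ms}.
* The QRS detector (|amplitude| ≥ 0.6 × median of 2-s block maxima, 250 ms
  refractory) is deliberately minimal; beats below threshold must be
  supplied explicitly to the amplitude-summing routine.
* Batch normalization precedes the activation; batches of size 1 are skipped
  during training.
* The axis formula atan2(U_I + 2·U_III, √3·U_I) assumes the Einthoven
  geometry; it is scale-invariant and undefined only at U_I = U_III = 0.
* The float64 CPU implementation favours clarity and exact reproducibility
  over speed; full-size inputs (64 × 64 × 400) are supported by the
  configuration but impractical to train here.
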